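"""Bayesian estimation of the compliance-type causal model.

Posterior simulation uses a Gibbs sampler with data augmentation.  Each
iteration cycles through

1. imputation of the latent compliance type for every intervention-arm
   subject, from its multinomial full conditional (type probabilities times
   the multivariate-normal likelihood of the subject's *observed* outcome
   coordinates);
2. imputation of missing outcome coordinates from their conditional normal
   given the observed coordinates, the current mean and covariance;
3. a joint draw of all mean coefficients (alpha, beta) from their Gaussian
   full conditional under independent zero-mean normal priors;
4. a draw of the unstructured covariance from its inverse-Wishart full
   conditional;
5. a Dirichlet draw of the compliance-type probabilities.

The mean structure is linear in the stacked coefficient vector on both the
visits and the days scale (on the days scale the piecewise-linear effect
contributes interpolation weights to the design row), so steps 3-4 are the
standard conjugate updates for a multivariate-normal regression.

Subjects sharing a design matrix (same arm, compliance type, and - on the
days scale - treatment day) are grouped, so the per-iteration cost is a
handful of small dense operations regardless of n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import logsumexp

from .data import TrialDataset
from .means import ModelParameters, beta_day_weights

__all__ = [
    "PriorSpec",
    "ChainConfig",
    "PosteriorChains",
    "compliance_posterior",
    "update_coefficients",
    "update_sigma",
    "impute_missing_outcomes",
    "update_gamma",
    "run_gibbs",
    "gelman_rubin",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration containers
# ---------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Priors for the Gibbs sampler.

    All mean coefficients (every ``alpha(c, j)`` and ``beta(k)``) get
    independent N(0, ``coef_prior_variance``) priors; the covariance gets an
    inverse Wishart with ``wishart_df`` degrees of freedom and scale matrix
    ``wishart_scale`` (parameterised so the prior mean is
    ``scale / (df - m - 1)``); the type probabilities get a Dirichlet prior.

    Defaults are diffuse: coefficient variance 1e6 on the outcome scale,
    ``df = m + 2`` (the smallest integer df with a finite prior mean) with
    identity scale, and a flat Dirichlet(1, ..., 1).
    """

    coef_prior_variance: float = 1e6
    wishart_df: int | None = None
    wishart_scale: np.ndarray | None = None
    gamma_prior: np.ndarray | None = None

    def resolve(self, m: int) -> "PriorSpec":
        """Fill dimension-dependent defaults for an m-visit outcome."""
        df = self.wishart_df if self.wishart_df is not None else m + 2
        scale = (np.eye(m) if self.wishart_scale is None
                 else np.asarray(self.wishart_scale, dtype=float))
        conc = (np.ones(m + 1) if self.gamma_prior is None
                else np.asarray(self.gamma_prior, dtype=float))
        if self.coef_prior_variance <= 0:
            raise ValueError("coef_prior_variance must be positive")
        if df < m:
            raise ValueError("wishart_df must be at least m")
        if scale.shape != (m, m):
            raise ValueError("wishart_scale must be m x m")
        if (conc <= 0).any() or conc.shape != (m + 1,):
            raise ValueError("gamma_prior must be m+1 positive concentrations")
        return PriorSpec(self.coef_prior_variance, df, scale, conc)


@dataclass
class ChainConfig:
    """Run-length, seeding and initial values for the sampler.

    Defaults mirror a long production run (100 000 iterations, 10 000
    burn-in, two chains started from deliberately different coefficient
    values); analyses in the test suite shorten these.
    """

    n_iterations: int = 100_000
    n_burnin: int = 10_000
    n_chains: int = 2
    thinning: int = 1
    seed: int | None = None
    # per-chain (alpha, beta) starting constants; cycled if fewer than n_chains
    initial_coefficients: tuple = ((20.0, -10.0), (10.0, -5.0))
    initial_type: int = 1

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iterations:
            raise ValueError("n_burnin must be smaller than n_iterations")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class PosteriorChains:
    """Stored draws from :func:`run_gibbs`, all iterations retained.

    Arrays are indexed ``[chain, iteration, ...]``; ``n_burnin`` marks how
    many leading iterations each summary should drop.  ``C_draws`` holds the
    imputed compliance type of every intervention-arm subject and
    ``missing_draws`` the imputed values of missing outcome cells (empty if
    the data are complete).
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    sigma: np.ndarray
    C_draws: np.ndarray
    missing_draws: np.ndarray
    n_burnin: int
    scale: str
    visit_days: np.ndarray
    treated_index: np.ndarray
    missing_index: tuple

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    @property
    def m(self) -> int:
        return self.beta.shape[-1]

    def kept(self, name: str) -> np.ndarray:
        """Post burn-in draws of one parameter block."""
        return getattr(self, name)[:, self.n_burnin:]

    def flat(self, name: str) -> np.ndarray:
        """Post burn-in draws pooled across chains."""
        arr = self.kept(name)
        return arr.reshape(-1, *arr.shape[2:])

    def posterior_mean_params(self) -> ModelParameters:
        return ModelParameters(
            alpha=self.flat("alpha").mean(axis=0),
            beta=self.flat("beta").mean(axis=0),
            gamma=self.flat("gamma").mean(axis=0),
            sigma=self.flat("sigma").mean(axis=0),
            scale=self.scale,
            visit_days=self.visit_days,
        )

    def scalar_draws(self) -> dict:
        """Every scalar parameter as a (n_chains, n_kept) array, keyed by label."""
        out = {}
        m = self.m
        for c in range(m + 1):
            for j in range(m):
                out[f"alpha[{c},{j + 1}]"] = self.kept("alpha")[:, :, c, j]
        for k in range(m):
            out[f"beta[{k + 1}]"] = self.kept("beta")[:, :, k]
        for c in range(m + 1):
            out[f"gamma[{c}]"] = self.kept("gamma")[:, :, c]
        for a in range(m):
            for b in range(a, m):
                out[f"sigma[{a + 1},{b + 1}]"] = self.kept("sigma")[:, :, a, b]
        return out


# ---------------------------------------------------------------------------
# elementary conditional draws (exposed for direct use and testing)
# ---------------------------------------------------------------------------

def compliance_posterior(y, r, d, params: ModelParameters,
                         visit_days=None) -> np.ndarray:
    """Full-conditional type probabilities for one subject.

    Controls reveal their type, so the distribution is a point mass at the
    observed departure ``d``.  For an intervention subject the posterior is
    proportional to ``gamma(c)`` times the multivariate-normal density of
    the observed outcome coordinates under the type-``c`` mean; computed in
    log space and renormalised, so it never returns NaN.
    """
    m = params.m
    if r == 0:
        out = np.zeros(m + 1)
        out[int(d)] = 1.0
        return out
    y = np.asarray(y, dtype=float)
    obs = ~np.isnan(y)
    if not obs.any():
        # no outcome information: prior weights only
        return params.gamma / params.gamma.sum()
    S = params.sigma[np.ix_(obs, obs)]
    L = np.linalg.cholesky(S)
    logp = np.empty(m + 1)
    for c in range(m + 1):
        # intervention arm: treated at baseline, mean alpha(c, j) + beta(j)
        mu = params.alpha[c] + params.beta
        z = solve_triangular(L, y[obs] - mu[obs], lower=True)
        with np.errstate(divide="ignore"):
            logp[c] = np.log(params.gamma[c]) - 0.5 * z @ z
    logp -= logsumexp(logp)
    p = np.exp(logp)
    return p / p.sum()


def update_coefficients(dataset: TrialDataset, C, Sigma, prior: PriorSpec, rng,
                        Y=None, scale: str = "visits", return_moments: bool = False):
    """Draw (alpha, beta) from their joint Gaussian full conditional.

    Requires complete compliance types ``C`` and complete outcomes (pass the
    imputed matrix as ``Y`` when the dataset has missing cells).  With the
    covariance known and independent normal priors on every coefficient this
    is an exact conjugate draw; as the prior variance grows the conditional
    mean tends to the generalised-least-squares estimate.

    Types absent from the augmented data leave their ``alpha(c, .)`` block
    supported by the prior alone (logged once per call site).
    """
    ws = _Workspace(dataset, scale)
    Y = dataset.outcomes if Y is None else np.asarray(Y, dtype=float)
    if np.isnan(Y).any():
        raise ValueError("outcomes must be complete; impute missing cells first")
    prior = prior.resolve(dataset.m)
    counts, sums, g_idx = ws.group_stats(np.asarray(C, dtype=int), Y)
    present = np.zeros(dataset.m + 1, dtype=bool)
    present[np.asarray(C, dtype=int)] = True
    if not present.all():
        logger.warning("compliance types %s absent from augmented data; their "
                       "alpha coefficients follow the prior",
                       list(np.flatnonzero(~present)))
    mean, chol_prec = _coef_conditional(ws, counts, sums, Sigma, prior)
    theta = mean + solve_triangular(chol_prec, rng.standard_normal(ws.p),
                                    lower=True, trans="T")
    if return_moments:
        return ws.unpack(theta), (ws.unpack(mean), chol_prec)
    return ws.unpack(theta)


def update_sigma(residuals, prior: PriorSpec, rng) -> np.ndarray:
    """Inverse-Wishart draw of the covariance given complete residuals.

    Posterior df is prior df plus n, posterior scale is the prior scale plus
    the residual cross-product; for large n the conditional mean approaches
    the empirical residual covariance.
    """
    residuals = np.atleast_2d(np.asarray(residuals, dtype=float))
    n, m = residuals.shape if residuals.size else (0, residuals.shape[1])
    prior = prior.resolve(m)
    scale = prior.wishart_scale + residuals.T @ residuals
    return _invwishart(prior.wishart_df + n, scale, rng)


def _invwishart(df: float, scale: np.ndarray, rng) -> np.ndarray:
    """Bartlett-decomposition inverse-Wishart draw (mean = scale/(df-m-1))."""
    m = scale.shape[0]
    # W = Sigma^{-1} ~ Wishart(df, scale^{-1}); draw via W^{1/2} = L_V A
    L_scale = np.linalg.cholesky(scale)
    A = np.zeros((m, m))
    idx = np.tril_indices(m, -1)
    A[idx] = rng.standard_normal(len(idx[0]))
    A[np.diag_indices(m)] = np.sqrt(rng.chisquare(df - np.arange(m)))
    # chol(V) = inv(L_scale)^T since V = scale^{-1}
    LA = solve_triangular(L_scale, A, lower=True, trans="T", check_finite=False)
    W = LA @ LA.T
    Winv = np.linalg.inv(W)
    return 0.5 * (Winv + Winv.T)


def impute_missing_outcomes(y_partial, mu, Sigma, rng) -> np.ndarray:
    """Complete one outcome vector by conditional-normal draws.

    Missing coordinates are drawn from their normal distribution conditional
    on the observed ones under the current mean and covariance; observed
    coordinates pass through untouched.  A fully missing vector is drawn
    from the unconditional normal.
    """
    y = np.asarray(y_partial, dtype=float).copy()
    mu = np.asarray(mu, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    mis = np.isnan(y)
    if not mis.any():
        return y
    if mis.all():
        L = np.linalg.cholesky(Sigma)
        return mu + L @ rng.standard_normal(len(y))
    obs = ~mis
    Soo = Sigma[np.ix_(obs, obs)]
    Smo = Sigma[np.ix_(mis, obs)]
    Smm = Sigma[np.ix_(mis, mis)]
    K = Smo @ np.linalg.inv(Soo)
    cond_mean = mu[mis] + K @ (y[obs] - mu[obs])
    cond_cov = Smm - K @ Smo.T
    L = np.linalg.cholesky(0.5 * (cond_cov + cond_cov.T))
    y[mis] = cond_mean + L @ rng.standard_normal(mis.sum())
    return y


def update_gamma(C, prior: PriorSpec, rng, m: int | None = None) -> np.ndarray:
    """Dirichlet draw of the type probabilities given complete types."""
    C = np.asarray(C, dtype=int)
    if m is None:
        m = int(C.max()) if C.size else 0
    prior = prior.resolve(m)
    counts = np.bincount(C, minlength=m + 1)
    return rng.dirichlet(prior.gamma_prior + counts)


# ---------------------------------------------------------------------------
# design bookkeeping
# ---------------------------------------------------------------------------

class _Workspace:
    """Precomputed design matrices for one dataset and elapsed-time scale.

    Subjects are grouped by design signature: intervention subjects by
    (hypothetical) compliance type, controls by their fixed (type, treatment
    day) pair.  ``group_stats`` turns a current type assignment into group
    counts and outcome sums, from which all conjugate updates follow.
    """

    def __init__(self, dataset: TrialDataset, scale: str = "visits"):
        if scale not in ("visits", "days"):
            raise ValueError("scale must be 'visits' or 'days'")
        m = dataset.m
        self.m = m
        self.n = dataset.n
        self.p = (m + 1) * m + m
        self.scale = scale
        self.grid = np.asarray(dataset.visit_days, dtype=float)
        self.treated = np.flatnonzero(dataset.arm == 1)
        self.control = np.flatnonzero(dataset.arm == 0)

        # intervention-arm designs, one per hypothetical type: treated at day
        # 0, so visit j carries exactly beta(j) on either scale
        self.X_treated = np.stack([self._design(c, effective_day=0.0)
                                   for c in range(m + 1)])

        # control designs: fixed per subject; group identical ones
        t0 = np.concatenate([[0.0], self.grid])
        sig_map: dict = {}
        self.control_group = np.empty(len(self.control), dtype=int)
        X_control = []
        for pos, i in enumerate(self.control):
            c = int(dataset.departure[i])
            if c == m:
                day = np.inf
            else:
                T = dataset.treatment_day[i]
                # unrecorded exact day: treatment "just after visit c"
                day = float(T) if np.isfinite(T) else float(t0[c])
            key = (c, day)
            if key not in sig_map:
                sig_map[key] = len(X_control)
                X_control.append(self._design(c, effective_day=day, arm=0))
            self.control_group[pos] = sig_map[key]
        self.X_control = (np.stack(X_control) if X_control
                          else np.empty((0, m, self.p)))
        self.n_control_groups = len(X_control)
        # all group designs stacked: controls first, then treated-by-type
        self.X_all = np.concatenate([self.X_control, self.X_treated])
        self.G = self.X_all.shape[0]
        # fixed part of per-subject group index
        self.subject_group = np.empty(self.n, dtype=int)
        self.subject_group[self.control] = self.control_group

    def _design(self, c: int, effective_day: float, arm: int = 1) -> np.ndarray:
        """m x p design for type ``c`` treated at ``effective_day`` (inf = never)."""
        m, p = self.m, self.p
        X = np.zeros((m, p))
        for j in range(1, m + 1):
            X[j - 1, c * m + (j - 1)] = 1.0
            if arm == 1:
                X[j - 1, (m + 1) * m + (j - 1)] = 1.0
            elif np.isfinite(effective_day):
                if self.scale == "visits":
                    k = j - c  # visits since treatment
                    if k >= 1:
                        X[j - 1, (m + 1) * m + (k - 1)] = 1.0
                else:
                    u = self.grid[j - 1] - effective_day
                    X[j - 1, (m + 1) * m:] = beta_day_weights(self.grid, u)
        return X

    def pack(self, alpha, beta) -> np.ndarray:
        return np.concatenate([np.asarray(alpha, float).ravel(),
                               np.asarray(beta, float).ravel()])

    def unpack(self, theta) -> tuple:
        m = self.m
        return theta[:(m + 1) * m].reshape(m + 1, m).copy(), theta[(m + 1) * m:].copy()

    def group_index(self, C_treated) -> np.ndarray:
        g = self.subject_group.copy()
        g[self.treated] = self.n_control_groups + np.asarray(C_treated, int)
        return g

    def group_stats(self, C, Y) -> tuple:
        """Counts and outcome sums per design group for a full type vector C."""
        g = self.group_index(np.asarray(C, int)[self.treated])
        counts = np.bincount(g, minlength=self.G).astype(float)
        sums = np.column_stack([np.bincount(g, weights=Y[:, j], minlength=self.G)
                                for j in range(self.m)])
        return counts, sums, g


def _coef_conditional(ws: _Workspace, counts, sums, Sigma, prior: PriorSpec,
                      Sinv=None):
    """Mean and Cholesky precision of the Gaussian coefficient conditional."""
    if Sinv is None:
        Sinv = cho_solve((np.linalg.cholesky(Sigma), True), np.eye(ws.m))
    # A = sum_g n_g X_g' Sinv X_g and b = sum_g X_g' Sinv s_g, as two GEMMs
    SX = np.matmul(Sinv, ws.X_all)  # (G, m, p)
    Xw = ws.X_all * counts[:, None, None]
    flat = (ws.G * ws.m, ws.p)
    A = Xw.reshape(flat).T @ SX.reshape(flat)
    b = SX.reshape(flat).T @ sums.reshape(-1)
    P = A + np.eye(ws.p) / prior.coef_prior_variance
    L = np.linalg.cholesky(P)
    mean = cho_solve((L, True), b)
    return mean, L


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

def run_gibbs(dataset: TrialDataset, model: str = "visits",
              prior: PriorSpec | None = None,
              config: ChainConfig | None = None) -> PosteriorChains:
    """Run the data-augmentation Gibbs sampler.

    Per iteration and chain: impute latent types for the intervention arm,
    impute missing outcome cells, then conjugate draws of the coefficients,
    the covariance and the type probabilities.  Chains are a pure function
    of (dataset, prior, config, seed): identical seeds give bit-identical
    chains.
    """
    prior = (prior or PriorSpec()).resolve(dataset.m)
    config = config or ChainConfig()
    m, n = dataset.m, dataset.n
    ws = _Workspace(dataset, model)
    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(config.n_chains)

    n_it = config.n_iterations
    treated = ws.treated
    mis_mask = dataset.missing_mask
    mis_rows = np.flatnonzero(mis_mask.any(axis=1))
    mis_index = tuple(np.nonzero(mis_mask))
    patterns = _missing_patterns(mis_mask)
    treated_patterns = _row_patterns(mis_mask[treated])

    out = dict(
        alpha=np.empty((config.n_chains, n_it, m + 1, m)),
        beta=np.empty((config.n_chains, n_it, m)),
        gamma=np.empty((config.n_chains, n_it, m + 1)),
        sigma=np.empty((config.n_chains, n_it, m, m)),
        C_draws=np.empty((config.n_chains, n_it, len(treated)), dtype=np.int16),
        missing_draws=np.empty((config.n_chains, n_it, len(mis_index[0]))),
    )

    inits = config.initial_coefficients
    for chain in range(config.n_chains):
        rng = np.random.default_rng(child_seeds[chain])
        a0, b0 = inits[chain % len(inits)]
        alpha = np.full((m + 1, m), float(a0))
        beta = np.full(m, float(b0))
        gamma = np.full(m + 1, 1.0 / (m + 1))
        obs_var = np.nanvar(dataset.outcomes, axis=0)
        Sigma = np.diag(np.where(obs_var > 0, obs_var, 1.0))
        C = dataset.departure.copy()
        C[treated] = min(config.initial_type, m)
        Ycur = dataset.outcomes.copy()

        for it in range(n_it):
            theta = ws.pack(alpha, beta)
            MuG = ws.X_all @ theta  # per-group mean vectors, (G, m)
            Mu_treat = MuG[ws.n_control_groups:]  # type-specific treated means

            # 1. impute latent types from observed coordinates
            C[treated] = _draw_types(dataset.outcomes[treated], Mu_treat, Sigma,
                                     gamma, rng, patterns=treated_patterns)

            # 2. impute missing outcome cells
            if mis_rows.size:
                g = ws.group_index(C[treated])
                Mu_all = MuG[g]
                _impute_block(Ycur, dataset.outcomes, Mu_all, Sigma, patterns, rng)

            # 3. coefficients
            counts, sums, g = ws.group_stats(C, Ycur)
            mean, Lp = _coef_conditional(ws, counts, sums, Sigma, prior)
            theta = mean + solve_triangular(Lp, rng.standard_normal(ws.p),
                                            lower=True, trans="T")
            alpha, beta = ws.unpack(theta)

            # 4. covariance
            MuG = ws.X_all @ theta
            resid = Ycur - MuG[g]
            Sigma = _invwishart(prior.wishart_df + n,
                                prior.wishart_scale + resid.T @ resid, rng)

            # 5. type probabilities
            gamma = rng.dirichlet(prior.gamma_prior + np.bincount(C, minlength=m + 1))

            if not (np.isfinite(theta).all() and np.isfinite(Sigma).all()
                    and np.isfinite(gamma).all()):
                bad = "sigma" if not np.isfinite(Sigma).all() else (
                    "gamma" if not np.isfinite(gamma).all() else "coefficients")
                raise FloatingPointError(
                    f"non-finite draw of {bad} at iteration {it} (chain {chain})")

            out["alpha"][chain, it] = alpha
            out["beta"][chain, it] = beta
            out["gamma"][chain, it] = gamma
            out["sigma"][chain, it] = Sigma
            out["C_draws"][chain, it] = C[treated]
            if mis_rows.size:
                out["missing_draws"][chain, it] = Ycur[mis_index]

    return PosteriorChains(n_burnin=config.n_burnin, scale=model,
                           visit_days=ws.grid, treated_index=treated,
                           missing_index=mis_index, **out)


def _missing_patterns(mask: np.ndarray):
    """Group row indices by missingness pattern (rows with any missing cell)."""
    patterns = []
    if not mask.any():
        return patterns
    rows = np.flatnonzero(mask.any(axis=1))
    keys = {}
    for i in rows:
        key = mask[i].tobytes()
        keys.setdefault(key, []).append(i)
    for key, idx in keys.items():
        pat = np.frombuffer(key, dtype=bool)
        patterns.append((pat, np.asarray(idx)))
    return patterns


def _impute_block(Ycur, Yobs, Mu, Sigma, patterns, rng) -> None:
    """Vectorised conditional-normal imputation, one pattern at a time."""
    for pat, idx in patterns:
        mis = pat
        obs = ~pat
        mu = Mu[idx]
        if not obs.any():
            L = np.linalg.cholesky(Sigma)
            Ycur[idx] = mu + rng.standard_normal((len(idx), len(pat))) @ L.T
            continue
        Soo = Sigma[np.ix_(obs, obs)]
        Smo = Sigma[np.ix_(mis, obs)]
        K = Smo @ np.linalg.inv(Soo)
        cond_cov = Sigma[np.ix_(mis, mis)] - K @ Smo.T
        L = np.linalg.cholesky(0.5 * (cond_cov + cond_cov.T))
        resid_obs = Yobs[idx][:, obs] - mu[:, obs]
        draws = (mu[:, mis] + resid_obs @ K.T
                 + rng.standard_normal((len(idx), mis.sum())) @ L.T)
        block = Ycur[idx]
        block[:, obs] = Yobs[idx][:, obs]
        block[:, mis] = draws
        Ycur[idx] = block


def _draw_types(Y_treated, Mu_treat, Sigma, gamma, rng,
                patterns=None) -> np.ndarray:
    """Multinomial type draw for all intervention subjects at once.

    Uses the marginal normal density over each subject's observed
    coordinates; the shared covariance makes its normalising constant
    cancel across types, leaving only quadratic forms.  Subjects are
    processed per missingness pattern so complete data reduce to one
    batched computation.
    """
    n1, m = Y_treated.shape
    n_types = m + 1
    C_new = np.empty(n1, dtype=int)
    with np.errstate(divide="ignore"):
        log_gamma = np.log(gamma)
    if patterns is None:
        patterns = _row_patterns(np.isnan(Y_treated))
    for pat, idx in patterns:
        obs = ~pat
        if not obs.any():
            logp = np.broadcast_to(log_gamma, (len(idx), n_types)).copy()
        else:
            Sinv_oo = np.linalg.inv(Sigma[np.ix_(obs, obs)])
            # delta[c, i, a] = y_ia - mu_ca over observed coords
            delta = Y_treated[np.ix_(idx, np.flatnonzero(obs))][None, :, :] \
                - Mu_treat[:, obs][:, None, :]
            quad = ((delta @ Sinv_oo) * delta).sum(axis=2)  # (n_types, n_idx)
            logp = log_gamma[None, :] - 0.5 * quad.T
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        p /= p.sum(axis=1, keepdims=True)
        u = rng.random(len(idx))
        C_new[idx] = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return C_new


def _row_patterns(mask: np.ndarray):
    """(pattern, row-index array) pairs covering every row of ``mask``."""
    if not mask.any():
        return [(np.zeros(mask.shape[1], dtype=bool), np.arange(len(mask)))]
    keys: dict = {}
    for i in range(len(mask)):
        keys.setdefault(mask[i].tobytes(), []).append(i)
    return [(np.frombuffer(k, dtype=bool), np.asarray(v))
            for k, v in keys.items()]


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def gelman_rubin(chains) -> float | dict:
    """Potential scale reduction factor.

    Accepts a (n_chains, n_draws) array for one scalar parameter, or a dict
    of such arrays (e.g. :meth:`PosteriorChains.scalar_draws`), returning a
    float or a dict of floats.  Degenerate chains with zero within-chain
    variance but distinct values give ``inf``.
    """
    if isinstance(chains, dict):
        return {k: gelman_rubin(v) for k, v in chains.items()}
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need draws from at least two chains")
    n_draws = chains.shape[1]
    W = chains.var(axis=1, ddof=1).mean()
    B_over_n = chains.mean(axis=1).var(ddof=1)
    if W == 0:
        return 1.0 if B_over_n == 0 else float("inf")
    V = (n_draws - 1) / n_draws * W + B_over_n
    return float(np.sqrt(V / W))
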
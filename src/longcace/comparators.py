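"""Comparator estimators: the ITT arm-means model and 2SLS IV.

* :func:`fit_itt` — maximum likelihood for the multivariate-normal
  arm-means model with unstructured covariance, handling missing outcome
  coordinates by EM under MAR.  With complete data the estimates reduce to
  the per-visit arm mean differences.
* :func:`fit_iv_2sls` — pooled two-stage least squares on person-visit
  rows: outcome on indicators of being treated exactly ``k`` visits ago
  (endogenous), instrumented by arm-by-visit interactions, with visit fixed
  effects; standard errors are cluster-robust by subject.  The coefficient
  on the ``k``-visits-ago indicator estimates the same elapsed-time causal
  effect ``beta(k)`` the model-based estimators target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import TrialDataset
from .means import ITTParameters

__all__ = ["fit_itt", "fit_iv_2sls", "ITTFit", "IVFit", "long_format"]


@dataclass
class ITTFit:
    params: ITTParameters
    delta_se: np.ndarray
    conf_int: np.ndarray  # (m, 2)
    n_iterations: int
    loglike: float


@dataclass
class IVFit:
    beta: np.ndarray
    bse: np.ndarray
    conf_int: np.ndarray
    visit_effects: np.ndarray
    n_obs: int


# ---------------------------------------------------------------------------
# ITT model: MVN arm means with EM over missing coordinates
# ---------------------------------------------------------------------------

def _em_mvn_two_group(Y, group, tol=1e-8, max_iter=10_000):
    """ML means-by-group and pooled covariance of an MVN with MAR missing."""
    n, m = Y.shape
    mu = np.vstack([np.nanmean(Y[group == g], axis=0) for g in (0, 1)])
    mu = np.nan_to_num(mu)
    import pandas as pd

    S0 = pd.DataFrame(Y).cov(min_periods=2).to_numpy()
    S0 = np.nan_to_num(S0)
    Sigma = S0 + 1e-6 * np.eye(m)
    if not np.all(np.linalg.eigvalsh(Sigma) > 0):
        Sigma = np.diag(np.clip(np.diag(S0), 1e-3, None))
    mask = np.isnan(Y)
    patterns = {}
    for i in range(n):
        patterns.setdefault((mask[i].tobytes(), group[i]), []).append(i)

    last_ll = -np.inf
    for it in range(1, max_iter + 1):
        EY = Y.copy()
        EYY = np.zeros((m, m))  # accumulated conditional covariance correction
        ll = 0.0
        for (key, g), idx in patterns.items():
            pat = np.frombuffer(key, dtype=bool)
            obs = ~pat
            idx = np.asarray(idx)
            mug = mu[g]
            if pat.all():
                EY[idx] = mug
                EYY += len(idx) * Sigma
                continue
            Soo = Sigma[np.ix_(obs, obs)]
            L = np.linalg.cholesky(Soo)
            resid = Y[idx][:, obs] - mug[obs]
            Z = np.linalg.solve(L, resid.T)
            ll += (-0.5 * (Z ** 2).sum()
                   - len(idx) * (np.log(np.diag(L)).sum()
                                 + 0.5 * obs.sum() * np.log(2 * np.pi)))
            if pat.any():
                K = np.linalg.solve(Soo, Sigma[np.ix_(obs, pat)]).T
                cond = mug[pat] + resid @ K.T
                block = EY[idx]
                block[:, pat] = cond
                EY[idx] = block
                Cmm = Sigma[np.ix_(pat, pat)] - K @ Sigma[np.ix_(obs, pat)]
                corr = np.zeros((m, m))
                corr[np.ix_(pat, pat)] = Cmm
                EYY += len(idx) * corr
        new_mu = np.vstack([EY[group == g].mean(axis=0) for g in (0, 1)])
        resid_full = EY - new_mu[group]
        new_Sigma = (resid_full.T @ resid_full + EYY) / n
        mu, Sigma = new_mu, new_Sigma
        if it > 1 and abs(ll - last_ll) <= tol * (abs(last_ll) + 1.0):
            return mu, Sigma, it, ll
        last_ll = ll
    raise RuntimeError(
        f"EM for the ITT model did not converge in {max_iter} iterations "
        f"(last log-likelihood change {ll - last_ll:.3e})")


def fit_itt(dataset: TrialDataset, alpha_level: float = 0.05) -> ITTFit:
    """ML fit of the arm-means model with unstructured covariance.

    The per-visit randomisation effect is the difference of fitted arm
    means; its standard error uses the observed-coordinate generalised
    least squares information at the ML covariance.
    """
    if not ((dataset.arm == 0).any() and (dataset.arm == 1).any()):
        raise ValueError("both randomised arms must be present")
    Y = dataset.outcomes
    m = dataset.m
    mu, Sigma, n_iter, ll = _em_mvn_two_group(Y, dataset.arm)
    delta = mu[1] - mu[0]

    # information for each arm mean from observed-coordinate GLS
    info = [np.zeros((m, m)), np.zeros((m, m))]
    mask = np.isnan(Y)
    for i in range(dataset.n):
        obs = ~mask[i]
        if not obs.any():
            continue
        Soo = Sigma[np.ix_(obs, obs)]
        Ii = np.zeros((m, m))
        Ii[np.ix_(obs, obs)] = np.linalg.inv(Soo)
        info[dataset.arm[i]] += Ii
    cov_delta = np.linalg.pinv(info[0]) + np.linalg.pinv(info[1])
    se = np.sqrt(np.diag(cov_delta))
    z = stats.norm.ppf(1 - alpha_level / 2)
    ci = np.column_stack([delta - z * se, delta + z * se])
    params = ITTParameters(control_mean=mu[0], delta=delta, sigma_itt=Sigma)
    return ITTFit(params=params, delta_se=se, conf_int=ci,
                  n_iterations=n_iter, loglike=ll)


# ---------------------------------------------------------------------------
# pooled 2SLS
# ---------------------------------------------------------------------------

def long_format(dataset: TrialDataset) -> dict:
    """Person-visit expansion (available-case rows only).

    Returns the pieces of the 2SLS regression: outcome ``y``; endogenous
    indicators ``E[:, k-1] = 1`` if the subject was treated exactly ``k``
    visits before this visit; visit dummies; arm-by-visit instrument
    columns; and the subject id of each row for clustering.
    """
    m = dataset.m
    rows_i, rows_j = np.nonzero(~dataset.missing_mask)
    y = dataset.outcomes[rows_i, rows_j]
    visit = rows_j + 1
    arm = dataset.arm[rows_i]
    dep = dataset.departure[rows_i]
    # visits since treatment at this visit (0 = untreated so far)
    k = np.where(arm == 1, visit, np.where(dep < visit, visit - dep, 0))
    E = np.zeros((len(y), m))
    treated_rows = k >= 1
    E[treated_rows, k[treated_rows] - 1] = 1.0
    V = np.zeros((len(y), m))
    V[np.arange(len(y)), visit - 1] = 1.0
    Zinstr = V * (arm == 1)[:, None]
    return {"y": y, "endog": E, "visit_dummies": V, "instruments": Zinstr,
            "subject": rows_i, "visit": visit}


def fit_iv_2sls(dataset: TrialDataset, alpha_level: float = 0.05) -> IVFit:
    """Pooled 2SLS of outcome on elapsed-treatment indicators.

    Just-identified: m endogenous indicators instrumented by the m
    arm-by-visit interactions, plus m visit fixed effects as included
    exogenous columns.  SEs are cluster-robust by subject.
    """
    parts = long_format(dataset)
    y = parts["y"]
    X = np.column_stack([parts["endog"], parts["visit_dummies"]])
    Z = np.column_stack([parts["instruments"], parts["visit_dummies"]])
    m = dataset.m
    ZtZ = Z.T @ Z
    if np.linalg.matrix_rank(ZtZ) < Z.shape[1]:
        raise ValueError("rank-deficient instrument matrix: some arm-by-visit "
                         "cell has no observed rows")
    ZtX = Z.T @ X
    if np.linalg.matrix_rank(ZtX) < X.shape[1]:
        raise ValueError("rank-deficient first stage: an elapsed-treatment "
                         "indicator is collinear with the instruments")
    # 2SLS: coef = (X' P_Z X)^{-1} X' P_Z y
    W = np.linalg.solve(ZtZ, np.column_stack([ZtX, Z.T @ y]))
    XPX = ZtX.T @ W[:, :-1]
    XPy = ZtX.T @ W[:, -1]
    coef = np.linalg.solve(XPX, XPy)

    # cluster-robust sandwich by subject on the IV moment conditions
    Xhat = Z @ W[:, :-1]
    u = y - X @ coef
    bread = np.linalg.inv(Xhat.T @ X)
    clusters = parts["subject"]
    order = np.argsort(clusters, kind="stable")
    cl = clusters[order]
    G = Xhat[order] * u[order, None]
    cuts = np.flatnonzero(np.diff(cl)) + 1
    sums = np.add.reduceat(G, np.concatenate([[0], cuts]), axis=0)
    meat = sums.T @ sums
    cov = bread @ meat @ bread.T
    bse = np.sqrt(np.diag(cov))

    zval = stats.norm.ppf(1 - alpha_level / 2)
    ci = np.column_stack([coef[:m] - zval * bse[:m], coef[:m] + zval * bse[:m]])
    return IVFit(beta=coef[:m], bse=bse[:m], conf_int=ci,
                 visit_effects=coef[m:], n_obs=len(y))
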
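"""Causal mean structures for the longitudinal compliance-type model.

Three mean models for the outcome at post-randomisation visit ``j``:

* the ITT model — arm means only, no compliance structure;
* the *visits* causal model — the treatment effect depends on the number of
  whole visits elapsed since treatment, ``beta(k)``;
* the *days* causal model — the effect depends on the actual number of days
  since treatment, piecewise linear between the scheduled visit days with
  ``beta(k)`` attained at ``t_k`` days.

All three are pure functions of parameter containers defined here.  The
exclusion restriction is built in: within a compliance type the untreated
mean ``alpha(c, j)`` does not depend on randomised arm, and arm enters the
mean only through the elapsed-time effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelParameters",
    "ITTParameters",
    "mean_visits",
    "beta_at_days",
    "beta_day_weights",
    "mean_days",
    "mean_itt",
]


def _check_spd(S: np.ndarray, name: str) -> None:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError(f"{name} must be symmetric")
    try:
        np.linalg.cholesky(S)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"{name} must be positive definite") from err


@dataclass
class ModelParameters:
    """Parameters of the compliance-type causal model.

    Attributes
    ----------
    alpha : (m+1, m) array
        ``alpha[c, j-1]`` — mean untreated outcome for compliance type ``c``
        at visit ``j`` (outcome units, e.g. dB hearing loss).
    beta : (m,) array
        ``beta[k-1]`` — causal effect of treatment ``k`` visits (or ``t_k``
        days, per ``scale``) after receiving it.
    gamma : (m+1,) array
        Compliance-type probabilities, a point on the simplex (saturated
        categorical model for the latent type).
    sigma : (m, m) array
        Unstructured covariance of the visit-level errors.
    scale : {"visits", "days"}
        Which elapsed-time scale ``beta`` lives on.
    visit_days : (m,) array, optional
        Scheduled visit days; required for the days scale.
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    sigma: np.ndarray
    scale: str = "visits"
    visit_days: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        m = self.alpha.shape[1]
        if self.alpha.shape != (m + 1, m):
            raise ValueError("alpha must be (m+1) x m")
        if self.beta.shape != (m,):
            raise ValueError("beta must have length m")
        if self.gamma.shape != (m + 1,):
            raise ValueError("gamma must have length m+1")
        if (self.gamma < -1e-12).any() or abs(self.gamma.sum() - 1.0) > 1e-8:
            raise ValueError("gamma must be nonnegative and sum to 1")
        _check_spd(self.sigma, "sigma")
        if self.scale not in ("visits", "days"):
            raise ValueError("scale must be 'visits' or 'days'")
        if self.scale == "days":
            if self.visit_days is None:
                raise ValueError("days scale requires visit_days")
            self.visit_days = np.asarray(self.visit_days, dtype=float)

    @property
    def m(self) -> int:
        return self.alpha.shape[1]

    def to_dict(self) -> dict:
        d = {"alpha": self.alpha.tolist(), "beta": self.beta.tolist(),
             "gamma": self.gamma.tolist(), "sigma": self.sigma.tolist(),
             "scale": self.scale}
        if self.visit_days is not None:
            d["visit_days"] = np.asarray(self.visit_days).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**{k: v for k, v in d.items()})


@dataclass
class ITTParameters:
    """Arm-means model: control mean and per-visit randomisation effect."""

    control_mean: np.ndarray
    delta: np.ndarray
    sigma_itt: np.ndarray

    def __post_init__(self) -> None:
        self.control_mean = np.asarray(self.control_mean, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.sigma_itt = np.asarray(self.sigma_itt, dtype=float)
        m = len(self.control_mean)
        if self.delta.shape != (m,):
            raise ValueError("delta must match control_mean in length")
        _check_spd(self.sigma_itt, "sigma_itt")

    @property
    def m(self) -> int:
        return len(self.control_mean)


def mean_visits(params: ModelParameters, c: int, r: int, j: int) -> float:
    """Expected outcome at visit ``j`` on the visits scale.

    Intervention subjects (treated just after baseline) carry the effect of
    ``j`` elapsed visits; controls of type ``c`` are untreated through visit
    ``c`` and carry ``beta(j - c)`` afterwards.
    """
    m = params.m
    if not (1 <= j <= m):
        raise IndexError(f"visit j={j} outside 1..{m}")
    if not (0 <= c <= m):
        raise IndexError(f"compliance type c={c} outside 0..{m}")
    mu = params.alpha[c, j - 1]
    if r == 1:
        mu += params.beta[j - 1]
    elif c < j:
        mu += params.beta[j - c - 1]
    return float(mu)


def beta_at_days(beta, visit_days, u) -> float:
    """Treatment effect ``u`` days after treatment, piecewise linear.

    Anchored at zero effect for ``u <= 0``, attains ``beta(k)`` at ``t_k``,
    interpolates linearly between grid days, and is held at ``beta(m)``
    beyond the last scheduled visit.
    """
    beta = np.asarray(beta, dtype=float)
    visit_days = np.asarray(visit_days, dtype=float)
    xp = np.concatenate([[0.0], visit_days])
    fp = np.concatenate([[0.0], beta])
    if np.ndim(u) == 0 and u <= 0:
        return 0.0
    return float(np.interp(u, xp, fp))


def beta_day_weights(visit_days, u) -> np.ndarray:
    """Interpolation weights ``w`` with ``beta_at_days(beta, grid, u) = w @ beta``.

    Used to build linear design rows for the days-scale model.
    """
    visit_days = np.asarray(visit_days, dtype=float)
    m = len(visit_days)
    w = np.zeros(m)
    if u <= 0:
        return w
    if u >= visit_days[-1]:
        w[-1] = 1.0
        return w
    grid = np.concatenate([[0.0], visit_days])
    k = int(np.searchsorted(grid, u, side="right")) - 1  # u in [grid[k], grid[k+1])
    frac = (u - grid[k]) / (grid[k + 1] - grid[k])
    if k >= 1:
        w[k - 1] = 1.0 - frac  # weight on beta(k); anchor at (0, 0) when k == 0
    w[k] = frac  # weight on beta(k+1)
    return w


def mean_days(params: ModelParameters, c: int, r: int, j: int, T,
              visit_days=None) -> float:
    """Expected outcome at visit ``j`` on the days scale.

    ``T`` is the treatment day for control subjects (``inf``/``None`` if
    untreated); intervention subjects are treated at day 0, so measurement
    at ``t_j`` lands exactly on the grid and no interpolation occurs.
    """
    if params.scale != "days":
        raise ValueError("mean_days requires days-scale parameters")
    grid = np.asarray(visit_days if visit_days is not None else params.visit_days,
                      dtype=float)
    m = params.m
    if not (1 <= j <= m):
        raise IndexError(f"visit j={j} outside 1..{m}")
    mu = params.alpha[c, j - 1]
    if r == 1:
        return float(mu + params.beta[j - 1])
    if T is None or (np.isscalar(T) and not np.isfinite(T)):
        return float(mu)
    T = float(T)
    expected_c = int(np.searchsorted(grid, T, side="left")) if T > 0 else -1
    if expected_c != c:
        raise ValueError(f"treatment day T={T} inconsistent with compliance type c={c}")
    if T > grid[j - 1]:
        return float(mu)
    return float(mu + beta_at_days(params.beta, grid, grid[j - 1] - T))


def mean_itt(params: ITTParameters, r: int, j: int) -> float:
    """Expected outcome at visit ``j`` under the arm-means (ITT) model."""
    if not (1 <= j <= params.m):
        raise IndexError(f"visit j={j} outside 1..{params.m}")
    return float(params.control_mean[j - 1] + params.delta[j - 1] * (r == 1))
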
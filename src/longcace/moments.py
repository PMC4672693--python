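"""Closed-form moment identification of the compliance-type model.

The visits-scale model is identified from arm-wise moments alone: the type
probabilities are the observed departure proportions in the control arm;
the per-visit ITT mean difference satisfies

    ITT(j) = beta(j) - sum_{c=0}^{j-1} gamma(c) * beta(j - c)

because the intervention arm all carry ``beta(j)`` while the control arm is
a mixture of types treated ``j - c`` visits ago (types ``c >= j`` are still
untreated and their ``alpha`` terms cancel across arms by the exclusion
restriction).  Solving forward in ``j`` gives a recursive estimator of
``beta``; subtracting the implied effect from within-type control means
then recovers ``alpha``.

The ``j = 1`` step is the classic Wald / instrumental-variable ratio:
``beta(1) = ITT(1) / (1 - gamma(0))``.

These estimators are fast and assumption-light (available-case means under
MAR); they serve as initial values and as an independent cross-check for
the Bayesian fit, which remains the principled treatment of missing data.
"""

from __future__ import annotations

import numpy as np

from .data import TrialDataset

__all__ = [
    "estimate_gamma",
    "itt_differences",
    "recursive_beta",
    "estimate_alpha",
    "population_itt",
    "fit_moments",
]


def estimate_gamma(dataset: TrialDataset) -> np.ndarray:
    """Empirical compliance-type proportions among controls."""
    ctrl = dataset.departure[dataset.arm == 0]
    if ctrl.size == 0:
        raise ValueError("no control-arm subjects: gamma is not estimable")
    counts = np.bincount(ctrl, minlength=dataset.m + 1)
    return counts / counts.sum()


def itt_differences(dataset: TrialDataset) -> np.ndarray:
    """Per-visit available-case mean difference, intervention minus control."""
    Y = dataset.outcomes
    out = np.empty(dataset.m)
    for j in range(dataset.m):
        col = Y[:, j]
        means = []
        for r in (1, 0):
            vals = col[(dataset.arm == r) & ~np.isnan(col)]
            if vals.size == 0:
                raise ValueError(f"no observed outcomes in arm {r} at visit {j + 1}")
            means.append(vals.mean())
        out[j] = means[0] - means[1]
    return out


def recursive_beta(itt, gamma) -> np.ndarray:
    """Invert the ITT mixture relation forward in j.

    ``beta(1) = ITT(1)/(1 - gamma(0))`` and, for later visits,
    ``beta(j) = [ITT(j) + sum_{c=1}^{j-1} gamma(c) beta(j-c)] / (1 - gamma(0))``.
    """
    itt = np.asarray(itt, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    m = len(itt)
    if gamma[0] >= 1.0 - 1e-12:
        raise ValueError("gamma(0) = 1: everyone departs immediately, "
                         "the effect is unidentified")
    beta = np.empty(m)
    for j in range(1, m + 1):
        acc = itt[j - 1]
        for c in range(1, j):
            acc += gamma[c] * beta[j - c - 1]
        beta[j - 1] = acc / (1.0 - gamma[0])
    return beta


def population_itt(gamma, beta) -> np.ndarray:
    """Population ITT differences implied by (gamma, beta).

    Brute-force evaluation of the mixture expectation, used as the
    independent check that :func:`recursive_beta` inverts it exactly.
    """
    gamma = np.asarray(gamma, dtype=float)
    beta = np.asarray(beta, dtype=float)
    m = len(beta)
    itt = np.empty(m)
    for j in range(1, m + 1):
        contaminated = sum(gamma[c] * beta[j - c - 1] for c in range(j))
        itt[j - 1] = beta[j - 1] - contaminated
    return itt


def estimate_alpha(dataset: TrialDataset, beta) -> np.ndarray:
    """Within-type control means minus the implied treatment effect.

    Cells (type, visit) with no observed control data come back as NaN;
    they are simply not identified from the control arm.
    """
    beta = np.asarray(beta, dtype=float)
    m = dataset.m
    alpha = np.full((m + 1, m), np.nan)
    ctrl = dataset.arm == 0
    for c in range(m + 1):
        rows = ctrl & (dataset.departure == c)
        if not rows.any():
            continue
        for j in range(1, m + 1):
            vals = dataset.outcomes[rows, j - 1]
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                continue
            adj = beta[j - c - 1] if c < j else 0.0
            alpha[c, j - 1] = vals.mean() - adj
    return alpha


def fit_moments(dataset: TrialDataset) -> dict:
    """Full recursive moment fit: gamma, beta, alpha."""
    gamma = estimate_gamma(dataset)
    beta = recursive_beta(itt_differences(dataset), gamma)
    alpha = estimate_alpha(dataset, beta)
    return {"gamma": gamma, "beta": beta, "alpha": alpha}
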
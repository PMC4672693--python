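"""Model and Results classes tying the estimators together.

Usage follows the familiar fit-and-summarise pattern::

    model = LongitudinalCACE(dataset, scale="visits")
    res = model.fit(method="gibbs", config=ChainConfig(n_iterations=3000,
                                                       n_burnin=500, seed=1))
    print(res.summary())
    res.beta, res.conf_int, res.rhat

`fit(method="moment")` gives the closed-form recursive estimate instead.
`ITTModel` and `IVCACE` expose the comparators the same way.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import comparators, moments
from .data import TrialDataset, trial_from_frame
from .gibbs import ChainConfig, PosteriorChains, PriorSpec, gelman_rubin, run_gibbs

__all__ = ["LongitudinalCACE", "ITTModel", "IVCACE",
           "GibbsCACEResults", "MomentCACEResults", "ITTResults", "IVResults"]


class _ModelBase:
    def __init__(self, data: TrialDataset):
        if not isinstance(data, TrialDataset):
            raise TypeError("data must be a TrialDataset")
        self.data = data

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, visit_days, schema=None, **kw):
        return cls(trial_from_frame(df, visit_days, schema), **kw)


class LongitudinalCACE(_ModelBase):
    """Compliance-type causal model for a longitudinal two-arm trial.

    Parameters
    ----------
    data : TrialDataset
    scale : {"visits", "days"}
        Whether the treatment-effect curve is indexed by whole visits since
        treatment or by (piecewise-linearly interpolated) days.
    """

    def __init__(self, data: TrialDataset, scale: str = "visits"):
        super().__init__(data)
        if scale not in ("visits", "days"):
            raise ValueError("scale must be 'visits' or 'days'")
        self.scale = scale

    def fit(self, method: str = "gibbs", prior: PriorSpec | None = None,
            config: ChainConfig | None = None):
        """Fit by Gibbs sampling (``"gibbs"``) or the recursive moment
        estimator (``"moment"``; visits scale only, point estimates)."""
        if method == "gibbs":
            chains = run_gibbs(self.data, model=self.scale, prior=prior,
                               config=config)
            return GibbsCACEResults(self, chains)
        if method == "moment":
            if self.scale != "visits":
                raise ValueError("the moment estimator is defined on the "
                                 "visits scale")
            return MomentCACEResults(self, moments.fit_moments(self.data))
        raise ValueError(f"unknown method {method!r}")


class GibbsCACEResults:
    """Posterior summaries of the Bayesian fit."""

    def __init__(self, model: LongitudinalCACE, chains: PosteriorChains):
        self.model = model
        self.chains = chains
        self.params = chains.posterior_mean_params()

    @property
    def beta(self) -> np.ndarray:
        """Posterior mean treatment-effect curve."""
        return self.params.beta

    @property
    def beta_sd(self) -> np.ndarray:
        return self.chains.flat("beta").std(axis=0, ddof=1)

    @property
    def conf_int(self) -> np.ndarray:
        """Equal-tailed 95% credible intervals for beta, (m, 2)."""
        lo, hi = np.percentile(self.chains.flat("beta"), [2.5, 97.5], axis=0)
        return np.column_stack([lo, hi])

    @property
    def rhat(self) -> dict:
        return gelman_rubin(self.chains.scalar_draws())

    def summary(self) -> pd.DataFrame:
        """One row per scalar parameter: posterior mean, SD, 95% interval,
        and the Gelman-Rubin R-hat (NaN with a single chain)."""
        draws = self.chains.scalar_draws()
        multi = self.chains.n_chains >= 2
        rows = []
        for name, arr in draws.items():
            flat = arr.reshape(-1)
            lo, hi = np.percentile(flat, [2.5, 97.5])
            rows.append({
                "parameter": name,
                "mean": flat.mean(),
                "sd": flat.std(ddof=1),
                "q2.5": lo,
                "q97.5": hi,
                "rhat": gelman_rubin(arr) if multi else np.nan,
            })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.summary().to_csv(path, index=False)

    def __str__(self) -> str:
        s = self.summary()
        keep = s[s["parameter"].str.startswith(("beta", "gamma"))]
        return ("Longitudinal CACE (Bayesian fit, scale="
                f"{self.model.scale})\n" + keep.to_string(index=False,
                                                          float_format="%.3f"))


class MomentCACEResults:
    """Closed-form recursive moment estimates (no interval columns)."""

    def __init__(self, model: LongitudinalCACE, fit: dict):
        self.model = model
        self.gamma = fit["gamma"]
        self.beta = fit["beta"]
        self.alpha = fit["alpha"]

    def summary(self) -> pd.DataFrame:
        m = len(self.beta)
        rows = []
        for c in range(m + 1):
            for j in range(m):
                rows.append({"parameter": f"alpha[{c},{j + 1}]",
                             "mean": self.alpha[c, j]})
        rows += [{"parameter": f"beta[{k + 1}]", "mean": self.beta[k]}
                 for k in range(m)]
        rows += [{"parameter": f"gamma[{c}]", "mean": self.gamma[c]}
                 for c in range(m + 1)]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.summary().to_csv(path, index=False)

    def __str__(self) -> str:
        return ("Longitudinal CACE (recursive moment fit)\n"
                + self.summary().to_string(index=False, float_format="%.3f"))


class ITTModel(_ModelBase):
    """Arm-means (intention-to-treat) multivariate-normal model."""

    def fit(self) -> "ITTResults":
        return ITTResults(self, comparators.fit_itt(self.data))


class ITTResults:
    def __init__(self, model: ITTModel, fit: comparators.ITTFit):
        self.model = model
        self._fit = fit
        self.params = fit.params

    @property
    def delta(self) -> np.ndarray:
        return self.params.delta

    @property
    def bse(self) -> np.ndarray:
        return self._fit.delta_se

    @property
    def conf_int(self) -> np.ndarray:
        return self._fit.conf_int

    def summary(self) -> pd.DataFrame:
        m = self.params.m
        return pd.DataFrame({
            "parameter": [f"delta[{j + 1}]" for j in range(m)],
            "mean": self.delta,
            "sd": self.bse,
            "q2.5": self.conf_int[:, 0],
            "q97.5": self.conf_int[:, 1],
        })

    def to_csv(self, path) -> None:
        self.summary().to_csv(path, index=False)

    def __str__(self) -> str:
        return ("ITT arm-means model\n"
                + self.summary().to_string(index=False, float_format="%.3f"))


class IVCACE(_ModelBase):
    """Pooled 2SLS instrumental-variables comparator."""

    def fit(self) -> "IVResults":
        return IVResults(self, comparators.fit_iv_2sls(self.data))


class IVResults:
    def __init__(self, model: IVCACE, fit: comparators.IVFit):
        self.model = model
        self._fit = fit

    @property
    def beta(self) -> np.ndarray:
        return self._fit.beta

    @property
    def bse(self) -> np.ndarray:
        return self._fit.bse

    @property
    def conf_int(self) -> np.ndarray:
        return self._fit.conf_int

    def summary(self) -> pd.DataFrame:
        m = len(self.beta)
        return pd.DataFrame({
            "parameter": [f"beta[{k + 1}]" for k in range(m)],
            "mean": self.beta,
            "sd": self.bse,
            "q2.5": self.conf_int[:, 0],
            "q97.5": self.conf_int[:, 1],
        })

    def to_csv(self, path) -> None:
        self.summary().to_csv(path, index=False)

    def __str__(self) -> str:
        return ("2SLS IV comparator (cluster-robust SEs)\n"
                + self.summary().to_string(index=False, float_format="%.3f"))
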
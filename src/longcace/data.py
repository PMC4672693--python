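"""Trial data containers, validation and CSV I/O.

The central object is :class:`TrialDataset`: one row per participant of a
two-arm randomised trial in which everyone randomised to the intervention
receives it just after baseline, while controls may cross over to the
one-off intervention at any time during follow-up.  Departure time is
recorded as the *grouped* time ``D`` (the last scheduled visit before
treatment, with ``D = m`` meaning never treated) and optionally as the
exact day ``T`` since randomisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrialDataset",
    "ComplianceState",
    "TrialDataError",
    "read_trial_csv",
    "write_trial_csv",
    "derive_compliance",
    "days_to_grouped",
]

NEVER = np.inf
"""Sentinel for a treatment day that never occurs."""


class TrialDataError(ValueError):
    """Raised when trial data violate the design assumptions."""


@dataclass
class TrialDataset:
    """Longitudinal two-arm trial with time-dependent control-arm crossover.

    Parameters
    ----------
    arm : (n,) int array
        Randomised arm, 1 = intervention, 0 = control.
    departure : (n,) int array
        Grouped departure time ``D`` in ``0..m``: the last visit before
        treatment was received (``0`` = treated between baseline and visit 1,
        ``m`` = never treated).  Intervention subjects are treated just after
        baseline and must have ``D = 0``.
    outcomes : (n, m) float array
        Outcome at post-randomisation visits ``1..m``; ``NaN`` marks a
        missing measurement.
    visit_days : (m,) float array
        Days from randomisation to each scheduled visit, strictly increasing.
    treatment_day : (n,) float array, optional
        Exact day of treatment; ``NaN`` = not recorded, ``inf`` = never
        treated.  When finite it must satisfy ``t_D < T <= t_{D+1}``.
    ids : sequence, optional
        Subject identifiers (defaults to ``0..n-1``).
    baseline : (n, k) array, optional
        Pre-randomisation outcome columns, stored but not modelled.
    """

    arm: np.ndarray
    departure: np.ndarray
    outcomes: np.ndarray
    visit_days: np.ndarray
    treatment_day: np.ndarray | None = None
    ids: np.ndarray | None = None
    baseline: np.ndarray | None = None
    strict: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.arm = np.asarray(self.arm, dtype=int)
        self.departure = np.asarray(self.departure, dtype=int)
        self.outcomes = np.asarray(self.outcomes, dtype=float)
        if self.outcomes.ndim != 2:
            raise TrialDataError("outcomes must be an n x m matrix")
        self.visit_days = np.asarray(self.visit_days, dtype=float)
        if self.treatment_day is None:
            self.treatment_day = np.full(self.n, np.nan)
        self.treatment_day = np.asarray(self.treatment_day, dtype=float)
        if self.ids is None:
            self.ids = np.arange(self.n)
        self.ids = np.asarray(self.ids)
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return self.outcomes.shape[0]

    @property
    def m(self) -> int:
        return self.outcomes.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean n x m mask, True where the outcome is missing."""
        return np.isnan(self.outcomes)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        n, m = self.outcomes.shape
        for name, arr in (("arm", self.arm), ("departure", self.departure),
                          ("treatment_day", self.treatment_day), ("ids", self.ids)):
            if len(arr) != n:
                raise TrialDataError(f"{name} has length {len(arr)}, expected {n}")
        if not np.isin(self.arm, (0, 1)).all():
            raise TrialDataError("arm indicator must be 0 or 1")
        if ((self.departure < 0) | (self.departure > m)).any():
            bad = int(np.argmax((self.departure < 0) | (self.departure > m)))
            raise TrialDataError(
                f"departure D={self.departure[bad]} outside 0..{m} for subject {self.ids[bad]}")
        off = (self.arm == 1) & (self.departure != 0)
        if off.any():
            msg = ("intervention-arm subjects are treated just after baseline and "
                   f"must have D=0; violated for subjects {list(self.ids[off])}")
            if self.strict:
                raise TrialDataError(msg)
            import warnings

            warnings.warn(msg, stacklevel=2)
        if self.m and (np.diff(self.visit_days) <= 0).any() or (self.visit_days <= 0).any():
            raise TrialDataError("visit_days must be positive and strictly increasing")
        finite = np.isfinite(self.treatment_day)
        if finite.any():
            t = np.concatenate([[0.0], self.visit_days, [np.inf]])
            d = self.departure[finite]
            T = self.treatment_day[finite]
            ok = (t[d] < T) & (T <= t[d + 1])
            if not ok.all():
                bad = self.ids[finite][~ok]
                raise TrialDataError(
                    f"treatment day inconsistent with grouped departure for subjects {list(bad)}")

    # -- conversion ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        cols = {"id": self.ids, "R": self.arm, "D": self.departure}
        td = self.treatment_day.copy().astype(object)
        td[np.isinf(self.treatment_day)] = "never"
        td[np.isnan(self.treatment_day)] = ""
        cols["T_days"] = td
        for j in range(self.m):
            cols[f"y{j + 1}"] = self.outcomes[:, j]
        return pd.DataFrame(cols)

    def __eq__(self, other: object) -> bool:  # value semantics for round-trips
        if not isinstance(other, TrialDataset):
            return NotImplemented
        same = (np.array_equal(self.arm, other.arm)
                and np.array_equal(self.departure, other.departure)
                and np.array_equal(self.outcomes, other.outcomes, equal_nan=True)
                and np.array_equal(self.visit_days, other.visit_days)
                and np.array_equal(self.treatment_day, other.treatment_day, equal_nan=True))
        return bool(same)


@dataclass
class ComplianceState:
    """Per-subject latent compliance type.

    ``C[i]`` is the last visit before which subject *i* would receive
    treatment under randomisation to control (``m`` = would never be
    treated).  It is observed (``known``) for controls, where it equals the
    recorded departure, and latent for intervention subjects until the
    sampler imputes it.
    """

    C: np.ndarray
    known: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=int)
        self.known = np.asarray(self.known, dtype=bool)


def derive_compliance(dataset: TrialDataset) -> ComplianceState:
    """Read off compliance types where observed.

    Controls reveal their own type (``C = D``); intervention subjects are
    all treated at baseline, so their type is latent.
    """
    known = dataset.arm == 0
    C = np.where(known, dataset.departure, -1)
    return ComplianceState(C=C, known=known)


def days_to_grouped(T, visit_days) -> int:
    """Map an exact treatment day to the grouped departure index.

    Returns ``c`` such that ``t_c < T <= t_{c+1}`` (with ``t_0 = 0``), i.e.
    treatment strictly after visit ``c`` and no later than visit ``c+1``;
    a day falling exactly on a visit is grouped with the preceding interval.
    ``"never"`` (or ``inf``) maps to ``m``.
    """
    visit_days = np.asarray(visit_days, dtype=float)
    if isinstance(T, str):
        if T.lower() == "never":
            return len(visit_days)
        T = float(T)
    if np.isinf(T):
        return len(visit_days)
    if T <= 0:
        raise TrialDataError(f"treatment day must be positive, got {T}")
    return int(np.searchsorted(visit_days, T, side="left"))


_DEFAULT_SCHEMA = {"id": "id", "R": "R", "D": "D", "T_days": "T_days"}


def read_trial_csv(path, visit_days, schema: dict | None = None,
                   strict: bool = True) -> TrialDataset:
    """Read a one-row-per-subject trial CSV.

    Expected columns (renamable through ``schema``): ``id``, ``R``, ``D``,
    optional ``T_days`` and outcomes ``y1..ym``; empty cells and NA tokens
    mark missing outcomes.  ``visit_days`` (the day of each scheduled
    visit) comes from configuration, not the CSV.
    """
    colmap = dict(_DEFAULT_SCHEMA, **(schema or {}))
    df = pd.read_csv(path, dtype={colmap.get("T_days", "T_days"): str})
    return trial_from_frame(df, visit_days, colmap, strict=strict)


def trial_from_frame(df: pd.DataFrame, visit_days, schema: dict | None = None,
                     strict: bool = True) -> TrialDataset:
    """Build a :class:`TrialDataset` from a dataframe in the CSV layout."""
    colmap = dict(_DEFAULT_SCHEMA, **(schema or {}))
    visit_days = np.asarray(visit_days, dtype=float)
    m = len(visit_days)
    ycols = [f"y{j + 1}" for j in range(m)]
    missing_cols = [c for c in (colmap["R"], colmap["D"], *ycols) if c not in df.columns]
    if missing_cols:
        raise TrialDataError(f"missing required columns: {missing_cols}")

    def _numeric(col, as_int=False):
        raw = df[col]
        try:
            out = pd.to_numeric(raw, errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(raw, errors="coerce")
            row = int(bad[bad.isna() & raw.notna()].index[0])
            raise TrialDataError(
                f"malformed numeric cell in column {col!r}, row {row}: {raw.iloc[row]!r}")
        return out.to_numpy(int if as_int else float)

    arm = _numeric(colmap["R"], as_int=True)
    dep = _numeric(colmap["D"], as_int=True)
    Y = np.column_stack([_numeric(c) for c in ycols]) if m else np.empty((len(df), 0))

    tcol = colmap["T_days"]
    if tcol in df.columns:
        raw = df[tcol].astype(str).str.strip().str.lower()
        T = np.full(len(df), np.nan)
        never = raw == "never"
        T[never] = np.inf
        has = ~never & (raw != "") & (raw != "nan")
        if has.any():
            T[has] = pd.to_numeric(df[tcol][has]).to_numpy(float)
    else:
        T = None

    ids = df[colmap["id"]].to_numpy() if colmap["id"] in df.columns else None
    return TrialDataset(arm=arm, departure=dep, outcomes=Y, visit_days=visit_days,
                        treatment_day=T, ids=ids, strict=strict)


def write_trial_csv(dataset: TrialDataset, path) -> None:
    """Write a dataset in the same layout :func:`read_trial_csv` reads."""
    dataset.to_frame().to_csv(path, index=False, na_rep="")
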
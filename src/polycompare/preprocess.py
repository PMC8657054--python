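"""Cohort ingest and preprocessing.

Person-level records carry two personality traits -- extraversion (E) and
neuroticism (N) -- and a loneliness outcome measured at baseline (L1) and,
optionally, one year later (L2).  Different instruments use different Likert
ranges, so all variables are brought onto a common 1-7 metric with
proportion-of-maximum scaling (POMS) before the traits are mean-centered and
the second-order design terms (E^2, E*N, N^2) are formed.  Influential cases
are screened on the full polynomial model with standard leverage/influence
diagnostics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence
import yaml

__all__ = [
    "Cohort",
    "PreparedData",
    "RangeBox",
    "InfluenceReport",
    "poms_rescale",
    "center",
    "build_design",
    "flag_influential",
    "load_cohort",
]

#: canonical column names of a cohort table
COHORT_COLUMNS = ("person_id", "E_raw", "N_raw", "L1", "L2")

#: common target range all variables are rescaled to
TARGET_RANGE = (1.0, 7.0)

DEFAULT_BOUNDS = {"E_raw": (1.0, 7.0), "N_raw": (1.0, 7.0), "L1": (1.0, 7.0), "L2": (1.0, 7.0)}


@dataclass(frozen=True)
class RangeBox:
    """Observed min/max of the centered traits; anchors range-dependent constraints."""

    e_lo: float
    e_hi: float
    n_lo: float
    n_hi: float

    def __post_init__(self) -> None:
        if not (self.e_lo < self.e_hi and self.n_lo < self.n_hi):
            raise ValueError(f"degenerate range box: {self}")

    @property
    def corners(self) -> list[tuple[float, float]]:
        return [
            (self.e_lo, self.n_lo),
            (self.e_lo, self.n_hi),
            (self.e_hi, self.n_lo),
            (self.e_hi, self.n_hi),
        ]


@dataclass
class Cohort:
    """Person-level raw records.

    ``data`` holds the columns of :data:`COHORT_COLUMNS`; only ``L2`` may contain
    missing values.  ``bounds`` maps each variable to its theoretical instrument
    range (e.g. 1-5 for a short Big-Five inventory).  ``meta`` carries
    provenance such as dropped-row counts or, for synthetic cohorts, the
    generating coefficients.
    """

    data: pd.DataFrame
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        bounds: Mapping[str, tuple[float, float]] | None = None,
        column_map: Mapping[str, str] | None = None,
    ) -> "Cohort":
        """Validate a raw table into a cohort.

        Rows missing a trait are dropped (count logged in ``meta``), rows missing
        the baseline outcome L1 are dropped likewise; only the follow-up outcome
        L2 may stay missing.  Values outside the instrument bounds are rejected.
        """
        bounds = dict(DEFAULT_BOUNDS) if bounds is None else dict(bounds)
        df = frame.rename(columns=dict(column_map or {})).copy()
        if "person_id" not in df.columns:
            df.insert(0, "person_id", np.arange(len(df)))
        if "L2" not in df.columns:
            df["L2"] = np.nan
        missing_cols = [c for c in ("E_raw", "N_raw", "L1") if c not in df.columns]
        if missing_cols:
            raise ValueError(f"cohort table lacks required columns: {missing_cols}")
        df = df.loc[:, list(COHORT_COLUMNS)]

        n0 = len(df)
        df = df.dropna(subset=["E_raw", "N_raw"])
        n_pred = n0 - len(df)
        df = df.dropna(subset=["L1"])
        n_out = n0 - n_pred - len(df)

        for col in ("E_raw", "N_raw", "L1", "L2"):
            lo, hi = bounds.get(col, TARGET_RANGE)
            vals = df[col]
            bad = vals.notna() & ((vals < lo) | (vals > hi))
            if bad.any():
                rows = df.loc[bad, "person_id"].tolist()[:5]
                raise ValueError(
                    f"{col} outside instrument bounds [{lo}, {hi}] for rows {rows}"
                )
        meta = {"n_dropped_missing_predictor": n_pred, "n_dropped_missing_outcome": n_out}
        return cls(data=df.reset_index(drop=True), bounds=bounds, meta=meta)

    @property
    def n(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class PreparedData:
    """Design-ready data: POMS-scaled, centered traits plus derived terms.

    ``frame`` has columns E, N, E2, EN, N2, L1 and (possibly all-missing) L2;
    outcomes stay on the 1-7 scale and are *not* centered.  ``trait_means``
    stores the pre-centering means for back-transformation.
    """

    frame: pd.DataFrame
    range_box: RangeBox
    trait_means: tuple[float, float]

    @property
    def n(self) -> int:
        return len(self.frame)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class InfluenceReport:
    """Per-row influence diagnostics from the full polynomial regression."""

    table: pd.DataFrame  # columns: person, dffits, cooks_d, hat, flagged
    cutoffs: dict[str, float]

    @property
    def flagged(self) -> pd.DataFrame:
        return self.table.loc[self.table["flagged"]]


def poms_rescale(
    x: np.ndarray | float,
    bounds: tuple[float, float],
    target: tuple[float, float] = TARGET_RANGE,
) -> np.ndarray | float:
    """Proportion-of-maximum scaling of a bounded score onto a target range.

    Linear map sending ``bounds`` onto ``target``:
    ``t_lo + (t_hi - t_lo) * (x - lo) / (hi - lo)``.  Missing values pass
    through; out-of-bounds values raise, naming the offending positions.
    """
    lo, hi = bounds
    if not lo < hi:
        raise ValueError(f"invalid scale bounds ({lo}, {hi})")
    arr = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (~np.isnan(arr)) & ((arr < lo) | (arr > hi))
    if np.any(bad):
        idx = np.flatnonzero(np.atleast_1d(bad))[:5].tolist()
        raise ValueError(f"values outside [{lo}, {hi}] at rows {idx}")
    t_lo, t_hi = target
    out = t_lo + (t_hi - t_lo) * (arr - lo) / (hi - lo)
    return float(out) if np.isscalar(x) else out


def center(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Mean-center a column; returns the centered values and the stored mean."""
    arr = np.asarray(values, dtype=float)
    finite = arr[~np.isnan(arr)]
    if finite.size < 2:
        raise ValueError("need at least 2 non-missing values to center")
    mean = float(finite.mean())
    return arr - mean, mean


def build_design(cohort: Cohort, rescale: bool = True) -> PreparedData:
    """Rescale, center and derive the second-order design terms.

    Derived terms are computed *after* POMS rescaling and centering of the
    traits.  Outcomes are rescaled to 1-7 but never centered.  Refuses cohorts
    with fewer than 10 rows, where a five-slope polynomial fit is degenerate.
    """
    if cohort.n < 10:
        raise ValueError(f"cohort has only {cohort.n} rows; refusing degenerate design")
    df = cohort.data

    def scaled(col: str) -> np.ndarray:
        vals = df[col].to_numpy(dtype=float)
        if rescale:
            return np.asarray(poms_rescale(vals, cohort.bounds.get(col, TARGET_RANGE)))
        return vals

    e, e_mean = center(scaled("E_raw"))
    n_, n_mean = center(scaled("N_raw"))
    frame = pd.DataFrame(
        {
            "E": e,
            "N": n_,
            "E2": e * e,
            "EN": e * n_,
            "N2": n_ * n_,
            "L1": scaled("L1"),
            "L2": scaled("L2"),
        }
    )
    box = RangeBox(float(e.min()), float(e.max()), float(n_.min()), float(n_.max()))
    return PreparedData(frame=frame, range_box=box, trait_means=(e_mean, n_mean))


def flag_influential(prepared: PreparedData, outcome: str = "L1") -> InfluenceReport:
    """Screen for influential cases using the full polynomial model.

    Diagnostics (DFFITS, Cook's D, hat values) come from an OLS fit of the
    outcome on the five design terms over complete cases.  A row is an
    influential case when its leverage exceeds the hat cutoff 2p/n *and* at
    least one of |DFFITS| > 2*sqrt(p/n) or Cook's D > 4/n fires, where p counts
    design columns including the intercept.  Flagged rows are reported, never
    deleted.
    """
    df = prepared.frame
    mask = df[outcome].notna().to_numpy()
    X = sm.add_constant(df.loc[mask, ["E", "N", "E2", "EN", "N2"]].to_numpy())
    y = df.loc[mask, outcome].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "singular design matrix; inspect predictor variance before influence screening"
        )
    res = sm.OLS(y, X).fit()
    infl = OLSInfluence(res)
    n, p = X.shape
    cutoffs = {
        "dffits": 2.0 * np.sqrt(p / n),
        "cooks_d": 4.0 / n,
        "hat": 2.0 * p / n,
    }
    dffits = infl.dffits[0]
    cooks = infl.cooks_distance[0]
    hat = infl.hat_matrix_diag
    flagged = (hat > cutoffs["hat"]) & (
        (np.abs(dffits) > cutoffs["dffits"]) | (cooks > cutoffs["cooks_d"])
    )
    table = pd.DataFrame(
        {
            "row": np.flatnonzero(mask),
            "dffits": dffits,
            "cooks_d": cooks,
            "hat": hat,
            "flagged": flagged,
        }
    )
    return InfluenceReport(table=table, cutoffs=cutoffs)


def load_cohort(path: str | Path, config: str | Path | Mapping | None = None) -> Cohort:
    """Read a cohort CSV with an optional YAML/JSON-style ingest config.

    The config may provide ``columns`` (mapping from canonical names
    ``E_raw``/``N_raw``/``L1``/``L2``/``person_id`` to the file's header names),
    ``bounds`` (instrument ranges per canonical column) and ``na_values``.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    config = dict(config or {})
    na_values = config.get("na_values")
    frame = pd.read_csv(path, na_values=na_values)
    columns = config.get("columns") or {}
    column_map = {v: k for k, v in columns.items()}  # file name -> canonical
    bounds = {k: tuple(v) for k, v in (config.get("bounds") or {}).items()} or None
    return Cohort.from_frame(frame, bounds=bounds, column_map=column_map)
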
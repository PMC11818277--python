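"""Longitudinal RBC panels, endpoints, anemia grading and group statistics.

A red-cell panel series is the time-ordered sequence of complete blood
count measurements for one patient during hospitalization: RBC count
(10^12/L), hemoglobin HGB (g/L), hematocrit HCT (fraction), mean
corpuscular volume MCV (fL), mean corpuscular hemoglobin MCH (pg), MCH
concentration MCHC (g/L) and red cell distribution width RDW (%).

Three endpoints are derived per parameter: the first and final
non-missing values by timestamp, and the "min-max" (worst) value — the
series minimum for every parameter except RDW, for which high values
are unfavorable and the maximum is taken.

Anemia is graded from a hemoglobin value: severe below 80 g/L,
moderate in [80, 110), below the sex-specific reference (130 g/L men,
120 g/L women) otherwise when under it, else none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .stats_core import bh_fdr, mann_whitney_u, spearman_rho

__all__ = ["PARAMETERS", "WORST_IS_MAX", "TIMEPOINTS", "RBCPanelSeries",
           "AnemiaGrade", "AnemiaStatus", "extract_endpoints",
           "extract_endpoints_table", "classify_anemia", "flag_threshold",
           "group_compare", "scale_correlations"]

PARAMETERS = ("RBC", "HGB", "HCT", "MCV", "MCH", "MCHC", "RDW")
WORST_IS_MAX = frozenset({"RDW"})
TIMEPOINTS = ("first", "final", "minmax")

SEX_HGB_REFERENCE = {"male": 130.0, "female": 120.0}
SEVERE_MAX = 80.0    # HGB < 80 g/L
MODERATE_MAX = 110.0  # 80 <= HGB < 110 g/L


@dataclass
class RBCPanelSeries:
    """Time-ordered CBC measurements for one sample.

    ``measurements`` holds a 'timestamp' column plus any subset of the
    seven panel parameters; values may be missing per time point.
    Timestamps must be strictly increasing; ties are tolerated with a
    warning and broken by input order.
    """

    sample_id: str
    measurements: pd.DataFrame

    def __post_init__(self) -> None:
        if "timestamp" not in self.measurements.columns:
            raise ValueError("measurements need a 'timestamp' column")
        if len(self.measurements) == 0:
            raise ValueError(f"empty series for sample {self.sample_id!r}")
        ts = self.measurements["timestamp"].to_numpy()
        if (np.diff(ts) < 0).any():
            self.measurements = (self.measurements
                                 .sort_values("timestamp", kind="stable")
                                 .reset_index(drop=True))
            ts = self.measurements["timestamp"].to_numpy()
        if (np.diff(ts) == 0).any():
            warnings.warn(f"tied timestamps for sample {self.sample_id!r}; "
                          "ties broken by input order")

    @property
    def parameters(self) -> list[str]:
        return [p for p in PARAMETERS if p in self.measurements.columns]


class AnemiaGrade(str, Enum):
    NONE = "none"
    BELOW_REFERENCE = "below-reference"
    MODERATE = "moderate"
    SEVERE = "severe"


@dataclass(frozen=True)
class AnemiaStatus:
    grade: AnemiaGrade
    hgb: float
    sex: str


def classify_anemia(hgb: float, sex: str) -> AnemiaStatus:
    """Grade anemia from a hemoglobin value (g/L) and sex.

    severe: HGB < 80; moderate: 80 <= HGB < 110; below-reference:
    110 <= HGB < sex reference (130 men / 120 women); none otherwise.
    The grading applies to whichever measurement the caller supplies
    (admission value, endpoint, ...).
    """
    if sex not in SEX_HGB_REFERENCE:
        raise ValueError(f"unknown sex {sex!r}; expected 'male' or 'female'")
    if not np.isfinite(hgb) or hgb <= 0:
        raise ValueError(f"HGB must be positive, got {hgb}")
    if hgb < SEVERE_MAX:
        grade = AnemiaGrade.SEVERE
    elif hgb < MODERATE_MAX:
        grade = AnemiaGrade.MODERATE
    elif hgb < SEX_HGB_REFERENCE[sex]:
        grade = AnemiaGrade.BELOW_REFERENCE
    else:
        grade = AnemiaGrade.NONE
    return AnemiaStatus(grade=grade, hgb=float(hgb), sex=sex)


def extract_endpoints(series: RBCPanelSeries) -> dict[str, dict[str, float]]:
    """First / final / min-max endpoints per parameter for one series.

    First and final are the earliest and latest non-missing values;
    min-max is the series minimum, except for RDW whose maximum is the
    unfavorable direction.  A parameter missing at every time point
    yields NaN endpoints.
    """
    out: dict[str, dict[str, float]] = {}
    for p in series.parameters:
        vals = series.measurements[p]
        ok = vals.dropna()
        if ok.empty:
            out[p] = {tp: float("nan") for tp in TIMEPOINTS}
            continue
        worst = ok.max() if p in WORST_IS_MAX else ok.min()
        out[p] = {"first": float(ok.iloc[0]), "final": float(ok.iloc[-1]),
                  "minmax": float(worst)}
    return out


def extract_endpoints_table(panel: pd.DataFrame) -> pd.DataFrame:
    """Endpoints for a long-format multi-sample panel table.

    ``panel`` has columns sample_id, timestamp and panel parameters.
    Returns a wide table indexed by sample_id with columns
    '<PARAM>_<timepoint>' (e.g. HGB_minmax).
    """
    for col in ("sample_id", "timestamp"):
        if col not in panel.columns:
            raise ValueError(f"panel table needs a {col!r} column")
    params = [p for p in PARAMETERS if p in panel.columns]
    ordered = panel.sort_values("timestamp", kind="stable")
    grouped = ordered.groupby("sample_id", sort=True)
    pieces = {}
    for p in params:
        g = grouped[p]
        pieces[f"{p}_first"] = g.first()   # earliest non-missing
        pieces[f"{p}_final"] = g.last()    # latest non-missing
        pieces[f"{p}_minmax"] = g.max() if p in WORST_IS_MAX else g.min()
    out = pd.DataFrame(pieces)
    out.index.name = "sample_id"
    return out


def flag_threshold(endpoints: pd.DataFrame, parameter: str, timepoint: str,
                   cutoff: float, direction: str = "below",
                   strict: bool = True) -> pd.Series:
    """Boolean flag per sample for an endpoint threshold rule.

    E.g. final HGB < 100 g/L.  Comparisons are strict by default
    (a final HGB of exactly 100 with cutoff 100 is NOT flagged).
    Missing endpoints yield missing flags (NaN).
    """
    col = f"{parameter}_{timepoint}"
    if col not in endpoints.columns:
        raise KeyError(f"endpoint column {col!r} not present")
    vals = endpoints[col]
    if direction == "below":
        flag = vals < cutoff if strict else vals <= cutoff
    elif direction == "above":
        flag = vals > cutoff if strict else vals >= cutoff
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return flag.mask(vals.isna())


def group_compare(endpoints: pd.DataFrame, grouping: pd.Series,
                  parameters: Sequence[str] = PARAMETERS,
                  timepoints: Sequence[str] = TIMEPOINTS,
                  fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Two-group Mann-Whitney comparison per (parameter, timepoint).

    Uses the tie-corrected normal-approximation MWU (two-sided) and BH
    adjustment across the whole comparison family.  A row is flagged
    low-coverage when a parameter is missing in more than half of
    either group.
    """
    g = grouping.dropna()
    levels = sorted(pd.unique(g))
    if len(levels) != 2:
        raise ValueError(f"grouping must have exactly 2 levels, got {levels}")
    rows = []
    for p in parameters:
        for tp in timepoints:
            col = f"{p}_{tp}"
            if col not in endpoints.columns:
                continue
            vals = endpoints[col].reindex(g.index)
            x = vals[g == levels[1]].dropna()
            y = vals[g == levels[0]].dropna()
            low_cov = (len(x) < 0.5 * (g == levels[1]).sum()
                       or len(y) < 0.5 * (g == levels[0]).sum())
            if x.empty or y.empty:
                rows.append({"parameter": p, "timepoint": tp, "n1": len(x),
                             "n0": len(y), "u": np.nan, "p": np.nan,
                             "low_coverage": True})
                continue
            res = mann_whitney_u(x.to_numpy(), y.to_numpy(), mode="normal")
            rows.append({"parameter": p, "timepoint": tp, "n1": len(x),
                         "n0": len(y), "u": res.statistic, "p": res.p_value,
                         "low_coverage": bool(low_cov)})
    out = pd.DataFrame(rows)
    q, reject = bh_fdr(out["p"].to_numpy(), threshold=fdr_threshold)
    out["q"] = q
    out["significant"] = reject
    return out


def scale_correlations(scores: pd.DataFrame, endpoints: pd.DataFrame,
                       parameters: Sequence[str] = PARAMETERS,
                       timepoints: Sequence[str] = ("first", "final"),
                       min_pairs: int = 5,
                       fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Spearman correlations of scale scores with RBC endpoints.

    Every numeric column of ``scores`` (indexed by sample id) is
    correlated with every (parameter, timepoint) endpoint; cells with
    fewer than ``min_pairs`` complete pairs are reported missing.  BH
    adjustment spans the whole matrix (one family).
    """
    rows = []
    for score_col in scores.columns:
        s = pd.to_numeric(scores[score_col], errors="coerce")
        for p in parameters:
            for tp in timepoints:
                col = f"{p}_{tp}"
                if col not in endpoints.columns:
                    continue
                pair = pd.concat([s, endpoints[col]], axis=1, join="inner").dropna()
                if len(pair) < min_pairs:
                    rows.append({"score": score_col, "parameter": p,
                                 "timepoint": tp, "n": len(pair),
                                 "rho": np.nan, "p": np.nan})
                    continue
                res = spearman_rho(pair.iloc[:, 0].to_numpy(),
                                   pair.iloc[:, 1].to_numpy())
                rows.append({"score": score_col, "parameter": p,
                             "timepoint": tp, "n": len(pair),
                             "rho": res.statistic, "p": res.p_value})
    out = pd.DataFrame(rows)
    q, reject = bh_fdr(out["p"].to_numpy(), threshold=fdr_threshold)
    out["q"] = q
    out["significant"] = reject
    return out
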
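"""Elementary statistics used throughout the pipeline.

Pure functions over plain numbers and arrays: Fisher's exact test,
chi-square with Yates' continuity correction, the likelihood-ratio
(G) test, the Mann-Whitney U test (exact and normal-approximation
modes), Spearman correlation, the Shapiro-Wilk normality test and
Benjamini-Hochberg FDR adjustment.  Every result is returned as a
:class:`TestResult` so downstream tables can carry the method label,
sidedness and any degeneracy flags alongside the p-value.

Standard distributions and reference implementations come from scipy
and statsmodels; the exact Mann-Whitney enumeration (which must handle
ties) is implemented here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Table2x2",
    "TestResult",
    "fisher_exact",
    "yates_chi2",
    "g_test",
    "mann_whitney_u",
    "spearman_rho",
    "shapiro_wilk",
    "bh_fdr",
]


class Table2x2(NamedTuple):
    """A 2x2 count table; rows are groups, columns trait present/absent."""

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def validate(self) -> "Table2x2":
        if any(x < 0 or int(x) != x for x in self):
            raise ValueError(f"cells must be non-negative integers, got {tuple(self)}")
        return Table2x2(*(int(x) for x in self))

    @property
    def margins(self) -> tuple[int, int, int, int]:
        a, b, c, d = self
        return (a + b, c + d, a + c, b + d)

    def has_zero_margin(self) -> bool:
        return 0 in self.margins


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    p_value: float
    method: str
    sided: str = "two-sided"
    estimate: float | None = None
    ci95: tuple[float, float] | None = None
    df: float | None = None
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")


def _degenerate(method: str, flag: str) -> TestResult:
    return TestResult(statistic=float("nan"), p_value=1.0, method=method, flags=(flag,))


def fisher_exact(table: Table2x2 | Sequence[int], sided: str = "two-sided") -> TestResult:
    """Fisher's exact test on a 2x2 table.

    The two-sided p-value sums hypergeometric probabilities of all
    tables with the same margins whose probability does not exceed the
    observed table's (minimum-likelihood convention).  A table with a
    zero margin is degenerate and returns p = 1 with a flag.
    """
    t = Table2x2(*table).validate()
    if sided != "two-sided":
        raise ValueError("only the two-sided Fisher test is provided")
    if t.has_zero_margin():
        return _degenerate("fisher_exact", "zero-margin")
    odds, p = sps.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    return TestResult(statistic=float(odds), p_value=float(min(p, 1.0)),
                      method="fisher_exact", estimate=float(odds))


def yates_chi2(table: Table2x2 | Sequence[int]) -> TestResult:
    """Chi-square test for a 2x2 table with Yates' continuity correction.

    statistic = n(|ad - bc| - n/2)^2 / [(a+b)(c+d)(a+c)(b+d)],
    clamped to 0 when |ad - bc| <= n/2; p from chi-square with 1 df.
    """
    t = Table2x2(*table).validate()
    if t.has_zero_margin():
        return _degenerate("yates_chi2", "zero-margin")
    a, b, c, d = t
    n = t.n
    diff = abs(a * d - b * c)
    if diff <= n / 2:
        stat = 0.0
    else:
        r1, r2, c1, c2 = t.margins
        stat = n * (diff - n / 2) ** 2 / (r1 * r2 * c1 * c2)
    return TestResult(statistic=float(stat), p_value=float(sps.chi2.sf(stat, 1)),
                      method="yates_chi2", df=1)


def g_test(table: Sequence[Sequence[float]]) -> TestResult:
    """Likelihood-ratio (G) test of independence for an r x c count table.

    G = 2 * sum O * ln(O/E) over cells with O > 0.  All-zero rows or
    columns are dropped (flagged) and the degrees of freedom adjusted.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("g_test expects a 2-D table")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if obs.sum() <= 0:
        raise ValueError("table total must be positive")
    flags: list[str] = []
    keep_r = obs.sum(axis=1) > 0
    keep_c = obs.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        flags.append("dropped-zero-margins")
        obs = obs[keep_r][:, keep_c]
    r, c = obs.shape
    df = (r - 1) * (c - 1)
    if df == 0:
        return TestResult(statistic=0.0, p_value=1.0, method="g_test", df=0,
                          flags=tuple(flags) + ("degenerate-df",))
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    mask = obs > 0
    g = 2.0 * float(np.sum(obs[mask] * np.log(obs[mask] / expected[mask])))
    g = max(g, 0.0)
    return TestResult(statistic=g, p_value=float(sps.chi2.sf(g, df)),
                      method="g_test", df=df, flags=tuple(flags))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    # U for sample x: number of (x_i, y_j) pairs with x_i > y_j, ties count 1/2
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


_EXACT_LIMIT = 400_000  # max number of labelings enumerated in exact mode


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   mode: str = "normal") -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``exact`` mode enumerates every assignment of the pooled values into
    the two groups (valid with ties; feasible for small samples only)
    and doubles the smaller tail of the permutation distribution of U.
    ``normal`` mode uses the tie-corrected normal approximation with
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.unique(np.concatenate([x, y])).size == 1:
        return TestResult(statistic=_u_statistic(x, y), p_value=1.0,
                          method="mann_whitney_u", flags=("all-identical",))
    n1, n2 = x.size, y.size
    u_obs = _u_statistic(x, y)
    mu = n1 * n2 / 2.0
    if mode == "exact":
        if math.comb(n1 + n2, n1) > _EXACT_LIMIT:
            raise ValueError("sample too large for exact enumeration; use mode='normal'")
        pooled = np.concatenate([x, y])
        idx = range(n1 + n2)
        lo = hi = 0
        total = 0
        for comb in itertools.combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(comb)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            lo += u <= u_obs
            hi += u >= u_obs
            total += 1
        p = min(1.0, 2.0 * min(lo, hi) / total)
        return TestResult(statistic=u_obs, p_value=p, method="mann_whitney_u_exact")
    if mode != "normal":
        raise ValueError(f"unknown mode {mode!r}")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
    # scipy reports U for x with the same pair-counting convention
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="mann_whitney_u_normal")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with t-approximation p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return TestResult(statistic=float("nan"), p_value=float("nan"),
                          method="spearman_rho", flags=("constant-input",))
    rho, p = sps.spearmanr(x, y)
    return TestResult(statistic=float(rho), p_value=float(p),
                      method="spearman_rho", estimate=float(rho))


def shapiro_wilk(x: Sequence[float]) -> TestResult:
    """Shapiro-Wilk W and p (Royston approximation, via scipy)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    w, p = sps.shapiro(x)
    return TestResult(statistic=float(w), p_value=float(p), method="shapiro_wilk")


def bh_fdr(p_values: Sequence[float], threshold: float = 0.05
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (q-values, reject flags) where reject means q < threshold.
    NaN p-values propagate to NaN q-values and are never rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    ok = ~np.isnan(p)
    if (p[ok] < 0).any() or (p[ok] > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if ok.any():
        _, q_ok, _, _ = multipletests(p[ok], alpha=threshold, method="fdr_bh")
        q[ok] = q_ok
    reject = np.zeros(p.shape, dtype=bool)
    reject[ok] = q[ok] < threshold
    return q, reject
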
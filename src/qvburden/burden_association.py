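"""Collapsing/burden association via the Cochran-Mantel-Haenszel framework.

Two analyses live here.  The exome-wide single-variant scan runs a
Fisher exact test on each variant's carrier 2x2 table against a binary
phenotype and reports the Bonferroni threshold, QQ coordinates and a
genomic-inflation factor.  The gene-set burden test cross-tabulates
carrier status against the phenotype within each gene of a set (one
stratum per gene by default; per-variant strata optional) and combines
the strata with the CMH test.

The CMH machinery reports the Mantel-Haenszel common odds ratio
    OR_MH = sum_i(a_i d_i / n_i) / sum_i(b_i c_i / n_i)
with a Robins-Breslow-Greenland 95% CI, and a two-sided p-value in one
of two modes: "exact", from the exact null distribution of the sum of
a-cells (the convolution of per-stratum central hypergeometric
distributions; two-sided as twice the smaller tail, capped at 1), or
"asymptotic", the continuity-corrected CMH chi-square with 1 df.  With
a single stratum the exact mode reduces to the tail-doubled Fisher
test and OR_MH to ad/bc.  The exact mode is the primary analysis: with
a handful of carriers per stratum the chi-square approximation is
unreliable, which is the regime small-cohort rare-variant studies
live in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.contingency_tables import StratifiedTable

from .gene_sets import BurdenProfile, GeneSetCollection, burden_profile
from .qv_selection import QVSet
from .stats_core import Table2x2, bh_fdr, fisher_exact
from .variant_catalog import MISSING_DOSAGE, GenotypeMatrix, VariantCatalog

__all__ = ["StratifiedTables", "CMHResult", "ScanResult", "build_strata",
           "cmh_test", "geneset_burden_test", "exome_wide_scan",
           "bonferroni_threshold"]

logger = logging.getLogger(__name__)

# median of the chi-square(1 df) distribution, the null expectation used
# by the genomic-inflation factor
_CHI2_1_MEDIAN = float(sps.chi2.ppf(0.5, 1))


@dataclass
class StratifiedTables:
    """An ordered list of labelled 2x2 strata.

    Rows of each stratum are phenotype groups (trait present first),
    columns are carrier / non-carrier, so a = carriers among cases.
    """

    labels: list[str]
    tables: list[Table2x2]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.tables):
            raise ValueError("labels and tables length mismatch")
        if not self.tables:
            raise ValueError("need at least one stratum")
        self.tables = [Table2x2(*t).validate() for t in self.tables]
        for lab, t in zip(self.labels, self.tables):
            if t.n <= 0:
                raise ValueError(f"stratum {lab!r} has zero total")

    def __len__(self) -> int:
        return len(self.tables)

    @classmethod
    def from_counts(cls, items: Sequence[tuple[str, Sequence[int]]]
                    ) -> "StratifiedTables":
        return cls([lab for lab, _ in items],
                   [Table2x2(*t) for _, t in items])

    def informative(self) -> "StratifiedTables":
        """Drop strata with zero carriers (or zero non-carriers) overall."""
        keep = [(lab, t) for lab, t in zip(self.labels, self.tables)
                if (t.a + t.c) > 0 and (t.b + t.d) > 0
                and (t.a + t.b) > 0 and (t.c + t.d) > 0]
        dropped = [lab for lab in self.labels if lab not in {l for l, _ in keep}]
        if dropped:
            logger.info("dropped %d uninformative strata: %s",
                        len(dropped), ", ".join(dropped))
        if not keep:
            raise ValueError("all strata are degenerate")
        return StratifiedTables.from_counts([(lab, tuple(t)) for lab, t in keep])


@dataclass
class CMHResult:
    """Combined association result over stratified 2x2 tables."""

    mh_or: float
    ci95: tuple[float, float]
    p_value: float
    mode: str
    strata_used: int
    statistic: float = float("nan")
    flags: tuple[str, ...] = ()


def build_strata(burden: BurdenProfile, groups: pd.Series, set_name: str,
                 stratify_by: str = "gene") -> StratifiedTables:
    """Cross-tabulate carrier status against a binary phenotype per stratum.

    ``groups`` is a binary (0/1 or boolean) series indexed by sample id;
    group 1 forms the first row of each table.  Strata are the genes of
    the set that harbor QVs (default) or the individual QV sites.
    Samples with missing carrier status in a stratum are excluded from
    that stratum; strata left with zero carriers in both groups are
    dropped with a log entry.
    """
    g = groups.dropna()
    vals = set(pd.unique(g))
    if not vals <= {0, 1, True, False}:
        raise ValueError(f"groups must be binary, got values {sorted(map(str, vals))}")
    g = g.astype(int)

    if stratify_by == "gene":
        units = burden.genes_by_set.get(set_name)
        if units is None:
            raise KeyError(f"unknown gene set {set_name!r}")
        carrier_src = burden.gene_carrier
    elif stratify_by == "variant":
        genes = set(burden.genes_by_set.get(set_name, []))
        units = [vid for vid, gene in burden.variant_gene.items() if gene in genes]
        carrier_src = burden.variant_carrier
    else:
        raise ValueError(f"unknown stratify_by {stratify_by!r}")
    if not units:
        raise ValueError(f"gene set {set_name!r} has no qualifying units")

    items = []
    for u in units:
        col = carrier_src[u].reindex(g.index)
        ok = col.notna()
        carr = col[ok] >= 1
        grp = g[ok]
        a = int(((grp == 1) & carr).sum())
        b = int(((grp == 1) & ~carr).sum())
        c = int(((grp == 0) & carr).sum())
        d = int(((grp == 0) & ~carr).sum())
        items.append((u, (a, b, c, d)))
    return StratifiedTables.from_counts(items).informative()


def _exact_cmh_p(tables: Sequence[Table2x2]) -> float:
    """Two-sided exact CMH p from the convolution of hypergeometric pmfs."""
    dist = np.array([1.0])
    offset = 0
    s_obs = 0
    for t in tables:
        n, k_row, m_col = t.n, t.a + t.b, t.a + t.c
        lo = max(0, k_row + m_col - n)
        hi = min(k_row, m_col)
        pmf = sps.hypergeom.pmf(np.arange(lo, hi + 1), n, k_row, m_col)
        dist = np.convolve(dist, pmf)
        offset += lo
        s_obs += t.a
    idx = s_obs - offset
    lower = float(dist[:idx + 1].sum())
    upper = float(dist[idx:].sum())
    return min(1.0, 2.0 * min(lower, upper))


def _asymptotic_cmh(tables: Sequence[Table2x2]) -> tuple[float, float]:
    """Continuity-corrected CMH chi-square statistic and p (1 df)."""
    s = e = v = 0.0
    for t in tables:
        n = t.n
        r1, r2, c1, c2 = t.margins
        s += t.a
        e += r1 * c1 / n
        v += r1 * r2 * c1 * c2 / (n ** 2 * (n - 1)) if n > 1 else 0.0
    if v <= 0:
        return float("nan"), float("nan")
    stat = (max(abs(s - e) - 0.5, 0.0)) ** 2 / v
    return stat, float(sps.chi2.sf(stat, 1))


def cmh_test(strata: StratifiedTables, mode: str = "exact") -> CMHResult:
    """CMH common odds ratio, RBG 95% CI and two-sided p-value.

    Degenerate inputs are flagged rather than raised: a zero
    sum(bc/n) denominator yields an infinite OR with a defined p; a CI
    that cannot be formed (zero cells in every stratum on one diagonal)
    is reported as (nan, nan) with a flag.
    """
    if mode not in ("exact", "asymptotic"):
        raise ValueError(f"unknown mode {mode!r}")
    tables = strata.tables
    flags: list[str] = []

    num = sum(t.a * t.d / t.n for t in tables)
    den = sum(t.b * t.c / t.n for t in tables)
    if den == 0 and num == 0:
        flags.append("no-discordant-pairs")
        mh_or = float("nan")
    elif den == 0:
        flags.append("infinite-or")
        mh_or = float("inf")
    else:
        mh_or = num / den

    ci = (float("nan"), float("nan"))
    if np.isfinite(mh_or) and mh_or > 0:
        st = StratifiedTable([np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
                              for t in tables])
        with np.errstate(divide="ignore", invalid="ignore"):
            lo, hi = st.oddsratio_pooled_confint(alpha=0.05)
        if np.isfinite(lo) and np.isfinite(hi):
            ci = (float(lo), float(hi))
        else:
            flags.append("ci-undefined")
    else:
        flags.append("ci-undefined")

    if mode == "exact":
        p = _exact_cmh_p(tables)
        stat = float("nan")
    else:
        stat, p = _asymptotic_cmh(tables)
        if np.isnan(p):
            flags.append("degenerate-variance")
            p = 1.0
    return CMHResult(mh_or=mh_or, ci95=ci, p_value=p, mode=mode,
                     strata_used=len(tables), statistic=stat,
                     flags=tuple(flags))


def geneset_burden_test(qvset: QVSet, genotypes: GenotypeMatrix,
                        catalog: VariantCatalog, collection: GeneSetCollection,
                        groups: pd.Series, mode: str = "exact",
                        stratify_by: str = "gene",
                        fdr_threshold: float = 0.05) -> pd.DataFrame:
    """CMH burden association for every set of a collection.

    Returns one row per gene set with the MH odds ratio, RBG 95% CI,
    p-value, BH q-value (one family = this collection), stratum count
    and a testable flag (false for sets with no QV genes).
    """
    g = groups.dropna().astype(int)
    if min((g == 1).sum(), (g == 0).sum()) < 2:
        raise ValueError("need at least 2 samples per phenotype group")
    profile = burden_profile(qvset, genotypes, catalog, collection)
    rows = []
    for name in collection.names:
        try:
            strata = build_strata(profile, g, name, stratify_by=stratify_by)
            res = cmh_test(strata, mode=mode)
            rows.append({"set": name, "or": res.mh_or, "ci_low": res.ci95[0],
                         "ci_high": res.ci95[1], "p": res.p_value,
                         "strata_used": res.strata_used, "mode": res.mode,
                         "testable": True, "flags": ";".join(res.flags)})
        except (ValueError, KeyError) as err:
            rows.append({"set": name, "or": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p": np.nan, "strata_used": 0,
                         "mode": mode, "testable": False, "flags": str(err)})
    out = pd.DataFrame(rows)
    q, reject = bh_fdr(out["p"].to_numpy(), threshold=fdr_threshold)
    out["q"] = q
    out["significant"] = reject
    return out[["set", "or", "ci_low", "ci_high", "p", "q", "significant",
                "strata_used", "mode", "testable", "flags"]]


def bonferroni_threshold(m_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / m."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return alpha / m_tests


@dataclass
class ScanResult:
    """Exome-wide single-variant association scan output."""

    table: pd.DataFrame  # variant_id, chrom, pos, gene, counts, p
    m_tested: int
    n_skipped: int
    bonferroni: float
    lambda_gc: float
    qq_expected: np.ndarray  # -log10 expected quantiles, sorted ascending p
    qq_observed: np.ndarray

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def exome_wide_scan(catalog: VariantCatalog, genotypes: GenotypeMatrix,
                    groups: pd.Series, alpha: float = 0.05) -> ScanResult:
    """Per-variant carrier Fisher scan against a binary phenotype.

    Variants with zero carriers among phenotyped samples are skipped
    (counted).  QQ expected quantiles are -log10((i - 0.5) / m); the
    genomic-inflation factor is the median observed chi-square quantile
    over the chi-square(1) median.
    """
    g = groups.dropna().astype(int)
    samples = [s for s in genotypes.sample_ids if s in set(g.index)]
    gm = genotypes.reorder_samples(samples)
    grp = g.loc[samples].to_numpy()
    carrier = gm.carrier_matrix()

    rows = []
    n_skipped = 0
    by_id = catalog.by_id()
    for j, vid in enumerate(gm.variant_ids):
        col = carrier[:, j]
        ok = col != MISSING_DOSAGE
        carr = col[ok] == 1
        gg = grp[ok]
        a = int((carr & (gg == 1)).sum())
        c = int((carr & (gg == 0)).sum())
        if a + c == 0:
            n_skipped += 1
            continue
        b = int((~carr & (gg == 1)).sum())
        d = int((~carr & (gg == 0)).sum())
        v = by_id[vid]
        res = fisher_exact((a, b, c, d))
        rows.append({"variant_id": vid, "chrom": v.chrom, "pos": v.pos,
                     "gene": v.gene, "carriers_case": a, "carriers_control": c,
                     "p": res.p_value})
    table = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "gene",
                                        "carriers_case", "carriers_control", "p"])
    m = len(table)
    if m == 0:
        raise ValueError("no testable variants (all zero-carrier)")
    p_sorted = np.sort(table["p"].to_numpy())
    qq_expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)[::-1]
    qq_observed = -np.log10(np.maximum(p_sorted, 1e-300))[::-1]
    chi = sps.chi2.isf(np.minimum(p_sorted, 1.0), 1)
    lambda_gc = float(np.median(chi) / _CHI2_1_MEDIAN)
    return ScanResult(table=table, m_tested=m, n_skipped=n_skipped,
                      bonferroni=bonferroni_threshold(m, alpha),
                      lambda_gc=lambda_gc,
                      qq_expected=qq_expected, qq_observed=qq_observed)
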
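"""Qualifying-variant (QV) selection.

A QV is a rare high-impact variant: consequence in the high-impact
class, population alternate-allele frequency below a threshold (default
0.001) or absent from the reference frequency database, and a cohort
alternate-allele count no greater than a cap chosen to match an
observed minor allele frequency (default 3%) in the analysis cohort.

Every excluded variant carries a machine-readable reason code; reasons
are assigned in a fixed precedence (impact class, then population AF,
then allele-count cap) so they partition the non-qualifying variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .variant_catalog import GenotypeMatrix, ImpactClass, VariantCatalog

__all__ = ["QVConfig", "QVSet", "max_alleles_for_maf", "qualify_variants",
           "REASON_IMPACT", "REASON_AF", "REASON_CAP", "REASON_PASS"]

REASON_PASS = ""
REASON_IMPACT = "impact-class"
REASON_AF = "pop-af"
REASON_CAP = "allele-count-cap"


def max_alleles_for_maf(n_samples: int, target_maf: float = 0.03) -> int:
    """Largest cohort alternate-allele count consistent with a target MAF.

    cap = floor(2 * n_samples * target_maf), at least 1, for a diploid
    cohort.  E.g. 50 samples at MAF <= 3% allow up to 3 alleles and 77
    samples allow up to 4.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not 0.0 < target_maf <= 0.5:
        raise ValueError("target_maf must be in (0, 0.5]")
    return max(1, math.floor(2 * n_samples * target_maf))


@dataclass
class QVConfig:
    """Filter thresholds for qualifying-variant selection."""

    af_max: float = 0.001
    include_missing_af: bool = True
    max_cohort_alt_alleles: int | None = None  # derived from target_maf if None
    target_maf: float = 0.03

    def __post_init__(self) -> None:
        if not 0.0 < self.af_max < 1.0:
            raise ValueError("af_max must be in (0, 1)")
        if self.max_cohort_alt_alleles is not None and self.max_cohort_alt_alleles < 1:
            raise ValueError("allele-count cap must be >= 1")

    def cap_for(self, n_samples: int) -> int:
        if self.max_cohort_alt_alleles is not None:
            return self.max_cohort_alt_alleles
        return max_alleles_for_maf(n_samples, self.target_maf)


@dataclass
class QVSet:
    """The qualifying subset of a catalog with per-variant audit records."""

    records: pd.DataFrame  # variant_id, gene, impact, pop_af, cohort_ac, qualified, reason
    config: QVConfig
    cap: int

    @property
    def variant_ids(self) -> list[str]:
        return self.records.loc[self.records["qualified"], "variant_id"].tolist()

    @property
    def genes(self) -> set[str]:
        return set(self.records.loc[self.records["qualified"], "gene"])

    def __len__(self) -> int:
        return int(self.records["qualified"].sum())

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in set(self.variant_ids)

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def qualify_variants(catalog: VariantCatalog, genotypes: GenotypeMatrix,
                     config: QVConfig | None = None) -> QVSet:
    """Apply the QV rules to an annotated catalog.

    A variant qualifies iff it is high-impact AND (pop_af < af_max, the
    comparison strict, OR pop_af missing when missing AFs are included)
    AND its cohort alternate-allele count (missing calls excluded) is
    <= the cap.  The cohort allele count is computed on the delivered
    genotype matrix, i.e. the analysis cohort after any upstream sample
    exclusions.
    """
    config = config or QVConfig()
    cap = config.cap_for(genotypes.n_samples)
    acs = genotypes.subset_variants(catalog.variant_ids).alt_allele_counts()
    rows = []
    for v, ac in zip(catalog, acs):
        impact = v.impact
        missing = v.pop_af is None or (isinstance(v.pop_af, float) and np.isnan(v.pop_af))
        if impact is not ImpactClass.HI:
            reason = REASON_IMPACT
        elif not (missing and config.include_missing_af) and not (
                not missing and v.pop_af < config.af_max):
            reason = REASON_AF
        elif ac > cap:
            reason = REASON_CAP
        else:
            reason = REASON_PASS
        rows.append({
            "variant_id": v.variant_id,
            "gene": v.gene,
            "impact": impact.value,
            "pop_af": np.nan if missing else float(v.pop_af),
            "cohort_ac": int(ac),
            "qualified": reason == REASON_PASS,
            "reason": reason,
        })
    records = pd.DataFrame(rows, columns=["variant_id", "gene", "impact", "pop_af",
                                          "cohort_ac", "qualified", "reason"])
    return QVSet(records=records, config=config, cap=cap)
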
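"""Annotated variant catalogs for small exome-sequenced cohorts.

Ingests per-cohort variant tables (VCF with per-sample genotypes, or a
flat TSV), decomposes multi-allelic records, classifies each variant by
consequence severity (high-impact / missense / synonymous / other),
variant type (SNV / insertion / deletion) and population allele
frequency bin, and produces the cohort spectrum and overlap summaries
that precede qualifying-variant selection.

Annotation is consumed, never computed: the gene symbol, consequence
term and population AF must already be present as input columns or
INFO fields (VEP/ANNOVAR-style upstream tools produce them).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ImpactClass",
    "VariantType",
    "AFBin",
    "AnnotatedVariant",
    "VariantCatalog",
    "GenotypeMatrix",
    "SpectrumSummary",
    "CatalogFormatError",
    "CatalogIntegrityError",
    "classify_impact",
    "classify_variant_type",
    "af_bin",
    "read_variant_table",
    "write_vcf",
    "write_tsv",
    "summarize_spectrum",
    "cohort_overlap",
    "percentage",
]

MISSING_DOSAGE = -1


class CatalogFormatError(ValueError):
    """Malformed or incomplete input table."""


class CatalogIntegrityError(ValueError):
    """Input violates catalog invariants (e.g. duplicate variant ids)."""


class ImpactClass(str, Enum):
    HI = "HI"
    MISSENSE = "MISSENSE"
    SYNONYMOUS = "SYNONYMOUS"
    OTHER = "OTHER"


class VariantType(str, Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"
    OTHER = "OTHER"  # equal-length multi-base substitutions (MNVs)


class AFBin(str, Enum):
    NO_AF = "no-AF"
    RARE = "rare"               # (0, 0.001)
    LOW_FREQUENCY = "low-frequency"  # [0.001, 0.01)
    COMMON = "common"           # [0.01, 1]


# Consequence terms Ensembl judges severe for protein structure/function.
HI_CONSEQUENCES = frozenset({
    "splice acceptor",
    "splice donor",
    "stop gained",
    "frameshift",
    "stop loss",
    "start loss",
})

MISSENSE_CONSEQUENCES = frozenset({"missense"})
SYNONYMOUS_CONSEQUENCES = frozenset({"synonymous"})

# Synonym map: canonical spelling <- accepted spellings (after lowering and
# replacing underscores with spaces).  Extendable by callers.
DEFAULT_CONSEQUENCE_SYNONYMS: dict[str, str] = {
    "splice acceptor variant": "splice acceptor",
    "acceptor splice": "splice acceptor",
    "splice donor variant": "splice donor",
    "donor splice": "splice donor",
    "stop gained": "stop gained",
    "stopgain": "stop gained",
    "frameshift variant": "frameshift",
    "frameshift": "frameshift",
    "stop lost": "stop loss",
    "stop loss": "stop loss",
    "stoploss": "stop loss",
    "start lost": "start loss",
    "start loss": "start loss",
    "startloss": "start loss",
    "missense variant": "missense",
    "missense": "missense",
    "nonsynonymous snv": "missense",
    "synonymous variant": "synonymous",
    "synonymous": "synonymous",
    "synonymous snv": "synonymous",
}

_IMPACT_SEVERITY = {ImpactClass.HI: 3, ImpactClass.MISSENSE: 2,
                    ImpactClass.SYNONYMOUS: 1, ImpactClass.OTHER: 0}


def classify_impact(consequence: str,
                    synonyms: dict[str, str] | None = None) -> ImpactClass:
    """Map a controlled consequence term to an impact class.

    Unrecognized terms — including severe-looking ones not on the
    high-impact list — map to OTHER, never silently to HI.
    """
    if consequence is None or not str(consequence).strip():
        raise ValueError("empty consequence term")
    table = DEFAULT_CONSEQUENCE_SYNONYMS if synonyms is None else synonyms
    norm = str(consequence).strip().lower().replace("_", " ")
    canon = table.get(norm, norm)
    if canon in HI_CONSEQUENCES:
        return ImpactClass.HI
    if canon in MISSENSE_CONSEQUENCES:
        return ImpactClass.MISSENSE
    if canon in SYNONYMOUS_CONSEQUENCES:
        return ImpactClass.SYNONYMOUS
    return ImpactClass.OTHER


def classify_variant_type(ref: str, alt: str) -> VariantType:
    if not ref or not alt:
        raise ValueError("ref and alt alleles must be non-empty")
    if len(ref) == 1 and len(alt) == 1:
        return VariantType.SNV
    if len(alt) > len(ref):
        return VariantType.INSERTION
    if len(alt) < len(ref):
        return VariantType.DELETION
    warnings.warn(f"equal-length multi-base substitution {ref}>{alt} classified OTHER")
    return VariantType.OTHER


def af_bin(pop_af: float | None,
           rare_max: float = 0.001, low_max: float = 0.01) -> AFBin:
    """Assign a population AF (or missing) to its frequency bin.

    Bins partition [0,1] plus the missing state:
    missing | (0, rare_max) | [rare_max, low_max) | [low_max, 1].
    An AF of exactly 0 counts as rare (absent from the reference at
    frequency below the rare bound).
    """
    if pop_af is None or (isinstance(pop_af, float) and np.isnan(pop_af)):
        return AFBin.NO_AF
    af = float(pop_af)
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"population AF out of [0,1]: {af}")
    if af < rare_max:
        return AFBin.RARE
    if af < low_max:
        return AFBin.LOW_FREQUENCY
    return AFBin.COMMON


@dataclass(frozen=True)
class AnnotatedVariant:
    """One decomposed variant site with its annotation."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    pop_af: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.alt == self.ref:
            raise ValueError(f"alt equals ref at {self.chrom}:{self.pos}")
        if self.pop_af is not None and not np.isnan(self.pop_af):
            if not 0.0 <= self.pop_af <= 1.0:
                raise ValueError(f"pop_af out of [0,1]: {self.pop_af}")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def impact(self) -> ImpactClass:
        return classify_impact(self.consequence)

    @property
    def variant_type(self) -> VariantType:
        return classify_variant_type(self.ref, self.alt)


class VariantCatalog(Sequence):
    """Ordered, id-unique collection of :class:`AnnotatedVariant`.

    Tracks the pre-decomposition source record count so spectrum
    summaries can report both totals.
    """

    def __init__(self, variants: Iterable[AnnotatedVariant],
                 n_source_records: int | None = None) -> None:
        self.variants: list[AnnotatedVariant] = list(variants)
        seen: set[str] = set()
        for v in self.variants:
            if v.variant_id in seen:
                raise CatalogIntegrityError(f"duplicate variant_id {v.variant_id}")
            seen.add(v.variant_id)
        self.n_source_records = (len(self.variants) if n_source_records is None
                                 else n_source_records)

    def __len__(self) -> int:
        return len(self.variants)

    def __getitem__(self, i):
        return self.variants[i]

    def __iter__(self) -> Iterator[AnnotatedVariant]:
        return iter(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def by_id(self) -> dict[str, AnnotatedVariant]:
        return {v.variant_id: v for v in self.variants}

    def genes(self) -> set[str]:
        return {v.gene for v in self.variants}


@dataclass
class GenotypeMatrix:
    """Samples x variants alternate-allele dosage matrix.

    Dosage is 0/1/2 with ``MISSING_DOSAGE`` (-1) for no-calls.  Cohort
    allele counts are sums over non-missing dosages only.
    """

    sample_ids: list[str]
    variant_ids: list[str]
    dosage: np.ndarray  # shape (n_samples, n_variants), int8

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError("dosage shape does not match id lists")
        bad = ~np.isin(self.dosage, [MISSING_DOSAGE, 0, 1, 2])
        if bad.any():
            raise ValueError("dosage values must be in {-1, 0, 1, 2}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise CatalogIntegrityError("duplicate sample ids")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise CatalogIntegrityError("duplicate variant ids")
        self._vidx = {vid: j for j, vid in enumerate(self.variant_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosage[:, self._vidx[variant_id]]

    def alt_allele_counts(self) -> np.ndarray:
        """Cohort alternate-allele count per variant (missing excluded)."""
        d = self.dosage.astype(np.int64)
        return np.where(d >= 0, d, 0).sum(axis=0)

    def carrier_matrix(self) -> np.ndarray:
        """Dominant-model carrier indicator; MISSING_DOSAGE propagates as -1."""
        out = np.where(self.dosage >= 1, 1, 0).astype(np.int8)
        out[self.dosage == MISSING_DOSAGE] = MISSING_DOSAGE
        return out

    def subset_variants(self, variant_ids: Sequence[str]) -> "GenotypeMatrix":
        cols = [self._vidx[v] for v in variant_ids]
        return GenotypeMatrix(list(self.sample_ids), list(variant_ids),
                              self.dosage[:, cols])

    def reorder_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        sidx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [sidx[s] for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), list(self.variant_ids),
                              self.dosage[rows, :])


def percentage(count: int, total: int) -> float:
    """Share of total as a percent, rounded half-up to two decimals."""
    if total <= 0:
        return float("nan")
    share = Decimal(count) / Decimal(total) * Decimal(100)
    return float(share.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Input / output
# ---------------------------------------------------------------------------

_TSV_REQUIRED = ("chrom", "pos", "ref", "alt", "gene", "consequence")


def _parse_af(value) -> float | None:
    if value is None:
        return None
    s = str(value).strip()
    if s in ("", ".", "NA", "nan", "None"):
        return None
    af = float(s)
    if np.isnan(af):
        return None
    return af


def _resolve_duplicates(records: list[tuple[AnnotatedVariant, np.ndarray]],
                        on_duplicate: str):
    by_id: dict[str, tuple[AnnotatedVariant, np.ndarray]] = {}
    for var, dos in records:
        vid = var.variant_id
        if vid not in by_id:
            by_id[vid] = (var, dos)
            continue
        if on_duplicate == "error":
            raise CatalogIntegrityError(f"duplicate variant_id {vid}")
        if on_duplicate == "most_severe":
            old, old_dos = by_id[vid]
            if _IMPACT_SEVERITY[var.impact] > _IMPACT_SEVERITY[old.impact]:
                by_id[vid] = (var, old_dos)
        else:
            raise ValueError(f"unknown on_duplicate policy {on_duplicate!r}")
    return list(by_id.values())


def read_variant_table(path: str | Path, format: str = "vcf", *,
                       gene_field: str = "GENE",
                       consequence_field: str = "CONSEQ",
                       af_field: str = "POP_AF",
                       on_duplicate: str = "error",
                       ) -> tuple[VariantCatalog, GenotypeMatrix]:
    """Read an annotated per-cohort variant table.

    VCF input: annotation is taken from INFO fields (names configurable;
    per-alternate-allele values may be comma-separated).  Multi-allelic
    records are decomposed into one variant per alternate allele, with
    per-allele dosages from the genotype calls.  TSV input: one row per
    decomposed variant with columns chrom, pos, ref, alt, gene,
    consequence, optional pop_af, and one dosage column per sample
    ('.' or empty = missing call).

    ``on_duplicate`` resolves conflicting annotations for the same
    variant id: "error" (default) or "most_severe".
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path, gene_field, consequence_field, af_field, on_duplicate)
    if format == "tsv":
        return _read_tsv(path, on_duplicate)
    raise ValueError(f"unknown format {format!r}")


def _per_alt(value, n_alt: int, record: str):
    """Expand an INFO value to a per-alternate-allele list."""
    if value is None:
        return [None] * n_alt
    if isinstance(value, (tuple, list, np.ndarray)):
        vals = list(value)
    else:
        vals = str(value).split(",") if isinstance(value, str) else [value]
    if len(vals) == 1 and n_alt > 1:
        vals = vals * n_alt
    if len(vals) != n_alt:
        raise CatalogFormatError(
            f"annotation cardinality mismatch at {record}: "
            f"{len(vals)} values for {n_alt} alternate alleles")
    return vals


def _read_vcf(path: Path, gene_field: str, consequence_field: str,
              af_field: str, on_duplicate: str):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[tuple[AnnotatedVariant, np.ndarray]] = []
    n_source = 0
    for rec in vcf:
        n_source += 1
        alts = list(rec.ALT)
        where = f"{rec.CHROM}:{rec.POS}"
        genes = _per_alt(rec.INFO.get(gene_field), len(alts), where)
        conseqs = _per_alt(rec.INFO.get(consequence_field), len(alts), where)
        afs = _per_alt(rec.INFO.get(af_field), len(alts), where)
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        for k, alt in enumerate(alts):
            gene, conseq = genes[k], conseqs[k]
            if gene is None:
                raise CatalogFormatError(
                    f"missing mandatory annotation field {gene_field!r} at {where}")
            if conseq is None:
                raise CatalogFormatError(
                    f"missing mandatory annotation field {consequence_field!r} at {where}")
            dosage = np.empty(len(samples), dtype=np.int8)
            for i, gt in enumerate(gts):
                alleles = gt[:-1]
                if any(a < 0 for a in alleles):
                    dosage[i] = MISSING_DOSAGE
                else:
                    dosage[i] = sum(1 for a in alleles if a == k + 1)
            var = AnnotatedVariant(chrom=str(rec.CHROM), pos=int(rec.POS),
                                   ref=str(rec.REF), alt=str(alt),
                                   gene=str(gene), consequence=str(conseq),
                                   pop_af=_parse_af(afs[k]))
            records.append((var, dosage))
    resolved = _resolve_duplicates(records, on_duplicate)
    catalog = VariantCatalog([v for v, _ in resolved], n_source_records=n_source)
    dosage = (np.stack([d for _, d in resolved], axis=1)
              if resolved else np.zeros((len(samples), 0), dtype=np.int8))
    return catalog, GenotypeMatrix(samples, catalog.variant_ids, dosage)


def _read_tsv(path: Path, on_duplicate: str):
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in _TSV_REQUIRED:
        if col not in df.columns:
            raise CatalogFormatError(f"missing mandatory column {col!r}")
    sample_cols = [c for c in df.columns if c not in _TSV_REQUIRED + ("pop_af",)]
    records: list[tuple[AnnotatedVariant, np.ndarray]] = []
    for _, row in df.iterrows():
        var = AnnotatedVariant(chrom=row["chrom"], pos=int(row["pos"]),
                               ref=row["ref"], alt=row["alt"], gene=row["gene"],
                               consequence=row["consequence"],
                               pop_af=_parse_af(row.get("pop_af")))
        dosage = np.array([MISSING_DOSAGE if str(row[s]).strip() in ("", ".", "nan")
                           else int(row[s]) for s in sample_cols], dtype=np.int8)
        records.append((var, dosage))
    resolved = _resolve_duplicates(records, on_duplicate)
    catalog = VariantCatalog([v for v, _ in resolved], n_source_records=len(df))
    dosage = (np.stack([d for _, d in resolved], axis=1)
              if resolved else np.zeros((len(sample_cols), 0), dtype=np.int8))
    return catalog, GenotypeMatrix(sample_cols, catalog.variant_ids, dosage)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING_DOSAGE: "./."}


def write_vcf(catalog: VariantCatalog, genotypes: GenotypeMatrix,
              path: str | Path, *, gene_field: str = "GENE",
              consequence_field: str = "CONSEQ", af_field: str = "POP_AF") -> None:
    """Write a decomposed catalog as a plain-text VCF v4.2."""
    path = Path(path)
    chroms = sorted({v.chrom for v in catalog}, key=str)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(f'##INFO=<ID={gene_field},Number=1,Type=String,Description="Gene symbol">\n')
        fh.write(f'##INFO=<ID={consequence_field},Number=1,Type=String,'
                 'Description="Consequence term">\n')
        fh.write(f'##INFO=<ID={af_field},Number=1,Type=Float,'
                 'Description="Population alternate allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.sample_ids) + "\n")
        for v in catalog:
            conseq = v.consequence.replace(" ", "_")
            info = f"{gene_field}={v.gene};{consequence_field}={conseq}"
            if v.pop_af is not None:
                info += f";{af_field}={v.pop_af:.6g}"
            gts = "\t".join(_GT_STRINGS[int(d)] for d in genotypes.column(v.variant_id))
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\tGT\t{gts}\n")


def write_tsv(catalog: VariantCatalog, genotypes: GenotypeMatrix,
              path: str | Path) -> None:
    """Write a decomposed catalog + dosages as a flat TSV."""
    rows = []
    for v in catalog:
        row = {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
               "gene": v.gene, "consequence": v.consequence,
               "pop_af": "" if v.pop_af is None else f"{v.pop_af:.6g}"}
        for s, d in zip(genotypes.sample_ids, genotypes.column(v.variant_id)):
            row[s] = "." if d == MISSING_DOSAGE else int(d)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass
class SpectrumSummary:
    """Cohort variant-spectrum summary (counts, shares, singletons)."""

    n_unique_variants: int
    n_source_records: int
    class_counts: dict[str, int]
    class_percent: dict[str, float]
    af_bin_counts: dict[str, int]
    singleton_af_bin_counts: dict[str, int]
    type_af_bin_counts: dict[str, dict[str, int]]
    n_singletons: int
    flags: tuple[str, ...] = ()

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2, default=str, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def to_frame(self) -> pd.DataFrame:
        rows = [{"section": "class", "key": k, "count": c,
                 "percent": self.class_percent[k]}
                for k, c in self.class_counts.items()]
        rows += [{"section": "af_bin", "key": k, "count": c, "percent": np.nan}
                 for k, c in self.af_bin_counts.items()]
        rows += [{"section": "singleton_af_bin", "key": k, "count": c,
                  "percent": np.nan}
                 for k, c in self.singleton_af_bin_counts.items()]
        for vt, bins in self.type_af_bin_counts.items():
            rows += [{"section": f"type:{vt}", "key": k, "count": c,
                      "percent": np.nan} for k, c in bins.items()]
        return pd.DataFrame(rows)


def summarize_spectrum(catalog: VariantCatalog,
                       genotypes: GenotypeMatrix | None = None) -> SpectrumSummary:
    """Count variants by impact class, AF bin and type; find singletons.

    Percentages are of total unique (decomposed) variants, rounded
    half-up to two decimals.  A singleton is a variant whose cohort
    alternate-allele count is exactly 1 (requires genotypes).
    """
    total = len(catalog)
    flags: list[str] = []
    class_counts = {c.value: 0 for c in ImpactClass}
    bin_counts = {b.value: 0 for b in AFBin}
    singleton_bins = {b.value: 0 for b in AFBin}
    type_bins = {t.value: {b.value: 0 for b in AFBin} for t in VariantType}
    for v in catalog:
        class_counts[v.impact.value] += 1
        b = af_bin(v.pop_af).value
        bin_counts[b] += 1
        type_bins[v.variant_type.value][b] += 1
    n_singletons = 0
    if genotypes is not None and total:
        acs = genotypes.subset_variants(catalog.variant_ids).alt_allele_counts()
        for v, ac in zip(catalog, acs):
            if ac == 1:
                n_singletons += 1
                singleton_bins[af_bin(v.pop_af).value] += 1
    if total == 0:
        flags.append("empty-catalog")
        class_percent = {k: float("nan") for k in class_counts}
    else:
        class_percent = {k: percentage(c, total) for k, c in class_counts.items()}
    return SpectrumSummary(
        n_unique_variants=total,
        n_source_records=catalog.n_source_records,
        class_counts=class_counts,
        class_percent=class_percent,
        af_bin_counts=bin_counts,
        singleton_af_bin_counts=singleton_bins,
        type_af_bin_counts=type_bins,
        n_singletons=n_singletons,
        flags=tuple(flags),
    )


def cohort_overlap(catalog_a: Iterable, catalog_b: Iterable,
                   key: str = "variant_id") -> dict[str, int]:
    """Counts of unique keys private to each cohort and shared.

    ``key`` is "variant_id" or "gene"; catalogs may also be plain
    iterables of keys.
    """
    def keys(cat) -> set[str]:
        out = set()
        for item in cat:
            if isinstance(item, AnnotatedVariant):
                out.add(getattr(item, key))
            else:
                out.add(str(item))
        return out

    ka, kb = keys(catalog_a), keys(catalog_b)
    return {"a_only": len(ka - kb), "shared": len(ka & kb), "b_only": len(kb - ka)}
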
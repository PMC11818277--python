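"""Gene-set collections (GMT) and per-person QV burden profiles.

Reads Broad-dialect GMT files (set name, description, tab-separated
gene symbols), supports overlap algebra over named sets, restricts a
collection to genes actually harboring qualifying variants in a cohort,
and builds the per-person burden profile used by the collapsing
association tests: for each (sample, gene set) the number of distinct
QV sites at which the sample carries at least one alternate allele
(dominant model: a homozygous site counts once), and per-gene carrier
indicators for stratified tables.

Gene symbol matching is case-sensitive exact match after whitespace
strip; alias resolution is an upstream concern.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .qv_selection import QVSet
from .variant_catalog import (
    MISSING_DOSAGE,
    GenotypeMatrix,
    VariantCatalog,
)

__all__ = ["GeneSet", "GeneSetCollection", "BurdenProfile",
           "read_gmt", "write_gmt", "collection_overlap",
           "restrict_to_qv_genes", "burden_profile", "GMTParseError"]


class GMTParseError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate genes within set {self.name!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


class GeneSetCollection:
    """Ordered mapping of unique set names to :class:`GeneSet`."""

    def __init__(self, sets: Iterable[GeneSet]) -> None:
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            if s.name in self._sets:
                raise ValueError(f"duplicate set name {s.name!r}")
            self._sets[s.name] = s

    @classmethod
    def from_dict(cls, d: dict[str, Sequence[str]],
                  descriptions: dict[str, str] | None = None) -> "GeneSetCollection":
        descriptions = descriptions or {}
        return cls(GeneSet(name, descriptions.get(name, ""), tuple(dict.fromkeys(genes)))
                   for name, genes in d.items())

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        if name not in self._sets:
            raise KeyError(f"unknown gene set {name!r}")
        return self._sets[name]

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def genes(self, name: str) -> set[str]:
        return set(self[name].genes)

    def union(self) -> set[str]:
        out: set[str] = set()
        for s in self:
            out |= set(s.genes)
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self._sets == other._sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name <TAB> description <TAB> gene [<TAB> gene ...].

    Duplicate genes within a set are removed with a warning; empty sets
    and malformed lines are rejected with the offending line number.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path.name}:{lineno}: expected name, description and at "
                    f"least one gene, got {len(fields)} field(s)")
            name, description = fields[0].strip(), fields[1].strip()
            if not name:
                raise GMTParseError(f"{path.name}:{lineno}: empty set name")
            genes = [g.strip() for g in fields[2:] if g.strip()]
            if not genes:
                raise GMTParseError(f"{path.name}:{lineno}: set {name!r} has no genes")
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                warnings.warn(f"{path.name}:{lineno}: duplicate genes in set "
                              f"{name!r} removed")
            sets.append(GeneSet(name, description, tuple(unique)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def collection_overlap(collection: GeneSetCollection,
                       set_names: Sequence[str]) -> dict[tuple[str, ...], int]:
    """Exclusive-region gene counts for the named sets (Venn regions).

    Keys are tuples of the set names a region belongs to (in input
    order); values are counts of genes exactly in those sets and no
    others among ``set_names``.  Region counts sum to the union size.
    """
    members = {name: collection.genes(name) for name in set_names}
    union = set().union(*members.values()) if set_names else set()
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(set_names) + 1):
        for combo in itertools.combinations(set_names, r):
            inside = set.intersection(*(members[n] for n in combo))
            outside = set().union(*(members[n] for n in set_names if n not in combo)) \
                if len(combo) < len(set_names) else set()
            regions[combo] = len(inside - outside)
    assert sum(regions.values()) == len(union)
    return regions


def restrict_to_qv_genes(collection: GeneSetCollection, qvset: QVSet,
                         catalog: VariantCatalog | None = None
                         ) -> GeneSetCollection:
    """Reduce each set to genes harboring at least one QV in the cohort.

    Empty restricted sets are kept (flagged by their zero size) so the
    association stage can report them as untestable.  The operation is
    idempotent.
    """
    qv_genes = qvset.genes
    restricted = []
    for s in collection:
        kept = tuple(g for g in s.genes if g in qv_genes)
        restricted.append(GeneSet(s.name, s.description, kept))
    return GeneSetCollection(restricted)


@dataclass
class BurdenProfile:
    """Per-person QV burden per gene set, plus per-gene/per-site carriers.

    qv_count[(sample, set)] is the number of distinct QV sites in the
    set's genes at which the sample carries >= 1 alternate allele
    (or the dosage sum in "dosage" mode).  carrier = qv_count >= 1.
    A sample whose QV genotypes are all missing within a unit gets a
    missing (NaN) count there.
    """

    qv_count: pd.DataFrame        # samples x sets (float; NaN = all-missing)
    carrier: pd.DataFrame         # samples x sets (boolean, NaN = all-missing)
    gene_carrier: pd.DataFrame    # samples x genes-with-QVs
    variant_carrier: pd.DataFrame  # samples x QV variant ids
    variant_gene: dict[str, str]  # QV variant id -> gene
    genes_by_set: dict[str, list[str]]
    mode: str = "carrier"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.qv_count.index)

    def to_tsv(self, path: str | Path) -> None:
        long = (self.qv_count.stack().rename("qv_count").reset_index())
        long.columns = ["sample_id", "set_name", "qv_count"]
        long["carrier"] = self.carrier.stack().to_numpy()
        long.to_csv(path, sep="\t", index=False)


def burden_profile(qvset: QVSet, genotypes: GenotypeMatrix,
                   catalog: VariantCatalog, collection: GeneSetCollection,
                   mode: str = "carrier") -> BurdenProfile:
    """Build per-person burden counts and carrier flags.

    ``mode`` "carrier" counts distinct QV sites with dosage >= 1 (the
    dominant model); "dosage" sums allele dosages instead (sensitivity
    analysis).  Missing genotypes are excluded; a sample missing at
    every QV of a unit is flagged missing for that unit.
    """
    if mode not in ("carrier", "dosage"):
        raise ValueError(f"unknown mode {mode!r}")
    by_id = catalog.by_id()
    qv_ids = [vid for vid in qvset.variant_ids if vid in by_id]
    variant_gene = {vid: by_id[vid].gene for vid in qv_ids}
    samples = list(genotypes.sample_ids)

    if qv_ids:
        sub = genotypes.subset_variants(qv_ids)
        dos = sub.dosage.astype(float)
        dos[dos == MISSING_DOSAGE] = np.nan
        site = np.where(np.isnan(dos), np.nan, (dos >= 1).astype(float)) \
            if mode == "carrier" else dos
    else:
        site = np.zeros((len(samples), 0))

    site_df = pd.DataFrame(site, index=samples, columns=qv_ids)
    variant_carrier = pd.DataFrame(
        np.where(np.isnan(site), np.nan, (site >= 1).astype(float)),
        index=samples, columns=qv_ids)

    genes = sorted(set(variant_gene.values()))
    gene_cols = {}
    for g in genes:
        vids = [vid for vid in qv_ids if variant_gene[vid] == g]
        block = variant_carrier[vids]
        any_carrier = (block >= 1).any(axis=1)
        all_missing = block.isna().all(axis=1)
        gene_cols[g] = np.where(all_missing, np.nan, any_carrier.astype(float))
    gene_carrier = pd.DataFrame(gene_cols, index=samples, columns=genes,
                                dtype=float)

    counts = {}
    carriers = {}
    genes_by_set: dict[str, list[str]] = {}
    for s in collection:
        vids = [vid for vid in qv_ids if variant_gene[vid] in set(s.genes)]
        genes_by_set[s.name] = sorted({variant_gene[v] for v in vids})
        if not vids:
            counts[s.name] = np.zeros(len(samples))
            carriers[s.name] = np.zeros(len(samples))
            continue
        block = site_df[vids]
        total = block.sum(axis=1, min_count=1)  # NaN when all missing
        counts[s.name] = total.to_numpy(dtype=float)
        carriers[s.name] = np.where(np.isnan(total), np.nan,
                                    (total >= 1).astype(float))
    qv_count = pd.DataFrame(counts, index=samples, columns=collection.names,
                            dtype=float)
    carrier = pd.DataFrame(carriers, index=samples, columns=collection.names,
                           dtype=float)
    return BurdenProfile(qv_count=qv_count, carrier=carrier,
                         gene_carrier=gene_carrier,
                         variant_carrier=variant_carrier,
                         variant_gene=variant_gene,
                         genes_by_set=genes_by_set, mode=mode)
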
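"""Synthetic exome cohorts with known ground truth.

Generates everything the pipeline consumes — an annotated variant
catalog with per-sample genotypes (VCF), gene-set collections (GMT),
and per-sample phenotype tables with longitudinal RBC panels (TSV) —
from a single seeded configuration, together with a ground-truth
record sufficient to score recovery of every planted signal.

What is emulated: a small critically-ill cohort (tens of diploid
samples), an exome-like variant spectrum with a small high-impact
class and a configurable fraction of variants absent from the
reference frequency database, gene sets with planted carrier odds
ratios on a binary anemia-like phenotype, and RBC endpoints with
linear (standardized) genetic effects plus covariate effects and
noise.  What is not: linkage disequilibrium, population structure and
sequencing error are deliberately absent.

The binary phenotype follows a logistic model on the number of
planted-set genes a person carries qualifying variants in (carrier
indicators per gene, summed).  Per-gene carrier exposure keeps the
gene-stratified CMH common odds ratio equal to the planted odds ratio
up to negligible non-collapsibility; a set-level 0/1 exposure would
attenuate it.  A count-based (qv_count) liability mode exists for
regression-oriented simulations via the endpoint effects, which are
linear in the per-person QV count.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .gene_sets import GeneSet, GeneSetCollection, write_gmt
from .qv_selection import max_alleles_for_maf
from .variant_catalog import (
    AnnotatedVariant,
    GenotypeMatrix,
    VariantCatalog,
    write_vcf,
)

__all__ = ["PlantedSet", "SimConfig", "SimulatedCohort", "simulate_cohort",
           "simulate_rbc_series", "RBC_PARAMS"]

# population-style means and SDs per panel parameter (units as labelled)
RBC_PARAMS: dict[str, tuple[float, float]] = {
    "RBC": (4.3, 0.55),    # 10^12/L
    "HGB": (118.0, 18.0),  # g/L
    "HCT": (0.37, 0.05),   # fraction
    "MCV": (90.0, 5.5),    # fL
    "MCH": (29.5, 2.2),    # pg
    "MCHC": (330.0, 12.0),  # g/L
    "RDW": (14.0, 1.6),    # %
}

_HI_TERMS = ("stop_gained", "frameshift_variant", "splice_acceptor_variant",
             "splice_donor_variant", "stop_lost", "start_lost")
_SCALES = ("GCS", "CRS-R", "DRS", "FOUR", "mRS")


@dataclass(frozen=True)
class PlantedSet:
    """A gene set with a planted carrier odds ratio on the phenotype."""

    name: str
    n_genes: int = 10
    carrier_or: float = 1.0
    qv_sites_per_gene: int = 8
    qv_af: float = 9e-4          # < 0.001, so sites qualify as rare
    n_overlap: int = 0           # genes shared with the previous set
    n_background_members: int = 3  # background genes also listed in the set

    def __post_init__(self) -> None:
        if self.carrier_or <= 0:
            raise ValueError("carrier OR must be positive")
        if not 0 < self.qv_af < 1:
            raise ValueError("qv_af must be in (0, 1)")


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate a TBI-style rehabilitation cohort: 50 diploid
    samples, an exome-like spectrum with ~2% high-impact variants, a
    quarter of variants absent from the reference AF database, four
    hematology-flavoured gene sets of which the GO-derived and Notch
    pathway sets carry a planted carrier OR of 2.5 on a binary
    anemia-like phenotype of prevalence 0.5, and a standardized
    genetic effect of -0.4 on MCHC through the GO-derived set count.
    """

    seed: int
    n_samples: int = 50
    n_background_genes: int = 120
    mean_variants_per_gene: float = 12.0
    impact_mix: tuple[tuple[str, float], ...] = (
        ("HI", 0.02), ("MISSENSE", 0.40), ("SYNONYMOUS", 0.35), ("OTHER", 0.23))
    af_point_masses: tuple[tuple[float, float], ...] = (
        (5e-5, 0.35), (5e-4, 0.20), (5e-3, 0.20), (0.05, 0.15), (0.30, 0.10))
    missing_af_fraction: float = 0.25
    variant_type_mix: tuple[tuple[str, float], ...] = (
        ("SNV", 0.90), ("insertion", 0.05), ("deletion", 0.05))
    planted_sets: tuple[PlantedSet, ...] = (
        PlantedSet("GO_derived", n_genes=12, carrier_or=2.5),
        PlantedSet("GWAS_derived", n_genes=15, carrier_or=1.0,
                   qv_sites_per_gene=6, n_overlap=4),
        PlantedSet("HPO_derived", n_genes=15, carrier_or=1.0,
                   qv_sites_per_gene=6, n_overlap=3),
        PlantedSet("hsa04330", n_genes=8, carrier_or=2.5, n_overlap=2),
    )
    prevalence: float = 0.5
    # standardized endpoint effects: parameter -> (gene set, beta per SD of qv_count)
    endpoint_genetic_effects: tuple[tuple[str, str, float], ...] = (
        ("MCHC", "GO_derived", -0.4),)
    age_beta: float = -0.10
    sex_betas: tuple[tuple[str, float], ...] = (
        ("RBC", -0.25), ("HGB", -0.25), ("HCT", -0.25))
    outcome_betas: tuple[tuple[str, float], ...] = (
        ("RBC", -0.45), ("HGB", -0.45), ("HCT", -0.45), ("MCHC", -0.45),
        ("RDW", 0.45))
    severity_betas: tuple[tuple[str, float], ...] = (
        ("RBC", -0.25), ("HGB", -0.25), ("HCT", -0.25), ("MCHC", -0.25),
        ("RDW", 0.25))
    worst_dip_sd: float = 0.15   # extra dip below min(first, final), SD units
    n_timepoints: int = 5
    interior_missing_rate: float = 0.05
    male_fraction: float = 0.70
    include_scale_scores: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        mix = dict(self.impact_mix)
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("impact mix proportions must sum to 1")
        if abs(sum(p for _, p in self.af_point_masses) - 1.0) > 1e-9:
            raise ValueError("AF point-mass probabilities must sum to 1")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.n_timepoints not in (2, 3, 5):
            raise ValueError("n_timepoints must be 2, 3 or 5")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SimulatedCohort:
    """In-memory simulated cohort plus its ground truth."""

    config: SimConfig
    catalog: VariantCatalog
    genotypes: GenotypeMatrix
    collection: GeneSetCollection
    pheno: pd.DataFrame          # long format: one row per (sample, timestamp)
    samples: pd.DataFrame        # static per-sample covariates + phenotype
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write VCF, GMT, phenotype TSV, truth JSON and a manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "cohort.vcf",
            "gmt": outdir / "sets.gmt",
            "pheno": outdir / "pheno.tsv",
            "truth": outdir / "truth.json",
            "manifest": outdir / "manifest.json",
        }
        write_vcf(self.catalog, self.genotypes, paths["vcf"])
        write_gmt(self.collection, paths["gmt"])
        merged = self.pheno.merge(self.samples.reset_index(), on="sample_id")
        merged.to_csv(paths["pheno"], sep="\t", index=False, float_format="%.10g")
        paths["truth"].write_text(json.dumps(self.truth, indent=2, sort_keys=True))
        manifest = {
            "seed": self.config.seed,
            "config_hash": self.config.config_hash(),
            "files": {k: _sha256(p) for k, p in paths.items() if k != "manifest"},
        }
        paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return paths


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _draw_variants(rng: np.random.Generator, cfg: SimConfig):
    """Lay out planted and background variants with true AFs and classes."""
    rows = []  # dicts: gene, impact, true_af, pop_af (None = missing), planted
    planted_genes: dict[str, list[str]] = {}
    prev_genes: list[str] = []
    for ps in cfg.planted_sets:
        shared = prev_genes[:ps.n_overlap]
        own = [f"{ps.name}:G{i:02d}" for i in range(ps.n_genes - len(shared))]
        genes = shared + own
        planted_genes[ps.name] = genes
        for g in own:  # shared genes already carry sites from the earlier set
            for _ in range(ps.qv_sites_per_gene):
                rows.append({"gene": g, "impact": "HI", "true_af": ps.qv_af,
                             "pop_af": ps.qv_af, "planted": True})
        prev_genes = genes
    classes, probs = zip(*cfg.impact_mix)
    afs, af_probs = zip(*cfg.af_point_masses)
    ultra_rare = 1.0 / (4.0 * cfg.n_samples)
    bg_genes = [f"BG{i:04d}" for i in range(cfg.n_background_genes)]
    n_per_gene = np.maximum(rng.poisson(cfg.mean_variants_per_gene,
                                        size=cfg.n_background_genes), 1)
    for g, n_var in zip(bg_genes, n_per_gene):
        cls = rng.choice(classes, size=n_var, p=probs)
        af = rng.choice(afs, size=n_var, p=af_probs)
        miss = rng.random(n_var) < cfg.missing_af_fraction
        for k in range(n_var):
            true_af = ultra_rare if miss[k] else float(af[k])
            rows.append({"gene": g, "impact": str(cls[k]), "true_af": true_af,
                         "pop_af": None if miss[k] else float(af[k]),
                         "planted": False})
    return rows, planted_genes, bg_genes


_CONSEQ_FOR = {"MISSENSE": "missense_variant", "SYNONYMOUS": "synonymous_variant",
               "OTHER": "intron_variant"}
_ALLELES = {"SNV": ("A", "G"), "insertion": ("A", "AT"), "deletion": ("AC", "A")}


def _build_catalog(rng: np.random.Generator, cfg: SimConfig, rows: list[dict]):
    types, type_probs = zip(*cfg.variant_type_mix)
    drawn_types = rng.choice(types, size=len(rows), p=type_probs)
    variants = []
    hi_cycle = 0
    for i, (row, vt) in enumerate(zip(rows, drawn_types)):
        if row["impact"] == "HI":
            conseq = _HI_TERMS[hi_cycle % len(_HI_TERMS)]
            hi_cycle += 1
        else:
            conseq = _CONSEQ_FOR[row["impact"]]
        ref, alt = _ALLELES[str(vt)]
        chrom = str(1 + (i % 22))
        pos = 1000 + 10 * i
        variants.append(AnnotatedVariant(
            chrom=chrom, pos=pos, ref=ref, alt=alt, gene=row["gene"],
            consequence=conseq, pop_af=row["pop_af"]))
    return variants


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Draw a full synthetic cohort from one seeded configuration.

    Genotypes are independent per-variant binomial(2, true AF) draws;
    the binary phenotype follows the logistic planted-set model; RBC
    panels carry linear standardized genetic and covariate effects.
    An identical seed reproduces byte-identical output files.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    rows, planted_genes, bg_genes = _draw_variants(rng, cfg)
    variants = _build_catalog(rng, cfg, rows)
    catalog = VariantCatalog(variants)
    true_af = np.array([r["true_af"] for r in rows])
    dosage = rng.binomial(2, true_af[None, :],
                          size=(cfg.n_samples, len(rows))).astype(np.int8)
    sample_ids = [f"S{i:04d}" for i in range(cfg.n_samples)]
    genotypes = GenotypeMatrix(sample_ids, catalog.variant_ids, dosage)

    # generator-side QV determination (the rules the pipeline applies)
    cap = max_alleles_for_maf(cfg.n_samples, 0.03)
    ac = dosage.astype(np.int64).sum(axis=0)
    impact = np.array([r["impact"] for r in rows])
    pop_af = np.array([np.nan if r["pop_af"] is None else r["pop_af"]
                       for r in rows])
    af_ok = np.isnan(pop_af) | (pop_af < 0.001)
    is_qv = (impact == "HI") & af_ok & (ac <= cap)

    # gene sets: planted genes + a few background members
    sets = []
    bg_cursor = 0
    for ps in cfg.planted_sets:
        extra = bg_genes[bg_cursor:bg_cursor + ps.n_background_members]
        bg_cursor += ps.n_background_members
        sets.append(GeneSet(ps.name, f"synthetic {ps.name}",
                            tuple(planted_genes[ps.name] + extra)))
    collection = GeneSetCollection(sets)

    genes_arr = np.array([r["gene"] for r in rows])
    carrier = dosage >= 1

    def gene_carrier_count(set_genes: Sequence[str], qv_only: np.ndarray
                           ) -> np.ndarray:
        """Per-sample count of set genes carrying >= 1 qualifying site."""
        count = np.zeros(cfg.n_samples, dtype=int)
        for g in set_genes:
            cols = (genes_arr == g) & qv_only
            if cols.any():
                count += carrier[:, cols].any(axis=1)
        return count

    def qv_site_count(set_genes: Sequence[str]) -> np.ndarray:
        cols = np.isin(genes_arr, list(set_genes)) & is_qv
        return carrier[:, cols].sum(axis=1)

    # binary phenotype: logistic on planted-gene carrier counts
    eta = np.zeros(cfg.n_samples)
    intercept = logit(cfg.prevalence)
    for ps in cfg.planted_sets:
        if ps.carrier_or == 1.0:
            continue
        counts = gene_carrier_count(planted_genes[ps.name], is_qv)
        beta = np.log(ps.carrier_or)
        eta += beta * counts
        # re-center so the marginal prevalence stays near the target
        intercept -= beta * counts.mean()
    p_case = expit(intercept + eta)
    phenotype = (rng.random(cfg.n_samples) < p_case).astype(int)

    # static covariates
    sex_code = np.where(rng.random(cfg.n_samples) < cfg.male_fraction, 1, 2)
    age = np.clip(rng.normal(50, 15, cfg.n_samples), 18, 90).round(1)
    outcome = rng.integers(0, 2, cfg.n_samples)
    severity = rng.integers(0, 2, cfg.n_samples)

    x_counts = {ps.name: qv_site_count(collection.genes(ps.name))
                for ps in cfg.planted_sets}
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "sex": np.where(sex_code == 1, "male", "female"),
        "sex_code": sex_code, "age": age,
        "severity_admission": severity, "outcome": outcome,
        "anemia": phenotype,
    }).set_index("sample_id")

    pheno, endpoints_truth = simulate_rbc_series(
        rng, cfg, sample_ids, x_counts, sex_code, age, severity, outcome)
    realized_betas = endpoints_truth.pop("_realized_betas", {})

    if cfg.include_scale_scores:
        hgb_first = np.array([endpoints_truth["HGB"]["first"][s]
                              for s in sample_ids])
        hgb_final = np.array([endpoints_truth["HGB"]["final"][s]
                              for s in sample_ids])
        for tp, hgb in (("first", hgb_first), ("final", hgb_final)):
            h = (hgb - hgb.mean()) / hgb.std(ddof=1)
            samples[f"GCS_{tp}"] = np.clip(
                np.round(10 + 2 * h + rng.normal(0, 2, cfg.n_samples)), 3, 15)
            samples[f"CRS-R_{tp}"] = np.clip(
                np.round(15 + 3 * h + rng.normal(0, 3, cfg.n_samples)), 0, 23)
            samples[f"FOUR_{tp}"] = np.clip(
                np.round(12 + 2 * h + rng.normal(0, 2, cfg.n_samples)), 0, 16)
            samples[f"DRS_{tp}"] = np.clip(
                np.round(12 - 3 * h + rng.normal(0, 3, cfg.n_samples)), 0, 29)
            samples[f"mRS_{tp}"] = np.clip(
                np.round(3.5 - h + rng.normal(0, 1, cfg.n_samples)), 0, 5)

    truth = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "allele_cap": int(cap),
        "variants": [{
            "variant_id": v.variant_id, "gene": r["gene"], "impact": r["impact"],
            "true_af": r["true_af"], "pop_af_missing": r["pop_af"] is None,
            "cohort_ac": int(a), "is_qv": bool(q), "planted": r["planted"],
        } for v, r, a, q in zip(catalog, rows, ac, is_qv)],
        "sets": [{
            "name": ps.name, "carrier_or": ps.carrier_or,
            "planted_genes": planted_genes[ps.name],
        } for ps in cfg.planted_sets],
        "endpoint_effects": [
            {"parameter": p, "set": s, "beta": b,
             "beta_std_realized": realized_betas.get(p)}
            for p, s, b in cfg.endpoint_genetic_effects],
        "samples": {
            "sample_id": sample_ids,
            "phenotype": phenotype.tolist(),
            "case_probability": p_case.round(6).tolist(),
            "qv_counts": {k: v.tolist() for k, v in x_counts.items()},
        },
        "endpoints": {p: {tp: [float(endpoints_truth[p][tp][s])
                               for s in sample_ids]
                          for tp in ("first", "final", "minmax")}
                      for p in RBC_PARAMS},
    }
    return SimulatedCohort(config=cfg, catalog=catalog, genotypes=genotypes,
                           collection=collection, pheno=pheno, samples=samples,
                           truth=truth)


_SCHEDULES = {2: [0, 14], 3: [0, 7, 21], 5: [0, 3, 7, 14, 21]}


def simulate_rbc_series(rng: np.random.Generator, cfg: SimConfig,
                        sample_ids: Sequence[str],
                        qv_counts: dict[str, np.ndarray],
                        sex_code: np.ndarray, age: np.ndarray,
                        severity: np.ndarray, outcome: np.ndarray,
                        ) -> tuple[pd.DataFrame, dict]:
    """Per-sample RBC panel series with planted endpoint structure.

    First and final values follow the standardized linear model (age,
    sex, clinical status, genetic count); the worst value dips below
    the better of the two (above, for RDW) by a half-normal amount.
    The series is constructed to pass exactly through the planted
    first / worst / final values so endpoint extraction recovers the
    planted values; interior points interpolate and may go missing.
    """
    n = len(sample_ids)
    eff = {p: (s, b) for p, s, b in cfg.endpoint_genetic_effects}
    sexb = dict(cfg.sex_betas)
    outb = dict(cfg.outcome_betas)
    sevb = dict(cfg.severity_betas)

    def z(v: np.ndarray) -> np.ndarray:
        sd = v.std(ddof=1)
        return np.zeros_like(v, dtype=float) if sd == 0 else (v - v.mean()) / sd

    age_z, sex_z, sev_z, out_z = z(age), z(sex_code), z(severity), z(outcome)
    endpoints: dict[str, dict[str, dict[str, float]]] = {}
    realized_betas: dict[str, dict[str, float]] = {}
    for p, (mean, sd) in RBC_PARAMS.items():
        b_sex = sexb.get(p, 0.0)
        b_out = outb.get(p, 0.0)
        b_sev = sevb.get(p, 0.0)
        if p in eff and eff[p][0] in qv_counts:
            set_name, b_g = eff[p]
            x_z = z(qv_counts[set_name].astype(float))
        else:  # no such set simulated: no genetic effect on this endpoint
            b_g, x_z = 0.0, np.zeros(n)
        base = cfg.age_beta * age_z + b_sex * sex_z + b_g * x_z
        var_used = cfg.age_beta ** 2 + b_sex ** 2 + b_g ** 2
        sigma_first = np.sqrt(max(1.0 - var_used - b_sev ** 2, 0.05))
        sigma_final = np.sqrt(max(1.0 - var_used - b_out ** 2, 0.05))
        first_std = base + b_sev * sev_z + rng.normal(0, sigma_first, n)
        final_std = base + b_out * out_z + rng.normal(0, sigma_final, n)
        dip = np.abs(rng.normal(0, cfg.worst_dip_sd, n))
        if cfg.n_timepoints == 2:
            dip = np.zeros(n)  # two-point series cannot hold a separate worst
        if p in ("RDW",):
            worst_std = np.maximum(first_std, final_std) + dip
        else:
            worst_std = np.minimum(first_std, final_std) - dip
        # round once here so the written series and the truth agree exactly
        first = np.round(mean + sd * first_std, 4)
        final = np.round(mean + sd * final_std, 4)
        worst = np.round(mean + sd * worst_std, 4)
        if p in ("RDW",):
            worst = np.maximum(worst, np.maximum(first, final))
        else:
            worst = np.minimum(worst, np.minimum(first, final))
        if b_g != 0.0:
            # realized standardized beta: the estimand of a standardized
            # regression on this cohort is b_g * SD(x_z) / SD(y) per endpoint
            realized_betas[p] = {
                "first": float(b_g / first_std.std(ddof=1)),
                "final": float(b_g / final_std.std(ddof=1)),
            }
        endpoints[p] = {
            "first": dict(zip(sample_ids, first)),
            "final": dict(zip(sample_ids, final)),
            "minmax": dict(zip(sample_ids, worst)),
        }

    endpoints["_realized_betas"] = realized_betas  # consumed by the caller
    schedule = _SCHEDULES[cfg.n_timepoints]
    records = []
    for i, sid in enumerate(sample_ids):
        for t_idx, day in enumerate(schedule):
            row = {"sample_id": sid, "timestamp": day}
            for p in RBC_PARAMS:
                f = endpoints[p]["first"][sid]
                l = endpoints[p]["final"][sid]
                w = endpoints[p]["minmax"][sid]
                if cfg.n_timepoints == 2:
                    vals = [f, l]
                elif cfg.n_timepoints == 3:
                    vals = [f, w, l]
                else:
                    vals = [f, (f + w) / 2, w, (w + l) / 2, l]
                v = vals[t_idx]
                # only interior, non-worst points may go missing
                interior = t_idx not in (0, len(schedule) - 1) and vals[t_idx] != w
                if interior and rng.random() < cfg.interior_missing_rate:
                    v = np.nan
                row[p] = float(v) if np.isfinite(v) else np.nan
            records.append(row)
    pheno = pd.DataFrame.from_records(records)
    return pheno, endpoints


def write_cohort(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Convenience: simulate and write in one call."""
    return simulate_cohort(config).write(outdir)
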
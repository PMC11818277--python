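"""End-to-end pipeline: catalog -> QV -> burden -> association -> regression.

A single YAML configuration drives every stage; all randomness flows
from one top-level seed (stage seeds are derived by stable hashing of
stage names), all outputs are plain TSV/JSON written in deterministic
order, and a reproducibility manifest records the config hash, input
checksums and per-stage row counts.  Re-running on identical inputs
reproduces identical output checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .burden_association import exome_wide_scan, geneset_burden_test
from .gene_sets import read_gmt, restrict_to_qv_genes
from .phenotype import PARAMETERS, extract_endpoints_table, group_compare
from .gene_sets import burden_profile
from .qv_selection import QVConfig, qualify_variants
from .regression import Covariate, ModelSpec, fit_mlr, model_screen
from .synthetic_data import PlantedSet, SimConfig, simulate_cohort
from .variant_catalog import read_variant_table, summarize_spectrum

__all__ = ["run_pipeline", "write_report", "ConfigError", "stage_seed"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


_TOP_KEYS = {"seed", "output_dir", "simulate", "inputs", "qv", "association",
             "phenotype", "regression"}

_STATUS_BY_TIMEPOINT = {"first": "severity_admission", "final": "outcome",
                        "minmax": "outcome"}


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed below 2^31 by stable hashing."""
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


def _validate(cfg: dict) -> None:
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    if "seed" not in cfg:
        raise ConfigError("missing required key 'seed'")
    if ("simulate" in cfg) == ("inputs" in cfg):
        raise ConfigError("exactly one of 'simulate' or 'inputs' is required")
    if "inputs" in cfg:
        inputs = cfg["inputs"]
        for key in ("vcf", "gmt", "pheno"):
            if key not in inputs:
                raise ConfigError(f"inputs section missing {key!r}")
            if not Path(inputs[key]).exists():
                raise ConfigError(f"input file not found: {inputs[key]}")


def _load_inputs(cfg: dict, outdir: Path):
    seed = int(cfg["seed"])
    if "simulate" in cfg:
        sim_kwargs = dict(cfg["simulate"] or {})
        if "planted_sets" in sim_kwargs:
            sim_kwargs["planted_sets"] = tuple(
                PlantedSet(**ps) for ps in sim_kwargs["planted_sets"])
        sim_cfg = SimConfig(seed=stage_seed(seed, "simulate"), **sim_kwargs)
        cohort = simulate_cohort(sim_cfg)
        cohort.write(outdir / "simulated")
        pheno_long = cohort.pheno
        samples = cohort.samples
        return cohort.catalog, cohort.genotypes, cohort.collection, \
            pheno_long, samples
    inputs = cfg["inputs"]
    catalog, genotypes = read_variant_table(inputs["vcf"], format="vcf")
    collection = read_gmt(inputs["gmt"])
    pheno = pd.read_csv(inputs["pheno"], sep="\t")
    panel_cols = ["sample_id", "timestamp", *[p for p in PARAMETERS
                                              if p in pheno.columns]]
    pheno_long = pheno[panel_cols]
    static_cols = [c for c in pheno.columns if c not in panel_cols[1:]]
    samples = pheno[static_cols].drop_duplicates("sample_id").set_index("sample_id")
    return catalog, genotypes, collection, pheno_long, samples


def run_pipeline(config_path: str | Path) -> Path:
    """Execute every stage in dependency order; return the output directory."""
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a mapping")
    _validate(cfg)
    outdir = Path(cfg.get("output_dir", "qvburden_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    counts: dict[str, int] = {}

    catalog, genotypes, collection, pheno_long, samples = _load_inputs(cfg, outdir)
    counts["variants"] = len(catalog)
    counts["samples"] = genotypes.n_samples
    counts["gene_sets"] = len(collection)

    # stage: catalog summary
    spectrum = summarize_spectrum(catalog, genotypes)
    spectrum.to_json(outdir / "spectrum.json")
    spectrum.to_frame().to_csv(outdir / "spectrum.tsv", sep="\t", index=False)

    # stage: QV selection
    qv_cfg = QVConfig(**(cfg.get("qv") or {}))
    qvset = qualify_variants(catalog, genotypes, qv_cfg)
    qvset.to_tsv(outdir / "qv.tsv")
    counts["qualifying_variants"] = len(qvset)

    # stage: gene sets restricted to QV genes
    restricted = restrict_to_qv_genes(collection, qvset)
    rest_rows = [{"set": s.name, "n_genes": len(collection[s.name]),
                  "n_qv_genes": len(s)} for s in restricted]
    pd.DataFrame(rest_rows).to_csv(outdir / "restricted_sets.tsv", sep="\t",
                                   index=False)

    # stage: burden profile
    profile = burden_profile(qvset, genotypes, catalog, collection)
    profile.to_tsv(outdir / "burden.tsv")

    # stage: phenotype endpoints and group comparison
    ph_cfg = cfg.get("phenotype") or {}
    endpoints = extract_endpoints_table(pheno_long)
    endpoints.to_csv(outdir / "endpoints.tsv", sep="\t")
    counts["endpoint_rows"] = len(endpoints)
    compare_group = ph_cfg.get("group", "outcome")
    if compare_group in samples.columns:
        gc = group_compare(endpoints, samples[compare_group],
                           fdr_threshold=float(ph_cfg.get("fdr", 0.05)))
        gc.to_csv(outdir / "group_compare.tsv", sep="\t", index=False)
        counts["group_comparisons"] = len(gc)

    # stage: association
    as_cfg = cfg.get("association") or {}
    assoc_group = as_cfg.get("group", "anemia")
    if assoc_group not in samples.columns:
        raise ConfigError(f"association group column {assoc_group!r} not in "
                          "phenotype table")
    groups = samples[assoc_group].reindex(genotypes.sample_ids)
    assoc = geneset_burden_test(
        qvset, genotypes, catalog, collection, groups,
        mode=as_cfg.get("mode", "exact"),
        stratify_by=as_cfg.get("stratify_by", "gene"),
        fdr_threshold=float(as_cfg.get("fdr", 0.05)))
    assoc.to_csv(outdir / "association.tsv", sep="\t", index=False)
    counts["sets_tested"] = int(assoc["testable"].sum())
    if as_cfg.get("scan", True):
        scan = exome_wide_scan(catalog, genotypes, groups)
        scan.to_tsv(outdir / "scan.tsv")
        json.dump({"m_tested": scan.m_tested, "n_skipped": scan.n_skipped,
                   "bonferroni_threshold": scan.bonferroni,
                   "lambda_gc": scan.lambda_gc},
                  open(outdir / "scan_summary.json", "w"), indent=2,
                  sort_keys=True)
        counts["variants_scanned"] = scan.m_tested

    # stage: regression grid
    rg_cfg = cfg.get("regression") or {}
    dependents = rg_cfg.get("dependents", list(PARAMETERS))
    timepoints = rg_cfg.get("timepoints", ["final", "minmax"])
    set_names = rg_cfg.get("gene_sets", collection.names)
    data = endpoints.join(samples, how="inner")
    for name in set_names:
        data[f"qv_count_{name}"] = profile.qv_count[name].reindex(data.index)
    results = []
    for dep in dependents:
        for tp in timepoints:
            col = f"{dep}_{tp}"
            if col not in data.columns:
                continue
            status_col = _STATUS_BY_TIMEPOINT[tp]
            for name in set_names:
                gcol = f"qv_count_{name}"
                if data[gcol].std(ddof=1) == 0:
                    continue  # burden constant in cohort; model untestable
                spec = ModelSpec(
                    dependent=col,
                    covariates=(
                        Covariate("sex_code", "dummy"),
                        Covariate("age", "continuous"),
                        Covariate(status_col, "dummy"),
                        Covariate(gcol, "continuous"),
                    ),
                    family_id=rg_cfg.get("family_id", "mlr"))
                res = fit_mlr(spec, data)
                res.coef = res.coef.assign(gene_set=name, timepoint=tp,
                                           parameter=dep)
                results.append(res)
    if results:
        screen = model_screen(results,
                              r2_fdr=float(rg_cfg.get("r2_fdr", 0.1)),
                              beta_fdr=float(rg_cfg.get("beta_fdr", 0.1)),
                              genetic_covariate="")
        # genetic covariate columns are named qv_count_<set>
        screen["genetic"] = screen["covariate"].str.startswith("qv_count_")
        screen.to_csv(outdir / "regression.tsv", sep="\t", index=False)
        counts["regression_models"] = len(results)

    manifest = {
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        "stage_counts": counts,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()
                          and p.name not in ("manifest.json", "report.txt")),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    write_report(outdir)
    return outdir


def write_report(outdir: str | Path) -> Path:
    """Render a human-readable summary of a pipeline output directory.

    Every number in the report is read back from a stage output file,
    so the report is regenerable and traceable.
    """
    outdir = Path(outdir)
    lines = ["qvburden pipeline report", "=" * 24]
    manifest = json.loads((outdir / "manifest.json").read_text())
    lines.append(f"seed: {manifest['seed']}   config: {manifest['config_hash'][:12]}")
    for k, v in sorted(manifest["stage_counts"].items()):
        lines.append(f"  {k}: {v}")
    assoc_path = outdir / "association.tsv"
    if assoc_path.exists():
        assoc = pd.read_csv(assoc_path, sep="\t")
        testable = assoc[assoc["testable"] == True]  # noqa: E712
        if testable.empty:
            lines.append("association: no testable sets")
        else:
            lines.append("association (per gene set):")
            for _, r in testable.sort_values("p").iterrows():
                lines.append(
                    f"  {r['set']}: OR={r['or']:.3g} "
                    f"({r['ci_low']:.3g}-{r['ci_high']:.3g}) "
                    f"p={r['p']:.3g} q={r['q']:.3g}")
    reg_path = outdir / "regression.tsv"
    if reg_path.exists():
        reg = pd.read_csv(reg_path, sep="\t")
        hits = reg[(reg["genetic"]) & (reg["significant"])]
        lines.append(f"regression: {reg['model'].nunique()} models; "
                     f"{len(hits)} significant genetic covariate(s) at FDR 0.1")
        for _, r in hits.iterrows():
            lines.append(f"  {r['parameter']}_{r['timepoint']} ~ {r['gene_set']}: "
                         f"beta={r['beta']:.3f} "
                         f"({r['ci_low']:.3f},{r['ci_high']:.3f}) q={r['q']:.3g}")
    report = outdir / "report.txt"
    report.write_text("\n".join(lines) + "\n")
    return report
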
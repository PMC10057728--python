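"""End-to-end orchestration: simulate -> scan -> outliers -> quality ->
nonparametric stats -> PLS-DA, from one declarative YAML config.

Every source of randomness derives from one root seed (per-stage child
seeds are spawned deterministically and logged in the run manifest), so
a rerun with the same config is bit-identical for the deterministic
stages.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fst_scan import fst_scan
from .grain_quality import cnv_call, kernel_cluster_summary, miller_volume, quantify_chip
from .io_formats import (
    read_annotation, write_genotypes_csv, write_labels_csv, write_marker_map,
    write_scan_result, write_traits,
)
from .outlier_regions import (
    colocalize_genes, fraction_above, manhattan_export, merge_outlier_regions,
    percentile_threshold, permutation_null, regions_table,
)
from .plsda import classify, fit_plsda, select_important
from .simulate import SimulationConfig, simulate_dpcr_chip, simulate_genotypes, simulate_kernel_traits
from .stats_nonparam import cluster_contrast_table

STAGES = ["simulate", "scan", "outliers", "quality", "stats", "plsda"]


@dataclass
class PipelineConfig:
    """Declarative settings for one full run."""

    seed: int = 0
    out_dir: str = "solina_run"
    simulation: dict = field(default_factory=dict)      # SimulationConfig overrides
    n_traits_per_cluster: int = 24
    q: float = 0.99
    n_perm: int = 100
    gap_mb: float = 15.0
    window_mb: float = 5.0
    vip_threshold: float = 0.8
    alpha: float = 0.05
    max_lv: int = 10
    genes_bed: str | None = None
    dpcr: dict = field(default_factory=lambda: {"target": 1000.0, "reference": 500.0})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage child seed derived from the root seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write all outputs under ``config.out_dir`` and
    return the run manifest (also written as manifest.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "root_seed": config.seed,
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, **info):
        manifest["stages"][stage] = {"seed": config.stage_seed(stage), **info}

    # -- simulate ----------------------------------------------------------
    sim_cfg = SimulationConfig(**{"seed": config.stage_seed("simulate"),
                                  **config.simulation})
    geno, marker_map, truth = simulate_genotypes(sim_cfg)
    write_genotypes_csv(geno, out / "genotypes.csv")
    write_labels_csv(geno, out / "labels.csv")
    write_marker_map(marker_map, out / "marker_map.csv")
    truth.to_json(out / "truth.json")
    traits = simulate_kernel_traits(
        n_per_cluster=config.n_traits_per_cluster, seed=config.stage_seed("traits")
    )
    write_traits(traits, out / "traits.csv")
    record("simulate", n_samples=geno.n_samples, n_markers=geno.n_markers,
           n_divergent=len(truth.divergent_locus_ids))

    # -- scan --------------------------------------------------------------
    scan = fst_scan(geno, marker_map)
    scan_table = scan.table.assign(
        marker=scan.table["marker_id"], pos_Mb=scan.table["pos_bp"] / 1e6,
        outlier_flag=False,
    )
    record("scan", **scan.meta)

    # -- outliers ----------------------------------------------------------
    null = permutation_null(geno, n_perm=config.n_perm,
                            seed=config.stage_seed("outliers"))
    perm_threshold = null.quantile_threshold(0.95)
    threshold, flagged = percentile_threshold(scan, config.q)
    scan_table["outlier_flag"] = scan_table["marker_id"].isin(set(flagged))
    write_scan_result(scan_table, out / "scan.tsv")
    pd.DataFrame({"max_fst": null.max_fst_values}).to_csv(
        out / "null_distribution.csv", index=False)
    regions = merge_outlier_regions(flagged, marker_map, config.gap_mb)
    genes = read_annotation(config.genes_bed) if config.genes_bed else []
    regions = colocalize_genes(regions, genes, config.window_mb)
    regions_table(regions).to_csv(out / "regions.tsv", sep="\t", index=False)
    manhattan_export(scan, flagged, threshold, str(out / "manhattan.png"))
    record("outliers", n_perm=config.n_perm, q=config.q,
           percentile_threshold=threshold,
           permutation_threshold_95=perm_threshold,
           fraction_above_permutation=fraction_above(scan, perm_threshold),
           n_flagged=len(flagged), n_regions=len(regions))

    # -- quality -----------------------------------------------------------
    kernels = kernel_cluster_summary(traits)
    kernels.to_csv(out / "kernel_summary.csv")
    chip = simulate_dpcr_chip(config.dpcr, seed=config.stage_seed("quality"))
    conc = quantify_chip(chip)
    ratio, call = cnv_call(conc["target"][0], conc["reference"][0])
    json.dump(
        {"copies_per_ul": {c: v[0] for c, v in conc.items()},
         "cnv_ratio": ratio, "copy_call": call},
        open(out / "dpcr.json", "w"), indent=2,
    )
    record("quality", cnv_ratio=ratio, copy_call=call)

    # -- stats -------------------------------------------------------------
    trait_cols = [c for c in traits.columns if c not in ("sample_id", "cluster")]
    contrast = cluster_contrast_table(
        traits.assign(accession=traits["sample_id"]), trait_cols)
    contrast.to_csv(out / "contrast.tsv", sep="\t", index=False)
    record("stats", n_traits=len(trait_cols))

    # -- plsda -------------------------------------------------------------
    x = traits[trait_cols].assign(V=miller_volume(
        traits["L1"], traits["L2"], traits["L3"]))
    model = fit_plsda(x, traits["cluster"], max_lv=config.max_lv)
    _, rates = classify(model, x, traits["cluster"])
    important = select_important(model.vip, config.vip_threshold)
    model.vip.sort_values(ascending=False).to_csv(out / "vip.csv")
    record("plsda", n_lv=model.n_lv, training_rate=rates["overall"],
           important_variables=list(important.index))

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
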
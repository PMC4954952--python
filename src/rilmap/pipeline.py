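"""End-to-end orchestration: heritability -> scans -> hotspots -> epistasis
-> stochastic-variation (CV) branch, with a reproducibility manifest.

Every stage draws from a named substream of the single configured seed, so
re-running with the same config and inputs reproduces byte-identical output
tables.  The CV branch recomputes per-line coefficients of variation and
then reuses the identical scan and hotspot stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._rng import derived_seed, substream
from .heritability import (
    HERITABILITY_COLUMNS,
    cv_trait_table,
    heritability_table,
    median_normalize,
)
from .hotspots import (
    find_hotspots,
    hotspot_permutation_threshold,
    marker_by_experiment_model,
    merge_hotspots,
    validate_hotspots_marker_model,
    window_counts,
)
from .epistasis import (
    EDGE_TABLE_COLUMNS,
    epistasis_anova_panel,
    epistatic_variance_fraction,
    epistasis_enrichment,
    export_network,
)
from .io import (
    read_genotype_map,
    read_trait_table,
    write_genotypes,
    write_map,
    write_table,
    write_trait_table,
)
from .mapping import build_scan_grid
from .scan import (
    INTERACTION_TABLE_COLUMNS,
    QTL_TABLE_COLUMNS,
    ScanConfig,
    scan_trait_panel,
)
from .simulate import (
    StudyDesign,
    lt_ril_template,
    mask_missing,
    sample_architectures,
    simulate_ril_genotypes,
    simulate_trait_panel,
)

logger = logging.getLogger("rilmap")

ALL_STAGES = ("heritability", "scan", "hotspots", "epistasis", "cv")


@dataclass
class SimulateConfig:
    """Generator settings for a self-contained synthetic study."""

    n_lines: int = 280
    n_traits: int = 500
    missing_rate: float = 0.02
    architecture: dict = field(default_factory=dict)  # sample_architectures kwargs


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str = "rilmap_out"
    map_path: str | None = None
    genotypes_path: str | None = None
    traits_path: str | None = None
    simulate: SimulateConfig | None = None
    datasets: tuple = ("combined", "exp1", "exp2")
    stages: tuple = ALL_STAGES
    normalize: bool = False
    scan: ScanConfig = field(default_factory=ScanConfig)
    window_cm: float = 10.0
    merge_radius_cm: float = 10.0
    hotspot_n_perm: int = 1000
    validation_n_perm: int = 500
    epistasis_n_perm: int = 500
    alpha: float = 0.05
    fdr: float = 0.05

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        have_files = self.map_path and self.genotypes_path and self.traits_path
        if not have_files and self.simulate is None:
            raise ValueError("either input paths or a simulate block is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = SimulateConfig(**raw["simulate"])
        if "scan" in raw and raw["scan"] is not None:
            raw["scan"] = ScanConfig(**raw["scan"])
        for key in ("datasets", "stages"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_snapshot(config: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return {
        k: enc(v) for k, v in dataclasses.asdict(config).items()
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "rilmap",
        "version": __version__,
        "config": _config_snapshot(config),
        "stages": {},
        "outputs": {},
    }
    t0 = time.time()

    def checkpoint(stage, paths):
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        for p in paths:
            manifest["outputs"][p.name] = _sha256(p)

    # ----- inputs -----
    if config.simulate is not None:
        sim = config.simulate
        gmap = lt_ril_template()
        geno_full = simulate_ril_genotypes(
            gmap, sim.n_lines, substream(config.seed, "genotypes")
        )
        archs = sample_architectures(
            gmap, sim.n_traits, substream(config.seed, "architectures"),
            **sim.architecture,
        )
        design = StudyDesign(n_lines=sim.n_lines)
        traits = simulate_trait_panel(
            geno_full, gmap, archs, design, substream(config.seed, "traits")
        )
        geno = mask_missing(
            geno_full, sim.missing_rate, substream(config.seed, "missing")
        )
        write_map(gmap, out / "map.csv")
        write_genotypes(gmap, geno, out / "genotypes.csv")
        write_trait_table(traits, out / "traits.csv")
        checkpoint("simulate", [out / "map.csv", out / "genotypes.csv", out / "traits.csv"])
    else:
        gmap, geno = read_genotype_map(config.map_path, config.genotypes_path)
        traits = read_trait_table(config.traits_path)
        manifest["inputs"] = {
            name: _sha256(Path(path))
            for name, path in (
                ("map", config.map_path),
                ("genotypes", config.genotypes_path),
                ("traits", config.traits_path),
            )
        }
    if config.normalize:
        traits = median_normalize(traits)

    # ----- heritability -----
    if "heritability" in config.stages:
        logger.info("stage heritability")
        h2 = heritability_table(traits)
        write_table(h2, HERITABILITY_COLUMNS, out / "heritability.csv", "heritability")
        checkpoint("heritability", [out / "heritability.csv"])

    # ----- scans -----
    qtl_tables = {}
    if "scan" in config.stages:
        for dataset in config.datasets:
            logger.info("stage scan dataset=%s", dataset)
            qtls, ixns = scan_trait_panel(
                traits, dataset, geno, gmap, config.scan, seed=config.seed
            )
            qtl_tables[dataset] = qtls
            write_table(
                qtls, QTL_TABLE_COLUMNS, out / f"qtl_{dataset}.csv", "qtl"
            )
            write_table(
                ixns,
                INTERACTION_TABLE_COLUMNS,
                out / f"qtl_interactions_{dataset}.csv",
                "qtl interactions",
            )
            checkpoint(
                f"scan_{dataset}",
                [out / f"qtl_{dataset}.csv", out / f"qtl_interactions_{dataset}.csv"],
            )

    # ----- hotspots -----
    hotspot_markers = []
    if "hotspots" in config.stages and qtl_tables:
        grid = build_scan_grid(gmap, config.scan.step)
        per_dataset = []
        files = []
        for dataset, qtls in qtl_tables.items():
            counts = window_counts(qtls, grid, config.window_cm)
            thr = hotspot_permutation_threshold(
                len(qtls),
                grid,
                config.window_cm,
                config.hotspot_n_perm,
                config.alpha,
                substream(config.seed, "hotspot_null", dataset),
            )
            hs = find_hotspots(counts, thr, gmap, dataset)
            per_dataset.append(hs)
            counts.to_csv(out / f"hotspot_profile_{dataset}.csv", index=False)
            hs.to_csv(out / f"hotspots_{dataset}.csv", index=False)
            files += [out / f"hotspot_profile_{dataset}.csv", out / f"hotspots_{dataset}.csv"]
        non_empty = [h for h in per_dataset if len(h)]
        all_hs = (
            pd.concat(non_empty, ignore_index=True) if non_empty else per_dataset[0]
        )
        merged = merge_hotspots(all_hs, config.merge_radius_cm, gmap)
        merged.to_csv(out / "hotspots_merged.csv", index=False)
        files.append(out / "hotspots_merged.csv")
        hotspot_markers = list(merged["nearest_marker"])
        if hotspot_markers:
            validation = validate_hotspots_marker_model(
                traits,
                hotspot_markers,
                geno,
                gmap,
                n_perm=config.validation_n_perm,
                alpha=config.alpha,
                fdr=config.fdr,
                rng=substream(config.seed, "hotspot_validation"),
            )
            mxe = marker_by_experiment_model(
                traits, hotspot_markers, geno, gmap, fdr=config.fdr
            )
            summary = merged.merge(
                validation, left_on="nearest_marker", right_on="marker"
            ).merge(mxe, on="marker")
            summary["dataset"] = "merged"
            summary = summary.rename(columns={"null_q": "threshold"})
            summary = summary[
                [
                    "dataset",
                    "chromosome",
                    "peak_cM",
                    "nearest_marker",
                    "count",
                    "threshold",
                    "validated",
                    "n_main",
                    "n_gxe",
                    "n_significant",
                    "n_members",
                    "main_dominant",
                ]
            ]
            summary.to_csv(out / "hotspots_validated.csv", index=False)
            files.append(out / "hotspots_validated.csv")
            hotspot_markers = list(
                summary.loc[summary["validated"], "nearest_marker"]
            )
        checkpoint("hotspots", files)

    # ----- epistasis -----
    if "epistasis" in config.stages and len(hotspot_markers) >= 2:
        logger.info("stage epistasis markers=%d", len(hotspot_markers))
        terms = epistasis_anova_panel(
            traits, hotspot_markers, geno, gmap, fdr=config.fdr
        )
        terms.to_csv(out / "epistasis_terms.csv", index=False)
        fractions = epistatic_variance_fraction(terms)
        fractions.rename_axis("trait").reset_index().to_csv(
            out / "epistasis_variance_fraction.csv", index=False
        )
        edges = epistasis_enrichment(
            traits,
            hotspot_markers,
            geno,
            gmap,
            n_perm=config.epistasis_n_perm,
            alpha=config.alpha,
            fdr=config.fdr,
            rng=substream(config.seed, "epistasis_null"),
        )
        write_table(edges, EDGE_TABLE_COLUMNS, out / "epistasis_edges.csv", "edges")
        retained = edges[edges["retained"]]
        export_network(retained, out / "epistasis.sif", out / "epistasis_edge_attrs.tsv")
        checkpoint(
            "epistasis",
            [
                out / "epistasis_terms.csv",
                out / "epistasis_variance_fraction.csv",
                out / "epistasis_edges.csv",
                out / "epistasis.sif",
                out / "epistasis_edge_attrs.tsv",
            ],
        )

    # ----- CV branch -----
    if "cv" in config.stages:
        logger.info("stage cv")
        cv_long = cv_trait_table(traits)
        write_trait_table(cv_long, out / "cv_traits.csv")
        cv_qtls, _ = scan_trait_panel(
            cv_long, "combined", geno, gmap, config.scan,
            seed=derived_seed(config.seed, "cv"),
        )
        cv_qtls = cv_qtls.assign(dataset="cv")
        write_table(cv_qtls, QTL_TABLE_COLUMNS, out / "qtl_cv.csv", "qtl")
        grid = build_scan_grid(gmap, config.scan.step)
        counts = window_counts(cv_qtls, grid, config.window_cm)
        thr = hotspot_permutation_threshold(
            len(cv_qtls),
            grid,
            config.window_cm,
            config.hotspot_n_perm,
            config.alpha,
            substream(config.seed, "hotspot_null", "cv"),
        )
        cv_hs = find_hotspots(counts, thr, gmap, "cv")
        cv_hs.to_csv(out / "hotspots_cv.csv", index=False)
        checkpoint("cv", [out / "cv_traits.csv", out / "qtl_cv.csv", out / "hotspots_cv.csv"])

    manifest["total_seconds"] = round(time.time() - t0, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
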
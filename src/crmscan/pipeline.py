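"""End-to-end pipeline orchestration.

``run_pipeline`` wires the stages together — PWM library, regions (extracted
from a genome or simulated), threshold calibration, scanning, conserved-module
detection, clustering statistics and a text report — into one deterministic
run directory.  Every stage is also callable on its own (see :mod:`.cli`),
reading/writing the same intermediate file formats, so subcommand runs compose
to the identical result.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from . import discovery, pwm, regions as regions_mod, report, simulate, stats

logger = logging.getLogger("crmscan.pipeline")


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run.

    Defaults carry the analysis parameters: 4500 bp upstream / 500 bp
    downstream regions, 0.75 core-similarity cut, background-calibrated
    matrix thresholds at 3 matches / 10 kb, module windows of at most
    1000 bp anchored on NEUR sites, and a minimum of 2 co-localized families.
    """

    upstream: int = 4500
    downstream: int = 500
    core_cut: float = 0.75
    target_rate: float = 3.0  # matches per 10 kb of calibration background
    max_span: int = 1000
    anchor_family: str = "NEUR"
    min_families: int = 2
    seed: int = 1
    background_gc: float = 0.41
    background_length: int = 100_000
    # inputs (files mode)
    genome_fasta: Optional[str] = None
    tss_bed: Optional[str] = None
    regions_fasta: Optional[str] = None
    pfm: Optional[str] = None
    # simulation mode
    simulate: bool = False
    species_count: int = 8
    window_span: int = 800
    distance_min: int = 1000
    distance_max: int = 3000
    per_site_substitutions: int = 1
    n_decoy_families: int = 4

    def __post_init__(self) -> None:
        for name in (
            "upstream", "downstream", "core_cut", "target_rate", "max_span",
            "min_families", "background_length", "species_count", "window_span",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.background_gc < 1:
            raise ValueError("background_gc must be in (0, 1)")

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    outdir: Path
    module: Optional[discovery.RegulatoryModule]
    status: str  # "module_found" | "no_module"
    files: dict[str, Path] = field(default_factory=dict)


def _setup_log(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    root = logging.getLogger("crmscan")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    return handler


def stage_library(config: PipelineConfig) -> pwm.PWMLibrary:
    if config.pfm:
        logger.info("stage=library source=%s", config.pfm)
        return pwm.PWMLibrary.read(config.pfm)
    if config.simulate:
        logger.info("stage=library simulated seed=%d", config.seed)
        return simulate.build_pwm_library(
            seed=config.seed, n_decoy_families=config.n_decoy_families
        )
    raise ValueError("no PFM library: set 'pfm' or 'simulate: true'")


def stage_regions(
    config: PipelineConfig, outdir: Optional[Path] = None
) -> list[regions_mod.RegulatoryRegion]:
    if config.regions_fasta:
        logger.info("stage=regions source=%s", config.regions_fasta)
        return regions_mod.read_regions_fasta(config.regions_fasta)
    if config.genome_fasta and config.tss_bed:
        logger.info(
            "stage=regions genome=%s bed=%s upstream=%d downstream=%d",
            config.genome_fasta, config.tss_bed, config.upstream, config.downstream,
        )
        return regions_mod.extract_regions(
            config.genome_fasta, config.tss_bed,
            upstream=config.upstream, downstream=config.downstream,
        )
    if config.simulate:
        library = stage_library(config)
        spec = simulate.PlantSpec(
            window_span=config.window_span,
            distance_range=(config.distance_min, config.distance_max),
            per_site_substitutions=config.per_site_substitutions,
            species_count=config.species_count,
            seed=config.seed,
        )
        logger.info("stage=regions simulated seed=%d species=%d", config.seed, config.species_count)
        regs, truth = simulate.simulate_ortholog_promoters(library, spec, gc=config.background_gc)
        if outdir is not None:
            truth.save(outdir / "truth.json")
            (outdir / "planted_sites.bed").write_text(truth.to_bed6())
        return regs
    raise ValueError("no regions: set 'regions_fasta', genome+bed, or 'simulate: true'")


def stage_calibrate(config: PipelineConfig, library: pwm.PWMLibrary) -> dict[str, float]:
    logger.info(
        "stage=calibrate target_rate=%g/10kb background=%dbp gc=%.2f seed=%d",
        config.target_rate, config.background_length, config.background_gc,
        config.seed + 1000,
    )
    return pwm.calibrate_library(
        library,
        background_gc=config.background_gc,
        target_rate=config.target_rate,
        seed=config.seed + 1000,  # decoupled from the simulation stream
        background_length=config.background_length,
        core_cut=config.core_cut,
    )


def stage_scan(
    config: PipelineConfig,
    library: pwm.PWMLibrary,
    regions: list[regions_mod.RegulatoryRegion],
    thresholds: dict[str, float],
) -> dict[str, list[pwm.TFBSHit]]:
    hits = {}
    for r in regions:
        hits[r.region_id] = pwm.scan_sequence(
            library, r.sequence, core_cut=config.core_cut,
            thresholds=thresholds, tss_offset=r.tss_offset,
        )
        logger.info("stage=scan region=%s hits=%d", r.region_id, len(hits[r.region_id]))
    return hits


def stage_module(
    config: PipelineConfig,
    hits_by_region: dict[str, list[pwm.TFBSHit]],
    regions: list[regions_mod.RegulatoryRegion],
    gene_id: str = "",
) -> Optional[discovery.RegulatoryModule]:
    by_species = {}
    for r in regions:
        by_species[r.species or r.region_id] = hits_by_region[r.region_id]
    module = discovery.detect_conserved_module(
        by_species,
        anchor_family=config.anchor_family,
        max_span=config.max_span,
        min_families=config.min_families,
        gene_id=gene_id,
        tss_offset=regions[0].tss_offset if regions else config.upstream,
    )
    logger.info(
        "stage=module result=%s",
        f"found families={','.join(module.families)}" if module else "none",
    )
    return module


def run_pipeline(config: PipelineConfig, outdir: Union[str, Path]) -> PipelineResult:
    """Run all stages, writing every intermediate and final artifact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_log(outdir)
    try:
        config.to_yaml(outdir / "config.yaml")
        library = stage_library(config)
        library.write(outdir / "library.pfm")
        regs = stage_regions(config, outdir)
        regions_mod.write_regions_fasta(regs, outdir / "regions.fasta")
        thresholds = stage_calibrate(config, library)
        pwm.write_thresholds_tsv(thresholds, outdir / "thresholds.tsv")
        hits = stage_scan(config, library, regs, thresholds)
        pwm.write_hits_tsv(hits, outdir / "hits.tsv")
        # round-trip through the TSV so stage-wise runs compose bit-for-bit
        hits = pwm.read_hits_tsv(outdir / "hits.tsv", library)
        gene_id = regs[0].gene_id if regs else ""
        module = stage_module(config, hits, regs, gene_id=gene_id)
        discovery.write_module_json(module, outdir / "module.json")
        files = {
            "config": outdir / "config.yaml",
            "library": outdir / "library.pfm",
            "regions": outdir / "regions.fasta",
            "thresholds": outdir / "thresholds.tsv",
            "hits": outdir / "hits.tsv",
            "module": outdir / "module.json",
        }
        if module is not None:
            df = stats.module_family_stats(
                module, library, thresholds,
                background_gc=config.background_gc,
                background_length=config.background_length,
                seed=config.seed + 2000,
                core_cut=config.core_cut,
            )
            stats.write_stats_tsv(df, outdir / "stats.tsv")
            (outdir / "report.txt").write_text(report.render_module_report(module))
            files["stats"] = outdir / "stats.tsv"
            files["report"] = outdir / "report.txt"
            status = "module_found"
        else:
            (outdir / "report.txt").write_text("no module found\n")
            files["report"] = outdir / "report.txt"
            status = "no_module"
        logger.info("stage=done status=%s", status)
        return PipelineResult(outdir=outdir, module=module, status=status, files=files)
    finally:
        logging.getLogger("crmscan").removeHandler(handler)
        handler.close()
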
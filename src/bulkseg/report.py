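"""Report arithmetic, run configuration, and end-to-end orchestration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("bulkseg")


def percentage(numerator: float, denominator: float) -> float | None:
    """100 * numerator / denominator, half-up rounded to 2 decimals.

    Returns None (a missing value) for a zero denominator.
    """
    if denominator == 0:
        return None
    pct = Decimal(numerator) / Decimal(denominator) * 100
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class RunConfig:
    """Everything one pipeline run needs; defaults are the published protocol
    values (trim window 5 with floors 2/20, 50 bp pair minimum, SNP filters
    FS<60 MQ>40 QD>4 GQ>20, 1 Mb windows with 50 kb steps, 95%/99% levels,
    bulks of 30)."""

    outdir: str = "bulkseg_run"
    seed: int = 0
    # stage toggles
    run_simulate: bool = True
    run_filter: bool = True
    run_index: bool = True
    run_ci: bool = True
    run_regions: bool = True
    make_plots: bool = True
    # simulation
    sim: dict = field(default_factory=dict)          # SimConfig overrides
    # trimming
    trim_window: int = 5
    trim_base_floor: int = 2
    trim_mean_floor: float = 20.0
    trim_min_len: int = 50
    # variant filters
    fs_max_snp: float = 60.0
    mq_min: float = 40.0
    qd_min_snp: float = 4.0
    gq_min: float = 20.0
    fs_max_indel: float = 200.0
    qd_min_indel: float = 4.0
    # windows and thresholds
    window_bp: int = 1_000_000
    step_bp: int = 50_000
    levels: list = field(default_factory=lambda: [0.95, 0.99])
    ci_reps: int = 10_000
    region_level: float = 0.99
    merge_gap_bp: int = 1_000_000
    bulk_low: str = "K21"
    bulk_high: str = "K5"
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    """A pipeline stage could not run; carries the stage name."""


def run_pipeline(config: RunConfig) -> Path:
    """Simulate -> filter -> index -> null thresholds -> candidate regions.

    Writes every stage output under ``config.outdir`` plus a manifest with
    parameters and a content hash per file.  Deterministic under fixed seed.
    A disabled prerequisite stage aborts the dependent stage by raising
    StageError naming it; outputs written so far are retained.
    """
    from . import bsa_index, ci_null, regions as regions_mod, variants as variants_mod
    from .simulate import SimConfig, simulate_experiment, write_truth_bed

    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    if not config.run_simulate:
        raise StageError("simulate: stage disabled but no external inputs are configured")
    sim_cfg = SimConfig(**{"seed": config.seed, **config.sim})
    log.info("simulate: %d chromosome(s), causal at %s:%d",
             sim_cfg.n_chromosomes, sim_cfg.causal_chrom, sim_cfg.causal_pos)
    result = simulate_experiment(sim_cfg)
    variants_mod.write_vcf(result.variants, out / "variants.vcf")
    result.variants.to_csv(out / "variants.tsv", sep="\t", index=False)
    write_truth_bed(sim_cfg, out / "truth.bed")
    outputs += [out / "variants.vcf", out / "variants.tsv", out / "truth.bed"]

    if config.run_filter:
        snp_params = variants_mod.SnpFilterParams(
            fs_max=config.fs_max_snp, mq_min=config.mq_min,
            qd_min=config.qd_min_snp, gq_min=config.gq_min,
        )
        indel_params = variants_mod.IndelFilterParams(
            fs_max=config.fs_max_indel, qd_min=config.qd_min_indel,
        )
        filtered, reasons = variants_mod.apply_filters(
            result.variants, snp_params, indel_params,
            bulks=(config.bulk_low, config.bulk_high),
        )
        log.info("filter: %d/%d sites pass", len(filtered), len(result.variants))
        filtered.to_csv(out / "filtered.tsv", sep="\t", index=False)
        variants_mod.write_vcf(filtered, out / "filtered.vcf")
        variants_mod.write_tally_report(filtered, out / "tally.tsv")
        outputs += [out / "filtered.tsv", out / "filtered.vcf", out / "tally.tsv"]
    else:
        filtered = result.variants

    if config.run_index:
        sites = bsa_index.compute_indices(
            filtered, bulk_low=config.bulk_low, bulk_high=config.bulk_high
        )
        chrom_lengths = {c: sim_cfg.chrom_length_bp for c in sim_cfg.chrom_names()}
        windows = bsa_index.window_average(
            sites, chrom_lengths, window_bp=config.window_bp, step_bp=config.step_bp
        )
        sites.to_csv(out / "sites.tsv", sep="\t", index=False)
        windows.to_csv(out / "windows.tsv", sep="\t", index=False)
        outputs += [out / "sites.tsv", out / "windows.tsv"]
    else:
        sites = windows = None

    if config.run_ci:
        depths = list(range(5, 105, 5))
        params = ci_null.NullParams(
            bulk_size=sim_cfg.bulk_size, n_reps=config.ci_reps,
            levels=tuple(config.levels), seed=config.seed,
        )
        table = ci_null.build_threshold_table(params, depths)
        table.to_csv(out / "thresholds.tsv", sep="\t", index=False)
        outputs.append(out / "thresholds.tsv")
    else:
        table = None

    if config.run_regions:
        if table is None:
            raise StageError("regions: requires the ci stage (no threshold table)")
        if sites is None:
            raise StageError("regions: requires the index stage (no per-site indices)")
        regs = regions_mod.call_regions(
            sites, table, level=config.region_level, merge_gap_bp=config.merge_gap_bp
        )
        regions_mod.write_regions(regs, out / "regions.tsv", out / "regions.bed")
        log.info("regions: %d candidate region(s)", len(regs))
        outputs += [out / "regions.tsv", out / "regions.bed"]

    if config.make_plots and sites is not None and windows is not None:
        bsa_index.plot_index_tracks(sites, windows, table, out / "snp_index.png")
        outputs.append(out / "snp_index.png")

    manifest = {
        "parameters": dataclasses.asdict(config),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
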
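"""End-to-end synthetic-to-report workflow orchestration.

A single root seed governs all randomness; each stage derives its own
stream from the root seed and a stable stage name, so identical configs
give byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import enrichment_stats, peak_analytics, synthetic_data
from .enrichment_stats import BinTrack
from .g4_scanner import PATTERNS, get_pattern, is_telomeric_read, scan_pg4
from .sequence_model import (
    Genome,
    Peak,
    TSSRecord,
    read_bed,
    read_chrom_sizes,
    read_fasta,
    write_bed,
)

logger = logging.getLogger("quadchip")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Inputs and parameters of one pipeline run.

    With ``fasta``/``rep1_bed``/``rep2_bed`` unset, inputs are generated by
    the synthetic module under ``synthetic`` (a :class:`SyntheticSpec`
    field mapping).
    """

    out_dir: str = "quadchip_out"
    seed: int = 0
    pattern: str = "G3L1-7"
    n_controls_per_peak: int = 100
    fdr: float = 0.05
    bin_size: int = 50
    subtelomeric_margin: int = peak_analytics.SUBTELOMERIC_MARGIN
    tss_thresholds: Tuple[int, ...] = (5000, 10000, 20000)
    tss_count: int = 50  # synthetic TSS sites when no table is supplied
    fasta: Optional[str] = None
    rep1_bed: Optional[str] = None
    rep2_bed: Optional[str] = None
    chrom_sizes: Optional[str] = None
    synthetic: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "tss_thresholds" in data:
            data["tss_thresholds"] = tuple(data["tss_thresholds"])
        return cls(**data)

    def validate(self) -> None:
        if self.pattern not in PATTERNS:
            raise ConfigError(f"unknown pattern preset {self.pattern!r}")
        if any(t <= 0 for t in self.tss_thresholds):
            raise ConfigError("tss_thresholds must be positive")
        for name in ("fasta", "rep1_bed", "rep2_bed", "chrom_sizes"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{name} path does not exist: {path}")


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed and stage name."""
    return (zlib.crc32(stage.encode()) ^ (int(root_seed) * 2654435761)) % (2**31)


def _synthetic_inputs(config: PipelineConfig):
    spec = synthetic_data.SyntheticSpec(
        **{**config.synthetic, "seed": config.synthetic.get("seed", stage_seed(config.seed, "simulate"))}
    )
    genome, planted, true_peaks = synthetic_data.generate_genome(spec)
    rep1, rep2 = synthetic_data.generate_replicate_peaks(true_peaks, spec)
    return spec, genome, true_peaks, rep1, rep2


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute scan -> common peaks -> annotations -> enrichment -> bins ->
    FRiP -> telomeric partition, writing a JSON summary and TSV tables."""
    config.validate()
    out = Path(config.out_dir)
    pattern = get_pattern(config.pattern)

    spec = None
    if config.fasta is None:
        spec, genome, true_peaks, rep1, rep2 = _synthetic_inputs(config)
        logger.info("synthetic inputs: seed=%d, %d true peaks", spec.seed, len(true_peaks))
    else:
        genome = read_fasta(config.fasta)
        true_peaks = []
        sizes = read_chrom_sizes(config.chrom_sizes) if config.chrom_sizes else genome.sizes
        if config.rep1_bed is None or config.rep2_bed is None:
            raise ConfigError("rep1_bed and rep2_bed are required with a FASTA input")
        rep1 = read_bed(config.rep1_bed, size_table=sizes)
        rep2 = read_bed(config.rep2_bed, size_table=sizes)

    out.mkdir(parents=True, exist_ok=True)
    sizes = genome.sizes

    # replicate intersection
    common = peak_analytics.common_peaks(rep1, rep2)
    write_bed(common, out / "common_peaks.bed")
    logger.info("common peaks: %d (rep1=%d, rep2=%d)", len(common), len(rep1), len(rep2))

    # genome-wide motif scan
    hits = []
    for chrom in genome:
        hits.extend(scan_pg4(genome.sequences[chrom], pattern, "both", chrom=chrom))
    write_bed(hits, out / "pg4_hits.bed")

    # TSS proximity (synthetic TSS positions when no table is available)
    tss_rng = np.random.default_rng(stage_seed(config.seed, "tss"))
    tss_list: List[TSSRecord] = []
    for chrom, length in sizes.items():
        for i, pos in enumerate(sorted(tss_rng.integers(0, length, size=config.tss_count // len(sizes) + 1))):
            tss_list.append(TSSRecord(f"{chrom}_gene{i}", chrom, int(pos), "+"))
    tss_counts = peak_analytics.tss_proximity_counts(common, tss_list, config.tss_thresholds)

    # enrichment against length-matched random controls
    ctrl_seed = stage_seed(config.seed, "controls")
    controls = enrichment_stats.sample_control_regions(
        common, sizes, n_per_peak=config.n_controls_per_peak, seed=ctrl_seed, genome=genome
    )
    count_report = enrichment_stats.motif_count_enrichment(
        common, controls, genome, pattern, config.n_controls_per_peak, ctrl_seed
    )
    presence_report = enrichment_stats.peak_presence_enrichment(
        common, controls, genome, pattern, config.n_controls_per_peak, ctrl_seed
    )
    logger.info(
        "enrichment (%s): count OR=%.3g p=%.3g; presence OR=%.3g p=%.3g",
        pattern.name, count_report.odds_ratio, count_report.p_two_sided,
        presence_report.odds_ratio, presence_report.p_two_sided,
    )

    # reads: ChIP-like (peak-enriched, telomeric subpopulation) + uniform input
    if spec is not None:
        read_seqs, placements = synthetic_data.generate_reads(genome, true_peaks, spec)
        input_spec = dataclasses.replace(
            spec, peak_read_fold=1.0, telomeric_fraction=0.0,
            seed=stage_seed(config.seed, "input_reads"),
        )
        _, input_placements = synthetic_data.generate_reads(genome, true_peaks, input_spec)
    else:
        read_seqs, placements, input_placements = [], [], []

    report: Dict[str, object] = {
        "config": {
            "seed": config.seed,
            "pattern": config.pattern,
            "n_controls_per_peak": config.n_controls_per_peak,
            "fdr": config.fdr,
            "bin_size": config.bin_size,
            "subtelomeric_margin": config.subtelomeric_margin,
            "tss_thresholds": list(config.tss_thresholds),
            "control_seed": ctrl_seed,
        },
        "peaks": {"rep1": len(rep1), "rep2": len(rep2), "common": len(common)},
        "pg4": {"genome_hits": len(hits)},
        "tss_proximity": {str(k): v for k, v in tss_counts.items()},
        "enrichment": {
            "motif_count": count_report.to_dict(),
            "peak_presence": presence_report.to_dict(),
        },
        "telomeric_repeat_peaks": len(
            peak_analytics.flag_telomeric_repeat_peaks(common, genome)
        ),
    }

    if placements:
        frip_value = peak_analytics.frip(placements, common)
        telomeric_frac = sum(is_telomeric_read(s) for s in read_seqs) / len(read_seqs)
        partition = peak_analytics.partition_read_counts(
            placements, sizes, margin=config.subtelomeric_margin
        )
        partition.to_csv(out / "read_partition.tsv", sep="\t")
        track = BinTrack.from_reads(placements, input_placements, sizes, config.bin_size)
        _, significant_fraction = enrichment_stats.bin_enrichment(track, config.fdr)
        report["reads"] = {
            "count": len(placements),
            "frip": frip_value,
            "telomeric_fraction": telomeric_frac,
            "bins_significant_fraction": significant_fraction,
        }
        report["read_partition"] = {
            chrom: {
                "subtelomeric": int(row["subtelomeric_reads"]),
                "interstitial": int(row["interstitial_reads"]),
            }
            for chrom, row in partition.iterrows()
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
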
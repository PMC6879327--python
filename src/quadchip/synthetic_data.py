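"""Synthetic inputs with known ground truth.

Generates multi-chromosome genomes with planted PG4 motifs at different
densities inside and outside designated peak regions, jittered replicate
peak sets, short reads with a controlled telomeric fraction and peak
over-representation, and noisy sigmoidal FID titrations with known DC50.

Every generator is a pure function of (spec, seed): the same inputs give
byte-identical outputs. Backgrounds are i.i.d. per-base (no higher-order
structure) — sufficient to calibrate length-matched nulls; planted motif
loops are drawn over {A,C,T} so they can never extend a G-tract.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .fid_assay import FIDSeries
from .g4_scanner import G4Pattern, MotifHit, TELOMERE_UNIT
from .peak_analytics import ReadPlacement
from .sequence_model import GenomicInterval, Genome, Peak

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_LOOP_BASES = "ACT"


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic pipeline inputs.

    Defaults describe a desk-scale genome (4 x 100 kb) carrying 40 peaks of
    1 kb with PG4 motifs planted five-fold denser inside peaks than in the
    background, a telomeric read fraction of 0.23, and 100 length-matched
    controls per peak.
    """

    n_chroms: int = 4
    chrom_length: int = 100_000
    base_composition: Tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    peak_count: int = 40
    peak_length: int = 1000
    motif_density_in_peaks: float = 1.5  # expected motifs per kb
    motif_density_background: float = 0.3
    pattern: G4Pattern = field(default_factory=lambda: G4Pattern(loop_max=7))
    replicate_jitter_sd: float = 25.0  # bp
    false_positive_peaks: int = 5  # decoys per replicate
    read_count: int = 10_000
    read_length: int = 36
    telomeric_fraction: float = 0.23
    peak_read_fold: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        if not (0.0 <= self.telomeric_fraction <= 1.0):
            raise ValueError("telomeric_fraction must lie in [0, 1]")
        for name in ("n_chroms", "chrom_length", "peak_count", "peak_length",
                     "false_positive_peaks", "read_count", "read_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        max_motif = 4 * self.pattern.run_len + 3 * self.pattern.loop_max
        if self.peak_count and max_motif >= self.peak_length:
            raise ValueError("planted motif length must be below peak_length")

    def null(self) -> "SyntheticSpec":
        """Same conditions with equal motif density inside and outside peaks."""
        return replace(self, motif_density_in_peaks=self.motif_density_background)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def _random_sequence(rng: np.random.Generator, length: int, probs: Sequence[float]) -> bytearray:
    idx = rng.choice(4, size=length, p=np.asarray(probs))
    return bytearray(_BASES[idx].tobytes())


def _build_motif(rng: np.random.Generator, pattern: G4Pattern) -> str:
    parts = []
    for i in range(pattern.n_runs):
        parts.append("G" * pattern.run_len)
        if i < pattern.n_runs - 1:
            loop_len = int(rng.integers(pattern.loop_min, pattern.loop_max + 1))
            parts.append("".join(rng.choice(list(_LOOP_BASES), size=loop_len)))
    return "".join(parts)


def _place_nonoverlapping(
    rng: np.random.Generator,
    lo: int,
    hi: int,
    length: int,
    occupied: List[Tuple[int, int]],
    retries: int = 100,
) -> Optional[int]:
    """A start in [lo, hi - length] avoiding occupied spans, or None."""
    if hi - lo < length:
        return None
    for _ in range(retries):
        s = int(rng.integers(lo, hi - length + 1))
        e = s + length
        if all(e <= os or s >= oe for os, oe in occupied):
            return s
    return None


def generate_genome(spec: SyntheticSpec) -> Tuple[Genome, List[MotifHit], List[Peak]]:
    """Background genome + planted motifs + true peak regions.

    Peaks are placed uniformly without overlap; motifs are planted at
    Poisson rates given by the per-kb densities inside and outside peaks,
    at positions not already holding a planted motif. Returns the exact
    ground truth.
    """
    rng = _rng(spec.seed, 1)
    sequences: Dict[str, bytearray] = {}
    for i in range(spec.n_chroms):
        sequences[f"chr{i + 1}"] = _random_sequence(
            rng, spec.chrom_length, spec.base_composition
        )
    chrom_names = list(sequences)

    # uniform non-overlapping peak placement across the genome
    peaks: List[Peak] = []
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chrom_names}
    lengths = np.array([spec.chrom_length] * spec.n_chroms, dtype=float)
    probs = lengths / lengths.sum()
    for k in range(spec.peak_count):
        placed = False
        for _ in range(1000):
            chrom = chrom_names[int(rng.choice(spec.n_chroms, p=probs))]
            s = _place_nonoverlapping(
                rng, 0, spec.chrom_length, spec.peak_length, occupied[chrom], retries=1
            )
            if s is not None:
                occupied[chrom].append((s, s + spec.peak_length))
                peaks.append(
                    Peak(GenomicInterval(chrom, s, s + spec.peak_length), name=f"true_{k}")
                )
                placed = True
                break
        if not placed:
            raise RuntimeError("could not place peaks without overlap; genome too small")
    peaks.sort(key=lambda p: (p.chrom, p.start))

    planted: List[MotifHit] = []
    motif_spans: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chrom_names}

    def plant(chrom: str, lo: int, hi: int, density_per_kb: float) -> None:
        n = rng.poisson(density_per_kb * (hi - lo) / 1000.0)
        for _ in range(n):
            motif = _build_motif(rng, spec.pattern)
            s = _place_nonoverlapping(rng, lo, hi, len(motif), motif_spans[chrom])
            if s is None:
                warnings.warn(f"dropped one planted motif on {chrom}: no free slot")
                continue
            sequences[chrom][s : s + len(motif)] = motif.encode()
            motif_spans[chrom].append((s, s + len(motif)))
            planted.append(
                MotifHit(GenomicInterval(chrom, s, s + len(motif)), "+", motif)
            )

    for peak in peaks:
        plant(peak.chrom, peak.start, peak.end, spec.motif_density_in_peaks)
    for chrom in chrom_names:
        spans = sorted(occupied[chrom])
        prev = 0
        for s, e in spans + [(spec.chrom_length, spec.chrom_length)]:
            if s > prev:
                plant(chrom, prev, s, spec.motif_density_background)
            prev = e

    genome = Genome({c: bytes(b).decode() for c, b in sequences.items()})
    planted.sort(key=lambda h: (h.interval.chrom, h.interval.start))
    return genome, planted, peaks


def generate_replicate_peaks(
    true_peaks: Sequence[Peak], spec: SyntheticSpec
) -> Tuple[List[Peak], List[Peak]]:
    """Two replicate peak sets: endpoint-jittered true peaks plus uniform decoys."""
    if spec.replicate_jitter_sd < 0:
        raise ValueError("jitter sd must be >= 0")
    rng = _rng(spec.seed, 2)
    replicates: List[List[Peak]] = []
    for rep in (1, 2):
        out: List[Peak] = []
        for i, peak in enumerate(true_peaks):
            s = peak.start + int(round(rng.normal(0, spec.replicate_jitter_sd)))
            e = peak.end + int(round(rng.normal(0, spec.replicate_jitter_sd)))
            s = max(0, min(s, spec.chrom_length - 1))
            e = max(s + 1, min(e, spec.chrom_length))
            out.append(Peak(GenomicInterval(peak.chrom, s, e), name=f"rep{rep}_{i}"))
        for j in range(spec.false_positive_peaks):
            chrom = f"chr{int(rng.integers(1, spec.n_chroms + 1))}"
            s = int(rng.integers(0, spec.chrom_length - spec.peak_length + 1))
            out.append(
                Peak(
                    GenomicInterval(chrom, s, s + spec.peak_length),
                    name=f"rep{rep}_decoy_{j}",
                )
            )
        out.sort(key=lambda p: (p.chrom, p.start))
        replicates.append(out)
    return replicates[0], replicates[1]


def generate_reads(
    genome: Genome, true_peaks: Sequence[Peak], spec: SyntheticSpec
) -> Tuple[List[str], List[ReadPlacement]]:
    """Reads from a two-rate start model with a telomeric sub-population.

    Read starts occur at a base rate everywhere and ``peak_read_fold``
    times that rate inside true peaks (sampled by thinning). A
    ``telomeric_fraction`` of reads is replaced by tandem TTAGGG repeat
    sequence at random phase; their placements are retained so FRiP and
    bin-level ground truth stay well-defined.
    """
    rng = _rng(spec.seed, 3)
    chrom_names = list(genome.sequences)
    lengths = np.array([genome.sizes[c] for c in chrom_names], dtype=float)
    probs = lengths / lengths.sum()
    fold = max(spec.peak_read_fold, 1.0)
    peak_spans: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chrom_names}
    for p in true_peaks:
        peak_spans[p.chrom].append((p.start, p.end))

    def in_peak(chrom: str, pos: int) -> bool:
        return any(s <= pos < e for s, e in peak_spans[chrom])

    placements: List[ReadPlacement] = []
    while len(placements) < spec.read_count:
        ci = int(rng.choice(len(chrom_names), p=probs))
        chrom = chrom_names[ci]
        pos = int(rng.integers(0, genome.sizes[chrom]))
        rate = fold if in_peak(chrom, pos) else 1.0
        if rng.random() >= rate / fold:  # thinning against the peak rate
            continue
        pos = min(pos, genome.sizes[chrom] - spec.read_length)
        placements.append(ReadPlacement(chrom, pos, spec.read_length))

    telomeric = rng.random(spec.read_count) < spec.telomeric_fraction
    tandem = TELOMERE_UNIT * (spec.read_length // len(TELOMERE_UNIT) + 2)
    sequences: List[str] = []
    for read, is_telo in zip(placements, telomeric):
        if is_telo:
            phase = int(rng.integers(0, len(TELOMERE_UNIT)))
            sequences.append(tandem[phase : phase + spec.read_length])
        else:
            sequences.append(
                genome.sequences[read.chrom][read.pos : read.pos + read.length]
            )
    return sequences, placements


DEFAULT_FID_CONCENTRATIONS = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0)


def generate_fid_series(
    dc50_true: float,
    hill: float = 1.0,
    noise_cv: float = 0.02,
    concentrations: Sequence[float] = DEFAULT_FID_CONCENTRATIONS,
    seed: int = 0,
    fa1: float = 100.0,
) -> FIDSeries:
    """Noisy sigmoidal titration with known DC50 (= Hill midpoint).

    FA_x = FA_1 * (1 - Hill(c)/100) * (1 + eps), eps ~ Normal(0, noise_cv);
    the first point is exactly (0, FA_1).
    """
    if dc50_true <= 0:
        raise ValueError("dc50_true must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = _rng(seed, 4)
    points: List[Tuple[float, float]] = []
    for c in concentrations:
        if c == 0:
            points.append((0.0, fa1))
            continue
        frac = c**hill / (c**hill + dc50_true**hill)
        eps = rng.normal(0.0, noise_cv) if noise_cv > 0 else 0.0
        points.append((float(c), max(fa1 * (1.0 - frac) * (1.0 + eps), 0.0)))
    return FIDSeries(points=tuple(points), fa1=float(fa1))
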
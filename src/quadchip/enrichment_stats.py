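"""Enrichment statistics: length-matched random control sampling, the two
Fisher's-exact peak/motif enrichment tests, 50-bp bin ChIP-vs-input
enrichment with Benjamini-Hochberg control.

The contingency constructions mirror the two directions of the peak-motif
association question: (i) do peaks carry more non-overlapping motif
occurrences per base than length-matched random regions, and (ii) is the
proportion of peaks harboring at least one motif higher than among random
regions. Controls are pooled, giving a single 2x2 table (and one Fisher p)
per pattern.
"""
from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .g4_scanner import G4Pattern, scan_pg4
from .peak_analytics import ReadPlacement, merge_intervals
from .sequence_model import GenomicInterval, Genome, Peak


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows: observed peaks vs pooled controls; columns: with vs without property."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table total must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @property
    def odds_ratio(self) -> float:
        a, b, c, d = self.a, self.b, self.c, self.d
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5  # Haldane-Anscombe
        return (a * d) / (b * c)


@dataclass(frozen=True)
class EnrichmentReport:
    pattern: str
    table: ContingencyTable2x2
    odds_ratio: float
    p_two_sided: float
    n_controls_per_peak: Optional[int] = None
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "pattern": self.pattern,
            "table": [[self.table.a, self.table.b], [self.table.c, self.table.d]],
            "odds_ratio": self.odds_ratio,
            "p_two_sided": self.p_two_sided,
            "n_controls_per_peak": self.n_controls_per_peak,
            "seed": self.seed,
        }


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 table.

    A degenerate margin (an all-zero row or column) carries no evidence and
    returns p = 1.0 with a warning.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 margin: returning p = 1.0")
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def _overlaps_sorted(starts: List[int], ends: List[int], s: int, e: int) -> bool:
    k = bisect_right(starts, s) - 1
    if k >= 0 and ends[k] > s:
        return True
    return k + 1 < len(starts) and starts[k + 1] < e


def sample_control_regions(
    peaks: Sequence[Peak],
    sizes: Mapping[str, int],
    n_per_peak: int = 100,
    seed: Optional[int] = None,
    exclusions: Optional[Sequence[GenomicInterval]] = None,
    genome: Optional[Genome] = None,
    max_n_fraction: float = 0.1,
    budget_per_region: int = 1000,
) -> List[GenomicInterval]:
    """Draw length-matched random control regions from across the genome.

    For each peak, exactly ``n_per_peak`` regions of that peak's exact
    length are drawn: the chromosome is chosen with probability
    proportional to its length (among chromosomes the region fits), the
    start uniformly among fitting positions. Draws overlapping any
    exclusion interval (default: the peaks themselves) or containing more
    than ``max_n_fraction`` N (when a genome is supplied) are rejected and
    redrawn, up to ``budget_per_region`` draws per region on average.
    """
    rng = np.random.default_rng(seed)
    if exclusions is None:
        exclusions = [p.interval for p in peaks]
    excl = merge_intervals(exclusions)
    chrom_names = list(sizes)
    chrom_lengths = np.array([sizes[c] for c in chrom_names], dtype=np.int64)

    controls: List[GenomicInterval] = []
    for peak in peaks:
        plen = peak.interval.length
        fits = np.where(chrom_lengths >= plen)[0]
        if fits.size == 0:
            raise RuntimeError(
                f"control sampling failed for peak {peak.name or peak.interval}: "
                f"no chromosome fits length {plen}"
            )
        probs = chrom_lengths[fits] / chrom_lengths[fits].sum()
        need = n_per_peak
        drawn = 0
        budget = budget_per_region * n_per_peak
        while need > 0:
            batch = min(max(2 * need, 32), budget - drawn)
            if batch <= 0:
                raise RuntimeError(
                    f"control sampling budget exhausted for peak "
                    f"{peak.name or peak.interval} (length {plen})"
                )
            ci = rng.choice(fits.size, size=batch, p=probs)
            highs = chrom_lengths[fits[ci]] - plen + 1
            starts = rng.integers(0, highs)
            drawn += batch
            for k in range(batch):
                if need == 0:
                    break
                chrom = chrom_names[fits[ci[k]]]
                s = int(starts[k])
                e = s + plen
                ex = excl.get(chrom)
                if ex is not None and _overlaps_sorted(ex[0], ex[1], s, e):
                    continue
                if genome is not None:
                    if genome.sequences[chrom].count("N", s, e) > max_n_fraction * plen:
                        continue
                controls.append(GenomicInterval(chrom, s, e))
                need -= 1
    return controls


def _covered_length(hits) -> int:
    """Union coverage (bp) of hit intervals on one region, across strands."""
    spans = sorted((h.interval.start, h.interval.end) for h in hits)
    total = 0
    cur_s, cur_e = None, None
    for s, e in spans:
        if cur_e is None or s >= cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def _region_stats(
    regions: Sequence[GenomicInterval], genome: Genome, pattern: G4Pattern
) -> Tuple[int, int, int]:
    """(total motif count, total bases not covered by motifs, regions with >= 1 hit)."""
    n_hits = 0
    uncovered = 0
    with_hit = 0
    for region in regions:
        seq = genome.fetch(region)
        hits = scan_pg4(seq, pattern, strand_mode="both", chrom=region.chrom,
                        offset=region.start)
        n_hits += len(hits)
        uncovered += region.length - _covered_length(hits)
        if hits:
            with_hit += 1
    return n_hits, uncovered, with_hit


def motif_count_enrichment(
    peaks: Sequence[Peak],
    controls: Sequence[GenomicInterval],
    genome: Genome,
    pattern: G4Pattern,
    n_controls_per_peak: Optional[int] = None,
    seed: Optional[int] = None,
) -> EnrichmentReport:
    """Fisher test of motif density in peaks vs pooled length-matched controls.

    Row 1 = (non-overlapping motif count in peaks, peak bases not covered
    by motifs); row 2 = the same over pooled controls.
    """
    if not peaks:
        raise ValueError("empty peak set")
    a, b, _ = _region_stats([p.interval for p in peaks], genome, pattern)
    c, d, _ = _region_stats(controls, genome, pattern)
    table = ContingencyTable2x2(a, b, c, d)
    return EnrichmentReport(
        pattern=pattern.name,
        table=table,
        odds_ratio=table.odds_ratio,
        p_two_sided=fisher_exact_2x2(table),
        n_controls_per_peak=n_controls_per_peak,
        seed=seed,
    )


def peak_presence_enrichment(
    peaks: Sequence[Peak],
    controls: Sequence[GenomicInterval],
    genome: Genome,
    pattern: G4Pattern,
    n_controls_per_peak: Optional[int] = None,
    seed: Optional[int] = None,
) -> EnrichmentReport:
    """Fisher test of the proportion of regions harboring >= 1 motif.

    Row 1 = (#peaks with >= 1 hit, #peaks with none); row 2 = the same
    over pooled controls.
    """
    if not peaks:
        raise ValueError("empty peak set")
    _, _, with_hit = _region_stats([p.interval for p in peaks], genome, pattern)
    _, _, ctrl_with = _region_stats(controls, genome, pattern)
    table = ContingencyTable2x2(
        with_hit, len(peaks) - with_hit, ctrl_with, len(controls) - ctrl_with
    )
    return EnrichmentReport(
        pattern=pattern.name,
        table=table,
        odds_ratio=table.odds_ratio,
        p_two_sided=fisher_exact_2x2(table),
        n_controls_per_peak=n_controls_per_peak,
        seed=seed,
    )


@dataclass
class BinTrack:
    """Fixed-width genome bins with ChIP and input (background) read counts."""

    bin_size: int
    chip: Dict[str, np.ndarray]
    input_: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @classmethod
    def from_reads(
        cls,
        chip_reads: Sequence[ReadPlacement],
        input_reads: Sequence[ReadPlacement],
        sizes: Mapping[str, int],
        bin_size: int = 50,
    ) -> "BinTrack":
        """Bin reads by midpoint into ceil(length / bin_size) bins per chromosome."""
        chip: Dict[str, np.ndarray] = {}
        inp: Dict[str, np.ndarray] = {}
        for chrom, length in sizes.items():
            n_bins = -(-length // bin_size)
            chip[chrom] = np.zeros(n_bins, dtype=np.int64)
            inp[chrom] = np.zeros(n_bins, dtype=np.int64)
        for reads, tracks in ((chip_reads, chip), (input_reads, inp)):
            for r in reads:
                tracks[r.chrom][min(r.midpoint // bin_size, len(tracks[r.chrom]) - 1)] += 1
        return cls(bin_size=bin_size, chip=chip, input_=inp)

    @property
    def chip_total(self) -> int:
        return int(sum(v.sum() for v in self.chip.values()))

    @property
    def input_total(self) -> int:
        return int(sum(v.sum() for v in self.input_.values()))

    @property
    def n_bins(self) -> int:
        return int(sum(v.size for v in self.chip.values()))


def bin_enrichment(track: BinTrack, fdr: float = 0.05) -> Tuple[np.ndarray, float]:
    """Per-bin one-sided binomial tests of ChIP counts against input.

    The per-bin success probability is (input_bin + 1) / (input_total +
    n_bins) — a +1 pseudo-count that keeps empty input bins testable.
    Returns the per-bin p-values (chromosomes concatenated in size-table
    order) and the fraction of bins significant after Benjamini-Hochberg
    control at ``fdr``.
    """
    if track.n_bins == 0:
        raise ValueError("zero bins")
    chip = np.concatenate([track.chip[c] for c in track.chip])
    inp = np.concatenate([track.input_[c] for c in track.input_])
    chip_total = track.chip_total
    if chip_total == 0 or track.input_total == 0:
        raise ValueError("ChIP and input totals must be positive")
    p0 = (inp + 1.0) / (track.input_total + track.n_bins)
    pvalues = stats.binom.sf(chip - 1, chip_total, p0)
    flags = bh_fdr(pvalues, fdr)
    return pvalues, float(flags.mean())


def bh_fdr(pvalues: Sequence[float], alpha: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level ``alpha``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject
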
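"""Peak-level analytics: replicate intersection, TSS proximity, genomic
feature annotation, sub-telomeric classification, interstitial telomere
repeats, and FRiP.
"""
from __future__ import annotations

import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .g4_scanner import TELOMERE_UNIT_RC, find_telomeric_tracts
from .sequence_model import (
    GenomicInterval,
    Genome,
    GeneModel,
    Peak,
    TSSRecord,
    interval_distance,
)

FEATURE_LABELS = ("promoter", "downstream", "exon", "intron", "intergenic")

SUBTELOMERIC_MARGIN = 500_000  # bp from either chromosome terminus


@dataclass(frozen=True)
class ReadPlacement:
    """An aligned read start: chromosome, 0-based start, and read length."""

    chrom: str
    pos: int
    length: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("read position must be >= 0")
        if self.length <= 0:
            raise ValueError("read length must be positive")

    @property
    def midpoint(self) -> int:
        return self.pos + self.length // 2


def common_peaks(rep1: Sequence[Peak], rep2: Sequence[Peak]) -> List[Peak]:
    """Merge replicate peak sets into common peaks.

    Every maximal connected component of mutually overlapping peaks that
    contains at least one peak from *each* replicate yields one common peak
    spanning [min(all starts), max(all ends)) — the min-start/max-end rule,
    generalized to overlap chains. Peaks overlapping only within one
    replicate emit nothing. Output is disjoint and sorted.
    """
    tagged: List[Tuple[str, int, int, int]] = [
        (p.chrom, p.start, p.end, 0) for p in rep1
    ] + [(p.chrom, p.start, p.end, 1) for p in rep2]
    tagged.sort()
    out: List[Peak] = []
    i = 0
    idx = 0
    n = len(tagged)
    while i < n:
        chrom, start, end, rep = tagged[i]
        reps = {rep}
        j = i + 1
        while j < n and tagged[j][0] == chrom and tagged[j][1] < end:
            end = max(end, tagged[j][2])
            reps.add(tagged[j][3])
            j += 1
        if len(reps) == 2:
            out.append(Peak(GenomicInterval(chrom, start, end), name=f"common_{idx}"))
            idx += 1
        i = j
    return out


def tss_proximity_counts(
    peaks: Sequence[Peak],
    tss_list: Sequence[TSSRecord],
    thresholds: Sequence[int],
) -> Dict[int, int]:
    """Count peaks whose nearest same-chromosome TSS lies within each threshold.

    Distance is measured from the whole peak interval (0 if a TSS falls
    inside the peak), so the counts are non-decreasing in the threshold.
    """
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    if not tss_list:
        warnings.warn("empty TSS list: all proximity counts are 0")
        return {int(t): 0 for t in thresholds}
    by_chrom: Dict[str, List[int]] = {}
    for t in tss_list:
        by_chrom.setdefault(t.chrom, []).append(t.pos)
    for positions in by_chrom.values():
        positions.sort()
    counts = {int(t): 0 for t in thresholds}
    for peak in peaks:
        positions = by_chrom.get(peak.chrom)
        if not positions:
            continue
        # candidate nearest TSS flank the peak in the sorted position list
        lo = bisect_left(positions, peak.start)
        best = min(
            interval_distance(peak.interval, positions[k])
            for k in range(max(0, lo - 1), min(len(positions), lo + 2))
        )
        for t in counts:
            if best <= t:
                counts[t] += 1
    return counts


def _item_span(item: Union[GenomicInterval, ReadPlacement]) -> Tuple[str, int, int]:
    if isinstance(item, ReadPlacement):
        return item.chrom, item.pos, item.pos + item.length
    if isinstance(item, Peak):
        return item.chrom, item.start, item.end
    return item.chrom, item.start, item.end


def classify_subtelomeric(
    item: Union[GenomicInterval, ReadPlacement, Peak],
    sizes: Mapping[str, int],
    margin: int = SUBTELOMERIC_MARGIN,
) -> str:
    """Classify an interval or read as 'sub-telomeric' or 'interstitial'.

    Sub-telomeric means any base lies within ``margin`` of position 0 or of
    the chromosome end.
    """
    chrom, start, end = _item_span(item)
    if chrom not in sizes:
        raise ValueError(f"unknown chromosome {chrom!r}")
    length = sizes[chrom]
    if start < margin or end > length - margin:
        return "sub-telomeric"
    return "interstitial"


def partition_read_counts(
    reads: Iterable[ReadPlacement],
    sizes: Mapping[str, int],
    margin: int = SUBTELOMERIC_MARGIN,
) -> pd.DataFrame:
    """Per-chromosome table of sub-telomeric vs interstitial read counts."""
    rows = {c: [0, 0] for c in sizes}
    for read in reads:
        label = classify_subtelomeric(read, sizes, margin)
        rows[read.chrom][0 if label == "sub-telomeric" else 1] += 1
    return pd.DataFrame(
        [(c, v[0], v[1]) for c, v in rows.items()],
        columns=["chrom", "subtelomeric_reads", "interstitial_reads"],
    ).set_index("chrom")


def flag_telomeric_repeat_peaks(peaks: Sequence[Peak], genome: Genome) -> List[Peak]:
    """Subset of peaks containing >= 1 TTAGGG unit on either strand, in order."""
    flagged: List[Peak] = []
    for peak in peaks:
        seq = genome.fetch(peak.interval)
        if find_telomeric_tracts(seq) or TELOMERE_UNIT_RC in seq:
            flagged.append(peak)
    return flagged


def merge_intervals(intervals: Iterable[GenomicInterval]) -> Dict[str, Tuple[List[int], List[int]]]:
    """Merge overlapping intervals; returns per-chromosome sorted start/end arrays."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: Dict[str, Tuple[List[int], List[int]]] = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        starts: List[int] = []
        ends: List[int] = []
        for s, e in spans:
            if ends and s < ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (starts, ends)
    return merged


def frip(reads: Sequence[ReadPlacement], peaks: Sequence[Peak]) -> float:
    """Fraction of reads whose midpoint falls inside any peak.

    Overlapping peaks are merged first so each read is counted once.
    """
    if not reads:
        raise ValueError("FRiP undefined for zero reads")
    merged = merge_intervals(p.interval for p in peaks)
    inside = 0
    for read in reads:
        spans = merged.get(read.chrom)
        if spans is None:
            continue
        starts, ends = spans
        k = bisect_right(starts, read.midpoint) - 1
        if k >= 0 and read.midpoint < ends[k]:
            inside += 1
    return inside / len(reads)


def annotate_feature(
    peak: Peak,
    gene_models: Sequence[GeneModel],
    promoter_halfwidth: int,
    downstream_extent: int = 5000,
) -> str:
    """Classify a peak midpoint against gene models.

    Priority: promoter > downstream > exon > intron > intergenic, where
    promoter = within ``promoter_halfwidth`` of a TSS and downstream =
    within ``downstream_extent`` past the transcript end on the gene strand.
    """
    mid = peak.interval.midpoint
    genes = [g for g in gene_models if g.chrom == peak.chrom]
    for g in genes:
        if abs(mid - g.tss) <= promoter_halfwidth:
            return "promoter"
    for g in genes:
        if g.strand == "+":
            if g.tx_end <= mid < g.tx_end + downstream_extent:
                return "downstream"
        else:
            if g.tx_start - downstream_extent <= mid < g.tx_start:
                return "downstream"
    for g in genes:
        for ex in g.exons:
            if ex.start <= mid < ex.end:
                return "exon"
    for g in genes:
        if g.tx_start <= mid < g.tx_end:
            return "intron"
    return "intergenic"
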
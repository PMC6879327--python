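"""Potential G-quadruplex (PG4) motif scanner and telomeric repeat detection.

A PG4 motif is four (or more) runs of at least ``run_len`` guanines
separated by loops whose lengths lie within configurable bounds — the
classic quadparser-style grammar. G-tracts are *maximal* G-runs: excess
guanines belong to the tract, never to the loop. Loops may contain any of
A/C/G/T (G only outside tracts); N never matches anywhere.

Matching is leftmost with lazy (shortest-first) loops, and hits on a strand
are non-overlapping: after a hit is accepted, scanning resumes at the base
following its end. The minus strand is scanned on the reverse complement
and hits are mapped back to plus-strand coordinates; plus- and minus-strand
hits are never merged, since G-rich and C-rich tracts are chemically
distinct sites.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .sequence_model import GenomicInterval, VALID_BASES

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

TELOMERE_UNIT = "TTAGGG"
TELOMERE_UNIT_RC = "CCCTAA"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class G4Pattern:
    """Parameters of a PG4 motif class, e.g. G3L1-15 = (G≥3)x4, loops 1–15 nt."""

    run_len: int = 3
    n_runs: int = 4
    loop_min: int = 1
    loop_max: int = 7

    def __post_init__(self) -> None:
        if self.run_len < 2:
            raise ValueError("run_len must be >= 2")
        if self.n_runs < 4:
            raise ValueError("n_runs must be >= 4")
        if not (1 <= self.loop_min <= self.loop_max):
            raise ValueError("require 1 <= loop_min <= loop_max")

    @property
    def min_length(self) -> int:
        return self.n_runs * self.run_len + (self.n_runs - 1) * self.loop_min

    @property
    def name(self) -> str:
        return f"G{self.run_len}L{self.loop_min}-{self.loop_max}"


#: Preset pattern registry, selected by name in configs and on the CLI.
PATTERNS: Dict[str, G4Pattern] = {
    "G3L1-7": G4Pattern(run_len=3, loop_min=1, loop_max=7),
    "G3L1-12": G4Pattern(run_len=3, loop_min=1, loop_max=12),
    "G3L1-15": G4Pattern(run_len=3, loop_min=1, loop_max=15),
}


def get_pattern(name: str) -> G4Pattern:
    try:
        return PATTERNS[name]
    except KeyError:
        raise KeyError(
            f"unknown pattern preset {name!r}; known: {sorted(PATTERNS)}"
        ) from None


@dataclass(frozen=True)
class MotifHit:
    """A located non-overlapping PG4 occurrence, in plus-strand coordinates."""

    interval: GenomicInterval
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.sequence) != self.interval.length:
            raise ValueError("sequence length must equal interval length")

    @property
    def name(self) -> str:
        return f"pg4_{self.interval.chrom}_{self.interval.start}"


def _validate_seq(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        offset = next(i for i, c in enumerate(seq) if c in bad)
        raise ValueError(f"invalid character {seq[offset]!r} at offset {offset}")
    return seq


def _g_runs(seq: str, run_len: int) -> List[Tuple[int, int]]:
    """Maximal G-runs of length >= run_len as (start, end) pairs."""
    return [m.span() for m in re.finditer("G{%d,}" % run_len, seq)]


def _scan_plus(seq: str, pattern: G4Pattern) -> List[Tuple[int, int]]:
    """Leftmost lazy non-overlapping matches on the given strand, as spans."""
    runs = _g_runs(seq, pattern.run_len)
    n_runs, lmin, lmax = pattern.n_runs, pattern.loop_min, pattern.loop_max
    n = len(runs)

    def chain_end(i: int, depth: int) -> Optional[int]:
        # runs[i] is tract number `depth`; loops tried shortest-first, which
        # together with the outer leftmost loop reproduces lazy regex order.
        if depth == n_runs:
            return runs[i][1]
        tract_end = runs[i][1]
        for k in range(i + 1, n):
            gap = runs[k][0] - tract_end
            if gap < lmin:
                continue
            if gap > lmax:
                break
            if "N" in seq[tract_end : runs[k][0]]:
                continue
            end = chain_end(k, depth + 1)
            if end is not None:
                return end
        return None

    spans: List[Tuple[int, int]] = []
    pos = 0
    j = 0
    while j < n:
        if runs[j][0] < pos:
            j += 1
            continue
        end = chain_end(j, 1)
        if end is None:
            j += 1
            continue
        spans.append((runs[j][0], end))
        pos = end  # resume past the hit: hits on a strand never overlap
        j += 1
    return spans


def scan_pg4(
    seq: str,
    pattern: G4Pattern,
    strand_mode: str = "both",
    chrom: str = "seq",
    offset: int = 0,
) -> List[MotifHit]:
    """Locate non-overlapping PG4 motifs in a DNA sequence.

    Parameters
    ----------
    seq:
        DNA over {A,C,G,T,N}; case-insensitive.
    pattern:
        The PG4 grammar parameters.
    strand_mode:
        "plus", "minus" or "both". Minus-strand hits are reported in
        plus-strand coordinates with the plus-strand sequence.
    chrom, offset:
        Coordinate frame for the reported intervals (``offset`` is added to
        all positions), so slices of a chromosome can be scanned in place.
    """
    if strand_mode not in ("plus", "minus", "both"):
        raise ValueError(f"strand_mode must be plus/minus/both, got {strand_mode!r}")
    seq = _validate_seq(seq)
    hits: List[MotifHit] = []
    if strand_mode in ("plus", "both"):
        for s, e in _scan_plus(seq, pattern):
            hits.append(
                MotifHit(GenomicInterval(chrom, offset + s, offset + e), "+", seq[s:e])
            )
    if strand_mode in ("minus", "both"):
        rc = reverse_complement(seq)
        L = len(seq)
        minus = []
        for s, e in _scan_plus(rc, pattern):
            ps, pe = L - e, L - s
            minus.append(
                MotifHit(GenomicInterval(chrom, offset + ps, offset + pe), "-", seq[ps:pe])
            )
        hits.extend(sorted(minus, key=lambda h: h.interval.start))
    return hits


def count_pg4(seq: str, pattern: G4Pattern, strand_mode: str = "both") -> int:
    """Number of non-overlapping PG4 hits (per strand, summed over strands)."""
    if not seq:
        return 0
    return len(scan_pg4(seq, pattern, strand_mode))


def is_telomeric_read(seq: str, min_units: int = 2) -> bool:
    """True iff the read contains ``min_units`` tandem TTAGGG copies on either strand.

    Characters outside the DNA alphabet simply never match.
    """
    if min_units < 1:
        raise ValueError("min_units must be >= 1")
    s = seq.upper()
    return (TELOMERE_UNIT * min_units in s) or (TELOMERE_UNIT_RC * min_units in s)


def find_telomeric_tracts(seq: str) -> List[int]:
    """All (possibly overlapping) start offsets of TTAGGG on the plus strand."""
    s = seq.upper()
    positions: List[int] = []
    i = s.find(TELOMERE_UNIT)
    while i != -1:
        positions.append(i)
        i = s.find(TELOMERE_UNIT, i + 1)
    return positions
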
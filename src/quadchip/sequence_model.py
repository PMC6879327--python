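"""Core sequence and interval data model with FASTA/BED/chrom.sizes/gene-model I/O.

All coordinates are 0-based half-open (BED convention) everywhere in the
package; a single convention eliminates off-by-one drift between modules.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open span [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A called ChIP peak: an interval plus optional score and replicate-consistency (IDR) value."""

    interval: GenomicInterval
    name: str = ""
    score: Optional[float] = None
    idr: Optional[float] = None

    def __post_init__(self) -> None:
        if self.idr is not None and not (0.0 <= self.idr <= 1.0):
            raise ValueError(f"idr must lie in [0, 1], got {self.idr}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


class Genome:
    """In-memory genome: chromosome name -> uppercase DNA string over {A,C,G,T,N}."""

    def __init__(self, sequences: Mapping[str, str], sizes: Optional[Mapping[str, int]] = None):
        self.sequences: Dict[str, str] = dict(sequences)
        if sizes is None:
            self.sizes: Dict[str, int] = {c: len(s) for c, s in self.sequences.items()}
        else:
            self.sizes = dict(sizes)
            for chrom, seq in self.sequences.items():
                if self.sizes.get(chrom) != len(seq):
                    raise ValueError(
                        f"size table inconsistent with sequence length for {chrom}: "
                        f"{self.sizes.get(chrom)} != {len(seq)}"
                    )

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __iter__(self):
        return iter(self.sequences)

    @property
    def total_length(self) -> int:
        return sum(self.sizes.values())

    def fetch(self, interval: GenomicInterval) -> str:
        """Extract the plus-strand sequence of an interval, bounds-checked."""
        if interval.chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {interval.chrom!r}")
        if interval.end > self.sizes[interval.chrom]:
            raise ValueError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} exceeds "
                f"chromosome length {self.sizes[interval.chrom]}"
            )
        return self.sequences[interval.chrom][interval.start : interval.end]


@dataclass(frozen=True)
class TSSRecord:
    gene: str
    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"TSS position must be >= 0, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class GeneModel:
    """A transcript model with exon structure, UCSC-refFlat-like."""

    gene: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(f"invalid transcript span [{self.tx_start}, {self.tx_end})")
        prev_end = self.tx_start
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError("exon chromosome differs from gene chromosome")
            if ex.start < prev_end or ex.end > self.tx_end:
                raise ValueError(
                    f"exons of {self.gene} must be sorted, disjoint and inside "
                    f"[{self.tx_start}, {self.tx_end})"
                )
            prev_end = ex.end

    @property
    def tss(self) -> int:
        """Transcription start site: leftmost base for '+' genes, rightmost for '-'."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path: Union[str, Path]) -> Genome:
    """Read a multi-record FASTA into a :class:`Genome`.

    Sequences are uppercased; only A, C, G, T, N are accepted. Duplicate
    record names and invalid characters (reported with their offset) raise
    ``ValueError``.
    """
    sequences: Dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in sequences:
            raise ValueError(f"duplicate FASTA record name {name!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            offset = next(i for i, c in enumerate(seq) if c in bad)
            raise ValueError(
                f"invalid character {seq[offset]!r} in record {name!r} at offset {offset}"
            )
        sequences[name] = seq
    return Genome(sequences)


def write_fasta(genome: Genome, path: Union[str, Path], width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_chrom_sizes(path: Union[str, Path]) -> Dict[str, int]:
    """Read a two-column (name, length) TSV."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            name, length = fields[0], int(fields[1])
            if length <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive chromosome length")
            sizes[name] = length
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


_BED_SKIP_PREFIXES = ("#", "track", "browser")


def read_bed(
    path: Union[str, Path],
    size_table: Optional[Mapping[str, int]] = None,
    idr_col: Optional[int] = None,
) -> List[Peak]:
    """Read BED3/BED6 (plus an optional extra numeric IDR column) into peaks.

    Coordinates are kept verbatim (0-based half-open). ``idr_col`` is the
    0-based index of the column holding an irreproducible-discovery-rate
    value in [0, 1].
    """
    peaks: List[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_BED_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            if size_table is not None:
                if chrom not in size_table:
                    raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if end > size_table[chrom]:
                    raise ValueError(
                        f"{path}:{lineno}: interval end {end} exceeds chromosome "
                        f"length {size_table[chrom]}"
                    )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else f"peak_{lineno}"
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            idr = None
            if idr_col is not None:
                if idr_col >= len(fields):
                    raise ValueError(f"{path}:{lineno}: missing IDR column {idr_col}")
                idr = float(fields[idr_col])
            peaks.append(Peak(GenomicInterval(chrom, start, end), name=name, score=score, idr=idr))
    return peaks


def write_bed(items: Iterable, path: Union[str, Path]) -> None:
    """Write peaks or motif hits as BED.

    Objects with a ``strand`` attribute are written as BED6; plain peaks as
    BED with name/score columns when present.
    """
    with open(path, "w") as fh:
        for item in items:
            iv = item.interval if hasattr(item, "interval") else item
            name = getattr(item, "name", "") or "."
            score = getattr(item, "score", None)
            strand = getattr(item, "strand", None)
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if strand is not None:
                cols += [name, "0" if score is None else f"{score:g}", strand]
            elif score is not None:
                cols += [name, f"{score:g}"]
            elif name != ".":
                cols += [name]
            fh.write("\t".join(cols) + "\n")


def read_tss_table(path: Union[str, Path]) -> List[TSSRecord]:
    """Read a TSS TSV with columns gene, chrom, pos, strand (header optional)."""
    records: List[TSSRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns (gene, chrom, pos, strand)")
            if lineno == 1 and not fields[2].lstrip("-").isdigit():
                continue  # header row
            records.append(TSSRecord(fields[0], fields[1], int(fields[2]), fields[3]))
    return records


def read_gene_models(path: Union[str, Path]) -> List[GeneModel]:
    """Read a gene-model TSV: gene, chrom, strand, txStart, txEnd, exonStarts, exonEnds.

    Exon start/end columns are comma-separated (a trailing comma, as UCSC
    tables emit, is tolerated).
    """
    models: List[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                if lineno == 1:
                    continue
                raise ValueError(f"{path}:{lineno}: expected 7 columns")
            if lineno == 1 and not fields[3].isdigit():
                continue  # header row
            gene, chrom, strand = fields[0], fields[1], fields[2]
            tx_start, tx_end = int(fields[3]), int(fields[4])
            starts = [int(x) for x in fields[5].rstrip(",").split(",") if x]
            ends = [int(x) for x in fields[6].rstrip(",").split(",") if x]
            if len(starts) != len(ends):
                raise ValueError(f"{path}:{lineno}: exon start/end count mismatch")
            exons = tuple(GenomicInterval(chrom, s, e) for s, e in zip(starts, ends))
            models.append(GeneModel(gene, chrom, strand, tx_start, tx_end, exons))
    return models


def tss_records(models: Sequence[GeneModel]) -> List[TSSRecord]:
    return [TSSRecord(m.gene, m.chrom, m.tss, m.strand) for m in models]


def interval_distance(iv: GenomicInterval, pos: int, chrom: Optional[str] = None) -> int:
    """Base-to-base distance from a point to an interval (0 if contained).

    The distance to a point outside the interval is measured to the nearest
    contained base — i.e. to ``start`` or ``end - 1``, not the exclusive end.
    """
    if chrom is not None and chrom != iv.chrom:
        raise ValueError(f"point on {chrom!r} but interval on {iv.chrom!r}")
    if iv.start <= pos < iv.end:
        return 0
    return min(abs(pos - iv.start), abs(pos - (iv.end - 1)))
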
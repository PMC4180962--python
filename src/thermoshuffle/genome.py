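"""Replicon/gene data model and interval arithmetic.

Internal coordinates are 0-based half-open throughout; format converters
(GenBank's 1-based inclusive convention) translate at the I/O boundary.
A gene wrapping the origin of a circular replicon is stored as two
segments sharing one gene id; distance computations use the midpoint of
the full arc.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

Interval = tuple[int, int]

_DNA_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class Gene:
    """A gene feature on a replicon.

    ``segments`` holds one (start, end) interval for ordinary genes and
    two for genes wrapping the origin of a circular replicon, in the
    order they are read along the strandless forward coordinate.
    """

    gene_id: str
    segments: tuple[Interval, ...]
    strand: str = "+"
    coding: bool = True
    product: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.segments:
            raise ValueError(f"gene {self.gene_id}: no segments")
        for s, e in self.segments:
            if s >= e:
                raise ValueError(
                    f"gene {self.gene_id}: segment ({s}, {e}) has start >= end"
                )

    @property
    def start(self) -> int:
        return self.segments[0][0]

    @property
    def end(self) -> int:
        return self.segments[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.segments)

    @property
    def wraps(self) -> bool:
        return len(self.segments) > 1

    def midpoint(self, genome_length: int) -> float:
        """Midpoint on the circle; wrapped genes are treated as one arc."""
        s = self.segments[0][0]
        return (s + self.length / 2.0) % genome_length


@dataclass
class Genome:
    """A single replicon with an ordered gene collection."""

    replicon_id: str
    length_bp: int
    circular: bool = True
    sequence: Optional[str] = None
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")
        if self.sequence is not None:
            if len(self.sequence) != self.length_bp:
                raise ValueError(
                    f"sequence length {len(self.sequence)} != length_bp {self.length_bp}"
                )
            bad = set(self.sequence) - _DNA_ALPHABET
            if bad:
                raise ValueError(f"sequence contains non-ACGTN symbols: {sorted(bad)}")
        index: dict[str, Gene] = {}
        for g in self.genes:
            if g.gene_id in index:
                raise ValueError(f"duplicate gene id {g.gene_id!r}")
            index[g.gene_id] = g
            for s, e in g.segments:
                if s < 0 or e > self.length_bp:
                    raise ValueError(
                        f"gene {g.gene_id} segment ({s}, {e}) outside "
                        f"[0, {self.length_bp})"
                    )
        self._gene_index = index

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> Gene:
        return self._gene_index[gene_id]

    @property
    def coding_genes(self) -> list[Gene]:
        return [g for g in self.genes if g.coding]


class ProteinSet(dict):
    """Mapping gene_id -> amino-acid sequence (20 letters + X)."""

    _AA = set("ACDEFGHIKLMNPQRSTVWYX*")

    def validate(self) -> None:
        for gid, seq in self.items():
            if not seq:
                raise ValueError(f"empty protein sequence for {gid}")
            bad = set(seq.upper()) - self._AA
            if bad:
                raise ValueError(f"protein {gid} has invalid symbols {sorted(bad)}")


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of half-open intervals, returned sorted and disjoint."""
    ivs = sorted(intervals)
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def complement_intervals(intervals: list[Interval], length: int) -> list[Interval]:
    """Complement of a sorted disjoint interval set within [0, length)."""
    out: list[Interval] = []
    prev = 0
    for s, e in intervals:
        if s > prev:
            out.append((prev, s))
        prev = max(prev, e)
    if prev < length:
        out.append((prev, length))
    return out


def noncoding_partition(genome: Genome) -> tuple[list[Interval], list[Interval]]:
    """Partition the replicon into merged coding intervals and their complement.

    Strand is ignored and overlapping coding features are merged, so the
    two interval sets tile [0, length_bp) exactly.
    """
    coding = merge_intervals(
        seg for g in genome.coding_genes for seg in g.segments
    )
    return coding, complement_intervals(coding, genome.length_bp)


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def circular_distance(a: float, b: float, length: int, circular: bool = True) -> float:
    """Minimal arc between two positions; linear difference if not circular."""
    d = abs(a - b)
    if circular:
        d = min(d, length - d)
    return d
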
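"""Synteny breakpoints from signed gene orders and motif-density statistics.

Breakpoints are detected as broken signed adjacencies: an adjacency
(x, y) of one order is conserved in the other iff (x, y) or (-y, -x)
appears there consecutively; circular orders close the cycle. The motif
statistics quantify GCGCGC density in breakpoint flanks versus the whole
replicon (fold enrichment) and in coding versus non-coding DNA (counts
per 10 kbp), counting overlapping occurrences.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .genome import (
    Genome,
    Interval,
    merge_intervals,
    noncoding_partition,
    total_length,
)

DENSITY_SCALE = 10_000  # report densities per 10 kbp


@dataclass
class SignedGeneOrder:
    """Ordered signed ortholog-group identifiers along one replicon."""

    replicon_id: str
    order: tuple[int, ...]
    circular: bool = True
    positions: Optional[tuple[float, ...]] = None  # bp midpoint per element

    def __post_init__(self) -> None:
        ids = [abs(x) for x in self.order]
        if len(ids) != len(set(ids)):
            raise ValueError("signed order contains a repeated identifier")
        if 0 in ids:
            raise ValueError("identifier 0 is not allowed (sign would be lost)")
        if self.positions is not None and len(self.positions) != len(self.order):
            raise ValueError("positions length differs from order length")


@dataclass
class BreakpointSet:
    replicon_id: str
    broken_adjacencies: list[tuple[int, int]]
    coordinates: list[float] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.broken_adjacencies)


def _adjacencies(order: Sequence[int], circular: bool) -> list[tuple[int, int]]:
    adj = list(zip(order, order[1:]))
    if circular and len(order) > 1:
        adj.append((order[-1], order[0]))
    return adj


def _adjacency_index(order: Sequence[int], circular: bool) -> set[tuple[int, int]]:
    """Orientation-free adjacency set: each adjacency stored canonically."""
    idx = set()
    for x, y in _adjacencies(order, circular):
        idx.add((x, y))
        idx.add((-y, -x))
    return idx


def detect_breakpoints(
    order_a: SignedGeneOrder, order_b: SignedGeneOrder
) -> BreakpointSet:
    """Breakpoints of ``order_a`` relative to ``order_b``.

    Both orders are first restricted to their shared identifiers. Each
    non-conserved adjacency of order_a is a breakpoint; its coordinate
    (when positions are available) is the midpoint between the two
    flanking genes.
    """
    shared = {abs(x) for x in order_a.order} & {abs(x) for x in order_b.order}
    if len(shared) < 2:
        raise ValueError("orders share fewer than 2 identifiers")

    def restrict(o: SignedGeneOrder) -> tuple[list[int], list[Optional[float]]]:
        kept = [
            (x, o.positions[i] if o.positions else None)
            for i, x in enumerate(o.order)
            if abs(x) in shared
        ]
        return [x for x, _ in kept], [p for _, p in kept]

    oa, pa = restrict(order_a)
    ob, _ = restrict(order_b)
    index_b = _adjacency_index(ob, order_b.circular)
    broken: list[tuple[int, int]] = []
    coords: list[float] = []
    n = len(oa)
    for i, (x, y) in enumerate(_adjacencies(oa, order_a.circular)):
        if (x, y) in index_b:
            continue
        broken.append((x, y))
        if order_a.positions is not None:
            p1, p2 = pa[i], pa[(i + 1) % n]
            if p1 is not None and p2 is not None:
                coords.append((p1 + p2) / 2.0)
    return BreakpointSet(
        replicon_id=order_a.replicon_id,
        broken_adjacencies=broken,
        coordinates=sorted(coords),
    )


def read_backbone_orders(
    path, replicon_a: str = "A", replicon_b: str = "B"
) -> tuple[SignedGeneOrder, SignedGeneOrder]:
    """Signed block orders from an aligner backbone table.

    The table is tab-separated with a header and four columns per
    pairwise comparison: seq0_leftend, seq0_rightend, seq1_leftend,
    seq1_rightend; negative coordinates mark reverse-strand blocks and
    0/0 rows mark blocks absent from that genome. Shared blocks are
    numbered in genome-A order and each genome's signed block order is
    returned, ready for ``detect_breakpoints``.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns[:4])
    blocks = []
    for idx, row in df.iterrows():
        a_lo, a_hi, b_lo, b_hi = (int(row[c]) for c in cols)
        if (a_lo == 0 and a_hi == 0) or (b_lo == 0 and b_hi == 0):
            continue  # genome-specific segment, not shared synteny
        blocks.append((a_lo, a_hi, b_lo, b_hi))
    if len(blocks) < 2:
        raise ValueError("backbone table holds fewer than 2 shared blocks")
    blocks.sort(key=lambda t: abs(t[0]))
    order_a, b_entries, positions_a = [], [], []
    for bid, (a_lo, a_hi, b_lo, b_hi) in enumerate(blocks, start=1):
        sign_a = -1 if a_lo < 0 else 1
        sign_b = -1 if b_lo < 0 else 1
        order_a.append(sign_a * bid)
        positions_a.append((abs(a_lo) + abs(a_hi)) / 2.0)
        # orientation of the block in B relative to its strand in A
        b_entries.append((abs(b_lo), sign_a * sign_b * bid))
    b_entries.sort()
    return (
        SignedGeneOrder(
            replicon_a, tuple(order_a), circular=False,
            positions=tuple(positions_a),
        ),
        SignedGeneOrder(
            replicon_b, tuple(x for _, x in b_entries), circular=False
        ),
    )


def count_motif(seq: str, motif: str) -> int:
    """Overlapping occurrences of ``motif`` on the given strand."""
    if not motif:
        raise ValueError("motif must be non-empty")
    n = 0
    i = seq.find(motif)
    while i != -1:
        n += 1
        i = seq.find(motif, i + 1)
    return n


@dataclass
class MotifStats:
    motif: str
    window_bp: int
    flank_count: int
    flank_length_bp: int
    genome_count: int
    genome_length_bp: int

    @property
    def flank_density(self) -> float:
        if self.flank_length_bp == 0:
            return 0.0
        return self.flank_count / self.flank_length_bp * DENSITY_SCALE

    @property
    def genome_density(self) -> float:
        return self.genome_count / self.genome_length_bp * DENSITY_SCALE

    @property
    def fold_enrichment(self) -> float:
        if self.genome_density == 0:
            return float("inf") if self.flank_density > 0 else 0.0
        return self.flank_density / self.genome_density


def _flank_windows(
    breakpoints: Sequence[float], window: int, length: int, circular: bool
) -> list[Interval]:
    """Union of +-window intervals around breakpoints, clipped or wrapped."""
    raw: list[Interval] = []
    for b in breakpoints:
        lo, hi = int(round(b)) - window, int(round(b)) + window
        if circular:
            lo %= length
            hi = lo + 2 * window
            if hi <= length:
                raw.append((lo, hi))
            else:
                raw.append((lo, length))
                raw.append((0, hi - length))
        else:
            raw.append((max(0, lo), min(length, hi)))
    return merge_intervals(raw)


def flank_enrichment(
    genome_seq: str,
    breakpoints: Sequence[float],
    motif: str = "GCGCGC",
    window: int = 40,
    circular: bool = True,
) -> MotifStats:
    """Motif density in breakpoint flanks versus the whole replicon.

    Flank windows are unioned before counting so overlapping windows are
    not double-counted. The whole-replicon count includes origin-spanning
    occurrences on circular sequences, making the density invariant to
    rotation.
    """
    L = len(genome_seq)
    windows = _flank_windows(breakpoints, window, L, circular)
    flank_count = sum(count_motif(genome_seq[s:e], motif) for s, e in windows)
    flank_len = total_length(windows)
    genome_count = count_motif(genome_seq, motif)
    if circular and len(motif) > 1:
        # occurrences spanning the origin
        joint = genome_seq[-(len(motif) - 1):] + genome_seq[: len(motif) - 1]
        genome_count += count_motif(joint, motif)
    return MotifStats(
        motif=motif,
        window_bp=window,
        flank_count=flank_count,
        flank_length_bp=flank_len,
        genome_count=genome_count,
        genome_length_bp=L,
    )


@dataclass
class PartitionDensities:
    motif: str
    coding_count: int
    coding_bp: int
    noncoding_count: int
    noncoding_bp: int

    def _density(self, count: int, bp: int) -> Optional[float]:
        if bp == 0:
            return None
        return count / bp * DENSITY_SCALE

    @property
    def coding_density(self) -> Optional[float]:
        return self._density(self.coding_count, self.coding_bp)

    @property
    def noncoding_density(self) -> Optional[float]:
        return self._density(self.noncoding_count, self.noncoding_bp)

    def report(self) -> dict:
        """One-decimal densities, the reporting convention for tables."""
        fmt = lambda v: None if v is None else round(v, 1)
        return {
            "motif": self.motif,
            "coding_per_10kbp": fmt(self.coding_density),
            "noncoding_per_10kbp": fmt(self.noncoding_density),
        }


def coding_noncoding_density(genome: Genome, motif: str) -> PartitionDensities:
    """Motif densities (per 10 kbp) in coding vs non-coding partitions.

    Each interval is scanned independently, so matches spanning interval
    junctions are never counted.
    """
    if genome.sequence is None:
        raise ValueError("genome has no sequence")
    coding, noncoding = noncoding_partition(genome)
    seq = genome.sequence

    def count_in(intervals: list[Interval]) -> int:
        return sum(count_motif(seq[s:e], motif) for s, e in intervals)

    return PartitionDensities(
        motif=motif,
        coding_count=count_in(coding),
        coding_bp=total_length(coding),
        noncoding_count=count_in(noncoding),
        noncoding_bp=total_length(noncoding),
    )
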
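"""Alignment filtering, distances, Neighbour-Joining and tree comparison.

Protein distances are Poisson-corrected p-distances, d = -ln(1 - p),
computed over mutually ungapped retained columns. Neighbour-Joining is
the canonical Saitou-Nei agglomeration with the Studier-Keppler Q
criterion; on additive matrices it recovers the generating tree exactly.
Topology comparison uses the unrooted Robinson-Foulds symmetric
difference; "same topology" means RF = 0.
"""
from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
from dendropy.calculate import treecompare

logger = logging.getLogger(__name__)

GAP_CHARS = set("-.")


@dataclass
class Alignment:
    """Equal-length aligned sequences with a retained-column mask."""

    taxa: list[str]
    rows: list[str]
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if self.rows:
            n = len(self.rows[0])
            if any(len(r) != n for r in self.rows):
                raise ValueError("alignment rows differ in length")
        if self.mask is None:
            self.mask = np.ones(self.n_columns, dtype=bool)
        elif len(self.mask) != self.n_columns:
            raise ValueError("mask length differs from alignment length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def retained(self) -> "Alignment":
        """Alignment restricted to masked-in columns."""
        idx = np.flatnonzero(self.mask)
        rows = ["".join(r[i] for i in idx) for r in self.rows]
        return Alignment(list(self.taxa), rows)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("distance matrix diagonal must be zero")

    def get(self, a: str, b: str) -> float:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.matrix[i, j])

    def reordered(self, taxa: Sequence[str]) -> "DistanceMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return DistanceMatrix(list(taxa), self.matrix[np.ix_(idx, idx)])


@dataclass
class FilterResult:
    alignment: Alignment
    retained_fraction: float
    passes_gate: bool


def conserved_block_filter(
    aln: Alignment,
    max_gap_fraction: float = 0.0,
    min_conservation: float = 0.5,
    min_retained_fraction: float = 0.75,
) -> FilterResult:
    """Drop ambiguous alignment columns and gate on the retained fraction.

    A column survives iff its gap fraction is at most ``max_gap_fraction``
    and the most frequent residue reaches ``min_conservation`` of the
    rows. Alignments keeping less than ``min_retained_fraction`` of their
    columns are flagged for downstream exclusion (``passes_gate=False``)
    rather than rejected here.
    """
    if len(aln.rows) < 2:
        raise ValueError("need at least 2 rows to filter")
    n_rows = len(aln.rows)
    ncol = aln.n_columns
    mask = np.zeros(ncol, dtype=bool)
    arr = np.array([list(r) for r in aln.rows])
    is_gap = np.isin(arr, list(GAP_CHARS))
    gap_frac = is_gap.mean(axis=0)
    for j in range(ncol):
        if gap_frac[j] > max_gap_fraction:
            continue
        residues = arr[~is_gap[:, j], j]
        if residues.size == 0:
            continue
        top = Counter(residues.tolist()).most_common(1)[0][1]
        if top / n_rows >= min_conservation:
            mask[j] = True
    frac = float(mask.sum()) / ncol if ncol else 0.0
    filtered = Alignment(list(aln.taxa), list(aln.rows), mask)
    return FilterResult(filtered, frac, frac >= min_retained_fraction)


def protein_distance(aln: Alignment) -> DistanceMatrix:
    """Poisson-corrected pairwise p-distance over retained columns."""
    if len(aln.rows) < 2:
        raise ValueError("need at least 2 rows")
    sub = aln.retained()
    n = len(sub.taxa)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pairs = [
                (a, b)
                for a, b in zip(sub.rows[i], sub.rows[j])
                if a not in GAP_CHARS and b not in GAP_CHARS
            ]
            if not pairs:
                raise ValueError(
                    f"no comparable columns between {sub.taxa[i]} and {sub.taxa[j]}"
                )
            p = sum(1 for a, b in pairs if a != b) / len(pairs)
            if p >= 1.0:
                raise ValueError(
                    f"saturated pair {sub.taxa[i]}/{sub.taxa[j]}: p-distance >= 1"
                )
            mat[i, j] = mat[j, i] = -math.log(1.0 - p)
    return DistanceMatrix(list(sub.taxa), mat)


class _NJNode:
    __slots__ = ("label", "newick", "rep")

    def __init__(self, label: str, newick: str, rep: str):
        self.label = label
        self.newick = newick
        self.rep = rep  # lexicographically smallest leaf, for tie-breaks


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei Neighbour-Joining with deterministic tie-breaking.

    Ties in the Q criterion are broken toward the pair whose
    (smallest-leaf, smallest-leaf) representative names sort first.
    Negative branch-length estimates are clamped to zero and the deficit
    logged.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [_NJNode(t, f"{t}", t) for t in dm.taxa]
    d = {
        (i, j): float(dm.matrix[i, j])
        for i in range(n)
        for j in range(n)
    }
    active = list(range(n))
    next_id = n

    def dist(i: int, j: int) -> float:
        return 0.0 if i == j else d[(min(i, j), max(i, j))]

    node_of = {i: nodes[i] for i in range(n)}

    def clamp(x: float, context: str) -> float:
        if x < 0:
            logger.debug("clamped negative branch length %.6g at %s", x, context)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        best_key = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                reps = tuple(sorted((node_of[i].rep, node_of[j].rep)))
                key = (q, reps)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (i, j)
        i, j = best  # type: ignore[misc]
        dij = dist(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li = clamp(li, node_of[i].label)
        lj = clamp(lj, node_of[j].label)
        ni, nj = node_of[i], node_of[j]
        rep = min(ni.rep, nj.rep)
        new = _NJNode(
            f"cl_{next_id}",
            f"({ni.newick}:{li:.12g},{nj.newick}:{lj:.12g})",
            rep,
        )
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (dist(i, k) + dist(j, k) - dij)
            d[(min(k, next_id), max(k, next_id))] = max(dk, 0.0)
        node_of[next_id] = new
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    # terminal three-star: branch lengths from the three-point formulas
    a, b, c = active
    la = clamp(0.5 * (dist(a, b) + dist(a, c) - dist(b, c)), "terminal")
    lb = clamp(0.5 * (dist(a, b) + dist(b, c) - dist(a, c)), "terminal")
    lc = clamp(0.5 * (dist(a, c) + dist(b, c) - dist(a, b)), "terminal")
    na, nb, nc = node_of[a], node_of[b], node_of[c]
    newick = (
        f"({na.newick}:{la:.12g},{nb.newick}:{lb:.12g},{nc.newick}:{lc:.12g});"
    )
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )


def total_branch_length(tree: dendropy.Tree) -> float:
    return sum(
        e.length for e in tree.preorder_edge_iter() if e.length is not None
    )


def patristic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix, taxa sorted by name."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(taxa)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(labels, mat)


def patristic_normalized(tree: dendropy.Tree) -> DistanceMatrix:
    """Patristic distances divided by the tree's total branch length."""
    total = total_branch_length(tree)
    if total <= 0:
        raise ValueError("tree has zero total branch length")
    pm = patristic_matrix(tree)
    return DistanceMatrix(pm.taxa, pm.matrix / total)


def _common_namespace(
    *trees: dendropy.Tree,
) -> list[dendropy.Tree]:
    tns = dendropy.TaxonNamespace()
    out = []
    for t in trees:
        out.append(
            dendropy.Tree.get(
                data=t.as_string(schema="newick"),
                schema="newick",
                taxon_namespace=tns,
                preserve_underscores=True,
            )
        )
    return out


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted Robinson-Foulds symmetric difference of bipartitions."""
    if leaf_labels(t1) != leaf_labels(t2):
        raise ValueError("trees have different leaf sets")
    a, b = _common_namespace(t1, t2)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(treecompare.symmetric_difference(a, b))


def topology_signature(tree: dendropy.Tree) -> frozenset[frozenset[str]]:
    """Unrooted topology fingerprint: the set of nontrivial bipartitions,
    each encoded as the smaller-by-sorting side's leaf set."""
    labels = sorted(leaf_labels(tree))
    full = frozenset(labels)
    (t,) = _common_namespace(tree)
    t.encode_bipartitions()
    sig = set()
    for bp in t.bipartition_encoding:
        side = frozenset(
            lf.label for lf in bp.leafset_taxa(t.taxon_namespace)
        )
        other = full - side
        if len(side) < 2 or len(other) < 2:
            continue
        sig.add(min(side, other, key=lambda s: sorted(s)))
    return frozenset(sig)


def majority_topology(
    trees: Sequence[dendropy.Tree],
    reference: Optional[dendropy.Tree] = None,
) -> dendropy.Tree:
    """Plurality unrooted topology among the input trees.

    Ties are broken toward ``reference``'s topology if supplied, else
    toward the first-seen topology.
    """
    if not trees:
        raise ValueError("no trees supplied")
    groups: dict[frozenset, list[int]] = {}
    for idx, t in enumerate(trees):
        groups.setdefault(topology_signature(t), []).append(idx)
    ref_sig = topology_signature(reference) if reference is not None else None
    best_sig = None
    best_rank = None
    for sig, members in groups.items():
        rank = (-len(members), 0 if sig == ref_sig else 1, members[0])
        if best_rank is None or rank < best_rank:
            best_rank = rank
            best_sig = sig
    return trees[groups[best_sig][0]]


def consensus_distances(
    normalized: Sequence[DistanceMatrix],
) -> DistanceMatrix:
    """Element-wise mean of per-tree normalized distance matrices."""
    if not normalized:
        raise ValueError("no matrices to average")
    taxa = normalized[0].taxa
    stack = np.stack([m.reordered(taxa).matrix for m in normalized])
    return DistanceMatrix(list(taxa), stack.mean(axis=0))
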
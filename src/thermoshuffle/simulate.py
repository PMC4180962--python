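"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the shape of the real inputs: a circular
bacterial chromosome with operon-structured gene coordinates and
pathway annotations that share compounds preferentially within operons;
ortholog protein pairs with a controllable directional substitution
bias; gene-tree sets derived from a five-taxon species tree (two
ingroup pairs plus an outgroup, mirroring the Thermus/Meiothermus
comparison) with planted transfer events; genome sequences with a motif
planted at a chosen fold around known breakpoints; and signed gene
orders scrambled by inversions and translocations.

All generators are deterministic given their seed, and every planted
element is recoverable by the corresponding analysis stage under
zero-noise settings.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .genome import Gene, Genome
from .metnet import OperonSet
from .skew import AMINO_ACIDS

# Five-taxon default mirroring the studied genomes: a pair of
# T. thermophilus strains, T. scotoductus, and the two Meiothermus
# species with M. ruber as the customary root.
DEFAULT_SPECIES_TREE = (
    "(((T_thermophilus_HB8:0.02,T_thermophilus_HB27:0.02):0.10,"
    "T_scotoductus:0.12):0.08,M_silvanus:0.06,M_ruber:0.09);"
)


@dataclass
class SimSpec:
    """Parameters of the synthetic study conditions."""

    seed: int
    n_genes: int = 600
    genome_length: int = 2_000_000
    operon_size_mean: float = 3.0
    n_pathways: int = 100
    leakage: float = 0.0
    gene_length_range: tuple[int, int] = (600, 1200)
    intra_gap_range: tuple[int, int] = (20, 100)
    inter_gap_range: tuple[int, int] = (150, 400)
    pathway_genes_range: tuple[int, int] = (2, 3)
    hgt_events: tuple[tuple[str, str, str], ...] = ()  # (gene_id, donor, recipient)
    substitution_bias: dict = field(default_factory=dict)  # (A1,A2) -> excess prob
    motif_enrichment: float = 4.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.leakage <= 1.0:
            raise ValueError("leakage must be in [0, 1]")
        if self.motif_enrichment < 0:
            raise ValueError("motif_enrichment must be >= 0")
        for v in self.substitution_bias.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("bias probabilities must be in [0, 1]")


@dataclass
class GroundTruth:
    operons: list[tuple[str, ...]] = field(default_factory=list)
    functional_pairs: set = field(default_factory=set)
    breakpoints: list = field(default_factory=list)
    transfer_events: list = field(default_factory=list)
    skew_bias: dict = field(default_factory=dict)
    planted_flank_count: int = 0
    planted_background_count: int = 0


# --- genome with operons and pathway annotation -------------------------

def _operon_sizes(rng: np.random.Generator, n_genes: int, mean: float,
                  cap: int = 15) -> list[int]:
    """Truncated-geometric operon sizes (support 1..cap) summing to n_genes."""
    p = 1.0 / mean
    sizes: list[int] = []
    total = 0
    while total < n_genes:
        s = min(int(rng.geometric(p)), cap, n_genes - total)
        sizes.append(s)
        total += s
    return sizes


def simulate_genome(
    spec: SimSpec,
) -> tuple[Genome, OperonSet, pd.DataFrame, GroundTruth]:
    """Circular genome with planted operons and pathway annotation.

    Genes are laid out in co-directional runs (operons) separated by
    larger intergenic gaps and possible strand flips; operon sizes
    follow a truncated geometric distribution with the requested mean.
    Each pathway annotates a contiguous run of genes inside one operon
    with a shared compound; with probability ``leakage`` a participant
    is swapped for a random gene elsewhere in the genome.
    """
    if spec.n_genes < 2:
        raise ValueError("need at least 2 genes")
    rng = np.random.default_rng(spec.seed)
    sizes = _operon_sizes(rng, spec.n_genes, spec.operon_size_mean)
    n_ops = len(sizes)

    # draw the layout first, then spread leftover length over the
    # inter-operon gaps so operons cover the whole circle
    gene_lengths = [
        [int(rng.integers(*spec.gene_length_range)) for _ in range(s)]
        for s in sizes
    ]
    intra_gaps = [
        [int(rng.integers(*spec.intra_gap_range)) for _ in range(s - 1)]
        for s in sizes
    ]
    inter_gaps = [int(rng.integers(*spec.inter_gap_range)) for _ in range(n_ops)]
    strands = ["+" if rng.random() < 0.5 else "-" for _ in range(n_ops)]
    footprint = (
        sum(sum(gl) for gl in gene_lengths)
        + sum(sum(ig) for ig in intra_gaps)
        + sum(inter_gaps)
    )
    leftover = spec.genome_length - footprint
    if leftover < 0:
        raise ValueError(
            "gene packing exceeds genome_length; "
            "increase genome_length or reduce n_genes"
        )
    extra = rng.multinomial(leftover, [1.0 / n_ops] * n_ops)

    genes: list[Gene] = []
    operons: list[tuple[str, ...]] = []
    pos = 0
    gid = 0
    for op_idx, size in enumerate(sizes):
        members = []
        for i in range(size):
            start = pos
            end = pos + gene_lengths[op_idx][i]
            gid += 1
            name = f"g{gid:05d}"
            genes.append(
                Gene(
                    gene_id=name,
                    segments=((start, end),),
                    strand=strands[op_idx],
                )
            )
            members.append(name)
            pos = end
            if i < size - 1:
                pos += intra_gaps[op_idx][i]
        operons.append(tuple(members))
        pos += inter_gaps[op_idx] + int(extra[op_idx])

    genome = Genome(
        replicon_id="sim_chromosome",
        length_bp=spec.genome_length,
        circular=True,
        genes=genes,
    )
    operon_set = OperonSet(operons=operons)

    all_gene_ids = [g.gene_id for g in genes]
    multi = [op for op in operons if len(op) >= 2]
    rows = []
    for p in range(spec.n_pathways):
        op = multi[int(rng.integers(len(multi)))]
        k = int(
            rng.integers(
                spec.pathway_genes_range[0],
                min(spec.pathway_genes_range[1], len(op)) + 1,
            )
        )
        start = int(rng.integers(0, len(op) - k + 1))
        chosen = list(op[start : start + k])
        for idx in range(len(chosen)):
            if rng.random() < spec.leakage:
                chosen[idx] = all_gene_ids[int(rng.integers(len(all_gene_ids)))]
        compound = f"C{p:04d}"
        pathway = f"PWY{p:04d}"
        for idx, g in enumerate(chosen):
            rows.append(
                {
                    "gene_id": g,
                    "pathway_id": pathway,
                    "compound_id": compound,
                    "role": "substrate" if idx % 2 == 0 else "product",
                }
            )
    annotation = pd.DataFrame(
        rows, columns=["gene_id", "pathway_id", "compound_id", "role"]
    )

    truth_pairs = set()
    for _, grp in annotation.groupby(["pathway_id", "compound_id"]):
        for a, b in combinations(sorted(set(grp["gene_id"])), 2):
            truth_pairs.add(frozenset((a, b)))
    truth = GroundTruth(operons=operons, functional_pairs=truth_pairs)
    return genome, operon_set, annotation, truth


# --- ortholog proteome pairs with substitution bias ---------------------

def simulate_proteome_pair(
    n_pairs: int = 100,
    length: int = 300,
    p_identity: float = 0.9,
    bias: Optional[dict] = None,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Gap-free ortholog alignments with a planted directional bias.

    Each site keeps the reference residue with probability
    ``p_identity``; otherwise the partner residue is drawn from a
    uniform base-exchange distribution over the other 19 residues with
    ``bias[(A1, A2)]`` added to the A1->A2 channel before
    renormalization.
    """
    bias = dict(bias or {})
    for (a1, a2), e in bias.items():
        if a1 not in AMINO_ACIDS or a2 not in AMINO_ACIDS:
            raise ValueError(f"bias names invalid amino acid: {(a1, a2)}")
        if 1.0 / 19.0 + e > 1.0:
            raise ValueError(f"bias {e} pushes a probability above 1")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    n_aa = len(aa)

    # per-reference-residue substitution target distribution
    q = np.full((n_aa, n_aa), 1.0 / (n_aa - 1))
    np.fill_diagonal(q, 0.0)
    for (a1, a2), e in bias.items():
        i, j = AMINO_ACIDS.index(a1), AMINO_ACIDS.index(a2)
        q[i, j] += e
    q /= q.sum(axis=1, keepdims=True)

    alignments = []
    for _ in range(n_pairs):
        ref_idx = rng.integers(0, n_aa, size=length)
        other_idx = ref_idx.copy()
        subst = np.flatnonzero(rng.random(length) >= p_identity)
        for r in range(n_aa):  # draw targets grouped by reference residue
            at = subst[ref_idx[subst] == r]
            if at.size:
                other_idx[at] = rng.choice(n_aa, size=at.size, p=q[r])
        alignments.append(
            ("".join(aa[ref_idx]), "".join(aa[other_idx]))
        )
    return alignments, GroundTruth(skew_bias=bias)


# --- gene trees with planted transfers ----------------------------------

def default_species_tree() -> dendropy.Tree:
    return dendropy.Tree.get(
        data=DEFAULT_SPECIES_TREE, schema="newick", preserve_underscores=True
    )


def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=tree.as_string(schema="newick"),
        schema="newick",
        preserve_underscores=True,
    )


def _jitter(tree: dendropy.Tree, noise_sd: float, rng: np.random.Generator) -> None:
    """Multiplicative lognormal noise on branch lengths (rate variation)."""
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and noise_sd > 0:
            edge.length = float(edge.length) * float(rng.lognormal(0.0, noise_sd))


def _apply_transfer(
    tree: dendropy.Tree, donor: str, recipient: str, shrink: float
) -> None:
    """Regraft the recipient next to the donor with the donor-recipient
    path shrunk to ``shrink`` of its original patristic length."""
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    for name in (donor, recipient):
        if name not in labels:
            raise ValueError(f"transfer names non-leaf taxon {name!r}")
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    d_orig = pdm.patristic_distance(
        tns.get_taxon(donor), tns.get_taxon(recipient)
    )
    target = shrink * d_orig

    tree.prune_taxa_with_labels([recipient])
    donor_leaf = next(
        lf for lf in tree.leaf_node_iter() if lf.taxon.label == donor
    )
    parent = donor_leaf.parent_node
    el = donor_leaf.edge.length or 0.0
    x = min(0.5 * el, 0.5 * target)
    y = max(target - x, 1e-9)
    parent.remove_child(donor_leaf)
    mid = parent.new_child(edge_length=max(el - x, 1e-9))
    donor_leaf.edge.length = x
    mid.add_child(donor_leaf)
    tax = tns.get_taxon(recipient) or tns.new_taxon(recipient)
    mid.new_child(taxon=tax, edge_length=y)


def simulate_gene_trees(
    species_tree: Optional[dendropy.Tree] = None,
    n_congruent: int = 50,
    transfers: Sequence[tuple[str, str]] = (),
    noise_sd: float = 0.02,
    shrink: float = 0.2,
    seed: int = 0,
) -> tuple[list[tuple[str, dendropy.Tree]], GroundTruth]:
    """Gene-tree set: jittered copies of the species tree plus one
    transferred tree per (donor, recipient) entry."""
    if species_tree is None:
        species_tree = default_species_tree()
    rng = np.random.default_rng(seed)
    trees: list[tuple[str, dendropy.Tree]] = []
    truth = GroundTruth()
    for i in range(n_congruent):
        t = _clone(species_tree)
        _jitter(t, noise_sd, rng)
        trees.append((f"cong_{i:04d}", t))
    for i, (donor, recipient) in enumerate(transfers):
        t = _clone(species_tree)
        _jitter(t, noise_sd, rng)
        _apply_transfer(t, donor, recipient, shrink)
        tree_id = f"hgt_{i:04d}"
        trees.append((tree_id, t))
        truth.transfer_events.append((tree_id, donor, recipient))
    return trees, truth


# --- breakpoint motif planting ------------------------------------------

def random_sequence(length: int, gc: float = 0.5, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _scrub_motif(seq: list[str], motif: str, rng: np.random.Generator) -> None:
    """Destroy every occurrence of motif in-place by mutating one base
    per occurrence (to a symbol absent from the motif)."""
    m = len(motif)
    safe = [c for c in "ACGT" if c not in motif] or ["A"]
    for _ in range(10):
        text = "".join(seq)
        starts = []
        i = text.find(motif)
        while i != -1:
            starts.append(i)
            i = text.find(motif, i + 1)
        if not starts:
            return
        for s in starts:
            if "".join(seq[s : s + m]) != motif:
                continue  # already destroyed via an overlapping occurrence
            j = s + int(rng.integers(m))
            seq[j] = safe[int(rng.integers(len(safe)))]


def plant_breakpoint_motifs(
    genome_sequence: str,
    breakpoints: Sequence[int],
    motif: str = "GCGCGC",
    fold: float = 4.0,
    rate: float = 1e-4,
    window: int = 40,
    seed: int = 0,
    max_tries: int = 10_000,
) -> tuple[str, GroundTruth]:
    """Plant motif copies at background rate ``rate`` per bp and at
    ``fold`` times that rate inside the +-window breakpoint flanks.

    Pre-existing occurrences are scrubbed first so realized counts are
    controlled; placements never overlap (rejection sampling). Realized
    flank/background placement counts are recorded as ground truth.
    """
    if fold < 1:
        raise ValueError("fold must be >= 1")
    L = len(genome_sequence)
    for b in breakpoints:
        if not 0 <= b < L:
            raise ValueError(f"breakpoint {b} outside sequence")
    rng = np.random.default_rng(seed)
    seq = list(genome_sequence)
    _scrub_motif(seq, motif, rng)

    flank_mask = np.zeros(L, dtype=bool)
    for b in breakpoints:
        lo, hi = b - window, b + window
        idx = np.arange(lo, hi) % L
        flank_mask[idx] = True
    # valid start positions: whole motif inside the region
    m = len(motif)
    shifted = np.stack([np.roll(flank_mask, -k) for k in range(m)])
    ok_start_flank = shifted.all(axis=0)
    ok_start_bg = ~shifted.any(axis=0)

    flank_len = int(flank_mask.sum())
    bg_len = L - flank_len
    n_flank = int(rng.poisson(fold * rate * flank_len))
    n_bg = int(rng.poisson(rate * bg_len))

    occupied = np.zeros(L, dtype=bool)
    truth = GroundTruth()
    planted_starts: set[int] = set()

    def place(n: int, ok_start: np.ndarray, label: str) -> int:
        placed = 0
        candidates = np.flatnonzero(ok_start)
        if candidates.size == 0 and n > 0:
            raise ValueError(f"no room to place motifs in {label} region")
        tries = 0
        while placed < n:
            tries += 1
            if tries > max_tries:
                raise ValueError(
                    f"rejection sampling failed after {max_tries} tries ({label})"
                )
            i = int(candidates[rng.integers(candidates.size)])
            span = np.arange(i, i + m) % L
            if occupied[span].any():
                continue
            for k, j in enumerate(span):
                seq[j] = motif[k]
            occupied[span] = True
            planted_starts.add(i)
            placed += 1
        return placed

    truth.planted_flank_count = place(n_flank, ok_start_flank, "flank")
    truth.planted_background_count = place(n_bg, ok_start_bg, "background")
    truth.breakpoints = list(breakpoints)

    # A placement next to another placement or a lucky background context
    # can spell extra overlapping occurrences of the (periodic) motif;
    # mutate a non-planted base of each unintended occurrence to a symbol
    # absent from the motif, which cannot seed a new one.
    safe = [c for c in "ACGT" if c not in motif] or ["A"]
    for _ in range(10):
        text = "".join(seq) + "".join(seq[: m - 1])  # catch origin-spanners
        extra = []
        p = text.find(motif)
        while p != -1:
            if p % L not in planted_starts:
                extra.append(p % L)
            p = text.find(motif, p + 1)
        if not extra:
            break
        for p in extra:
            for j in range(p, p + m):
                if not occupied[j % L]:
                    seq[j % L] = safe[int(rng.integers(len(safe)))]
                    break
    return "".join(seq), truth


# --- rearranged signed gene orders --------------------------------------

def _broken_adjacencies(
    original: Sequence[int], rearranged: Sequence[int], circular: bool = True
) -> set[tuple[int, int]]:
    """Adjacencies of ``original`` absent (up to orientation) from
    ``rearranged``. Standalone ground-truth computation for the simulator."""
    def adj(order):
        pairs = list(zip(order, order[1:]))
        if circular and len(order) > 1:
            pairs.append((order[-1], order[0]))
        return pairs

    present = set()
    for x, y in adj(rearranged):
        present.add((x, y))
        present.add((-y, -x))
    return {(x, y) for x, y in adj(original) if (x, y) not in present}


def simulate_rearranged_order(
    gene_order: Sequence[int],
    n_inversions: int = 1,
    n_translocations: int = 0,
    seed: int = 0,
    circular: bool = True,
) -> tuple[tuple[int, ...], set[tuple[int, int]]]:
    """Scramble a signed order by random inversions and block
    translocations; return the new order and the exact set of original
    adjacencies broken in the final product."""
    order = list(gene_order)
    n = len(order)
    if n < 2:
        raise ValueError("order too short to rearrange")
    rng = np.random.default_rng(seed)
    for _ in range(n_inversions):
        i, j = sorted(rng.integers(0, n, size=2))
        j = min(j + 1, n)
        if i == j:
            j = min(i + 1, n)
        order[i:j] = [-x for x in reversed(order[i:j])]
    for _ in range(n_translocations):
        i, j = sorted(rng.integers(0, n, size=2))
        j = min(j + 1, n)
        if j - i >= n:
            continue
        block = order[i:j]
        rest = order[:i] + order[j:]
        k = int(rng.integers(0, len(rest) + 1))
        order = rest[:k] + block + rest[k:]
    new_order = tuple(order)
    return new_order, _broken_adjacencies(gene_order, new_order, circular)
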
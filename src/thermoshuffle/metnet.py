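"""Metabolic network construction and cross-clustering against the genome.

Two genes are metabolic neighbors when their enzymes act on the same
chemical compound (substrate or product). Abundant currency compounds
(water, ATP, co-factors) are removed by a gene-degree filter: any
compound annotated to more than ``max_links`` distinct genes is
discarded before edges are drawn. The cross-clustering coefficient of a
node is the probability that two of its metabolic neighbors also share
a genomic edge (same operon, or chromosomal distance at most the
average operon length of 10 kb); the genome-wide coefficient averages
over all nodes with at least two neighbors.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import networkx as nx
import pandas as pd

from .genome import Genome
from .colocalization import gene_distance

DEFAULT_MAX_LINKS = 10
DEFAULT_OPERON_LENGTH = 10_000  # bp; average operon length


@dataclass
class OperonSet:
    """Operons as ordered tuples of gene ids, with a reverse index."""

    operons: list[tuple[str, ...]]
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            for i, op in enumerate(self.operons):
                for g in op:
                    self.index[g] = i

    def same_operon(self, g1: str, g2: str) -> bool:
        i, j = self.index.get(g1), self.index.get(g2)
        return i is not None and i == j

    @property
    def mean_size(self) -> float:
        return sum(len(o) for o in self.operons) / len(self.operons)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"operon_id": i, "rank": r, "gene_id": g}
                for i, op in enumerate(self.operons)
                for r, g in enumerate(op)
            ]
        )


def build_network(
    annotation: pd.DataFrame,
    max_links: int = DEFAULT_MAX_LINKS,
    pathway_whitelist: Optional[Sequence[str]] = None,
) -> nx.Graph:
    """Metabolic graph over genes from a (gene, pathway, compound, role)
    annotation table.

    A compound is discarded iff strictly more than ``max_links`` distinct
    genes are annotated to it; surviving compounds connect every pair of
    their genes. Discarded compounds are recorded on the graph as
    ``G.graph["discarded_compounds"]``. An optional pathway whitelist
    restricts the annotation first (the well-annotated common-pathway
    mode).
    """
    df = annotation
    if pathway_whitelist is not None:
        df = df[df["pathway_id"].isin(set(pathway_whitelist))]
    g = nx.Graph(discarded_compounds=[])
    g.add_nodes_from(sorted(set(df["gene_id"])))
    for compound, grp in df.groupby("compound_id"):
        genes = sorted(set(grp["gene_id"]))
        if len(genes) > max_links:
            g.graph["discarded_compounds"].append((compound, len(genes)))
            continue
        for a, b in combinations(genes, 2):
            if g.has_edge(a, b):
                g.edges[a, b]["compounds"].add(compound)
            else:
                g.add_edge(a, b, compounds={compound})
    return g


def genomic_edge(
    genome: Genome,
    operons: OperonSet,
    g1: str,
    g2: str,
    max_dist: int = DEFAULT_OPERON_LENGTH,
) -> bool:
    """True iff the genes share an operon or lie within ``max_dist`` bp
    (inclusive boundary). Genes missing from the genome never link."""
    if g1 == g2:
        return False
    if operons.same_operon(g1, g2):
        return True
    try:
        d = gene_distance(genome, g1, g2)
    except KeyError:
        return False
    return d <= max_dist


@dataclass
class CrossClusteringResult:
    per_node: dict[str, float]
    genome_wide: Optional[float]
    n_evaluated: int
    n_undefined: int
    n_pairs_total: int

    def to_frame(self, network: nx.Graph) -> pd.DataFrame:
        rows = []
        for node, c in sorted(self.per_node.items()):
            deg = network.degree(node)
            rows.append(
                {
                    "node": node,
                    "degree": deg,
                    "neighbor_pairs": deg * (deg - 1) // 2,
                    "C_i": c,
                }
            )
        return pd.DataFrame(rows, columns=["node", "degree", "neighbor_pairs", "C_i"])


def cross_clustering(
    network: nx.Graph,
    genome: Genome,
    operons: OperonSet,
    max_dist: int = DEFAULT_OPERON_LENGTH,
) -> CrossClusteringResult:
    """Per-node and genome-wide cross-clustering coefficients.

    C_i = (# neighbor pairs of i with a genomic edge) / (# neighbor
    pairs of i). Nodes with fewer than two metabolic neighbors have no
    pairs, so their coefficient is undefined and they are excluded from
    (but counted alongside) the genome-wide mean.
    """
    per_node: dict[str, float] = {}
    n_undefined = 0
    n_pairs_total = 0
    for node in network.nodes:
        nbrs = sorted(network.neighbors(node))
        if len(nbrs) < 2:
            n_undefined += 1
            continue
        pairs = list(combinations(nbrs, 2))
        linked = sum(
            1 for a, b in pairs if genomic_edge(genome, operons, a, b, max_dist)
        )
        n_pairs_total += len(pairs)
        per_node[node] = linked / len(pairs)
    genome_wide = (
        sum(per_node.values()) / len(per_node) if per_node else None
    )
    return CrossClusteringResult(
        per_node=per_node,
        genome_wide=genome_wide,
        n_evaluated=len(per_node),
        n_undefined=n_undefined,
        n_pairs_total=n_pairs_total,
    )


def predict_operons(
    genome: Genome,
    max_gap: int = 100,
    require_same_strand: bool = True,
) -> OperonSet:
    """Operons as maximal same-strand gene runs with small intergenic gaps.

    Genes are taken in coordinate order; a run breaks at a strand switch
    (when ``require_same_strand``) or an intergenic gap above ``max_gap``
    bp. On circular replicons the first and last runs merge when they
    are compatible across the origin. Singleton genes form size-1
    operons.
    """
    genes = sorted(genome.genes, key=lambda g: g.start)
    if not genes:
        return OperonSet(operons=[])
    runs: list[list] = [[genes[0]]]
    for prev, cur in zip(genes, genes[1:]):
        gap = cur.start - prev.end
        same = (not require_same_strand) or (cur.strand == prev.strand)
        if same and 0 <= gap <= max_gap:
            runs[-1].append(cur)
        else:
            runs.append([cur])
    if genome.circular and len(runs) > 1:
        first, last = runs[0], runs[-1]
        gap = genome.length_bp - last[-1].end + first[0].start
        same = (not require_same_strand) or (
            first[0].strand == last[-1].strand
        )
        if same and 0 <= gap <= max_gap:
            runs[0] = last + first
            runs.pop()
    return OperonSet(operons=[tuple(g.gene_id for g in r) for r in runs])


def read_operon_table(path) -> OperonSet:
    """Operons from a tab-separated (operon_id, rank, gene_id) table."""
    df = pd.read_csv(path, sep="\t")
    ops = [
        tuple(grp.sort_values("rank")["gene_id"])
        for _, grp in df.groupby("operon_id", sort=True)
    ]
    return OperonSet(operons=ops)
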
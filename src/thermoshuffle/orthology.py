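"""Reciprocal-best-hit orthology with a coverage filter and core groups.

A pair of genes from two genomes is an ortholog candidate when each is
the other's unique best-scoring hit in the cross-genome searches. False
positives are removed when the pairwise alignment covers less than 70%
of either protein. Core groups across N genomes are complete cliques of
filtered pairs: one member per genome, all N(N-1)/2 pairs present.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    genome_a: str
    genome_b: str
    coverage_a: float = 1.0
    coverage_b: float = 1.0

    def __post_init__(self) -> None:
        if self.genome_a == self.genome_b:
            raise ValueError("ortholog pair must span two genomes")

    @property
    def key(self) -> frozenset:
        return frozenset(
            [(self.genome_a, self.gene_a), (self.genome_b, self.gene_b)]
        )


@dataclass(frozen=True)
class OrthologGroup:
    group_id: str
    members: tuple[tuple[str, str], ...]  # (genome_id, gene_id), sorted

    def gene_in(self, genome_id: str) -> str:
        for g, gene in self.members:
            if g == genome_id:
                return gene
        raise KeyError(genome_id)


def _best_hits(
    table: pd.DataFrame, tie_policy: str
) -> dict[str, Optional[str]]:
    """query -> unique best subject (None when dropped by tie policy)."""
    best: dict[str, Optional[str]] = {}
    for query, grp in table.groupby("query"):
        top = grp["bitscore"].max()
        winners = sorted(grp.loc[grp["bitscore"] == top, "subject"])
        if len(winners) == 1:
            best[query] = winners[0]
        elif tie_policy == "lexicographic":
            logger.info(
                "bitscore tie for %s among %s; chose %s",
                query,
                winners,
                winners[0],
            )
            best[query] = winners[0]
        elif tie_policy == "drop":
            logger.info("bitscore tie for %s; dropped (policy=drop)", query)
            best[query] = None
        else:
            raise ValueError(f"unknown tie policy {tie_policy!r}")
    return best


def reciprocal_best_hits(
    ab: pd.DataFrame,
    ba: pd.DataFrame,
    genome_a: str = "A",
    genome_b: str = "B",
    tie_policy: str = "lexicographic",
) -> list[OrthologPair]:
    """Mutual-unique-best-hit pairs from two directed hit tables.

    ``ab`` queries genome A's proteins against genome B, ``ba`` the
    reverse. Score ties are resolved by ``tie_policy``: the default
    keeps the lexicographically smallest subject (and logs it);
    ``drop`` discards the ambiguous query instead.
    """
    qa, qb = set(ab["query"]), set(ba["query"])
    if qa & qb:
        raise ValueError(
            "same ids appear as queries in both tables - are the tables swapped?"
        )
    best_ab = _best_hits(ab, tie_policy)
    best_ba = _best_hits(ba, tie_policy)
    pairs = []
    for a, b in sorted(best_ab.items()):
        if b is not None and best_ba.get(b) == a:
            pairs.append(
                OrthologPair(gene_a=a, gene_b=b, genome_a=genome_a, genome_b=genome_b)
            )
    return pairs


# --- coverage filtering -------------------------------------------------

def make_aligner() -> Align.PairwiseAligner:
    """Affine-gap global protein aligner: BLOSUM62, open 11, extend 1."""
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    # terminal gaps free so coverage reflects the aligned core
    aligner.target_end_gap_score = 0.0
    aligner.query_end_gap_score = 0.0
    return aligner


def alignment_coverage(row_a: str, row_b: str) -> tuple[float, float]:
    """Fraction of each ungapped sequence inside the aligned core.

    The core is the column span between the first and last column where
    both rows carry a residue; terminal overhangs do not count.
    """
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows differ in length")
    both = [
        i for i, (x, y) in enumerate(zip(row_a, row_b)) if x != "-" and y != "-"
    ]
    if not both:
        return 0.0, 0.0
    lo, hi = both[0], both[-1] + 1
    core_a = sum(1 for c in row_a[lo:hi] if c != "-")
    core_b = sum(1 for c in row_b[lo:hi] if c != "-")
    len_a = sum(1 for c in row_a if c != "-")
    len_b = sum(1 for c in row_b if c != "-")
    return core_a / len_a, core_b / len_b


def align_pair(seq_a: str, seq_b: str) -> tuple[str, str]:
    aligner = make_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    a, b = str(aln[0]), str(aln[1])
    return a, b


def coverage_filter(
    pair: OrthologPair,
    alignment: tuple[str, str],
    min_fraction: float = 0.70,
    require_both: bool = True,
) -> bool:
    """Keep the pair iff the aligned core covers >= min_fraction of both
    sequences (inclusive boundary). ``require_both=False`` relaxes the
    rule to either sequence."""
    row_a, row_b = alignment
    if not row_a or not row_b:
        logger.warning("empty alignment for pair %s/%s: dropped", pair.gene_a, pair.gene_b)
        return False
    cov_a, cov_b = alignment_coverage(row_a, row_b)
    if require_both:
        return cov_a >= min_fraction and cov_b >= min_fraction
    return cov_a >= min_fraction or cov_b >= min_fraction


# --- core groups --------------------------------------------------------

def core_groups(
    pairs: Iterable[OrthologPair],
    genomes: Sequence[str],
) -> list[OrthologGroup]:
    """Complete-clique ortholog groups with one member per genome.

    A group over genomes G1..GN is emitted iff every one of its
    N(N-1)/2 cross-genome pairs is present in ``pairs``. Clique (rather
    than transitive-closure) grouping prevents paralog chaining. Each
    gene belongs to at most one group because RBH pairs are unique per
    genome pair.
    """
    genomes = list(genomes)
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    # partner[(genome_x, gene)][genome_y] -> gene in genome_y
    partner: dict[tuple[str, str], dict[str, str]] = {}
    for p in pairs:
        partner.setdefault((p.genome_a, p.gene_a), {})[p.genome_b] = p.gene_b
        partner.setdefault((p.genome_b, p.gene_b), {})[p.genome_a] = p.gene_a
    anchor = genomes[0]
    groups = []
    counter = 0
    anchor_genes = sorted(
        gene for (gnm, gene) in partner if gnm == anchor
    )
    for gene in anchor_genes:
        members = {anchor: gene}
        ok = True
        for other in genomes[1:]:
            hit = partner.get((anchor, gene), {}).get(other)
            if hit is None:
                ok = False
                break
            members[other] = hit
        if not ok:
            continue
        # verify the full clique
        for g1, g2 in itertools.combinations(genomes, 2):
            if partner.get((g1, members[g1]), {}).get(g2) != members[g2]:
                ok = False
                break
        if ok:
            counter += 1
            groups.append(
                OrthologGroup(
                    group_id=f"OG{counter:05d}",
                    members=tuple(sorted(members.items())),
                )
            )
    return groups


def pairs_to_frame(pairs: Iterable[OrthologPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_a": p.genome_a,
                "gene_a": p.gene_a,
                "genome_b": p.genome_b,
                "gene_b": p.gene_b,
                "coverage_a": p.coverage_a,
                "coverage_b": p.coverage_b,
            }
            for p in pairs
        ]
    )
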
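"""Horizontal-gene-transfer inference from gene-tree incongruence.

Incongruent gene trees (unrooted RF > 0 against the consensus topology)
are scored per taxon with the movement statistic

    S_ij = sum_{k != j} | dist^i_jk - dist^cons_jk |

where dist^i is the gene tree's patristic distance matrix normalized by
that tree's total branch length and dist^cons is the element-wise mean
of the normalized matrices over all congruent trees. The taxon with the
maximal S_ij is called the likely recipient; among taxa that got closer
to the recipient than in the consensus, the one with the largest
decrease is the putative donor; if every taxon moved away, the source
is UNKNOWN.

The module also carries the oligonucleotide-usage "stratigraphy": the
compositional distance between a genomic island and its host chromosome
ranks the island's relative age (larger distance = more recent, still
un-ameliorated acquisition).
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .phylo import (
    DistanceMatrix,
    leaf_labels,
    patristic_normalized,
    rf_distance,
    topology_signature,
)

logger = logging.getLogger(__name__)

UNKNOWN = "UNKNOWN"

_COMP = str.maketrans("ACGT", "TGCA")


@dataclass
class TopologyCensus:
    n_congruent: int
    congruent_ids: list[str]
    incongruent_groups: dict[frozenset, list[str]]  # signature -> tree ids
    skipped: list[str] = field(default_factory=list)

    @property
    def n_incongruent(self) -> int:
        return sum(len(v) for v in self.incongruent_groups.values())

    @property
    def group_sizes(self) -> list[int]:
        return sorted((len(v) for v in self.incongruent_groups.values()), reverse=True)


def topology_census(
    gene_trees: Sequence[tuple[str, dendropy.Tree]],
    consensus: dendropy.Tree,
) -> TopologyCensus:
    """Partition gene trees into congruent (RF=0 to the consensus) and
    incongruent, grouping the latter by shared alternative topology."""
    ref_labels = leaf_labels(consensus)
    congruent: list[str] = []
    groups: dict[frozenset, list[str]] = {}
    skipped: list[str] = []
    for tree_id, tree in gene_trees:
        if leaf_labels(tree) != ref_labels:
            logger.warning("tree %s: leaf set mismatch, skipped", tree_id)
            skipped.append(tree_id)
            continue
        if rf_distance(tree, consensus) == 0:
            congruent.append(tree_id)
        else:
            groups.setdefault(topology_signature(tree), []).append(tree_id)
    return TopologyCensus(
        n_congruent=len(congruent),
        congruent_ids=congruent,
        incongruent_groups=groups,
        skipped=skipped,
    )


def movement_scores(
    norm_dists: DistanceMatrix,
    consensus: DistanceMatrix,
    form: str = "abs",
) -> dict[str, float]:
    """Per-taxon movement score of a gene tree against the consensus.

    ``form="abs"`` sums absolute deviations (default); ``form="sq"``
    sums squared deviations.
    """
    cons = consensus.reordered(norm_dists.taxa)
    delta = norm_dists.matrix - cons.matrix
    if form == "abs":
        dev = np.abs(delta)
    elif form == "sq":
        dev = delta**2
    else:
        raise ValueError(f"unknown form {form!r}")
    np.fill_diagonal(dev, 0.0)
    return {t: float(dev[i].sum()) for i, t in enumerate(norm_dists.taxa)}


@dataclass
class TransferCall:
    tree_id: str
    recipient: str
    donor: str
    scores: dict[str, float]
    deltas_to_recipient: dict[str, float]
    ambiguous: bool = False
    tied_recipients: tuple[str, ...] = ()


def call_transfer(
    tree_id: str,
    norm_dists: DistanceMatrix,
    consensus: DistanceMatrix,
    form: str = "abs",
) -> TransferCall:
    """Call recipient and donor for one incongruent gene tree.

    Recipient = argmax_j S_ij (ties flagged ambiguous, all reported,
    lexicographically first used). Donor = the taxon with the most
    negative change in normalized distance to the recipient; if no
    taxon got closer, the donor is UNKNOWN.
    """
    scores = movement_scores(norm_dists, consensus, form=form)
    smax = max(scores.values())
    tied = tuple(sorted(t for t, s in scores.items() if s == smax))
    recipient = tied[0]
    cons = consensus.reordered(norm_dists.taxa)
    ridx = norm_dists.taxa.index(recipient)
    deltas = {
        t: float(norm_dists.matrix[ridx, k] - cons.matrix[ridx, k])
        for k, t in enumerate(norm_dists.taxa)
        if t != recipient
    }
    closer = {t: d for t, d in deltas.items() if d < 0}
    donor = min(closer, key=lambda t: (closer[t], t)) if closer else UNKNOWN
    return TransferCall(
        tree_id=tree_id,
        recipient=recipient,
        donor=donor,
        scores=scores,
        deltas_to_recipient=deltas,
        ambiguous=len(tied) > 1,
        tied_recipients=tied,
    )


def donor_recipient_summary(calls: Sequence[TransferCall]) -> pd.DataFrame:
    """Directed donor -> recipient count table (UNKNOWN donors included)."""
    counts = Counter((c.donor, c.recipient) for c in calls)
    rows = [
        {"donor": d, "recipient": r, "count": n}
        for (d, r), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["donor", "recipient", "count"])


# --- oligonucleotide-usage stratigraphy ---------------------------------

def _kmers(k: int) -> list[str]:
    return ["".join(p) for p in product("ACGT", repeat=k)]


@dataclass
class OUPattern:
    """Normalized k-mer frequency vector of a sequence (both strands)."""

    sequence_id: str
    k: int
    frequencies: np.ndarray  # length 4**k, sums to 1

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.shape != (4**self.k,):
            raise ValueError("frequency vector length must be 4^k")


def ou_pattern(sequence: str, sequence_id: str = "", k: int = 4) -> OUPattern:
    """Count overlapping k-mers on both strands and normalize to sum 1.

    Windows containing N (or any non-ACGT symbol) are skipped. Sequences
    much shorter than 4^k words are accepted with a warning since their
    pattern estimate is noisy.
    """
    seq = sequence.upper()
    if len(seq) < 40 * 4**k // 10:
        logger.warning(
            "sequence %s is short (%d bp) for k=%d pattern estimation",
            sequence_id,
            len(seq),
            k,
        )
    counts = np.zeros(4**k, dtype=float)
    rc = seq.translate(_COMP)[::-1]
    code = np.full(256, -1, dtype=np.int64)
    for i, base in enumerate("ACGT"):
        code[ord(base)] = i
    for strand_seq in (seq, rc):
        vals = code[np.frombuffer(strand_seq.encode(), dtype=np.uint8)]
        if len(vals) < k:
            continue
        windows = np.stack([vals[i : len(vals) - k + 1 + i] for i in range(k)])
        valid = (windows >= 0).all(axis=0)
        powers = 4 ** np.arange(k - 1, -1, -1)
        words = (windows[:, valid] * powers[:, None]).sum(axis=0)
        np.add.at(counts, words, 1.0)
    total = counts.sum()
    if total == 0:
        raise ValueError(f"sequence {sequence_id!r} has no valid {k}-mers")
    return OUPattern(sequence_id, k, counts / total)


def ou_distance(island: OUPattern, host: OUPattern) -> float:
    """Scaled mean absolute difference between two OU patterns."""
    if island.k != host.k:
        raise ValueError("patterns computed with different word lengths")
    return float(
        np.abs(island.frequencies - host.frequencies).mean() * 4**island.k
    )


def rank_relative_age(
    islands: Sequence[OUPattern], host: OUPattern
) -> list[tuple[str, float]]:
    """Rank islands most-recent-first by compositional distance to host.

    Amelioration drives an island's composition toward the host's, so a
    larger distance marks a more recent acquisition.
    """
    scored = [(isl.sequence_id, ou_distance(isl, host)) for isl in islands]
    return sorted(scored, key=lambda x: (-x[1], x[0]))
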
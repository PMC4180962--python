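"""Directional amino-acid substitution skew between two proteomes.

Given pairwise ortholog alignments with a designated reference
proteome, substitutions are tallied into a 20x20 matrix N where
N[A1][A2] counts columns showing residue A1 in the reference and A2 in
the other proteome (the diagonal holds identity matches M[A]). The
skew of an ordered residue pair is

    skew(A1, A2) = (N[A1][A2] - N[A2][A1]) / (M[A1] + M[A2])

an antisymmetric statistic whose sign marks the direction of the
substitution pressure between the two lineages (e.g. alanine
accumulation in extreme thermophiles).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class SubstitutionCounts:
    matrix: np.ndarray  # 20x20, diagonal = identity matches

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (20, 20):
            raise ValueError("substitution count matrix must be 20x20")
        if (self.matrix < 0).any():
            raise ValueError("negative count")

    def n(self, a1: str, a2: str) -> float:
        return float(self.matrix[_AA_INDEX[a1], _AA_INDEX[a2]])

    @property
    def matches(self) -> np.ndarray:
        return np.diag(self.matrix)

    @property
    def total(self) -> float:
        return float(self.matrix.sum())


@dataclass
class SkewMatrix:
    values: np.ndarray  # antisymmetric 20x20
    defined: np.ndarray  # bool mask; False where the normalizer was 0
    normalizer: str = "matches"

    def skew(self, a1: str, a2: str) -> float:
        i, j = _AA_INDEX[a1], _AA_INDEX[a2]
        if not self.defined[i, j]:
            raise ValueError(f"skew({a1},{a2}) undefined: zero normalizer")
        return float(self.values[i, j])

    def to_frame(self, counts: SubstitutionCounts) -> pd.DataFrame:
        rows = []
        m = counts.matches
        for i, a1 in enumerate(AMINO_ACIDS):
            for j, a2 in enumerate(AMINO_ACIDS):
                if i >= j:
                    continue
                rows.append(
                    {
                        "A1": a1,
                        "A2": a2,
                        "N12": counts.matrix[i, j],
                        "N21": counts.matrix[j, i],
                        "M1": m[i],
                        "M2": m[j],
                        "skew": self.values[i, j] if self.defined[i, j] else np.nan,
                        "normalizer": self.normalizer,
                    }
                )
        return pd.DataFrame(rows)


def substitution_counts(
    alignments: Sequence[tuple[str, str]], reference_first: bool = True
) -> SubstitutionCounts:
    """Tally aligned residue pairs over a set of pairwise alignments.

    Each alignment is a (reference_row, other_row) tuple of equal-length
    aligned strings; when ``reference_first`` is False the roles are
    swapped. Columns with gaps, X, or any non-standard symbol in either
    row are skipped.
    """
    mat = np.zeros((20, 20))
    for aln in alignments:
        if len(aln) != 2:
            raise ValueError("each alignment must have exactly 2 rows")
        ref, other = aln if reference_first else (aln[1], aln[0])
        if len(ref) != len(other):
            raise ValueError("alignment rows differ in length")
        for r, o in zip(ref.upper(), other.upper()):
            i = _AA_INDEX.get(r)
            j = _AA_INDEX.get(o)
            if i is None or j is None:
                continue
            mat[i, j] += 1
    return SubstitutionCounts(mat)


def skewness(
    counts: SubstitutionCounts, normalizer: str = "matches"
) -> SkewMatrix:
    """Antisymmetric skew matrix from substitution counts.

    ``normalizer="matches"`` (default) divides by M[A1] + M[A2], the
    identity-match counts of the two residues; ``"total"`` divides by
    the total number of counted columns instead. Entries with a zero
    normalizer are flagged undefined.
    """
    n = counts.matrix
    diff = n - n.T
    if normalizer == "matches":
        m = counts.matches
        denom = m[:, None] + m[None, :]
    elif normalizer == "total":
        denom = np.full((20, 20), counts.total)
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    defined = denom > 0
    values = np.zeros((20, 20))
    np.divide(diff, denom, out=values, where=defined)
    np.fill_diagonal(values, 0.0)
    return SkewMatrix(values=values, defined=defined, normalizer=normalizer)
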
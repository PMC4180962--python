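"""Chromosomal co-localization of functionally related genes.

Pairwise distances between genes sharing a metabolite within a pathway
are binned into four genomic-distance categories (operon scale, gene
scale, and two successive orders of magnitude). The statistic per
category is log10(observed / expected frequency), where the expectation
comes from a uniform-random placement null on the circular chromosome:
for two independent uniform points the minimal arc distance falls in
(a, b] with probability 2(b-a)/L (b <= L/2), which carries the
genome-length normalization.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import Genome, circular_distance

logger = logging.getLogger(__name__)

DEFAULT_CATEGORIES: tuple[tuple[int, int], ...] = (
    (0, 1_000),
    (1_000, 10_000),
    (10_000, 100_000),
    (100_000, 1_000_000),
)


@dataclass
class DistanceCategoryProfile:
    categories: tuple[tuple[int, int], ...]
    observed_counts: list[int]
    observed_freq: list[float]
    expected_freq: list[float]
    log_ratio: list[float]
    n_pairs: int
    out_of_range: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category_lo": [c[0] for c in self.categories],
                "category_hi": [c[1] for c in self.categories],
                "observed": self.observed_counts,
                "observed_freq": self.observed_freq,
                "expected_freq": self.expected_freq,
                "log_ratio": self.log_ratio,
            }
        )


def gene_distance(genome: Genome, g1: str, g2: str) -> float:
    """Distance in bp between gene midpoints: minimal arc on circular
    replicons, plain difference on linear ones."""
    a = genome.gene(g1).midpoint(genome.length_bp)
    b = genome.gene(g2).midpoint(genome.length_bp)
    return circular_distance(a, b, genome.length_bp, genome.circular)


def functional_pairs(annotation: pd.DataFrame) -> set[frozenset]:
    """Unordered gene pairs sharing >= 1 (pathway, compound), any roles.

    ``annotation`` has columns gene_id, pathway_id, compound_id, role.
    """
    pairs: set[frozenset] = set()
    for _, grp in annotation.groupby(["pathway_id", "compound_id"]):
        genes = sorted(set(grp["gene_id"]))
        for g1, g2 in combinations(genes, 2):
            pairs.add(frozenset((g1, g2)))
    return pairs


def expected_category_frequencies(
    genome_length: int,
    categories: Sequence[tuple[int, int]] = DEFAULT_CATEGORIES,
    circular: bool = True,
) -> list[float]:
    """Analytic null: P(distance in (a, b]) for two uniform points.

    On a circle of length L the minimal arc is uniform on (0, L/2] with
    density 2/L, so the probability mass of (a, b] is 2(b-a)/L. Category
    bounds beyond L/2 are truncated with a warning. For linear replicons
    the triangular density 2(L-d)/L^2 is integrated instead.
    """
    L = genome_length
    out = []
    for a, b in categories:
        if circular:
            half = L / 2
            lo, hi = min(a, half), min(b, half)
            if hi < b:
                logger.warning(
                    "category (%d, %d] truncated at L/2 = %.0f", a, b, half
                )
            out.append(2.0 * (hi - lo) / L)
        else:
            lo, hi = min(a, L), min(b, L)
            cdf = lambda d: (2 * L * d - d * d) / (L * L)
            out.append(cdf(hi) - cdf(lo))
    return out


def expected_category_frequencies_mc(
    genome_length: int,
    categories: Sequence[tuple[int, int]] = DEFAULT_CATEGORIES,
    n_samples: int = 100_000,
    seed: int = 0,
    circular: bool = True,
) -> list[float]:
    """Monte-Carlo version of the null: sampled random position pairs."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(0, genome_length, size=n_samples)
    b = rng.uniform(0, genome_length, size=n_samples)
    d = np.abs(a - b)
    if circular:
        d = np.minimum(d, genome_length - d)
    return [
        float(np.mean((d > lo) & (d <= hi)) if lo > 0 else np.mean(d <= hi))
        for lo, hi in categories
    ]


def colocalization_profile(
    genome: Genome,
    pairs: Sequence[frozenset],
    categories: Sequence[tuple[int, int]] = DEFAULT_CATEGORIES,
    expected: Optional[Sequence[float]] = None,
) -> DistanceCategoryProfile:
    """Observed vs expected distance-category frequencies for gene pairs.

    Zero observed count in a category gives a -inf log-ratio sentinel.
    Pairs farther apart than the last bound count as out-of-range mass.
    """
    if not pairs:
        raise ValueError("no functional pairs supplied")
    if expected is None:
        expected = expected_category_frequencies(
            genome.length_bp, categories, genome.circular
        )
    counts = [0] * len(categories)
    out_of_range = 0
    for pair in pairs:
        g1, g2 = tuple(pair)
        d = gene_distance(genome, g1, g2)
        for i, (lo, hi) in enumerate(categories):
            if (d > lo or (lo == 0 and d >= 0)) and d <= hi:
                counts[i] += 1
                break
        else:
            out_of_range += 1
    n = len(pairs)
    obs_freq = [c / n for c in counts]
    log_ratio = []
    for of, ef in zip(obs_freq, expected):
        if of == 0:
            log_ratio.append(float("-inf"))
        else:
            log_ratio.append(math.log10(of / ef))
    return DistanceCategoryProfile(
        categories=tuple(categories),
        observed_counts=counts,
        observed_freq=obs_freq,
        expected_freq=list(expected),
        log_ratio=log_ratio,
        n_pairs=n,
        out_of_range=out_of_range,
    )
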
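"""Haploid diversity statistics for Y-chromosome haplotype samples.

Implements the unbiased haplotype (gene) diversity of Nei (1987) with its
sampling variance, nucleotide diversity per site from haplotype frequencies
and pairwise differences, and the segregating-site count.  These are the
estimators population-genetics software (e.g. DnaSP) reports for haploid
Y data:

    h  = n/(n-1) * (1 - sum p_i^2)
    V(h) = 2/(n(n-1)) * { 2(n-2) [sum p_i^3 - (sum p_i^2)^2]
                          + sum p_i^2 - (sum p_i^2)^2 }
    pi = n/(n-1) * sum_{u<v} 2 p_u p_v d_uv / L
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "FrequencySpectrum",
    "DiversityResult",
    "haplotype_diversity",
    "nucleotide_diversity",
    "count_segregating_sites",
    "hamming",
]


@dataclass(frozen=True)
class FrequencySpectrum:
    """Carrier counts of the distinct haplotypes in one population sample."""

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.counts or any(c < 1 for c in self.counts):
            raise ValueError("counts must be a non-empty list of positive integers")
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))

    @property
    def n(self) -> int:
        return sum(self.counts)

    @property
    def k(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class DiversityResult:
    h: float
    h_se: float
    pi: float
    pi_se: float
    segregating_sites: int


def haplotype_diversity(spec: FrequencySpectrum) -> tuple[float, float]:
    """Unbiased haplotype diversity and its standard error.

    h is the bias-corrected probability that two chromosomes drawn without
    replacement carry different haplotypes; undefined for n < 2.
    """
    n = spec.n
    if n < 2:
        raise ValueError("haplotype diversity needs n >= 2")
    p = np.asarray(spec.counts, dtype=float) / n
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    h = n / (n - 1) * (1.0 - s2)
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (s3 - s2**2) + s2 - s2**2)
    return h, math.sqrt(max(var, 0.0))


def hamming(u: Sequence[str], v: Sequence[str]) -> int:
    """Number of sites whose call-strings differ.

    A double call (e.g. "G/A") is an atomic state: distance 1 from either
    homozygous call and from a different double call.
    """
    if len(u) != len(v):
        raise ValueError("call vectors must share a panel")
    return sum(a != b for a, b in zip(u, v))


def nucleotide_diversity(
    haplotypes: Sequence[tuple[Sequence[str], int]], L: int
) -> tuple[float, float]:
    """Nucleotide diversity per site and its standard error.

    Parameters
    ----------
    haplotypes:
        ``(call_vector, carrier_count)`` pairs.
    L:
        Number of sites analysed (the screened length), the denominator
        that converts mean pairwise differences into per-site diversity.

    The point estimate uses the unbiased frequency weighting consistent
    with ``haplotype_diversity``; the standard error is the stochastic
    variance of Nei (1987, eq. 10.7):
    ``V(pi) = (n+1)/(3(n-1)L) * pi + 2(n^2+n+3)/(9n(n-1)) * pi^2``.
    """
    if L < 1:
        raise ValueError("L (sites analysed) must be >= 1")
    n = sum(c for _, c in haplotypes)
    if n < 2:
        raise ValueError("nucleotide diversity needs n >= 2")
    vectors = [tuple(v) for v, _ in haplotypes]
    counts = np.asarray([c for _, c in haplotypes], dtype=float)
    p = counts / n
    pi = 0.0
    for u, v in itertools.combinations(range(len(vectors)), 2):
        pi += 2.0 * p[u] * p[v] * hamming(vectors[u], vectors[v])
    pi *= n / (n - 1) / L
    var = (n + 1) / (3.0 * (n - 1) * L) * pi + (
        2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    ) * pi**2
    return pi, math.sqrt(max(var, 0.0))


def count_segregating_sites(vectors: Sequence[Sequence[str]]) -> int:
    """Number of panel sites with >= 2 distinct call-strings among carriers."""
    if not vectors:
        return 0
    L = len(vectors[0])
    if any(len(v) != L for v in vectors):
        raise ValueError("call vectors must share a panel")
    return sum(len({v[i] for v in vectors}) > 1 for i in range(L))
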
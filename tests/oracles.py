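"""Independent brute-force reference implementations used only by tests.

These deliberately use the most direct formulation possible (prefix
hashing, exhaustive interval enumeration, textbook formulas) so they stay
independent of the library's optimized code paths.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def ehh_bruteforce(hap: np.ndarray, focal: int, allele: int, cols: list[int]) -> list[float]:
    """EHH along ``cols`` by hashing haplotype stretches and counting pairs.

    ``cols`` are the marker indices walked away from the focal SNP (the
    focal itself is position 0 with EHH 1).  At marker x the carriers are
    grouped by the tuple of their alleles from the focal SNP through x.
    """
    carriers = [i for i in range(hap.shape[0]) if hap[i, focal] == allele]
    n = len(carriers)
    values = [1.0]
    for k in range(1, len(cols) + 1):
        span = [focal] + cols[:k]
        groups: dict[tuple, int] = {}
        for i in carriers:
            key = tuple(hap[i, c] for c in span)
            groups[key] = groups.get(key, 0) + 1
        pairs = sum(c * (c - 1) // 2 for c in groups.values())
        values.append(pairs / (n * (n - 1) // 2))
    return values


def ehhs_bruteforce(hap: np.ndarray, focal: int, cols: list[int]) -> list[float]:
    """Squared-frequency-weighted EHHS via :func:`ehh_bruteforce`."""
    nh = hap.shape[0]
    q = hap[:, focal].mean()
    p = 1 - q
    e0 = ehh_bruteforce(hap, focal, 0, cols)
    e1 = ehh_bruteforce(hap, focal, 1, cols)
    return [
        (p * p * a + q * q * b) / (p * p + q * q) for a, b in zip(e0, e1)
    ]


def roh_bruteforce(genos: np.ndarray, pos: np.ndarray, params) -> list[tuple[int, int]]:
    """All surviving ROH as (i, j) SNP-index windows by exhaustive search.

    Tests every window for the het/missing budgets and the gap rule, keeps
    maximal ones, applies the count/length/density filters, then resolves
    overlaps greedily by length (ties -> leftmost).
    """
    m = len(genos)
    missing = -1

    def valid(i, j):
        g = genos[i : j + 1]
        if (g == 1).sum() > params.max_het or (g == missing).sum() > params.max_missing:
            return False
        return all(pos[k + 1] - pos[k] <= params.max_gap_bp for k in range(i, j))

    windows = [(i, j) for i in range(m) for j in range(i, m) if valid(i, j)]
    maximal = [
        (i, j)
        for (i, j) in windows
        if not any((a <= i and j <= b and (a, b) != (i, j)) for (a, b) in windows)
    ]
    survivors = [
        (i, j)
        for (i, j) in maximal
        if (
            pos[j] - pos[i] + 1 >= params.min_length_bp
            and j - i + 1 >= params.min_snps
            and (pos[j] - pos[i] + 1) / (j - i + 1) <= params.min_density_bp_per_snp
        )
    ]
    kept: list[tuple[int, int]] = []
    for i, j in sorted(survivors, key=lambda w: (-(pos[w[1]] - pos[w[0]] + 1), pos[w[0]])):
        if not any(pos[a] <= pos[j] and pos[i] <= pos[b] for a, b in kept):
            kept.append((i, j))
    return sorted(kept)


def fst_wright(c1: int, t1: int, c2: int, t2: int) -> float:
    """Textbook Wright FST on one SNP's allele counts."""
    p1, p2 = c1 / t1, c2 / t2
    pbar = (p1 + p2) / 2
    ht = 2 * pbar * (1 - pbar)
    if ht == 0:
        return 0.0
    hs = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2
    return (ht - hs) / ht


def pearson_chi2_2x2(a: float, b: float, c: float, d: float) -> float:
    """Pearson chi-square of the 2x2 table [[a,b],[c,d]] from expecteds."""
    n = a + b + c + d
    stat = 0.0
    for obs, rm, cm in (
        (a, a + b, a + c),
        (b, a + b, b + d),
        (c, c + d, a + c),
        (d, c + d, b + d),
    ):
        exp = rm * cm / n
        if exp > 0:
            stat += (obs - exp) ** 2 / exp
    return stat
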
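"""Pairwise identity-by-state distances and classical (Torgerson) MDS.

Used to visualize genetic relationships among breeds and to motivate the
declared fat-tail vs thin-tail comparison groups; grouping itself is
user-declared, not inferred.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from tailscan.genotype_io import MISSING, GenotypeDataset


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    d: np.ndarray  # symmetric, zero diagonal, entries in [0,1]


@dataclass
class MdsResult:
    coords: np.ndarray  # n_samples x k
    variance_fraction: np.ndarray  # length k, non-increasing


def ibs_distance(ds: GenotypeDataset) -> DistanceMatrix:
    """1 minus mean fraction of shared alleles over jointly called SNPs.

    d(i,j) = 1 - mean_{SNPs called in both} (2 - |g_i - g_j|) / 2, the
    allele-sharing complement of identity-by-state.
    """
    if ds.n_samples < 2:
        raise ValueError("need at least 2 samples")
    g = ds.calls.astype(np.float64)
    called = ds.calls != MISSING
    g[~called] = 0.0
    c = called.astype(np.float64)

    # sum over jointly called SNPs of |gi - gj| via the identity
    # |gi-gj| expansion is not bilinear, so loop rows (n is small on arrays)
    n = ds.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(g[i] - g)  # rows j
        joint = called[i] & called
        n_joint = joint.sum(axis=1)
        if np.any(n_joint == 0):
            j = int(np.flatnonzero(n_joint == 0)[0])
            if j != i:
                raise ValueError(
                    f"samples {ds.sample_ids[i]!r} and {ds.sample_ids[j]!r} share no called SNPs"
                )
        sim = ((2.0 - diff) / 2.0 * joint).sum(axis=1) / np.maximum(n_joint, 1)
        d[i] = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(ds.sample_ids), d)


def classical_mds(dm: DistanceMatrix, k: int = 2) -> MdsResult:
    """Torgerson MDS: double-center squared distances, eigendecompose.

    Coordinates are the top-k positive-eigenvalue axes scaled by sqrt of the
    eigenvalues; ``variance_fraction[i]`` is eigenvalue i over the sum of all
    positive eigenvalues.  If fewer than k eigenvalues are positive, fewer
    columns are returned with a warning.
    """
    n = len(dm.sample_ids)
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_samples, got k={k}, n={n}")
    d2 = np.asarray(dm.d, dtype=np.float64) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-12
    n_pos = int(pos.sum())
    k_eff = min(k, n_pos)
    if k_eff < k:
        warnings.warn(f"only {n_pos} positive eigenvalues; returning {k_eff} axes", stacklevel=2)
    coords = evecs[:, :k_eff] * np.sqrt(evals[:k_eff])
    varfrac = evals[:k_eff] / evals[pos].sum()
    return MdsResult(coords, varfrac)
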
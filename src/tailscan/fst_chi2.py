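"""Per-SNP allele-frequency differentiation: Wright FST and Pearson chi2.

Both statistics work on the 2x2 allele-count table of a SNP in two
populations.  FST here is Wright's allele-frequency form with unweighted
within-population heterozygosity (HS); the chi-square is Pearson's on allele
counts with 1 df and no continuity correction, with Bonferroni control over
the number of tested SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from tailscan.genotype_io import MISSING, GenotypeDataset


@dataclass
class FreqTable:
    """Per-SNP allele_b counts and called-allele totals for two groups."""

    snps: pd.DataFrame  # snp_id, chrom, pos_bp
    count1: np.ndarray
    total1: np.ndarray
    count2: np.ndarray
    total2: np.ndarray
    group1: str = ""
    group2: str = ""


def allele_counts(ds: GenotypeDataset, group1: str, group2: str) -> FreqTable:
    """Count allele_b copies and called alleles per SNP for two disjoint groups."""
    i1, i2 = ds.group_indices(group1), ds.group_indices(group2)
    if set(i1) & set(i2):
        raise ValueError("groups overlap")

    def _counts(idx):
        g = ds.calls[idx]
        called = g != MISSING
        count = np.where(called, g, 0).sum(axis=0)
        total = 2 * called.sum(axis=0)
        return count.astype(np.int64), total.astype(np.int64)

    c1, t1 = _counts(i1)
    c2, t2 = _counts(i2)
    return FreqTable(ds.snps[["snp_id", "chrom", "pos_bp"]].copy(), c1, t1, c2, t2, group1, group2)


def fst_per_snp(ft: FreqTable) -> np.ndarray:
    """Wright's FST from allele frequencies.

    p_bar = (p1+p2)/2, HT = 2 p_bar (1-p_bar), HS = mean of the two
    within-population heterozygosities; FST = (HT - HS)/HT, defined as 0
    where HT = 0 (monomorphic across both groups).
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = ft.count1 / ft.total1
        p2 = ft.count2 / ft.total2
    pbar = (p1 + p2) / 2
    ht = 2 * pbar * (1 - pbar)
    hs = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(ht > 0, (ht - hs) / np.where(ht > 0, ht, 1.0), 0.0)
    return fst


def chi2_per_snp(ft: FreqTable) -> tuple[np.ndarray, np.ndarray]:
    """Pearson chi2 (1 df, no continuity correction) on the 2x2 allele table.

    Returns (chi2, p).  SNPs with a zero marginal (monomorphic across both
    populations, or an empty group) yield chi2 = 0 and P = 1.
    """
    a = ft.count1.astype(float)
    b = (ft.total1 - ft.count1).astype(float)
    c = ft.count2.astype(float)
    d = (ft.total2 - ft.count2).astype(float)
    n = a + b + c + d
    det = a * d - b * c
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(denom > 0, n * det * det / np.where(denom > 0, denom, 1.0), 0.0)
    p = chi2_dist.sf(stat, df=1)
    p = np.where(denom > 0, p, 1.0)
    return stat, p


def bonferroni_adjust(p: np.ndarray) -> np.ndarray:
    """min(1, p * m) with m the number of tested SNPs."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("P-values must lie in [0,1]")
    return np.minimum(1.0, p * p.size)


def diff_scan(ds: GenotypeDataset, group1: str, group2: str) -> pd.DataFrame:
    """Per-SNP FST, chi2, raw and Bonferroni-adjusted P for two groups."""
    ft = allele_counts(ds, group1, group2)
    stat, p = chi2_per_snp(ft)
    out = ft.snps.copy()
    out["fst"] = fst_per_snp(ft)
    out["chi2"] = stat
    out["p"] = p
    out["p_bonf"] = bonferroni_adjust(p)
    return out
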
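"""Cross-population Rsb statistic and its one-sided significance transform.

Rsb at a SNP is the natural log of the ratio of iES values in two
populations; after median/SD standardization, large positive values indicate
unusually extended haplotype homozygosity in the first population (the
selected-candidate, fat-tail group).  The one-sided score is
-log10(1 - Phi(Rsb)) with Phi the standard normal CDF, so a score of 3.3
corresponds to a one-sided P of 5e-4 and 4 to 1e-4.

Standardization (median-centering, SD-scaling) is applied before the
Gaussian transform; raw ln-ratios are also carried through so the choice is
transparent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm


def rsb_raw(ies1: pd.DataFrame, ies2: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP ln(iES_pop1 / iES_pop2) over SNPs valid in both populations.

    ``ies1`` is the fat-tail (selected-candidate) population.  SNPs flagged
    monomorphic, missing, or with non-positive iES in either table are
    excluded.  Tables must share the SNP map.
    """
    if len(ies1) != len(ies2) or not (
        ies1["snp_id"].to_numpy() == ies2["snp_id"].to_numpy()
    ).all():
        raise ValueError("iES tables were not computed on the same SNP map")
    a = ies1["ies"].to_numpy(dtype=float)
    b = ies2["ies"].to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(b) & (a > 0) & (b > 0)
    out = ies1[["snp_id", "chrom", "pos_bp"]].copy()
    out["ies1"] = a
    out["ies2"] = b
    out["raw_rsb"] = np.where(ok, np.log(np.where(ok, a, 1.0) / np.where(ok, b, 1.0)), np.nan)
    return out[ok].reset_index(drop=True)


def rsb_standardize(raw: np.ndarray) -> np.ndarray:
    """(x - median(x)) / sd(x), with the n-1 (sample) standard deviation."""
    x = np.asarray(raw, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("need at least 2 finite values to standardize")
    sd = np.std(x[finite], ddof=1)
    if sd == 0:
        raise ValueError("degenerate scan: zero standard deviation")
    return (x - np.median(x[finite])) / sd


def rsb_score(std: np.ndarray) -> np.ndarray:
    """One-sided score -log10(1 - Phi(x)) via the upper-tail function.

    Using the survival function keeps precision for large x (a standardized
    Rsb of 6 still maps to a finite score near 9.9 instead of rounding the
    tail probability to 0).
    """
    return -np.log10(norm.sf(np.asarray(std, dtype=float)))


def rsb_scan(ies1: pd.DataFrame, ies2: pd.DataFrame, comparison: str = "") -> pd.DataFrame:
    """Full per-SNP scan table: raw Rsb, standardized Rsb, one-sided score."""
    out = rsb_raw(ies1, ies2)
    out["std_rsb"] = rsb_standardize(out["raw_rsb"].to_numpy())
    out["score"] = rsb_score(out["std_rsb"].to_numpy())
    out["comparison"] = comparison
    return out
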
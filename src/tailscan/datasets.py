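"""Bundled coordinate tables from a published sheep fat-tail selection scan.

Two small tab-separated tables ship with the package: the per-comparison
candidate-region intervals and the per-group ROH islands reported by a
published genome-wide comparison of fat-tail and thin-tail sheep breeds on
the OvineSNP50 array (Oar_v4.0 coordinates).  They serve as worked-example
inputs for the interval operations (cross-comparison sharing, region-island
overlap) without requiring the original genotype data, which were never
deposited.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from tailscan.regions import ComparisonRegion
from tailscan.roh import RohIsland


def _read(name: str) -> pd.DataFrame:
    with resources.files("tailscan.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_candidate_region_table() -> pd.DataFrame:
    """Published per-comparison candidate intervals (chrom, comparison,
    start_bp, end_bp; 1-based inclusive)."""
    df = _read("published_candidate_regions.tsv")
    df["chrom"] = df["chrom"].astype(str)
    df["comparison"] = df["comparison"].astype(str)
    return df


def load_candidate_regions() -> list[ComparisonRegion]:
    """The same intervals as :class:`~tailscan.regions.ComparisonRegion`
    objects ready for the sharing rule (member SNP ids are not published and
    are left empty)."""
    return [
        ComparisonRegion(row.comparison, row.chrom, int(row.start_bp), int(row.end_bp), [])
        for row in load_candidate_region_table().itertuples(index=False)
    ]


def load_roh_island_table() -> pd.DataFrame:
    """Published ROH islands (group, tail_type, chrom, n_snps, start_bp,
    end_bp; 1-based inclusive)."""
    df = _read("published_roh_islands.tsv")
    df["chrom"] = df["chrom"].astype(str)
    return df


def load_roh_islands(tail_type: str | None = None) -> dict[str, list[RohIsland]]:
    """Published islands grouped by breed/group, optionally filtered to
    ``tail_type`` "fat" or "thin"."""
    df = load_roh_island_table()
    if tail_type is not None:
        df = df[df["tail_type"] == tail_type]
    out: dict[str, list[RohIsland]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.group, []).append(
            RohIsland(row.chrom, int(row.start_bp), int(row.end_bp), int(row.n_snps), float("nan"))
        )
    return out
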
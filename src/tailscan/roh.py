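"""Runs of homozygosity, per-locus incidence, and percentile-threshold islands.

A ROH is a maximal chromosomal interval of one individual's genotypes
satisfying five criteria: span at least ``min_length_bp``; at most
``max_het`` heterozygous and ``max_missing`` missing calls; at least
``min_snps`` markers; average marker spacing (span / n_snps) no larger than
``min_density_bp_per_snp``; and no inter-marker gap above ``max_gap_bp``.
Calling is by exact enumeration of maximal qualifying intervals (two-pointer
over SNP indices) rather than a sliding-window heuristic, followed by a
greedy longest-first resolution of overlaps.

Locus homozygosity for a group is, per SNP, the fraction of its individuals
whose ROH covers the SNP; ROH islands are runs of SNPs whose incidence
reaches the top quantile (default 0.9999) of the genome-wide incidence
distribution, ties included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tailscan.genotype_io import MISSING, GenotypeDataset, chrom_sort_key


@dataclass(frozen=True)
class RohParams:
    min_length_bp: int = 1_000_000
    max_het: int = 1
    max_missing: int = 1
    min_snps: int = 30
    min_density_bp_per_snp: int = 100_000
    max_gap_bp: int = 1_000_000

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class RohSegment:
    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class LocusHomozygosity:
    group: str
    group_size: int
    incidence: np.ndarray  # per SNP, in [0,1]


@dataclass(frozen=True)
class RohIsland:
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    threshold: float


def _maximal_windows(genos: np.ndarray, pos: np.ndarray, p: RohParams):
    """Yield (i, j) maximal index windows meeting het/missing budgets and the
    gap rule; any sub-window of a valid window is valid, so a window is
    maximal iff it cannot be extended either way."""
    m = genos.size
    het = genos == 1
    mis = genos == MISSING
    j_max = np.empty(m, dtype=int)
    j = -1
    n_het = n_mis = 0
    for i in range(m):
        if j < i - 1:  # restart pointer
            j = i - 1
            n_het = n_mis = 0
        while j + 1 < m:
            nj = j + 1
            if nj > i and pos[nj] - pos[j] > p.max_gap_bp:
                break
            if n_het + het[nj] > p.max_het or n_mis + mis[nj] > p.max_missing:
                break
            n_het += het[nj]
            n_mis += mis[nj]
            j = nj
        j_max[i] = j
        if j >= i:  # element i is in the window; drop it for the next start
            n_het -= het[i]
            n_mis -= mis[i]
    for i in range(m):
        if j_max[i] >= i and (i == 0 or j_max[i - 1] < j_max[i]):
            yield i, j_max[i]


def _passes_filters(i: int, j: int, pos: np.ndarray, p: RohParams) -> bool:
    span = int(pos[j]) - int(pos[i]) + 1
    n = j - i + 1
    return span >= p.min_length_bp and n >= p.min_snps and span / n <= p.min_density_bp_per_snp


def resolve_overlaps(segments: list[RohSegment]) -> list[RohSegment]:
    """Greedy longest-first (ties -> leftmost) removal of overlapped segments."""
    kept: list[RohSegment] = []
    for seg in sorted(segments, key=lambda s: (-s.length_bp, s.start_bp)):
        if not any(
            k.chrom == seg.chrom and k.start_bp <= seg.end_bp and seg.start_bp <= k.end_bp
            for k in kept
        ):
            kept.append(seg)
    return sorted(kept, key=lambda s: (chrom_sort_key(s.chrom), s.start_bp))


def call_roh(ds: GenotypeDataset, sample_id: str, params: RohParams = RohParams()) -> list[RohSegment]:
    """All ROH of one individual, per chromosome.

    Segment boundaries are the first/last member SNP positions (1-based
    inclusive).
    """
    i = ds.sample_index(sample_id)
    g = ds.calls[i]
    out: list[RohSegment] = []
    for chrom, sub in ds.snps.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos_bp"].to_numpy(dtype=np.int64)
        genos = g[idx]
        cands = [
            RohSegment(
                sample_id,
                str(chrom),
                int(pos[a]),
                int(pos[b]),
                b - a + 1,
                int((genos[a : b + 1] == 1).sum()),
                int((genos[a : b + 1] == MISSING).sum()),
            )
            for a, b in _maximal_windows(genos, pos, params)
            if _passes_filters(a, b, pos, params)
        ]
        out.extend(resolve_overlaps(cands))
    return sorted(out, key=lambda s: (chrom_sort_key(s.chrom), s.start_bp))


def call_roh_group(ds: GenotypeDataset, group: str, params: RohParams = RohParams()) -> dict[str, list[RohSegment]]:
    """ROH per individual for all members of a group."""
    return {
        ds.sample_ids[i]: call_roh(ds, ds.sample_ids[i], params)
        for i in ds.group_indices(group)
    }


def locus_homozygosity(
    segments: dict[str, list[RohSegment]], ds: GenotypeDataset, group: str
) -> LocusHomozygosity:
    """Per-SNP fraction of group individuals whose ROH covers the SNP."""
    idx = ds.group_indices(group)
    n = idx.size
    if n == 0:
        raise ValueError(f"empty group {group!r}")
    chroms = ds.snps["chrom"].to_numpy()
    pos = ds.snps["pos_bp"].to_numpy()
    count = np.zeros(ds.n_snps, dtype=np.int64)
    members = {ds.sample_ids[i] for i in idx}
    for sid, segs in segments.items():
        if sid not in members:
            continue
        covered = np.zeros(ds.n_snps, dtype=bool)
        for s in segs:
            covered |= (chroms == s.chrom) & (pos >= s.start_bp) & (pos <= s.end_bp)
        count += covered
    return LocusHomozygosity(group, n, count / n)


def roh_islands(
    lh: LocusHomozygosity,
    snp_map: pd.DataFrame,
    quantile: float = 0.9999,
    merge_gap_bp: int = 1_000_000,
    min_island_snps: int = 3,
) -> list[RohIsland]:
    """High-incidence intervals: SNPs at or above the genome-wide incidence
    quantile (linear interpolation; ties at the threshold included), merged
    while consecutive selected SNPs are within ``merge_gap_bp``.
    """
    inc = np.asarray(lh.incidence, dtype=float)
    if np.all(inc == inc[0]):
        raise ValueError("no island structure: all-equal incidence")
    threshold = float(np.quantile(inc, quantile))
    selected = np.flatnonzero(inc >= threshold)
    chroms = snp_map["chrom"].to_numpy()
    pos = snp_map["pos_bp"].to_numpy(dtype=np.int64)
    islands: list[RohIsland] = []
    run: list[int] = []

    def _flush():
        if len(run) >= min_island_snps:
            islands.append(
                RohIsland(str(chroms[run[0]]), int(pos[run[0]]), int(pos[run[-1]]), len(run), threshold)
            )

    for j in selected:
        if run and (chroms[j] != chroms[run[-1]] or pos[j] - pos[run[-1]] > merge_gap_bp):
            _flush()
            run = []
        run.append(j)
    _flush()
    return islands


def segments_to_frame(segments: dict[str, list[RohSegment]]) -> pd.DataFrame:
    rows = [
        (s.sample_id, s.chrom, s.start_bp, s.end_bp, s.n_snps, s.n_het, s.n_missing)
        for segs in segments.values()
        for s in segs
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "chrom", "start_bp", "end_bp", "n_snps", "n_het", "n_missing"]
    )
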
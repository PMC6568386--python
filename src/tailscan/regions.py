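"""Candidate selection-signature regions and their corroboration.

A candidate region for one comparison is a chain of threshold-passing scan
SNPs in which consecutive significant SNPs lie within ``max_gap_bp`` of each
other (default 200 kb) with at least ``min_snps`` members, bounded by the
first and last significant SNP.  Regions are promoted to shared candidate
regions when, after extending every interval by ``flank_bp`` in both
directions, same-chromosome intervals from two or more distinct comparisons
intersect (transitive closure).  Corroboration marks regions with a
Bonferroni-significant chi-square SNP within the same flank; ROH-island
overlap and gene annotation are plain 1-based-inclusive interval
intersection (>= 1 shared bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from tailscan.genotype_io import chrom_sort_key
from tailscan.roh import RohIsland


@dataclass
class ComparisonRegion:
    """A significant-SNP chain from a single pair-wise comparison."""

    comparison: str
    chrom: str
    start_bp: int
    end_bp: int
    snp_ids: list[str]

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class CandidateRegion:
    """A cluster of comparison regions shared by >= 2 comparisons."""

    chrom: str
    start_bp: int
    end_bp: int
    members: list[ComparisonRegion]
    chi2_support: dict[str, bool] = field(default_factory=dict)
    islands: list = field(default_factory=list)
    genes: list[str] = field(default_factory=list)

    @property
    def comparisons(self) -> set[str]:
        return {m.comparison for m in self.members}

    @property
    def snp_ids(self) -> list[str]:
        seen: list[str] = []
        for m in self.members:
            seen.extend(s for s in m.snp_ids if s not in seen)
        return seen


@dataclass
class MergedIsland:
    chrom: str
    start_bp: int
    end_bp: int
    groups: set[str]


@dataclass
class OverlapResult:
    pairs: list[tuple[CandidateRegion, MergedIsland]]
    merged_islands: list[MergedIsland]
    n_overlapping_islands: int


def _overlap_1based(s1: int, e1: int, s2: int, e2: int) -> bool:
    return s1 <= e2 and s2 <= e1


def significant_clusters(
    scan: pd.DataFrame,
    threshold: float = 3.3,
    max_gap_bp: int = 200_000,
    min_snps: int = 2,
    comparison: str | None = None,
) -> list[ComparisonRegion]:
    """Chain threshold-passing SNPs of one comparison into candidate regions.

    ``scan`` needs columns snp_id, chrom, pos_bp, score (position-sorted per
    chromosome); the comparison label is taken from the ``comparison``
    column unless given explicitly.
    """
    if comparison is None:
        comparison = str(scan["comparison"].iloc[0]) if "comparison" in scan and len(scan) else ""
    out: list[ComparisonRegion] = []
    sig = scan[scan["score"] >= threshold]
    for chrom, sub in sig.groupby("chrom", sort=False):
        pos = sub["pos_bp"].to_numpy(dtype=np.int64)
        ids = sub["snp_id"].to_list()
        order = np.argsort(pos, kind="stable")
        pos, ids = pos[order], [ids[k] for k in order]
        start = 0
        for k in range(1, len(pos) + 1):
            if k == len(pos) or pos[k] - pos[k - 1] > max_gap_bp:
                if k - start >= min_snps:
                    out.append(
                        ComparisonRegion(comparison, str(chrom), int(pos[start]), int(pos[k - 1]), ids[start:k])
                    )
                start = k
    out.sort(key=lambda r: (chrom_sort_key(r.chrom), r.start_bp))
    return out


def shared_regions(
    region_lists,
    flank_bp: int = 200_000,
    min_comparisons: int = 2,
) -> list[CandidateRegion]:
    """Cluster per-comparison regions shared by >= ``min_comparisons``.

    ``region_lists`` is one list of :class:`ComparisonRegion` per comparison
    (a flat list also works).  Same-chromosome regions belong to one cluster
    when their ``flank_bp``-extended intervals intersect, closed
    transitively; the cluster span is the union of the raw member intervals.
    """
    flat: list[ComparisonRegion] = []
    for item in region_lists:
        if isinstance(item, ComparisonRegion):
            flat.append(item)
        else:
            flat.extend(item)
    flat = sorted(flat, key=lambda r: (chrom_sort_key(r.chrom), r.start_bp, r.end_bp, r.comparison))

    clusters: list[CandidateRegion] = []
    current: list[ComparisonRegion] = []
    reach = None  # max extended end of the open cluster

    def _close():
        if current and len({m.comparison for m in current}) >= min_comparisons:
            clusters.append(
                CandidateRegion(
                    current[0].chrom,
                    min(m.start_bp for m in current),
                    max(m.end_bp for m in current),
                    list(current),
                )
            )

    for r in flat:
        if current and (r.chrom != current[-1].chrom or r.start_bp - flank_bp > reach):
            _close()
            current = []
            reach = None
        current.append(r)
        reach = r.end_bp + flank_bp if reach is None else max(reach, r.end_bp + flank_bp)
    _close()
    return clusters


def corroborate_chi2(
    regions: list[CandidateRegion],
    diff_by_comparison: dict[str, pd.DataFrame],
    flank_bp: int = 200_000,
    alpha: float = 0.05,
) -> list[CandidateRegion]:
    """Flag regions with a Bonferroni-significant chi2 SNP within the flank.

    ``diff_by_comparison`` maps comparison label to a per-SNP table with
    columns chrom, pos_bp, p_bonf.  Boundaries are inclusive:
    [start - flank_bp, end + flank_bp].
    """
    for region in regions:
        for comp, diff in diff_by_comparison.items():
            sub = diff[diff["chrom"].astype(str) == region.chrom]
            pos = sub["pos_bp"].to_numpy(dtype=np.int64)
            hit = (
                (pos >= region.start_bp - flank_bp)
                & (pos <= region.end_bp + flank_bp)
                & (sub["p_bonf"].to_numpy() <= alpha)
            )
            region.chi2_support[comp] = bool(hit.any())
    return regions


def merge_island_lists(islands_by_group: dict[str, list[RohIsland]]) -> list[MergedIsland]:
    """Merge islands across groups when they themselves intersect (>= 1 bp)."""
    flat = [
        (isl.chrom, isl.start_bp, isl.end_bp, group)
        for group, isls in islands_by_group.items()
        for isl in isls
    ]
    flat.sort(key=lambda t: (chrom_sort_key(t[0]), t[1], t[2]))
    merged: list[MergedIsland] = []
    for chrom, s, e, group in flat:
        if merged and merged[-1].chrom == chrom and s <= merged[-1].end_bp:
            merged[-1].end_bp = max(merged[-1].end_bp, e)
            merged[-1].groups.add(group)
        else:
            merged.append(MergedIsland(chrom, s, e, {group}))
    return merged


def overlap_islands(
    regions: list[CandidateRegion],
    islands_by_group: dict[str, list[RohIsland]],
    merge_islands: bool = True,
) -> OverlapResult:
    """Intersect candidate regions with (merged) ROH islands.

    Returns the (region, island) pairs sharing >= 1 bp and the number of
    distinct merged islands overlapping any region.
    """
    if merge_islands:
        merged = merge_island_lists(islands_by_group)
    else:
        merged = [
            MergedIsland(isl.chrom, isl.start_bp, isl.end_bp, {group})
            for group, isls in islands_by_group.items()
            for isl in isls
        ]
    pairs: list[tuple[CandidateRegion, MergedIsland]] = []
    hit_islands = []
    for isl in merged:
        hit = False
        for region in regions:
            if region.chrom == isl.chrom and _overlap_1based(
                region.start_bp, region.end_bp, isl.start_bp, isl.end_bp
            ):
                pairs.append((region, isl))
                region.islands.append(isl)
                hit = True
        if hit:
            hit_islands.append(isl)
    return OverlapResult(pairs, merged, len(hit_islands))


# ---------------------------------------------------------------------------
# Gene annotation


def read_bed(path) -> pd.DataFrame:
    """BED gene intervals (0-based half-open), converted to 1-based inclusive."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {ln}: BED needs >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {ln}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else f"feature_{ln}"
            rows.append((str(fields[0]), start + 1, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "name"])


def _gff3_attr(attrs: str, keys=("Name", "gene_name", "ID")) -> str | None:
    fields = dict(
        kv.split("=", 1) for kv in attrs.strip().split(";") if "=" in kv
    )
    for k in keys:
        if k in fields:
            return fields[k]
    return None


def read_gff3(path, feature_types: tuple[str, ...] = ("gene",)) -> pd.DataFrame:
    """GFF3 gene intervals (already 1-based inclusive)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: line {ln}: GFF3 needs 9 columns, got {len(fields)}")
            if fields[2] not in feature_types:
                continue
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}: line {ln}: non-integer coordinates") from exc
            name = _gff3_attr(fields[8]) or f"feature_{ln}"
            rows.append((str(fields[0]), start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "name"])


def annotate_genes(regions: list[CandidateRegion], genes: pd.DataFrame) -> list[CandidateRegion]:
    """Attach genes overlapping each region by >= 1 bp, in genomic order.

    ``genes`` uses 1-based inclusive coordinates (see :func:`read_bed` /
    :func:`read_gff3` for format dialects).
    """
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples(index=False):
        trees.setdefault(str(row.chrom), IntervalTree()).addi(
            int(row.start_bp), int(row.end_bp) + 1, str(row.name)
        )
    for region in regions:
        tree = trees.get(region.chrom)
        hits = sorted(tree.overlap(region.start_bp, region.end_bp + 1)) if tree else []
        region.genes = [iv.data for iv in hits]
    return regions


def regions_to_frame(regions: list[CandidateRegion]) -> pd.DataFrame:
    """Tabular view: one row per region, per-comparison sub-intervals joined."""
    rows = []
    for r in regions:
        per_comp = {}
        for m in r.members:
            per_comp.setdefault(m.comparison, []).append(f"{m.start_bp}-{m.end_bp}")
        rows.append(
            {
                "chrom": r.chrom,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "n_comparisons": len(r.comparisons),
                "comparisons": ",".join(sorted(r.comparisons)),
                "intervals": ";".join(
                    f"{c}:{'|'.join(v)}" for c, v in sorted(per_comp.items())
                ),
                "chi2_support": ",".join(sorted(c for c, ok in r.chi2_support.items() if ok)),
                "genes": ",".join(r.genes),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start_bp",
            "end_bp",
            "n_comparisons",
            "comparisons",
            "intervals",
            "chi2_support",
            "genes",
        ],
    )
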
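"""Extended haplotype homozygosity: per-allele EHH, site-specific EHHS, iES.

EHH at a marker x for carriers of a focal allele is the probability that two
randomly drawn carrier haplotypes are identical over the interval from the
focal SNP to x inclusive.  EHHS combines the two per-allele curves weighted
by squared allele frequencies, normalized so that EHHS equals 1 at the focal
SNP.  iES is the trapezoidal area (in bp) under the EHHS decay curve on both
sides of the focal SNP, truncated at a small-EHHS cutoff (linearly
interpolated crossing), at the chromosome terminus, or at an excessive
inter-marker gap.

The curve-level API (:func:`ehh_decay`, :func:`ehhs_site`,
:func:`integrate_ies`) is plain numpy and is the reference semantics; the
genome scan :func:`ies_table` runs a numba kernel with identical behaviour
(asserted in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd

from tailscan.genotype_io import GenotypeDataset

# flag bits shared by the kernel and the table
FLAG_MONO = 1
FLAG_END_LEFT = 2
FLAG_END_RIGHT = 4
FLAG_GAP_LEFT = 8
FLAG_GAP_RIGHT = 16
FLAG_CUTOFF_LEFT = 32
FLAG_CUTOFF_RIGHT = 64

_FLAG_NAMES = {
    FLAG_MONO: "monomorphic",
    FLAG_END_LEFT: "end_left",
    FLAG_END_RIGHT: "end_right",
    FLAG_GAP_LEFT: "gap_left",
    FLAG_GAP_RIGHT: "gap_right",
    FLAG_CUTOFF_LEFT: "cutoff_left",
    FLAG_CUTOFF_RIGHT: "cutoff_right",
}


class MonomorphicFocalError(ValueError):
    """Focal SNP lacks two carriers of each allele; EHHS is undefined."""


@dataclass(frozen=True)
class IesParams:
    """Integration controls for iES.

    ehhs_cutoff:
        Integration stops where EHHS falls below this value (the crossing
        point is linearly interpolated).  0 integrates to chromosome ends.
    max_gap_bp:
        Integration stops before an inter-marker gap larger than this
        (sparse-coverage guard); the affected side is flagged.
    """

    ehhs_cutoff: float = 0.05
    max_gap_bp: int = 500_000


@dataclass
class EhhCurve:
    """One-sided decay curve anchored at a focal SNP.

    ``positions_bp`` are distances from the focal SNP (first entry 0) and
    ``values`` the EHH or EHHS values (first entry 1).  ``reached_end`` marks
    curves that ran to the chromosome terminus.
    """

    focal_index: int
    side: str  # "left" | "right"
    positions_bp: np.ndarray
    values: np.ndarray
    reached_end: bool = True


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes over a SNP map for one population."""

    haplotypes: np.ndarray  # (2*n_individuals, n_snps) uint8 in {0,1}
    map: pd.DataFrame  # columns chrom, snp_id, pos_bp (sorted)
    population_label: str = ""
    _chrom_bounds: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != len(self.map):
            raise ValueError("haplotype column count must equal map length")
        if self.haplotypes.size and not np.isin(self.haplotypes, [0, 1]).all():
            raise ValueError("haplotypes must be binary with no missing values")
        chroms = self.map["chrom"].to_numpy()
        bounds = {}
        start = 0
        for j in range(1, len(chroms) + 1):
            if j == len(chroms) or chroms[j] != chroms[start]:
                bounds[chroms[start]] = (start, j)
                start = j
        self._chrom_bounds = bounds

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    def chrom_span(self, focal: int) -> tuple[int, int]:
        """(lo, hi) half-open SNP-index range of the focal SNP's chromosome."""
        return self._chrom_bounds[self.map["chrom"].iat[focal]]


def haplotype_set(ds: GenotypeDataset, group: str) -> HaplotypeSet:
    """Extract the phased haplotypes of one group from a dataset.

    Requires ``ds.haplotypes`` (simulator output, or a phased PED read via
    ``read_plink(..., phased=True)``); no phasing algorithm is applied here.
    """
    if ds.haplotypes is None:
        raise ValueError(
            "dataset carries no phase; read with phased=True (optionally impute_missing=True) "
            "or use simulator output"
        )
    idx = ds.group_indices(group)
    rows = np.column_stack([2 * idx, 2 * idx + 1]).ravel()
    label = group if isinstance(group, str) else "+".join(group)
    return HaplotypeSet(ds.haplotypes[rows], ds.snps[["chrom", "snp_id", "pos_bp"]].copy(), label)


# ---------------------------------------------------------------------------
# Reference (numpy) curve computations


def _pair_fraction(labels: np.ndarray) -> float:
    """Sum over groups of C(size,2) / C(n,2) for a label partition."""
    n = labels.size
    _, counts = np.unique(labels, return_counts=True)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def _walk_columns(focal: int, side: str, lo: int, hi: int):
    if side == "left":
        return range(focal - 1, lo - 1, -1)
    if side == "right":
        return range(focal + 1, hi)
    raise ValueError(f"side must be 'left' or 'right', got {side!r}")


def ehh_decay(h: HaplotypeSet, focal: int, allele: int, side: str) -> EhhCurve:
    """Per-allele EHH decay from the focal SNP to the chromosome terminus.

    Carriers of ``allele`` at the focal SNP are progressively partitioned by
    their haplotype spelled from the focal SNP to each marker; EHH is the
    fraction of carrier pairs still identical.  The walk stops early once
    EHH reaches 0 (it cannot recover).
    """
    lo, hi = h.chrom_span(focal)
    carriers = np.flatnonzero(h.haplotypes[:, focal] == allele)
    if carriers.size < 2:
        raise MonomorphicFocalError(
            f"allele {allele} at SNP index {focal} has {carriers.size} carriers (<2)"
        )
    pos = h.map["pos_bp"].to_numpy()
    dist = [0]
    values = [1.0]
    labels = np.zeros(carriers.size, dtype=np.int64)
    reached_end = True
    for x in _walk_columns(focal, side, lo, hi):
        labels = labels * 2 + h.haplotypes[carriers, x]
        _, labels = np.unique(labels, return_inverse=True)
        v = _pair_fraction(labels)
        dist.append(abs(int(pos[x]) - int(pos[focal])))
        values.append(v)
        if v == 0.0:
            reached_end = x == (lo if side == "left" else hi - 1)
            break
    return EhhCurve(focal, side, np.asarray(dist), np.asarray(values), reached_end)


def ehhs_site(h: HaplotypeSet, focal: int, side: str, stop_below: float | None = None) -> EhhCurve:
    """Site-specific EHH: squared-frequency-weighted average of the two
    per-allele EHH curves, normalized to 1 at the focal SNP.

    EHHS(x) = (p^2 EHH_0(x) + q^2 EHH_1(x)) / (p^2 + q^2).  With
    ``stop_below`` set, the walk stops at the first marker whose EHHS falls
    below it (that marker is included, for crossing interpolation).
    """
    lo, hi = h.chrom_span(focal)
    col = h.haplotypes[:, focal]
    carriers = [np.flatnonzero(col == a) for a in (0, 1)]
    if min(c.size for c in carriers) < 2:
        raise MonomorphicFocalError(
            f"SNP index {focal}: carrier classes {[c.size for c in carriers]}; need >=2 each"
        )
    nh = h.n_haplotypes
    q, p = carriers[1].size / nh, carriers[0].size / nh  # p: allele 0, q: allele 1
    w = np.array([p * p, q * q])
    denom = w.sum()

    pos = h.map["pos_bp"].to_numpy()
    dist = [0]
    values = [1.0]
    labels = [np.zeros(c.size, dtype=np.int64) for c in carriers]
    ehh = [1.0, 1.0]
    reached_end = True
    for x in _walk_columns(focal, side, lo, hi):
        for a in (0, 1):
            if ehh[a] > 0.0:
                labels[a] = labels[a] * 2 + h.haplotypes[carriers[a], x]
                _, labels[a] = np.unique(labels[a], return_inverse=True)
                ehh[a] = _pair_fraction(labels[a])
        v = float((w[0] * ehh[0] + w[1] * ehh[1]) / denom)
        dist.append(abs(int(pos[x]) - int(pos[focal])))
        values.append(v)
        if stop_below is not None and v < stop_below:
            reached_end = False
            break
        if v == 0.0:
            reached_end = x == (lo if side == "left" else hi - 1)
            break
    return EhhCurve(focal, side, np.asarray(dist), np.asarray(values), reached_end)


def _integrate_side(curve: EhhCurve, params: IesParams) -> tuple[float, bool, bool, bool]:
    """Trapezoidal area of one side; returns (area, hit_cutoff, hit_gap, hit_end)."""
    d, v = curve.positions_bp, curve.values
    area = 0.0
    for k in range(1, len(d)):
        gap = d[k] - d[k - 1]
        if gap > params.max_gap_bp:
            return area, False, True, False
        if v[k] < params.ehhs_cutoff:
            prev = v[k - 1]
            # linear interpolation of the cutoff crossing
            dx = gap * (prev - params.ehhs_cutoff) / (prev - v[k])
            area += 0.5 * (prev + params.ehhs_cutoff) * dx
            return area, True, False, False
        area += 0.5 * (v[k] + v[k - 1]) * gap
    return area, False, False, curve.reached_end


def integrate_ies(left: EhhCurve, right: EhhCurve, params: IesParams = IesParams()) -> tuple[float, int]:
    """iES: combined bp-scaled area under the left and right EHHS curves.

    Returns ``(ies, flags)`` where ``flags`` is a bitmask of truncation
    conditions (cutoff / chromosome end / gap, per side).
    """
    if left.focal_index != right.focal_index:
        raise ValueError("curves must share the focal SNP")
    flags = 0
    area_l, cut, gap, end = _integrate_side(left, params)
    flags |= (FLAG_CUTOFF_LEFT if cut else 0) | (FLAG_GAP_LEFT if gap else 0) | (FLAG_END_LEFT if end else 0)
    area_r, cut, gap, end = _integrate_side(right, params)
    flags |= (FLAG_CUTOFF_RIGHT if cut else 0) | (FLAG_GAP_RIGHT if gap else 0) | (FLAG_END_RIGHT if end else 0)
    return area_l + area_r, flags


# ---------------------------------------------------------------------------
# Fast genome scan (numba)


@numba.njit(cache=False)
def _ehh_step(hap, col, carriers, labels):  # pragma: no cover - exercised via kernel
    n = carriers.size
    for i in range(n):
        labels[i] = labels[i] * 2 + hap[carriers[i], col]
    order = np.argsort(labels)
    pairs = 0.0
    rank = 0
    run = 1
    for t in range(1, n):
        if labels[order[t]] == labels[order[t - 1]]:
            run += 1
        else:
            pairs += run * (run - 1)
            rank += 1
            run = 1
    pairs += run * (run - 1)
    # compress labels to ranks to keep values small
    rank = 0
    prev = labels[order[0]]
    tmp = np.empty(n, dtype=np.int64)
    tmp[order[0]] = 0
    for t in range(1, n):
        if labels[order[t]] != prev:
            rank += 1
            prev = labels[order[t]]
        tmp[order[t]] = rank
    labels[:] = tmp
    return pairs / (n * (n - 1))


@numba.njit(cache=False)
def _ies_one_side(hap, pos, focal, step, bound, cutoff, max_gap, carriers0, carriers1, w0, w1):
    denom = w0 + w1
    labels0 = np.zeros(carriers0.size, dtype=np.int64)
    labels1 = np.zeros(carriers1.size, dtype=np.int64)
    ehh0 = 1.0
    ehh1 = 1.0
    prev_v = 1.0
    prev_pos = pos[focal]
    area = 0.0
    x = focal + step
    while x != bound + step:
        gap = pos[x] - prev_pos if step == 1 else prev_pos - pos[x]
        if gap > max_gap:
            return area, 2  # gap truncation
        if ehh0 > 0.0:
            ehh0 = _ehh_step(hap, x, carriers0, labels0)
        if ehh1 > 0.0:
            ehh1 = _ehh_step(hap, x, carriers1, labels1)
        v = (w0 * ehh0 + w1 * ehh1) / denom
        if v < cutoff:
            dx = gap * (prev_v - cutoff) / (prev_v - v)
            area += 0.5 * (prev_v + cutoff) * dx
            return area, 1  # cutoff truncation
        area += 0.5 * (prev_v + v) * gap
        if v == 0.0:  # cannot recover; matches the reference walk's early stop
            return area, 3 if x == bound else 0
        prev_v = v
        prev_pos = pos[x]
        x += step
    return area, 3  # chromosome end


@numba.njit(cache=False)
def _ies_chrom(hap, pos, cutoff, max_gap):
    m = pos.size
    nh = hap.shape[0]
    ies = np.full(m, np.nan)
    flags = np.zeros(m, dtype=np.int64)
    for focal in range(m):
        n1 = 0
        for i in range(nh):
            n1 += hap[i, focal]
        n0 = nh - n1
        if n0 < 2 or n1 < 2:
            flags[focal] = FLAG_MONO
            continue
        carriers0 = np.empty(n0, dtype=np.int64)
        carriers1 = np.empty(n1, dtype=np.int64)
        k0 = 0
        k1 = 0
        for i in range(nh):
            if hap[i, focal] == 1:
                carriers1[k1] = i
                k1 += 1
            else:
                carriers0[k0] = i
                k0 += 1
        p = n0 / nh
        q = n1 / nh
        w0 = p * p
        w1 = q * q
        area_l, code_l = _ies_one_side(hap, pos, focal, -1, 0, cutoff, max_gap, carriers0, carriers1, w0, w1)
        area_r, code_r = _ies_one_side(hap, pos, focal, 1, m - 1, cutoff, max_gap, carriers0, carriers1, w0, w1)
        f = 0
        if code_l == 1:
            f |= FLAG_CUTOFF_LEFT
        elif code_l == 2:
            f |= FLAG_GAP_LEFT
        elif code_l == 3:
            f |= FLAG_END_LEFT
        if code_r == 1:
            f |= FLAG_CUTOFF_RIGHT
        elif code_r == 2:
            f |= FLAG_GAP_RIGHT
        elif code_r == 3:
            f |= FLAG_END_RIGHT
        ies[focal] = area_l + area_r
        flags[focal] = f
    return ies, flags


def flag_names(flags: int) -> str:
    """Human-readable comma-joined names for a truncation bitmask."""
    names = [name for bit, name in _FLAG_NAMES.items() if flags & bit]
    return ",".join(names) if names else "ok"


def ies_table(h: HaplotypeSet, params: IesParams = IesParams()) -> pd.DataFrame:
    """Per-SNP iES for a population.

    Returns a DataFrame (snp_id, chrom, pos_bp, pop, ies, flags, flag_names);
    SNPs without two carriers of each allele get NaN iES and the
    ``monomorphic`` flag.
    """
    pos_all = h.map["pos_bp"].to_numpy(dtype=np.int64)
    ies = np.full(len(h.map), np.nan)
    flags = np.zeros(len(h.map), dtype=np.int64)
    for _, (lo, hi) in h._chrom_bounds.items():
        sub = np.ascontiguousarray(h.haplotypes[:, lo:hi])
        ies[lo:hi], flags[lo:hi] = _ies_chrom(
            sub, pos_all[lo:hi], float(params.ehhs_cutoff), int(params.max_gap_bp)
        )
    out = h.map[["snp_id", "chrom", "pos_bp"]].copy()
    out["pop"] = h.population_label
    out["ies"] = ies
    out["flags"] = flags
    out["flag_names"] = [flag_names(int(f)) for f in flags]
    return out
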
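"""Read, write, merge and quality-filter PLINK PED/MAP SNP-array genotypes.

Genotype calls are stored as counts of ``allele_b``, the file-wise minor
allele (ties broken alphabetically, the later allele becoming ``allele_b``),
with ``-1`` marking missing calls.  Coordinates are 1-based inclusive
throughout, following the MAP convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: default autosome label set for sheep (Ovis aries, 26 autosomes)
SHEEP_AUTOSOMES = frozenset(str(i) for i in range(1, 27))


class PlinkParseError(ValueError):
    """Raised when a PED/MAP file is structurally malformed."""


@dataclass(frozen=True)
class SnpRecord:
    """One array marker: chromosome, identifier, 1-based position, alleles."""

    chrom: str
    snp_id: str
    pos_bp: int
    allele_a: str
    allele_b: str


def chrom_sort_key(label: str):
    """Natural chromosome ordering: numeric labels first, then lexical."""
    s = str(label)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


SNP_COLUMNS = ["chrom", "snp_id", "pos_bp", "allele_a", "allele_b"]


@dataclass
class GenotypeDataset:
    """samples x SNPs genotype matrix with map and group labels.

    Attributes
    ----------
    sample_ids, groups:
        Parallel lists; ``groups[i]`` is the population/breed label of
        ``sample_ids[i]`` (the PED family-ID column).
    snps:
        DataFrame with columns ``chrom, snp_id, pos_bp, allele_a, allele_b``,
        sorted by (chrom, pos_bp) with natural chromosome order.
    calls:
        int8 array (n_samples, n_snps); counts of ``allele_b`` in {0,1,2},
        ``-1`` for missing.
    haplotypes:
        Optional uint8 array (2*n_samples, n_snps) of phased binary
        haplotypes (1 = ``allele_b``); rows ``2i`` and ``2i+1`` belong to
        sample ``i``.  Present when the source data carry phase (e.g. the
        bundled simulator) and there are no missing calls.
    """

    sample_ids: list[str]
    groups: list[str]
    snps: pd.DataFrame
    calls: np.ndarray
    haplotypes: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def samples(self) -> list[tuple[str, str]]:
        return list(zip(self.sample_ids, self.groups))

    def snp_records(self) -> list[SnpRecord]:
        return [SnpRecord(*row) for row in self.snps[SNP_COLUMNS].itertuples(index=False)]

    def group_indices(self, label: str | Iterable[str]) -> np.ndarray:
        """Sample indices of one group label, or the pooled union of several."""
        labels = [label] if isinstance(label, str) else list(label)
        arr = np.asarray(self.groups)
        for lab in labels:
            if not (arr == lab).any():
                raise KeyError(f"unknown group label: {lab!r}")
        return np.flatnonzero(np.isin(arr, labels))

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample: {sample_id!r}") from None

    def validate(self) -> None:
        n, m = self.calls.shape
        if n != self.n_samples or m != self.n_snps:
            raise ValueError("calls dimensions do not match samples x snps")
        if len(self.groups) != n:
            raise ValueError("groups length does not match samples")
        if any(not g for g in self.groups):
            raise ValueError("empty group label")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample_id")
        if self.snps["snp_id"].duplicated().any():
            dup = self.snps.loc[self.snps["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate snp_id: {dup}")
        if not np.isin(self.calls, [MISSING, 0, 1, 2]).all():
            raise ValueError("genotype codes outside {missing,0,1,2}")
        for chrom, sub in self.snps.groupby("chrom", sort=False):
            pos = sub["pos_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chrom {chrom}")
        if self.haplotypes is not None:
            if self.haplotypes.shape != (2 * n, m):
                raise ValueError("haplotypes dimensions do not match 2*samples x snps")

    def subset(self, sample_idx: np.ndarray | None = None, snp_idx: np.ndarray | None = None) -> "GenotypeDataset":
        ds = self
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            hap = None
            if ds.haplotypes is not None:
                hap_rows = np.column_stack([2 * sample_idx, 2 * sample_idx + 1]).ravel()
                hap = ds.haplotypes[hap_rows]
            ds = GenotypeDataset(
                [ds.sample_ids[i] for i in sample_idx],
                [ds.groups[i] for i in sample_idx],
                ds.snps,
                ds.calls[sample_idx],
                hap,
            )
        if snp_idx is not None:
            snp_idx = np.asarray(snp_idx)
            ds = GenotypeDataset(
                ds.sample_ids,
                ds.groups,
                ds.snps.iloc[snp_idx].reset_index(drop=True),
                ds.calls[:, snp_idx],
                None if ds.haplotypes is None else ds.haplotypes[:, snp_idx],
            )
        return ds


@dataclass(frozen=True)
class QcParams:
    """Quality-control thresholds.

    Samples with a missing fraction strictly above ``max_sample_missing`` are
    removed; SNPs with call rate strictly below ``min_snp_call_rate`` or
    minor allele frequency strictly below ``min_maf`` are removed.  With
    ``autosomes_only`` set, markers whose chromosome label is outside
    ``autosome_labels`` (default: sheep autosomes "1".."26") are dropped
    first.
    """

    max_sample_missing: float = 0.10
    min_snp_call_rate: float = 0.95
    min_maf: float = 0.01
    autosomes_only: bool = True
    autosome_labels: frozenset[str] = SHEEP_AUTOSOMES

    def __post_init__(self):
        for name in ("max_sample_missing", "min_snp_call_rate", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass(frozen=True)
class QcReport:
    n_samples_removed: int
    n_snps_removed_nonautosomal: int
    n_snps_removed_callrate: int
    n_snps_removed_maf: int
    n_samples_retained: int
    n_snps_retained: int

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame([self.__dict__]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PED/MAP reading and writing


def _read_map(map_path: str | Path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise PlinkParseError(f"{map_path}: line {ln}: expected 4 columns, got {len(fields)}")
            chrom, snp_id, _cm, pos = fields
            rows.append((str(chrom), snp_id, int(pos)))
    df = pd.DataFrame(rows, columns=["chrom", "snp_id", "pos_bp"])
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise PlinkParseError(f"{map_path}: duplicate snp_id {dup}")
    return df


def read_plink(
    ped_path: str | Path,
    map_path: str | Path,
    phased: bool = False,
    impute_missing: bool = False,
) -> GenotypeDataset:
    """Read a PED/MAP pair into a :class:`GenotypeDataset`.

    Genotypes are coded against ``allele_b``, the minor allele observed in
    the file; "0" alleles mark missing calls.  SNPs are returned sorted by
    (chrom, pos_bp).  With ``phased=True`` the two PED allele columns of each
    marker are interpreted as ordered haplotypes; this requires complete
    data unless ``impute_missing`` is set, which replaces each missing
    allele pair by the modal non-missing ordered pair at that SNP within the
    sample's group (no phasing algorithm is applied).
    """
    snp_df = _read_map(map_path)
    m = len(snp_df)

    sample_ids: list[str] = []
    groups: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise PlinkParseError(
                    f"{ped_path}: line {ln}: expected {6 + 2 * m} fields, got {len(fields)}"
                )
            groups.append(fields[0])
            sample_ids.append(fields[1])
            allele_rows.append(np.array(fields[6:], dtype=object))
    n = len(sample_ids)
    alleles = (
        np.array(allele_rows, dtype=object).reshape(n, m, 2)
        if n
        else np.empty((0, m, 2), dtype=object)
    )

    if phased and impute_missing and n:
        from collections import Counter

        groups_arr = np.asarray(groups)
        for j in range(m):
            col = alleles[:, j, :]
            missing_pair = (col == "0").any(axis=1)
            if not missing_pair.any():
                continue
            for i in np.flatnonzero(missing_pair):
                same = (groups_arr == groups_arr[i]) & ~missing_pair
                pool = col[same] if same.any() else col[~missing_pair]
                if pool.size == 0:
                    raise PlinkParseError(
                        f"{ped_path}: SNP {snp_df['snp_id'][j]}: all calls missing, cannot impute"
                    )
                modal = Counter(map(tuple, pool.tolist())).most_common(1)[0][0]
                col[i] = modal

    calls = np.full((n, m), MISSING, dtype=np.int8)
    hap = np.zeros((2 * n, m), dtype=np.uint8) if phased else None
    allele_a = np.empty(m, dtype=object)
    allele_b = np.empty(m, dtype=object)
    for j in range(m):
        col = alleles[:, j, :]
        missing_pair = (col == "0").any(axis=1)
        obs = col[~missing_pair].ravel()
        uniq, counts = (np.unique(obs, return_counts=True) if obs.size else (np.array([]), np.array([])))
        if len(uniq) > 2:
            raise PlinkParseError(
                f"{ped_path}: SNP {snp_df['snp_id'][j]}: more than two alleles {sorted(uniq)}"
            )
        if len(uniq) == 0:
            allele_a[j], allele_b[j] = "0", "0"
        elif len(uniq) == 1:
            allele_a[j], allele_b[j] = uniq[0], "0"
        else:
            if counts[0] == counts[1]:  # tie -> alphabetically later allele is allele_b
                a, b = sorted(uniq)
            elif counts[0] > counts[1]:
                a, b = uniq[0], uniq[1]
            else:
                a, b = uniq[1], uniq[0]
            allele_a[j], allele_b[j] = a, b
        is_b = col == allele_b[j]
        calls[:, j] = np.where(missing_pair, MISSING, is_b.sum(axis=1))
        if phased:
            if missing_pair.any():
                raise PlinkParseError(
                    f"{ped_path}: phased read requires complete data (missing at SNP {snp_df['snp_id'][j]})"
                )
            hap[0::2, j] = is_b[:, 0]
            hap[1::2, j] = is_b[:, 1]

    snp_df["allele_a"] = allele_a
    snp_df["allele_b"] = allele_b

    order = sorted(range(m), key=lambda j: (chrom_sort_key(snp_df["chrom"][j]), snp_df["pos_bp"][j]))
    order = np.asarray(order, dtype=int)
    ds = GenotypeDataset(
        sample_ids,
        groups,
        snp_df.iloc[order].reset_index(drop=True),
        calls[:, order] if m else calls,
        None if hap is None else hap[:, order],
    )
    ds.validate()
    return ds


def write_plink(ds: GenotypeDataset, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``prefix``.ped and ``prefix``.map (missing calls as "0 0").

    When the dataset carries phased haplotypes the PED allele order encodes
    the phase; otherwise heterozygotes are written ``allele_a allele_b``.
    """
    prefix = Path(prefix)
    ped_path, map_path = prefix.with_suffix(".ped"), prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for row in ds.snps.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos_bp}\n")

    a = ds.snps["allele_a"].to_numpy(dtype=object)
    b = ds.snps["allele_b"].to_numpy(dtype=object)
    with open(ped_path, "w") as fh:
        for i, (sid, grp) in enumerate(zip(ds.sample_ids, ds.groups)):
            pairs = np.empty((ds.n_snps, 2), dtype=object)
            if ds.haplotypes is not None:
                h0, h1 = ds.haplotypes[2 * i], ds.haplotypes[2 * i + 1]
                pairs[:, 0] = np.where(h0 == 1, b, a)
                pairs[:, 1] = np.where(h1 == 1, b, a)
            else:
                g = ds.calls[i]
                pairs[:, 0] = np.where(g >= 1, b, a)
                pairs[:, 1] = np.where(g == 2, b, a)
                pairs[g == MISSING] = "0"
            fh.write(" ".join([grp, sid, "0", "0", "0", "-9"] + pairs.ravel().tolist()))
            fh.write("\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# Merging and QC


def merge_datasets(datasets: Sequence[GenotypeDataset]) -> GenotypeDataset:
    """Concatenate samples over the SNP intersection of several datasets.

    SNPs are matched on (snp_id, chrom, pos_bp); calls from datasets whose
    allele coding is swapped relative to the first dataset are recoded.
    Incompatible allele pairs raise a ValueError naming the offending SNPs.
    """
    if not datasets:
        raise ValueError("no datasets to merge")
    keys = [set(zip(d.snps["snp_id"], d.snps["chrom"], d.snps["pos_bp"])) for d in datasets]
    common = set.intersection(*keys)
    ref = datasets[0]
    ref_mask = [
        (sid, c, p) in common
        for sid, c, p in zip(ref.snps["snp_id"], ref.snps["chrom"], ref.snps["pos_bp"])
    ]
    ref_idx = np.flatnonzero(ref_mask)
    snps = ref.snps.iloc[ref_idx].reset_index(drop=True).copy()
    id_to_col = {sid: j for j, sid in enumerate(snps["snp_id"])}

    # consensus allele pair per SNP: first polymorphic pair seen wins; a
    # dataset monomorphic at the SNP must carry one of the consensus alleles
    alle_a = snps["allele_a"].to_numpy(dtype=object)
    alle_b = snps["allele_b"].to_numpy(dtype=object)
    conflicts: list[str] = []
    for d in datasets[1:]:
        for j_d, sid in enumerate(d.snps["snp_id"]):
            j = id_to_col.get(sid)
            if j is None:
                continue
            da, db = d.snps["allele_a"][j_d], d.snps["allele_b"][j_d]
            obs_d = {x for x in (da, db) if x != "0"}
            obs_r = {x for x in (alle_a[j], alle_b[j]) if x != "0"}
            if not obs_d <= obs_r:
                if alle_b[j] == "0" and len(obs_d | obs_r) <= 2:
                    merged_obs = sorted(obs_d | obs_r)
                    if len(merged_obs) == 2:
                        # adopt the polymorphic dataset's orientation
                        if db != "0":
                            alle_a[j], alle_b[j] = da, db
                        else:
                            alle_a[j], alle_b[j] = merged_obs[0], merged_obs[1]
                else:
                    conflicts.append(sid)
    if conflicts:
        raise ValueError(f"allele coding conflict at SNPs: {', '.join(sorted(set(conflicts)))}")
    snps["allele_a"], snps["allele_b"] = alle_a, alle_b

    sample_ids: list[str] = []
    groups: list[str] = []
    blocks: list[np.ndarray] = []
    for d in datasets:
        cols = np.full(len(snps), -1, dtype=int)
        flip = np.zeros(len(snps), dtype=bool)
        mono_to_b = np.zeros(len(snps), dtype=bool)
        for j_d, sid in enumerate(d.snps["snp_id"]):
            j = id_to_col.get(sid)
            if j is None:
                continue
            cols[j] = j_d
            ra, rb = alle_a[j], alle_b[j]
            da, db = d.snps["allele_a"][j_d], d.snps["allele_b"][j_d]
            if (da, db) == (ra, rb):
                continue
            if (da, db) == (rb, ra):
                flip[j] = True
            elif db == "0":  # monomorphic in this dataset; calls are all 0 or missing
                mono_to_b[j] = da == rb
        g = d.calls[:, cols]
        g = np.where((g != MISSING) & flip[None, :], 2 - g, g)
        g = np.where((g != MISSING) & mono_to_b[None, :], 2, g)
        blocks.append(g.astype(np.int8))
        sample_ids.extend(d.sample_ids)
        groups.extend(d.groups)

    merged = GenotypeDataset(sample_ids, groups, snps, np.vstack(blocks) if blocks else np.empty((0, 0), np.int8))
    merged.validate()
    return merged


def apply_qc(ds: GenotypeDataset, params: QcParams = QcParams()) -> tuple[GenotypeDataset, QcReport]:
    """Apply the fixed-order quality filters and report per-step counts.

    Order: (1) drop non-autosomal/unassigned SNPs, (2) drop samples with a
    missing fraction above ``max_sample_missing``, (3) drop SNPs with call
    rate below ``min_snp_call_rate`` over retained samples, (4) drop SNPs
    with MAF below ``min_maf`` computed on retained samples.
    """
    n_in, m_in = ds.n_samples, ds.n_snps

    if params.autosomes_only:
        keep_snp = ds.snps["chrom"].astype(str).isin(params.autosome_labels).to_numpy()
    else:
        keep_snp = np.ones(m_in, dtype=bool)
    n_nonauto = int((~keep_snp).sum())
    ds = ds.subset(snp_idx=np.flatnonzero(keep_snp))

    miss_frac = (ds.calls == MISSING).mean(axis=1) if ds.n_snps else np.zeros(ds.n_samples)
    keep_sample = miss_frac <= params.max_sample_missing
    n_samples_removed = int((~keep_sample).sum())
    ds = ds.subset(sample_idx=np.flatnonzero(keep_sample))
    if ds.n_samples == 0:
        raise ValueError("empty dataset after QC")

    called = (ds.calls != MISSING).sum(axis=0)
    call_rate = called / ds.n_samples
    keep_cr = call_rate >= params.min_snp_call_rate
    n_callrate = int((~keep_cr).sum())
    ds = ds.subset(snp_idx=np.flatnonzero(keep_cr))

    called = (ds.calls != MISSING).sum(axis=0)
    b_count = np.where(ds.calls == MISSING, 0, ds.calls).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(called > 0, b_count / np.maximum(called, 1), 0.0)
    maf = np.minimum(freq, 1 - freq)
    keep_maf = maf >= params.min_maf
    n_maf = int((~keep_maf).sum())
    ds = ds.subset(snp_idx=np.flatnonzero(keep_maf))

    report = QcReport(
        n_samples_removed=n_samples_removed,
        n_snps_removed_nonautosomal=n_nonauto,
        n_snps_removed_callrate=n_callrate,
        n_snps_removed_maf=n_maf,
        n_samples_retained=ds.n_samples,
        n_snps_retained=ds.n_snps,
    )
    assert report.n_samples_retained + report.n_samples_removed == n_in
    assert (
        report.n_snps_retained
        + report.n_snps_removed_nonautosomal
        + report.n_snps_removed_callrate
        + report.n_snps_removed_maf
        == m_in
    )
    return ds, report
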
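import numpy as np
import pytest

from conftest import make_dataset, random_dataset
from tailscan.genotype_io import (
    MISSING,
    PlinkParseError,
    QcParams,
    apply_qc,
    merge_datasets,
    read_plink,
    write_plink,
)


def write_files(tmp_path, ped_text, map_text):
    ped = tmp_path / "t.ped"
    map_ = tmp_path / "t.map"
    ped.write_text(ped_text)
    map_.write_text(map_text)
    return ped, map_


MAP3 = "1 snpA 0 1000\n1 snpB 0 2000\n1 snpC 0 3000\n"


class TestReadPlink:
    def test_toy_transcription(self, tmp_path):
        """2-sample, 3-SNP PED/MAP transcribes to a 2x3 call matrix coded
        against the file-minor allele."""
        ped, map_ = write_files(
            tmp_path,
            "f1 i1 0 0 0 -9 A A A G G G\n" "f2 i2 0 0 0 -9 A A G G 0 0\n",
            MAP3,
        )
        ds = read_plink(ped, map_)
        assert ds.sample_ids == ["i1", "i2"]
        assert ds.groups == ["f1", "f2"]
        # snpA monomorphic A; snpB has A:1 G:3 so minor allele A is
        # allele_b; snpC observed only in i1 (G G), i2 missing
        assert list(ds.snps["allele_b"]) == ["0", "A", "0"]
        assert ds.calls[0].tolist() == [0, 1, 0]
        assert ds.calls[1].tolist() == [0, 0, MISSING]

    def test_missing_pair_becomes_missing(self, tmp_path):
        ped, map_ = write_files(
            tmp_path, "f i1 0 0 0 -9 A G 0 0 A A\n" "f i2 0 0 0 -9 A A A G A G\n", MAP3
        )
        ds = read_plink(ped, map_)
        assert ds.calls[0, 1] == MISSING

    def test_ragged_ped_row_names_line(self, tmp_path):
        ped, map_ = write_files(tmp_path, "f i1 0 0 0 -9 A A G G\n", MAP3)
        with pytest.raises(PlinkParseError, match="line 1"):
            read_plink(ped, map_)

    def test_duplicate_snp_id_rejected(self, tmp_path):
        ped, map_ = write_files(
            tmp_path, "f i1 0 0 0 -9 A A G G\n", "1 dup 0 1000\n1 dup 0 2000\n"
        )
        with pytest.raises(PlinkParseError, match="dup"):
            read_plink(ped, map_)

    def test_map_sorted_on_read(self, tmp_path):
        """SNPs come back ordered by (chrom, pos) regardless of file order."""
        ped, map_ = write_files(
            tmp_path,
            "f i1 0 0 0 -9 A G C C T T\n" "f i2 0 0 0 -9 G G C A T A\n",
            "2 s1 0 500\n1 s2 0 9000\n1 s3 0 100\n",
        )
        ds = read_plink(ped, map_)
        assert list(ds.snps["snp_id"]) == ["s3", "s2", "s1"]
        assert list(ds.snps["pos_bp"]) == [100, 9000, 500]


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path, rng):
        original = random_dataset(rng)
        ped, map_ = write_plink(original, tmp_path / "rt")
        back = read_plink(ped, map_)
        # reading determines allele_b as file-minor; re-writing and
        # re-reading must then be the identity
        ped2, map2 = write_plink(back, tmp_path / "rt2")
        again = read_plink(ped2, map2)
        assert np.array_equal(back.calls, again.calls)
        assert back.snps.equals(again.snps)
        assert back.sample_ids == again.sample_ids

    def test_phase_preserved_through_ped(self, tmp_path, tiny):
        ped, map_ = write_plink(tiny, tmp_path / "ph")
        back = read_plink(ped, map_, phased=True)
        assert back.haplotypes is not None
        assert np.array_equal(back.haplotypes, tiny.haplotypes)

    def test_empty_dataset_roundtrip(self, tmp_path):
        ds = make_dataset(np.zeros((0, 0), dtype=np.int8), pos=[], chroms=[], groups=[])
        ped, map_ = write_plink(ds, tmp_path / "e")
        back = read_plink(ped, map_)
        assert back.n_samples == 0 and back.n_snps == 0

    def test_impute_missing_enables_phased_read(self, tmp_path):
        ped, map_ = write_files(
            tmp_path,
            "f i1 0 0 0 -9 A G 0 0 A A\n"
            "f i2 0 0 0 -9 A G A A A G\n"
            "f i3 0 0 0 -9 A G A A A A\n",
            MAP3,
        )
        ds = read_plink(ped, map_, phased=True, impute_missing=True)
        # missing pair replaced by the modal ordered pair (A A) of the group
        assert ds.calls[0, 1] == ds.calls[1, 1] == 0


class TestApplyQc:
    def test_sample_above_missing_threshold_removed(self):
        mask = np.zeros((2, 50), dtype=bool)
        mask[0, :6] = True  # 12% missing > 10% threshold
        ds = make_dataset(np.tile([0, 1], (2, 25)), missing_mask=mask)
        out, rep = apply_qc(ds, QcParams(min_maf=0.0, min_snp_call_rate=0.0))
        assert rep.n_samples_removed == 1
        assert out.sample_ids == ["i1"]

    def test_low_maf_snp_removed(self):
        # 100 samples; one SNP with a single heterozygote -> MAF 0.5%
        calls = np.ones((100, 2), dtype=np.int8)
        calls[:, 1] = 0
        calls[0, 1] = 1
        ds = make_dataset(calls)
        out, rep = apply_qc(ds, QcParams())
        assert rep.n_snps_removed_maf == 1
        assert out.n_snps == 1

    def test_call_rate_step_count(self):
        """Call rates {1.0, 0.96, 0.94, 1.0, 1.0} at threshold 0.95 remove
        exactly one SNP at the call-rate step."""
        n = 50
        calls = np.tile([0, 1], (n, 3))[:, :5].astype(np.int8)
        calls[:] = np.array([[0, 1, 0, 1, 0]] * n)
        calls[n // 2 :, :] = np.array([[1, 0, 1, 0, 1]] * (n - n // 2))
        mask = np.zeros((n, 5), dtype=bool)
        mask[:2, 1] = True  # call rate 0.96
        mask[:3, 2] = True  # call rate 0.94
        ds = make_dataset(calls, missing_mask=mask)
        out, rep = apply_qc(ds, QcParams(max_sample_missing=1.0))
        assert rep.n_snps_removed_callrate == 1
        assert rep.n_snps_removed_maf == 0

    def test_nonautosomal_dropped_first(self):
        calls = np.tile([0, 1, 2], (4, 2)).astype(np.int8)
        ds = make_dataset(calls, chroms=["1", "X", "27", "2", "2", "1"],
                          pos=[100, 100, 100, 100, 200, 200])
        out, rep = apply_qc(ds, QcParams())
        assert rep.n_snps_removed_nonautosomal == 2
        assert set(out.snps["chrom"]) <= {"1", "2"}

    def test_idempotent(self, rng):
        ds = random_dataset(rng, n=20, m=40, missing_rate=0.05)
        once, rep1 = apply_qc(ds, QcParams())
        twice, rep2 = apply_qc(once, QcParams())
        assert np.array_equal(once.calls, twice.calls)
        assert rep2.n_samples_removed == 0
        assert rep2.n_snps_removed_callrate == rep2.n_snps_removed_maf == 0

    def test_counts_reconcile(self, rng):
        ds = random_dataset(rng, n=15, m=30, missing_rate=0.2)
        out, rep = apply_qc(ds, QcParams())
        assert rep.n_samples_retained + rep.n_samples_removed == 15
        assert (
            rep.n_snps_retained
            + rep.n_snps_removed_nonautosomal
            + rep.n_snps_removed_callrate
            + rep.n_snps_removed_maf
            == 30
        )

    def test_all_samples_removed_errors(self):
        calls = np.zeros((2, 10), dtype=np.int8)
        ds = make_dataset(calls, missing_mask=np.ones((2, 10), dtype=bool))
        with pytest.raises(ValueError, match="empty dataset after QC"):
            apply_qc(ds, QcParams())


class TestMerge:
    def test_disjoint_samples_same_map(self, rng):
        a = random_dataset(rng, n=3, m=5, missing_rate=0, groups=["x"] * 3)
        b = random_dataset(rng, n=2, m=5, missing_rate=0, groups=["y"] * 2)
        b.sample_ids = ["j0", "j1"]
        merged = merge_datasets([a, b])
        assert merged.n_samples == 5
        assert merged.groups == ["x"] * 3 + ["y"] * 2
        assert np.array_equal(merged.calls[:3], a.calls)

    def test_map_intersection(self, rng):
        a = random_dataset(rng, n=2, m=3, missing_rate=0)
        b = random_dataset(rng, n=2, m=3, missing_rate=0)
        b.sample_ids = ["j0", "j1"]
        b.snps.loc[2, "snp_id"] = "other"
        merged = merge_datasets([a, b])
        assert merged.n_snps == 2

    def test_swapped_coding_recoded(self):
        a = make_dataset([[0, 2], [1, 1]])
        b = make_dataset([[2, 0], [1, 1]])
        b.sample_ids = ["j0", "j1"]
        b.snps["allele_a"], b.snps["allele_b"] = "B", "A"
        merged = merge_datasets([a, b])
        assert merged.calls[2].tolist() == [0, 2]

    def test_conflicting_alleles_error(self):
        a = make_dataset([[0, 1], [1, 2]])
        b = make_dataset([[0, 1], [1, 2]])
        b.sample_ids = ["j0", "j1"]
        b.snps.loc[0, "allele_a"] = "T"
        b.snps.loc[0, "allele_b"] = "C"
        with pytest.raises(ValueError, match="s0"):
            merge_datasets([a, b])
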
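import numpy as np
import pandas as pd
import pytest

from oracles import ehh_bruteforce, ehhs_bruteforce
from tailscan import ehh_core
from tailscan.ehh_core import (
    EhhCurve,
    HaplotypeSet,
    IesParams,
    MonomorphicFocalError,
    ehh_decay,
    ehhs_site,
    ies_table,
    integrate_ies,
)


def hapset(rows, pos=None, chroms=None):
    rows = np.asarray(rows, dtype=np.uint8)
    m = rows.shape[1]
    pos = pos if pos is not None else [(j + 1) * 100_000 for j in range(m)]
    return HaplotypeSet(
        rows,
        pd.DataFrame(
            {"chrom": chroms or ["1"] * m, "snp_id": [f"s{j}" for j in range(m)], "pos_bp": pos}
        ),
        "p",
    )


class TestEhhDecay:
    def test_identical_carriers_stay_at_one(self):
        h = hapset([[1, 0, 1, 0]] * 4 + [[0, 1, 1, 0]] * 2)
        curve = ehh_decay(h, 0, 1, "right")
        assert np.all(curve.values == 1.0)

    def test_two_two_split(self):
        # 4 carriers split 2/2 at the next marker: C(2,2)*2 / C(4,2) = 1/3
        h = hapset([[1, 0], [1, 0], [1, 1], [1, 1], [0, 0], [0, 1]])
        curve = ehh_decay(h, 0, 1, "right")
        assert curve.values[1] == pytest.approx(1 / 3)

    def test_two_one_split(self):
        # 3 carriers split 2/1: C(2,2)/C(3,2) = 1/3
        h = hapset([[1, 0], [1, 0], [1, 1], [0, 0]])
        curve = ehh_decay(h, 0, 1, "right")
        assert curve.values[1] == pytest.approx(1 / 3)

    def test_single_carrier_errors(self):
        h = hapset([[1, 0], [0, 0], [0, 1]])
        with pytest.raises(MonomorphicFocalError):
            ehh_decay(h, 0, 1, "right")

    @pytest.mark.parametrize("side", ["left", "right"])
    def test_non_increasing(self, rng, side):
        hap = rng.integers(0, 2, size=(16, 30)).astype(np.uint8)
        hap[:, 15] = [0, 1] * 8
        h = hapset(hap)
        for allele in (0, 1):
            v = ehh_decay(h, 15, allele, side).values
            assert np.all(np.diff(v) <= 1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        """EHH equals prefix-hash pair counting on random instances."""
        for _ in range(60):
            nh = int(rng.integers(4, 21))
            m = int(rng.integers(5, 51))
            hap = (rng.random((nh, m)) < rng.uniform(0.2, 0.8)).astype(np.uint8)
            focal = int(rng.integers(0, m))
            allele = int(rng.integers(0, 2))
            if min((hap[:, focal] == a).sum() for a in (0, 1)) < 2:
                continue
            h = hapset(hap)
            for side, cols in (("right", list(range(focal + 1, m))), ("left", list(range(focal - 1, -1, -1)))):
                got = ehh_decay(h, focal, allele, side).values
                want = ehh_bruteforce(hap, focal, allele, cols)
                assert np.allclose(got, want[: len(got)])
                # engine may stop early once EHH hits 0; oracle stays 0 after
                assert np.all(np.asarray(want[len(got):]) == 0)

    def test_row_permutation_invariance(self, rng):
        hap = rng.integers(0, 2, size=(12, 20)).astype(np.uint8)
        hap[:, 5] = [0, 1] * 6
        perm = rng.permutation(12)
        a = ehh_decay(hapset(hap), 5, 1, "right").values
        b = ehh_decay(hapset(hap[perm]), 5, 1, "right").values
        assert np.array_equal(a, b)

    def test_duplicating_carrier_never_decreases_ehh(self, rng):
        hap = rng.integers(0, 2, size=(10, 15)).astype(np.uint8)
        hap[:, 0] = [0, 1] * 5
        carrier = np.flatnonzero(hap[:, 0] == 1)[0]
        bigger = np.vstack([hap, hap[carrier]])
        a = ehh_decay(hapset(hap), 0, 1, "right").values
        b = ehh_decay(hapset(bigger), 0, 1, "right").values
        k = min(len(a), len(b))
        assert np.all(b[:k] - a[:k] >= -1e-12)


class TestEhhs:
    def test_equal_curves_give_one(self):
        h = hapset([[1, 0, 0], [1, 0, 0], [0, 1, 1], [0, 1, 1], [1, 0, 0], [0, 1, 1]])
        curve = ehhs_site(h, 0, "right")
        assert np.all(curve.values == 1.0)

    def test_half_half_mixture(self):
        # p = q = 0.5; EHH_0 stays 1, EHH_1 drops to 0 -> EHHS = 0.5
        h = hapset([[0, 0], [0, 0], [1, 0], [1, 1]])
        curve = ehhs_site(h, 0, "right")
        assert curve.values[1] == pytest.approx(0.5)

    def test_bounded_by_max_per_allele(self, rng):
        hap = rng.integers(0, 2, size=(14, 25)).astype(np.uint8)
        hap[:, 10] = [0, 1] * 7
        h = hapset(hap)
        s = ehhs_site(h, 10, "right").values
        e0 = ehh_decay(h, 10, 0, "right").values
        e1 = ehh_decay(h, 10, 1, "right").values
        k = min(len(s), len(e0), len(e1))
        assert np.all(s[:k] <= np.maximum(e0[:k], e1[:k]) + 1e-12)

    def test_matches_bruteforce(self, rng):
        for _ in range(40):
            nh, m = int(rng.integers(6, 16)), int(rng.integers(4, 30))
            hap = (rng.random((nh, m)) < 0.5).astype(np.uint8)
            focal = int(rng.integers(0, m))
            if min((hap[:, focal] == a).sum() for a in (0, 1)) < 2:
                continue
            got = ehhs_site(hapset(hap), focal, "right").values
            want = ehhs_bruteforce(hap, focal, list(range(focal + 1, m)))
            assert np.allclose(got, want[: len(got)])

    def test_monomorphic_flagged(self):
        h = hapset([[1, 0], [1, 0], [1, 1]])
        with pytest.raises(MonomorphicFocalError):
            ehhs_site(h, 0, "right")


class TestIntegrateIes:
    def test_rectangle(self):
        left = EhhCurve(5, "left", np.array([0, 100_000]), np.array([1.0, 1.0]), True)
        right = EhhCurve(5, "right", np.array([0, 100_000]), np.array([1.0, 1.0]), True)
        ies, flags = integrate_ies(left, right, IesParams(ehhs_cutoff=0.0))
        assert ies == pytest.approx(200_000)

    def test_triangle_one_side(self):
        left = EhhCurve(0, "left", np.array([0]), np.array([1.0]), True)
        right = EhhCurve(0, "right", np.array([0, 100_000]), np.array([1.0, 0.0]), True)
        ies, flags = integrate_ies(left, right, IesParams(ehhs_cutoff=0.0))
        assert ies == pytest.approx(50_000)

    def test_cutoff_crossing_interpolated(self):
        # drops 1 -> 0.04 over 100 kb; cutoff 0.05 crossed at 98,958.33 bp
        right = EhhCurve(0, "right", np.array([0, 100_000]), np.array([1.0, 0.04]), True)
        left = EhhCurve(0, "left", np.array([0]), np.array([1.0]), True)
        ies, flags = integrate_ies(left, right, IesParams(ehhs_cutoff=0.05))
        dx = 100_000 * (1 - 0.05) / (1 - 0.04)
        assert ies == pytest.approx(0.5 * (1 + 0.05) * dx)
        assert flags & ehh_core.FLAG_CUTOFF_RIGHT

    def test_gap_truncates_and_flags(self):
        right = EhhCurve(
            0, "right", np.array([0, 100_000, 700_000]), np.array([1.0, 0.9, 0.8]), True
        )
        left = EhhCurve(0, "left", np.array([0]), np.array([1.0]), True)
        ies, flags = integrate_ies(left, right, IesParams(ehhs_cutoff=0.0, max_gap_bp=500_000))
        assert ies == pytest.approx(0.5 * (1 + 0.9) * 100_000)
        assert flags & ehh_core.FLAG_GAP_RIGHT


class TestIesTable:
    def test_kernel_matches_reference_path(self, rng):
        """The numba scan kernel reproduces the reference curve pipeline
        (ehhs_site + integrate_ies) exactly, including flags."""
        params = IesParams(ehhs_cutoff=0.05, max_gap_bp=400_000)
        for _ in range(25):
            nh, m = int(rng.integers(6, 20)), int(rng.integers(5, 40))
            hap = (rng.random((nh, m)) < rng.uniform(0.3, 0.7)).astype(np.uint8)
            pos = np.cumsum(rng.integers(10_000, 600_000, size=m))
            h = hapset(hap, pos=list(pos))
            table = ies_table(h, params)
            for focal in range(m):
                if min((hap[:, focal] == a).sum() for a in (0, 1)) < 2:
                    assert table["flags"][focal] == ehh_core.FLAG_MONO
                    assert np.isnan(table["ies"][focal])
                    continue
                left = ehhs_site(h, focal, "left", stop_below=params.ehhs_cutoff)
                right = ehhs_site(h, focal, "right", stop_below=params.ehhs_cutoff)
                want, want_flags = integrate_ies(left, right, params)
                assert table["ies"][focal] == pytest.approx(want, rel=1e-12, abs=1e-9)
                assert int(table["flags"][focal]) == want_flags

    def test_multi_chromosome_isolation(self, rng):
        """Walks never cross a chromosome boundary."""
        hap = rng.integers(0, 2, size=(10, 8)).astype(np.uint8)
        chroms = ["1"] * 4 + ["2"] * 4
        pos = [100, 200, 300, 400, 100, 200, 300, 400]
        h = hapset(hap, pos=pos, chroms=chroms)
        t = ies_table(h, IesParams(ehhs_cutoff=0.0))
        # every computed SNP on chrom 1 must flag a chromosome end
        for j in range(4):
            if t["flags"][j] != ehh_core.FLAG_MONO:
                assert t["flags"][j] & (ehh_core.FLAG_END_LEFT | ehh_core.FLAG_END_RIGHT)


class TestTinyFixtureHandValues:
    """Hand-computed EHH combinatorics for the bundled 4-sample fixture.

    pop1 holds haplotype rows 0-3.  At the first SNP, rows {0,1} carry
    allele 0 and rows {2,3} allele 1; each pair stays identical through
    SNP 4 and first differs at SNP 5, so both per-allele EHH curves are
    1,1,1,1,1,0 and EHHS matches.  With 100 kb marker spacing and cutoff
    0.05, the right-side area is 400,000 + 0.5*(1+0.05)*95,000 = 449,875
    and the left side is empty (focal at the chromosome start).
    """

    def test_ehh_curves(self, tiny):
        h = ehh_core.haplotype_set(tiny, "pop1")
        for allele in (0, 1):
            v = ehh_decay(h, 0, allele, "right").values
            assert v[:6].tolist() == [1, 1, 1, 1, 1, 0]

    def test_ies_value(self, tiny):
        h = ehh_core.haplotype_set(tiny, "pop1")
        t = ies_table(h, IesParams(ehhs_cutoff=0.05))
        assert t["ies"][0] == pytest.approx(449_875.0)
        assert int(t["flags"][0]) & ehh_core.FLAG_END_LEFT
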
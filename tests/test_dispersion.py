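import numpy as np
import pytest

from halovasc import (
    BinaryVolume,
    FillCurve,
    HaloDispersion,
    cohort_normalization_count,
    fill_curve,
    halo_index,
    normalized_halo,
    rhombicuboctahedral_step,
)
from halovasc.phantoms import point_phantom

from oracles import CROSS_OFFSETS, CUBE_OFFSETS, dilate_shift_union


def _center_voxel(n=3):
    v = np.zeros((n, n, n), bool)
    v[n // 2, n // 2, n // 2] = True
    return BinaryVolume(v)


class TestRhombicuboctahedralStep:
    def test_cross_cycle_gives_7_voxels(self):
        out = rhombicuboctahedral_step(_center_voxel(7), 1)
        assert out.foreground_count == 7

    def test_cube_cycle_on_cross_gives_81(self):
        # union of seven 3x3x3 cubes centred on the cross voxels
        grown = rhombicuboctahedral_step(_center_voxel(9), 1)
        out = rhombicuboctahedral_step(grown, 2)
        expected = dilate_shift_union(grown.voxels, CUBE_OFFSETS)
        assert out.foreground_count == expected.sum() == 81
        assert np.array_equal(out.voxels, expected)

    def test_full_volume_is_absorbing(self):
        v = BinaryVolume(np.ones((4, 4, 4), bool))
        assert rhombicuboctahedral_step(v, 1).foreground_count == 64

    def test_cycle_index_is_one_based(self):
        with pytest.raises(ValueError):
            rhombicuboctahedral_step(_center_voxel(), 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_equivalence_with_shift_union_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.random((20, 20, 20)) < 0.02
        if not v.any():
            v[10, 10, 10] = True
        current = BinaryVolume(v)
        oracle = v.copy()
        for cycle in range(1, 5):
            current = rhombicuboctahedral_step(current, cycle)
            offsets = CROSS_OFFSETS if cycle % 2 == 1 else CUBE_OFFSETS
            oracle = dilate_shift_union(oracle, offsets)
            assert np.array_equal(current.voxels, oracle)

    def test_monotone_in_the_input(self, rng):
        a = rng.random((12, 12, 12)) < 0.05
        b = a | (rng.random((12, 12, 12)) < 0.05)
        ga = rhombicuboctahedral_step(BinaryVolume(a), 1)
        gb = rhombicuboctahedral_step(BinaryVolume(b), 1)
        assert np.all(gb.voxels[ga.voxels])


class TestFillCurve:
    def test_center_voxel_hand_enumeration(self):
        curve = fill_curve(_center_voxel(), 0.9)
        assert curve.counts.tolist() == [1, 7, 27]
        assert curve.fractions.tolist() == [1 / 27, 7 / 27, 1.0]

    def test_degenerate_when_initially_above_target(self):
        v = BinaryVolume(np.ones((3, 3, 3), bool))
        curve = fill_curve(v, 0.9)
        assert curve.counts.tolist() == [27]

    def test_fractions_strictly_increase_until_stop(self, rng):
        v = BinaryVolume(rng.random((15, 15, 15)) < 0.01)
        if v.foreground_count == 0:
            pytest.skip("empty draw")
        curve = fill_curve(v, 0.9)
        assert (np.diff(curve.counts) > 0).all()

    def test_empty_volume_rejected(self):
        with pytest.raises(ValueError, match="foreground"):
            fill_curve(BinaryVolume(np.zeros((3, 3, 3), bool)))


class TestHaloIndex:
    def test_hand_computed_center_voxel_value(self):
        curve = fill_curve(_center_voxel(), 0.9)
        hv = halo_index(curve, 0.9)
        assert hv == pytest.approx(1 + (0.9 - 7 / 27) / (1 - 7 / 27), abs=1e-12)
        assert round(hv, 3) == 1.865

    def test_zero_when_initial_fraction_meets_target(self):
        curve = FillCurve(counts=np.array([95]), total_voxels=100)
        assert halo_index(curve, 0.9) == 0.0

    def test_exact_hit_is_integer_cycles(self):
        curve = FillCurve(counts=np.array([10, 50, 90]), total_voxels=100)
        assert halo_index(curve, 0.9) == pytest.approx(2.0)

    def test_non_monotone_curve_is_an_upstream_bug(self):
        curve = FillCurve(counts=np.array([10, 50, 40, 90]), total_voxels=100)
        with pytest.raises(ValueError, match="monotone"):
            halo_index(curve, 0.9)

    def test_hv_non_increasing_under_extra_foreground(self, rng):
        base = rng.random((16, 16, 16)) < 0.01
        base[8, 8, 8] = True
        more = base | (rng.random((16, 16, 16)) < 0.02)
        hv_base = halo_index(fill_curve(BinaryVolume(base), 0.9), 0.9)
        hv_more = halo_index(fill_curve(BinaryVolume(more), 0.9), 0.9)
        assert hv_more <= hv_base + 1e-12


class TestNormalization:
    def test_cohort_maximum(self, rng):
        def vol(n):
            v = np.zeros((10, 10, 10), bool)
            flat = rng.choice(1000, size=n, replace=False)
            v.ravel()[flat] = True
            return BinaryVolume(v)

        samples = [vol(120), vol(80), vol(95)]
        assert cohort_normalization_count(samples) == 120

    def test_single_sample_is_its_own_count(self):
        v = BinaryVolume(np.pad(np.ones((2, 2, 2), bool), 2))
        assert cohort_normalization_count([v]) == 8

    def test_mismatched_shapes_rejected(self):
        a = BinaryVolume(np.ones((4, 4, 4), bool))
        b = BinaryVolume(np.ones((5, 4, 4), bool))
        with pytest.raises(ValueError, match="dimensions"):
            cohort_normalization_count([a, b])

    def test_largest_sample_has_zero_norm_cycles(self, rng):
        v = BinaryVolume(rng.random((12, 12, 12)) < 0.03)
        res = normalized_halo(v, v.foreground_count)
        assert res.norm_cycles == 0.0
        assert res.nhv == res.hv

    def test_normalization_below_initial_count_rejected(self, rng):
        v = BinaryVolume(rng.random((12, 12, 12)) < 0.1)
        with pytest.raises(ValueError, match="normalization"):
            normalized_halo(v, v.foreground_count - 1)

    def test_nhv_invariant_to_duplicating_largest_sample(self, rng):
        vols = [BinaryVolume(rng.random((14, 14, 14)) < p) for p in (0.02, 0.04, 0.06)]
        norm1 = cohort_normalization_count(vols)
        norm2 = cohort_normalization_count(vols + [vols[-1]])
        assert norm1 == norm2
        r1 = [normalized_halo(v, norm1).nhv for v in vols]
        r2 = [normalized_halo(v, norm2).nhv for v in vols]
        assert r1 == r2

    def test_nhv_bounded_by_hv(self, rng):
        vols = [BinaryVolume(rng.random((14, 14, 14)) < p) for p in (0.02, 0.05)]
        norm = cohort_normalization_count(vols)
        for v in vols:
            res = normalized_halo(v, norm)
            assert res.nhv <= res.hv + 1e-12


class TestLayoutDiscrimination:
    def test_clustered_layout_has_higher_nhv(self):
        norm = 150
        hom = point_phantom((32, 32, 32), norm, "homogeneous", seed=1)
        clu = point_phantom((32, 32, 32), norm, "clustered", seed=1, cluster_sd=2.5)
        r_hom = normalized_halo(hom, norm)
        r_clu = normalized_halo(clu, norm)
        assert r_clu.nhv > r_hom.nhv

    def test_planar_limit_single_slice(self):
        # 2D limit: a single-slice volume with evenly spread vs blobbed pixels
        hom = np.zeros((1, 24, 24), bool)
        hom[0, 2::7, 2::7] = True
        clu = np.zeros((1, 24, 24), bool)
        n = hom.sum()
        ys, xs = np.unravel_index(np.arange(n), (4, 4))
        clu[0, 10 + ys, 10 + xs] = True
        assert clu.sum() == n
        hv_hom = halo_index(fill_curve(BinaryVolume(hom), 0.9), 0.9)
        hv_clu = halo_index(fill_curve(BinaryVolume(clu), 0.9), 0.9)
        assert hv_clu > hv_hom


class TestHaloDispersionEstimator:
    def test_fit_records_cohort_count_and_transform_matches_function(self, rng):
        vols = [BinaryVolume(rng.random((12, 12, 12)) < p) for p in (0.02, 0.05)]
        est = HaloDispersion().fit(vols)
        assert est.normalization_count_ == max(v.foreground_count for v in vols)
        results = est.transform(vols)
        direct = normalized_halo(vols[0], est.normalization_count_)
        assert results[0].nhv == pytest.approx(direct.nhv)

    def test_empty_class_is_missing_by_design(self, rng):
        vols = [
            BinaryVolume(rng.random((10, 10, 10)) < 0.05),
            BinaryVolume(np.zeros((10, 10, 10), bool)),
        ]
        results = HaloDispersion().fit(vols).transform(vols)
        assert np.isnan(results[1].nhv) and np.isnan(results[1].hv)

    def test_integer_norm_option(self, rng):
        vols = [BinaryVolume(rng.random((12, 12, 12)) < p) for p in (0.01, 0.05)]
        frac = HaloDispersion().fit(vols).transform(vols)[0]
        whole = HaloDispersion(integer_norm=True).fit(vols).transform(vols)[0]
        assert whole.norm_cycles == np.ceil(frac.norm_cycles)

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = HaloDispersion(target_fraction=0.8, cross_first=False)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
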
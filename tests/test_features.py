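"""Texture-feature families against hand computations and naive oracles."""

import numpy as np
import pytest

from conftest import quantized_from_dense, random_quantized
from oracles import (
    glcm_pairs,
    gradient_magnitudes_naive,
    haralick_naive,
    rlm_runs,
    rlm_stats_naive,
)

from phyllotex.features import (
    CooccurrenceMatrix,
    build_glcm,
    build_rlm,
    extract_all,
    glcm_features,
    gradient_features,
    histogram_features,
    rlm_features,
)
from phyllotex.registry import GLCM_STATISTICS, RLM_STATISTICS
from phyllotex.voi import VolumeWithMask, normalize_voi


class TestHistogram:
    def test_constant_voi(self):
        q = quantized_from_dense(np.full((2, 2, 2), 5))
        fv = histogram_features(q)
        assert fv["Mean"] == 5
        assert fv["Variance"] == 0
        for name in ("Perc.01%", "Perc.10%", "Perc.50%", "Perc.90%", "Perc.99%"):
            assert fv[name] == 5
        assert "Skewness" in fv.undefined and "Kurtosis" in fv.undefined

    def test_four_distinct_levels_hand_arithmetic(self):
        q = quantized_from_dense(np.array([[[1, 2, 3, 4]]]))
        fv = histogram_features(q)
        assert fv["Mean"] == pytest.approx(2.5)
        assert fv["Variance"] == pytest.approx(1.25)  # population convention
        # cumulative-count percentile: smallest level with cumcount >= q*Np
        assert fv["Perc.50%"] == 2
        assert fv["Perc.90%"] == 4
        assert fv["Perc.01%"] == 1

    def test_symmetric_multiset_has_zero_skewness(self):
        q = quantized_from_dense(np.array([[[1, 2, 2, 3]]]))
        assert histogram_features(q)["Skewness"] == pytest.approx(0.0)


class TestGLCMBuild:
    def test_constant_image_single_cell(self):
        q = quantized_from_dense(np.ones((2, 2, 1), dtype=int))
        m = build_glcm(q, (1, 0, 0))
        assert m.p[0, 0] == pytest.approx(1.0)
        assert m.p.sum() == pytest.approx(1.0)

    def test_alternating_strip_by_hand(self):
        # levels [1,2,1,2] along rows: three (row) pairs, symmetrized
        q = quantized_from_dense(np.array([[1], [2], [1], [2]])[..., None])
        m = build_glcm(q, (1, 0, 0))
        assert m.p[0, 1] == pytest.approx(0.5)
        assert m.p[1, 0] == pytest.approx(0.5)
        assert m.p[0, 0] == 0 and m.p[1, 1] == 0

    def test_zero_valid_pairs_flagged_empty(self):
        dense = np.zeros((3, 1, 1), dtype=int)
        dense[0, 0, 0] = 1  # single voxel: no pair at offset 1
        q = quantized_from_dense(dense)
        m = build_glcm(q, (1, 0, 0))
        assert m.empty
        fv = glcm_features(m)
        assert len(fv.undefined) == len(GLCM_STATISTICS)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        q = random_quantized(rng, shape=(4, 4, 4), n_levels=4)
        offsets = [
            (d * a, d * b, d * c)
            for d in (1, 2)
            for a, b, c in [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0), (1, -1, 0)]
        ]
        dense = q.to_dense()
        for off in offsets:
            m = build_glcm(q, off)
            counts = glcm_pairs(dense, off, q.n_levels)
            total = counts.sum()
            if total == 0:
                assert m.empty
            else:
                np.testing.assert_allclose(m.p, counts / total, atol=1e-15)

    def test_symmetry_and_normalization(self, rng):
        q = random_quantized(rng, shape=(6, 6, 6), n_levels=6)
        m = build_glcm(q, (0, 1, 0))
        assert m.p.sum() == pytest.approx(1.0)
        np.testing.assert_array_equal(m.p, m.p.T)


class TestGLCMStatistics:
    def test_single_cell_matrix(self):
        p = np.zeros((4, 4))
        p[2, 2] = 1.0
        fv = glcm_features(CooccurrenceMatrix(p=p, offset=(1, 0, 0), n_pairs=10),
                           prefix="")
        assert fv["AngScMom"] == pytest.approx(1.0)
        assert fv["Contrast"] == pytest.approx(0.0)
        assert fv["Entropy"] == pytest.approx(0.0)
        assert fv["InvDfMom"] == pytest.approx(1.0)

    def test_two_cell_matrix_closed_form(self):
        p = np.zeros((2, 2))
        p[0, 1] = p[1, 0] = 0.5
        fv = glcm_features(CooccurrenceMatrix(p=p, offset=(1, 0, 0), n_pairs=2),
                           prefix="")
        assert fv["AngScMom"] == pytest.approx(0.5)
        assert fv["Contrast"] == pytest.approx(1.0)
        assert fv["Entropy"] == pytest.approx(np.log(2))

    @pytest.mark.parametrize("seed", range(5))
    def test_all_eleven_match_naive_summation(self, seed):
        rng = np.random.default_rng(seed)
        ng = int(rng.integers(3, 9))
        raw = rng.uniform(size=(ng, ng))
        raw = raw + raw.T
        p = raw / raw.sum()
        fv = glcm_features(CooccurrenceMatrix(p=p, offset=(0, 0, 1), n_pairs=100),
                           prefix="")
        expected = haralick_naive(p)
        for stat in GLCM_STATISTICS:
            assert fv[stat] == pytest.approx(expected[stat], abs=1e-12), stat

    def test_angscmom_is_one_iff_single_nonzero_cell(self, rng):
        # single cell -> exactly 1; any two cells -> strictly below 1
        p1 = np.zeros((3, 3)); p1[1, 1] = 1.0
        fv1 = glcm_features(CooccurrenceMatrix(p1, (1, 0, 0), 4), prefix="")
        assert fv1["AngScMom"] == 1.0
        p2 = np.zeros((3, 3)); p2[0, 1] = p2[1, 0] = 0.5
        fv2 = glcm_features(CooccurrenceMatrix(p2, (1, 0, 0), 4), prefix="")
        assert 0 < fv2["AngScMom"] < 1


class TestRLM:
    def test_single_full_run_along_z(self):
        q = quantized_from_dense(np.full((1, 1, 4), 3))
        rlm = build_rlm(q, "Z")
        assert rlm.n_runs == 1
        assert rlm.r[2, 3] == 1  # level 3, length 4

    def test_two_runs_by_hand(self):
        q = quantized_from_dense(np.array([[1, 1, 2, 2]])[None, ...].reshape(1, 4, 1))
        rlm = build_rlm(q, "Horzl")
        fv = rlm_features(rlm)
        assert rlm.n_runs == 2
        assert fv["Horzl_GLevNonU"] == pytest.approx(1.0)
        assert fv["Horzl_RLNonUni"] == pytest.approx(2.0)
        assert fv["Horzl_LngREmph"] == pytest.approx(4.0)
        assert fv["Horzl_ShrtREmp"] == pytest.approx(0.25)
        assert fv["Horzl_Fraction"] == pytest.approx(0.5)

    def test_constant_line_statistics(self):
        q = quantized_from_dense(np.full((1, 4, 1), 2))
        fv = rlm_features(build_rlm(q, "Horzl"))
        assert fv["Horzl_GLevNonU"] == pytest.approx(1.0)
        assert fv["Horzl_LngREmph"] == pytest.approx(16.0)
        assert fv["Horzl_Fraction"] == pytest.approx(0.25)

    @pytest.mark.parametrize("direction", ["Z", "Horzl", "Vertl", "45dgr", "135dr"])
    @pytest.mark.parametrize("seed", range(3))
    def test_matches_scanline_oracle_with_holes(self, direction, seed):
        rng = np.random.default_rng(seed)
        q = random_quantized(rng, shape=(5, 5, 3), n_levels=3, p_mask=0.7)
        dense = q.to_dense()
        rlm = build_rlm(q, direction)
        runs = rlm_runs(dense, direction)
        assert rlm.n_runs == len(runs)
        expected = rlm_stats_naive(runs, q.n_voxels)
        fv = rlm_features(rlm)
        for stat in RLM_STATISTICS:
            name = f"{direction}_{stat}"
            assert fv[name] == pytest.approx(expected[stat], rel=1e-12), name

    @pytest.mark.parametrize("direction", ["Z", "Horzl", "Vertl", "45dgr", "135dr"])
    def test_voxel_conservation(self, rng, direction):
        # every VOI voxel is covered by exactly one run in each direction
        q = random_quantized(rng, shape=(6, 5, 4), n_levels=4, p_mask=0.6)
        rlm = build_rlm(q, direction)
        j = np.arange(1, rlm.r.shape[1] + 1)
        assert (rlm.r * j).sum() == q.n_voxels

    def test_concentrating_runs_into_fewer_levels_raises_glevnonu(self):
        spread = quantized_from_dense(np.array([[1, 1, 2, 2, 3, 3]]).reshape(1, 6, 1))
        packed = quantized_from_dense(np.array([[1, 1, 2, 1, 1, 2]]).reshape(1, 6, 1))
        g_spread = rlm_features(build_rlm(spread, "Horzl"))["Horzl_GLevNonU"]
        g_packed = rlm_features(build_rlm(packed, "Horzl"))["Horzl_GLevNonU"]
        # both have Nr; packed concentrates runs on fewer gray levels
        assert g_packed > g_spread


class TestGradient:
    def test_constant_volume(self):
        vm = VolumeWithMask(np.full((5, 5, 5), 7.0), np.ones((5, 5, 5), bool))
        q, _ = normalize_voi(vm)
        fv = gradient_features(q)
        assert fv["GrMean"] == 0.0
        assert fv["GrNonZeros"] == 0.0

    def test_linear_ramp_constant_magnitude(self):
        dense = np.tile(np.arange(1, 9)[:, None, None], (1, 5, 5))
        q = quantized_from_dense(dense)
        fv = gradient_features(q)
        assert fv["GrMean"] == pytest.approx(1.0)  # level step 1 per voxel
        assert fv["GrVariance"] == pytest.approx(0.0)
        assert fv["GrNonZeros"] == pytest.approx(1.0)

    def test_matches_finite_difference_oracle(self, rng):
        q = random_quantized(rng, shape=(6, 6, 6), n_levels=8, p_mask=0.9)
        fv = gradient_features(q)
        mags = gradient_magnitudes_naive(q.to_dense().astype(float), q.mask)
        if not mags:
            assert "GrMean" in fv.undefined
            return
        mags = np.asarray(mags)
        assert fv["GrMean"] == pytest.approx(mags.mean())
        assert fv["GrVariance"] == pytest.approx(mags.var())
        assert fv["GrNonZeros"] == pytest.approx((mags > 0).mean())

    def test_no_interior_voxels_all_undefined(self):
        dense = np.zeros((3, 3, 3), dtype=int)
        dense[1, 1, 1] = 2  # lone voxel: 6-neighborhood not in VOI
        q = quantized_from_dense(dense)
        fv = gradient_features(q)
        assert len(fv.undefined) == 5
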
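import numpy as np
import pytest

from restdyn.geometry import BinaryMask, VolumeGeometry, VolumeMap
from restdyn.stats import (
    StatThresholds,
    bh_q,
    curve_table,
    fdr_at_threshold,
    pearson_roi,
    sign_test,
    spearman_map,
    threshold_clusters,
    two_sample_t_map,
)

from .oracles import (
    bh_oracle,
    flood_fill_clusters,
    pearson_oracle,
    pooled_t_oracle,
    spearman_oracle,
)

GEOM1 = VolumeGeometry((1, 1, 1), (1.0, 1.0, 1.0))


def scalar_maps(values):
    return [VolumeMap(np.full((1, 1, 1), v), GEOM1) for v in values]


class TestTMap:
    def test_closed_form_example(self):
        sm = two_sample_t_map(scalar_maps([0, 1, 2]), scalar_maps([3, 4, 5]))
        assert sm.t[0, 0, 0] == pytest.approx(-3 / np.sqrt(2 / 3))
        assert sm.df == 4
        assert sm.effect[0, 0, 0] == -3.0

    def test_identical_groups_give_null(self):
        with pytest.warns(UserWarning, match="zero pooled"):
            sm = two_sample_t_map(scalar_maps([2, 2, 2]), scalar_maps([2, 2, 2]))
        assert sm.t[0, 0, 0] == 0.0
        assert sm.p[0, 0, 0] == 1.0

    def test_group_swap_antisymmetry(self, rng):
        geom = VolumeGeometry((3, 3, 3), (1.0, 1.0, 1.0))
        a = [VolumeMap(rng.standard_normal(geom.shape), geom) for _ in range(5)]
        b = [VolumeMap(rng.standard_normal(geom.shape), geom) for _ in range(6)]
        ab = two_sample_t_map(a, b)
        ba = two_sample_t_map(b, a)
        assert np.allclose(ab.t, -ba.t)
        assert np.allclose(ab.p, ba.p)

    def test_matches_textbook_oracle(self, rng):
        a_vals = rng.standard_normal(7)
        b_vals = rng.standard_normal(5) + 0.5
        sm = two_sample_t_map(scalar_maps(a_vals), scalar_maps(b_vals))
        t_exp, p_exp = pooled_t_oracle(a_vals, b_vals)
        assert abs(sm.t[0, 0, 0] - t_exp) < 1e-10
        assert abs(sm.p[0, 0, 0] - p_exp) < 1e-10


class TestClusters:
    def make_stat_map(self, supra, t_sign=1.0):
        geom = VolumeGeometry(supra.shape, (1.0, 1.0, 1.0))
        p = np.where(supra, 0.001, 0.5)
        t = np.where(supra, t_sign, 0.0)
        from restdyn.stats import StatMap

        return StatMap(
            effect=t, t=t, p=p, q=p, geometry=geom,
            mask=np.ones(supra.shape, dtype=bool),
        )

    def test_extent_threshold_semantics(self):
        supra = np.zeros((10, 10, 10), dtype=bool)
        supra[0, 0, :], supra[0, 1, :] = True, True  # 20-voxel slab
        supra[5, :, 0] = True  # second component
        supra[5, :9, 1] = True  # total 19 voxels
        sm = self.make_stat_map(supra)
        out = threshold_clusters(sm, StatThresholds(min_cluster_voxels=20))
        labelled = out.cluster_labels
        assert labelled[0, 0, 0] == 1
        assert labelled[5, 0, 0] == 0  # 19-voxel component removed

    def test_no_suprathreshold_voxels(self):
        sm = self.make_stat_map(np.zeros((4, 4, 4), dtype=bool))
        out = threshold_clusters(sm, StatThresholds())
        assert out.cluster_labels.max() == 0

    def test_signs_clustered_separately(self):
        supra = np.zeros((6, 6, 6), dtype=bool)
        supra[0, 0, 0:3] = True
        supra[0, 0, 3:6] = True  # adjacent run, opposite sign below
        t = np.zeros(supra.shape)
        t[0, 0, 0:3], t[0, 0, 3:6] = 1.0, -1.0
        from restdyn.stats import StatMap

        sm = StatMap(
            effect=t, t=t, p=np.where(supra, 0.001, 0.5), q=t,
            geometry=VolumeGeometry(supra.shape, (1.0, 1.0, 1.0)),
            mask=np.ones(supra.shape, dtype=bool),
        )
        out = threshold_clusters(sm, StatThresholds(min_cluster_voxels=2))
        assert out.cluster_labels[0, 0, 0] != out.cluster_labels[0, 0, 4]

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(5):
            supra = rng.random((8, 8, 8)) < 0.25
            sm = self.make_stat_map(supra)
            out = threshold_clusters(sm, StatThresholds(min_cluster_voxels=3))
            _, sizes = flood_fill_clusters(supra, connectivity=6)
            surviving = sorted(s for s in sizes if s >= 3)
            ours = sorted(
                np.bincount(out.cluster_labels.ravel())[1:].tolist()
            )
            assert ours == surviving


class TestFDR:
    def test_full_discovery_gives_p0(self):
        p = np.full(200, 0.005)
        assert fdr_at_threshold(p, 0.01) == pytest.approx(0.01)

    def test_sparse_discovery_clips_to_one(self):
        p = np.concatenate([np.full(10, 0.001), np.full(990, 0.5)])
        assert fdr_at_threshold(p, 0.01) == 1.0

    def test_no_discoveries_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(fdr_at_threshold(np.full(10, 0.9), 0.01))

    def test_bh_stepup_example(self):
        q = bh_q(np.array([0.01, 0.02, 0.03, 0.5]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5], atol=1e-12)

    def test_bh_matches_enumeration_oracle(self, rng):
        p = rng.random(100)
        assert np.allclose(bh_q(p), bh_oracle(p), atol=1e-12)

    def test_bh_q_dominates_p(self, rng):
        p = rng.random(50)
        assert (bh_q(p) >= p - 1e-12).all()


class TestSpearmanMap:
    def test_monotone_transform_gives_one(self, rng):
        x_vals = rng.standard_normal(8)
        x = scalar_maps(x_vals)
        y = scalar_maps(np.exp(x_vals))  # strictly increasing transform
        sm = spearman_map(x, y)
        assert sm.effect[0, 0, 0] == pytest.approx(1.0)

    def test_negating_y_negates_rho(self, rng):
        x_vals, y_vals = rng.standard_normal(9), rng.standard_normal(9)
        r1 = spearman_map(scalar_maps(x_vals), scalar_maps(y_vals)).effect[0, 0, 0]
        r2 = spearman_map(scalar_maps(x_vals), scalar_maps(-y_vals)).effect[0, 0, 0]
        assert r1 == pytest.approx(-r2)

    def test_matches_rank_then_pearson_oracle(self, rng):
        x_vals = rng.integers(0, 5, size=12).astype(float)  # with ties
        y_vals = rng.standard_normal(12)
        rho = spearman_map(scalar_maps(x_vals), scalar_maps(y_vals)).effect[0, 0, 0]
        assert abs(rho - spearman_oracle(x_vals, y_vals)) < 1e-12

    def test_constant_variable_flagged(self, rng):
        with pytest.warns(UserWarning, match="constant"):
            sm = spearman_map(
                scalar_maps([1.0] * 6), scalar_maps(rng.standard_normal(6))
            )
        assert np.isnan(sm.effect[0, 0, 0])


class TestPearsonROI:
    def test_perfect_linearity(self):
        x = np.arange(5.0)
        res = pearson_roi(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        x, y = rng.standard_normal(19), rng.standard_normal(19)
        r1 = pearson_roi(x, y).r
        r2 = pearson_roi(3 * x - 2, 0.5 * y + 4).r
        assert r1 == pytest.approx(r2)

    def test_matches_formula_oracle(self, rng):
        x, y = rng.standard_normal(19), rng.standard_normal(19)
        res = pearson_roi(x, y)
        r_exp, p_exp = pearson_oracle(x, y)
        assert abs(res.r - r_exp) < 1e-10
        assert abs(res.p - p_exp) < 1e-10

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            res = pearson_roi([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])
        assert np.isnan(res.r)

    def test_spearman_option(self, rng):
        x, y = rng.standard_normal(10), rng.standard_normal(10)
        res = pearson_roi(x, y, method="spearman")
        assert abs(res.r - spearman_oracle(x, y)) < 1e-12


class TestSignTest:
    def test_unanimous_direction(self):
        n_pos, n, p = sign_test(np.ones(19))
        assert (n_pos, n) == (19, 19)
        assert p == pytest.approx(2 * 0.5**19)

    def test_balanced_is_nonsignificant(self):
        _, _, p = sign_test([1, -1] * 8)
        assert p == pytest.approx(1.0)

    def test_zeros_dropped(self):
        n_pos, n, _ = sign_test([0.0, 1.0, -1.0, 0.0])
        assert (n_pos, n) == (1, 2)


class TestCurveTable:
    def test_sem_definition(self, rng):
        rim = rng.standard_normal((7, 5))
        mir = rng.standard_normal((7, 5))
        table = curve_table(np.arange(5), rim, mir)
        expected_sem = rim.std(axis=0, ddof=1) / np.sqrt(7)
        assert np.allclose(table["rim_sem"], expected_sem)
        assert np.allclose(table["rim_mean"], rim.mean(axis=0))

    def test_identical_rois_coincide(self, rng):
        rim = rng.standard_normal((4, 6))
        table = curve_table(np.arange(6), rim, rim.copy())
        assert np.allclose(table["rim_mean"], table["mirror_mean"])
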
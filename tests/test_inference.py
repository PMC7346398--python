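import math

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from fcstrength.inference import (
    cluster_corrected_p,
    dice_coefficient,
    estimate_smoothness,
    expected_cluster_count,
    grf_cluster_inference,
    posthoc_lsd,
    voxelwise_group_stat,
)
from fcstrength.types import FcsMap, SmoothnessEstimate, StatMap


def maps_from_values(values, shape=(1, 1, 1)):
    """One FcsMap per subject holding a constant value."""
    mask = np.ones(shape, dtype=bool)
    return [
        FcsMap(np.full(shape, v, dtype=float), mask, 0.1, "mean", (2, 2, 2))
        for v in values
    ]


def random_maps(rng, n, shape=(6, 6, 4)):
    mask = np.ones(shape, dtype=bool)
    return [
        FcsMap(rng.normal(size=shape), mask, 0.1, "mean", (2, 2, 2))
        for _ in range(n)
    ]


class TestVoxelwiseStats:
    def test_identical_maps_give_zero_statistics(self, rng):
        base = rng.normal(size=(4, 4, 2))
        mask = np.ones((4, 4, 2), bool)
        maps = [FcsMap(base.copy(), mask, 0.1, "mean", (2, 2, 2)) for _ in range(9)]
        genos = ["AA"] * 3 + ["AG"] * 3 + ["GG"] * 3
        f_map, _ = voxelwise_group_stat(maps, genos, "additive")
        assert np.all(f_map.data == 0)
        t_map, _ = voxelwise_group_stat(maps, genos, "dominant")
        assert np.all(t_map.data == 0)

    def test_repeated_group_pattern_gives_zero_f(self):
        maps = maps_from_values([1, 2, 3, 1, 2, 3, 1, 2, 3])
        genos = ["AA", "AA", "AA", "AG", "AG", "AG", "GG", "GG", "GG"]
        f_map, _ = voxelwise_group_stat(maps, genos, "additive")
        assert f_map.data[0, 0, 0] == pytest.approx(0.0)

    def test_single_voxel_anova_matches_textbook(self):
        # groups {0.1,0.2}, {0.5,0.6}, {0.9,1.0}: SSB=0.64, SSW=0.015
        maps = maps_from_values([0.1, 0.2, 0.5, 0.6, 0.9, 1.0])
        genos = ["AA", "AA", "AG", "AG", "GG", "GG"]
        f_map, _ = voxelwise_group_stat(maps, genos, "additive")
        ssb, ssw = 0.64, 0.015
        expected = (ssb / 2) / (ssw / 3)
        assert f_map.data[0, 0, 0] == pytest.approx(expected)
        assert f_map.df == (2.0, 3.0)

    def test_f_equals_t_squared_for_two_group_data(self, rng):
        # dominant model merges AA+AG; an additive ANOVA on the same
        # two-group labels must equal the squared two-sample t
        mask = np.ones((3, 3, 2), bool)
        maps = random_maps(rng, 12, (3, 3, 2))
        genos = ["AA"] * 6 + ["GG"] * 6
        t_map, _ = voxelwise_group_stat(maps, genos, "dominant")
        f_num, p_den = stats.f_oneway(
            np.stack([m.data[mask] for m in maps[:6]]),
            np.stack([m.data[mask] for m in maps[6:]]),
        )
        np.testing.assert_allclose(t_map.data[mask] ** 2, f_num, atol=1e-10)

    def test_covariates_reduce_error_df(self, rng):
        maps = random_maps(rng, 12, (2, 2, 1))
        genos = ["AA"] * 4 + ["AG"] * 4 + ["GG"] * 4
        covars = pd.DataFrame(
            {"sex": ["male", "female"] * 6, "age": rng.normal(21, 1, 12)}
        )
        f_map, _ = voxelwise_group_stat(maps, genos, "additive", covars)
        assert f_map.df == (2.0, 12 - 3 - 2)

    def test_unknown_genotype_rejected(self, rng):
        maps = random_maps(rng, 4, (2, 2, 1))
        with pytest.raises(ValueError, match="unknown genotype"):
            voxelwise_group_stat(maps, ["AA", "AA", "XY", "GG"], "additive")

    def test_model_collapsing_to_one_group_rejected(self, rng):
        maps = random_maps(rng, 4, (2, 2, 1))
        with pytest.raises(ValueError):
            voxelwise_group_stat(maps, ["GG"] * 4, "dominant")


class TestSmoothness:
    def test_white_noise_hits_analytic_floor(self, rng):
        """i.i.d. residuals: forward-difference estimator returns
        sqrt(2 ln 2) ~ 1.1774 voxels per axis."""
        mask = np.ones((20, 20, 12), bool)
        resid = [rng.normal(size=(20, 20, 12)) for _ in range(40)]
        est = estimate_smoothness(resid, mask)
        expected = math.sqrt(2 * math.log(2))
        for f in est.fwhm_vox:
            assert f == pytest.approx(expected, rel=0.02)

    def test_known_smoothing_recovered_within_ten_percent(self, rng):
        fwhm = 3.0
        sigma = fwhm / math.sqrt(8 * math.log(2))
        mask = np.ones((30, 30, 20), bool)
        resid = [
            ndimage.gaussian_filter(rng.normal(size=(30, 30, 20)), sigma, mode="wrap")
            for _ in range(30)
        ]
        est = estimate_smoothness(resid, mask)
        for f in est.fwhm_vox:
            assert abs(f - fwhm) / fwhm < 0.10

    def test_resel_count_is_extensive(self, rng):
        resid_small = [rng.normal(size=(10, 10, 10)) for _ in range(20)]
        rng2 = np.random.default_rng(42)
        resid_big = [rng2.normal(size=(20, 10, 10)) for _ in range(20)]
        small = estimate_smoothness(resid_small, np.ones((10, 10, 10), bool))
        big = estimate_smoothness(resid_big, np.ones((20, 10, 10), bool))
        assert big.resel_count == pytest.approx(2 * small.resel_count, rel=0.1)

    def test_flat_residuals_rejected(self):
        with pytest.raises(ValueError):
            estimate_smoothness(
                [np.zeros((5, 5, 5)), np.zeros((5, 5, 5))], np.ones((5, 5, 5), bool)
            )


class TestGrfInference:
    def _smoothness(self, resels=150.0, n_vox=3888):
        f = (n_vox / resels) ** (1 / 3)
        return SmoothnessEstimate((f, f, f), resels, n_vox)

    def test_expected_cluster_count_matches_closed_form(self):
        u, resels = 3.09, 123.4
        # EC density of a 3D Z field, coded independently:
        rho3 = (
            (4 * math.log(2)) ** 1.5
            / (2 * math.pi) ** 2
            * (u ** 2 - 1)
            * math.exp(-(u ** 2) / 2)
        )
        assert expected_cluster_count(u, resels) == pytest.approx(resels * rho3)

    def test_infinite_threshold_gives_empty_table(self, rng):
        mask = np.ones((6, 6, 4), bool)
        stat = StatMap(np.abs(rng.normal(size=(6, 6, 4))), "F", (2.0, 50.0), mask)
        table = grf_cluster_inference(
            stat, self._smoothness(), voxel_forming_p=1e-12
        )
        assert table.n_clusters == 0

    def test_corrected_p_monotone_in_cluster_size(self):
        sm = self._smoothness()
        u = float(stats.norm.isf(0.001))
        ps = [cluster_corrected_p(k, u, sm) for k in (1, 5, 20, 80)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_fixed_cluster_more_surprising_in_rough_field(self):
        # a rough field (more resels in the same voxel volume) produces
        # smaller null clusters, so a fixed 20-voxel cluster earns a
        # smaller corrected p
        u = float(stats.norm.isf(0.001))
        p_smooth = cluster_corrected_p(20, u, self._smoothness(resels=50))
        p_rough = cluster_corrected_p(20, u, self._smoothness(resels=500))
        assert p_rough < p_smooth

    def test_cluster_membership_partitions_suprathreshold_set(self, rng):
        mask = np.ones((10, 10, 6), bool)
        data = np.zeros((10, 10, 6))
        data[2:5, 2:5, 1:4] = 80.0  # one strong block
        data[7:9, 7:9, 4:6] = 60.0  # another
        stat = StatMap(data, "F", (2.0, 100.0), mask)
        table = grf_cluster_inference(stat, self._smoothness(), cluster_alpha=0.9)
        labels = table.labels
        assert table.n_clusters == 2
        assert set(np.unique(labels)) == {0, 1, 2}
        sizes = sorted(table.table["size_vox"])
        assert sizes == sorted([(labels == i).sum() for i in (1, 2)])

    def test_t_map_reports_both_signs(self):
        mask = np.ones((8, 8, 4), bool)
        data = np.zeros((8, 8, 4))
        data[1:4, 1:4, 1:3] = 9.0
        data[5:8, 5:8, 1:3] = -9.0
        stat = StatMap(data, "t", (60.0,), mask)
        table = grf_cluster_inference(stat, self._smoothness(), cluster_alpha=0.9)
        assert set(table.table["sign"]) == {1, -1}


class TestPosthocLsd:
    def test_identical_groups_give_p_one(self):
        vals = [1.0, 2.0, 1.0, 2.0, 5.0, 6.0]
        genos = ["AA", "AA", "AG", "AG", "GG", "GG"]
        table = posthoc_lsd(vals, genos).set_index(["group_a", "group_b"])
        assert table.loc[("AA", "AG"), "p"] == pytest.approx(1.0)

    def test_textbook_arithmetic(self):
        # groups {1,2},{1,2},{5,6}: MSE = 0.5 with df 3; SE = sqrt(0.5*(1))
        vals = [1.0, 2.0, 1.0, 2.0, 5.0, 6.0]
        genos = ["AA", "AA", "AG", "AG", "GG", "GG"]
        table = posthoc_lsd(vals, genos).set_index(["group_a", "group_b"])
        se = math.sqrt(0.5 * (0.5 + 0.5))
        t_expected = (1.5 - 5.5) / se
        assert table.loc[("AA", "GG"), "t"] == pytest.approx(t_expected)
        assert table.loc[("AA", "GG"), "df"] == 3

    def test_largest_mean_gap_has_smallest_p(self, rng):
        vals = np.concatenate(
            [rng.normal(0, 1, 10), rng.normal(1, 1, 10), rng.normal(5, 1, 10)]
        )
        genos = ["AA"] * 10 + ["AG"] * 10 + ["GG"] * 10
        table = posthoc_lsd(vals, genos)
        gaps = table["mean_diff"].abs()
        assert table.loc[gaps.idxmax(), "p"] == table["p"].min()

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            posthoc_lsd([1.0, 2.0, 3.0], ["AA", "AA", "GG"])


def test_dice_coefficient_basics():
    a = np.zeros((4, 4, 1), bool); a[:2] = True
    b = np.zeros((4, 4, 1), bool); b[1:3] = True
    assert dice_coefficient(a, a) == 1.0
    assert dice_coefficient(a, ~a) == 0.0
    assert dice_coefficient(a, b) == pytest.approx(0.5)
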
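import numpy as np
import pytest

from conftest import make_run

from fcstrength.preprocess import (
    bandpass,
    build_design,
    discard_initial,
    extract_nuisance_signals,
    friston24,
    regress_out,
)
from fcstrength.types import MotionTrace, NuisanceDesign


class TestDiscard:
    def test_default_discard_drops_five_volumes(self, rng):
        run = make_run(rng.normal(size=(4, 4, 2, 217)))
        assert discard_initial(run, 5).n_volumes == 212

    def test_zero_discard_is_identity(self, small_run):
        out = discard_initial(small_run, 0)
        np.testing.assert_array_equal(out.data, small_run.data)

    def test_discarding_everything_raises(self, small_run):
        with pytest.raises(ValueError):
            discard_initial(small_run, small_run.n_volumes)


class TestFriston24:
    def test_zero_motion_gives_zero_design(self):
        f24 = friston24(MotionTrace(np.zeros((20, 6))))
        assert f24.shape == (20, 24)
        assert np.all(f24 == 0)

    def test_single_entry_propagates_to_square_and_lag(self):
        params = np.zeros((10, 6))
        params[3, 0] = 2.0
        f24 = friston24(MotionTrace(params))
        assert f24[3, 0] == 2.0       # R
        assert f24[3, 6] == 4.0       # R^2
        assert f24[4, 12] == 2.0      # R_-1
        assert f24[4, 18] == 4.0      # R_-1^2
        assert f24[0, 12] == 0.0      # zero-padded first lag row

    def test_matches_bruteforce_loop_construction(self, rng):
        params = rng.normal(size=(10, 6))
        f24 = friston24(MotionTrace(params))
        expected = np.zeros((10, 24))
        for t in range(10):
            for j in range(6):
                expected[t, j] = params[t, j]
                expected[t, 6 + j] = params[t, j] ** 2
                if t > 0:
                    expected[t, 12 + j] = params[t - 1, j]
                    expected[t, 18 + j] = params[t - 1, j] ** 2
        np.testing.assert_allclose(f24, expected)


class TestNuisanceSignals:
    def test_constant_image_gives_zero_signals(self):
        run = make_run(np.full((4, 4, 2, 30), 7.0))
        masks = np.zeros((4, 4, 2), dtype=bool)
        wm = masks.copy(); wm[0, 0, 0] = True
        csf = masks.copy(); csf[3, 3, 1] = True
        for sig in extract_nuisance_signals(run, wm, csf):
            np.testing.assert_allclose(sig, 0.0, atol=1e-12)

    def test_single_voxel_wm_mask_returns_that_series(self, rng):
        data = rng.normal(size=(3, 3, 2, 25))
        run = make_run(data)
        wm = np.zeros((3, 3, 2), dtype=bool); wm[1, 2, 0] = True
        csf = np.zeros((3, 3, 2), dtype=bool); csf[0, 0, 0] = True
        wm_sig, _, _ = extract_nuisance_signals(run, wm, csf)
        series = data[1, 2, 0]
        np.testing.assert_allclose(wm_sig, series - series.mean())

    def test_opposing_series_cancel_to_zero_mean_course(self):
        data = np.zeros((2, 1, 1, 3))
        data[0, 0, 0] = [1, 2, 3]
        data[1, 0, 0] = [3, 2, 1]
        run = make_run(data)
        mask = np.ones((2, 1, 1), dtype=bool)
        wm_sig, _, _ = extract_nuisance_signals(run, mask, mask)
        np.testing.assert_allclose(wm_sig, 0.0, atol=1e-12)

    def test_empty_mask_error_names_the_mask(self, small_run):
        empty = np.zeros(small_run.spatial_shape, dtype=bool)
        ok = np.ones_like(empty)
        with pytest.raises(ValueError, match="csf"):
            extract_nuisance_signals(small_run, ok, empty)


class TestRegression:
    def _intercept_design(self, t):
        return NuisanceDesign(np.ones((t, 1)), ("intercept",))

    def test_intercept_only_mean_centers(self, small_run):
        out = regress_out(small_run, self._intercept_design(small_run.n_volumes))
        expected = small_run.data - small_run.data.mean(axis=3, keepdims=True)
        np.testing.assert_allclose(out.data, expected, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        run = make_run(rng.normal(size=(3, 3, 2, 20)))
        x = np.column_stack([np.ones(20), rng.normal(size=(20, 2))])
        design = NuisanceDesign(x, ("intercept", "a", "b"))
        out = regress_out(run, design)
        resid = out.data.reshape(-1, 20)
        assert np.abs(resid @ x).max() < 1e-8

    def test_series_equal_to_regressor_becomes_zero(self, rng):
        reg = rng.normal(size=30)
        data = np.tile(reg, (2, 2, 1, 1))
        run = make_run(data)
        design = NuisanceDesign(
            np.column_stack([np.ones(30), reg]), ("intercept", "reg")
        )
        out = regress_out(run, design)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    def test_idempotence(self, rng):
        run = make_run(rng.normal(size=(3, 3, 2, 25)))
        x = np.column_stack([np.ones(25), rng.normal(size=(25, 3))])
        design = NuisanceDesign(x, ("intercept", "a", "b", "c"))
        once = regress_out(run, design)
        twice = regress_out(once, design)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-10)

    def test_collinear_columns_dropped_with_warning(self, rng, caplog):
        run = make_run(rng.normal(size=(2, 2, 1, 20)))
        a = rng.normal(size=20)
        x = np.column_stack([np.ones(20), a, 2 * a])
        design = NuisanceDesign(x, ("intercept", "a", "a2"))
        with caplog.at_level("WARNING"):
            regress_out(run, design)
        assert any("collinear" in r.message for r in caplog.records)

    def test_full_design_has_28_columns(self, rng):
        mot = MotionTrace(rng.normal(size=(30, 6)))
        sig = rng.normal(size=30)
        design = build_design(mot, wm=sig, csf=sig * 2, global_sig=sig * 3)
        assert design.matrix.shape == (30, 28)
        assert design.column_names[-1] == "intercept"


class TestBandpass:
    def test_constant_series_annihilated(self):
        run = make_run(np.full((2, 2, 1, 100), 5.0))
        out = bandpass(run, 0.01, 0.1)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    @pytest.mark.parametrize(
        "freq, min_ratio, max_ratio",
        [(0.05, 0.9, 1.1), (0.18, 0.0, 0.1)],
    )
    def test_sinusoid_gain_inside_and_outside_band(self, freq, min_ratio, max_ratio):
        tr, nt = 2.4, 212
        t = np.arange(nt) * tr
        sig = np.sin(2 * np.pi * freq * t)
        run = make_run(sig.reshape(1, 1, 1, nt), tr=tr)
        out = bandpass(run, 0.01, 0.1)
        ratio = (out.data ** 2).sum() / (sig ** 2).sum()
        assert min_ratio <= ratio <= max_ratio

    def test_band_beyond_nyquist_raises(self, small_run):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(small_run, 0.01, 0.5)  # tr=2.4 -> Nyquist ~ 0.208

    def test_filter_commutes_with_correlation(self, rng):
        """Filtering is per-voxel: correlating filtered series equals
        filtering then correlating (no cross-voxel leakage)."""
        data = rng.normal(size=(2, 1, 1, 80))
        run = make_run(data)
        out = bandpass(run, 0.01, 0.1)
        a, b = out.data[0, 0, 0], out.data[1, 0, 0]
        single_a = bandpass(make_run(data[:1]), 0.01, 0.1).data[0, 0, 0]
        np.testing.assert_allclose(a, single_a, atol=1e-12)
        r_joint = np.corrcoef(a, b)[0, 1]
        single_b = bandpass(make_run(data[1:]), 0.01, 0.1).data[0, 0, 0]
        assert r_joint == pytest.approx(np.corrcoef(single_a, single_b)[0, 1])
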
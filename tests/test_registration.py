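"""Quadratic splines, GCP extraction and affine registration."""

import numpy as np
import pytest

from blastoderm_atlas import (
    AffineMap1D,
    CohortConfig,
    ConfigurationError,
    DegenerateInputError,
    GCPSet,
    apply_affine,
    estimate_affine,
    extract_gcps,
    fit_quadratic_spline,
    make_pattern_model,
    register_cohort,
)
from blastoderm_atlas.pipeline import prepare_profiles, PipelineConfig
from blastoderm_atlas.synthetic import evaluate_pattern, make_cohort

from conftest import synthetic_profile


class TestSplineFit:
    def test_parabola_reproduced_exactly(self):
        x = np.linspace(0, 100, 80)
        y = 3.0 + 0.2 * x - 0.01 * x**2
        model = fit_quadratic_spline((x, y), n_knots=10)
        np.testing.assert_allclose(model(x), y, atol=1e-8)

    def test_constant_data_gives_constant_spline(self):
        x = np.linspace(0, 100, 50)
        model = fit_quadratic_spline((x, np.full_like(x, 4.0)), n_knots=8)
        np.testing.assert_allclose(model(np.linspace(0, 100, 33)), 4.0, atol=1e-9)

    def test_rss_not_worse_than_single_quadratic(self):
        rng = np.random.default_rng(3)
        x = np.sort(rng.uniform(0, 100, 300))
        y = np.sin(x / 8.0) * 40 + rng.normal(0, 2, x.size)
        model = fit_quadratic_spline((x, y), n_knots=20)
        rss_spline = np.sum((model(x) - y) ** 2)
        rss_quad = np.sum((np.polyval(np.polyfit(x, y, 2), x) - y) ** 2)
        assert rss_spline <= rss_quad + 1e-9

    def test_noiseless_pattern_fit_close_to_pattern(self):
        model8 = make_pattern_model("eve", "T8")
        x = np.linspace(0.5, 99.5, 300)
        y = evaluate_pattern(model8, x)
        spline = fit_quadratic_spline((x, y))
        amp = y.max()
        assert np.abs(spline(x) - y).max() < 0.02 * amp

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_quadratic_spline((np.arange(10.0), np.arange(10.0)), n_knots=20)


class TestGCPs:
    def test_single_gaussian_yields_one_peak_near_center(self):
        x = np.linspace(0, 100, 400)
        y = 10.0 * np.exp(-((x - 40.0) ** 2) / 8.0)
        gcps = extract_gcps(fit_quadratic_spline((x, y), n_knots=40))
        peaks = [p for f, p in gcps.features if f.startswith("peak")]
        assert len(peaks) == 1
        assert peaks[0] == pytest.approx(40.0, abs=0.5)

    def test_monotone_profile_has_no_gcps(self):
        x = np.linspace(0, 100, 200)
        with pytest.warns(UserWarning):
            gcps = extract_gcps(fit_quadratic_spline((x, 0.5 * x), n_knots=10))
        assert len(gcps) == 0

    def test_six_stripe_profile_gives_six_peaks_five_troughs(self):
        model8 = make_pattern_model("eve", "T8")
        x = np.linspace(0.5, 99.5, 400)
        gcps = extract_gcps(fit_quadratic_spline((x, evaluate_pattern(model8, x))))
        kinds = [f.split("_")[0] for f, _ in gcps.features]
        assert kinds.count("peak") == 6
        assert kinds.count("trough") >= 5
        truth = sorted(s.center for s in model8.stripes)
        peaks = [p for f, p in gcps.features if f.startswith("peak")]
        np.testing.assert_allclose(peaks, truth, atol=0.5)

    def test_positions_strictly_increasing_invariant(self):
        with pytest.raises(ConfigurationError):
            GCPSet([("peak_1", 30.0), ("trough_1", 20.0)])


class TestAffine:
    def test_identical_gcps_give_identity_maps(self):
        g = GCPSet([("peak_1", 30.0), ("trough_1", 45.0), ("peak_2", 60.0)])
        maps = estimate_affine({"a": g, "b": g, "c": g})
        for m in maps.values():
            assert m.a == pytest.approx(1.0, abs=1e-9)
            assert m.b == pytest.approx(0.0, abs=1e-9)

    def test_pure_shift_recovered_between_embryos(self):
        base = [("peak_1", 30.0), ("trough_1", 45.0), ("peak_2", 60.0)]
        shifted = [(f, p + 2.0) for f, p in base]
        maps = estimate_affine({"a": GCPSet(base), "b": GCPSet(shifted)})
        # gauge-fixed: relative offset between the two maps is the 2% EL shift
        assert maps["a"].b - maps["b"].b == pytest.approx(2.0, abs=1e-6)
        assert maps["a"].a == pytest.approx(maps["b"].a, abs=1e-9)

    def test_single_feature_falls_back_to_identity_with_warning(self):
        full = GCPSet([("peak_1", 30.0), ("peak_2", 60.0)])
        lone = GCPSet([("peak_1", 31.0)])
        with pytest.warns(UserWarning, match="identity"):
            maps = estimate_affine({"a": full, "b": full, "c": lone}, gauge_fix=False)
        assert maps["c"] == AffineMap1D()

    def test_apply_identity_is_noop(self):
        p = synthetic_profile([10.0, 50.0, 90.0], intensities={"eve": [1, 2, 3]})
        out = apply_affine(p, AffineMap1D())
        np.testing.assert_array_equal(out.data["x"], p.data["x"])

    def test_apply_then_inverse_restores_positions(self):
        p = synthetic_profile([20.0, 50.0, 80.0], intensities={"eve": [1, 2, 3]})
        m = AffineMap1D(1.03, -2.0)
        back = apply_affine(apply_affine(p, m), m.inverse())
        np.testing.assert_allclose(back.data["x"], p.data["x"], atol=1e-9)

    def test_nuclei_leaving_the_axis_are_clipped_and_counted(self):
        p = synthetic_profile([1.0, 50.0, 99.0], intensities={"eve": [1, 2, 3]})
        out = apply_affine(p, AffineMap1D(1.0, 5.0))
        assert out.n_nuclei == 2
        assert out.meta["n_clipped"] == 1

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ConfigurationError):
            AffineMap1D(-1.0, 0.0)


class TestCohortRegistration:
    def test_known_jitter_recovered_and_variance_reduced(self):
        cfg = CohortConfig(classes=("T8",), n_embryos_per_class=10, seed=31,
                           noise_sigma=0.0, background=(0, 0, 0))
        cohort, ledger = make_cohort(cfg)
        prep = prepare_profiles(cohort, PipelineConfig(cohort=cfg))
        registered, maps = register_cohort(prep)
        tr = ledger.set_index("embryo_id")
        a_t = tr["a_true"].to_numpy()
        b_t = tr["b_true"].to_numpy()
        a_g, b_g = a_t / a_t.mean(), (b_t - b_t.mean()) / a_t.mean()
        est = np.array([[maps[e].a, maps[e].b] for e in tr.index])
        assert np.abs(est[:, 1] - b_g).max() < 0.3
        assert np.abs(est[:, 0] - a_g).max() < 0.01
        # registration must not increase across-embryo GCP variance
        s1_pre = [min(p for f, p in _gcps(p0).features if f.startswith("peak"))
                  for p0 in prep]
        s1_post = [min(p for f, p in _gcps(p1).features if f.startswith("peak"))
                   for p1 in registered]
        assert np.std(s1_post) < np.std(s1_pre)

    def test_hb_channel_receives_the_identical_map(self):
        cfg = CohortConfig(classes=("T8",), n_embryos_per_class=4, seed=32)
        cohort, _ = make_cohort(cfg)
        prep = prepare_profiles(cohort, PipelineConfig(cohort=cfg))
        registered, maps = register_cohort(prep)
        for before, after in zip(prep, registered):
            m = maps[before.embryo_id]
            kept = after.data["nucleus_id"]
            src = before.data.set_index("nucleus_id").loc[kept]
            np.testing.assert_allclose(after.data["x"], m(src["x"].to_numpy()), atol=1e-9)
            np.testing.assert_array_equal(after.data["I_hb"], src["I_hb"])


def _gcps(profile):
    return extract_gcps(
        fit_quadratic_spline(profile, "eve"),
    )
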
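"""Generator: species presets, pattern evaluation, cohort sampling."""

import numpy as np
import pandas as pd
import pytest

from blastoderm_atlas import (
    CohortConfig,
    ConfigurationError,
    DomainSpec,
    PatternModel,
    StripeSpec,
    cohort_truth_features,
    evaluate_pattern,
    make_cohort,
    make_pattern_model,
    sample_embryo,
)
from blastoderm_atlas.core import C14A_CLASSES
from blastoderm_atlas.synthetic import stripe_count


class TestPatternPresets:
    def test_first_stripe_resolves_at_t2_next_to_broad_domain(self):
        m = make_pattern_model("eve", "T2", "clogmia")
        assert len(m.stripes) == 1 and m.stripes[0].label == 1
        assert len(m.domains) == 1
        assert m.stripes[0].center < m.domains[0].anterior_edge

    def test_six_stripes_at_t8_none_posterior_of_stripe_six(self):
        m = make_pattern_model("eve", "T8", "clogmia")
        assert sorted(s.label for s in m.stripes) == [1, 2, 3, 4, 5, 6]
        s6 = max(m.stripes, key=lambda s: s.label)
        assert all(s.center <= s6.center for s in m.stripes)
        assert not m.domains

    def test_hb_t8_truth_edges_at_25_and_52(self):
        t = make_pattern_model("hb", "T8", "clogmia").truth.set_index("feature")
        assert t.loc["edge_anterior", "position"] == pytest.approx(25.0)
        assert t.loc["edge_posterior", "position"] == pytest.approx(52.0)

    def test_hb_posterior_boundary_drifts_anteriorly_by_2_15_between_t3_and_t8(self):
        t3 = make_pattern_model("hb", "T3", "clogmia").truth.set_index("feature")
        t8 = make_pattern_model("hb", "T8", "clogmia").truth.set_index("feature")
        assert t3.loc["edge_posterior", "position"] - t8.loc["edge_posterior", "position"] == pytest.approx(2.15)

    def test_stripe_counts_monotone_in_time(self):
        for preset in ("clogmia", "drosophila"):
            counts = [stripe_count(preset, tc) for tc in C14A_CLASSES]
            assert counts == sorted(counts)

    def test_drosophila_has_all_seven_stripes_by_t4(self):
        assert stripe_count("drosophila", "T4") == 7
        assert stripe_count("clogmia", "T8") == 6

    @pytest.mark.parametrize("gene,tc,preset", [
        ("ftz", "T8", "clogmia"), ("eve", "T9", "clogmia"), ("eve", "T8", "anopheles"),
    ])
    def test_unknown_gene_class_or_preset_rejected(self, gene, tc, preset):
        with pytest.raises(ConfigurationError):
            make_pattern_model(gene, tc, preset)

    def test_truth_consistent_with_components(self):
        m = make_pattern_model("eve", "T8", "clogmia")
        truth = m.truth.set_index("feature")
        for s in m.stripes:
            assert truth.loc[f"peak_s{s.label}", "position"] == s.center


class TestEvaluatePattern:
    def test_isolated_stripe_peaks_at_center_with_amplitude(self):
        m = PatternModel("eve", "T8", [StripeSpec(1, 40.0, 2.0, 5.0)], [])
        assert evaluate_pattern(m, 40.0) == pytest.approx(5.0)

    def test_empty_model_is_zero_everywhere(self):
        m = PatternModel("eve", "T8", [], [])
        assert np.all(evaluate_pattern(m, np.linspace(0, 100, 11)) == 0.0)

    def test_domain_at_half_maximum_on_its_edge(self):
        m = PatternModel("hb", "T8", [], [DomainSpec(25.0, 52.0, 1.5, 100.0)])
        assert evaluate_pattern(m, 52.0) == pytest.approx(50.0, rel=1e-4)

    def test_nonnegative_and_additive(self):
        m = PatternModel("eve", "T8",
                         [StripeSpec(1, 30.0, 2.0, 5.0), StripeSpec(2, 60.0, 2.0, 7.0)],
                         [DomainSpec(40.0, 50.0, 1.0, 3.0)])
        x = np.linspace(0, 100, 201)
        total = evaluate_pattern(m, x)
        parts = sum(
            evaluate_pattern(PatternModel("eve", "T8", [s], []), x) for s in m.stripes
        ) + evaluate_pattern(PatternModel("eve", "T8", [], m.domains), x)
        assert np.all(total >= 0)
        np.testing.assert_allclose(total, parts, rtol=1e-12)

    def test_spec_validation(self):
        with pytest.raises(ConfigurationError):
            StripeSpec(1, 150.0, 2.0, 5.0)
        with pytest.raises(ConfigurationError):
            DomainSpec(50.0, 40.0, 1.0, 5.0)
        with pytest.raises(ConfigurationError):
            DomainSpec(10.0, 40.0, -1.0, 5.0)


class TestSampling:
    def test_same_seed_gives_bit_identical_embryos(self):
        cfg = CohortConfig(classes=("T8",), n_embryos_per_class=2, seed=5)
        models = {g: make_pattern_model(g, "T8") for g in ("eve", "hb")}
        p1, r1 = sample_embryo(models, cfg, 0)
        p2, r2 = sample_embryo(models, cfg, 0)
        pd.testing.assert_frame_equal(p1.data, p2.data)
        assert r1 == r2

    def test_clean_embryo_intensity_equals_pattern(self, clean_t8_profile):
        p = clean_t8_profile
        model = make_pattern_model("eve", "T8")
        np.testing.assert_allclose(
            p.data["I_eve"].to_numpy(),
            evaluate_pattern(model, p.data["x"].to_numpy()),
            atol=1e-9,
        )

    def test_offset_jitter_sd_matches_configuration(self):
        # Monte-Carlo: with sigma = 2% EL, the sample s.d. over 200 embryos
        # lies within the sampling distribution of the s.d.
        cfg = CohortConfig(classes=("T8",), n_embryos_per_class=200,
                           n_nuclei=60, jitter_offset=2.0, seed=11)
        _, ledger = make_cohort(cfg)
        assert 1.6 <= ledger["b_true"].std() <= 2.4

    def test_noise_calibration(self):
        # empirical residual s.d. about the clean signal matches noise_sigma
        cfg = CohortConfig(classes=("T8",), n_embryos_per_class=1, seed=3,
                           jitter_scale=0.0, jitter_offset=0.0, background=(0, 0, 0))
        cohort, _ = make_cohort(cfg)
        p = cohort[0]
        model = make_pattern_model("eve", "T8")
        clean = evaluate_pattern(model, p.data["x"].to_numpy())
        resid = p.data["I_eve"].to_numpy() - clean
        resid = resid[clean > 3 * cfg.noise_sigma]      # avoid zero-clipped region
        assert len(resid) >= 500
        assert abs(resid.std() - cfg.noise_sigma) <= 0.15 * cfg.noise_sigma


class TestCohort:
    def test_ledger_has_one_row_per_embryo(self):
        cfg = CohortConfig(n_embryos_per_class=10, n_nuclei=120, seed=1)
        cohort, ledger = make_cohort(cfg)
        assert len(cohort) == len(ledger) == 8 * 10
        assert ledger["time_class"].nunique() == 8

    def test_truth_features_cover_all_classes(self):
        cfg = CohortConfig(seed=0)
        truth = cohort_truth_features(cfg)
        assert set(truth["time_class"]) == set(C14A_CLASSES)
        eve_peaks = truth[(truth["gene"] == "eve") & (truth["kind"] == "stripe_peak")]
        assert len(eve_peaks) == sum(stripe_count("clogmia", tc) for tc in C14A_CLASSES)

    def test_nucleus_count_halves_per_earlier_cycle(self):
        cfg = CohortConfig(classes=("C12", "C13", "T1"), n_embryos_per_class=1,
                           n_nuclei=2000, seed=2)
        _, ledger = make_cohort(cfg)
        n = ledger.set_index("time_class")["n_nuclei"]
        assert n["T1"] / n["C13"] == pytest.approx(2.0, rel=0.1)
        assert n["C13"] / n["C12"] == pytest.approx(2.0, rel=0.1)
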
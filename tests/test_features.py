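"""Stripe peaks, domain boundaries, shifts, widths and the Welch test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from blastoderm_atlas import (
    BinnedProfile,
    ConfigurationError,
    DegenerateInputError,
    domain_width,
    find_boundary,
    find_stripe_peaks,
    label_stripes,
    track_shifts,
    welch_test,
)
from blastoderm_atlas.features import profile_peaks


def binned_from_function(fn, gene="eve", time_class="T8") -> BinnedProfile:
    x = np.arange(100) + 0.5
    table = pd.DataFrame(
        {"bin": np.arange(100), "x_mid": x, "mean": fn(x),
         "sd": np.zeros(100), "n": np.full(100, 10), "interpolated": False}
    )
    return BinnedProfile(gene=gene, time_class=time_class, table=table,
                         meta={"n_bins": 100})


class TestPeaks:
    def test_single_gaussian_peak_recovered(self):
        prof = binned_from_function(lambda x: 90 * np.exp(-((x - 40) ** 2) / 8.0))
        peaks = find_stripe_peaks(prof)
        assert len(peaks) == 1
        assert peaks["position"].iloc[0] == pytest.approx(40.0, abs=0.5)

    def test_two_stripes_labeled_anterior_to_posterior(self):
        prof = binned_from_function(
            lambda x: 90 * np.exp(-((x - 30) ** 2) / 8.0) + 70 * np.exp(-((x - 50) ** 2) / 8.0)
        )
        peaks = find_stripe_peaks(prof)
        assert list(peaks["stripe"]) == [1, 2]
        assert peaks["position"].is_monotonic_increasing

    def test_peak_extraction_commutes_with_mirroring(self):
        fn = lambda x: (80 * np.exp(-((x - 30) ** 2) / 8.0)
                        + 60 * np.exp(-((x - 62) ** 2) / 10.0))
        direct = find_stripe_peaks(binned_from_function(fn))
        mirrored = find_stripe_peaks(binned_from_function(lambda x: fn(100.0 - x)))
        np.testing.assert_allclose(
            sorted(100.0 - mirrored["position"]), sorted(direct["position"]), atol=0.1
        )

    def test_broad_domain_flagged_not_stripe(self):
        from scipy.special import expit
        prof = binned_from_function(
            lambda x: 60 * expit((x - 50) / 1.5) * expit((80 - x) / 1.5)
        )
        peaks = profile_peaks(prof.x, prof.mean)
        assert not peaks["is_stripe"].any()


class TestBoundary:
    def test_logistic_edge_boundary_at_midpoint(self):
        from scipy.special import expit
        prof = binned_from_function(
            lambda x: 100 * expit((x - 20) / 1.5) * expit((52 - x) / 1.0), gene="hb"
        )
        assert find_boundary(prof, "posterior") == pytest.approx(52.0, abs=0.5)
        assert find_boundary(prof, "anterior") == pytest.approx(20.0, abs=0.75)

    def test_step_function_boundary_within_a_bin(self):
        prof = binned_from_function(lambda x: np.where(x < 60, 100.0, 0.0), gene="hb")
        assert find_boundary(prof, "posterior") == pytest.approx(60.0, abs=1.0)

    def test_no_crossing_rejected(self):
        prof = binned_from_function(lambda x: np.full_like(x, 50.0), gene="hb")
        with pytest.raises(DegenerateInputError):
            find_boundary(prof, "posterior")

    def test_invalid_side_rejected(self):
        prof = binned_from_function(lambda x: np.where(x < 60, 100.0, 0.0), gene="hb")
        with pytest.raises(ConfigurationError):
            find_boundary(prof, "dorsal")


class TestTracking:
    def _tables(self, trajectories):
        """trajectories: {tc: [centers]} -> per-class stripe tables."""
        tables = {}
        for tc, centers in trajectories.items():
            fn = lambda x, cs=centers: sum(
                90 * np.exp(-((x - c) ** 2) / 8.0) for c in cs
            )
            tables[tc] = find_stripe_peaks(binned_from_function(fn, time_class=tc))
        return tables

    def test_stationary_stripes_have_zero_shift(self):
        tables = self._tables({"T7": [30.0, 50.0], "T8": [30.0, 50.0]})
        labeled = label_stripes(tables, class_order=["T7", "T8"])
        shifts = track_shifts(labeled, spacing_el=1.0, class_order=["T7", "T8"])
        np.testing.assert_allclose(shifts["shift"], 0.0, atol=0.1)

    def test_linear_trajectory_shift_is_position_difference(self):
        tables = self._tables({"T2": [40.0], "T5": [37.0], "T8": [34.0]})
        labeled = label_stripes(tables, class_order=["T2", "T5", "T8"])
        shifts = track_shifts(labeled, spacing_el=1.5, class_order=["T2", "T5", "T8"])
        assert shifts["shift"].iloc[0] == pytest.approx(6.0, abs=0.4)
        assert shifts["shift_nuclei"].iloc[0] == pytest.approx(4.0, abs=0.3)
        assert shifts["appearance_class"].iloc[0] == "T2"

    def test_late_appearing_stripe_tracked_from_its_first_class(self):
        tables = self._tables({"T6": [30.0], "T7": [29.0, 60.0], "T8": [28.0, 58.0]})
        labeled = label_stripes(tables, class_order=["T6", "T7", "T8"])
        shifts = track_shifts(labeled, 1.0, class_order=["T6", "T7", "T8"]).set_index("stripe")
        assert shifts.loc[2, "appearance_class"] == "T7"
        assert shifts.loc[2, "shift"] == pytest.approx(2.0, abs=0.2)


class TestDomainWidth:
    def _table(self):
        return pd.DataFrame(
            {"time_class": ["T8", "T8"], "stripe": [1, 6],
             "position": [30.0, 80.0], "is_stripe": [True, True]}
        )

    def test_width_is_peak_distance(self):
        assert domain_width(self._table(), 1, 6, "T8") == pytest.approx(50.0)

    def test_same_stripe_gives_zero(self):
        assert domain_width(self._table(), 1, 1, "T8") == 0.0

    def test_missing_stripe_rejected(self):
        with pytest.raises(DegenerateInputError):
            domain_width(self._table(), 1, 7, "T8")


class TestWelch:
    def test_identical_groups(self):
        r = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # means 2 and 3, both variances 1: t = -1/sqrt(2/3), nu = 4
        r = welch_test([1, 2, 3], [2, 3, 4])
        assert r.t == pytest.approx(-np.sqrt(1.5), abs=1e-9)
        assert r.df == pytest.approx(4.0, abs=1e-9)
        assert r.p == pytest.approx(2 * stats.t.sf(np.sqrt(1.5), 4), abs=1e-12)

    def test_matches_scipy_on_random_samples(self):
        rng = np.random.default_rng(9)
        a = rng.normal(10, 2, 14)
        b = rng.normal(11, 4, 9)
        r = welch_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert r.t == pytest.approx(ref.statistic, abs=1e-10)
        assert r.p == pytest.approx(ref.pvalue, abs=1e-10)
        assert r.df == pytest.approx(ref.df, abs=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=5.0), st.floats(min_value=-3.0, max_value=3.0))
    def test_ranked_test_invariant_under_monotone_transforms(self, scale, shift):
        a = np.array([3.0, 5.0, 9.0, 11.0])
        b = np.array([4.0, 6.0, 10.0, 14.0])
        base = welch_test(a, b, ranked=True)
        transformed = welch_test(np.exp(scale * a + shift), np.exp(scale * b + shift),
                                 ranked=True)
        assert transformed.t == pytest.approx(base.t, abs=1e-9)
        assert transformed.p == pytest.approx(base.p, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            welch_test([1.0], [2.0, 3.0])
        with pytest.raises(DegenerateInputError):
            welch_test([2.0, 2.0], [3.0, 3.0])
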
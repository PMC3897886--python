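"""Cycle assignment, chi-square distances, signatures and clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from blastoderm_atlas import (
    CohortConfig,
    ConfigurationError,
    DegenerateInputError,
    DistanceMatrix,
    assign_cleavage_cycle,
    cluster_embryos,
    make_pattern_model,
    pairwise_distance,
    stripe_signatures,
)
from blastoderm_atlas.synthetic import evaluate_pattern, sample_embryo

from conftest import synthetic_profile


class TestCleavageCycle:
    def _profile(self, n):
        rng = np.random.default_rng(0)
        return synthetic_profile(rng.uniform(0, 100, n), intensities={"eve": np.zeros(n)})

    @pytest.mark.parametrize("n,expected", [
        (300, "C14A"),      # calibration density
        (150, "C13"),       # one halving
        (19, "C10"),        # four halvings
    ])
    def test_density_halvings_map_to_cycles(self, n, expected):
        assert assign_cleavage_cycle(self._profile(n), strip_count_c14a=300) == expected

    def test_clamped_to_c10(self):
        assert assign_cleavage_cycle(self._profile(2), strip_count_c14a=300) == "C10"

    def test_empty_profile_rejected(self):
        p = synthetic_profile(np.array([1.0]), intensities={"eve": [0.0]})
        p.data = p.data.iloc[:0]
        with pytest.raises(DegenerateInputError):
            assign_cleavage_cycle(p)


class TestPairwiseDistance:
    def test_identical_noiseless_embryos_at_distance_zero(self):
        # data lying exactly in the quadratic-spline space: residuals vanish
        x = np.linspace(0, 100, 150)
        i = 50.0 + 0.01 * (x - 50.0) ** 2
        e1 = synthetic_profile(x, intensities={"eve": i}, embryo_id="a")
        e2 = synthetic_profile(x, intensities={"eve": i.copy()}, embryo_id="b")
        assert pairwise_distance(e1, e2, n_knots=10) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_by_construction(self):
        rng = np.random.default_rng(4)
        x = np.sort(rng.uniform(0, 100, 200))
        m5 = make_pattern_model("eve", "T5")
        m8 = make_pattern_model("eve", "T8")
        e1 = synthetic_profile(x, intensities={"eve": evaluate_pattern(m5, x) + rng.normal(0, 5, x.size)})
        e2 = synthetic_profile(x, intensities={"eve": evaluate_pattern(m8, x) + rng.normal(0, 5, x.size)})
        assert pairwise_distance(e1, e2) == pytest.approx(pairwise_distance(e2, e1))

    def test_cross_class_pairs_farther_than_within_class(self):
        cfg = CohortConfig(classes=("T7", "T8"), n_embryos_per_class=3, seed=6,
                           n_nuclei=1500)
        groups = {}
        for tc in ("T7", "T8"):
            models = {g: make_pattern_model(g, tc) for g in ("eve", "hb")}
            groups[tc] = [sample_embryo(models, cfg, i, time_class=tc)[0] for i in range(3)]
        within = [pairwise_distance(groups["T8"][0], groups["T8"][i]) for i in (1, 2)]
        across = [pairwise_distance(groups["T8"][0], groups["T7"][i]) for i in (0, 1, 2)]
        assert max(within) < min(across)

    def test_too_few_nuclei_rejected(self):
        x = np.linspace(0, 100, 150)
        e1 = synthetic_profile(x, intensities={"eve": np.sin(x)})
        e2 = synthetic_profile(x[:20], intensities={"eve": np.sin(x[:20])})
        with pytest.raises(DegenerateInputError):
            pairwise_distance(e1, e2, n_knots=40)


class TestSignatures:
    def _four_equal_stripes(self):
        x = np.linspace(0.5, 99.5, 500)
        i = sum(80.0 * np.exp(-((x - c) ** 2) / (2 * 2.0**2)) for c in (20, 40, 60, 80))
        return synthetic_profile(x, intensities={"eve": i})

    def test_identical_first_and_last_stripes_give_unit_ratios(self):
        sig = stripe_signatures([self._four_equal_stripes()])
        assert sig["intensity_ratio"].iloc[0] == pytest.approx(1.0, abs=0.05)
        assert sig["width_ratio"].iloc[0] == pytest.approx(1.0, abs=0.05)

    def test_perfectly_correlated_ratios_explained_by_one_component(self):
        x = np.linspace(0.5, 99.5, 500)
        profiles = []
        for k, a6 in enumerate((40.0, 60.0, 80.0, 100.0)):
            i = 100.0 * np.exp(-((x - 20) ** 2) / 8.0)
            i += a6 * np.exp(-((x - 80) ** 2) / 8.0)
            i += sum(70.0 * np.exp(-((x - c) ** 2) / 8.0) for c in (40, 60))
            profiles.append(synthetic_profile(x, intensities={"eve": i}, embryo_id=f"e{k}"))
        sig = stripe_signatures(profiles)
        # equal widths make the standardized pair effectively rank one
        assert sig.attrs["pc1_explained"] >= 0.9

    def test_pca_score_monotone_in_time_class_at_zero_noise(self):
        cfg = CohortConfig(noise_sigma=0.0, jitter_scale=0.0, jitter_offset=0.0,
                           background=(0, 0, 0), seed=8)
        profiles, order = [], ["T5", "T6", "T7", "T8"]
        for tc in order:
            models = {g: make_pattern_model(g, tc) for g in ("eve", "hb")}
            profiles.append(sample_embryo(models, cfg, 0, time_class=tc)[0])
        sig = stripe_signatures(profiles)
        scores = [sig.loc[p.embryo_id, "pca_score"] for p in profiles]
        assert np.all(np.diff(scores) > 0) or np.all(np.diff(scores) < 0)

    def test_missing_stripe_six_marks_signatures_absent(self):
        x = np.linspace(0.5, 99.5, 500)
        i = 100.0 * np.exp(-((x - 40) ** 2) / 8.0)      # a single stripe
        sig = stripe_signatures([synthetic_profile(x, intensities={"eve": i})])
        assert sig["intensity_ratio"].isna().all()


class TestClustering:
    def _dmat(self, values, ids=None):
        values = np.asarray(values, dtype=float)
        ids = ids or [f"e{i}" for i in range(len(values))]
        return DistanceMatrix(ids=list(ids), values=values)

    def test_k_equals_n_gives_singletons(self):
        d = self._dmat(squareform([0.5, 0.6, 0.7, 0.8, 0.9, 0.4]))
        out = cluster_embryos(d, 4)
        assert out.n_clusters == 4
        assert sorted(out.labels.values()) == [0, 1, 2, 3]

    def test_two_tight_pairs_recovered(self):
        m = np.full((4, 4), 0.9)
        np.fill_diagonal(m, 0.0)
        m[0, 1] = m[1, 0] = 0.1
        m[2, 3] = m[3, 2] = 0.2
        out = cluster_embryos(self._dmat(m, ids=list("ABCD")), 2)
        assert out.labels["A"] == out.labels["B"]
        assert out.labels["C"] == out.labels["D"]
        assert out.labels["A"] != out.labels["C"]

    def test_input_order_invariance(self):
        rng = np.random.default_rng(12)
        n = 12
        m = rng.uniform(0.2, 1.0, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        ids = [f"e{i:02d}" for i in range(n)]
        ref = cluster_embryos(self._dmat(m, ids), 3).labels
        perm = rng.permutation(n)
        shuffled = cluster_embryos(
            self._dmat(m[np.ix_(perm, perm)], [ids[i] for i in perm]), 3
        ).labels
        groups_ref = {}
        groups_shuf = {}
        for e in ids:
            groups_ref.setdefault(ref[e], set()).add(e)
            groups_shuf.setdefault(shuffled[e], set()).add(e)
        assert set(map(frozenset, groups_ref.values())) == set(map(frozenset, groups_shuf.values()))

    def test_matches_scipy_weighted_linkage(self):
        # independent oracle: scipy's WPGMA implements the same
        # mean-of-the-merged-pair update
        rng = np.random.default_rng(5)
        n = 10
        m = rng.uniform(0.1, 0.9, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        ids = [f"e{i:02d}" for i in range(n)]
        ours = cluster_embryos(self._dmat(m, ids), 3).labels
        z = linkage(squareform(m, checks=False), method="weighted")
        theirs = fcluster(z, t=3, criterion="maxclust")
        ours_sets = {}
        theirs_sets = {}
        for i, e in enumerate(ids):
            ours_sets.setdefault(ours[e], set()).add(e)
            theirs_sets.setdefault(theirs[i], set()).add(e)
        assert set(map(frozenset, ours_sets.values())) == set(map(frozenset, theirs_sets.values()))

    def test_clean_separation_recovered_exactly_at_true_k(self):
        # between-class distance above every within-class distance
        rng = np.random.default_rng(7)
        blocks = np.full((9, 9), 0.9)
        for b in range(3):
            sl = slice(3 * b, 3 * b + 3)
            blocks[sl, sl] = 0.2 + 0.05 * rng.random((3, 3))
        blocks = (blocks + blocks.T) / 2
        np.fill_diagonal(blocks, 0.0)
        out = cluster_embryos(self._dmat(blocks), 3)
        labels = [out.labels[f"e{i}"] for i in range(9)]
        assert labels[0] == labels[1] == labels[2]
        assert labels[3] == labels[4] == labels[5]
        assert labels[6] == labels[7] == labels[8]
        assert len({labels[0], labels[3], labels[6]}) == 3

    def test_merge_heights_non_decreasing_on_clean_input(self):
        m = np.full((4, 4), 0.9)
        np.fill_diagonal(m, 0.0)
        m[0, 1] = m[1, 0] = 0.1
        m[2, 3] = m[3, 2] = 0.2
        out = cluster_embryos(self._dmat(m), 1)
        heights = [h for _, _, h in out.history]
        assert heights == sorted(heights)

    def test_k_out_of_range_rejected(self):
        d = self._dmat(np.zeros((3, 3)))
        with pytest.raises(ConfigurationError):
            cluster_embryos(d, 5)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ConfigurationError):
            DistanceMatrix(ids=["a", "b"], values=np.array([[0.0, 0.4], [0.5, 0.0]]))
        with pytest.raises(ConfigurationError):
            DistanceMatrix(ids=["a", "b"], values=np.array([[0.0, 1.4], [1.4, 0.0]]))
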
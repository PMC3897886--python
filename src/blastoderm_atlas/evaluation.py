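"""Parameter-recovery evaluation on synthetic cohorts.

Every function here builds a cohort with known ground truth, runs the
relevant pipeline stages, and measures how well the known quantities are
recovered.  The analysis drivers and the acceptance checks are thin
wrappers around these functions.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import pearsonr
from sklearn.metrics import adjusted_rand_score

from . import features as feat
from . import pipeline as pl
from . import registration as reg
from . import staging
from .core import C14A_CLASSES
from .render import render_images
from .segmentation import segment_embryo
from .synthetic import (
    CohortConfig,
    cohort_truth_features,
    evaluate_pattern,
    make_cohort,
    make_pattern_model,
)


@contextmanager
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


def segmentation_recovery(seed: int, n_embryos: int = 20) -> dict:
    """Render a cohort, segment it back, compare counts and intensities."""
    cfg = CohortConfig(classes=("T8",), n_embryos_per_class=n_embryos, seed=seed)
    cohort, _ = make_cohort(cfg)
    n_true = n_detected = 0
    rs = []
    for p in cohort:
        nuclear, channels, placement = render_images(p, config=cfg)
        mask, prof = segment_embryo(nuclear, channels, embryo_id=p.embryo_id)
        n_true += p.n_nuclei
        n_detected += mask.n_nuclei
        tree = cKDTree(placement[["row", "col"]].to_numpy())
        d, idx = tree.query(mask.centroids, k=1)
        ok = d < 4
        rs.append(pearsonr(p.data["I_eve"].to_numpy()[idx[ok]],
                           prof.data["I_eve"].to_numpy()[ok])[0])
    return {
        "n_embryos": n_embryos,
        "count_error_fraction": abs(n_detected - n_true) / n_true,
        "min_intensity_r": float(min(rs)),
        "mean_intensity_r": float(np.mean(rs)),
    }


def registration_recovery(seed: int, n_embryos: int = 30) -> dict:
    """Zero-noise cohort with affine jitter: recover the per-embryo maps."""
    cfg = CohortConfig(classes=("T8",), n_embryos_per_class=n_embryos, seed=seed,
                       noise_sigma=0.0, background=(0.0, 0.0, 0.0),
                       jitter_scale=0.02, jitter_offset=2.0)
    cohort, ledger = make_cohort(cfg)
    pc = pl.PipelineConfig(cohort=cfg)
    with _quiet():
        prep = pl.prepare_profiles(cohort, pc)
        registered, maps = reg.register_cohort(prep)
    tr = ledger.set_index("embryo_id")
    a_t = tr["a_true"].to_numpy()
    b_t = tr["b_true"].to_numpy()
    a_gauge = a_t / a_t.mean()
    b_gauge = (b_t - b_t.mean()) / a_t.mean()
    est = np.array([[maps[e].a, maps[e].b] for e in tr.index])

    def stripe1_positions(profiles):
        out = []
        for p in profiles:
            peaks = feat.profile_peaks(p.data["x"].to_numpy(),
                                       p.intensity("eve").to_numpy())
            peaks = peaks[peaks["is_stripe"]]
            out.append(float(peaks["position"].iloc[0]) if len(peaks) else np.nan)
        return np.asarray(out)

    sd_pre = float(np.nanstd(stripe1_positions(prep)))
    sd_post = float(np.nanstd(stripe1_positions(registered)))
    return {
        "n_embryos": n_embryos,
        "offset_max_error_el": float(np.abs(est[:, 1] - b_gauge).max()),
        "scale_max_error": float(np.abs(est[:, 0] - a_gauge).max()),
        "stripe1_sd_reduction_fraction": 1.0 - sd_post / sd_pre,
    }


def staging_recovery(seed: int, n_per_class: int = 15) -> dict:
    """T5-T8 cohort at default noise: chi-square + signature clustering."""
    cfg = CohortConfig(classes=("T5", "T6", "T7", "T8"),
                       n_embryos_per_class=n_per_class, seed=seed)
    cohort, ledger = make_cohort(cfg)
    with _quiet():
        prep = pl.prepare_profiles(cohort, pl.PipelineConfig(cohort=cfg))
        dmat = staging.distance_matrix(prep)
        sig = staging.stripe_signatures(prep)
        clusters = staging.cluster_embryos(dmat, 4, signatures=sig)
    labels = [clusters.labels[e] for e in ledger["embryo_id"]]
    return {
        "n_embryos": len(cohort),
        "ari": float(adjusted_rand_score(ledger["time_class"].to_list(), labels)),
    }


def atlas_fidelity_noiseless(seed: int, n_per_class: int = 3) -> dict:
    """Degenerate cohort (no noise, jitter or background): atlas vs pattern."""
    cfg = CohortConfig(seed=seed, n_embryos_per_class=n_per_class,
                       noise_sigma=0.0, jitter_scale=0.0, jitter_offset=0.0,
                       position_jitter=0.0, background=(0.0, 0.0, 0.0))
    with _quiet():
        res = pl.run_pipeline(pl.PipelineConfig(cohort=cfg, use_true_classes=True))
    worst = 0.0
    for (gene, tc), bp in res.atlas_raw.items():
        expected = evaluate_pattern(make_pattern_model(gene, tc, cfg.species_preset), bp.x)
        amp = max(float(expected.max()), 1.0)
        worst = max(worst, float(np.abs(bp.mean - expected).max()) / amp)
    return {"n_embryos": len(res.profiles), "max_error_fraction_of_amplitude": worst}


def true_stripe_shifts(config: CohortConfig) -> pd.DataFrame:
    """Configured per-stripe total shifts from the analytic truth tables."""
    truth = cohort_truth_features(config)
    peaks = truth[truth["kind"] == "stripe_peak"]
    order = [tc for tc in config.classes if tc in C14A_CLASSES]
    final = order[-1]
    rows = []
    for label, grp in peaks[peaks["gene"] == "eve"].groupby("label"):
        grp = grp.set_index("time_class")
        present = [tc for tc in order if tc in grp.index]
        if final not in present:
            continue
        rows.append({"stripe": int(label), "appearance_class": present[0],
                     "shift": float(grp.loc[present[0], "position"]
                                    - grp.loc[final, "position"])})
    return pd.DataFrame(rows)


def feature_recovery(
    seed: int,
    species: str = "clogmia",
    n_per_class: int = 20,
    use_true_classes: bool = False,
) -> dict:
    """Full pipeline at default noise: measured features vs analytic truth.

    Returns the pipeline result plus error summaries for stripe peaks,
    half-maximum Hb boundaries, per-stripe shifts and Eve domain widths.
    """
    cfg = CohortConfig(species_preset=species, seed=seed,
                       n_embryos_per_class=n_per_class)
    with _quiet():
        res = pl.run_pipeline(pl.PipelineConfig(cohort=cfg,
                                                use_true_classes=use_true_classes))
    truth = cohort_truth_features(cfg)

    peaks_truth = truth[truth["kind"] == "stripe_peak"]
    st = res.stripe_table[res.stripe_table["stripe"] > 0]
    merged = st.merge(
        peaks_truth, left_on=["time_class", "stripe"],
        right_on=["time_class", "label"], suffixes=("", "_true"),
    )
    peak_errors = (merged["position"] - merged["position_true"]).abs()

    edge_truth = truth[(truth["gene"] == "hb") & truth["kind"].str.startswith("edge")]
    bm = res.boundaries.merge(edge_truth, on="time_class")
    bm = bm[((bm["side"] == "anterior") & (bm["kind"] == "edge_anterior"))
            | ((bm["side"] == "posterior") & (bm["kind"] == "edge_posterior"))]
    boundary_errors = (bm["position_x"] - bm["position_y"]).abs()

    shift_truth = true_stripe_shifts(cfg).set_index("stripe")["shift"]
    measured_shift = res.shifts.set_index("stripe")["shift"] if len(res.shifts) else pd.Series(dtype=float)
    shift_errors = (measured_shift.reindex(shift_truth.index) - shift_truth).abs()

    n_stripes = {"clogmia": 6, "drosophila": 7}[species]
    widths = feat.domain_width(res.stripe_table, 1, n_stripes)

    hb_pos = res.boundaries.set_index(["time_class", "side"])["position"]
    hb_shift = np.nan
    if ("T3", "posterior") in hb_pos.index and ("T8", "posterior") in hb_pos.index:
        hb_shift = float(hb_pos[("T3", "posterior")] - hb_pos[("T8", "posterior")])

    all_errors = pd.concat([peak_errors, boundary_errors, shift_errors.dropna()])
    return {
        "result": res,
        "n_embryos": len(res.profiles),
        "n_peaks_matched": int(len(merged)),
        "n_peaks_truth": int(len(peaks_truth)),
        "peak_mae_el": float(peak_errors.mean()),
        "boundary_mae_el": float(boundary_errors.mean()),
        "shift_mae_el": float(shift_errors.mean()),
        "all_feature_mae_el": float(all_errors.mean()),
        "shifts": measured_shift,
        "mean_shift_nuclei": float(res.shifts["shift_nuclei"].mean()) if len(res.shifts) else np.nan,
        "widths": widths,
        "hb_boundary_shift_el": hb_shift,
        "spacing_el": res.spacing_el,
    }


def determinism_check(seed: int) -> dict:
    """Two pipeline runs with one seed must agree bit for bit."""
    import hashlib

    def digest():
        cfg = CohortConfig(classes=("T7", "T8"), n_embryos_per_class=3,
                           n_nuclei=1500, seed=seed)
        with _quiet():
            res = pl.run_pipeline(pl.PipelineConfig(cohort=cfg, use_true_classes=True))
        h = hashlib.sha256()
        for key in sorted(res.atlas):
            h.update(res.atlas[key].table.to_csv().encode())
        h.update(res.stripe_table.to_csv().encode())
        h.update(res.boundaries.to_csv().encode())
        return h.hexdigest()

    a, b = digest(), digest()
    return {"identical": a == b, "digest": a}
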
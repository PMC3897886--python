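"""End-to-end orchestration: simulate -> profile -> stage -> register ->
integrate -> features.

``run_pipeline`` executes the quantification chain on a (synthetic or
loaded) cohort, persists every stage's output as tab-delimited text under
an output directory, and returns the in-memory results.  All randomness
flows from the single seed in the configuration, so reruns with the same
configuration are file-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from . import integration, io, profiles, registration, staging
from .core import C14A_CLASSES, DegenerateInputError, EmbryoProfile
from .integration import BinnedProfile
from .synthetic import CohortConfig, cohort_truth_features, make_cohort

log = logging.getLogger("blastoderm_atlas")


@dataclass
class PipelineConfig:
    """Paper-derived pipeline defaults, named after their processing step.

    strip_fraction: lateral strip covering 10% of embryo height;
    n_bins: 100 A-P integration bins; kernel_width_nuclei: Gaussian
    smoothing kernel of three nuclei; target_max: 0-255 relative scale;
    n_time_classes: eight C14A classes.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    strip_fraction: float = 0.10
    n_bins: int = 100
    kernel_width_nuclei: float = 3.0
    target_max: float = 255.0
    n_time_classes: int = 8
    use_true_classes: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["classes"] = list(d["cohort"]["classes"])
        d["cohort"]["background"] = list(d["cohort"]["background"])
        return d


@dataclass
class PipelineResult:
    profiles: list[EmbryoProfile]
    ledger: pd.DataFrame
    assignments: dict[str, str]
    maps: dict[str, registration.AffineMap1D]
    atlas_raw: dict[tuple[str, str], BinnedProfile]       # pre-smoothing
    atlas: dict[tuple[str, str], BinnedProfile]           # smoothed + scaled
    stripe_table: pd.DataFrame
    shifts: pd.DataFrame
    boundaries: pd.DataFrame
    spacing_el: float
    report: dict


def prepare_profiles(
    cohort: list[EmbryoProfile], config: PipelineConfig
) -> list[EmbryoProfile]:
    """Strip extraction, background removal and A-P orientation per embryo."""
    out = []
    for p in cohort:
        q = profiles.extract_lateral_strip(p, config.strip_fraction)
        for ch in q.channels:
            q = profiles.remove_background(q, ch)
        q = profiles.orient_anterior(q)
        out.append(q)
    return out


def stage_profiles(
    prepared: list[EmbryoProfile], config: PipelineConfig
) -> dict[str, str]:
    """Cycle assignment by density; C14A embryos get T1-T8 classes."""
    strip_count = config.cohort.n_nuclei * config.strip_fraction
    cycles = {p.embryo_id: staging.assign_cleavage_cycle(p, strip_count_c14a=strip_count)
              for p in prepared}
    c14a = [p for p in prepared if cycles[p.embryo_id] == "C14A"]
    assignment = dict(cycles)
    if c14a:
        tclasses = staging.assign_time_classes(c14a, config.cohort.species_preset)
        assignment.update(tclasses)
    return assignment


def build_atlas(
    prepared: list[EmbryoProfile],
    assignments: dict[str, str],
    config: PipelineConfig,
) -> tuple[dict, dict, dict, float]:
    """Per-class registration and per-gene/per-class integration."""
    spacing = integration.mean_internuclear_spacing(
        [p for p in prepared if assignments[p.embryo_id] in C14A_CLASSES] or prepared,
        height_to_length=config.cohort.height_to_length,
    )
    by_class: dict[str, list[EmbryoProfile]] = {}
    for p in prepared:
        by_class.setdefault(assignments[p.embryo_id], []).append(p)

    maps: dict[str, registration.AffineMap1D] = {}
    atlas_raw: dict[tuple[str, str], BinnedProfile] = {}
    atlas: dict[tuple[str, str], BinnedProfile] = {}
    genes = prepared[0].channels
    per_gene_max: dict[str, float] = {g: 0.0 for g in genes}
    smoothed: dict[tuple[str, str], BinnedProfile] = {}
    for tc, group in by_class.items():
        if len(group) >= 2 and tc in C14A_CLASSES:
            registered, class_maps = registration.register_cohort(group)
            maps.update(class_maps)
        else:
            registered = group
            maps.update({p.embryo_id: registration.AffineMap1D() for p in group})
        for gene in genes:
            raw = integration.bin_and_average(registered, gene, tc, config.n_bins)
            atlas_raw[(gene, tc)] = raw
            sm = integration.smooth_profile(raw, config.kernel_width_nuclei,
                                            spacing_el=spacing)
            smoothed[(gene, tc)] = sm
            per_gene_max[gene] = max(per_gene_max[gene], float(sm.mean.max()))
    # scaling is joint per gene across time classes so temporal amplitude
    # dynamics survive the 0-255 normalization
    for (gene, tc), sm in smoothed.items():
        atlas[(gene, tc)] = integration.scale_levels(
            sm, config.target_max, reference_max=per_gene_max[gene]
        )
    return maps, atlas_raw, atlas, spacing


def extract_features(
    atlas: dict[tuple[str, str], BinnedProfile],
    spacing_el: float,
    *,
    class_order: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Stripe table (tracked labels), shift records and Hb boundaries."""
    if class_order is None:
        class_order = [tc for tc in C14A_CLASSES if ("eve", tc) in atlas]
    eve_tables = {tc: feat.find_stripe_peaks(atlas[("eve", tc)])
                  for tc in class_order if ("eve", tc) in atlas}
    stripe_table = feat.label_stripes(eve_tables, class_order=list(eve_tables))
    try:
        shifts = feat.track_shifts(stripe_table, spacing_el, class_order=list(eve_tables))
    except DegenerateInputError:
        shifts = pd.DataFrame()
    rows = []
    for tc in class_order:
        if ("hb", tc) not in atlas:
            continue
        for side in ("anterior", "posterior"):
            try:
                pos = feat.find_boundary(atlas[("hb", tc)], side)
            except DegenerateInputError:
                continue
            rows.append({"gene": "hb", "time_class": tc, "side": side, "position": pos})
    boundaries = pd.DataFrame(rows)
    return stripe_table, shifts, boundaries


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Execute the full chain on a simulated cohort; persist all outputs."""
    stage = "simulate"
    try:
        cohort, ledger = make_cohort(config.cohort)
        stage = "profile"
        prepared = prepare_profiles(cohort, config)
        stage = "stage"
        if config.use_true_classes:
            assignments = dict(zip(ledger["embryo_id"], ledger["time_class"]))
        else:
            assignments = stage_profiles(prepared, config)
        stage = "register/integrate"
        maps, atlas_raw, atlas, spacing = build_atlas(prepared, assignments, config)
        stage = "features"
        class_order = [tc for tc in config.cohort.classes if tc in C14A_CLASSES]
        # feature positions are read off the unsmoothed binned atlas: the
        # quadratic-spline refit provides the regularization, and the wide
        # display-smoothing kernel would otherwise inflate stripe widths
        stripe_table, shifts, boundaries = extract_features(
            atlas_raw, spacing, class_order=class_order
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    n_clipped = sum(p.meta.get("n_clipped", 0) for p in prepared)
    report = {
        "n_embryos": len(cohort),
        "n_nuclei_strip": int(sum(p.n_nuclei for p in prepared)),
        "n_nuclei_clipped": int(n_clipped),
        "n_bins_interpolated": int(
            sum(int(bp.table["interpolated"].sum()) for bp in atlas_raw.values())
        ),
        "spacing_el": spacing,
        "classes": sorted(set(assignments.values())),
    }
    result = PipelineResult(
        profiles=prepared, ledger=ledger, assignments=assignments, maps=maps,
        atlas_raw=atlas_raw, atlas=atlas, stripe_table=stripe_table,
        shifts=shifts, boundaries=boundaries, spacing_el=spacing, report=report,
    )
    if out_dir is not None:
        persist_result(result, config, Path(out_dir))
    return result


def persist_result(result: PipelineResult, config: PipelineConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    io.write_nucleus_table(out_dir / "profiles.tsv", result.profiles)
    result.ledger.to_csv(out_dir / "ledger.tsv", sep="\t", index=False)
    io.write_affine_maps(out_dir / "affine_maps.tsv", result.maps)
    io.write_atlas(out_dir / "atlas.tsv", list(result.atlas.values()))
    io.write_atlas(out_dir / "atlas_raw.tsv", list(result.atlas_raw.values()))
    result.stripe_table.to_csv(out_dir / "stripe_table.tsv", sep="\t", index=False)
    result.shifts.to_csv(out_dir / "stripe_shifts.tsv", sep="\t", index=False)
    result.boundaries.to_csv(out_dir / "hb_boundaries.tsv", sep="\t", index=False)
    pd.Series(result.assignments, name="time_class").rename_axis("embryo_id").to_csv(
        out_dir / "assignments.tsv", sep="\t"
    )
    io.write_config_echo(out_dir / "config.yaml", config.to_dict())
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)
    try:
        plot_stripe_trajectories(result.stripe_table, out_dir / "stripe_trajectories.png")
    except Exception:       # plotting must never fail the pipeline
        log.exception("trajectory plot failed")


def plot_stripe_trajectories(stripe_table: pd.DataFrame, path) -> None:
    """Time-space plot of Eve stripe peak positions (time flowing downward)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labeled = stripe_table[stripe_table["stripe"] > 0]
    if labeled.empty:
        return
    class_order = list(dict.fromkeys(stripe_table["time_class"]))
    rank = {tc: i for i, tc in enumerate(class_order)}
    fig, ax = plt.subplots(figsize=(6, 4))
    for lab, grp in labeled.groupby("stripe"):
        grp = grp.sort_values("time_class", key=lambda s: s.map(rank))
        ax.plot(grp["position"], grp["time_class"].map(rank), "o-", label=f"S{lab}")
    ax.invert_yaxis()
    ax.set_yticks(range(len(class_order)), class_order)
    ax.set_xlabel("A-P position (% EL)")
    ax.set_ylabel("time class")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def truth_features_table(config: PipelineConfig) -> pd.DataFrame:
    """Analytic ground-truth feature positions for the configured cohort."""
    return cohort_truth_features(config.cohort)
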
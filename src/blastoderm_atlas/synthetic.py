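"""Generative models of blastoderm segmentation-gene expression.

Every downstream stage of the pipeline is tested against cohorts produced
here, because they come with exact ground truth: per-embryo affine
positional jitter, per-class stripe/domain feature positions, and the
noise/background model.

The expression pattern of a gene at a given time class is a sum of
components along the A-P axis:

* pair-rule stripes are Gaussian bumps ``A * exp(-(x - c)^2 / (2 s^2))``;
* broad (gap-gene-like) domains are products of two logistic sigmoids with
  half-maximum points at the domain edges, optionally attenuated towards
  the anterior by a plateau factor.

These functional forms make the ground-truth features analytic: the peak
of an isolated stripe is its center; the half-maximum point of an isolated
domain edge is its edge parameter.

Two species presets are provided.  The ``clogmia`` preset emulates the
moth midge *Clogmia albipunctata*: at most six Eve stripes resolve before
gastrulation, budding off an initially broad domain one by one (stripe 1
at T2, stripe 2 at T3, stripe 3 and 6 at T5, stripes 4/5 clearing at T7),
with strong anterior shifts of stripe peaks over C14A, and an anterior Hb
domain reaching 25-52% EL at T8 whose posterior boundary drifts 2.15% EL
anteriorly between T3 and T8.  The ``drosophila`` preset emulates
*Drosophila melanogaster*: all seven Eve stripes visible by T4, smaller
anterior shifts that increase posteriorly, and a stationary Hb boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import (
    C14A_CLASSES,
    TIME_CLASSES,
    ConfigurationError,
    EmbryoProfile,
    cycle_of_class,
    time_class_index,
)

# --------------------------------------------------------------------------
# pattern component types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StripeSpec:
    """One pair-rule stripe: a Gaussian bump on the A-P axis."""

    label: int
    center: float          # % EL
    width_sigma: float     # % EL, Gaussian s.d.
    amplitude: float       # a.u.
    present: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.center <= 100.0:
            raise ConfigurationError(f"stripe center {self.center} outside [0, 100] %EL")
        if self.width_sigma <= 0:
            raise ConfigurationError("stripe width_sigma must be > 0")
        if self.amplitude < 0:
            raise ConfigurationError("stripe amplitude must be >= 0")


@dataclass(frozen=True)
class DomainSpec:
    """A broad expression domain bounded by two logistic edges.

    ``anterior_plateau_factor`` < 1 lowers expression towards the anterior
    part of the domain (an interior ramp; the edges themselves keep their
    analytic half-maximum points to good approximation).
    """

    anterior_edge: float        # % EL, half-maximum of the anterior edge
    posterior_edge: float       # % EL, half-maximum of the posterior edge
    edge_steepness: float       # % EL, logistic scale
    amplitude: float            # a.u.
    anterior_plateau_factor: float = 1.0

    def __post_init__(self) -> None:
        if not self.anterior_edge < self.posterior_edge:
            raise ConfigurationError("domain requires anterior_edge < posterior_edge")
        if self.edge_steepness <= 0:
            raise ConfigurationError("domain edge_steepness must be > 0")
        if self.amplitude < 0:
            raise ConfigurationError("domain amplitude must be >= 0")
        if not 0.0 <= self.anterior_plateau_factor <= 1.0:
            raise ConfigurationError("anterior_plateau_factor must be in [0, 1]")


@dataclass
class PatternModel:
    """Expression pattern of one gene at one time class, with ground truth.

    ``truth`` is a table of analytic feature positions with columns
    ``feature`` (e.g. ``peak_s1``, ``edge_posterior``), ``kind``
    (``stripe_peak`` / ``edge_anterior`` / ``edge_posterior``),
    ``label`` (stripe label or NA) and ``position`` (% EL).
    """

    gene: str
    time_class: str
    stripes: list[StripeSpec]
    domains: list[DomainSpec]
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.truth is None or len(self.truth) == 0:
            self.truth = _truth_table(self.stripes, self.domains)


def _truth_table(stripes: Sequence[StripeSpec], domains: Sequence[DomainSpec]) -> pd.DataFrame:
    rows = []
    for s in stripes:
        if s.present:
            rows.append(
                {"feature": f"peak_s{s.label}", "kind": "stripe_peak",
                 "label": s.label, "position": s.center,
                 "amplitude": s.amplitude, "width_sigma": s.width_sigma}
            )
    for d in domains:
        rows.append({"feature": "edge_anterior", "kind": "edge_anterior",
                     "label": pd.NA, "position": d.anterior_edge,
                     "amplitude": d.amplitude, "width_sigma": d.edge_steepness})
        rows.append({"feature": "edge_posterior", "kind": "edge_posterior",
                     "label": pd.NA, "position": d.posterior_edge,
                     "amplitude": d.amplitude, "width_sigma": d.edge_steepness})
    return pd.DataFrame(rows, columns=["feature", "kind", "label", "position",
                                       "amplitude", "width_sigma"])


def evaluate_pattern(model: PatternModel, x) -> np.ndarray:
    """Noise-free expression level of ``model`` at A-P position(s) ``x`` (% EL)."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x, dtype=float)
    for s in model.stripes:
        if s.present:
            out += s.amplitude * np.exp(-((x - s.center) ** 2) / (2.0 * s.width_sigma**2))
    for d in model.domains:
        body = expit((x - d.anterior_edge) / d.edge_steepness)
        body *= expit((d.posterior_edge - x) / d.edge_steepness)
        if d.anterior_plateau_factor < 1.0:
            span = d.posterior_edge - d.anterior_edge
            ramp_mid = d.anterior_edge + 0.35 * span
            ramp_w = 0.15 * span
            f = d.anterior_plateau_factor
            body *= f + (1.0 - f) * expit((x - ramp_mid) / ramp_w)
        out += d.amplitude * body
    return out


# --------------------------------------------------------------------------
# species presets
# --------------------------------------------------------------------------

SPECIES_PRESETS = ("clogmia", "drosophila")

# Clogmia Eve: T8 peak positions, appearance classes and total anterior
# shifts (% EL, appearance -> T8) for stripes 1-6.  The mean total shift is
# ~5.3% EL at ~1% EL internuclear spacing; stripes 1 and 2 shift the most.
_CLOGMIA_EVE = {
    "centers_t8": {1: 32.0, 2: 42.0, 3: 52.0, 4: 62.0, 5: 72.0, 6: 82.0},
    "appearance": {1: 2, 2: 3, 3: 5, 4: 6, 5: 6, 6: 5},
    "shifts": {1: 5.72, 2: 6.99, 3: 6.0, 4: 5.5, 5: 5.0, 6: 2.7},
    # amplitude at appearance -> T8 (stripes brighten as they mature)
    "amp": {1: (70.0, 100.0), 2: (70.0, 100.0), 3: (70.0, 100.0),
            4: (70.0, 100.0), 5: (70.0, 100.0), 6: (55.0, 100.0)},
    # Gaussian s.d. at appearance -> T8 (stripes sharpen)
    "sigma": {1: (2.6, 2.0), 2: (2.6, 2.0), 3: (2.6, 2.0),
              4: (2.6, 2.0), 5: (2.6, 2.0), 6: (2.6, 2.0)},
}

# Drosophila Eve: all 7 stripes by T4; posterior stripes shift more.
_DROSOPHILA_EVE = {
    "centers_t8": {1: 35.0, 2: 41.0, 3: 47.0, 4: 53.0, 5: 59.0, 6: 65.0, 7: 71.0},
    "appearance": {1: 3, 2: 3, 3: 3, 4: 4, 5: 4, 6: 4, 7: 4},
    "shifts": {1: 1.4, 2: 1.7, 3: 2.0, 4: 2.5, 5: 2.9, 6: 3.3, 7: 4.1},
    "amp": {k: (70.0, 100.0) for k in range(1, 8)},
    # Drosophila stripes are narrow relative to their ~6% EL period
    "sigma": {k: (1.8, 1.5) for k in range(1, 8)},
}

# Clogmia Hb anterior domain: per-class (anterior edge, posterior edge,
# amplitude).  Posterior boundary drifts 2.15% EL between T3 and T8; the
# domain retracts from the anterior pole over T5-T8; expression peaks at T3.
_CLOGMIA_HB = {
    "C13": (12.0, 78.0, 60.0),
    "T1": (12.0, 60.0, 80.0),
    "T2": (12.0, 57.0, 90.0),
    "T3": (12.0, 54.15, 100.0),
    "T4": (12.0, 53.72, 95.0),
    "T5": (18.0, 53.29, 90.0),
    "T6": (21.0, 52.86, 85.0),
    "T7": (23.5, 52.43, 80.0),
    "T8": (25.0, 52.0, 75.0),
}

# Drosophila Hb anterior domain: stationary boundaries, maximum level at T4.
_DROSOPHILA_HB_AMP = {"C13": 60.0, "T1": 75.0, "T2": 85.0, "T3": 95.0,
                      "T4": 100.0, "T5": 95.0, "T6": 90.0, "T7": 85.0, "T8": 80.0}
_DROSOPHILA_HB_EDGES = (18.0, 47.0)


def _lerp(pair: tuple[float, float], frac: float) -> float:
    a, b = pair
    return a + (b - a) * frac


def _eve_stripes(params: Mapping, idx: int) -> list[StripeSpec]:
    stripes = []
    for label, app in params["appearance"].items():
        if idx < app:
            continue
        frac = 1.0 if idx == 8 and app == 8 else (idx - app) / (8 - app) if app < 8 else 1.0
        center = params["centers_t8"][label] + params["shifts"][label] * (8 - idx) / (8 - app)
        stripes.append(
            StripeSpec(
                label=label,
                center=center,
                width_sigma=_lerp(params["sigma"][label], frac),
                amplitude=_lerp(params["amp"][label], frac),
            )
        )
    return sorted(stripes, key=lambda s: s.center)


def _clogmia_eve(time_class: str) -> tuple[list[StripeSpec], list[DomainSpec]]:
    if time_class in ("C10", "C11", "C12"):
        return [], []
    if time_class == "C13":
        # broad initial expression from ~40% EL to the posterior tip
        return [], [DomainSpec(40.0, 96.0, 2.5, 50.0)]
    idx = time_class_index(time_class)
    params = _CLOGMIA_EVE
    stripes = _eve_stripes(params, idx)
    unresolved = [lab for lab, app in params["appearance"].items() if idx < app]
    domains: list[DomainSpec] = []
    if unresolved:
        # residual broad domain covering the not-yet-resolved stripe region;
        # it weakens as stripes bud off and inter-stripe minima deepen
        first = min(unresolved)
        anterior = params["centers_t8"][first] + params["shifts"][first] - 2.0
        if 6 in unresolved:
            posterior = 95.0    # domain still reaches the posterior pole
        else:
            last = max(unresolved)
            posterior = params["centers_t8"][last] + params["shifts"][last] + 2.0
        domains.append(DomainSpec(anterior, posterior, 1.5, 65.0 - 5.0 * idx))
    return stripes, domains


def _drosophila_eve(time_class: str) -> tuple[list[StripeSpec], list[DomainSpec]]:
    if time_class in ("C10", "C11", "C12"):
        return [], []
    if time_class == "C13":
        return [], [DomainSpec(30.0, 75.0, 2.5, 50.0)]
    idx = time_class_index(time_class)
    if idx == 1:
        return [], [DomainSpec(30.0, 73.0, 2.0, 55.0)]
    if idx == 2:
        # the broad pattern splits into anterior and posterior sub-domains
        return [], [DomainSpec(33.5, 49.0, 1.5, 60.0), DomainSpec(52.5, 68.0, 1.5, 60.0)]
    stripes = _eve_stripes(_DROSOPHILA_EVE, idx)
    domains = []
    if idx == 3:
        domains.append(DomainSpec(53.0, 70.0, 1.5, 60.0))  # stripes 4-6 unresolved
    return stripes, domains


def _hb_model(species: str, time_class: str) -> tuple[list[StripeSpec], list[DomainSpec]]:
    if time_class in ("C10", "C11"):
        return [], []
    if time_class == "C12":
        # shallow early A-P gradient
        return [], [DomainSpec(0.5, 60.0, 8.0, 20.0)]
    if species == "clogmia":
        a, p, amp = _CLOGMIA_HB[time_class]
        return [], [DomainSpec(a, p, 1.5, amp, anterior_plateau_factor=0.9)]
    a, p = _DROSOPHILA_HB_EDGES
    return [], [DomainSpec(a, p, 1.5, _DROSOPHILA_HB_AMP[time_class])]


def make_pattern_model(gene: str, time_class: str, species_preset: str = "clogmia") -> PatternModel:
    """Resolved stripe/domain pattern of ``gene`` at ``time_class``.

    Follows the preset species' stripe-formation sequence; per-stripe peak
    positions drift anteriorly, linearly in time-class index, by the
    preset's configured total shift between appearance and T8.
    """
    if species_preset not in SPECIES_PRESETS:
        raise ConfigurationError(f"unknown species preset {species_preset!r}")
    if gene not in ("eve", "hb"):
        raise ConfigurationError(f"unknown gene {gene!r}")
    if time_class not in TIME_CLASSES:
        raise ConfigurationError(f"unknown time class {time_class!r}")
    if gene == "eve":
        stripes, domains = (_clogmia_eve if species_preset == "clogmia" else _drosophila_eve)(time_class)
    else:
        stripes, domains = _hb_model(species_preset, time_class)
    return PatternModel(gene=gene, time_class=time_class, stripes=stripes, domains=domains)


def stripe_count(species_preset: str, time_class: str) -> int:
    """Number of resolved Eve stripes at ``time_class`` for the preset."""
    return len(make_pattern_model("eve", time_class, species_preset).stripes)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate a C14A dataset: ~3000 nuclei per embryo arranged on a
    jittered grid (about 100 nuclear columns along the A-P axis, i.e. ~1% EL
    internuclear spacing), per-embryo affine positional jitter with scale
    s.d. 0.02 and offset s.d. 2% EL, a paraboloid background field, and
    additive Gaussian intensity noise of 5 a.u. (roughly 5% of a mature
    stripe's amplitude).
    """

    species_preset: str = "clogmia"
    classes: tuple[str, ...] = C14A_CLASSES
    n_embryos_per_class: int = 20
    n_nuclei: int = 3000
    jitter_scale: float = 0.02        # s.d. of per-embryo affine scale
    jitter_offset: float = 2.0        # s.d. of per-embryo affine offset, % EL
    position_jitter: float = 0.1      # nucleus placement jitter, fraction of grid pitch
    background: tuple[float, float, float] = (20.0, 10.0, 5.0)  # paraboloid coefficients
    noise_sigma: float = 5.0          # a.u., per-nucleus additive noise
    height_to_length: float = 0.4     # embryo aspect, converts % height to % EL units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.species_preset not in SPECIES_PRESETS:
            raise ConfigurationError(f"unknown species preset {self.species_preset!r}")
        for tc in self.classes:
            if tc not in TIME_CLASSES:
                raise ConfigurationError(f"unknown time class {tc!r}")
        if self.n_nuclei <= 0 or self.n_embryos_per_class <= 0:
            raise ConfigurationError("counts must be positive")
        if min(self.jitter_scale, self.jitter_offset, self.position_jitter,
               self.noise_sigma) < 0:
            raise ConfigurationError("jitter and noise magnitudes must be >= 0")


def _grid_shape(n_nuclei: int) -> tuple[int, int]:
    """Grid columns x rows for ``n_nuclei`` at a fixed 10:3 layout ratio."""
    nx = max(2, round(math.sqrt(n_nuclei * 10.0 / 3.0)))
    ny = max(1, round(n_nuclei / nx))
    return nx, ny


def class_nucleus_count(config: CohortConfig, time_class: str) -> int:
    """Nuclei per embryo at ``time_class``; density halves per earlier cycle."""
    cycle = cycle_of_class(time_class)
    halvings = {"C14A": 0, "C13": 1, "C12": 2, "C11": 3, "C10": 4}[cycle]
    return max(8, config.n_nuclei // (2**halvings))


def background_field(config: CohortConfig, x, y) -> np.ndarray:
    """Paraboloid non-specific staining field b(x, y)."""
    c0, cx, cy = config.background
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return c0 + cx * ((x - 50.0) / 50.0) ** 2 + cy * ((y - 50.0) / 50.0) ** 2


def _embryo_rng(config: CohortConfig, class_pos: int, embryo_index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, class_pos, embryo_index])


def sample_embryo(
    models: Mapping[str, PatternModel],
    config: CohortConfig,
    embryo_index: int,
    *,
    time_class: str | None = None,
    embryo_id: str | None = None,
) -> tuple[EmbryoProfile, dict]:
    """Draw one embryo from the given per-gene pattern models.

    Nuclei sit on a jittered rectangular grid covering the whole embryo.
    Each nucleus at position ``x`` carries, per channel, the pattern
    evaluated at ``a*x + b`` (the embryo's affine positional jitter) plus
    the paraboloid background and Gaussian noise.  Returns the profile and
    a ground-truth record with the drawn ``(a, b)``.
    """
    tcs = {m.time_class for m in models.values()}
    if time_class is None:
        time_class = tcs.pop() if len(tcs) == 1 else None
    if time_class is None:
        raise ConfigurationError("models disagree on time class; pass time_class explicitly")
    class_pos = TIME_CLASSES.index(time_class)
    rng = _embryo_rng(config, class_pos, embryo_index)

    a = float(np.clip(1.0 + config.jitter_scale * rng.standard_normal(), 0.5, 1.5))
    b = float(config.jitter_offset * rng.standard_normal())

    n = class_nucleus_count(config, time_class)
    nx, ny = _grid_shape(n)
    dx, dy = 100.0 / nx, 100.0 / ny
    gx, gy = np.meshgrid((np.arange(nx) + 0.5) * dx, (np.arange(ny) + 0.5) * dy)
    x = gx.ravel() + config.position_jitter * dx * rng.standard_normal(gx.size)
    y = gy.ravel() + config.position_jitter * dy * rng.standard_normal(gy.size)
    x = np.clip(x, 0.0, 100.0)
    y = np.clip(y, 0.0, 100.0)

    if embryo_id is None:
        embryo_id = f"{config.species_preset}_{time_class}_e{embryo_index:03d}"
    data = pd.DataFrame({"nucleus_id": np.arange(x.size), "x": x, "y": y})
    bg = background_field(config, x, y)
    for gene in sorted(models):
        signal = evaluate_pattern(models[gene], a * x + b)
        noise = config.noise_sigma * rng.standard_normal(x.size)
        data[f"I_{gene}"] = np.clip(signal + bg + noise, 0.0, None)

    profile = EmbryoProfile(
        embryo_id=embryo_id,
        data=data,
        cycle=cycle_of_class(time_class),
        time_class=time_class,
        meta={"grid": (nx, ny), "true_affine": (a, b)},
    )
    record = {
        "embryo_id": embryo_id,
        "species": config.species_preset,
        "time_class": time_class,
        "cycle": cycle_of_class(time_class),
        "a_true": a,
        "b_true": b,
        "n_nuclei": int(x.size),
        "grid_nx": nx,
        "grid_ny": ny,
    }
    return profile, record


def make_cohort(config: CohortConfig) -> tuple[list[EmbryoProfile], pd.DataFrame]:
    """Full cohort over ``config.classes`` plus its ground-truth ledger.

    The ledger has one row per embryo (true time class, true affine
    perturbation, nucleus count); analytic feature positions per class are
    available from :func:`cohort_truth_features`.
    """
    profiles: list[EmbryoProfile] = []
    records: list[dict] = []
    for tc in config.classes:
        models = {g: make_pattern_model(g, tc, config.species_preset) for g in ("eve", "hb")}
        for i in range(config.n_embryos_per_class):
            profile, rec = sample_embryo(models, config, i, time_class=tc)
            profiles.append(profile)
            records.append(rec)
    return profiles, pd.DataFrame(records)


def cohort_truth_features(config: CohortConfig) -> pd.DataFrame:
    """Analytic feature positions (stripe peaks, domain edges) per gene/class."""
    frames = []
    for tc in config.classes:
        for gene in ("eve", "hb"):
            t = make_pattern_model(gene, tc, config.species_preset).truth.copy()
            t.insert(0, "gene", gene)
            t.insert(1, "time_class", tc)
            frames.append(t)
    return pd.concat(frames, ignore_index=True)


def grid_spacing_el(config: CohortConfig, time_class: str = "T8") -> float:
    """Nominal A-P internuclear spacing of the generating grid (% EL)."""
    nx, _ = _grid_shape(class_nucleus_count(config, time_class))
    return 100.0 / nx
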
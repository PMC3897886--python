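"""Spline/GCP-based affine registration of expression profiles.

Per embryo, the Eve profile is approximated by a least-squares quadratic
spline; the spline's interior extrema (peaks and troughs, found exactly as
roots of its piecewise-linear derivative) are extracted as ground control
points (GCPs).  A per-embryo 1D affine map is then fitted so that shared
GCPs land on the per-time-class mean positions, removing embryo-to-embryo
positional variation.  The same map is applied to every channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import LSQUnivariateSpline
from scipy.signal import find_peaks, peak_widths

from .core import ConfigurationError, DegenerateInputError, EmbryoProfile

#: interior knots over the observed x-range (~1.7% EL spacing at C14A);
#: coarser grids leave percent-level lack-of-fit on mature stripes
DEFAULT_N_KNOTS = 60
DEFAULT_PROMINENCE_FRACTION = 0.10   # of the fitted profile's range


@dataclass
class SplineModel:
    """Least-squares quadratic spline over the observed A-P range."""

    spline: LSQUnivariateSpline
    domain: tuple[float, float]
    n_coefficients: int

    def __call__(self, x) -> np.ndarray:
        return self.spline(np.clip(np.asarray(x, dtype=float), *self.domain))

    def derivative_roots(self) -> tuple[np.ndarray, np.ndarray]:
        """Exact interior extrema: (positions, derivative-slope signs).

        The derivative of a quadratic spline is piecewise linear between
        knots, so its roots are found exactly by bracketing sign changes
        on the knot grid.
        """
        deriv = self.spline.derivative()
        knots = np.unique(self.spline.get_knots())
        grid = np.union1d(knots, np.linspace(*self.domain, 4 * len(knots)))
        vals = deriv(grid)
        roots, curvatures = [], []
        for i in range(len(grid) - 1):
            v0, v1 = vals[i], vals[i + 1]
            if v0 == 0.0 and v1 != 0.0:
                roots.append(grid[i]); curvatures.append(np.sign(v1))
            elif v0 * v1 < 0:
                t = v0 / (v0 - v1)
                roots.append(grid[i] + t * (grid[i + 1] - grid[i]))
                curvatures.append(np.sign(v1 - v0))
        return np.asarray(roots), np.asarray(curvatures)


@dataclass
class GCPSet:
    """Ordered expression landmarks: (feature_id, position % EL)."""

    features: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        pos = [p for _, p in self.features]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ConfigurationError("GCP positions must be strictly increasing")
        ids = [f for f, _ in self.features]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("GCP feature ids must be unique")

    def as_dict(self) -> dict[str, float]:
        return dict(self.features)

    def __len__(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class AffineMap1D:
    """Orientation-preserving A-P coordinate map x -> a*x + b."""

    a: float = 1.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ConfigurationError("affine scale must be > 0")

    def __call__(self, x):
        return self.a * np.asarray(x, dtype=float) + self.b

    def inverse(self) -> "AffineMap1D":
        return AffineMap1D(1.0 / self.a, -self.b / self.a)

    def compose(self, other: "AffineMap1D") -> "AffineMap1D":
        """self after other: x -> self(other(x))."""
        return AffineMap1D(self.a * other.a, self.a * other.b + self.b)


def fit_quadratic_spline(
    profile: EmbryoProfile | tuple[np.ndarray, np.ndarray],
    channel: str | None = None,
    n_knots: int = DEFAULT_N_KNOTS,
) -> SplineModel:
    """Least-squares quadratic spline on uniform interior knots.

    Accepts an :class:`EmbryoProfile` plus channel name, or a raw (x, y)
    pair.  Requires at least ``n_knots + 3`` points (the coefficient
    count of the spline).
    """
    if isinstance(profile, EmbryoProfile):
        if channel is None:
            raise ConfigurationError("channel required when fitting a profile")
        x = profile.data["x"].to_numpy(dtype=float)
        y = profile.intensity(channel).to_numpy(dtype=float)
    else:
        x, y = np.asarray(profile[0], dtype=float), np.asarray(profile[1], dtype=float)
    if len(x) < n_knots + 3:
        raise DegenerateInputError(
            f"need >= {n_knots + 3} nuclei for a quadratic spline with {n_knots} knots"
        )
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    xmin, xmax = float(x[0]), float(x[-1])
    for k in range(n_knots, -1, -1):
        interior = np.linspace(xmin, xmax, k + 2)[1:-1]
        try:
            spl = LSQUnivariateSpline(x, y, interior, k=2)
            return SplineModel(spline=spl, domain=(xmin, xmax), n_coefficients=k + 3)
        except ValueError:
            continue    # Schoenberg-Whitney violation: retry with fewer knots
    raise DegenerateInputError("could not satisfy spline interpolation conditions")


def extract_gcps(model: SplineModel, min_prominence: float | None = None) -> GCPSet:
    """Interior spline extrema with sufficient prominence, labeled A->P.

    Peaks are labeled ``peak_1..`` and troughs ``trough_1..`` in
    anterior-to-posterior order.  ``min_prominence`` defaults to 5% of the
    fitted profile's range.  Returns an empty set (with a warning) when no
    extremum passes.
    """
    dense_x = np.linspace(*model.domain, 2000)
    dense_y = model(dense_x)
    rng = float(np.ptp(dense_y))
    if min_prominence is None:
        min_prominence = DEFAULT_PROMINENCE_FRACTION * rng
    roots, curv = model.derivative_roots()
    if len(roots) == 0 or rng == 0.0:
        warnings.warn("no extremum found on spline; empty GCP set", stacklevel=2)
        return GCPSet([])

    kept: list[tuple[float, int]] = []    # (position, +1 peak / -1 trough)
    for sign, name in ((1, "peak"), (-1, "trough")):
        idx, props = find_peaks(sign * dense_y, prominence=min_prominence)
        for i in idx:
            cand = roots[curv == -sign]   # peaks: derivative slope negative
            if len(cand) == 0:
                continue
            j = np.argmin(np.abs(cand - dense_x[i]))
            if abs(cand[j] - dense_x[i]) <= 2.0 * (dense_x[1] - dense_x[0]) * 10:
                kept.append((float(cand[j]), sign))
    if not kept:
        warnings.warn("no extremum passed the prominence filter; empty GCP set", stacklevel=2)
        return GCPSet([])
    kept = sorted(set(kept))
    features = []
    counters = {1: 0, -1: 0}
    for pos, sign in kept:
        counters[sign] += 1
        name = "peak" if sign == 1 else "trough"
        features.append((f"{name}_{counters[sign]}", pos))
    return GCPSet(features)


def refine_gcps(
    gcps: GCPSet,
    x: np.ndarray,
    y: np.ndarray,
    *,
    half_window: float = 2.5,
    max_move: float = 1.0,
) -> GCPSet:
    """Refine peak GCP positions with a local parabola fit to the nuclei.

    The spline extremum inherits a small position bias from how the
    pattern aligns with the knot grid; re-fitting a quadratic to the raw
    per-nucleus intensities within ``half_window`` % EL of each peak
    removes it.  Refinements that move a peak more than ``max_move`` % EL
    (a failed local fit) are discarded; troughs are left untouched.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    refined = []
    for fid, pos in gcps.features:
        if fid.startswith("peak"):
            sel = np.abs(x - pos) <= half_window
            if sel.sum() >= 6:
                a2, a1, _ = np.polyfit(x[sel], y[sel], 2)
                if a2 < 0:
                    vertex = -a1 / (2.0 * a2)
                    if abs(vertex - pos) <= max_move:
                        pos = float(vertex)
        refined.append((fid, pos))
    refined.sort(key=lambda t: t[1])
    # a refinement may not reorder features; fall back if it would
    if all(b[1] > a[1] for a, b in zip(refined, refined[1:])):
        return GCPSet(refined)
    return gcps


def _select_landmarks(
    gcps: GCPSet,
    model: SplineModel,
    *,
    max_width: float = 7.5,
    min_prominence_fraction: float = 0.15,
) -> tuple[GCPSet, int]:
    """Keep only registration-grade landmarks; count the stripe peaks.

    Peaks wider than ``max_width`` % EL at half local prominence are flat
    residual-domain tops whose positions wander by several % EL, and
    extrema below ``min_prominence_fraction`` of the profile range are
    noise wiggles; either kind pollutes the affine fit and, worse, makes
    the landmark structure differ from embryo to embryo so that
    order-based pairing breaks down.  Returns the filtered set and the
    number of retained (stripe-like) peaks.
    """
    grid = np.linspace(*model.domain, 2000)
    dense = model(grid)
    step = grid[1] - grid[0]
    rng = float(np.ptp(dense))
    wlen = max(3, int(12.0 / step) | 1)
    floor = 0.02 * max(rng, 1e-9)
    strict = min_prominence_fraction * rng

    info: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for kind, sign in (("peak", 1.0), ("trough", -1.0)):
        idx, props = find_peaks(sign * dense, prominence=floor, wlen=wlen)
        if len(idx):
            pdata = (props["prominences"], props["left_bases"], props["right_bases"])
            widths = peak_widths(sign * dense, idx, rel_height=0.5,
                                 prominence_data=pdata)[0] * step
            info[kind] = (grid[idx], props["prominences"], widths)
        else:
            info[kind] = (np.empty(0), np.empty(0), np.empty(0))

    kept = []
    n_peaks = 0
    for fid, pos in gcps.features:
        kind = fid.split("_")[0]
        positions, proms, widths = info[kind]
        if len(positions) == 0:
            continue
        j = int(np.argmin(np.abs(positions - pos)))
        if abs(positions[j] - pos) >= 2.0:
            continue
        if proms[j] < strict:
            continue
        if kind == "peak" and widths[j] > max_width:
            continue
        if kind == "peak":
            n_peaks += 1
        kept.append((fid, pos))
    # renumber features to keep ids unique and ordered
    counters = {"peak": 0, "trough": 0}
    renamed = []
    for fid, pos in kept:
        kind = fid.split("_")[0]
        counters[kind] += 1
        renamed.append((f"{kind}_{counters[kind]}", pos))
    return GCPSet(renamed), n_peaks


def _regress_map(src: np.ndarray, dst: np.ndarray) -> AffineMap1D:
    """Closed-form least squares for dst ~ a*src + b, with outlier trimming.

    Two trimming passes drop landmarks whose residual exceeds 2.5 robust
    standard deviations (spurious low-amplitude extrema near the profile
    ends have noisy positions and would otherwise bias the map).
    """
    keep = np.ones(len(src), dtype=bool)
    fit = None
    for _ in range(3):
        if keep.sum() < 2 or np.ptp(src[keep]) == 0:
            break
        a, b = np.polyfit(src[keep], dst[keep], 1)
        if a <= 0:
            break
        fit = AffineMap1D(float(a), float(b))
        resid = dst - (a * src + b)
        scale = max(0.3, 1.4826 * float(np.median(np.abs(resid[keep] - np.median(resid[keep])))))
        new_keep = np.abs(resid) <= 2.5 * scale
        if new_keep.sum() < 2 or new_keep.all() == keep.all() and (new_keep == keep).all():
            break
        keep = new_keep
    return fit if fit is not None else AffineMap1D()


def _by_type(gcps: GCPSet) -> dict[str, np.ndarray]:
    out: dict[str, list[float]] = {"peak": [], "trough": []}
    for fid, pos in gcps.features:
        out[fid.split("_")[0]].append(pos)
    return {t: np.asarray(v) for t, v in out.items()}


def _match_to_reference(
    feats: dict[str, np.ndarray],
    ref: dict[str, np.ndarray],
    max_residual: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy nearest-position matching of an embryo's GCPs to reference slots.

    A coarse A-P shift scan first aligns the embryo's feature set with the
    reference (embryo offsets can approach the inter-stripe spacing, which
    would otherwise match landmarks one stripe off).  Matching is then per
    feature type (peaks to peaks, troughs to troughs), closest pairs
    first, each slot used once; pairs further apart than ``max_residual``
    % EL (after the coarse shift) are discarded.  Position-based matching
    is robust to the occasional spurious or missing extremum that would
    derail matching by sequential labels.
    """

    def n_aligned(delta: float, tol: float = 2.5) -> int:
        c = 0
        for t, ref_pos in ref.items():
            emb = feats.get(t, np.empty(0))
            for e in emb:
                if len(ref_pos) and np.min(np.abs(ref_pos - (e - delta))) <= tol:
                    c += 1
        return c

    scan = np.arange(-10.0, 10.001, 0.25)
    shift = float(max(scan, key=lambda d: (n_aligned(d), -abs(d))))

    src: list[float] = []
    dst: list[float] = []
    for t, ref_pos in ref.items():
        emb_pos = feats.get(t, np.empty(0))
        cand = sorted(
            (abs(e - shift - r), i, j)
            for i, e in enumerate(emb_pos)
            for j, r in enumerate(ref_pos)
            if abs(e - shift - r) <= max_residual
        )
        used_i: set[int] = set()
        used_j: set[int] = set()
        for _, i, j in cand:
            if i in used_i or j in used_j:
                continue
            used_i.add(i)
            used_j.add(j)
            src.append(float(emb_pos[i]))
            dst.append(float(ref_pos[j]))
    return np.asarray(src), np.asarray(dst)


def estimate_affine(
    gcp_sets: dict[str, GCPSet],
    *,
    min_shared: int = 2,
    max_residual: float = 5.0,
    two_pass: bool = True,
    gauge_fix: bool = True,
    max_scale_dev: float = 0.12,
    max_offset: float = 12.0,
) -> dict[str, AffineMap1D]:
    """Per-embryo affine maps aligning GCPs to their cohort mean positions.

    The reference structure is taken from the embryos with the modal
    (peak count, trough count) signature: slot-wise mean positions per
    feature type.  Embryos sharing the modal structure are paired to the
    reference slot-by-slot in A-P order (immune to one-stripe-period
    slips on periodic patterns); the rest are matched to reference slots
    by nearest position (within ``max_residual`` % EL, after a coarse
    shift scan).  The map is the closed-form least-squares line through
    the matched pairs; the
    reference is recomputed once from transformed positions (two-pass).
    Embryos with fewer than ``min_shared`` matches, or whose fitted map is
    implausible (scale outside 1 +/- ``max_scale_dev`` or |offset| beyond
    ``max_offset`` % EL), receive the identity map with a warning.  The
    cohort-mean map is finally constrained to the identity (gauge fixing)
    so the ensemble cannot drift as a whole.
    """
    tables = {eid: _by_type(g) for eid, g in gcp_sets.items()}
    ref_signature: tuple[int, int] | None = None

    def reference(current: dict[str, dict[str, np.ndarray]]) -> dict[str, np.ndarray]:
        nonlocal ref_signature
        signature = {eid: (len(f["peak"]), len(f["trough"])) for eid, f in current.items()}
        counts: dict[tuple[int, int], int] = {}
        for sig in signature.values():
            counts[sig] = counts.get(sig, 0) + 1
        modal = max(counts, key=lambda s: (counts[s], s))
        ref_signature = modal
        members = [eid for eid, s in signature.items() if s == modal]
        return {
            t: np.mean([np.sort(current[eid][t]) for eid in members], axis=0)
            if modal[("peak", "trough").index(t)] > 0 else np.empty(0)
            for t in ("peak", "trough")
        }

    def solve(ref: dict[str, np.ndarray]) -> dict[str, AffineMap1D]:
        maps = {}
        for eid, feats in tables.items():
            if ref_signature is not None and (
                len(feats["peak"]), len(feats["trough"])
            ) == ref_signature:
                # same landmark structure as the reference: pair by order,
                # which cannot slip by a stripe period however large the
                # embryo's offset is
                src = np.concatenate([np.sort(feats["peak"]), np.sort(feats["trough"])])
                dst = np.concatenate([ref["peak"], ref["trough"]])
            else:
                src, dst = _match_to_reference(feats, ref, max_residual)
            if len(src) < min_shared:
                warnings.warn(
                    f"embryo {eid}: fewer than {min_shared} shared GCPs; identity map",
                    stacklevel=3,
                )
                maps[eid] = AffineMap1D()
                continue
            m = _regress_map(src, dst)
            if abs(m.a - 1.0) > max_scale_dev or abs(m.b) > max_offset:
                warnings.warn(f"embryo {eid}: implausible affine map {m}; identity map",
                              stacklevel=3)
                m = AffineMap1D()
            maps[eid] = m
        return maps

    maps = solve(reference(tables))
    if two_pass:
        transformed = {
            eid: {t: maps[eid](p) for t, p in feats.items()} for eid, feats in tables.items()
        }
        maps = solve(reference(transformed))
    if gauge_fix and maps:
        a_bar = float(np.mean([m.a for m in maps.values()]))
        b_bar = float(np.mean([m.b for m in maps.values()]))
        correction = AffineMap1D(a_bar, b_bar).inverse()
        maps = {eid: correction.compose(m) for eid, m in maps.items()}
    return maps


def apply_affine(profile: EmbryoProfile, amap: AffineMap1D) -> EmbryoProfile:
    """Map all nuclei x -> a*x + b; nuclei leaving [0, 100] are clipped out."""
    data = profile.data.copy()
    data["x"] = amap(data["x"].to_numpy())
    inside = (data["x"] >= 0.0) & (data["x"] <= 100.0)
    n_clipped = int((~inside).sum())
    return profile.with_data(data[inside], affine=(amap.a, amap.b), n_clipped=n_clipped)


def register_cohort(
    profiles: list[EmbryoProfile],
    *,
    channel: str = "eve",
    n_knots: int = DEFAULT_N_KNOTS,
    min_prominence: float | None = None,
) -> tuple[list[EmbryoProfile], dict[str, AffineMap1D]]:
    """Register one time class: GCPs from ``channel``, maps applied to all.

    Eve has the richest landmark structure, so its GCPs drive the
    transform; other channels (Hb) are transformed passively with the
    identical map.
    """
    gcps = {}
    peak_counts = []
    for p in profiles:
        model = fit_quadratic_spline(p, channel, n_knots=n_knots)
        g = extract_gcps(model, min_prominence)
        # wide peaks (flat residual-domain tops) and weak extrema have
        # noisy positions and poison the affine fit; only stripe-like
        # prominent landmarks are kept
        g, n_narrow = _select_landmarks(g, model)
        gcps[p.embryo_id] = refine_gcps(
            g, p.data["x"].to_numpy(), p.intensity(channel).to_numpy()
        )
        peak_counts.append(n_narrow)
    if np.median(peak_counts) < 2:
        # too little landmark structure (early classes with at most one
        # resolved stripe): nothing reliable to anchor an affine fit, so
        # these cohorts are left unregistered
        maps = {p.embryo_id: AffineMap1D() for p in profiles}
    else:
        maps = estimate_affine(gcps)
    registered = [apply_affine(p, maps[p.embryo_id]) for p in profiles]
    return registered, maps
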
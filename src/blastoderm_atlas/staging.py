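"""Temporal staging of embryos: cleavage cycles and C14A time classes.

Cleavage cycles C10-C14A are assigned from nuclear density (density
doubles per synchronous division).  Within C14A, embryos are sorted into
time classes T1-T8; the visual stripe-count assignment is verified by a
clustering algorithm: all embryo pairs are fitted against each other with
quadratic splines, the upper-tail probability of the resulting chi-square
statistic defines a relative distance in [0, 1], and embryos are merged
agglomeratively, at each step recalculating distances to the merged pair
as the mean of the two (WPGMA-style).  Stripe-signature ratios
(stripe 1 vs stripe 6 intensity and width), merged into a single variable
by PCA, can refine the distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .core import ConfigurationError, DegenerateInputError, EmbryoProfile
from .features import profile_peaks
from .registration import fit_quadratic_spline

DEFAULT_STRIP_COUNT_C14A = 300.0   # calibration: nuclei per lateral strip at C14A
DEFAULT_SIGNATURE_WEIGHT = 0.5     # alpha in alpha*D + (1-alpha)*|dPCA|


# --------------------------------------------------------------------------
# cleavage cycles
# --------------------------------------------------------------------------


def assign_cleavage_cycle(
    profile: EmbryoProfile, *, strip_count_c14a: float = DEFAULT_STRIP_COUNT_C14A
) -> str:
    """Cycle from nuclear density: C14A minus observed density halvings.

    ``strip_count_c14a`` calibrates the expected number of strip nuclei at
    C14A; each earlier cycle halves it.  Result clamped to [C10, C14A].
    """
    n = profile.n_nuclei
    if n == 0:
        raise DegenerateInputError("no nuclei; cannot assign a cleavage cycle")
    halvings = int(np.clip(round(np.log2(strip_count_c14a / n)), 0, 4))
    return "C14A" if halvings == 0 else f"C{14 - halvings}"


# --------------------------------------------------------------------------
# pairwise chi-square distance
# --------------------------------------------------------------------------


@dataclass
class _EmbryoFit:
    """Cached per-embryo spline fit and local noise-variance estimate."""

    x: np.ndarray
    y: np.ndarray
    model: object               # SplineModel
    local_var: np.ndarray       # per-nucleus variance, x-sorted order
    model_var: float            # mean estimation variance of the spline


def _prepare(profile: EmbryoProfile, channel: str, n_knots: int,
             window: int = 31) -> _EmbryoFit:
    model = fit_quadratic_spline(profile, channel, n_knots=n_knots)
    x = profile.data["x"].to_numpy(dtype=float)
    y = profile.intensity(channel).to_numpy(dtype=float)
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    resid = y - model(x)
    local = (
        pd.Series(resid**2)
        .rolling(window, center=True, min_periods=5)
        .mean()
        .to_numpy()
    )
    local = np.where(np.isfinite(local), local, np.nanmean(local))
    k = model.n_coefficients
    model_var = float(np.mean(resid**2)) * k / max(len(x), 1)
    return _EmbryoFit(x=x, y=y, model=model, local_var=np.clip(local, 1e-12, None),
                      model_var=model_var)


def _directed_p(model_fit: _EmbryoFit, data_fit: _EmbryoFit) -> float:
    """Upper-tail chi-square probability of fitting data to the other's model.

    The data embryo is aligned to the model by a free affine x-transform
    and linear intensity rescaling (embryos differ by exactly such nuisance
    transformations); the residual chi-square uses the data embryo's local
    noise variance, augmented by the model spline's estimation variance and
    a finite-sample n/(n-k) correction, with nu = n - k degrees of freedom
    (k = spline coefficient count).
    """
    n = len(data_fit.x)
    k = model_fit.model.n_coefficients
    nu = n - k
    if nu <= 0:
        raise DegenerateInputError("data embryo has fewer nuclei than spline coefficients")
    # calibration: the raw residual expectation is sigma^2 + Var(spline),
    # while local_var + model_var underestimates it by (n-k)/n; a second
    # n/nu factor centres the null expectation of chi-square at nu, so the
    # upper-tail probability is approximately uniform for same-shape pairs
    var = (data_fit.local_var + model_fit.model_var) * (n / nu) ** 2
    w = 1.0 / var

    def objective(params: np.ndarray) -> float:
        a, b = params
        if a <= 0.2 or a >= 5.0:
            return 1e18
        m = model_fit.model(a * data_fit.x + b)
        # closed-form weighted linear intensity match y ~ s*m + o
        sw = w.sum()
        mw, yw = (w * m).sum() / sw, (w * data_fit.y).sum() / sw
        cov = (w * (m - mw) * (data_fit.y - yw)).sum()
        varm = (w * (m - mw) ** 2).sum()
        s = cov / varm if varm > 0 else 0.0
        o = yw - s * mw
        r = data_fit.y - (s * m + o)
        return float((w * r**2).sum())

    # the objective oscillates in b with the stripe period, so a local
    # search from b = 0 can fall into the wrong valley for embryos with
    # large offsets; a coarse scan picks the right basin first
    b_grid = np.arange(-8.0, 8.01, 0.5)
    b0 = float(b_grid[np.argmin([objective(np.array([1.0, b])) for b in b_grid])])
    res = minimize(objective, x0=np.array([1.0, b0]), method="Nelder-Mead",
                   options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 200})
    chisq = float(res.fun)
    if chisq < 1e-9:     # residuals numerically zero (e.g. identical embryos)
        return 1.0
    return float(chi2.sf(chisq, nu))


def pairwise_distance(
    e1: EmbryoProfile,
    e2: EmbryoProfile,
    channel: str = "eve",
    *,
    n_knots: int = 40,
) -> float:
    """Symmetric chi-square-probability distance between two embryos in [0, 1].

    distance = 1 - (p(1->2) + p(2->1)) / 2, where p is the upper-tail
    probability of the pairwise-fit chi-square (see :func:`_directed_p`).
    Identical noiseless embryos give chi-square 0 and distance 0.
    """
    f1 = _prepare(e1, channel, n_knots)
    f2 = _prepare(e2, channel, n_knots)
    return 1.0 - 0.5 * (_directed_p(f1, f2) + _directed_p(f2, f1))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise embryo distances in [0, 1], zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ConfigurationError("distance matrix shape mismatch")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise ConfigurationError("distance matrix must be symmetric with zero diagonal")
        if v.min() < -1e-12 or v.max() > 1.0 + 1e-12:
            raise ConfigurationError("distances must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def distance_matrix(
    profiles: list[EmbryoProfile], channel: str = "eve", *, n_knots: int = 40
) -> DistanceMatrix:
    """All-pairs chi-square distance matrix over a cohort."""
    fits = {p.embryo_id: _prepare(p, channel, n_knots) for p in profiles}
    ids = [p.embryo_id for p in profiles]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p_ij = _directed_p(fits[ids[i]], fits[ids[j]])
            p_ji = _directed_p(fits[ids[j]], fits[ids[i]])
            d[i, j] = d[j, i] = 1.0 - 0.5 * (p_ij + p_ji)
    return DistanceMatrix(ids=ids, values=np.clip(d, 0.0, 1.0))


# --------------------------------------------------------------------------
# stripe signatures
# --------------------------------------------------------------------------


def stripe_signatures(
    profiles: list[EmbryoProfile],
    channel: str = "eve",
    *,
    min_peaks: int = 4,
) -> pd.DataFrame:
    """Stripe-1/6 intensity and width ratios per embryo, merged by PCA.

    Requires stripes 1 and 6 to be detectable (at least ``min_peaks``
    stripe-like peaks; the most anterior peak is stripe 1, the most
    posterior stripe 6 in a pre-gastrulation C14A embryo).  Embryos where
    stripe 6 is missing get NaN signatures and are excluded from the
    signature refinement, not from clustering.  ``pca_score`` is the
    projection of the standardized ratio pair on the first principal
    component over the cohort; the result's ``attrs['pc1_explained']``
    records the explained variance fraction.
    """
    rows = []
    for p in profiles:
        x = p.data["x"].to_numpy(dtype=float)
        y = p.intensity(channel).to_numpy(dtype=float)
        peaks = profile_peaks(x, y)
        peaks = peaks[peaks["is_stripe"]]
        if len(peaks) >= min_peaks:
            first, last = peaks.iloc[0], peaks.iloc[-1]
            # stripe width from the curvature of a local parabola fit to
            # the nuclei around the peak (a Gaussian bump has
            # sigma^2 = -I(p)/I''(p)); unlike half-height widths this is
            # insensitive to the depth of neighbouring troughs, and the
            # data-level fit avoids the spline's knot-quantized curvature
            widths = {}
            for name, row in (("first", first), ("last", last)):
                sel = np.abs(x - row["position"]) <= 2.5
                widths[name] = np.nan
                if sel.sum() >= 6:
                    a2 = np.polyfit(x[sel], y[sel], 2)[0]
                    if a2 < 0:
                        widths[name] = float(
                            np.sqrt(max(row["intensity"], 1e-9) / (-2.0 * a2))
                        )
            rows.append(
                {"embryo_id": p.embryo_id,
                 "intensity_ratio": first["intensity"] / last["intensity"],
                 "width_ratio": widths["first"] / widths["last"]}
            )
        else:
            rows.append({"embryo_id": p.embryo_id,
                         "intensity_ratio": np.nan, "width_ratio": np.nan})
    out = pd.DataFrame(rows).set_index("embryo_id")
    valid = out.dropna()
    out["pca_score"] = np.nan
    if len(valid) >= 2:
        z = (valid - valid.mean()) / valid.std(ddof=0).replace(0.0, 1.0)
        z = z.to_numpy()
        _, s, vt = np.linalg.svd(z - z.mean(axis=0), full_matrices=False)
        pc1 = vt[0]
        if pc1[1] < 0:      # orient: width ratio grows with developmental time
            pc1 = -pc1
        out.loc[valid.index, "pca_score"] = z @ pc1
        total = (s**2).sum()
        out.attrs["pc1_explained"] = float(s[0] ** 2 / total) if total > 0 else 1.0
    return out


# --------------------------------------------------------------------------
# agglomerative clustering (mean-of-the-two update)
# --------------------------------------------------------------------------


@dataclass
class ClusterAssignment:
    """Flat cluster labels plus the agglomeration history."""

    labels: dict[str, int]
    history: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))


def combine_with_signatures(
    dmat: DistanceMatrix,
    signatures: pd.DataFrame,
    alpha: float = DEFAULT_SIGNATURE_WEIGHT,
) -> DistanceMatrix:
    """Blend the chi-square distance with |delta pca_score|, rescaled to [0, 1].

    Pairs where either embryo lacks signatures fall back to the chi-square
    distance alone.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ConfigurationError("alpha must be in [0, 1]")
    score = signatures["pca_score"].reindex(dmat.ids).to_numpy(dtype=float)
    delta = np.abs(score[:, None] - score[None, :])
    finite = np.isfinite(delta)
    if finite.any() and np.nanmax(delta) > 0:
        delta = delta / np.nanmax(delta[finite])
    combined = np.where(finite, alpha * dmat.values + (1 - alpha) * delta, dmat.values)
    np.fill_diagonal(combined, 0.0)
    return DistanceMatrix(ids=list(dmat.ids), values=np.clip(combined, 0.0, 1.0))


def cluster_embryos(
    dmat: DistanceMatrix,
    k: int,
    signatures: pd.DataFrame | None = None,
    *,
    alpha: float = DEFAULT_SIGNATURE_WEIGHT,
) -> ClusterAssignment:
    """Agglomerative clustering with the mean-of-the-merged-pair update.

    Starting from singleton clusters, the two closest clusters are merged
    at each iteration and distances to every other cluster recalculated as
    the mean of the two merged clusters' distances (WPGMA-style); the
    process stops at ``k`` clusters.  Ties are broken by the lowest
    embryo-id pair, which makes the result independent of input order.

    With ``signatures``, the refinement is two-stage: the chi-square
    distance merges as far as it can discriminate (until the remaining
    pair probabilities have all underflowed), and the stripe-signature pca
    score, blended per :meth:`_WpgmaState.blend_signatures`, orders the
    remaining merges down to ``k``.  Per-embryo pca scores are too noisy
    near stripe-6 formation to outvote an informative chi-square fit, but
    their cluster means separate otherwise indistinguishable clusters.
    """
    n = len(dmat.ids)
    if not 1 <= k <= n:
        raise ConfigurationError(f"k must be in [1, {n}]")
    state = _WpgmaState.from_matrix(dmat)
    if signatures is None or k >= n:
        state.reduce_to(k)
        return state.assignment()
    state.reduce_to(k, stop_at_saturation=True)
    if len(state.active) > k:
        state.blend_signatures(signatures, alpha)
        state.reduce_to(k)
    return state.assignment()


class _WpgmaState:
    """Working state of the mean-of-the-two agglomeration.

    Keeping the working distance matrix between the over-clustering and
    the signature-refined merge stage matters: recomputing cluster
    distances as plain means saturates them (cross-cluster chi-square
    probabilities underflow), while the running WPGMA averages preserve
    the faint but correctly ordered differences.
    """

    def __init__(self, ids: list[str], d: np.ndarray):
        self.ids = ids
        self.d = d
        n = len(ids)
        self.members: dict[int, list[str]] = {i: [ids[i]] for i in range(n)}
        self.rep: dict[int, str] = {i: ids[i] for i in range(n)}
        self.active: list[int] = list(range(n))
        self.history: list[tuple[str, str, float]] = []
        self._last_height = -np.inf

    @classmethod
    def from_matrix(cls, dmat: DistanceMatrix) -> "_WpgmaState":
        # id-sorted order makes tie-breaking independent of input order
        order = np.argsort(np.asarray(dmat.ids, dtype=object))
        ids = [dmat.ids[i] for i in order]
        return cls(ids, dmat.values[np.ix_(order, order)].astype(float))

    def reduce_to(self, k: int, stop_at_saturation: bool = False) -> None:
        """Merge until ``k`` clusters remain.

        With ``stop_at_saturation`` the agglomeration also stops when every
        remaining pair distance equals 1.0 exactly (all pairwise
        chi-square probabilities underflowed): beyond that point the
        chi-square fit carries no ordering information.
        """
        while len(self.active) > k:
            best = None
            for ai in range(len(self.active)):
                for aj in range(ai + 1, len(self.active)):
                    i, j = self.active[ai], self.active[aj]
                    key = (self.d[i, j], *sorted((self.rep[i], self.rep[j])))
                    if best is None or key < best[0]:
                        best = (key, i, j)
            if stop_at_saturation and best[0][0] >= 1.0:
                return
            _, i, j = best
            height = self.d[i, j]
            if height < self._last_height - 1e-12:
                warnings.warn("non-monotone merge height in agglomeration", stacklevel=2)
            self._last_height = max(self._last_height, height)
            # mean-of-the-two distance update
            for m in self.active:
                if m not in (i, j):
                    self.d[i, m] = self.d[m, i] = 0.5 * (self.d[i, m] + self.d[j, m])
            self.history.append((self.rep[i], self.rep[j], float(height)))
            self.members[i] = self.members[i] + self.members[j]
            self.rep[i] = min(self.rep[i], self.rep[j])
            self.active.remove(j)

    def blend_signatures(self, signatures: pd.DataFrame, alpha: float,
                         saturation: float = 1.0) -> None:
        """Refine the working inter-cluster distances with pca signatures.

        The chi-square distance is precise shape evidence wherever it is
        informative, but cross-class (and occasionally outlier) pair
        probabilities underflow and saturate at exactly 1, where it can no
        longer order merges.  The refined distance is therefore
        lexicographic: informative pairs (working distance strictly below
        1; underflowed probabilities give exactly 1.0 in floating point)
        keep their chi-square ordering in the band [0, alpha); saturated
        pairs move to the band [alpha, 1]
        ordered by ``alpha + (1 - alpha) * |delta mean pca|`` (rescaled),
        so signatures decide among clusters the chi-square fit cannot
        tell apart.  Saturated pairs without any scored member rank last
        within their band (no similarity evidence).
        """
        if not 0.0 <= alpha <= 1.0:
            raise ConfigurationError("alpha must be in [0, 1]")
        score = signatures["pca_score"]
        act = self.active
        pairs = [(i, j) for ai, i in enumerate(act) for j in act[ai + 1:]]
        if not pairs:
            return
        dv = np.array([self.d[i, j] for i, j in pairs])
        means = {}
        for i in act:
            s = score.reindex(self.members[i]).dropna()
            means[i] = float(s.mean()) if len(s) else np.nan
        sv = np.array([abs(means[i] - means[j]) for i, j in pairs])
        finite = np.isfinite(sv)
        if finite.any() and np.nanmax(sv[finite]) > 0:
            sv = sv / np.nanmax(sv[finite])
        sv = np.where(finite, sv, 1.0)
        combined = np.where(dv < saturation, alpha * dv, alpha + (1 - alpha) * sv)
        for (i, j), v in zip(pairs, combined):
            self.d[i, j] = self.d[j, i] = float(v)
        self._last_height = -np.inf   # new scale: reset monotonicity tracking

    def assignment(self) -> ClusterAssignment:
        labels: dict[str, int] = {}
        for label, ci in enumerate(sorted(self.active, key=lambda c: self.rep[c])):
            for eid in self.members[ci]:
                labels[eid] = label
        return ClusterAssignment(labels=labels, history=self.history)


# --------------------------------------------------------------------------
# time-class assignment (stripe-count rules + clustering verification)
# --------------------------------------------------------------------------


def assign_time_classes(
    profiles: list[EmbryoProfile],
    species_preset: str = "clogmia",
    *,
    channel: str = "eve",
) -> dict[str, str]:
    """T1-T8 assignment from stripe counts, refined by clustering.

    The species' stripe-formation sequence fixes the number of resolved
    stripes per class; embryos are first grouped by the nearest preset
    stripe count.  Where two classes share a count, the group is split by
    the chi-square clustering (k = number of candidate classes) and the
    sub-clusters ordered by mean stripe intensity, which rises as stripes
    mature.
    """
    from .synthetic import stripe_count   # deferred: synthetic imports core only

    counts = {tc: stripe_count(species_preset, tc) for tc in
              ("T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8")}
    by_count: dict[int, list[str]] = {}
    for tc, c in counts.items():
        by_count.setdefault(c, []).append(tc)

    observed: dict[str, tuple[int, float]] = {}
    for p in profiles:
        x = p.data["x"].to_numpy(dtype=float)
        y = p.intensity(channel).to_numpy(dtype=float)
        # stricter prominence and width for counting: a miscounted noise
        # bump or residual-domain hump moves the embryo a whole class group
        peaks = profile_peaks(
            x, y, min_prominence=0.15 * float(np.ptp(y)), max_stripe_width=7.0
        )
        stripe_peaks = peaks[peaks["is_stripe"]]
        mean_intensity = float(stripe_peaks["intensity"].mean()) if len(stripe_peaks) else 0.0
        observed[p.embryo_id] = (len(stripe_peaks), mean_intensity)

    assignment: dict[str, str] = {}
    groups: dict[tuple[str, ...], list[EmbryoProfile]] = {}
    for p in profiles:
        c, _ = observed[p.embryo_id]
        nearest = min(by_count, key=lambda cc: (abs(cc - c), -cc))
        groups.setdefault(tuple(by_count[nearest]), []).append(p)

    for candidates, group in groups.items():
        if len(candidates) == 1 or len(group) < 2:
            for p in group:
                assignment[p.embryo_id] = candidates[0]
            continue
        dmat = distance_matrix(group, channel)
        k = min(len(candidates), len(group))
        clusters = cluster_embryos(dmat, k)
        sub: dict[int, list[str]] = {}
        for eid, lab in clusters.labels.items():
            sub.setdefault(lab, []).append(eid)
        if min(len(v) for v in sub.values()) < 0.25 * len(group) / k:
            # mean-linkage collapsed into strongly unbalanced clusters
            # (consecutive classes with near-identical stripe geometry);
            # fall back to splitting on stripe brightness, which rises
            # monotonically as stripes mature
            ranked_eids = sorted(group, key=lambda p: observed[p.embryo_id][1])
            size = len(group) // k
            sub = {}
            for ci in range(k):
                lo = ci * size
                hi = (ci + 1) * size if ci < k - 1 else len(group)
                sub[ci] = [p.embryo_id for p in ranked_eids[lo:hi]]
        # stripes brighten with time: earlier candidate = dimmer sub-cluster
        ranked = sorted(sub.values(),
                        key=lambda eids: np.mean([observed[e][1] for e in eids]))
        for tc, eids in zip(candidates, ranked):
            for eid in eids:
                assignment[eid] = tc
        for extra in ranked[len(candidates):]:
            for eid in extra:
                assignment[eid] = candidates[-1]
    return assignment
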
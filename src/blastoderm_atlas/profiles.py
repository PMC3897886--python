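"""Lateral-strip extraction, background removal and A-P orientation.

Per-nucleus records are reduced to the band along the lateral midline
(10% of embryo height by default, which avoids the extraembryonic
anlage), the smooth non-specific staining background is estimated and
subtracted per channel, and the anterior-posterior orientation is fixed
using the anterior Hb domain.
"""

from __future__ import annotations

import numpy as np

from .core import ConfigurationError, DegenerateInputError, EmbryoProfile


def extract_lateral_strip(profile: EmbryoProfile, fraction: float = 0.10) -> EmbryoProfile:
    """Keep nuclei within the central band |y - 50| <= 100 * fraction / 2."""
    if not 0.0 < fraction <= 1.0:
        raise ConfigurationError("strip fraction must be in (0, 1]")
    half = 100.0 * fraction / 2.0
    kept = profile.data[np.abs(profile.data["y"] - 50.0) <= half]
    if len(kept) == 0:
        raise DegenerateInputError("lateral strip contains no nuclei")
    return profile.with_data(kept, strip_fraction=fraction)


def _baseline_fit(x: np.ndarray, i: np.ndarray, *, n_windows: int,
                  quartile: float, n_iter: int) -> tuple[np.ndarray, float, float]:
    """Background fit b(x) = p0 + p1*x + p2*x^2 with its support range.

    Candidate background levels are the means of the lowest-``quartile``
    intensities in windows along x.  Windows that lie inside a broad
    expression domain never reach the background floor, so the quadratic
    is fitted to the lowest third of the levels and the floor set then
    evolves by region growing: windows adjacent (along x) to the current
    set join when consistent with the fit (within 2.5 robust standard
    deviations, but at least 2% of the level range - windows partially
    straddling a domain edge sit clearly above the floor), and
    inconsistent members are trimmed.  Growth is restricted to adjacent
    windows because the quadratic's extrapolation into far, unobserved
    territory can pass through contaminated levels.  Returns the
    coefficients plus the x-range of the windows that support the fit;
    outside it the quadratic extrapolates without data and should be held
    constant.
    """
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], i[order]
    edges = np.linspace(xs[0], xs[-1], n_windows + 1)
    wx, wy = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_win = (xs >= lo) & (xs <= hi)
        if in_win.sum() < 4:
            continue
        vals = ys[in_win]
        keep = vals <= np.quantile(vals, quartile)
        wx.append(float(np.mean(xs[in_win][keep])))
        wy.append(float(np.mean(vals[keep])))
    wx_arr, wy_arr = np.asarray(wx), np.asarray(wy)

    deg = 2 if len(wx_arr) >= 4 else max(0, len(wx_arr) - 1)
    # start from the lowest third of the levels: windows inside (or
    # straddling) a broad expression domain sit high and would otherwise
    # anchor the first fit above the floor
    keep = wy_arr <= np.quantile(wy_arr, 1.0 / 3.0)
    if keep.sum() < deg + 1:
        keep = np.ones(len(wx_arr), dtype=bool)
    coef = np.polyfit(wx_arr[keep], wy_arr[keep], deg)
    level_floor = 0.02 * float(np.ptp(wy_arr))
    n_win = len(wx_arr)
    for _ in range(n_iter):
        resid = wy_arr - np.polyval(coef, wx_arr)
        scale = 1.4826 * float(np.median(np.abs(resid[keep] - np.median(resid[keep]))))
        thr = max(2.5 * scale, level_floor, 1e-6)
        adjacent = np.zeros(n_win, dtype=bool)
        for j in np.flatnonzero(keep):
            if j > 0:
                adjacent[j - 1] = True
            if j < n_win - 1:
                adjacent[j + 1] = True
        consistent = np.abs(resid) <= thr
        new_keep = (keep | adjacent) & consistent
        if new_keep.sum() < deg + 1:
            break
        coef = np.polyfit(wx_arr[new_keep], wy_arr[new_keep], deg)
        if (new_keep == keep).all():
            break
        keep = new_keep
    return coef, float(wx_arr[keep].min()), float(wx_arr[keep].max())


def remove_background(
    profile: EmbryoProfile,
    channel: str,
    *,
    n_windows: int = 12,
    quartile: float = 0.25,
    n_iter: int = 30,
) -> EmbryoProfile:
    """Subtract a quadratic-in-x background estimate; clamp negatives to 0.

    The strip is narrow in y, so the paraboloid staining field reduces to
    a 1D quadratic b(x) = p0 + p1*x + p2*x^2 there; adding a constant to
    all intensities is absorbed by p0 and leaves the output unchanged.
    The estimated baseline is clipped at zero so the correction never
    increases any intensity.  With fewer than 10 nuclei the profile is
    returned unchanged with a warning flag.
    """
    col = f"I_{channel}"
    if col not in profile.data.columns:
        raise ConfigurationError(f"channel {channel!r} not present")
    if profile.n_nuclei < 10:
        return profile.with_data(profile.data, background_warning=channel)
    x = profile.data["x"].to_numpy(dtype=float)
    i = profile.data[col].to_numpy(dtype=float)
    coef, x_lo, x_hi = _baseline_fit(x, i, n_windows=n_windows, quartile=quartile,
                                     n_iter=n_iter)
    # hold the fit constant beyond its supporting windows (no data there)
    baseline = np.clip(np.polyval(coef, np.clip(x, x_lo, x_hi)), 0.0, None)
    data = profile.data.copy()
    data[col] = np.clip(i - baseline, 0.0, None)
    removed = dict(profile.meta.get("background_removed", {}))
    removed[channel] = tuple(coef)
    return profile.with_data(data, background_removed=removed)


def orient_anterior(profile: EmbryoProfile, *, channel: str = "hb") -> EmbryoProfile:
    """Flip x -> 100 - x if the Hb-rich half lies posterior.

    The anterior Hb domain marks the head end: if mean Hb intensity in
    x < 50 is lower than in x > 50 the embryo is mirrored.  A symmetric
    pattern is left unflipped (deterministic tie-break) with a warning
    flag; a missing Hb channel leaves the orientation unknown.
    """
    col = f"I_{channel}"
    if col not in profile.data.columns:
        out = profile.with_data(profile.data, orientation_warning="missing channel")
        out.orientation_known = False
        return out
    x = profile.data["x"].to_numpy(dtype=float)
    i = profile.data[col].to_numpy(dtype=float)
    anterior = i[x < 50.0]
    posterior = i[x > 50.0]
    mean_a = anterior.mean() if len(anterior) else 0.0
    mean_p = posterior.mean() if len(posterior) else 0.0
    if mean_a == mean_p:
        out = profile.with_data(profile.data, orientation_warning="symmetric pattern",
                                flipped=False)
    elif mean_a < mean_p:
        data = profile.data.copy()
        data["x"] = 100.0 - data["x"].to_numpy()
        out = profile.with_data(data, flipped=True)
    else:
        out = profile.with_data(profile.data, flipped=False)
    out.orientation_known = True
    return out
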
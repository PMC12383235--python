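"""Assembly kinetics: ThT lag-phase timing and real-time AFM growth tracking.

ThT fluorescence reports total fibril mass; the quantity of interest here
is the *end of the lag phase*, operationally the time at which the
normalized signal first crosses 10% of its plateau.  AFM time series of a
single elongating oligomer are reduced to per-end excursion-vs-time tracks
and ordinary least-squares growth rates, convertible to monomer addition
rates through the 0.48 nm cross-beta strand rise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage, stats

from .containers import HeightMapSeries, KineticCurve
from .morphometry import trace_filament
from .stoichiometry import StoichiometryConstants

__all__ = [
    "normalize_curve",
    "lag_end_time",
    "GrowthTrack",
    "track_growth",
    "GrowthRates",
    "fit_growth_rates",
    "normalize_influx",
]


def normalize_curve(curve: KineticCurve) -> KineticCurve:
    """Rescale a kinetic curve to fraction-of-maximum.

    baseline = mean of the first 5% of points, plateau = mean of the top 5%
    of values; both 5%-tail estimators are robust to small pre-transition
    drift.  Output is (f - baseline) / (plateau - baseline).
    """
    n = len(curve.f)
    k = max(1, int(np.ceil(0.05 * n)))
    baseline = float(np.mean(curve.f[:k]))
    plateau = float(np.mean(np.sort(curve.f)[-k:]))
    if plateau - baseline <= 0 or np.isclose(plateau, baseline):
        raise ValueError("no transition: curve is flat")
    return KineticCurve(curve.t.copy(), (curve.f - baseline) / (plateau - baseline),
                        curve.time_unit)


def lag_end_time(
    curve: KineticCurve,
    threshold_fraction: float = 0.10,
    normalized: bool = False,
    smooth_points: int = 11,
) -> dict:
    """Lag-phase end: first upward crossing of ``threshold_fraction``.

    The curve is normalized first (unless already normalized); the crossing
    time is linearly interpolated.  Also returns the 0.5-crossing
    (midpoint) time.  A curve starting above threshold, or crossing it
    upward more than once after light smoothing, is rejected as
    non-sigmoidal.
    """
    norm = curve if normalized else normalize_curve(curve)
    f = norm.f
    if f[0] >= threshold_fraction:
        raise ValueError("curve starts above threshold: lag phase not observed")
    fs = ndimage.uniform_filter1d(f, max(1, smooth_points)) if len(f) > smooth_points else f
    up = np.flatnonzero((fs[:-1] < threshold_fraction) & (fs[1:] >= threshold_fraction))
    if len(up) != 1:
        raise ValueError("non-sigmoidal: expected exactly one upward threshold crossing")

    def crossing(level: float) -> float:
        # crossings are located on the lightly smoothed series: the
        # smoothing window is short against the transition so the crossing
        # is unbiased, while sample noise at the threshold is suppressed
        idx = np.flatnonzero((fs[:-1] < level) & (fs[1:] >= level))
        i = idx[0]
        return float(
            norm.t[i]
            + (level - fs[i]) / (fs[i + 1] - fs[i]) * (norm.t[i + 1] - norm.t[i])
        )

    return {
        "lag_end": crossing(threshold_fraction),
        "midpoint": crossing(0.5),
        "threshold_fraction": threshold_fraction,
    }


@dataclass
class GrowthTrack:
    """Per-frame elongation bookkeeping for one tracked assembly.

    Excursions are measured as *arc length along the current skeleton* from
    the point nearest the frame-0 anchor to each end, minus their frame-0
    values — Euclidean endpoint displacement undercounts curvilinear
    growth.
    """

    timestamps: np.ndarray        # min
    total_length: np.ndarray      # nm
    end_a_excursion: np.ndarray   # nm
    end_b_excursion: np.ndarray   # nm
    anchor: np.ndarray            # nm (y, x)
    truncated: bool = False       # track cut short (merge / left the field)


def _arc_splits(points: np.ndarray, anchor: np.ndarray) -> tuple[float, float, float]:
    """(arc to end_a, arc to end_b, total) measured from the position on the
    polyline nearest the anchor (densely resampled, so the split is not
    quantized to the original vertex spacing)."""
    steps = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(steps)])
    ss = np.linspace(0.0, s[-1], max(int(s[-1] / 0.5), 2))
    dense = np.column_stack([np.interp(ss, s, points[:, k]) for k in range(points.shape[1])])
    i = int(np.argmin(np.linalg.norm(dense - anchor, axis=1)))
    return float(ss[i]), float(s[-1] - ss[i]), float(s[-1])


def track_growth(
    series: HeightMapSeries,
    threshold: Optional[float] = None,
) -> GrowthTrack:
    """Track one elongating object across an AFM series.

    Per frame the filament is traced, the anchor is the centroid of the
    frame-0 object, and end identity is propagated by nearest-endpoint
    matching to the previous frame.  If the object disappears, merges, or
    leaves the field, the track is truncated at the last clean frame.
    """
    n = series.n_frames
    tot = np.full(n, np.nan)
    ea = np.full(n, np.nan)
    eb = np.full(n, np.nan)
    anchor = None
    prev_ends = None
    base = None
    truncated = False
    last = 0
    from skimage.filters import apply_hysteresis_threshold

    for f in range(n):
        frame = series.frames[f]
        if threshold is not None:
            paths = trace_filament(frame, pixel_size=series.pixel_size, threshold=threshold)
        else:
            # light smoothing + hysteresis: the ridge of a tip-broadened
            # filament dips where pixel centres straddle it, so a single
            # threshold fragments it, while roughness never reaches the
            # high level to seed a spurious object
            sm = ndimage.gaussian_filter(frame, 0.7)
            lo = float(np.median(sm))
            amp = float(sm.max()) - lo
            hmask = apply_hysteresis_threshold(sm - lo, 0.15 * amp, 0.6 * amp)
            paths = trace_filament(frame, pixel_size=series.pixel_size, mask=hmask,
                                   extend_grid=sm, extend_level=lo + 0.15 * amp)
        if not paths:
            truncated = f > 0
            break
        if anchor is None:
            # frame 0: the longest object defines the track; anchor at the
            # arc-length midpoint (index midpoint can fall on a tip for
            # sparse paths)
            paths.sort(key=lambda p: -p.arc_length[-1])
            path = paths[0]
            s = path.arc_length
            anchor = np.array([
                np.interp(s[-1] / 2, s, path.points[:, k]) for k in range(2)
            ])
        else:
            path = min(paths, key=lambda p: np.min(np.linalg.norm(p.points - anchor, axis=1)))
        if path.border and f > 0:
            truncated = True
            break
        pts = path.points
        if prev_ends is not None:
            d_keep = np.linalg.norm(pts[0] - prev_ends[0]) + np.linalg.norm(pts[-1] - prev_ends[1])
            d_swap = np.linalg.norm(pts[-1] - prev_ends[0]) + np.linalg.norm(pts[0] - prev_ends[1])
            if d_swap < d_keep:
                pts = pts[::-1]
        a, b, t = _arc_splits(pts, anchor)
        if base is None:
            base = (a, b)
        ea[f], eb[f], tot[f] = a - base[0], b - base[1], t
        prev_ends = (pts[0].copy(), pts[-1].copy())
        last = f
    if anchor is None:
        raise ValueError("no traceable object in frame 0")
    sl = slice(0, last + 1)
    return GrowthTrack(series.timestamps[sl], tot[sl], ea[sl], eb[sl], anchor, truncated)


@dataclass
class GrowthRates:
    rate_a: float                 # nm/min
    rate_b: float                 # nm/min
    r_squared_a: float
    r_squared_b: float
    monomers_per_min_a: float
    monomers_per_min_b: float

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def fit_growth_rates(
    track: GrowthTrack,
    strand_rise_nm: float = 0.48,
) -> GrowthRates:
    """OLS slope of each end's excursion versus time ("linear best fit").

    monomers_per_min = rate / strand_rise.  Timestamp scaling by c scales
    rates by 1/c exactly (equivariance of least squares).
    """
    ok = np.isfinite(track.end_a_excursion) & np.isfinite(track.end_b_excursion)
    if ok.sum() < 3:
        raise ValueError("need at least 3 valid frames to fit growth rates")
    t = track.timestamps[ok]
    fits = []
    for y in (track.end_a_excursion[ok], track.end_b_excursion[ok]):
        res = stats.linregress(t, y)
        fits.append((res.slope, res.rvalue**2))
    (ra, r2a), (rb, r2b) = fits
    return GrowthRates(ra, rb, r2a, r2b, ra / strand_rise_nm, rb / strand_rise_nm)


def normalize_influx(f: np.ndarray, f0: float) -> np.ndarray:
    """Calcium-influx normalization (F/F0) - 1 against pre-addition baseline."""
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    return np.asarray(f, dtype=float) / f0 - 1.0
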
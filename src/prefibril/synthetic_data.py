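"""Synthetic generators for every input modality of the pipeline.

Each generator emulates one experimental data stream with known ground
truth so that every downstream analysis stage can be validated by a
render-then-measure round trip:

* AFM time series of an oligomer elongating bidirectionally on a support,
  imaged through a spherical-tip contact model (grayscale dilation) — the
  reason AFM overestimates widths but not heights;
* EM-style 2D images (line-of-sight projections) and 3D volumes of tubes
  and annuli with Gaussian blur and noise;
* single-channel current traces from continuous-time Markov gating under a
  step-voltage protocol, low-pass filtered;
* sigmoidal ThT aggregation curves with a prescribed lag time;
* lognormal length populations with a prescribed distribution mode.

Every generator takes an explicit seed; there is no hidden global RNG
state.  Ground truth is returned in physical units (nm, pS, pA),
independent of pixelation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal
from scipy.spatial import cKDTree

from .containers import CurrentTrace, DensityField, HeightMapSeries, KineticCurve, LengthPopulation

__all__ = [
    "AssemblyGroundTruth",
    "ChannelSimParams",
    "GrowthSimParams",
    "gen_afm_series",
    "gen_density_field",
    "gen_current_trace",
    "gen_tht_curve",
    "gen_length_population",
    "persistent_path",
]

#: Tube diameter of oligomers / curvilinear protofibrils (nm).
TUBE_DIAMETER_NM = 2.8


@dataclass
class AssemblyGroundTruth:
    """Ground-truth geometry of one simulated assembly."""

    kind: str                                  # oligomer | curvilinear | annulus | fibril
    centerline: np.ndarray                     # (n, 2) or (n, 3) nm; ring centre for annuli
    tube_diameter: float = TUBE_DIAMETER_NM
    ring_outer_diameter: Optional[float] = None
    ring_inner_diameter: Optional[float] = None
    channel_length: Optional[float] = None
    arc_length: float = 0.0                    # exact generator bookkeeping, nm

    def __post_init__(self) -> None:
        self.centerline = np.atleast_2d(np.asarray(self.centerline, dtype=float))
        if self.tube_diameter <= 0:
            raise ValueError("tube_diameter must be positive")
        if self.kind == "annulus":
            if self.ring_inner_diameter is None or self.ring_outer_diameter is None:
                raise ValueError("annulus requires inner and outer diameters")
            if not self.ring_inner_diameter < self.ring_outer_diameter:
                raise ValueError("ring_inner_diameter must be < ring_outer_diameter")


@dataclass(frozen=True)
class ChannelSimParams:
    """Two-state (or multi-level) channel simulation parameters.

    Multi-level gating uses independent open levels sharing one closed
    state; dwell times are exponential (memoryless).  Defaults follow the
    recording conditions the analyses assume: 2 kHz sampling, 0.2 kHz
    low-pass, +/-80 mV steps, and dwell times long enough that channels
    "stay open for long periods" (mean 50 ms).
    """

    conductance_levels: Tuple[float, ...] = (320.0,)
    open_rate: float = 20.0          # 1/s, closed -> open (total)
    close_rate: float = 20.0         # 1/s, open -> closed
    baseline_sd: float = 2.0         # pA, pre-filter
    drift_amplitude: float = 0.0     # pA, slow sinusoidal baseline drift
    drift_period_s: float = 10.0
    sampling_rate: float = 2000.0    # Hz
    filter_cutoff: float = 200.0     # Hz, -3 dB
    voltage_protocol: Tuple[Tuple[float, float], ...] = ((1000.0, -80.0), (1000.0, 0.0), (1000.0, 80.0))

    def __post_init__(self) -> None:
        if self.open_rate <= 0 or self.close_rate <= 0:
            raise ValueError("rates must be positive")
        if not all(0 < g <= 2000 for g in self.conductance_levels):
            raise ValueError("conductance levels must be in (0, 2000] pS")
        if self.sampling_rate <= 2 * self.filter_cutoff:
            raise ValueError("sampling_rate must exceed 2 x filter_cutoff")


@dataclass(frozen=True)
class GrowthSimParams:
    """AFM elongation time-series parameters (one assembly on a support)."""

    rate_end_a: float = 8.0          # nm/min
    rate_end_b: float = 8.0          # nm/min
    frame_interval: float = 8.0      # min
    n_frames: int = 6
    pixel_size: float = 12.0         # nm
    field_size: float = 1200.0       # nm, square field
    tip_radius: float = 20.0         # nm
    roughness_sd: float = 0.2        # nm
    persistence_length: float = 600.0  # nm, of the centerline walk
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_end_a < 0 or self.rate_end_b < 0:
            raise ValueError("rates must be >= 0")
        if not 1 <= self.pixel_size <= 50:
            raise ValueError("pixel_size must be within [1, 50] nm")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        for r in (self.rate_end_a, self.rate_end_b):
            ext = r * self.frame_interval
            if 0 < ext < 0.1 * self.pixel_size:
                raise ValueError(
                    "unobservable growth: per-frame extension below 0.1 pixel"
                )


# ---------------------------------------------------------------------------
# centerline generation
# ---------------------------------------------------------------------------

def persistent_path(
    length: float,
    rng: np.random.Generator,
    start: Sequence[float] = (0.0, 0.0),
    direction: float = 0.0,
    persistence_length: float = 600.0,
    step: float = 1.0,
    avoid: Optional[np.ndarray] = None,
    min_clearance: float = TUBE_DIAMETER_NM,
) -> np.ndarray:
    """Persistent random walk of a given arc length in 2D.

    Heading increments are Gaussian with variance ``step / persistence_length``;
    self-intersection within ``min_clearance`` is avoided by rejection
    (re-drawing the increment with growing straightening bias).  The exact
    arc length is ``n_steps * step`` with ``n_steps = round(length / step)``.
    """
    n = int(round(length / step))
    pts = np.empty((n + 1, 2))
    pts[0] = start
    theta = direction
    sd = np.sqrt(step / persistence_length)
    recent = max(2 * int(np.ceil(min_clearance / step)), 4)
    for i in range(n):
        for attempt in range(20):
            dth = rng.normal(0.0, sd * (1.0 if attempt < 10 else 0.3))
            cand_theta = theta + dth
            cand = pts[i] + step * np.array([np.cos(cand_theta), np.sin(cand_theta)])
            prior = pts[max(0, i - 2000): max(0, i + 1 - recent)]
            ok = True
            if len(prior):
                if np.min(np.linalg.norm(prior - cand, axis=1)) < min_clearance:
                    ok = False
            if ok and avoid is not None and len(avoid):
                if np.min(np.linalg.norm(avoid - cand, axis=1)) < min_clearance:
                    ok = False
            if ok:
                break
        theta = cand_theta
        pts[i + 1] = cand
    return pts


# ---------------------------------------------------------------------------
# AFM series
# ---------------------------------------------------------------------------

def _dilated_tube_profile(tube_radius: float, tip_radius: float,
                          ds: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Radial height profile of a surface-bound cylinder imaged by a
    spherical tip (grayscale dilation of the contact surface)."""
    R, Rt = tube_radius, tip_radius
    w = R + np.sqrt(max(2 * Rt * 2 * R, 1e-9)) + 2 * ds  # conservative support
    u = np.arange(-w, w + ds, ds)
    cyl = np.where(np.abs(u) <= R, R + np.sqrt(np.clip(R * R - u * u, 0, None)), 0.0)
    x = np.arange(0.0, w + ds, ds)
    cap_off = np.arange(-Rt, Rt + ds, ds)
    cap = np.sqrt(np.clip(Rt * Rt - cap_off**2, 0, None)) - Rt
    prof = np.empty_like(x)
    for k, xx in enumerate(x):
        idx = np.searchsorted(u, xx + cap_off)
        idx = np.clip(idx, 0, len(u) - 1)
        prof[k] = np.max(cyl[idx] + cap)
    return x, np.clip(prof, 0.0, None)


def _render_height_frame(
    centerline: np.ndarray,
    shape: tuple[int, int],
    pixel_size: float,
    tube_diameter: float,
    tip_radius: float,
) -> np.ndarray:
    """Height map (nm) of one tube through the spherical-tip contact model."""
    r_prof, h_prof = _dilated_tube_profile(tube_diameter / 2.0, tip_radius)
    reach = r_prof[-1]
    # dense resampling of the centerline so point distance ~ curve distance
    seg = np.linalg.norm(np.diff(centerline, axis=0), axis=1)
    if len(centerline) > 1 and seg.max() > 0.5:
        s = np.concatenate([[0], np.cumsum(seg)])
        ss = np.arange(0, s[-1] + 0.25, 0.5)
        dense = np.column_stack([np.interp(ss, s, centerline[:, k]) for k in range(2)])
    else:
        dense = centerline
    tree = cKDTree(dense)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    px_centers = np.column_stack([(yy.ravel() + 0.5), (xx.ravel() + 0.5)]) * pixel_size
    d, _ = tree.query(px_centers, distance_upper_bound=reach + 1.0)
    h = np.zeros(len(px_centers))
    hit = np.isfinite(d)
    h[hit] = np.interp(d[hit], r_prof, h_prof, right=0.0)
    return h.reshape(shape)


def gen_afm_series(
    params: GrowthSimParams,
    initial_length: float = 20.0,
) -> tuple[HeightMapSeries, List[AssemblyGroundTruth], dict]:
    """Simulate an oligomer elongating bidirectionally on a flat support.

    Frame 0 holds an oligomer of ``initial_length`` (2.8 nm tube height);
    each later frame extends the centerline by ``rate * frame_interval``
    at each end along a persistent random walk.  The height map is the
    tube surface dilated by a spherical tip of ``tip_radius`` plus
    Gaussian roughness.

    Returns ``(series, ground_truths, truth)`` where ``truth`` carries the
    exact per-frame end excursions and total arc lengths (nm).
    """
    rng = np.random.default_rng(params.seed)
    step = 0.5
    centre = np.array([params.field_size / 2, params.field_size / 2])
    theta0 = rng.uniform(0, 2 * np.pi)

    base = persistent_path(
        initial_length, rng, start=centre, direction=theta0,
        persistence_length=params.persistence_length, step=step,
    )
    n_px = int(round(params.field_size / params.pixel_size))
    frames, gts = [], []
    exc_a = np.zeros(params.n_frames)
    exc_b = np.zeros(params.n_frames)
    totals = np.zeros(params.n_frames)
    path = base
    for f in range(params.n_frames):
        if f > 0:
            da = params.rate_end_a * params.frame_interval
            db = params.rate_end_b * params.frame_interval
            if da > 0:
                t_a = path[0] - path[1]
                seg = persistent_path(
                    da, rng, start=path[0], direction=float(np.arctan2(t_a[1], t_a[0])),
                    persistence_length=params.persistence_length, step=step, avoid=path[12:],
                )
                path = np.vstack([seg[1:][::-1], path])
                exc_a[f] = exc_a[f - 1] + round(da / step) * step
            else:
                exc_a[f] = exc_a[f - 1]
            if db > 0:
                t_b = path[-1] - path[-2]
                seg = persistent_path(
                    db, rng, start=path[-1], direction=float(np.arctan2(t_b[1], t_b[0])),
                    persistence_length=params.persistence_length, step=step, avoid=path[:-12],
                )
                path = np.vstack([path, seg[1:]])
                exc_b[f] = exc_b[f - 1] + round(db / step) * step
            else:
                exc_b[f] = exc_b[f - 1]
        totals[f] = round(initial_length / step) * step + exc_a[f] + exc_b[f]
        frame = _render_height_frame(
            path, (n_px, n_px), params.pixel_size, TUBE_DIAMETER_NM, params.tip_radius
        )
        frame += rng.normal(0.0, params.roughness_sd, frame.shape)
        frames.append(frame)
        kind = "oligomer" if totals[f] < 15 else "curvilinear"
        gts.append(AssemblyGroundTruth(kind, path.copy(), arc_length=float(totals[f])))
    series = HeightMapSeries(
        np.stack(frames), params.pixel_size, params.frame_interval,
        params.frame_interval * np.arange(params.n_frames),
    )
    truth = {
        "end_a_excursion": exc_a,
        "end_b_excursion": exc_b,
        "total_length": totals,
        "rate_end_a": params.rate_end_a,
        "rate_end_b": params.rate_end_b,
    }
    return series, gts, truth


# ---------------------------------------------------------------------------
# EM-style density fields
# ---------------------------------------------------------------------------

def _check_layout(assemblies: Sequence[AssemblyGroundTruth], dims_nm: np.ndarray) -> None:
    for a in assemblies:
        margin = a.tube_diameter
        hi = dims_nm[-a.centerline.shape[1]:]
        ext = (a.ring_outer_diameter or a.tube_diameter) / 2.0
        if (a.centerline - ext < margin).any() or (a.centerline + ext > hi - margin).any():
            raise ValueError("assembly does not fit inside dims with one tube-diameter margin")
    for i in range(len(assemblies)):
        for j in range(i + 1, len(assemblies)):
            ti = cKDTree(assemblies[i].centerline)
            d = ti.query(assemblies[j].centerline)[0].min()
            limit = max(assemblies[i].tube_diameter, assemblies[j].tube_diameter)
            extra = sum((a.ring_outer_diameter or 0.0) / 2.0 for a in (assemblies[i], assemblies[j]))
            if d < limit + extra:
                raise ValueError("assemblies closer than one tube diameter: ambiguous ground truth")


def _dense_centerline(cl: np.ndarray, spacing: float = 0.25) -> np.ndarray:
    if len(cl) < 2:
        return cl
    seg = np.linalg.norm(np.diff(cl, axis=0), axis=1)
    s = np.concatenate([[0], np.cumsum(seg)])
    if s[-1] == 0:
        return cl[:1]
    ss = np.arange(0, s[-1] + spacing / 2, spacing)
    return np.column_stack([np.interp(ss, s, cl[:, k]) for k in range(cl.shape[1])])


def gen_density_field(
    assemblies: Sequence[AssemblyGroundTruth],
    dims: tuple,
    voxel_size: float,
    blur_sd: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DensityField:
    """Render assemblies into a 2D image or 3D volume.

    Tubes are constant-density solid cylinders along their centerlines: a
    3D volume holds density 1 inside the tube; a 2D image holds the
    line-of-sight projection (chord length through the cylinder), which is
    what class averages and micrographs show.  Annuli with a stated
    ``channel_length`` are cylindrical shells of that axial length; without
    one they are circular-cross-section tori.  Gaussian blur of ``blur_sd``
    (nm) is applied, then additive Gaussian noise.  Ground truth is never
    modified by rendering.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    dims = tuple(int(d) for d in dims)
    nd = len(dims)
    if nd not in (2, 3):
        raise ValueError("dims must be 2D or 3D")
    dims_nm = np.asarray(dims, dtype=float) * voxel_size
    _check_layout(assemblies, dims_nm)

    grid = np.zeros(dims)
    axes = np.meshgrid(*[(np.arange(n) + 0.5) * voxel_size for n in dims], indexing="ij")
    pts = np.column_stack([a.ravel() for a in axes])

    for a in assemblies:
        R = a.tube_diameter / 2.0
        if a.kind == "annulus":
            grid += _render_annulus(a, pts, nd).reshape(dims)
            continue
        dense = _dense_centerline(a.centerline)
        if dense.shape[1] != nd:
            raise ValueError("centerline dimensionality must match dims")
        tree = cKDTree(dense)
        d, _ = tree.query(pts, distance_upper_bound=R + voxel_size)
        d = np.where(np.isfinite(d), d, np.inf)
        if nd == 3:
            grid += (d <= R).astype(float).reshape(dims)
        else:
            # projection: chord length through the cylinder
            vals = np.zeros(len(pts))
            inside = d <= R
            vals[inside] = 2.0 * np.sqrt(R * R - d[inside] ** 2)
            grid += vals.reshape(dims)

    if blur_sd > 0:
        grid = gaussian_filter(grid, blur_sd / voxel_size)
    if noise_sd > 0:
        grid = grid + rng.normal(0.0, noise_sd, grid.shape)
    return DensityField(grid, voxel_size)


def _render_annulus(a: AssemblyGroundTruth, pts: np.ndarray, nd: int) -> np.ndarray:
    """Annulus density at the sample points: cylindrical shell if a channel
    length is stated, circular-cross-section torus otherwise; 2D output is
    the projection down the ring axis."""
    c = a.centerline[0]
    Ro, Ri = a.ring_outer_diameter / 2.0, a.ring_inner_diameter / 2.0
    Rc, rt = 0.5 * (Ro + Ri), 0.5 * (Ro - Ri)
    if nd == 2:
        r = np.linalg.norm(pts - c[None, :2], axis=1)
        if a.channel_length is not None:
            return np.where((r >= Ri) & (r <= Ro), a.channel_length, 0.0)
        under = np.clip(rt**2 - (r - Rc) ** 2, 0.0, None)
        return 2.0 * np.sqrt(under)
    # 3D: axis 0 is the ring axis
    z = pts[:, 0] - c[0]
    r = np.linalg.norm(pts[:, 1:] - c[None, 1:], axis=1)
    if a.channel_length is not None:
        L = a.channel_length
        return ((r >= Ri) & (r <= Ro) & (np.abs(z) <= L / 2.0)).astype(float)
    return (((r - Rc) ** 2 + z**2) <= rt**2).astype(float)


# ---------------------------------------------------------------------------
# current traces
# ---------------------------------------------------------------------------

def _protocol_voltage(protocol, t_ms: np.ndarray) -> np.ndarray:
    durs = np.array([p[0] for p in protocol], dtype=float)
    volts = np.array([p[1] for p in protocol], dtype=float)
    cycle = durs.sum()
    edges = np.concatenate([[0.0], np.cumsum(durs)])
    phase = np.mod(t_ms, cycle)
    idx = np.searchsorted(edges, phase, side="right") - 1
    return volts[np.clip(idx, 0, len(volts) - 1)]


def gen_current_trace(
    params: ChannelSimParams,
    duration_ms: float,
    seed: int = 0,
) -> tuple[CurrentTrace, np.ndarray]:
    """Simulate a single-channel current trace.

    Continuous-time Markov gating (exponential dwells) is sampled at
    ``sampling_rate``; the current is ``g_state * V(t)`` plus drift and
    Gaussian noise, then zero-phase low-pass filtered (8-pole Bessel
    design at the stated -3 dB cutoff).  Returns the trace and the
    ground-truth state per sample (0 closed, k>=1 open level k).
    """
    cycle_ms = sum(p[0] for p in params.voltage_protocol)
    if duration_ms < cycle_ms:
        raise ValueError("duration must cover at least one protocol cycle")
    rng = np.random.default_rng(seed)
    n = int(round(duration_ms / 1000.0 * params.sampling_rate))
    t_ms = np.arange(n) / params.sampling_rate * 1000.0
    v = _protocol_voltage(params.voltage_protocol, t_ms)
    if np.all(v == 0):
        warnings.warn("zero voltage throughout: conductance unobservable at 0 mV")

    # CTMC: shared closed state, K independent open levels
    K = len(params.conductance_levels)
    states = np.zeros(n, dtype=int)
    t_s = 0.0
    state = 0
    T = duration_ms / 1000.0
    while t_s < T:
        if state == 0:
            dwell = rng.exponential(1.0 / params.open_rate)
            nxt = 1 + rng.integers(K)
        else:
            dwell = rng.exponential(1.0 / params.close_rate)
            nxt = 0
        i0 = int(np.ceil(t_s * params.sampling_rate))
        i1 = min(int(np.ceil((t_s + dwell) * params.sampling_rate)), n)
        states[i0:i1] = state
        t_s += dwell
        state = nxt

    g = np.concatenate([[0.0], np.asarray(params.conductance_levels, dtype=float)])
    i_pa = g[states] * v / 1000.0  # pS * mV -> pA
    if params.drift_amplitude > 0:
        i_pa = i_pa + params.drift_amplitude * np.sin(
            2 * np.pi * t_ms / 1000.0 / params.drift_period_s
        )
    if params.baseline_sd > 0:
        i_pa = i_pa + rng.normal(0.0, params.baseline_sd, n)
    # zero-phase low-pass with Bessel magnitude at the stated cutoff
    sos = signal.bessel(8, params.filter_cutoff, fs=params.sampling_rate,
                        output="sos", norm="mag")
    i_pa = signal.sosfiltfilt(sos, i_pa)
    trace = CurrentTrace(t_ms, i_pa, v, params.sampling_rate, params.filter_cutoff)
    return trace, states


# ---------------------------------------------------------------------------
# kinetic curves and length populations
# ---------------------------------------------------------------------------

def gen_tht_curve(
    lag_h: float,
    midpoint_h: float,
    plateau: float,
    noise_sd: float,
    t_grid: np.ndarray,
    seed: int = 0,
) -> KineticCurve:
    """Sigmoidal (logistic) aggregation curve.

    The steepness is chosen so the 10%-of-plateau crossing falls exactly at
    ``lag_h``:  k = ln(9) / (midpoint_h - lag_h).
    """
    if not 0 < lag_h < midpoint_h:
        raise ValueError("require 0 < lag_h < midpoint_h")
    t = np.asarray(t_grid, dtype=float)
    k = np.log(9.0) / (midpoint_h - lag_h)
    f = plateau / (1.0 + np.exp(-k * (t - midpoint_h)))
    if noise_sd > 0:
        f = f + np.random.default_rng(seed).normal(0.0, noise_sd, len(t))
    return KineticCurve(t, f)


def gen_length_population(
    t_points: Sequence[float],
    modal_lengths: Sequence[float],
    dispersion: float = 0.4,
    n_per_t: int = 100,
    seed: int = 0,
) -> List[LengthPopulation]:
    """Lognormal length samples whose distribution *mode* equals the request.

    For lognormal(mu, sigma) the mode is exp(mu - sigma^2), so
    mu = ln(mode) + sigma^2 with sigma = ``dispersion``.
    """
    if len(t_points) != len(modal_lengths):
        raise ValueError("t_points and modal_lengths must align")
    if any(m <= 0 for m in modal_lengths):
        raise ValueError("modal lengths must be positive")
    if n_per_t < 30:
        warnings.warn("n_per_t < 30: mode estimation is unstable")
    rng = np.random.default_rng(seed)
    pops = []
    for t, m in zip(t_points, modal_lengths):
        mu = np.log(m) + dispersion**2
        if dispersion == 0:
            lengths = np.full(n_per_t, m)
        else:
            lengths = rng.lognormal(mu, dispersion, n_per_t)
        pops.append(LengthPopulation(lengths, t_label=t))
    return pops
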
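"""Single-channel electrophysiology analysis.

Covers the path from a raw voltage-clamp current trace to a pore-diameter
estimate:

1. per-sample conductance ``g = I/V`` on polarized epochs,
2. idealization into discrete open/closed states (half-amplitude threshold
   between histogram-detected conductance levels),
3. windowed conductance distributions whose per-window mode is the summary
   data point,
4. the Hille access-resistance model mapping conductance to pore diameter.

Hille model
-----------
A cylindrical pore of diameter ``d`` and length ``l`` in solution of
resistivity ``rho`` has resistance

    1/g = 4*rho*l / (pi * d**2)  +  rho / d

where the second term is the access (convergence) resistance, rho/(2d) at
each mouth.  Solving for the positive root of the quadratic in ``d``:

    d = ( rho*g + sqrt((rho*g)**2 + 16*rho*g*l/pi) ) / 2

with ``rho*g`` expressed in length units.  In the limit ``l = 0`` the pore
is all mouth and ``d = rho*g`` exactly.  With rho in ohm*cm and g in pS,
``rho*g`` is in units of 1e-5 nm (1 ohm*cm * 1 pS = 1e-12 ohm*cm*S
= 1e-12 cm = 1e-5 nm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import signal

from .containers import CurrentTrace

__all__ = [
    "PoreModel",
    "hille_diameter",
    "hille_conductance",
    "conductance_series",
    "idealize",
    "IdealizedTrace",
    "ConductanceWindowStats",
    "windowed_modal_conductance",
    "conductance_summary",
]

# 1 ohm*cm * 1 pS, expressed in nm.
_OHMCM_PS_TO_NM = 1e-5


@dataclass(frozen=True)
class PoreModel:
    """Channel length (nm) and solution resistivity (ohm*cm)."""

    l_nm: float = 5.4
    rho_ohm_cm: float = 80.0

    def __post_init__(self) -> None:
        if self.l_nm < 0:
            raise ValueError("channel length must be >= 0")
        if self.rho_ohm_cm <= 0:
            raise ValueError("resistivity must be positive")


def hille_diameter(g_ps: float, model: PoreModel = PoreModel()) -> float:
    """Pore diameter (nm) for an ionic conductance ``g_ps`` (pS)."""
    g_ps = np.asarray(g_ps, dtype=float)
    if np.any(g_ps <= 0):
        raise ValueError("conductance must be positive")
    rg = model.rho_ohm_cm * g_ps * _OHMCM_PS_TO_NM  # nm
    d = 0.5 * (rg + np.sqrt(rg * rg + 16.0 * model.l_nm * rg / np.pi))
    return float(d) if d.ndim == 0 else d


def hille_conductance(d_nm: float, model: PoreModel = PoreModel()) -> float:
    """Conductance (pS) of a pore of diameter ``d_nm`` (nm); inverse of
    :func:`hille_diameter`."""
    d_nm = np.asarray(d_nm, dtype=float)
    if np.any(d_nm <= 0):
        raise ValueError("diameter must be positive")
    # resistance in units of (ohm*cm / nm); conductance back to pS
    r = model.rho_ohm_cm * (4.0 * model.l_nm / (np.pi * d_nm**2) + 1.0 / d_nm)
    g = 1.0 / (r * _OHMCM_PS_TO_NM)
    return float(g) if g.ndim == 0 else g


def conductance_series(
    trace: CurrentTrace,
    baseline_pa: float = 0.0,
    v_min_mv: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample conductance in pS and a validity mask.

    Samples with ``|V| < v_min_mv`` are masked (conductance is unobservable
    near 0 mV, not zero).  Sign convention: an ohmic open channel whose
    current reverses with voltage yields positive g at both polarities.

    Returns ``(g_ps, mask)`` where masked-out samples hold NaN.
    """
    mask = np.abs(trace.v) >= v_min_mv
    if not np.any(mask):
        raise ValueError("no polarized epochs: all samples below |V| threshold")
    g = np.full(len(trace.i), np.nan)
    # pA / mV = nS; *1000 -> pS
    g[mask] = (trace.i[mask] - baseline_pa) / trace.v[mask] * 1000.0
    return g, mask


@dataclass
class IdealizedTrace:
    """Discrete state sequence and level estimates for one trace.

    ``states`` holds 0 for closed and k>=1 for the k-th open level; samples
    outside polarized epochs are closed by definition of observability and
    excluded from statistics via ``mask``.
    """

    states: np.ndarray
    levels_ps: np.ndarray        # open-level conductances, ascending
    baseline_pa: float
    open_probability: float
    mask: np.ndarray
    g_ps: np.ndarray

    @property
    def open(self) -> np.ndarray:
        return self.states > 0


def _histogram_levels(g: np.ndarray, bin_ps: float, min_sep_ps: float) -> np.ndarray:
    """Open-level candidates as smoothed-histogram peaks above zero."""
    hi = max(float(np.nanmax(g)) + 5 * bin_ps, 10 * bin_ps)
    edges = np.arange(-hi, hi + bin_ps, bin_ps)
    counts, edges = np.histogram(g[np.isfinite(g)], bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = np.convolve(counts, np.exp(-0.5 * (np.arange(-4, 5) / 1.5) ** 2), mode="same")
    peaks, _ = signal.find_peaks(smooth, prominence=0.02 * smooth.max())
    # keep peaks clearly away from the closed level at 0
    sel = centers[peaks] > min_sep_ps
    levels, heights = centers[peaks][sel], smooth[peaks][sel]
    # merge peaks closer than the separation floor, keeping the taller
    keep: list[float] = []
    for lv, _h in sorted(zip(levels, heights), key=lambda t: -t[1]):
        if all(abs(lv - k) > min_sep_ps for k in keep):
            keep.append(lv)
    return np.sort(np.asarray(keep))


def idealize(
    trace: CurrentTrace,
    baseline_window_ms: float = 250.0,
    bin_ps: float = 5.0,
    v_min_mv: float = 5.0,
    require_channel: bool = True,
) -> IdealizedTrace:
    """Idealize a trace into open/closed states.

    The baseline current is taken from the unpolarized (|V| < 5 mV) epochs
    of the step protocol when present — channel current vanishes there
    regardless of gating state — otherwise as the median over the first
    ``baseline_window_ms`` (which must then be an all-closed epoch).
    Conductance levels are modes of the baseline-subtracted conductance
    histogram; states are assigned by the half-amplitude threshold between
    adjacent levels; events shorter than two filter time constants are
    merged into their predecessor.
    """
    zero_v = np.abs(trace.v) < v_min_mv
    if zero_v.sum() >= 50:
        base_samples = trace.i[zero_v]
    else:
        n_base = max(1, int(round(baseline_window_ms / 1000.0 * trace.sampling_rate)))
        base_samples = trace.i[:n_base]
    baseline = float(np.median(base_samples))
    noise_sd_pa = 1.4826 * float(np.median(np.abs(base_samples - baseline)))

    g, mask = conductance_series(trace, baseline_pa=baseline, v_min_mv=v_min_mv)
    v_typ = float(np.median(np.abs(trace.v[mask])))
    noise_sd_ps = noise_sd_pa / v_typ * 1000.0

    levels = _histogram_levels(g[mask], bin_ps=bin_ps, min_sep_ps=max(4 * noise_sd_ps, 4 * bin_ps))
    if len(levels) == 0:
        if require_channel:
            raise ValueError(
                "no channel detected: no level separated from baseline by > 4 x noise SD"
            )
        return IdealizedTrace(np.zeros(len(g), dtype=int), levels, baseline, 0.0, mask, g)

    # half-amplitude thresholds: between 0 and levels[0], then between levels
    bounds = np.concatenate([[0.5 * levels[0]], 0.5 * (levels[:-1] + levels[1:])])
    states = np.zeros(len(g), dtype=int)
    gi = np.where(mask, g, 0.0)
    for k, b in enumerate(bounds, start=1):
        states[gi >= b] = k
    states[~mask] = 0

    # minimum event duration: 2 filter time constants (tau = 1/(2 pi fc))
    if trace.filter_cutoff:
        tau_s = 1.0 / (2.0 * np.pi * trace.filter_cutoff)
        min_samples = max(1, int(np.ceil(2.0 * tau_s * trace.sampling_rate)))
        states = _enforce_min_duration(states, min_samples)

    p_open = float(np.mean(states[mask] > 0)) if np.any(mask) else 0.0
    return IdealizedTrace(states, levels, baseline, p_open, mask, g)


def _enforce_min_duration(states: np.ndarray, min_samples: int) -> np.ndarray:
    """Merge runs shorter than ``min_samples`` into the preceding state."""
    if min_samples <= 1:
        return states
    out = states.copy()
    # run-length encode
    change = np.flatnonzero(np.diff(out) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(out)]])
    for s, e in zip(starts, ends):
        if e - s < min_samples and s > 0:
            out[s:e] = out[s - 1]
    return out


@dataclass
class ConductanceWindowStats:
    """Summary of one fixed-length analysis window."""

    window_start_ms: float
    window_length_ms: float
    bin_edges_ps: np.ndarray
    counts: np.ndarray
    modal_g_ps: float
    peaks_ps: np.ndarray
    open_probability: float
    no_open_flag: bool


def windowed_modal_conductance(
    trace: CurrentTrace,
    ideal: Optional[IdealizedTrace] = None,
    window_ms: float = 2500.0,
    bin_ps: float = 10.0,
    open_only: bool = True,
) -> List[ConductanceWindowStats]:
    """Per-window conductance histograms and modal conductance.

    Each window of ``window_ms`` yields one data point: the centre of the
    highest-count histogram bin of the open-state conductance samples.
    Windows with no open samples report ``modal_g_ps = 0`` and are flagged.
    Negative conductance excursions (noise near the closed level) are
    clipped into the zero bin rather than discarded so that open
    probability stays unbiased.
    """
    if ideal is None:
        ideal = idealize(trace)
    n_win = int(round(window_ms / 1000.0 * trace.sampling_rate))
    if n_win < 1 or n_win > len(trace.i):
        raise ValueError("trace shorter than one window")
    g_hi = max(float(np.nanmax(ideal.g_ps[ideal.mask])) + bin_ps, 10 * bin_ps)
    # bins centred on multiples of the bin width (edges at half-widths), so
    # a level sitting exactly on a round number is not split across two bins
    edges = np.arange(-bin_ps / 2.0, g_hi + bin_ps, bin_ps)
    out: List[ConductanceWindowStats] = []
    for start in range(0, len(trace.i) - n_win + 1, n_win):
        sl = slice(start, start + n_win)
        m = ideal.mask[sl]
        sel = (ideal.open[sl] & m) if open_only else m
        gs = np.clip(ideal.g_ps[sl][sel], 0.0, None)
        counts, _ = np.histogram(gs, bins=edges)
        p_open = float(np.mean(ideal.open[sl][m])) if np.any(m) else 0.0
        if gs.size == 0:
            out.append(ConductanceWindowStats(
                start / trace.sampling_rate * 1000.0, window_ms, edges, counts,
                0.0, np.array([]), p_open, True))
            continue
        centers = 0.5 * (edges[:-1] + edges[1:])
        modal = float(centers[np.argmax(counts)])
        pk, _ = signal.find_peaks(counts, prominence=0.1 * counts.max())
        out.append(ConductanceWindowStats(
            start / trace.sampling_rate * 1000.0, window_ms, edges, counts,
            modal, centers[pk], p_open, False))
    return out


def conductance_summary(
    windows: List[ConductanceWindowStats], model: PoreModel = PoreModel()
) -> dict:
    """Aggregate per-window modal conductances into the per-recording summary.

    Reports the median modal conductance, both a percentile (20th-80th) and
    a min/max range of the per-window modes, and the corresponding Hille
    pore diameters.
    """
    modes = np.array([w.modal_g_ps for w in windows if not w.no_open_flag])
    if modes.size == 0:
        return {"n_windows": 0, "median_modal_g_ps": 0.0}
    med = float(np.median(modes))
    p20, p80 = (float(x) for x in np.percentile(modes, [20, 80]))
    return {
        "n_windows": int(modes.size),
        "median_modal_g_ps": med,
        "g_range_ps_minmax": [float(modes.min()), float(modes.max())],
        "g_range_ps_p20_p80": [p20, p80],
        "d_nm_point": hille_diameter(med, model) if med > 0 else None,
        "d_nm_range": [hille_diameter(p, model) if p > 0 else None for p in (p20, p80)],
    }
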
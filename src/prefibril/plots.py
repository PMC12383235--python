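"""Standard diagnostic plots (PNG/SVG via matplotlib)."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .containers import KineticCurve
from .kinetics import GrowthRates, GrowthTrack

__all__ = ["plot_growth_track", "plot_normalized_tht"]


def plot_growth_track(
    track: GrowthTrack,
    rates: Optional[GrowthRates] = None,
    out: Union[str, Path, None] = None,
):
    """Per-end excursion and total length versus time, with OLS fit lines."""
    fig, ax = plt.subplots(figsize=(5, 4))
    t = track.timestamps
    ax.plot(t, track.end_a_excursion, "o", label="end A excursion")
    ax.plot(t, track.end_b_excursion, "s", label="end B excursion")
    ax.plot(t, track.total_length, "k.--", alpha=0.5, label="total length")
    if rates is not None:
        for rate, y, style in ((rates.rate_a, track.end_a_excursion, "-"),
                               (rates.rate_b, track.end_b_excursion, "-")):
            b = np.mean(y) - rate * np.mean(t)
            ax.plot(t, rate * t + b, style, lw=1,
                    label=f"fit {rate:.1f} nm/min")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("length (nm)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig


def plot_normalized_tht(
    curve: KineticCurve,
    lag_result: Optional[dict] = None,
    out: Union[str, Path, None] = None,
):
    """Normalized aggregation curve with lag-end / midpoint markers."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.t, curve.f, lw=1)
    if lag_result is not None:
        thr = lag_result.get("threshold_fraction", 0.10)
        ax.axhline(thr, color="gray", ls=":", lw=0.8)
        ax.axvline(lag_result["lag_end"], color="C3", ls="--", lw=1,
                   label=f"lag end {lag_result['lag_end']:.1f} {curve.time_unit}")
        ax.axvline(lag_result["midpoint"], color="C2", ls="--", lw=1,
                   label=f"midpoint {lag_result['midpoint']:.1f} {curve.time_unit}")
        ax.legend(fontsize=8)
    ax.set_xlabel(f"time ({curve.time_unit})")
    ax.set_ylabel("fraction of maximum")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig
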
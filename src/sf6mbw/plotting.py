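"""Diagnostic figures: boundary respirograms and correction traces."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from matplotlib.figure import Figure

from .pipeline import AnalysisResult
from .signal_io import RawRecording
from .tidal import EXPIRATION, INSPIRATION, MAX_SF6, MIN_SF6

__all__ = ["plot_respirograms", "plot_correction"]


def plot_respirograms(respirograms: dict, path: str | Path) -> None:
    """Volume-domain boundary traces, one panel per half-breath phase."""
    fig = Figure(figsize=(8, 3.5))
    axes = fig.subplots(1, 2)
    for ax, phase in zip(axes, (INSPIRATION, EXPIRATION)):
        for boundary, style in ((MIN_SF6, "-"), (MAX_SF6, "--")):
            r = respirograms[(boundary, phase)]
            ax.plot(r.centers_ml, r.values_gmol, style, label=boundary)
        ax.set_xlabel(f"{phase} volume (mL)")
        ax.set_ylabel("molar mass (g/mol)")
        ax.set_title(phase)
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)


def plot_correction(result: AnalysisResult, rec: RawRecording, path: str | Path) -> None:
    """Normalised signal with side-chamber curves, and the extracted SF6."""
    fig = Figure(figsize=(8, 6))
    ax1, ax2 = fig.subplots(2, 1, sharex=True)
    t = rec.time[result.norm.index]
    ax1.plot(t, result.norm.x, "k-", lw=0.6, label="normalised signal")
    if result.curves is not None:
        ax1.plot(t, result.curves.minimum, "r-", lw=0.8, label="0% SF6 curve")
        ax1.plot(t, result.curves.maximum, "r--", lw=0.8, label="max SF6 curve")
    ax1.set_ylabel("fraction of maximum")
    ax1.legend(fontsize=8)
    ax2.plot(rec.time[result.sf6.index], 100.0 * result.sf6.sf6, "k-", lw=0.6)
    et = result.sf6.end_tidal
    bt = sorted(et)
    t_et = [rec.time[result.breaths[b].i_end - 1] for b in bt]
    ax2.plot(t_et, [100.0 * et[b] for b in bt], "bo", ms=3, label="end-tidal")
    ax2.set_xlabel("time (s)")
    ax2.set_ylabel("SF6 (%)")
    ax2.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
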
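"""Breath segmentation and washin/washout phase assignment.

Breaths are cut at flow zero crossings with a hysteresis band (a fraction of
the 95th percentile of |flow|), then candidates below a minimum volume or
duration are merged into their neighbours.  The end-tidal molar mass of a
breath is the median over the last few percent of its expired volume, which
is robust to sensor noise and, in a well-mixed lung, samples the alveolar
plateau.

Phases are assigned on the per-breath end-tidal series: the washin starts at
the first breath whose end-tidal molar mass rises clearly above the
pre-phase baseline (heavy SF6 raises the molar mass), the washout at the
first subsequent clear drop from the running washin maximum.  The washin is
flagged complete when the last few washin breaths form a tight plateau —
a precondition for using them as the known-concentration boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import BreathDetectionError, PhaseError
from .signal_io import AnalysisConfig, RawRecording

__all__ = ["Breath", "PhaseAnnotation", "integrate_volume", "detect_breaths", "detect_phases"]


@dataclass(frozen=True)
class Breath:
    """One breath: inspiration [i_insp, i_exp), expiration [i_exp, i_end)."""

    i_insp: int
    i_exp: int
    i_end: int
    inspired_volume_ml: float
    expired_volume_ml: float
    end_tidal_molar_mass: float
    duration_s: float

    def __post_init__(self) -> None:
        if not (self.i_insp < self.i_exp < self.i_end):
            raise ValueError("breath indices must be strictly ordered")
        if self.inspired_volume_ml <= 0 or self.expired_volume_ml <= 0:
            raise ValueError("breath volumes must be positive")


@dataclass(frozen=True)
class PhaseAnnotation:
    """Contiguous breath-index ranges [start, stop) for the three phases."""

    pre: tuple[int, int]
    washin: tuple[int, int]
    washout: tuple[int, int]
    washin_complete: bool

    def __post_init__(self) -> None:
        if not (self.pre[1] == self.washin[0] and self.washin[1] == self.washout[0]):
            raise ValueError("phase ranges must be contiguous and ordered")
        if self.washout[1] <= self.washout[0]:
            raise ValueError("washout must be non-empty")


def integrate_volume(rec: RawRecording) -> np.ndarray:
    """Cumulative trapezoidal integral of flow, in mL (signed)."""
    return cumulative_trapezoid(rec.flow * 1000.0, rec.time, initial=0.0)


def segment_volume_ml(rec: RawRecording, start: int, stop: int) -> float:
    """Unsigned volume moved in [start, stop), mL (trapezoid of |net flow|)."""
    return abs(float(np.trapezoid(rec.flow[start:stop] * 1000.0, rec.time[start:stop])))


def phase_volume_trace(rec: RawRecording, start: int, stop: int) -> np.ndarray:
    """Cumulative |volume| within one inspiration or expiration, mL."""
    seg = np.abs(rec.flow[start:stop]) * 1000.0
    return cumulative_trapezoid(seg, rec.time[start:stop], initial=0.0)


def _segments(flow: np.ndarray, threshold: float) -> list[tuple[int, int, int]]:
    """(start, stop, sign) runs of inspiratory(+)/expiratory(-) flow.

    Samples inside the hysteresis band inherit the previous direction, so
    small zero-crossing chatter does not split breaths.
    """
    sign = np.where(flow > threshold, 1, np.where(flow < -threshold, -1, 0))
    idx = np.nonzero(sign)[0]
    if idx.size == 0:
        return []
    # forward-fill zeros with the last decided direction (vectorised)
    carrier = np.where(sign != 0, np.arange(sign.size), 0)
    np.maximum.accumulate(carrier, out=carrier)
    filled = sign[carrier]
    filled[: idx[0]] = sign[idx[0]]
    changes = np.nonzero(np.diff(filled))[0] + 1
    bounds = np.concatenate(([0], changes, [filled.size]))
    return [(int(bounds[k]), int(bounds[k + 1]), int(filled[bounds[k]])) for k in range(len(bounds) - 1)]


def _merge_small(
    segs: list[tuple[int, int, int]], rec: RawRecording, cfg: AnalysisConfig
) -> list[tuple[int, int, int]]:
    """Merge segments below the volume/duration minima into their neighbours."""
    dt = rec.dt

    def ok(s: tuple[int, int, int]) -> bool:
        vol = segment_volume_ml(rec, s[0], s[1])
        dur = (s[1] - s[0]) * dt
        return vol >= cfg.min_breath_volume_ml and dur >= cfg.min_breath_duration_s

    segs = list(segs)
    changed = True
    while changed and len(segs) > 1:
        changed = False
        for i, s in enumerate(segs):
            if ok(s):
                continue
            # merge into the previous segment if any, else the next
            if i > 0:
                prev = segs[i - 1]
                segs[i - 1] = (prev[0], s[1], prev[2])
            else:
                nxt = segs[i + 1]
                segs[i + 1] = (s[0], nxt[1], nxt[2])
            del segs[i]
            changed = True
            break
    # collapse any neighbouring same-sign segments the merge produced
    out: list[tuple[int, int, int]] = []
    for s in segs:
        if out and out[-1][2] == s[2]:
            out[-1] = (out[-1][0], s[1], s[2])
        else:
            out.append(s)
    return out


def _end_tidal(rec: RawRecording, i_exp: int, i_end: int, window_fraction: float) -> float:
    v = phase_volume_trace(rec, i_exp, i_end)
    total = v[-1]
    mask = v >= (1.0 - window_fraction) * total
    return float(np.median(rec.molar_mass[i_exp:i_end][mask]))


def detect_breaths(rec: RawRecording, cfg: AnalysisConfig | None = None) -> list[Breath]:
    """Segment the recording into breaths (inspiration followed by expiration)."""
    cfg = cfg or AnalysisConfig()
    if rec.duration_s < 2.0:
        raise BreathDetectionError("recording shorter than 2 s")
    scale = float(np.percentile(np.abs(rec.flow), 95))
    if scale <= 0.0:
        raise BreathDetectionError("no breaths: flow is identically zero")
    threshold = cfg.flow_hysteresis_fraction * scale
    segs = _segments(rec.flow, threshold)
    segs = _merge_small(segs, rec, cfg)
    breaths: list[Breath] = []
    for k in range(len(segs) - 1):
        a, b = segs[k], segs[k + 1]
        if a[2] != 1 or b[2] != -1:
            continue
        i_insp, i_exp, i_end = a[0], a[1], b[1]
        vi = segment_volume_ml(rec, i_insp, i_exp)
        ve = segment_volume_ml(rec, i_exp, i_end)
        if vi < cfg.min_breath_volume_ml or ve < cfg.min_breath_volume_ml:
            continue
        breaths.append(
            Breath(
                i_insp=i_insp,
                i_exp=i_exp,
                i_end=i_end,
                inspired_volume_ml=vi,
                expired_volume_ml=ve,
                end_tidal_molar_mass=_end_tidal(rec, i_exp, i_end, cfg.end_tidal_window_fraction),
                duration_s=(i_end - i_insp) * rec.dt,
            )
        )
    if not breaths:
        raise BreathDetectionError("no breaths detected")
    return breaths


def detect_phases(
    rec: RawRecording, breaths: list[Breath], cfg: AnalysisConfig | None = None
) -> PhaseAnnotation:
    """Assign breaths to pre-phase, washin and washout from end-tidal molar mass."""
    cfg = cfg or AnalysisConfig()
    if len(breaths) < 3:
        raise PhaseError("need at least 3 breaths for phase detection")
    ets = np.array([b.end_tidal_molar_mass for b in breaths])
    base = ets[: min(3, len(ets))]
    spread = 1.4826 * float(np.median(np.abs(base - np.median(base))))
    threshold = max(cfg.phase_jump_k * spread, cfg.phase_jump_min_gmol)
    baseline = float(np.median(base))
    washin_start = None
    for i in range(1, len(ets)):
        if ets[i] > baseline + threshold:
            washin_start = i
            break
    if washin_start is None or washin_start < 1:
        raise PhaseError("missing washin: no end-tidal molar-mass rise found")
    # refine the baseline over the full pre-phase
    baseline = float(np.median(ets[:washin_start]))
    washout_start = None
    run_max = ets[washin_start]
    for i in range(washin_start + 1, len(ets)):
        if ets[i] < run_max - threshold:
            washout_start = i
            break
        run_max = max(run_max, ets[i])
    if washout_start is None:
        raise PhaseError("missing washout: end-tidal molar mass never falls")
    n_plateau = min(cfg.washin_plateau_breaths, washout_start - washin_start)
    plateau = ets[washout_start - n_plateau : washout_start]
    rel_spread = float((np.max(plateau) - np.min(plateau)) / np.median(plateau))
    washin_complete = (
        n_plateau >= cfg.washin_plateau_breaths and rel_spread < cfg.washin_plateau_tolerance
    )
    return PhaseAnnotation(
        pre=(0, washin_start),
        washin=(washin_start, washout_start),
        washout=(washout_start, len(breaths)),
        washin_complete=washin_complete,
    )
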
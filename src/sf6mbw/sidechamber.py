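"""Side-chamber correction of the normalised tracer signal.

The flowmeter's measurement path includes semi-accessible side chambers
whose gas exchanges with the main stream only gradually, so the normalised
signal ``x`` is a blend of the main-stream tracer fraction and a lagging
chamber state.  During washout *inspirations* the main stream is known to be
tracer-free, so whatever signal remains is the chamber contribution.  Each
washout inspiration is therefore fitted with a first-order washout curve
``s(v) = a * exp(-v / lambda)`` in inspired volume ``v`` (the chamber is
flushed by through-flow, not by time).  The per-inspiration estimates are
interpolated across expirations to give a continuous minimum (0%-SF6) curve
over the whole washout.  The corresponding maximum curve is an affine
transform of the minimum curve anchored at two instants where both main
stream and chambers are known: the first washin inspiration (main stream at
the tracer fraction, chambers still clean — fixing the intercept) and the
end-of-washin plateau (both at the tracer fraction — fixing the slope).
Solving the blend for the main-stream concentration yields the final SF6
signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import ScalingDegenerateError, SF6MBWError
from .signal_io import AnalysisConfig
from .tidal import NormalizedSignal

__all__ = [
    "InspirationFit",
    "SideChamberCurves",
    "SF6Signal",
    "fit_inspiration_minimum",
    "fit_washin_anchor",
    "interpolate_minimum_curve",
    "scale_maximum_curve",
    "extract_sf6",
    "apply_side_chamber_correction",
]

_LAM_BOUNDS = (0.5, 500.0)  # mL of through-flow

#: fraction of a half-breath's volume trimmed at both ends before fitting;
#: samples near flow zero crossings sit inside the detector's hysteresis band
#: and can carry the neighbouring phase's gas
_EDGE_TRIM = 0.02


def _trim_edges(v: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    v_end = v[-1]
    keep = (v >= _EDGE_TRIM * v_end) & (v <= (1.0 - _EDGE_TRIM) * v_end)
    if np.sum(keep) < 8:
        return v, x
    return v[keep], x[keep]


def _isotonic_decreasing(y: np.ndarray) -> np.ndarray:
    """Least-squares monotone non-increasing fit (pool adjacent violators)."""
    vals = list(-np.asarray(y, dtype=float))
    weights = [1.0] * len(vals)
    blocks: list[tuple[float, float, int]] = []  # (mean, weight, count)
    for v, w in zip(vals, weights):
        mean, weight, count = v, w, 1
        while blocks and blocks[-1][0] > mean:
            m2, w2, c2 = blocks.pop()
            weight_new = weight + w2
            mean = (mean * weight + m2 * w2) / weight_new
            weight, count = weight_new, count + c2
        blocks.append((mean, weight, count))
    out = np.empty(len(vals))
    pos = 0
    for mean, _, count in blocks:
        out[pos : pos + count] = mean
        pos += count
    return -out


@dataclass
class InspirationFit:
    """Chamber carry-over model for one washout inspiration."""

    breath: int
    a: float  # carry-over at inspiration start (normalised units)
    lam_ml: float  # chamber washout volume constant
    v_end_ml: float
    fallback: bool = False
    v_grid: np.ndarray | None = None  # isotonic fallback support
    y_grid: np.ndarray | None = None

    def __call__(self, v: np.ndarray) -> np.ndarray:
        if self.fallback:
            return np.interp(v, self.v_grid, self.y_grid)
        return self.a * np.exp(-np.asarray(v) / self.lam_ml)

    @property
    def end_value(self) -> float:
        return float(self(np.array([self.v_end_ml]))[0])


@dataclass
class SideChamberCurves:
    """Minimum/maximum boundary curves aligned with the normalised samples."""

    minimum: np.ndarray
    maximum: np.ndarray
    alpha: float
    beta: float
    fits: list[InspirationFit]


@dataclass
class SF6Signal:
    """Extracted SF6 mole-fraction trace over the washout."""

    index: np.ndarray
    sf6: np.ndarray  # clamped to [0, clamp_ceiling_factor * c_max]
    sf6_unclamped: np.ndarray  # for integral outcomes: clamping rectifies noise
    phase: np.ndarray
    v_ml: np.ndarray
    breath: np.ndarray
    dt: float
    end_tidal: dict[int, float]
    washout_breaths: tuple[int, ...]
    initial_breath: int | None
    initial_end_tidal: float
    clamped_fraction: float


def _exp_model(v: np.ndarray, a: float, lam: float) -> np.ndarray:
    return a * np.exp(-v / lam)


def fit_inspiration_minimum(
    norm: NormalizedSignal, washout_breaths: list[int]
) -> list[InspirationFit]:
    """Fit ``a * exp(-v/lambda)`` to each washout inspiration's signal."""
    fits: list[InspirationFit] = []
    for bi in washout_breaths:
        sel = norm.samples_of(bi, phase=1)
        if sel.size == 0:
            continue
        v, x = _trim_edges(norm.v_ml[sel], norm.x[sel])
        fits.append(_fit_one(bi, v, x))
    if not fits:
        raise SF6MBWError("no washout inspirations to fit")
    return fits


def _fit_one(bi: int, v: np.ndarray, x: np.ndarray) -> InspirationFit:
    v_end = float(v[-1])
    if v.size < 8:
        return _fallback_fit(bi, v, x)
    if np.all(x <= 0.0):
        return InspirationFit(breath=bi, a=0.0, lam_ml=15.0, v_end_ml=v_end)
    a0 = float(np.clip(np.median(x[: max(3, x.size // 10)]), 1e-4, 1.5))
    try:
        popt, _ = curve_fit(
            _exp_model, v, x, p0=(a0, 15.0),
            bounds=([0.0, _LAM_BOUNDS[0]], [2.0, _LAM_BOUNDS[1]]), maxfev=5000,
        )
    except (RuntimeError, ValueError):
        return _fallback_fit(bi, v, x)
    a, lam = float(popt[0]), float(popt[1])
    if lam >= 0.98 * _LAM_BOUNDS[1]:  # lambda pinned at the bound: model misfit
        return _fallback_fit(bi, v, x)
    return InspirationFit(breath=bi, a=a, lam_ml=lam, v_end_ml=v_end)


def _fallback_fit(bi: int, v: np.ndarray, x: np.ndarray) -> InspirationFit:
    order = np.argsort(v)
    y = np.clip(_isotonic_decreasing(x[order]), 0.0, None)
    return InspirationFit(
        breath=bi, a=float(y[0]), lam_ml=float("nan"), v_end_ml=float(v[order][-1]),
        fallback=True, v_grid=v[order], y_grid=y,
    )


def fit_washin_anchor(norm_anchor: NormalizedSignal, breath: int) -> float:
    """Intercept of the first washin inspiration at zero inspired volume.

    At that instant the main stream already carries the full tracer fraction
    while the chambers are still clean, so the extrapolated intercept equals
    the main-stream share of the measured signal (1 - chamber fraction).
    The rising chamber content during the inspiration is absorbed by the
    exponential term of ``A - B * exp(-v/lambda)``.
    """
    sel = norm_anchor.samples_of(breath, phase=1)
    v, x = _trim_edges(norm_anchor.v_ml[sel], norm_anchor.x[sel])
    if v.size < 8:
        raise ScalingDegenerateError("first washin inspiration too short to anchor")

    def model(vv, A, B, lam):
        return A - B * np.exp(-vv / lam)

    try:
        popt, _ = curve_fit(
            model, v, x, p0=(float(x[-1]), max(float(x[-1] - x[0]), 0.01), 15.0),
            bounds=([0.0, 0.0, _LAM_BOUNDS[0]], [2.0, 2.0, _LAM_BOUNDS[1]]), maxfev=5000,
        )
        alpha = float(popt[0] - popt[1])
    except (RuntimeError, ValueError):
        alpha = float(np.median(x[: max(3, x.size // 10)]))
    if not (0.2 <= alpha <= 1.2):
        raise ScalingDegenerateError(f"washin anchor intercept {alpha:.3f} outside [0.2, 1.2]")
    return alpha


def interpolate_minimum_curve(
    fits: list[InspirationFit], norm: NormalizedSignal
) -> np.ndarray:
    """Continuous 0%-SF6 curve over all samples of ``norm``.

    Inspiration samples of a fitted breath take the fit's value at their
    inspired volume; expiration samples are linear in time between the end
    value of the preceding fit and the start value ``a`` of the following
    fit.  Samples before the first fitted breath take its ``a`` (the chamber
    is still at the washin plateau there); samples after the last fit extend
    its end value.
    """
    if len(fits) < 2:
        raise SF6MBWError("need at least 2 inspiration fits to interpolate")
    by_breath = {f.breath: f for f in fits}
    fitted = sorted(by_breath)
    m = np.empty_like(norm.x)
    breaths_in_norm = np.unique(norm.breath)
    for bi in breaths_in_norm:
        f = by_breath.get(bi)
        sel_i = norm.samples_of(bi, phase=1)
        sel_e = norm.samples_of(bi, phase=-1)
        if f is None:
            # before the first washout inspiration the chambers still hold the
            # plateau gas: constant at the first fit's starting value
            anchor = by_breath[fitted[0]].a if bi < fitted[0] else by_breath[fitted[-1]].end_value
            m[sel_i] = anchor
            m[sel_e] = anchor
            continue
        m[sel_i] = f(norm.v_ml[sel_i])
        if sel_e.size == 0:
            continue
        nxt = next((k for k in fitted if k > bi), None)
        start_val = f.end_value
        end_val = by_breath[nxt].a if nxt is not None else start_val
        t = norm.index[sel_e].astype(float)
        if t[-1] > t[0]:
            frac = (t - t[0]) / (t[-1] - t[0])
        else:
            frac = np.zeros_like(t)
        m[sel_e] = start_val + (end_val - start_val) * frac
    return m


def scale_maximum_curve(
    min_curve: np.ndarray,
    norm: NormalizedSignal,
    fits: list[InspirationFit],
    alpha: float,
    anchor_breath: int,
    cfg: AnalysisConfig | None = None,
) -> tuple[np.ndarray, float]:
    """Maximum-signal curve ``alpha + beta * min_curve`` from the two anchors.

    ``alpha`` comes from the washin-side anchor; ``beta`` is set so that the
    end-tidal plateau of ``anchor_breath`` (the last washin breath: main
    stream and chambers both at the tracer fraction) extracts to exactly the
    tracer maximum.  With clean chambers (carry-over below noise) the system
    is degenerate and beta falls back to 1, the no-chamber limit.
    """
    cfg = cfg or AnalysisConfig()
    a1 = sorted(fits, key=lambda f: f.breath)[0].a
    x_et = _end_tidal_of(norm, anchor_breath, norm.x, cfg.end_tidal_window_fraction)
    m_et = _end_tidal_of(norm, anchor_breath, min_curve, cfg.end_tidal_window_fraction)
    floor = cfg.chamber_detection_floor
    if cfg.side_chamber_scaling == "multiplicative":
        if m_et < floor:
            raise ScalingDegenerateError("multiplicative scaling needs a nonzero chamber anchor")
        beta = (x_et - 0.0) / m_et
        return beta * min_curve, beta
    if m_et < floor or a1 < floor:
        beta = 1.0  # no measurable chamber carry-over
    else:
        beta = (x_et - alpha) / m_et
        if beta <= 0.0:
            raise ScalingDegenerateError(f"anchor system gave beta={beta:.3f} <= 0")
    max_curve = alpha + beta * min_curve
    if np.any(max_curve < min_curve):
        raise ScalingDegenerateError("maximum curve fell below minimum curve")
    return max_curve, beta


def _end_tidal_of(
    norm: NormalizedSignal, breath: int, values: np.ndarray, window_fraction: float
) -> float:
    sel = norm.samples_of(breath, phase=-1)
    if sel.size == 0:
        raise SF6MBWError(f"breath {breath} has no expiration samples")
    v = norm.v_ml[sel]
    mask = v >= (1.0 - window_fraction) * v[-1]
    return float(np.median(values[sel][mask]))


def extract_sf6(
    norm: NormalizedSignal,
    min_curve: np.ndarray,
    max_curve: np.ndarray,
    c_max: float,
    washout_breaths: list[int],
    initial_breath: int | None = None,
    cfg: AnalysisConfig | None = None,
) -> SF6Signal:
    """Solve the chamber blend for the main-stream SF6 mole fraction.

    ``SF6 = c_max * (x - min) / (max - min)``, clamped to
    [0, clamp_ceiling_factor * c_max] with the clamped fraction reported.
    """
    cfg = cfg or AnalysisConfig()
    den = max_curve - min_curve
    if np.any(den < cfg.extraction_denominator_min):
        raise SF6MBWError(
            f"extraction denominator below {cfg.extraction_denominator_min}"
        )
    u = (norm.x - min_curve) / den
    sf6_raw = c_max * u
    ceiling = cfg.clamp_ceiling_factor * c_max
    sf6 = np.clip(sf6_raw, 0.0, ceiling)
    # output is clamped at zero, but only samples outside the diagnostic band
    # [-0.25, 1.25]*c_max count as clamped: noise straddling zero is expected
    clamped = float(np.mean((sf6_raw < -0.25 * c_max) | (sf6_raw > ceiling)))
    end_tidal: dict[int, float] = {}
    for bi in np.unique(norm.breath):
        sel = norm.samples_of(int(bi), phase=-1)
        if sel.size == 0:
            continue
        v = norm.v_ml[sel]
        mask = v >= (1.0 - cfg.end_tidal_window_fraction) * v[-1]
        end_tidal[int(bi)] = float(np.median(sf6[sel][mask]))
    if initial_breath is not None and initial_breath in end_tidal:
        initial_et = end_tidal[initial_breath]
    else:
        initial_et = end_tidal[min(washout_breaths)]
    return SF6Signal(
        index=norm.index,
        sf6=sf6,
        sf6_unclamped=sf6_raw,
        phase=norm.phase,
        v_ml=norm.v_ml,
        breath=norm.breath,
        dt=norm.dt,
        end_tidal=end_tidal,
        washout_breaths=tuple(washout_breaths),
        initial_breath=initial_breath,
        initial_end_tidal=initial_et,
        clamped_fraction=clamped,
    )


def apply_side_chamber_correction(
    norm_main: NormalizedSignal,
    norm_anchor: NormalizedSignal,
    washout_breaths: list[int],
    anchor_washin_first: int,
    anchor_washin_last: int,
    c_max: float,
    cfg: AnalysisConfig | None = None,
) -> tuple[SF6Signal, SideChamberCurves]:
    """Full correction: fits, interpolation, scaling and extraction."""
    cfg = cfg or AnalysisConfig()
    fits = fit_inspiration_minimum(norm_main, washout_breaths)
    a1 = sorted(fits, key=lambda f: f.breath)[0].a
    if a1 < cfg.chamber_detection_floor:
        # carry-over at the artefact level: treat the chambers as absent
        # rather than subtracting a fitted noise pattern
        min_curve = np.zeros_like(norm_main.x)
    else:
        min_curve = interpolate_minimum_curve(fits, norm_main)
    alpha = fit_washin_anchor(norm_anchor, anchor_washin_first)
    max_curve, beta = scale_maximum_curve(
        min_curve, norm_main, fits, alpha, anchor_washin_last, cfg
    )
    sf6 = extract_sf6(
        norm_main, min_curve, max_curve, c_max, washout_breaths,
        initial_breath=anchor_washin_last, cfg=cfg,
    )
    curves = SideChamberCurves(
        minimum=min_curve, maximum=max_curve, alpha=alpha, beta=beta, fits=fits
    )
    return sf6, curves
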
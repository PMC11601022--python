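"""Tidal-change correction: normalise molar mass against boundary respirograms.

The raw molar-mass trace is confounded by tidal temperature, humidity and
CO2/O2 swings.  Those confounders repeat breath by breath as a function of
the volume moved within the breath, while the tracer content differs between
known phases: during the pre-phase the gas holds 0% SF6 and at the end of a
complete washin it holds the full tracer fraction (typically 4%).

For each of the four boundary conditions (0%/max SF6 x inspiration/
expiration) a *respirogram* is built: contributing breaths are re-indexed by
cumulative volume within the breath, binned on a common volume grid, and the
per-bin median across breaths taken.  Each washout sample is then expressed
as its linear position between the matching-phase 0% and max-SF6 boundary
traces, which cancels every confounder that is a stable function of
volume-in-breath and leaves a dimensionless fraction-of-maximum signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .breaths import Breath, PhaseAnnotation, phase_volume_trace
from .errors import BoundaryIndistinctError, InsufficientBoundaryBreathsError
from .signal_io import AnalysisConfig, RawRecording

__all__ = ["Respirogram", "NormalizedSignal", "build_respirograms", "apply_tcc"]

#: boundary labels
MIN_SF6 = "min_sf6"
MAX_SF6 = "max_sf6"
INSPIRATION = "inspiration"
EXPIRATION = "expiration"


@dataclass(frozen=True)
class Respirogram:
    """Median molar mass vs volume-in-breath for one boundary condition."""

    centers_ml: np.ndarray
    values_gmol: np.ndarray
    boundary: str
    phase: str
    n_breaths: int

    def __post_init__(self) -> None:
        if self.n_breaths < 3:
            raise InsufficientBoundaryBreathsError(
                f"respirogram ({self.boundary}, {self.phase}) built from "
                f"{self.n_breaths} breaths; need >= 3"
            )
        if np.any(np.diff(self.centers_ml) <= 0) or not np.all(np.isfinite(self.values_gmol)):
            raise ValueError("respirogram grid must be increasing with finite values")

    def __call__(self, v_ml: np.ndarray) -> np.ndarray:
        """Linear interpolation, clamped to the first/last bin beyond range."""
        return np.interp(v_ml, self.centers_ml, self.values_gmol)

    @property
    def max_volume_ml(self) -> float:
        return float(self.centers_ml[-1])


@dataclass
class NormalizedSignal:
    """Per-sample normalised tracer signal with phase/volume tags.

    ``x`` is 0 on the 0%-SF6 boundary trace and 1 on the max-SF6 trace.
    ``phase`` is +1 for inspiration samples, -1 for expiration.
    """

    index: np.ndarray  # sample indices into the recording
    x: np.ndarray
    phase: np.ndarray
    v_ml: np.ndarray  # cumulative volume within the current half-breath
    breath: np.ndarray  # breath index per sample
    over_range: np.ndarray  # True where v exceeded the respirogram grid
    dt: float
    flagged_breaths: tuple[int, ...] = ()

    def samples_of(self, breath_idx: int, phase: int | None = None) -> np.ndarray:
        m = self.breath == breath_idx
        if phase is not None:
            m &= self.phase == phase
        return np.nonzero(m)[0]


def _breath_phase_samples(
    rec: RawRecording, b: Breath, phase: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(sample indices, volume-in-phase, molar mass) for one half-breath."""
    if phase == INSPIRATION:
        start, stop = b.i_insp, b.i_exp
    else:
        start, stop = b.i_exp, b.i_end
    idx = np.arange(start, stop)
    v = phase_volume_trace(rec, start, stop)
    return idx, v, rec.molar_mass[start:stop]


def _bin_breaths(
    rec: RawRecording, breaths: Iterable[Breath], phase: str, bin_ml: float
) -> tuple[np.ndarray, np.ndarray, int]:
    """Common-grid per-bin medians across breaths (bin-mean within a breath)."""
    breaths = list(breaths)
    vmax = max(
        (b.inspired_volume_ml if phase == INSPIRATION else b.expired_volume_ml) for b in breaths
    )
    n_bins = max(int(np.ceil(vmax / bin_ml)), 1)
    edges = np.arange(n_bins + 1) * bin_ml
    centers = 0.5 * (edges[:-1] + edges[1:])
    per_breath = np.full((len(breaths), n_bins), np.nan)
    for i, b in enumerate(breaths):
        _, v, mm = _breath_phase_samples(rec, b, phase)
        which = np.clip((v / bin_ml).astype(int), 0, n_bins - 1)
        sums = np.bincount(which, weights=mm, minlength=n_bins)
        counts = np.bincount(which, minlength=n_bins)
        got = counts > 0
        per_breath[i, got] = sums[got] / counts[got]
    with np.errstate(all="ignore"):
        values = np.nanmedian(per_breath, axis=0)
    # a breath contributes only to bins inside its own volume range; bins no
    # breath reached are interpolated from their neighbours
    valid = np.isfinite(values)
    if not np.all(valid):
        values = np.interp(centers, centers[valid], values[valid])
    return centers, values, len(breaths)


def build_respirograms(
    rec: RawRecording,
    breaths: list[Breath],
    phases: PhaseAnnotation,
    cfg: AnalysisConfig | None = None,
) -> dict[tuple[str, str], Respirogram]:
    """Build the four boundary respirograms (0%/max SF6 x insp/exp).

    The 0%-SF6 boundary uses the last pre-phase breaths, the max-SF6 boundary
    the last washin breaths before the washout (the plateau that the
    washin-complete check guards).
    """
    cfg = cfg or AnalysisConfig()
    n = cfg.boundary_breaths
    pre_lo, pre_hi = phases.pre
    wi_lo, wi_hi = phases.washin
    groups = {
        MIN_SF6: breaths[max(pre_lo, pre_hi - n) : pre_hi],
        MAX_SF6: breaths[max(wi_lo, wi_hi - n) : wi_hi],
    }
    out: dict[tuple[str, str], Respirogram] = {}
    for boundary, grp in groups.items():
        if len(grp) < 3:
            raise InsufficientBoundaryBreathsError(
                f"only {len(grp)} breaths available for the {boundary} boundary"
            )
        for phase in (INSPIRATION, EXPIRATION):
            centers, values, m = _bin_breaths(rec, grp, phase, cfg.respirogram_bin_ml)
            out[(boundary, phase)] = Respirogram(
                centers_ml=centers, values_gmol=values, boundary=boundary, phase=phase, n_breaths=m
            )
    return out


def apply_tcc(
    rec: RawRecording,
    breaths: list[Breath],
    respirograms: Mapping[tuple[str, str], Respirogram],
    breath_indices: Iterable[int],
    cfg: AnalysisConfig | None = None,
) -> NormalizedSignal:
    """Normalise the selected breaths between the 0% and max-SF6 boundaries.

    Each sample with volume-in-breath ``v`` and phase ``p`` becomes
    ``x = (MM - MM0_p(v)) / (MMmax_p(v) - MM0_p(v))``.  Samples beyond the
    boundary volume range use the clamped boundary value and are flagged;
    breaths with more than ``tcc_overrange_breath_fraction`` flagged samples
    are reported in ``flagged_breaths``.
    """
    cfg = cfg or AnalysisConfig()
    idx_parts: list[np.ndarray] = []
    x_parts: list[np.ndarray] = []
    ph_parts: list[np.ndarray] = []
    v_parts: list[np.ndarray] = []
    b_parts: list[np.ndarray] = []
    ov_parts: list[np.ndarray] = []
    flagged: list[int] = []
    for bi in breath_indices:
        b = breaths[bi]
        n_over = 0
        n_tot = 0
        for phase, tag in ((INSPIRATION, 1), (EXPIRATION, -1)):
            idx, v, mm = _breath_phase_samples(rec, b, phase)
            lo = respirograms[(MIN_SF6, phase)]
            hi = respirograms[(MAX_SF6, phase)]
            mm0 = lo(v)
            mm4 = hi(v)
            den = mm4 - mm0
            if np.any(np.abs(den) < cfg.boundary_min_separation_gmol):
                raise BoundaryIndistinctError(
                    f"boundary traces indistinct (|separation| < "
                    f"{cfg.boundary_min_separation_gmol} g/mol) in breath {bi}, {phase}"
                )
            over = v > min(lo.max_volume_ml, hi.max_volume_ml)
            n_over += int(np.sum(over))
            n_tot += idx.size
            idx_parts.append(idx)
            x_parts.append((mm - mm0) / den)
            ph_parts.append(np.full(idx.size, tag, dtype=np.int8))
            v_parts.append(v)
            b_parts.append(np.full(idx.size, bi, dtype=int))
            ov_parts.append(over)
        if n_tot and n_over / n_tot > cfg.tcc_overrange_breath_fraction:
            flagged.append(bi)
    order = np.argsort(np.concatenate(idx_parts), kind="stable")
    return NormalizedSignal(
        index=np.concatenate(idx_parts)[order],
        x=np.concatenate(x_parts)[order],
        phase=np.concatenate(ph_parts)[order],
        v_ml=np.concatenate(v_parts)[order],
        breath=np.concatenate(b_parts)[order],
        over_range=np.concatenate(ov_parts)[order],
        dt=rec.dt,
        flagged_breaths=tuple(flagged),
    )
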
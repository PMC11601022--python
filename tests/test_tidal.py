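"""Boundary respirograms and the tidal-change correction."""

import numpy as np
import pytest

from sf6mbw.breaths import detect_breaths, detect_phases
from sf6mbw.errors import BoundaryIndistinctError, InsufficientBoundaryBreathsError
from sf6mbw.signal_io import AnalysisConfig, RawRecording
from sf6mbw.simulator import SimulationConfig, simulate_recording
from sf6mbw.tidal import (
    EXPIRATION,
    INSPIRATION,
    MAX_SF6,
    MIN_SF6,
    Respirogram,
    apply_tcc,
    build_respirograms,
)


def _flat_respirograms(mm0=29.0, mm4=33.7, vmax=40.0):
    centers = np.arange(0.5, vmax, 1.0)
    out = {}
    for phase in (INSPIRATION, EXPIRATION):
        out[(MIN_SF6, phase)] = Respirogram(centers, np.full(centers.size, mm0),
                                            MIN_SF6, phase, 5)
        out[(MAX_SF6, phase)] = Respirogram(centers, np.full(centers.size, mm4),
                                            MAX_SF6, phase, 5)
    return out


def _sine_recording(mm_value, n_breaths=4, sr=200.0):
    t = np.arange(int(n_breaths * 2 * sr)) / sr  # 2 s breaths
    flow = 0.05 * np.sin(2 * np.pi * 0.5 * t)
    n = t.size
    return RawRecording(time=t, flow=flow, molar_mass=np.full(n, mm_value),
                        sampling_rate_hz=sr)


@pytest.mark.parametrize(
    "mm,expected", [(29.0, 0.0), (33.7, 1.0), (31.35, 0.5)],
    ids=["on-min-trace", "on-max-trace", "midpoint"],
)
def test_tcc_identity_cases(mm, expected):
    """Samples lying on a boundary trace map to 0/1; midpoints to 0.5."""
    rec = _sine_recording(mm)
    breaths = detect_breaths(rec)
    norm = apply_tcc(rec, breaths, _flat_respirograms(), list(range(len(breaths))))
    np.testing.assert_allclose(norm.x, expected, atol=1e-12)


def test_tcc_rejects_indistinct_boundaries():
    rec = _sine_recording(29.0)
    breaths = detect_breaths(rec)
    close = _flat_respirograms(mm0=29.0, mm4=29.02)
    with pytest.raises(BoundaryIndistinctError):
        apply_tcc(rec, breaths, close, [0])


def test_tcc_flags_over_range_breaths():
    rec = _sine_recording(29.0)
    breaths = detect_breaths(rec)
    small_grid = _flat_respirograms(vmax=10.0)  # breaths move ~32 mL
    norm = apply_tcc(rec, breaths, small_grid, [0, 1])
    assert norm.over_range.mean() > 0.5
    assert 0 in norm.flagged_breaths and 1 in norm.flagged_breaths


def test_respirogram_needs_three_breaths(std_sim):
    rec, _ = std_sim
    breaths = detect_breaths(rec)
    centers = np.arange(0.5, 30.0, 1.0)
    with pytest.raises(InsufficientBoundaryBreathsError):
        Respirogram(centers, np.full(centers.size, 29.0), MIN_SF6, INSPIRATION, 2)


def test_max_boundary_lies_above_min_boundary(std_result):
    """4% SF6 raises the molar mass at every shared volume bin."""
    resp = std_result.respirograms
    for phase in (INSPIRATION, EXPIRATION):
        lo = resp[(MIN_SF6, phase)]
        hi = resp[(MAX_SF6, phase)]
        shared = min(lo.max_volume_ml, hi.max_volume_ml)
        grid = np.arange(0.5, shared, 1.0)
        assert np.all(hi(grid) > lo(grid) + 3.0)  # ~4.7 g/mol separation


def test_respirogram_median_robust_to_one_corrupt_breath(noiseless_sim):
    """With 1 of 5 contributing breaths corrupted the per-bin median is unchanged."""
    rec, truth = noiseless_sim
    breaths = detect_breaths(rec)
    phases = detect_phases(rec, breaths)
    clean = build_respirograms(rec, breaths, phases)
    bad = rec.molar_mass.copy()
    victim = breaths[phases.pre[1] - 2]  # one of the five boundary breaths
    bad[victim.i_insp : victim.i_end] += 5.0
    rec_bad = RawRecording(time=rec.time, flow=rec.flow, molar_mass=bad,
                           sampling_rate_hz=rec.sampling_rate_hz, meta=rec.meta)
    # same segmentation and phase ranges: only the medians are being probed
    corrupt = build_respirograms(rec_bad, breaths, phases)
    for phase in (INSPIRATION, EXPIRATION):
        a = clean[(MIN_SF6, phase)].values_gmol
        b = corrupt[(MIN_SF6, phase)].values_gmol
        np.testing.assert_allclose(a, b, atol=1e-9)


def test_noiseless_respirogram_matches_single_breath(noiseless_sim):
    """Identical noiseless breaths: the median trace equals any one of them."""
    rec, _ = noiseless_sim
    breaths = detect_breaths(rec)
    phases = detect_phases(rec, breaths)
    resp = build_respirograms(rec, breaths, phases)
    r = resp[(MIN_SF6, EXPIRATION)]
    b = breaths[phases.pre[1] - 1]
    from sf6mbw.breaths import phase_volume_trace

    v = phase_volume_trace(rec, b.i_exp, b.i_end)
    mm = rec.molar_mass[b.i_exp : b.i_end]
    inner = (v > 2.0) & (v < v[-1] - 2.0)
    np.testing.assert_allclose(r(v[inner]), mm[inner], atol=0.05)


def test_confounder_cancellation_on_held_out_phases(std_sim):
    """Pre-phase maps near 0 and the washin plateau near 1 despite tidal
    temperature and humidity swings."""
    rec, _ = std_sim
    breaths = detect_breaths(rec)
    phases = detect_phases(rec, breaths)
    resp = build_respirograms(rec, breaths, phases)
    pre_eval = list(range(2, phases.pre[1] - 5))  # not used for the boundary
    plat_eval = list(range(phases.washin[1] - 10, phases.washin[1] - 5))
    x_pre = apply_tcc(rec, breaths, resp, pre_eval).x
    x_plat = apply_tcc(rec, breaths, resp, plat_eval).x
    assert np.mean(np.abs(x_pre)) < 0.02
    assert np.mean(np.abs(x_plat - 1.0)) < 0.02
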
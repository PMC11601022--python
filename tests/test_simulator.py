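"""Forward-model contracts: determinism, conservation, exact limits, grid."""

import dataclasses
import math

import numpy as np
import pytest

from sf6mbw.pipeline import analyze_recording
from sf6mbw.simulator import SimulationConfig, condition_grid, simulate_recording


def test_same_seed_bit_identical_different_seed_same_truth():
    cfg = SimulationConfig(seed=21)
    rec1, t1 = simulate_recording(cfg)
    rec2, t2 = simulate_recording(cfg)
    np.testing.assert_array_equal(rec1.molar_mass, rec2.molar_mass)
    np.testing.assert_array_equal(rec1.flow, rec2.flow)
    rec3, t3 = simulate_recording(dataclasses.replace(cfg, seed=22))
    assert not np.array_equal(rec1.molar_mass, rec3.molar_mass)
    # noise lives only in the recording; the gas transport is identical
    np.testing.assert_array_equal(t1.end_tidal_sf6, t3.end_tidal_sf6)


def test_tracer_mass_conservation(std_sim):
    """Distal content at washout start equals final content plus the net
    tracer volume that crossed the sensor plane."""
    _, truth = std_sim
    lhs = truth.content_washout_start_ml
    rhs = truth.content_final_ml + truth.net_expired_washout_ml
    assert abs(lhs - rhs) <= 1e-6 * lhs


@pytest.mark.parametrize("frc,vt,rr", [(80.0, 30.0, 30.0), (210.0, 50.0, 20.0)])
def test_exact_model_limit_recovers_frc(frc, vt, rr):
    cfg = SimulationConfig(frc_ml=(frc,), vt_ml=vt, rr_bpm=rr, chamber_fraction=0.0,
                           noise_mm_sd=0.0, noise_flow_sd=0.0, seed=1)
    rec, truth = simulate_recording(cfg)
    res = analyze_recording(rec)
    assert abs(res.outcomes.frc_ml - frc) / frc < 0.01


def test_ground_truth_follows_geometric_dilution():
    """Single compartment, no dead space: end-tidal follows C * r^n exactly."""
    frc, vt = 100.0, 30.0
    cfg = SimulationConfig(frc_ml=(frc,), vt_ml=vt, dead_space_ml=0.0,
                           noise_mm_sd=0.0, noise_flow_sd=0.0, seed=1)
    rec, truth = simulate_recording(cfg)
    r = frc / (frc + vt)
    ws = truth.washout[0]
    n = np.arange(1, truth.n_breaths - ws + 1)
    expected = truth.end_tidal_sf6[ws - 1] * r ** n
    np.testing.assert_allclose(truth.end_tidal_sf6[ws:], expected, rtol=1e-9)


def test_simulated_breaths_have_configured_tidal_volume():
    cfg = SimulationConfig(seed=4, noise_flow_sd=0.0)
    rec, truth = simulate_recording(cfg)
    vols = []
    edges = list(truth.breath_starts) + [rec.time.size]
    for lo, hi in zip(edges[:-1], edges[1:]):
        half = lo + (hi - lo) // 2
        vols.append(np.sum(rec.flow[lo:half]) * rec.dt * 1000.0)
    assert np.allclose(vols, 30.0, atol=0.2)


@pytest.mark.parametrize("profile", ["square", "harmonic"])
def test_alternative_flow_profiles_analyzable(profile):
    cfg = SimulationConfig(seed=6, flow_profile=profile)
    rec, truth = simulate_recording(cfg)
    res = analyze_recording(rec)
    assert abs(res.outcomes.frc_ml - truth.frc_true_ml) / truth.frc_true_ml < 0.05


def test_two_state_chamber_still_corrected():
    """Model mismatch stress: a two-time-constant chamber is still mostly
    removed by the single-exponential correction."""
    cfg = SimulationConfig(seed=8, chamber_two_state=True)
    rec, truth = simulate_recording(cfg)
    res = analyze_recording(rec)
    assert abs(res.outcomes.frc_ml - truth.frc_true_ml) / truth.frc_true_ml < 0.05


def test_condition_grid_layout():
    grid = condition_grid(replicates=6, base_seed=0)
    assert len(grid) == 60
    by = {(s.size, s.condition) for s in grid}
    assert len(by) == 10
    seeds = {s.config.seed for s in grid}
    assert len(seeds) == 60  # all replicates distinct
    cfg = {(s.size, s.condition): s.config for s in grid}
    small_std = cfg[("small", "standard")]
    assert (small_std.total_frc_ml, small_std.vt_ml, small_std.rr_bpm) == (80.0, 30.0, 30.0)
    large_std = cfg[("large", "standard")]
    assert (large_std.total_frc_ml, large_std.vt_ml, large_std.rr_bpm) == (210.0, 50.0, 20.0)
    assert cfg[("small", "+RR")].rr_bpm == pytest.approx(30.0 * 1.66)  # +66%
    assert cfg[("large", "+RR")].rr_bpm == pytest.approx(30.0)  # +50%
    assert cfg[("small", "+VT")].vt_ml == 50.0
    assert cfg[("large", "+VT")].vt_ml == 80.0  # +60%
    assert cfg[("small", "-T")].bath_temperature_k == pytest.approx(293.15)
    vi = cfg[("large", "+VI")]
    assert len(vi.frc_ml) == 2 and vi.total_frc_ml == 210.0
    assert vi.ventilation_fractions != (0.5, 0.5)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(ventilation_fractions=(0.5, 0.4), frc_ml=(40.0, 40.0))
    with pytest.raises(ValueError):
        SimulationConfig(vt_ml=-5.0)
    with pytest.raises(ValueError):
        SimulationConfig(dead_space_ml=35.0)  # exceeds VT
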
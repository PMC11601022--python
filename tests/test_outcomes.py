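"""End-of-test rule, FRC/CEV/LCI computation and flow correction."""

import math

import numpy as np
import pytest

from sf6mbw.errors import OutcomeError, WashoutIncompleteError
from sf6mbw.gas_physics import AmbientConditions, btps_factor
from sf6mbw.outcomes import (
    MBWOutcomes,
    btps_correct_flow,
    compute_frc,
    detect_end_of_test,
)
from sf6mbw.pipeline import analyze_recording, config_for
from sf6mbw.sidechamber import SF6Signal
from sf6mbw.signal_io import RawRecording
from sf6mbw.simulator import SimulationConfig, simulate_recording


def _sf6_series(values, initial=0.04):
    n = len(values)
    return SF6Signal(
        index=np.arange(n), sf6=np.asarray(values), sf6_unclamped=np.asarray(values),
        phase=-np.ones(n, dtype=np.int8), v_ml=np.zeros(n), breath=np.arange(n),
        dt=0.005, end_tidal={i: v for i, v in enumerate(values)},
        washout_breaths=tuple(range(n)), initial_breath=None, initial_end_tidal=initial,
        clamped_fraction=0.0,
    )


def test_end_of_test_on_printed_series():
    """4, 2, 1, 0.2, 0.09 % vs 2.5% of 4% -> the fifth breath (0.09 < 0.1)."""
    sig = _sf6_series([0.04, 0.02, 0.01, 0.002, 0.0009])
    assert detect_end_of_test(sig, 0.025) == 4  # 0-based -> breath 5


def test_end_of_test_never_reached():
    sig = _sf6_series([0.04, 0.02, 0.01])
    with pytest.raises(WashoutIncompleteError):
        detect_end_of_test(sig, 0.025)


def test_end_of_test_consensus_mode_skips_single_dips():
    sig = _sf6_series([0.04, 0.0009, 0.02, 0.0008, 0.0007, 0.0006])
    assert detect_end_of_test(sig, 0.025, consensus=False) == 1
    assert detect_end_of_test(sig, 0.025, consensus=True) == 3


@pytest.mark.parametrize("frc,vt", [(80.0, 30.0), (100.0, 30.0), (210.0, 50.0)])
def test_single_compartment_end_of_test_matches_geometric_oracle(frc, vt):
    """Detection breath equals ceil(ln 40 / ln((FRC+VA)/FRC)) for pure dilution."""
    cfg = SimulationConfig(
        frc_ml=(frc,), vt_ml=vt, rr_bpm=30.0, dead_space_ml=0.0, chamber_fraction=0.0,
        noise_mm_sd=0.0, noise_flow_sd=0.0, seed=9,
    )
    rec, truth = simulate_recording(cfg)
    res = analyze_recording(rec, config_for(rec))
    n_oracle = math.ceil(math.log(40.0) / math.log((frc + vt) / frc))
    assert res.outcomes.breath_count_to_end == n_oracle
    # LCI agrees with the closed form within one breath-equivalent of CEV/FRC
    assert abs(res.outcomes.lci_to - n_oracle * vt / frc) <= vt / frc


def test_dead_space_subtracts_exactly(noiseless_result, noiseless_sim):
    rec, _ = noiseless_sim
    res = noiseless_result
    frc0 = compute_frc(res.sf6, res.flow_corrected, rec, res.outcomes.end_of_test_breath, 0.0)
    frc46 = compute_frc(res.sf6, res.flow_corrected, rec, res.outcomes.end_of_test_breath, 4.6)
    assert frc0 - frc46 == pytest.approx(4.6, abs=1e-12)


def test_frc_invariant_under_time_rescaling(noiseless_sim):
    """Doubling all flows and halving time leaves the volume-domain analysis
    and hence FRC unchanged."""
    rec, truth = noiseless_sim
    fast = RawRecording(time=rec.time / 2.0, flow=2.0 * rec.flow,
                        molar_mass=rec.molar_mass,
                        sampling_rate_hz=2.0 * rec.sampling_rate_hz, meta=rec.meta)
    a = analyze_recording(rec).outcomes
    b = analyze_recording(fast).outcomes
    assert b.frc_ml == pytest.approx(a.frc_ml, rel=1e-6)
    assert b.cev_ml == pytest.approx(a.cev_ml, rel=1e-6)


def test_frc_rejects_non_falling_concentration(noiseless_result, noiseless_sim):
    rec, _ = noiseless_sim
    res = noiseless_result
    broken = _sf6_series([0.04, 0.04, 0.04])
    with pytest.raises(OutcomeError):
        compute_frc(broken, np.zeros(3), rec, 2, 0.0)


def test_lci_is_cev_over_frc_enforced():
    with pytest.raises(OutcomeError):
        MBWOutcomes(frc_ml=100.0, cev_ml=700.0, lci_to=6.0, end_of_test_breath=1,
                    breath_count_to_end=2, initial_end_tidal_sf6=0.04,
                    final_end_tidal_sf6=0.001, end_tidal_sf6=[0.001],
                    dead_space_ml=0.0, clamped_sample_fraction=0.0)
    ok = MBWOutcomes(frc_ml=100.0, cev_ml=700.0, lci_to=7.0, end_of_test_breath=1,
                     breath_count_to_end=2, initial_end_tidal_sf6=0.04,
                     final_end_tidal_sf6=0.001, end_tidal_sf6=[0.001],
                     dead_space_ml=0.0, clamped_sample_fraction=0.0)
    assert ok.lci_to == pytest.approx(ok.cev_ml / ok.frc_ml, rel=1e-12)


def test_btps_identity_in_atp_mode(std_sim):
    rec, _ = std_sim
    from sf6mbw.breaths import detect_breaths

    breaths = detect_breaths(rec)
    corrected = btps_correct_flow(rec, breaths, config_for(rec))  # atp default
    np.testing.assert_array_equal(corrected, rec.flow)


def test_btps_scales_phases_separately(std_sim):
    rec, _ = std_sim
    from sf6mbw.breaths import detect_breaths

    breaths = detect_breaths(rec)
    cfg = config_for(rec, volume_mode="btps", sensor_temperature_k=303.15)
    cond = rec.meta.ambient
    corrected = btps_correct_flow(rec, breaths, cfg, cond)
    f_in = btps_factor(cond, "inspiration")
    f_ex = btps_factor(cond, "expiration", sensor_temperature_k=303.15)
    b = breaths[5]
    np.testing.assert_allclose(corrected[b.i_insp : b.i_exp],
                               rec.flow[b.i_insp : b.i_exp] * f_in, rtol=1e-12)
    np.testing.assert_allclose(corrected[b.i_exp : b.i_end],
                               rec.flow[b.i_exp : b.i_end] * f_ex, rtol=1e-12)
    assert f_in > 1.0 and f_ex > 1.0


def test_two_compartment_asymmetry_raises_lci():
    """Unequal specific ventilation prolongs the washout at fixed total FRC."""
    sym = SimulationConfig(frc_ml=(40.0, 40.0), ventilation_fractions=(0.5, 0.5),
                           seed=2, noise_mm_sd=0.0, noise_flow_sd=0.0)
    asym = SimulationConfig(frc_ml=(40.0, 40.0), ventilation_fractions=(0.75, 0.25),
                            seed=2, noise_mm_sd=0.0, noise_flow_sd=0.0)
    lci = []
    for cfg in (sym, asym):
        rec, _ = simulate_recording(cfg)
        lci.append(analyze_recording(rec).outcomes.lci_to)
    assert lci[1] > lci[0]
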
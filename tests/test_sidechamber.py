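"""Side-chamber fits, minimum-curve interpolation, scaling and extraction."""

import numpy as np
import pytest

from sf6mbw.sidechamber import (
    InspirationFit,
    _isotonic_decreasing,
    extract_sf6,
    fit_inspiration_minimum,
    interpolate_minimum_curve,
)
from sf6mbw.tidal import NormalizedSignal


def _norm_from_breaths(segments, dt=0.005):
    """Assemble a NormalizedSignal from (breath, phase, v, x) segments."""
    idx, xs, ph, vs, bs = [], [], [], [], []
    pos = 0
    for breath, phase, v, x in segments:
        n = len(v)
        idx.append(np.arange(pos, pos + n))
        xs.append(np.asarray(x, dtype=float))
        ph.append(np.full(n, phase, dtype=np.int8))
        vs.append(np.asarray(v, dtype=float))
        bs.append(np.full(n, breath, dtype=int))
        pos += n
    return NormalizedSignal(
        index=np.concatenate(idx), x=np.concatenate(xs), phase=np.concatenate(ph),
        v_ml=np.concatenate(vs), breath=np.concatenate(bs),
        over_range=np.zeros(pos, dtype=bool), dt=dt,
    )


def test_exponential_fit_recovers_parameters():
    """a=0.3, lambda=15 mL plus 1% noise -> both recovered within 5%."""
    rng = np.random.default_rng(7)
    v = np.linspace(0.0, 30.0, 200)
    x = 0.3 * np.exp(-v / 15.0) + 0.003 * rng.standard_normal(v.size)
    norm = _norm_from_breaths([(0, 1, v, x)])
    fit = fit_inspiration_minimum(norm, [0])[0]
    assert fit.a == pytest.approx(0.3, rel=0.05)
    assert fit.lam_ml == pytest.approx(15.0, rel=0.05)
    assert not fit.fallback


def test_zero_signal_gives_zero_carryover():
    v = np.linspace(0.0, 30.0, 100)
    norm = _norm_from_breaths([(0, 1, v, np.zeros_like(v))])
    fit = fit_inspiration_minimum(norm, [0])[0]
    assert fit.a == 0.0


def test_fit_decays_to_zero_at_large_volume():
    v = np.linspace(0.0, 30.0, 120)
    norm = _norm_from_breaths([(0, 1, v, 0.2 * np.exp(-v / 10.0))])
    fit = fit_inspiration_minimum(norm, [0])[0]
    assert fit(np.array([1e4]))[0] == pytest.approx(0.0, abs=1e-12)


def test_isotonic_fallback_is_monotone():
    rng = np.random.default_rng(1)
    y = np.r_[np.linspace(0.3, 0.0, 30), 0.05 * rng.standard_normal(30)]
    fitted = _isotonic_decreasing(y)
    assert np.all(np.diff(fitted) <= 1e-12)
    # idempotent on already-decreasing data
    dec = np.linspace(0.4, 0.0, 20)
    np.testing.assert_allclose(_isotonic_decreasing(dec), dec, atol=1e-12)


def test_minimum_curve_constant_between_identical_fits():
    v = np.linspace(0.0, 30.0, 50)
    x = 0.2 * np.exp(-v / 1e3)
    t_exp = np.linspace(0.0, 20.0, 30)
    norm = _norm_from_breaths([
        (0, 1, v, x), (0, -1, t_exp, np.ones(30)),
        (1, 1, v, x), (1, -1, t_exp, np.ones(30)),
    ])
    fits = fit_inspiration_minimum(norm, [0, 1])
    curve = interpolate_minimum_curve(fits, norm)
    exp_sel = norm.samples_of(0, phase=-1)
    # flanking values nearly identical -> interpolant nearly constant
    assert np.ptp(curve[exp_sel]) < 0.01


def test_minimum_curve_continuous_at_breath_boundaries(noiseless_result):
    res = noiseless_result
    norm, curve = res.norm, res.curves.minimum
    for bi in res.sf6.washout_breaths[:-1]:
        insp = norm.samples_of(bi, phase=1)
        exp = norm.samples_of(bi, phase=-1)
        if insp.size and exp.size:
            assert abs(curve[exp[0]] - curve[insp[-1]]) < 0.02


def test_minimum_curve_tracks_true_chamber_state(noiseless_result, noiseless_sim):
    """RMS error of the estimated chamber curve < 15% of its dynamic range."""
    rec, truth = noiseless_sim
    res = noiseless_result
    u_true = truth.chamber_state[res.norm.index] / truth.tracer_fraction
    m_true = 0.10 * u_true  # configured chamber fraction
    rms = float(np.sqrt(np.mean((res.curves.minimum - m_true) ** 2)))
    assert rms < 0.15 * float(m_true.max() - m_true.min())


def test_scaling_anchors_recover_chamber_blend(noiseless_result):
    """alpha -> 1 - chamber fraction, beta -> 1 in the matched forward model."""
    curves = noiseless_result.curves
    assert curves.alpha == pytest.approx(0.90, abs=0.02)
    assert curves.beta == pytest.approx(1.0, abs=0.05)


def test_anchor_breath_extracts_exactly_the_tracer_maximum(noiseless_result):
    """By construction the washin-plateau anchor end-tidal equals C_max."""
    assert noiseless_result.sf6.initial_end_tidal == pytest.approx(0.04, abs=1e-9)


def test_extraction_identity_cases():
    v = np.linspace(0.0, 20.0, 40)
    norm = _norm_from_breaths([(0, 1, v, np.zeros_like(v)),
                               (0, -1, v, np.ones_like(v))])
    minimum = np.zeros(norm.x.size)
    maximum = np.ones(norm.x.size)
    sig = extract_sf6(norm, minimum, maximum, 0.04, [0], initial_breath=0)
    insp = norm.samples_of(0, phase=1)
    exp = norm.samples_of(0, phase=-1)
    np.testing.assert_allclose(sig.sf6[insp], 0.0, atol=1e-12)  # on the min curve
    np.testing.assert_allclose(sig.sf6[exp], 0.04, atol=1e-12)  # on the max curve


def test_extracted_end_tidal_matches_ground_truth(noiseless_result, noiseless_sim):
    """Per-breath end-tidal SF6 within 2% of C_max of the simulator's truth."""
    rec, truth = noiseless_sim
    sf6 = noiseless_result.sf6
    est = np.array([sf6.end_tidal[b] for b in sf6.washout_breaths])
    true = truth.end_tidal_sf6[truth.washout[0] : truth.washout[1]]
    assert np.max(np.abs(est - true)) < 0.02 * truth.tracer_fraction


def test_end_tidal_sequence_monotone_after_smoothing(noiseless_result):
    sf6 = noiseless_result.sf6
    et = np.array([sf6.end_tidal[b] for b in sf6.washout_breaths])
    smoothed = np.array([np.median(et[max(0, i - 1) : i + 2]) for i in range(et.size)])
    assert np.all(np.diff(smoothed) <= 1e-9)


def test_correction_reduces_frc_error_on_chambered_model(noiseless_sim, reanalyze,
                                                         noiseless_result):
    rec, truth = noiseless_sim
    off = reanalyze(rec, side_chamber_correction=False)
    err_on = abs(noiseless_result.outcomes.frc_ml - truth.frc_true_ml)
    err_off = abs(off.outcomes.frc_ml - truth.frc_true_ml)
    assert err_on < err_off
    # the anchored correction removes at least half of the uncorrected bias
    assert err_on <= 0.5 * err_off
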
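"""Shared simulated fixtures (session-scoped: simulations are reused)."""

from __future__ import annotations

import pytest

from sf6mbw import SimulationConfig, analyze_recording, simulate_recording
from sf6mbw.pipeline import config_for


@pytest.fixture(scope="session")
def std_sim():
    """Small-volume baseline with realistic noise and side chambers."""
    return simulate_recording(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def std_result(std_sim):
    rec, _ = std_sim
    return analyze_recording(rec)


@pytest.fixture(scope="session")
def noiseless_sim():
    """Chambered but noise-free: isolates the systematic error budget."""
    return simulate_recording(
        SimulationConfig(seed=3, noise_mm_sd=0.0, noise_flow_sd=0.0)
    )


@pytest.fixture(scope="session")
def noiseless_result(noiseless_sim):
    rec, _ = noiseless_sim
    return analyze_recording(rec)


@pytest.fixture()
def reanalyze():
    """Re-run the pipeline with config overrides."""

    def _run(rec, **overrides):
        return analyze_recording(rec, config_for(rec, **overrides))

    return _run
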
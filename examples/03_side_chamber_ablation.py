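"""What the side-chamber correction buys.

The flowmeter's semi-accessible side chambers hold gas that lags the main
stream, contaminating the molar-mass signal.  Running the same recording
with and without the correction shows the size of the resulting FRC bias.
"""

from sf6mbw import SimulationConfig, analyze_recording, simulate_recording
from sf6mbw.pipeline import config_for

rec, truth = simulate_recording(SimulationConfig(seed=3, noise_mm_sd=0.0,
                                                 noise_flow_sd=0.0))
for label, enabled in (("with correction", True), ("without correction", False)):
    res = analyze_recording(rec, config_for(rec, side_chamber_correction=enabled))
    err = 100 * (res.outcomes.frc_ml - truth.frc_true_ml) / truth.frc_true_ml
    print(f"{label:>20}: FRC {res.outcomes.frc_ml:6.1f} mL  error {err:+6.2f}%")
print("\nWithout the correction the lagging chamber gas masquerades as tracer "
      "in the main stream - most harmfully as re-inspired tracer during "
      "inspirations - and the FRC bias grows by an order of magnitude.")
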
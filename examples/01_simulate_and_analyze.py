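"""Simulate one infant SF6 washout trial and run the full analysis.

The simulated trial is the small in-vitro baseline: an 80 mL lung model
ventilated at 30 mL tidal volume, 30 breaths/min, washed in with 4% SF6,
recorded through a sensor with tidal temperature/humidity confounders and
side-chamber dynamics.  The analysis never sees the true FRC.
"""

from sf6mbw import SimulationConfig, analyze_recording, simulate_recording

cfg = SimulationConfig(seed=11)  # small baseline: FRC 80 mL, VT 30 mL, RR 30/min
rec, truth = simulate_recording(cfg)
print(f"recording: {rec.duration_s:.0f} s at {rec.sampling_rate_hz:.0f} Hz, "
      f"{truth.n_breaths} breaths")

result = analyze_recording(rec)
o = result.outcomes
print(f"phases: pre {result.phases.pre}  washin {result.phases.washin}  "
      f"washout {result.phases.washout}")
print(f"FRC  {o.frc_ml:6.1f} mL   (true {truth.frc_true_ml:.0f} mL, "
      f"error {100 * (o.frc_ml - truth.frc_true_ml) / truth.frc_true_ml:+.2f}%)")
print(f"CEV  {o.cev_ml:6.1f} mL   expired to the end-of-test breath")
print(f"LCI  {o.lci_to:6.2f} TO   turnovers of FRC needed to clear the tracer")
print(f"end of test at washout breath {o.breath_count_to_end} "
      f"(end-tidal SF6 fell below 2.5% of its initial {o.initial_end_tidal_sf6:.1%})")

# The LCI is the primary outcome: the number of FRC-equivalents of expired
# volume needed to wash the tracer down to 2.5% of its starting level.
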
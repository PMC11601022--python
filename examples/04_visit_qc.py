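"""Visit-level quality control: the 25% agreement rule.

A visit needs at least two acceptable trials whose LCI and FRC lie within
25% of the accepted-set mean; deviating trials are excluded and the means
recomputed to a fixed point.
"""

from sf6mbw import SimulationConfig, analyze_recording, assess_visit, simulate_recording
from sf6mbw.qc import TrialQC

trials = []
for seed in (31, 32, 33):
    rec, _ = simulate_recording(SimulationConfig(seed=seed))
    res = analyze_recording(rec)
    trials.append(TrialQC(outcomes=res.outcomes, flags=res.flags))
    print(f"trial seed {seed}: FRC {res.outcomes.frc_ml:6.1f} mL  "
          f"LCI {res.outcomes.lci_to:5.2f} TO  flags {res.flags}")

visit = assess_visit(trials)
print(f"\nvisit valid: {visit.valid}  accepted trials: {visit.accepted}")
print(f"mean FRC {visit.mean_frc_ml:.1f} mL, mean LCI {visit.mean_lci:.2f} TO")
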
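# The 2-volume x 5-condition in-vitro validation grid, 6 replicates per cell.
# Small baseline: FRC 80 mL, VT 30 mL, RR 30/min; large: 210 mL / 50 mL / 20 per min.
grid:
  replicates: 6
  base_seed: 0
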
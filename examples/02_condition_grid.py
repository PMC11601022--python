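"""FRC accuracy over the in-vitro condition grid (reduced: 1 replicate/cell).

Reproduces the shape of the validation experiment: two lung-model volumes
under five conditions each (baseline, room temperature, raised respiratory
rate, raised tidal volume, added ventilation inhomogeneity).  With the full
six replicates per cell this is exactly what scripts/acceptance.py runs.
"""

from sf6mbw import condition_grid, run_grid, summarize_grid

scenarios = condition_grid(replicates=1, base_seed=0)
df = run_grid(scenarios)
print(summarize_grid(df).to_string(index=False))
print("\nEach row: mean/SD of |FRC_est - FRC_true| / FRC_true over the cell's runs.")
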
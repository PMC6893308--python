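"""Simulate a graded-stress FTIR experiment and write it to disk.

A control plus four inhibitor-mixture levels (A < B < C < D) with a linearly
growing additive effect on the amide II shoulder band (1,507-1,518 cm^-1),
three replicates per condition, on the full 4,000-400 cm^-1 grid.  The wide
CSV and the ground-truth effect mask feed the downstream scripts.
"""

from pathlib import Path

import pandas as pd

from ftirswa import graded_stress_scenario, simulate_experiment, write_spectrum_table

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1

cfg = graded_stress_scenario(["A", "B", "C", "D"], base_delta=5e-4, seed=SEED)
groups, mask = simulate_experiment(cfg)

OUT.mkdir(exist_ok=True)
write_spectrum_table(groups, OUT / "simulated_spectra.csv", "wide_csv")
pd.DataFrame({"wavenumber_cm-1": cfg.wavenumbers(), "affected": mask}).to_csv(
    OUT / "ground_truth_mask.csv", index=False
)

print(f"conditions: {cfg.conditions}, {cfg.n_replicates} replicates each")
print(f"grid: {cfg.grid[0]:.0f}-{cfg.grid[1]:.0f} cm^-1, {cfg.wavenumbers().size} points")
print(f"truly affected wavenumbers: {int(mask.sum())} (band 1,507-1,518 cm^-1)")
print(f"wrote {OUT / 'simulated_spectra.csv'} and {OUT / 'ground_truth_mask.csv'}")
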
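"""Viability and fermentation-yield metrics on a synthetic plate-count table.

Mimics an inhibitor-mixture tolerance assay: triplicate serial-dilution
counts per mixture level, mortality M = (1 - Cv/Ct) x 100 against the
untreated control, plus worked theoretical-yield percentages for a
glucose and a cellobiose fermentation.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ftirswa import (
    glucose_equivalents,
    mortality_table,
    percent_theoretical_yield,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)

# synthetic triplicate counts: survival drops with mixture strength
rng = np.random.default_rng(1)
survival = {"control": 1.0, "mixA": 0.88, "mixB": 0.55, "mixC": 0.0, "mixD": 0.0}
rows = []
for cond, frac in survival.items():
    lam = 120 * frac
    for rep, count in enumerate(rng.poisson(lam, 3), start=1):
        rows.append((cond, rep, 1e5, int(count)))
counts = pd.DataFrame(rows, columns=["condition", "replicate", "dilution_factor", "colony_count"])
counts.to_csv(RESULTS / "plate_counts.csv", index=False)

table = mortality_table(counts, "control")
table.to_csv(RESULTS / "mortality.csv", index=False)
print("mortality by inhibitor mixture:")
print(table[["condition", "mortality_pct"]].to_string(index=False))

# yield arithmetic for two fermentations (concentrations in g/L)
glucose_run = percent_theoretical_yield(6.0, 18.0)
cellobiose_consumed = glucose_equivalents(7.5)
cellobiose_run = percent_theoretical_yield(3.0, cellobiose_consumed)
print(f"\nglucose run: 6.0 g/L ethanol from 18.0 g/L consumed -> {glucose_run:.1f}% of theoretical")
print(
    f"cellobiose run: 3.0 g/L ethanol from 7.5 g/L cellobiose "
    f"(= {cellobiose_consumed:.2f} g/L glucose equivalents) -> {cellobiose_run:.1f}% of theoretical"
)
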
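"""Attribute the significant wavenumbers to spectral regions.

Summarizes the strongest contrast (control vs D) per W1-W5 window and looks
up functional-group band assignments for the persistently significant
wavenumbers.
"""

from pathlib import Path

import pandas as pd

from ftirswa import lookup_bands, region_summary

RESULTS = Path(__file__).resolve().parents[1] / "results"

sig = pd.read_csv(RESULTS / "swa_vs_control_significant.csv", index_col=0)
grid = sig.columns.to_numpy(dtype=float)
row = sig.loc["control vs D"].to_numpy()

table = region_summary(row, grid)
table.to_csv(RESULTS / "region_summary_control_vs_D.csv", index=False)
print("control vs D, significant wavenumbers per region:")
print(table.to_string(index=False))

persistent = pd.read_csv(RESULTS / "persistent_significant.csv")
hits = persistent.loc[persistent["persistent"] == 1, "wavenumber_cm-1"]
labels = sorted({b.label for w in hits for b in lookup_bands(float(w))})
print(f"\npersistent wavenumbers: {len(hits)}; band assignments: {labels or 'none'}")
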
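"""Per-wavelength significance analysis of the preprocessed spectra.

Runs both comparison modes on the analysis range (3,800-600 cm^-1 minus
2,800-1,800 cm^-1): every condition against the control, and all pairwise
comparisons.  Writes the p-value / binary matrices, the percent-significant
square matrix, the dot-track plot, and the wavenumbers that stay significant
across the whole dose ladder.
"""

from pathlib import Path

import matplotlib.pyplot as plt
import pandas as pd

from ftirswa import (
    PreprocessParams,
    SWAParams,
    SpectrumGroup,
    persistent_significant,
    read_spectrum_table,
    render_swa_plot,
    run_swa,
    select_analysis_range,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"

pre = PreprocessParams()
groups = [
    SpectrumGroup(g.condition, [select_analysis_range(s, pre) for s in g.spectra])
    for g in read_spectrum_table(RESULTS / "preprocessed_spectra.csv", "wide_csv")
]

vs_control = run_swa(
    groups, SWAParams(mode="vs_control", control_condition="control", smoothing_window=1)
)
vs_control.to_csv(RESULTS, prefix="swa_vs_control")
fig = render_swa_plot(vs_control, RESULTS / "swa_vs_control_dots.png")
plt.close(fig)

all_pairs = run_swa(groups, SWAParams(mode="all_pairs", smoothing_window=1))
all_pairs.to_csv(RESULTS, prefix="swa_all_pairs")

print("percent significant vs control:")
for (a, b), pct in zip(vs_control.comparisons, vs_control.percent_significant()):
    print(f"  {a} vs {b}: {pct:.2f}%")

mask, count = persistent_significant(list(vs_control.significant))
pd.DataFrame(
    {"wavenumber_cm-1": vs_control.wavenumbers, "persistent": mask}
).to_csv(RESULTS / "persistent_significant.csv", index=False)
print(f"wavenumbers significant in EVERY dose comparison: {count}")
print(f"all-pairs comparisons: {len(all_pairs.comparisons)} (= (5^2-5)/2)")
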
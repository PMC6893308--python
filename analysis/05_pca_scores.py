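"""PCA of the preprocessed fingerprints over the analysis range.

Mean-centered covariance PCA; writes scores, explained-variance percentages,
and the PC1/PC2 score plot colored by condition.
"""

from pathlib import Path

import matplotlib.pyplot as plt

from ftirswa import PreprocessParams, pca_fingerprints, read_spectrum_table, render_score_plot

RESULTS = Path(__file__).resolve().parents[1] / "results"

groups = read_spectrum_table(RESULTS / "preprocessed_spectra.csv", "wide_csv")
res = pca_fingerprints(groups, PreprocessParams())
res.to_csv(RESULTS)
fig = render_score_plot(res, (1, 2), RESULTS / "pca_scores.png")
plt.close(fig)

print("explained variance by component:")
for i, pct in enumerate(res.explained_pct[:4], start=1):
    print(f"  PC{i}: {pct:.2f}%")
print(f"wrote {RESULTS / 'pca_scores.csv'} and {RESULTS / 'pca_scores.png'}")
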
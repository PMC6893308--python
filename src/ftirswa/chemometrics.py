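"""Covariance PCA of preprocessed fingerprints over the analysis range.

Spectra are mean-centered per wavenumber (no unit-variance scaling — all
points share the absorbance unit) and decomposed by SVD.  Loadings carry a
deterministic sign convention: each component is oriented so that its
largest-magnitude loading element is positive, making score plots
reproducible across linear-algebra backends.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateVarianceError, ReplicateCountError
from .preprocess import PreprocessParams, select_analysis_range
from .spectra_io import SpectrumGroup


@dataclass
class PCAResult:
    scores: np.ndarray  # samples x components
    explained_pct: np.ndarray  # per-component percent of total variance
    loadings: np.ndarray  # wavenumbers x components
    sample_labels: list[str]
    conditions: list[str]
    wavenumbers: np.ndarray
    mean_: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def scores_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores,
            index=self.sample_labels,
            columns=[f"PC{i + 1}" for i in range(self.n_components)],
        )
        df.insert(0, "condition", self.conditions)
        return df

    def to_csv(self, outdir: str | Path, prefix: str = "pca") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "scores": outdir / f"{prefix}_scores.csv",
            "explained": outdir / f"{prefix}_explained_pct.csv",
        }
        self.scores_frame().to_csv(paths["scores"], index_label="sample_id")
        pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(self.n_components)],
                "explained_pct": self.explained_pct,
            }
        ).to_csv(paths["explained"], index=False)
        return paths


def pca_fingerprints(
    groups: list[SpectrumGroup], p: PreprocessParams | None = None
) -> PCAResult:
    """PCA of all spectra in *groups*, restricted to the analysis range.

    Keeps min(n_samples - 1, n_wavenumbers) components; ``explained_pct``
    are the sample-covariance eigenvalues normalized to sum to 100.
    """
    p = p or PreprocessParams()
    spectra = [s for g in groups for s in g.spectra]
    if len(spectra) < 3:
        raise ReplicateCountError(f"PCA needs >= 3 spectra, got {len(spectra)}")
    selected = [select_analysis_range(s, p) for s in spectra]
    w = selected[0].wavenumbers
    X = np.vstack([s.absorbance for s in selected])
    mean = X.mean(axis=0)
    Xc = X - mean
    total_var = float((Xc**2).sum())
    if total_var == 0.0:
        raise DegenerateVarianceError("all spectra identical: zero total variance")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(X.shape[0] - 1, X.shape[1])
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    # orient each component so its largest-magnitude loading is positive
    for j in range(k):
        i_max = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i_max] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    eig = S**2 / (X.shape[0] - 1)
    return PCAResult(
        scores=U * S,
        explained_pct=100.0 * eig / eig.sum(),
        loadings=Vt.T,
        sample_labels=[s.sample_id for s in spectra],
        conditions=[s.condition for s in spectra],
        wavenumbers=w,
        mean_=mean,
    )


def render_score_plot(
    r: PCAResult, axes: tuple[int, int] = (1, 2), path: str | Path | None = None
):
    """2-D score scatter colored by condition, axis labels carrying the
    explained-variance percentages.  Returns the Figure; saves when *path*
    is given."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    i, j = axes
    if not (1 <= i <= r.n_components and 1 <= j <= r.n_components):
        raise IndexError(
            f"components {axes} out of range 1..{r.n_components}"
        )
    fig, ax = plt.subplots(figsize=(6, 5))
    conds = list(dict.fromkeys(r.conditions))
    for c in conds:
        mask = np.asarray([cc == c for cc in r.conditions])
        ax.scatter(r.scores[mask, i - 1], r.scores[mask, j - 1], label=c, s=35)
    ax.axhline(0.0, lw=0.5, color="gray")
    ax.axvline(0.0, lw=0.5, color="gray")
    ax.set_xlabel(f"PC{i} ({r.explained_pct[i - 1]:.2f}%)")
    ax.set_ylabel(f"PC{j} ({r.explained_pct[j - 1]:.2f}%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
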
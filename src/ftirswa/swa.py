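"""Significant Wavelengths Analysis (SWA).

Replicated spectra of two conditions are compared with a two-sided Student
t-test at every wavenumber independently (optionally after a moving average
of the absorbance traces).  The per-wavenumber p-values are binarized at a
significance threshold (default p < 0.01), assembled into a comparisons x
wavenumbers matrix — either all (n^2 - n)/2 pairwise comparisons or the n - 1
comparisons against a control condition — and summarized as a square
condition x condition matrix of the percentage of significantly different
wavenumbers.  No multiple-testing correction is applied by default: the
product is a spatial significance pattern over the spectrum, not a single
inference (a Benjamini-Hochberg option exists for sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, GridMismatchError, ReplicateCountError
from .spectra_io import Spectrum, SpectrumGroup, grids_equal


@dataclass
class SWAParams:
    """Parameters of one SWA run.

    alpha
        Binarization threshold: a wavenumber is significant iff p < alpha
        (strict; p == alpha maps to 0).
    smoothing_window
        Width, in grid points, of the centered moving average applied to the
        absorbance traces before testing; 1 disables smoothing.
    mode
        ``all_pairs`` or ``vs_control`` (the latter needs
        ``control_condition``).
    welch
        Use the Welch (unequal-variance) t statistic instead of the pooled
        Student statistic.
    correction
        ``none`` (default, faithful to the procedure) or ``bh`` for a
        per-comparison Benjamini-Hochberg adjustment before binarization.
    """

    alpha: float = 0.01
    smoothing_window: int = 10
    mode: str = "all_pairs"
    control_condition: str | None = None
    welch: bool = False
    correction: str = "none"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie strictly between 0 and 1")
        if int(self.smoothing_window) < 1:
            raise ConfigError("smoothing_window must be a positive integer")
        self.smoothing_window = int(self.smoothing_window)
        if self.mode not in ("all_pairs", "vs_control"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "vs_control" and not self.control_condition:
            raise ConfigError("vs_control mode requires control_condition")
        if self.correction not in ("none", "bh"):
            raise ConfigError(f"unknown correction {self.correction!r}")


@dataclass
class SWAResult:
    """Significance pattern over comparisons x wavenumbers."""

    wavenumbers: np.ndarray
    comparisons: list[tuple[str, str]]
    pvalues: np.ndarray  # comparisons x wavenumbers, in [0, 1]
    significant: np.ndarray  # same shape, {0, 1}
    percent_matrix: pd.DataFrame  # condition x condition, NaN where untested
    alpha: float = 0.01
    mode: str = "all_pairs"

    @property
    def comparison_labels(self) -> list[str]:
        return [f"{a} vs {b}" for a, b in self.comparisons]

    def percent_significant(self) -> np.ndarray:
        """Per-comparison percentage of significant wavenumbers."""
        return 100.0 * self.significant.mean(axis=1)

    def pvalues_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pvalues, index=self.comparison_labels, columns=self.wavenumbers
        )

    def significant_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.significant, index=self.comparison_labels, columns=self.wavenumbers
        )

    def to_csv(self, outdir: str | Path, prefix: str = "swa") -> dict[str, Path]:
        """Write p-value, binary, and percent matrices as CSV files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "pvalues": outdir / f"{prefix}_pvalues.csv",
            "significant": outdir / f"{prefix}_significant.csv",
            "percent": outdir / f"{prefix}_percent_matrix.csv",
        }
        self.pvalues_frame().to_csv(paths["pvalues"], index_label="comparison")
        self.significant_frame().to_csv(paths["significant"], index_label="comparison")
        self.percent_matrix.to_csv(paths["percent"], index_label="condition")
        return paths


# ---------------------------------------------------------------------------
# primitives


def ttest_per_wavelength(
    a: SpectrumGroup, b: SpectrumGroup, welch: bool = False
) -> np.ndarray:
    """Two-sided two-sample t-test p-value at every shared wavenumber.

    Pooled-variance Student statistic by default (df = nA + nB - 2).  Where
    the pooled variance is exactly zero the test is degenerate: p = 1 if the
    group means are equal, p = 0 otherwise.
    """
    if a.n_replicates < 3 or b.n_replicates < 3:
        raise ReplicateCountError(
            f"SWA needs >= 3 replicates per condition, got "
            f"{a.n_replicates} ({a.condition!r}) and {b.n_replicates} ({b.condition!r})"
        )
    if not grids_equal(a.wavenumbers, b.wavenumbers):
        raise GridMismatchError(
            f"groups {a.condition!r} and {b.condition!r} are on different grids"
        )
    A, B = a.absorbance_matrix(), b.absorbance_matrix()
    na, nb = A.shape[0], B.shape[0]
    ma, mb = A.mean(axis=0), B.mean(axis=0)
    va, vb = A.var(axis=0, ddof=1), B.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if welch:
            se2 = va / na + vb / nb
            t = (ma - mb) / np.sqrt(se2)
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        else:
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
            df = np.full_like(t, float(na + nb - 2))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = ~np.isfinite(t)
    if np.any(degenerate):
        p = np.where(degenerate & (ma == mb), 1.0, np.where(degenerate, 0.0, p))
    return np.clip(p, 0.0, 1.0)


def smooth_moving_average(s: Spectrum, window: int) -> Spectrum:
    """Centered moving average over *window* grid points.

    Edge points average over the truncated available window, so the output
    grid is unchanged; windows wider than the spectrum degrade gracefully to
    the full-spectrum mean at every point.  ``window=1`` is the identity.
    """
    if int(window) < 1:
        raise ConfigError("smoothing window must be >= 1")
    window = int(window)
    if window == 1:
        return s
    n = len(s)
    half_lo, half_hi = (window - 1) // 2, window // 2
    csum = np.concatenate(([0.0], np.cumsum(s.absorbance)))
    i = np.arange(n)
    lo = np.maximum(0, i - half_lo)
    hi = np.minimum(n, i + half_hi + 1)
    return s.with_absorbance((csum[hi] - csum[lo]) / (hi - lo))


def binarize_pvalues(p: np.ndarray, alpha: float = 0.01) -> np.ndarray:
    """1 where p < alpha, else 0 (p == alpha maps to 0)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0.0) | (p > 1.0) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return (p < alpha).astype(int)


def persistent_significant(results: list[np.ndarray]) -> tuple[np.ndarray, int]:
    """Element-wise AND of binary significance vectors, plus the count.

    A wavenumber is persistently significant only if it is significant in
    every supplied vector (e.g. at every sampled timepoint of a growth
    curve).  Returns ``(mask, count)``.
    """
    if not results:
        raise ValueError("persistent_significant needs at least one vector")
    vectors = [np.asarray(v, dtype=int) for v in results]
    n = vectors[0].size
    for v in vectors[1:]:
        if v.size != n:
            raise GridMismatchError("binary vectors differ in length")
    mask = vectors[0].copy()
    for v in vectors[1:]:
        mask &= v
    return mask, int(mask.sum())


# ---------------------------------------------------------------------------
# assembly


def _comparison_pairs(conditions: list[str], params: SWAParams) -> list[tuple[str, str]]:
    ordered = sorted(conditions)
    if params.mode == "all_pairs":
        return list(combinations(ordered, 2))
    control = params.control_condition
    if control not in ordered:
        raise ConfigError(f"control condition {control!r} not among {ordered}")
    return [(control, c) for c in ordered if c != control]


def run_swa(groups: list[SpectrumGroup], params: SWAParams | None = None) -> SWAResult:
    """Run the full SWA procedure over >= 2 condition groups.

    Order of operations: optional moving-average smoothing of every
    spectrum; per-wavenumber t-tests for every comparison pair (all pairs,
    or each condition against the control); binarization at ``alpha``;
    percent-significant summary matrix.  Comparisons are ordered
    lexicographically by condition label.
    """
    params = params or SWAParams()
    if len(groups) < 2:
        raise ConfigError("SWA needs at least 2 condition groups")
    by_cond = {g.condition: g for g in groups}
    if len(by_cond) != len(groups):
        raise ConfigError("duplicate condition labels among groups")
    ref = groups[0].wavenumbers
    for g in groups[1:]:
        if not grids_equal(ref, g.wavenumbers):
            raise GridMismatchError("condition groups are on different grids")
    if params.smoothing_window > 1:
        by_cond = {
            c: SpectrumGroup(
                c, [smooth_moving_average(s, params.smoothing_window) for s in g.spectra]
            )
            for c, g in by_cond.items()
        }
    pairs = _comparison_pairs(list(by_cond), params)
    pvals = np.empty((len(pairs), ref.size))
    for i, (ca, cb) in enumerate(pairs):
        pvals[i] = ttest_per_wavelength(by_cond[ca], by_cond[cb], welch=params.welch)
    if params.correction == "bh":
        from statsmodels.stats.multitest import multipletests

        pvals = np.vstack(
            [multipletests(row, method="fdr_bh")[1] for row in pvals]
        )
    sig = np.vstack([binarize_pvalues(row, params.alpha) for row in pvals])

    conditions = sorted(by_cond)
    percent = pd.DataFrame(np.nan, index=conditions, columns=conditions)
    np.fill_diagonal(percent.values, 0.0)
    for (ca, cb), row in zip(pairs, sig):
        pct = 100.0 * row.sum() / row.size
        percent.loc[ca, cb] = pct
        percent.loc[cb, ca] = pct
    return SWAResult(
        wavenumbers=ref.copy(),
        comparisons=pairs,
        pvalues=pvals,
        significant=sig,
        percent_matrix=percent,
        alpha=params.alpha,
        mode=params.mode,
    )


# ---------------------------------------------------------------------------
# plotting


def render_swa_plot(r: SWAResult, path: str | Path | None = None):
    """Dot-track plot: one horizontal track per comparison, a dot per
    significant wavenumber, x-axis in descending wavenumber (FTIR
    convention), annotated with each comparison's percent significant.

    Returns the matplotlib Figure; saves to *path* when given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if r.significant.size == 0:
        raise ValueError("empty SWA result")
    fig, ax = plt.subplots(figsize=(9, 1.0 + 0.5 * len(r.comparisons)))
    pct = r.percent_significant()
    for i, label in enumerate(r.comparison_labels):
        x = r.wavenumbers[r.significant[i] == 1]
        ax.scatter(x, np.full(x.size, i), s=6, marker=".", label=label)
        ax.annotate(
            f"{pct[i]:.1f}%",
            xy=(1.005, i),
            xycoords=("axes fraction", "data"),
            va="center",
            fontsize=8,
        )
    ax.set_yticks(range(len(r.comparisons)))
    ax.set_yticklabels(r.comparison_labels, fontsize=8)
    ax.set_ylim(-0.5, len(r.comparisons) - 0.5)
    ax.set_xlim(float(r.wavenumbers.max()), float(r.wavenumbers.min()))
    ax.set_xlabel("wavenumber (cm$^{-1}$)")
    ax.set_title(f"Significant wavelengths (p < {r.alpha:g})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
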
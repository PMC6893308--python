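"""Spectral preprocessing: SNR quality gate, rubberband baseline, vector
normalization, and analysis-range selection.

The chain mirrors standard transmission-FTIR practice for whole-cell
fingerprints: spectra failing a signal-to-noise test in the absorption-silent
2,100-1,900 cm^-1 window are discarded; the remaining spectra get a rubberband
(lower convex hull) baseline subtraction and are scaled to unit Euclidean
norm.  Multivariate analyses then run on 3,800-600 cm^-1 with the
2,800-1,800 cm^-1 window (CO2 band, silent region) excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DegenerateSpectrumError, ReplicateCountError
from .spectra_io import Spectrum, SpectrumGroup, require_window

#: absorption band used as the "signal" numerator of the SNR estimate (amide I)
SIGNAL_WINDOW = (1600.0, 1700.0)


@dataclass
class PreprocessParams:
    """Tunable knobs of the preprocessing chain.

    snr_threshold
        Quality gate; spectra with estimated SNR at or below it are dropped.
    snr_window
        Absorption-silent interval (cm^-1) where noise is estimated.
    n_anchor
        Number of equally spaced candidate anchor wavenumbers for the
        rubberband hull (endpoints always included).
    analysis_include / analysis_exclude
        The multivariate analysis range: points kept are those inside
        ``analysis_include`` but not strictly inside ``analysis_exclude``
        (interval boundaries are retained).
    normalization_scope
        ``whole_spectrum`` (default) or ``analysis_range``.
    """

    snr_threshold: float = 4000.0
    snr_window: tuple[float, float] = (1900.0, 2100.0)
    n_anchor: int = 64
    analysis_include: tuple[float, float] = (600.0, 3800.0)
    analysis_exclude: tuple[float, float] = (1800.0, 2800.0)
    normalization_scope: str = "whole_spectrum"

    def __post_init__(self) -> None:
        if self.snr_threshold <= 0:
            raise ConfigError("snr_threshold must be positive")
        if self.n_anchor < 3:
            raise ConfigError("n_anchor must be at least 3")
        ilo, ihi = self.analysis_include
        elo, ehi = self.analysis_exclude
        if not (ilo < ihi and elo < ehi):
            raise ConfigError("analysis intervals must be ordered (lo, hi)")
        if not (ilo <= elo and ehi <= ihi):
            raise ConfigError("exclude interval must nest inside include interval")
        if self.normalization_scope not in ("whole_spectrum", "analysis_range"):
            raise ConfigError(
                f"unknown normalization_scope {self.normalization_scope!r}"
            )

    def to_dict(self) -> dict:
        return {
            "snr_threshold": self.snr_threshold,
            "snr_window": list(self.snr_window),
            "n_anchor": self.n_anchor,
            "analysis_include": list(self.analysis_include),
            "analysis_exclude": list(self.analysis_exclude),
            "normalization_scope": self.normalization_scope,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessParams":
        d = dict(d)
        for k in ("snr_window", "analysis_include", "analysis_exclude"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class QCReport:
    sample_id: str
    snr_estimate: float
    passed: bool
    details: str = ""


# ---------------------------------------------------------------------------
# rubberband baseline


def _anchor_indices(n: int, n_anchor: int) -> np.ndarray:
    """Equally spaced candidate indices including both endpoints."""
    if n_anchor >= n:
        return np.arange(n)
    return np.unique(np.round(np.linspace(0, n - 1, n_anchor)).astype(int))


def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Andrew monotone-chain lower hull of points sorted by x."""
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # pop k if it lies on or above segment (j, i)
            cross = (x[k] - x[j]) * (y[i] - y[j]) - (y[k] - y[j]) * (x[i] - x[j])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull)


def rubberband_baseline(s: Spectrum, n_anchor: int = 64) -> Spectrum:
    """Subtract the piecewise-linear lower convex hull ("rubberband").

    The hull is computed over *n_anchor* equally spaced candidate anchor
    wavenumbers (endpoints always included); the spectrum minus the hull
    interpolant is exactly zero at hull contact points and non-negative at
    every candidate anchor.  Adding any linear function of wavenumber to the
    input leaves the output unchanged.
    """
    if n_anchor < 3:
        raise ConfigError("rubberband needs at least 3 anchor candidates")
    n = len(s)
    if n < n_anchor:
        warnings.warn(
            f"spectrum has {n} points < n_anchor={n_anchor}; using all points",
            stacklevel=2,
        )
    idx = _anchor_indices(n, n_anchor)
    xs, ys = s.wavenumbers[idx], s.absorbance[idx]
    hull = _lower_hull_indices(xs, ys)
    baseline = np.interp(s.wavenumbers, xs[hull], ys[hull])
    return s.with_absorbance(s.absorbance - baseline)


# ---------------------------------------------------------------------------
# normalization


def _analysis_mask(w: np.ndarray, p: PreprocessParams) -> np.ndarray:
    ilo, ihi = p.analysis_include
    elo, ehi = p.analysis_exclude
    return (w >= ilo) & (w <= ihi) & ~((w > elo) & (w < ehi))


def vector_normalize(
    s: Spectrum,
    scope: str = "whole_spectrum",
    params: PreprocessParams | None = None,
) -> Spectrum:
    """Scale so the Euclidean norm over the scoped range is exactly 1.

    Out-of-scope points are scaled by the same factor, so
    ``normalize(c * x) == normalize(x)`` for any c > 0 and
    ``normalize(normalize(x)) == normalize(x)``.
    """
    if scope == "whole_spectrum":
        scoped = s.absorbance
    elif scope == "analysis_range":
        params = params or PreprocessParams()
        scoped = s.absorbance[_analysis_mask(s.wavenumbers, params)]
    else:
        raise ConfigError(f"unknown normalization scope {scope!r}")
    norm = float(np.linalg.norm(scoped))
    if norm == 0.0:
        raise DegenerateSpectrumError(
            f"{s.sample_id}: all-zero absorbance over the {scope} range"
        )
    return s.with_absorbance(s.absorbance / norm)


# ---------------------------------------------------------------------------
# quality gate


def quality_check(s: Spectrum, p: PreprocessParams | None = None) -> QCReport:
    """Estimate SNR and compare against the quality threshold.

    Signal is the maximum baseline-corrected absorbance in the amide-I window
    (1,600-1,700 cm^-1).  Noise is estimated in the absorption-silent
    ``snr_window`` from first differences, whose RMS is sqrt(2) times the
    point noise standard deviation for white noise (the differencing removes
    any slowly varying residual baseline).
    """
    p = p or PreprocessParams()
    lo, hi = p.snr_window
    require_window(s, lo, hi, "snr_window")
    require_window(s, *SIGNAL_WINDOW, "signal window")
    corrected = rubberband_baseline(s, p.n_anchor)
    w, a = corrected.wavenumbers, corrected.absorbance
    sig_mask = (w >= SIGNAL_WINDOW[0]) & (w <= SIGNAL_WINDOW[1])
    peak = float(a[sig_mask].max())
    noise_mask = (w >= lo) & (w <= hi)
    d = np.diff(a[noise_mask])
    noise = float(np.sqrt(np.mean(d**2) / 2.0)) if d.size else 0.0
    snr = np.inf if noise == 0.0 else peak / noise
    passed = bool(snr > p.snr_threshold)
    return QCReport(
        sample_id=s.sample_id,
        snr_estimate=snr,
        passed=passed,
        details=f"peak={peak:.4g} in {SIGNAL_WINDOW}, noise={noise:.4g} in ({lo}, {hi})",
    )


# ---------------------------------------------------------------------------
# analysis range


def select_analysis_range(s: Spectrum, p: PreprocessParams | None = None) -> Spectrum:
    """Restrict to the analysis range (include minus open-interior exclude).

    With the defaults this keeps [600, 1,800] and [2,800, 3,800] cm^-1;
    points exactly on 1,800 or 2,800 are retained (closed retention).
    """
    p = p or PreprocessParams()
    require_window(s, *p.analysis_include, "analysis_include")
    mask = _analysis_mask(s.wavenumbers, p)
    from dataclasses import replace

    return replace(s, wavenumbers=s.wavenumbers[mask], absorbance=s.absorbance[mask])


# ---------------------------------------------------------------------------
# pipeline


def preprocess_pipeline(
    g: SpectrumGroup, p: PreprocessParams | None = None
) -> tuple[SpectrumGroup, list[QCReport]]:
    """QC -> rubberband baseline -> vector normalization, per replicate.

    Failed-QC spectra are excluded from the returned group but their reports
    are kept.  Range selection is deliberately left to the analysis stage so
    that normalization acts on the whole recorded spectrum.
    """
    p = p or PreprocessParams()
    reports = [quality_check(s, p) for s in g.spectra]
    survivors = [s for s, r in zip(g.spectra, reports) if r.passed]
    if not survivors:
        raise ReplicateCountError(
            f"all {len(g.spectra)} spectra of {g.condition!r} failed the SNR gate"
        )
    processed = [
        vector_normalize(rubberband_baseline(s, p.n_anchor), p.normalization_scope, p)
        for s in survivors
    ]
    return SpectrumGroup(g.condition, processed), reports


def qc_reports_frame(reports: list[QCReport]):
    """QC reports as a DataFrame (sample_id, snr_estimate, passed)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in reports],
            "snr_estimate": [r.snr_estimate for r in reports],
            "passed": [r.passed for r in reports],
        }
    )
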
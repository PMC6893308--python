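"""Synthetic whole-cell FTIR spectra with known ground truth.

A simulated experiment draws, per condition and replicate,

    absorbance = gain * (sum of Gaussian peaks + condition effects)
                 + baseline + iid Gaussian noise

where ``gain ~ 1 + N(0, gain_sd)`` models pathlength/biomass variation
between replicates (the thing vector normalization removes), the baseline is
a low-order polynomial plus one broad hump (what the rubberband removes),
and effects are additive offsets confined to stated wavenumber bands (what
the significance analysis must detect and localize).  Every draw is
reproducible from the top-level seed: per-spectrum streams are derived from
(seed, condition index, replicate index), so adding a condition never
perturbs existing draws.

Defaults emulate a yeast transmission spectrum on 4,000-400 cm^-1 at
2 cm^-1 spacing with three replicates per condition and noise low enough to
clear the SNR > 4,000 quality gate, as a well-run instrument would.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .spectra_io import Spectrum, SpectrumGroup


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian absorption band: amplitude * exp(-(w-center)^2 / 2 width^2)."""

    center: float  # cm^-1
    width: float  # Gaussian sigma, cm^-1
    amplitude: float  # absorbance units

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigError("peak width must be positive")
        if self.amplitude < 0:
            raise ConfigError("peak amplitude must be non-negative")


@dataclass(frozen=True)
class EffectSpec:
    """Additive absorbance offset on a wavenumber band for one condition."""

    band: tuple[float, float]  # closed interval, cm^-1
    delta: float
    applies_to: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta):
            raise ConfigError("effect delta must be finite")
        if self.band[0] > self.band[1]:
            raise ConfigError("effect band must be ordered (lo, hi)")


def default_yeast_profile() -> list[PeakSpec]:
    """Gaussian band set mimicking a yeast whole-cell IR spectrum.

    Covers all five fingerprint windows: amide A/O-H stretch, CH2/CH3
    stretches (W1), the amide I/II complex with its beta-sheet component and
    the 1,518-1,507 shoulder (W2), CH2 bend and carboxylate (W3), phosphate
    and polysaccharide C-O (W4), and the 723-702 nucleic-acid marks (W5).
    """
    return [
        PeakSpec(3290, 120, 0.55),  # amide A / O-H stretch
        PeakSpec(2960, 10, 0.15),  # CH3 asym stretch (W1)
        PeakSpec(2925, 12, 0.25),  # CH2 asym stretch (W1)
        PeakSpec(2855, 10, 0.12),  # CH2 sym stretch (W1)
        PeakSpec(1741, 8, 0.10),  # ester C=O
        PeakSpec(1655, 18, 1.00),  # amide I
        PeakSpec(1638, 12, 0.55),  # amide I, beta-sheet
        PeakSpec(1540, 15, 0.60),  # amide II
        PeakSpec(1512, 6, 0.12),  # amide II shoulder
        PeakSpec(1457, 10, 0.18),  # CH2 bend (W3)
        PeakSpec(1400, 10, 0.15),  # COO- sym stretch
        PeakSpec(1240, 14, 0.25),  # P=O asym (W3/W4 edge)
        PeakSpec(1080, 25, 0.70),  # P=O sym / C-O (W4)
        PeakSpec(1045, 20, 0.55),  # polysaccharide C-O (W4)
        PeakSpec(900, 15, 0.08),  # W4/W5 edge
        PeakSpec(716, 8, 0.05),  # nucleic-acid marker (W5)
    ]


@dataclass
class SyntheticConfig:
    """Full generative description of one simulated experiment."""

    grid: tuple[float, float, float] = (400.0, 4000.0, 2.0)  # lo, hi, step cm^-1
    peaks: list[PeakSpec] = field(default_factory=default_yeast_profile)
    baseline_poly: tuple[float, ...] = (0.02, 0.01)  # coefficients in u=(w-lo)/(hi-lo)
    hump_amplitude: float = 0.01  # broad Gaussian hump at 2,000 cm^-1, sigma 800
    gain_sd: float = 0.01  # relative multiplicative replicate gain spread
    noise_sd: float = 2e-4  # additive Gaussian noise (SNR ~ 5,000 at peak 1)
    n_replicates: int = 3
    conditions: list[str] = field(default_factory=lambda: ["control"])
    effects: list[EffectSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi, step = self.grid
        if not (lo < hi and step > 0):
            raise ConfigError("grid must be (lo, hi, step) with lo < hi, step > 0")
        if self.noise_sd < 0 or self.gain_sd < 0:
            raise ConfigError("noise_sd and gain_sd must be non-negative")
        if self.n_replicates < 3:
            raise ConfigError("n_replicates must be >= 3 for downstream testing")
        if len(set(self.conditions)) != len(self.conditions) or not self.conditions:
            raise ConfigError("conditions must be nonempty and unique")
        for e in self.effects:
            if e.applies_to not in self.conditions:
                raise ConfigError(f"effect targets unknown condition {e.applies_to!r}")
            if e.band[0] < lo or e.band[1] > hi:
                raise ConfigError(f"effect band {e.band} outside grid span")

    def wavenumbers(self) -> np.ndarray:
        lo, hi, step = self.grid
        n = int(round((hi - lo) / step)) + 1
        return lo + step * np.arange(n)

    def peak_sum(self, w: np.ndarray) -> np.ndarray:
        """Noise-free peak superposition (no baseline, no effects)."""
        out = np.zeros_like(w, dtype=float)
        for pk in self.peaks:
            out += pk.amplitude * np.exp(-0.5 * ((w - pk.center) / pk.width) ** 2)
        return out

    def baseline(self, w: np.ndarray) -> np.ndarray:
        lo, hi, _ = self.grid
        u = (w - lo) / (hi - lo)
        out = np.zeros_like(w, dtype=float)
        for k, c in enumerate(self.baseline_poly):
            out += c * u**k
        out += self.hump_amplitude * np.exp(-0.5 * ((w - 2000.0) / 800.0) ** 2)
        return out

    def condition_signal(self, w: np.ndarray, condition: str) -> np.ndarray:
        """Peak sum plus this condition's band effects (pre-gain, pre-noise)."""
        signal = self.peak_sum(w)
        for e in self.effects:
            if e.applies_to == condition:
                signal = signal + e.delta * ((w >= e.band[0]) & (w <= e.band[1]))
        return signal

    def expected_absorbance(self, w: np.ndarray, condition: str) -> np.ndarray:
        """Analytic mean spectrum (E[gain] = 1, E[noise] = 0)."""
        return self.condition_signal(w, condition) + self.baseline(w)

    def effect_mask(self, w: np.ndarray | None = None) -> np.ndarray:
        """Binary ground truth: 1 where any configured effect touches the grid."""
        if w is None:
            w = self.wavenumbers()
        mask = np.zeros(w.size, dtype=int)
        for e in self.effects:
            mask |= ((w >= e.band[0]) & (w <= e.band[1])).astype(int)
        return mask


def _spectrum_rng(cfg: SyntheticConfig, condition: str, replicate: int) -> np.random.Generator:
    cond_index = cfg.conditions.index(condition)
    ss = np.random.SeedSequence(cfg.seed, spawn_key=(cond_index, replicate))
    return np.random.default_rng(ss)


def simulate_spectrum(cfg: SyntheticConfig, condition: str, replicate: int) -> Spectrum:
    """Draw one replicate spectrum; bit-reproducible from
    (cfg.seed, condition, replicate).  Draw order is fixed: gain first, then
    the noise vector."""
    if condition not in cfg.conditions:
        raise ConfigError(f"unknown condition {condition!r}")
    rng = _spectrum_rng(cfg, condition, replicate)
    w = cfg.wavenumbers()
    gain = 1.0 + cfg.gain_sd * rng.standard_normal()
    noise = cfg.noise_sd * rng.standard_normal(w.size)
    a = gain * cfg.condition_signal(w, condition) + cfg.baseline(w) + noise
    return Spectrum(
        wavenumbers=w,
        absorbance=a,
        sample_id=f"{condition}__rep{replicate}",
        condition=condition,
        replicate=replicate,
    )


def simulate_experiment(cfg: SyntheticConfig) -> tuple[list[SpectrumGroup], np.ndarray]:
    """One group per condition with ``n_replicates`` spectra, plus the binary
    ground-truth mask of truly affected wavenumbers (for power/localization
    scoring)."""
    groups = [
        SpectrumGroup(
            c, [simulate_spectrum(cfg, c, r) for r in range(1, cfg.n_replicates + 1)]
        )
        for c in cfg.conditions
    ]
    return groups, cfg.effect_mask()


def graded_stress_scenario(
    levels: list[str],
    base_delta: float,
    band: tuple[float, float] = (1507.0, 1518.0),
    **overrides,
) -> SyntheticConfig:
    """Control plus a monotone severity ladder of band effects.

    Level k (1-based) gets an effect of k x *base_delta* on *band*,
    mimicking an inhibitor-mixture concentration ladder (A < B < C < D)
    whose biochemical impact grows with dose.
    """
    if not levels:
        raise ConfigError("graded scenario needs at least one level")
    conditions = ["control"] + list(levels)
    effects = [
        EffectSpec(band=band, delta=(k + 1) * base_delta, applies_to=level)
        for k, level in enumerate(levels)
    ]
    return SyntheticConfig(conditions=conditions, effects=effects, **overrides)
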
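"""Cell-viability and fermentation-yield metrics.

Mortality is the percent loss of viable cells relative to an untreated
control suspension, M = (1 - Cv/Ct) x 100, computed from dilution-corrected
plate counts.  Ethanol yields are expressed as percent of the theoretical
maximum (0.51 g ethanol per g of consumed glucose equivalent); cellobiose is
converted to glucose equivalents by the hydrolysis mass gain 360.3/342.3
(one water added per glycosidic bond).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError


@dataclass(frozen=True)
class YieldConstants:
    #: g ethanol per g glucose consumed at the stoichiometric maximum
    max_theoretical_yield: float = 0.51
    #: mass gain on hydrolysis of cellobiose to two glucose (360.3/342.3)
    cellobiose_to_glucose_factor: float = 360.3 / 342.3

    def __post_init__(self) -> None:
        if self.max_theoretical_yield <= 0 or self.cellobiose_to_glucose_factor <= 0:
            raise ConfigError("yield constants must be positive")


@dataclass
class ViabilityRecord:
    """Viable counts of one treated sample and its control."""

    condition: str
    cv: float  # viable count, tested sample (dilution-corrected)
    ct: float  # viable count, control suspension

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ConfigError("control count Ct must be positive")
        if self.cv < 0:
            raise ConfigError("sample count Cv must be non-negative")


def mortality(r: ViabilityRecord) -> float:
    """M = (1 - Cv/Ct) x 100, in percent.

    Values outside [0, 100] are returned unclamped (Cv > Ct means net
    growth in the treated sample) but trigger a warning.
    """
    m = (1.0 - r.cv / r.ct) * 100.0
    if not 0.0 <= m <= 100.0:
        warnings.warn(
            f"{r.condition!r}: mortality {m:.1f}% outside [0, 100] "
            "(treated count exceeds control)",
            stacklevel=2,
        )
    return m


def percent_theoretical_yield(
    ethanol_g_per_l: float,
    consumed_glucose_equiv_g_per_l: float,
    k: YieldConstants = YieldConstants(),
) -> float:
    """Ethanol yield as percent of the stoichiometric maximum."""
    if consumed_glucose_equiv_g_per_l <= 0:
        raise ConfigError("consumed substrate must be positive")
    if ethanol_g_per_l < 0:
        raise ConfigError("ethanol concentration must be non-negative")
    return 100.0 * ethanol_g_per_l / (consumed_glucose_equiv_g_per_l * k.max_theoretical_yield)


def glucose_equivalents(
    cellobiose_g_per_l: float, k: YieldConstants = YieldConstants()
) -> float:
    """Convert a cellobiose concentration to glucose equivalents (g/L)."""
    if cellobiose_g_per_l < 0:
        raise ConfigError("cellobiose concentration must be non-negative")
    return cellobiose_g_per_l * k.cellobiose_to_glucose_factor


def reduce_dilution_series(
    colony_counts, dilution_factors
) -> float:
    """Dilution-corrected viable count: mean of count x dilution factor.

    Plate counting is done in triplicate; no outlier rule is applied, so the
    plain mean of the corrected counts is returned.
    """
    counts = np.asarray(colony_counts, dtype=float)
    dils = np.asarray(dilution_factors, dtype=float)
    if counts.size == 0 or counts.shape != dils.shape:
        raise ConfigError("counts and dilution factors must be equal-length, nonempty")
    if np.any(counts < 0) or np.any(dils <= 0):
        raise ConfigError("counts must be >= 0 and dilution factors > 0")
    return float(np.mean(counts * dils))


def mortality_table(counts: pd.DataFrame, control: str) -> pd.DataFrame:
    """Per-condition mortality from a plate-count table.

    *counts* needs columns ``condition, replicate, dilution_factor,
    colony_count``; each condition's viable count is the mean of its
    dilution-corrected replicate counts, and mortality is taken against the
    *control* condition's count.
    """
    required = {"condition", "replicate", "dilution_factor", "colony_count"}
    missing = required - set(counts.columns)
    if missing:
        raise ConfigError(f"counts table missing column(s) {sorted(missing)}")
    viable = {
        str(cond): reduce_dilution_series(
            sub["colony_count"].to_numpy(), sub["dilution_factor"].to_numpy()
        )
        for cond, sub in counts.groupby("condition", sort=True)
    }
    if control not in viable:
        raise ConfigError(f"control condition {control!r} not in table")
    ct = viable[control]
    rows = []
    for cond, cv in viable.items():
        if cond == control:
            continue
        rows.append((cond, cv, ct, mortality(ViabilityRecord(cond, cv, ct))))
    return pd.DataFrame(rows, columns=["condition", "cv", "ct", "mortality_pct"])
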
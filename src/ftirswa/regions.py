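"""Spectral region windows (W1-W5) and functional-group band assignments.

The microbial whole-cell IR literature conventionally splits the fingerprint
into five windows: fatty acids (W1, 3,000-2,800), amides (W2, 1,800-1,500),
mixed proteins/lipids (W3, 1,500-1,200), polysaccharides (W4, 1,200-900) and
the true fingerprint / "typing" region (W5, 900-600).  Adjacent windows share
their boundary wavenumber; a shared boundary is assigned to the window where
it is the UPPER endpoint (so 1,500 belongs to W3), matching how published
band tables place e.g. the 1,500-1,483 carboxylate band in the mixed region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, GridMismatchError


@dataclass(frozen=True)
class RegionEntry:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ConfigError(f"region {self.name!r}: lo must be < hi")


@dataclass
class RegionMap:
    """Named, interior-disjoint spectral windows."""

    entries: list[RegionEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = [
            e if isinstance(e, RegionEntry) else RegionEntry(*e) for e in self.entries
        ]
        ordered = sorted(self.entries, key=lambda e: e.lo)
        for a, b in zip(ordered, ordered[1:]):
            if b.lo < a.hi:  # shared endpoints allowed, overlapping interiors not
                raise ConfigError(f"regions {a.name!r} and {b.name!r} overlap")

    def assign(self, wavenumber: float) -> str | None:
        """Region name for a wavenumber, or None if unassigned.

        Scans windows in ascending order, so a shared boundary goes to the
        window whose upper endpoint it is.
        """
        for e in sorted(self.entries, key=lambda e: e.lo):
            if e.lo <= wavenumber <= e.hi:
                return e.name
        return None

    def masks(self, grid: np.ndarray) -> dict[str, np.ndarray]:
        """Boolean membership mask per region over *grid* (disjoint)."""
        grid = np.asarray(grid, dtype=float)
        taken = np.zeros(grid.size, dtype=bool)
        out: dict[str, np.ndarray] = {}
        for e in sorted(self.entries, key=lambda e: e.lo):
            m = (grid >= e.lo) & (grid <= e.hi) & ~taken
            out[e.name] = m
            taken |= m
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.name, e.lo, e.hi) for e in self.entries], columns=["name", "lo", "hi"]
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegionMap":
        df = pd.read_csv(path)
        return cls(
            [
                RegionEntry(str(n), float(lo), float(hi))
                for n, lo, hi in zip(df["name"], df["lo"], df["hi"])
            ]
        )


def default_region_map() -> RegionMap:
    """The conventional five microbial-IR windows."""
    return RegionMap(
        [
            RegionEntry("W1 fatty acids", 2800.0, 3000.0),
            RegionEntry("W2 amides", 1500.0, 1800.0),
            RegionEntry("W3 mixed", 1200.0, 1500.0),
            RegionEntry("W4 polysaccharides", 900.0, 1200.0),
            RegionEntry("W5 typing", 600.0, 900.0),
        ]
    )


@dataclass(frozen=True)
class BandAssignment:
    """One functional-group band: [lo, hi] cm^-1 with a label and source key."""

    lo: float
    hi: float
    label: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ConfigError("band lo must be <= hi")

    def contains(self, wavenumber: float) -> bool:
        return self.lo <= wavenumber <= self.hi


def default_band_table() -> list[BandAssignment]:
    """Functional-group bands that distinguish parental vs. recombinant yeast
    fingerprints during stationary growth (aerobic glycerol and
    oxygen-limited glucose blocks)."""
    glycerol = [
        BandAssignment(1711, 1742, "C=O (1,741); Amide I", "glycerol/W2"),
        BandAssignment(1699, 1705, "Amide I", "glycerol/W2"),
        BandAssignment(1686, 1692, "beta-turn (1,686)", "glycerol/W2"),
        BandAssignment(1638, 1638, "Amide I of beta-sheet", "glycerol/W2"),
        BandAssignment(1568, 1624, "Amide I of beta-sheet", "glycerol/W2"),
        BandAssignment(1555, 1559, "Urea/triglycerides", "glycerol/W2"),
        BandAssignment(1501, 1541, "Amide II (1,540)", "glycerol/W2"),
        BandAssignment(1483, 1500, "O=C-O(-) stretch (1,490)", "glycerol/W3"),
        BandAssignment(1470, 1474, "O=C-O(-) stretch", "glycerol/W3"),
        BandAssignment(1454, 1458, "CH2 (1,457)", "glycerol/W3"),
    ]
    glucose = [
        BandAssignment(1634, 1638, "Amide I of beta-sheet", "glucose/W2"),
        BandAssignment(1611, 1626, "Amide I of beta-sheet", "glucose/W2"),
        BandAssignment(1672, 1672, "Turns", "glucose/W2"),
        BandAssignment(1507, 1518, "Amide II shoulder", "glucose/W2"),
        BandAssignment(723, 723, "Phosphate group - nucleic acid", "glucose/W5"),
        BandAssignment(702, 716, "Phosphate group - nucleic acid", "glucose/W5"),
    ]
    return glycerol + glucose


def lookup_bands(
    wavenumber: float, bands: list[BandAssignment] | None = None
) -> list[BandAssignment]:
    """All band assignments whose range contains *wavenumber*."""
    bands = bands if bands is not None else default_band_table()
    return [b for b in bands if b.contains(wavenumber)]


def band_table_frame(bands: list[BandAssignment] | None = None) -> pd.DataFrame:
    bands = bands if bands is not None else default_band_table()
    return pd.DataFrame(
        [(b.lo, b.hi, b.label, b.source) for b in bands],
        columns=["lo", "hi", "label", "source"],
    )


def region_summary(
    sig: np.ndarray, grid: np.ndarray, region_map: RegionMap | None = None
) -> pd.DataFrame:
    """Per-region tally of a binary significance vector.

    Rows: one per region plus an ``unassigned`` bucket; columns:
    ``n_significant`` (significant points in the region), ``n_points``
    (grid points in the region) and ``percent`` (their ratio x 100; 0 for
    empty regions).  Counts across rows partition the totals exactly.
    """
    sig = np.asarray(sig, dtype=int)
    grid = np.asarray(grid, dtype=float)
    if sig.size != grid.size:
        raise GridMismatchError(
            f"significance vector ({sig.size}) and grid ({grid.size}) differ in length"
        )
    region_map = region_map or default_region_map()
    masks = region_map.masks(grid)
    assigned = np.zeros(grid.size, dtype=bool)
    rows = []
    for name, m in masks.items():
        assigned |= m
        n_pts = int(m.sum())
        n_sig = int(sig[m].sum())
        rows.append((name, n_sig, n_pts, 100.0 * n_sig / n_pts if n_pts else 0.0))
    m = ~assigned
    n_pts = int(m.sum())
    n_sig = int(sig[m].sum())
    rows.append(("unassigned", n_sig, n_pts, 100.0 * n_sig / n_pts if n_pts else 0.0))
    return pd.DataFrame(rows, columns=["region", "n_significant", "n_points", "percent"])
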
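"""Containers and file I/O for replicated FTIR absorbance spectra.

A :class:`Spectrum` is one replicate's absorbance trace on a wavenumber grid
(cm^-1); a :class:`SpectrumGroup` collects the replicates of one experimental
condition on an identical grid.  Files may store the grid in either direction
(instrument convention is descending wavenumber); internally the grid is
always ascending, with absorbance values kept paired on reversal.

Supported table dialects:

* ``wide_csv`` — column 1 ``wavenumber_cm-1``, one column per replicate named
  ``<condition>__rep<k>``.
* ``long_csv`` — columns ``wavenumber_cm-1, absorbance, sample_id, condition,
  replicate`` and optional ``timepoint_h``.
* ``jcampdx`` — read-only, ``XYDATA=(X++(Y..Y))`` blocks only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CoverageError,
    ExtrapolationError,
    GridMismatchError,
    SpectrumParseError,
    UniquenessError,
)

#: Two wavenumber grids closer than this (cm^-1, per point) count as identical.
GRID_TOL = 1e-6

WAVENUMBER_COLUMN = "wavenumber_cm-1"

_WIDE_HEADER_RE = re.compile(r"^(?P<condition>.+)__rep(?P<replicate>\d+)$")


@dataclass
class Spectrum:
    """One replicate's absorbance values on an ascending wavenumber grid."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_id: str = ""
    condition: str = ""
    replicate: int = 1
    timepoint_h: float | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if w.ndim != 1 or a.ndim != 1 or w.shape != a.shape:
            raise SpectrumParseError(
                f"wavenumbers and absorbance must be 1-D of equal length, "
                f"got {w.shape} and {a.shape}"
            )
        if w.size < 1:
            raise SpectrumParseError("a spectrum needs at least 1 grid point")
        dw = np.diff(w)
        if w.size >= 2 and np.all(dw < 0):  # descending file order: canonicalize
            w, a = w[::-1], a[::-1]
            dw = -dw[::-1]
        if not np.all(dw > 0):
            raise SpectrumParseError("wavenumber grid must be strictly monotonic")
        if not np.all(np.isfinite(a)):
            raise SpectrumParseError("absorbance contains non-finite values")
        if not np.all(np.isfinite(w)):
            raise SpectrumParseError("wavenumbers contain non-finite values")
        if int(self.replicate) < 1:
            raise SpectrumParseError("replicate index must be a positive integer")
        self.wavenumbers = w
        self.absorbance = a
        self.replicate = int(self.replicate)
        if not self.sample_id:
            self.sample_id = f"{self.condition}__rep{self.replicate}"

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_absorbance(self, absorbance: np.ndarray) -> "Spectrum":
        """Copy of this spectrum with new absorbance, metadata preserved."""
        return replace(self, absorbance=np.asarray(absorbance, dtype=float))


def grids_equal(w1: np.ndarray, w2: np.ndarray, tol: float = GRID_TOL) -> bool:
    return w1.shape == w2.shape and bool(np.all(np.abs(w1 - w2) <= tol))


@dataclass
class SpectrumGroup:
    """Replicate spectra of one condition, all on one identical grid."""

    condition: str
    spectra: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.spectra:
            raise SpectrumParseError(f"group {self.condition!r} has no spectra")
        ref = self.spectra[0].wavenumbers
        for s in self.spectra[1:]:
            if not grids_equal(ref, s.wavenumbers):
                raise GridMismatchError(
                    f"replicates of {self.condition!r} are on different grids"
                )

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.spectra[0].wavenumbers

    @property
    def n_replicates(self) -> int:
        return len(self.spectra)

    def absorbance_matrix(self) -> np.ndarray:
        """Replicates x wavenumbers matrix."""
        return np.vstack([s.absorbance for s in self.spectra])

    def __len__(self) -> int:
        return len(self.spectra)


# ---------------------------------------------------------------------------
# reading


def _read_wide(path: Path) -> list[SpectrumGroup]:
    with open(path) as fh:  # raw header: pandas silently renames duplicates
        header = fh.readline().rstrip("\n").split(",")
    dupes = {c for c in header if header.count(c) > 1}
    if dupes:
        raise UniquenessError(f"duplicate sample column(s) {sorted(dupes)}")
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != WAVENUMBER_COLUMN:
        raise SpectrumParseError(
            f"first column must be {WAVENUMBER_COLUMN!r}, got {df.columns[0]!r}"
        )
    keys: list[tuple[str, int]] = []
    for col in df.columns[1:]:
        m = _WIDE_HEADER_RE.match(col)
        if m is None:
            raise SpectrumParseError(
                f"sample column {col!r} does not match '<condition>__rep<k>'"
            )
        key = (m["condition"], int(m["replicate"]))
        if key in keys:
            raise UniquenessError(f"duplicate sample column for {key}")
        keys.append(key)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            raise SpectrumParseError(
                f"non-numeric value in column {col!r} at row {int(bad.idxmax())}"
            )
        if vals.isna().any():
            raise SpectrumParseError(f"missing value in column {col!r}")
        df[col] = vals
    w = df[WAVENUMBER_COLUMN].to_numpy(dtype=float)
    groups: dict[str, list[Spectrum]] = {}
    for col, (condition, rep) in zip(df.columns[1:], keys):
        s = Spectrum(
            wavenumbers=w,
            absorbance=df[col].to_numpy(dtype=float),
            sample_id=col,
            condition=condition,
            replicate=rep,
        )
        groups.setdefault(condition, []).append(s)
    return [SpectrumGroup(c, specs) for c, specs in groups.items()]


_LONG_REQUIRED = [WAVENUMBER_COLUMN, "absorbance", "sample_id", "condition", "replicate"]


def _read_long(path: Path) -> list[SpectrumGroup]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _LONG_REQUIRED if c not in df.columns]
    if missing:
        raise SpectrumParseError(f"long CSV missing column(s) {missing}")
    for col in (WAVENUMBER_COLUMN, "absorbance"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            raise SpectrumParseError(
                f"non-numeric value in column {col!r} at row {int(bad.idxmax())}"
            )
        df[col] = vals
    groups: dict[str, list[Spectrum]] = {}
    seen: set[tuple[str, int]] = set()
    for (condition, rep), sub in df.groupby(["condition", "replicate"], sort=True):
        key = (str(condition), int(rep))
        if key in seen:  # pragma: no cover - groupby already dedupes keys
            raise UniquenessError(f"duplicate (condition, replicate) {key}")
        seen.add(key)
        sub = sub.sort_values(WAVENUMBER_COLUMN)
        if sub[WAVENUMBER_COLUMN].duplicated().any():
            raise UniquenessError(
                f"duplicate wavenumber rows for (condition, replicate) {key}"
            )
        tp = None
        if "timepoint_h" in sub.columns and sub["timepoint_h"].notna().any():
            tp = float(sub["timepoint_h"].iloc[0])
        s = Spectrum(
            wavenumbers=sub[WAVENUMBER_COLUMN].to_numpy(dtype=float),
            absorbance=sub["absorbance"].to_numpy(dtype=float),
            sample_id=str(sub["sample_id"].iloc[0]),
            condition=str(condition),
            replicate=int(rep),
            timepoint_h=tp,
        )
        groups.setdefault(str(condition), []).append(s)
    return [SpectrumGroup(c, specs) for c, specs in groups.items()]


def _read_jcampdx(path: Path) -> list[SpectrumGroup]:
    """Minimal JCAMP-DX reader for ``XYDATA=(X++(Y..Y))`` AFFN blocks."""
    text = Path(path).read_text()
    fields: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("##"):
            name, _, value = line[2:].partition("=")
            name = name.strip().upper().replace(" ", "")
            value = value.strip()
            if name == "XYDATA":
                if value.replace(" ", "") != "(X++(Y..Y))":
                    raise SpectrumParseError(
                        f"unsupported XYDATA dialect {value!r}; "
                        "only (X++(Y..Y)) is handled"
                    )
                in_data = True
                continue
            if name == "END":
                in_data = False
                continue
            fields[name] = value
        elif in_data:
            data_lines.append(line)
    if not data_lines:
        raise SpectrumParseError("no XYDATA=(X++(Y..Y)) block found")
    try:
        npoints = int(float(fields["NPOINTS"]))
        firstx = float(fields["FIRSTX"])
        lastx = float(fields["LASTX"])
    except KeyError as exc:
        raise SpectrumParseError(f"missing required JCAMP-DX field ##{exc.args[0]}")
    xfactor = float(fields.get("XFACTOR", 1.0))
    yfactor = float(fields.get("YFACTOR", 1.0))
    ys: list[float] = []
    for line in data_lines:
        tokens = line.split()
        try:
            values = [float(t) for t in tokens]
        except ValueError:
            raise SpectrumParseError(f"non-numeric JCAMP-DX data line: {line!r}")
        ys.extend(values[1:])  # token 0 is the line's leading X value
    if len(ys) != npoints:
        raise SpectrumParseError(
            f"##NPOINTS={npoints} but data block holds {len(ys)} Y values"
        )
    w = (firstx + (lastx - firstx) * np.arange(npoints) / (npoints - 1)) * xfactor
    a = np.asarray(ys, dtype=float) * yfactor
    title = fields.get("TITLE", Path(path).stem)
    s = Spectrum(wavenumbers=w, absorbance=a, sample_id=title, condition=title)
    return [SpectrumGroup(s.condition, [s])]


_READERS = {"wide_csv": _read_wide, "long_csv": _read_long, "jcampdx": _read_jcampdx}


def read_spectrum_table(path: str | Path, dialect: str = "wide_csv") -> list[SpectrumGroup]:
    """Read replicated spectra from *path*, grouped by condition.

    Grids written in descending order are reversed to the canonical ascending
    order with absorbance values kept paired, so both encodings of the same
    data produce identical in-memory objects.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        reader = _READERS[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(_READERS)}")
    return reader(path)


# ---------------------------------------------------------------------------
# writing


def write_spectrum_table(
    groups: Sequence[SpectrumGroup], path: str | Path, dialect: str = "wide_csv"
) -> Path:
    """Write *groups* to *path*; ``read(write(x))`` reproduces ``x`` exactly.

    Floats are serialized at full ``repr`` precision so the round trip is
    bit-for-bit.  All groups must share one grid (wide dialect).
    """
    path = Path(path)
    if dialect == "wide_csv":
        cols: dict[str, np.ndarray] = {}
        ref: np.ndarray | None = None
        for g in groups:
            if ref is None:
                ref = g.wavenumbers
            elif not grids_equal(ref, g.wavenumbers):
                raise GridMismatchError("groups to be written share no common grid")
            for s in g.spectra:
                cols[f"{s.condition}__rep{s.replicate}"] = s.absorbance
        if ref is None:  # empty group list -> header-only file
            pd.DataFrame(columns=[WAVENUMBER_COLUMN]).to_csv(path, index=False)
            return path
        df = pd.DataFrame({WAVENUMBER_COLUMN: ref, **cols})
        # repr() emits the shortest string that parses back to the same float,
        # making the round trip bit-for-bit
        df.to_csv(path, index=False, float_format=lambda x: repr(float(x)))
        return path
    if dialect == "long_csv":
        rows = []
        for g in groups:
            for s in g.spectra:
                rows.append(
                    pd.DataFrame(
                        {
                            WAVENUMBER_COLUMN: s.wavenumbers,
                            "absorbance": s.absorbance,
                            "sample_id": s.sample_id,
                            "condition": s.condition,
                            "replicate": s.replicate,
                            "timepoint_h": s.timepoint_h,
                        }
                    )
                )
        if rows:
            pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format=lambda x: repr(float(x)))
        else:
            pd.DataFrame(columns=_LONG_REQUIRED + ["timepoint_h"]).to_csv(path, index=False)
        return path
    raise ValueError(f"unknown dialect {dialect!r} for writing")


# ---------------------------------------------------------------------------
# resampling


def resample_to_grid(s: Spectrum, grid: Iterable[float]) -> Spectrum:
    """Linearly interpolate *s* onto *grid* (must lie within the source span)."""
    grid = np.asarray(list(grid) if not isinstance(grid, np.ndarray) else grid, dtype=float)
    lo, hi = s.wavenumbers[0], s.wavenumbers[-1]
    if grid.min() < lo - GRID_TOL or grid.max() > hi + GRID_TOL:
        raise ExtrapolationError(
            f"target grid [{grid.min()}, {grid.max()}] exceeds source span [{lo}, {hi}]"
        )
    a = np.interp(grid, s.wavenumbers, s.absorbance)
    return replace(s, wavenumbers=grid, absorbance=a)


def require_window(s: Spectrum, lo: float, hi: float, what: str = "window") -> None:
    """Raise CoverageError unless the grid spans [lo, hi]."""
    if s.wavenumbers[0] > lo + GRID_TOL or s.wavenumbers[-1] < hi - GRID_TOL:
        raise CoverageError(
            f"grid [{s.wavenumbers[0]}, {s.wavenumbers[-1]}] does not cover "
            f"{what} [{lo}, {hi}]"
        )
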
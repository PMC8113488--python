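"""Localization-table I/O and the coordinate conventions shared by all modules.

Coordinates are continuous positions in nanometers. The origin sits at the
field-of-view corner, with x increasing rightward and y increasing downward
(matching image row/column order: row = y, column = x). All spatial intervals
are half-open on the right/bottom, so a localization exactly on the far edge
of a field of view or pixel belongs to the next bin and is excluded.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LocalizationTable",
    "FieldOfView",
    "LocalizationFormatError",
    "LocalizationParseError",
    "read_localizations",
    "write_localizations",
    "filter_fov",
    "subsample",
]


class LocalizationFormatError(ValueError):
    """Input file lacks a required column or has an unusable layout."""


class LocalizationParseError(ValueError):
    """A cell in the input file could not be converted to a number."""


# Header spellings accepted for automatic column detection. Keys are canonical
# field names; values are lower-cased candidate headers (whitespace collapsed).
_HEADER_ALIASES = {
    "x": ("x [nm]", "x[nm]", "x (nm)", "x_nm", "x"),
    "y": ("y [nm]", "y[nm]", "y (nm)", "y_nm", "y"),
    "uncertainty": (
        "uncertainty [nm]",
        "uncertainty_xy [nm]",
        "uncertainty[nm]",
        "uncertainty",
        "precision [nm]",
        "precision",
    ),
    "frame": ("frame", "frame_ix", "t"),
}


@dataclass(frozen=True)
class LocalizationTable:
    """Ordered records of 2D emitter localizations.

    Parameters
    ----------
    x, y:
        Positions in nm; equal-length 1D arrays.
    uncertainty:
        Optional per-localization precision (nm), non-negative.
    frame:
        Optional acquisition frame index per localization.
    """

    x: np.ndarray
    y: np.ndarray
    uncertainty: np.ndarray | None = None
    frame: np.ndarray | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be 1D arrays of equal length")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("localization positions must be finite")
        if self.uncertainty is not None:
            u = np.asarray(self.uncertainty, dtype=float)
            object.__setattr__(self, "uncertainty", u)
            if u.shape != x.shape:
                raise ValueError("uncertainty length must match x/y")
            if np.any(u < 0):
                raise ValueError("uncertainties must be non-negative")
        if self.frame is not None:
            f = np.asarray(self.frame)
            if not np.issubdtype(f.dtype, np.integer):
                f = f.astype(np.int64)
            object.__setattr__(self, "frame", f)
            if f.shape != x.shape:
                raise ValueError("frame length must match x/y")

    def __len__(self) -> int:
        return self.x.size

    def take(self, idx: np.ndarray) -> "LocalizationTable":
        """Return the sub-table at integer/boolean index ``idx`` (order kept)."""
        return LocalizationTable(
            x=self.x[idx],
            y=self.y[idx],
            uncertainty=None if self.uncertainty is None else self.uncertainty[idx],
            frame=None if self.frame is None else self.frame[idx],
        )


@dataclass(frozen=True)
class FieldOfView:
    """Axis-aligned rectangle in nm; membership is half-open on the far edges."""

    x0: float
    y0: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError("FieldOfView width and height must be positive")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (
            (x >= self.x0)
            & (x < self.x0 + self.width)
            & (y >= self.y0)
            & (y < self.y0 + self.height)
        )


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def _normalize(name: str) -> str:
    return " ".join(str(name).strip().lower().split())


def _resolve_columns(columns, column_map):
    resolved: dict[str, str] = {}
    if column_map:
        for canonical, actual in column_map.items():
            if actual in columns:
                resolved[canonical] = actual
    normed = {_normalize(c): c for c in columns}
    for canonical, aliases in _HEADER_ALIASES.items():
        if canonical in resolved:
            continue
        for alias in aliases:
            if alias in normed:
                resolved[canonical] = normed[alias]
                break
    return resolved


def read_localizations(
    path,
    column_map: dict[str, str] | None = None,
    unit_scale: float = 1.0,
) -> LocalizationTable:
    """Read a delimited localization table (ThunderSTORM-style headers).

    Parameters
    ----------
    path:
        Delimited text file with one header row; comma, semicolon or tab
        delimited (auto-detected).
    column_map:
        Optional mapping from canonical names (``x``, ``y``, ``uncertainty``,
        ``frame``) to the actual column headers, overriding auto-detection.
    unit_scale:
        Multiplier converting file position units to nm (e.g. 1000 for µm
        data). Applied to x, y and uncertainty.

    Returns
    -------
    LocalizationTable
        Positions in nm, with uncertainty and frame columns when present.
    """
    with open(path, "r", newline="") as fh:
        text = fh.read()
    header_line = text.splitlines()[0] if text else ""
    sep = _sniff_delimiter(header_line or text[:4096])
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str, skipinitialspace=True)

    cols = _resolve_columns(df.columns, column_map)
    for required in ("x", "y"):
        if required not in cols:
            raise LocalizationFormatError(
                f"no '{required}' column found in {path!s}; "
                f"available columns: {list(df.columns)}"
            )

    def _numeric(canonical: str) -> np.ndarray:
        raw = df[cols[canonical]]
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna() & raw.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise LocalizationParseError(
                f"non-numeric value {raw.iloc[row]!r} in column "
                f"{cols[canonical]!r} at data row {row + 1}"
            )
        return vals.to_numpy(dtype=float)

    x = _numeric("x") * unit_scale
    y = _numeric("y") * unit_scale
    uncertainty = _numeric("uncertainty") * unit_scale if "uncertainty" in cols else None
    frame = None
    if "frame" in cols:
        frame = _numeric("frame").astype(np.int64)
    return LocalizationTable(x=x, y=y, uncertainty=uncertainty, frame=frame)


def write_localizations(table: LocalizationTable, path) -> None:
    """Write a table as CSV with ThunderSTORM-style headers, ≥9 sig. digits."""
    data: dict[str, np.ndarray] = {"x [nm]": table.x, "y [nm]": table.y}
    if table.uncertainty is not None:
        data["uncertainty [nm]"] = table.uncertainty
    if table.frame is not None:
        data["frame"] = table.frame
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")


def filter_fov(table: LocalizationTable, fov: FieldOfView) -> LocalizationTable:
    """Keep localizations inside ``fov`` and shift them to the FOV origin.

    Membership is half-open (a point exactly on the right/bottom edge is
    dropped); record order is preserved. Returned coordinates have the FOV
    corner at (0, 0), which guarantees valid pixel indices downstream.
    """
    keep = fov.contains(table.x, table.y)
    out = table.take(keep)
    return replace(out, x=out.x - fov.x0, y=out.y - fov.y0)


def subsample(
    table: LocalizationTable,
    n: int,
    mode: str = "first_by_frame",
    seed: int = 0,
) -> LocalizationTable:
    """Return ``n`` localizations, by acquisition order or at random.

    ``first_by_frame`` keeps the n records with the smallest frame index
    (stable tie-break by record order) and requires a frame column;
    ``random`` draws n records without replacement using ``seed``.
    ``n >= len(table)`` returns the full table.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n >= len(table):
        return table
    if mode == "first_by_frame":
        if table.frame is None:
            raise ValueError(
                "table has no frame column; use mode='random' to subsample"
            )
        order = np.argsort(table.frame, kind="stable")
        idx = np.sort(order[:n])  # keep original record order
        return table.take(idx)
    if mode == "random":
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(table), size=n, replace=False))
        return table.take(idx)
    raise ValueError(f"unknown subsample mode {mode!r}")
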
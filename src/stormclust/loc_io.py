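"""Reading and writing localization tables and cluster tables.

The native format is plain CSV with header
``blink_id,frame,x_nm,y_nm,channel,intensity``; only the coordinate columns
are mandatory on input, the rest are defaulted. A ThunderSTORM-style dialect
(columns like ``x [nm]`` / ``x [um]``, ``frame``, ``id``) is also readable;
coordinates are converted to nm on ingest so everything downstream works in
a single unit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ValidationError
from .geometry import NM_PER_UM, FieldGeometry

NATIVE_COLUMNS = ["blink_id", "frame", "x_nm", "y_nm", "channel", "intensity"]

# ThunderSTORM exports name coordinate columns "x [nm]" or "x [um]" (unit in
# brackets); "id" and "frame" are plain. Intensity may carry a unit too.
_TS_COORD = re.compile(r"^\s*([xy])\s*\[\s*(nm|um|µm)\s*\]\s*$")
_TS_INTENSITY = re.compile(r"^\s*intensity(\s*\[.*\])?\s*$")


@dataclass
class LocalizationTable:
    """A table of single-molecule localizations ("blinks").

    One row per detected blink: integer ``blink_id`` (unique), ``frame``,
    coordinates ``x_nm``/``y_nm`` in nanometres, small-integer ``channel``
    (0-based, contiguous) and optional ``intensity`` (arbitrary units, NaN
    when absent). ``geometry`` describes the analysis region.
    """

    data: pd.DataFrame
    geometry: FieldGeometry

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in NATIVE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"localization table missing columns {missing}")
        self.data = df = df[NATIVE_COLUMNS].reset_index(drop=True)
        for col, dtype in (("blink_id", np.int64), ("frame", np.int64), ("channel", np.int64)):
            df[col] = df[col].astype(dtype)
        for col in ("x_nm", "y_nm", "intensity"):
            df[col] = df[col].astype(np.float64)
        self.validate()

    def validate(self) -> None:
        df = self.data
        if len(df) == 0:
            return
        xy = df[["x_nm", "y_nm"]].to_numpy()
        if not np.isfinite(xy).all():
            raise ValidationError("coordinates must be finite")
        g = self.geometry
        if xy[:, 0].min() < 0 or xy[:, 0].max() > g.width or xy[:, 1].min() < 0 or xy[:, 1].max() > g.height:
            raise ValidationError("coordinates fall outside the field geometry")
        if df["blink_id"].duplicated().any():
            raise ValidationError("blink_id values must be unique")
        channels = np.sort(df["channel"].unique())
        if not np.array_equal(channels, np.arange(len(channels))):
            raise ValidationError("channel values must be contiguous starting at 0")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_channels(self) -> int:
        return 0 if len(self.data) == 0 else int(self.data["channel"].max()) + 1

    def points(self, channel: Optional[int] = None) -> np.ndarray:
        """(n, 2) array of coordinates in nm, optionally for one channel."""
        df = self.data if channel is None else self.data[self.data["channel"] == channel]
        return df[["x_nm", "y_nm"]].to_numpy()

    def select_channel(self, channel: int) -> "LocalizationTable":
        df = self.data[self.data["channel"] == channel].copy()
        df["channel"] = 0
        return LocalizationTable(df, self.geometry)

    def crop(self, x0: float, y0: float, x1: float, y1: float) -> "LocalizationTable":
        """Region-of-interest crop; coordinates re-referenced to the ROI origin."""
        df = self.data
        keep = (df["x_nm"] >= x0) & (df["x_nm"] <= x1) & (df["y_nm"] >= y0) & (df["y_nm"] <= y1)
        out = df[keep].copy()
        out["x_nm"] -= x0
        out["y_nm"] -= y0
        geom = FieldGeometry(x1 - x0, y1 - y0, "open")
        return LocalizationTable(out, geom)

    @classmethod
    def from_arrays(
        cls,
        x_nm: np.ndarray,
        y_nm: np.ndarray,
        frame: Optional[np.ndarray] = None,
        channel: Optional[np.ndarray] = None,
        intensity: Optional[np.ndarray] = None,
        geometry: Optional[FieldGeometry] = None,
    ) -> "LocalizationTable":
        x = np.asarray(x_nm, dtype=float)
        n = len(x)
        df = pd.DataFrame(
            {
                "blink_id": np.arange(n, dtype=np.int64),
                "frame": np.zeros(n, dtype=np.int64) if frame is None else np.asarray(frame),
                "x_nm": x,
                "y_nm": np.asarray(y_nm, dtype=float),
                "channel": np.zeros(n, dtype=np.int64) if channel is None else np.asarray(channel),
                "intensity": np.full(n, np.nan) if intensity is None else np.asarray(intensity, dtype=float),
            }
        )
        if geometry is None:
            geometry = FieldGeometry.from_bounding_box(df[["x_nm", "y_nm"]].to_numpy())
        return cls(df, geometry)


def _coerce_numeric(series: pd.Series, colname: str) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"non-numeric value {series.iloc[row]!r} in column {colname!r} at data row {row + 1}"
        )
    return out


def read_localizations(
    path: str | Path,
    dialect: str = "native",
    geometry: Optional[FieldGeometry] = None,
) -> LocalizationTable:
    """Read a localization table, normalizing coordinates to nm.

    Parameters
    ----------
    path : path to a delimited text file with a header row.
    dialect : {"native", "thunderstorm"}
        ``native`` expects ``x_nm``/``y_nm`` (other native columns optional);
        ``thunderstorm`` expects ``x [nm]``/``y [nm]`` or ``x [um]``/``y [um]``.
    geometry : FieldGeometry, optional
        If absent, inferred as the bounding box rounded up to whole um.
    """
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip().strip('"') for c in raw.columns]
    if dialect == "native":
        cols = {c: c for c in raw.columns}
        required = ("x_nm", "y_nm")
        scale = {"x_nm": 1.0, "y_nm": 1.0}
        mapping = {"x_nm": "x_nm", "y_nm": "y_nm", "blink_id": "blink_id",
                   "frame": "frame", "channel": "channel", "intensity": "intensity"}
        for col in required:
            if col not in cols:
                raise FormatError(f"native dialect requires column {col!r}")
    elif dialect == "thunderstorm":
        mapping, scale = {}, {}
        for c in raw.columns:
            m = _TS_COORD.match(c)
            if m:
                axis, unit = m.group(1), m.group(2)
                mapping[f"{axis}_nm"] = c
                scale[f"{axis}_nm"] = 1.0 if unit == "nm" else NM_PER_UM
            elif c.strip().lower() == "id":
                mapping["blink_id"] = c
            elif c.strip().lower() == "frame":
                mapping["frame"] = c
            elif c.strip().lower() == "channel":
                mapping["channel"] = c
            elif _TS_INTENSITY.match(c.strip().lower()):
                mapping["intensity"] = c
        for col in ("x_nm", "y_nm"):
            if col not in mapping:
                raise FormatError(
                    f"thunderstorm dialect requires a column like '{col[0]} [nm]' (missing {col!r})"
                )
    else:
        raise FormatError(f"unknown dialect {dialect!r}")

    n = len(raw)
    out = pd.DataFrame(index=range(n))
    for col in ("x_nm", "y_nm"):
        out[col] = _coerce_numeric(raw[mapping[col]], mapping[col]) * scale.get(col, 1.0)
    for col, default in (("blink_id", None), ("frame", 0), ("channel", 0), ("intensity", np.nan)):
        if col in mapping and mapping[col] in raw.columns:
            out[col] = _coerce_numeric(raw[mapping[col]], mapping[col])
            if col != "intensity":
                out[col] = out[col].fillna(0).astype(np.int64)
        elif default is None:
            out[col] = np.arange(n, dtype=np.int64)
        else:
            out[col] = default
    if geometry is None:
        geometry = FieldGeometry.from_bounding_box(out[["x_nm", "y_nm"]].to_numpy())
    return LocalizationTable(out, geometry)


def write_localizations(table: LocalizationTable, path: str | Path) -> None:
    """Write the native CSV format; round-trips exactly for finite decimal input."""
    table.data.to_csv(path, index=False, columns=NATIVE_COLUMNS)


def write_cluster_table(assignment, path: str | Path) -> None:
    """Write per-blink cluster labels (noise encoded as -1)."""
    df = pd.DataFrame(
        {
            "blink_id": assignment.source.data["blink_id"].to_numpy(),
            "coarse_label": assignment.coarse_label,
            "final_label": assignment.final_label,
        }
    )
    df.to_csv(path, index=False)


def read_cluster_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("blink_id", "coarse_label", "final_label") if c not in df.columns]
    if missing:
        raise FormatError(f"cluster table missing columns {missing}")
    return df.astype(np.int64)
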
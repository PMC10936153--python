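"""Volume and table I/O plus the shared two-channel data model.

Axis convention used throughout the package: ``(t,) z, y, x`` with 0-based
indices.  The time axis, when present, is the leading axis.  Volumes are
written as multi-page TIFF, one file per channel; results go to CSV.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import ShapeMismatchError

#: Fixed column order of the colocalization CSV (see write_coloc_csv).
COLOC_CSV_COLUMNS = [
    "image_id",
    "t",
    "pcc",
    "m1",
    "m2",
    "overlap",
    "threshold_green",
    "threshold_red_low",
    "threshold_red_high",
    "n_region_voxels",
    "region_mode",
    "qc_fail",
    "qc_reason",
]


@dataclass
class ChannelPairVolume:
    """Aligned red/green intensity volumes.

    Parameters
    ----------
    red, green:
        Arrays of identical shape, either ``(z, y, x)`` or ``(t, z, y, x)``.
        Intensities must be non-negative.
    voxel_size_um:
        Physical voxel spacing ``(dz, dy, dx)`` in micrometres.
    """

    red: np.ndarray
    green: np.ndarray
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red)
        self.green = np.asarray(self.green)
        if self.red.shape != self.green.shape:
            raise ShapeMismatchError(
                f"red shape {self.red.shape} != green shape {self.green.shape}"
            )
        if self.red.ndim not in (3, 4):
            raise ValueError(
                f"expected (z,y,x) or (t,z,y,x) volume, got ndim={self.red.ndim}"
            )
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)  # type: ignore[assignment]
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError(f"invalid voxel size {self.voxel_size_um}")
        if self.red.size and (self.red.min() < 0 or self.green.min() < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def has_time(self) -> bool:
        return self.red.ndim == 4

    @property
    def n_timepoints(self) -> int:
        return self.red.shape[0] if self.has_time else 1

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return tuple(self.red.shape[-3:])  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size_um
        return dz * dy * dx

    def frame(self, t: int) -> "ChannelPairVolume":
        """Single-timepoint view of a 4D pair (identity for 3D pairs at t=0)."""
        if not self.has_time:
            if t != 0:
                raise IndexError("3D pair has a single timepoint, t must be 0")
            return self
        return ChannelPairVolume(self.red[t], self.green[t], self.voxel_size_um)


def read_pair(
    red_path: str | Path,
    green_path: str | Path,
    voxel_size_um: tuple[float, float, float],
) -> ChannelPairVolume:
    """Read one multi-page TIFF per channel into an aligned pair.

    2D images are promoted to single-slice 3D volumes.  Shape disagreement
    between the channels raises :class:`ShapeMismatchError` naming both
    shapes.
    """
    red = tifffile.imread(str(red_path))
    green = tifffile.imread(str(green_path))
    if red.ndim == 2:
        red = red[np.newaxis]
    if green.ndim == 2:
        green = green[np.newaxis]
    if red.shape != green.shape:
        raise ShapeMismatchError(
            f"red {red_path} has shape {red.shape} but green {green_path} "
            f"has shape {green.shape}"
        )
    return ChannelPairVolume(red, green, voxel_size_um)


def write_pair(
    pair: ChannelPairVolume, red_path: str | Path, green_path: str | Path
) -> None:
    """Write each channel as a multi-page TIFF (bit-exact round trip)."""
    tifffile.imwrite(str(red_path), pair.red, photometric="minisblack")
    tifffile.imwrite(str(green_path), pair.green, photometric="minisblack")


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float) and math.isnan(value):
        return ""
    if isinstance(value, bool) or isinstance(value, np.bool_):
        return "true" if value else "false"
    if isinstance(value, float):
        return format(value, ".12g")
    return str(value)


def write_coloc_csv(results: Sequence, path: str | Path) -> None:
    """Write colocalization results to CSV, one row per image/timepoint.

    Column order is fixed (:data:`COLOC_CSV_COLUMNS`); floats are written
    with 12 significant digits; NaN coefficients become empty cells and are
    flagged through the ``qc_fail`` column.
    """
    if len(results) == 0:
        raise ValueError("cannot write an empty result list")
    rows = []
    for r in results:
        row = r.to_row() if hasattr(r, "to_row") else dict(r)
        rows.append({c: _format_cell(row.get(c)) for c in COLOC_CSV_COLUMNS})
    frame = pd.DataFrame(rows, columns=COLOC_CSV_COLUMNS)
    frame.to_csv(str(path), index=False)


def read_coloc_csv(path: str | Path) -> pd.DataFrame:
    """Read a colocalization CSV back into a typed DataFrame."""
    frame = pd.read_csv(str(path))
    for col in ("pcc", "m1", "m2", "overlap", "threshold_green",
                "threshold_red_low", "threshold_red_high"):
        if col in frame:
            frame[col] = pd.to_numeric(frame[col], errors="coerce")
    if "qc_fail" in frame:
        frame["qc_fail"] = frame["qc_fail"].map(
            lambda v: str(v).strip().lower() == "true"
        )
    return frame


def results_to_frame(results: Sequence) -> pd.DataFrame:
    """In-memory DataFrame with the same columns as the CSV on disk."""
    rows = [r.to_row() if hasattr(r, "to_row") else dict(r) for r in results]
    return pd.DataFrame(rows, columns=COLOC_CSV_COLUMNS)
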
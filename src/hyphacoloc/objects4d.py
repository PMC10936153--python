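"""Object-level analysis of compartments over time.

Connected-component labeling of foreground masks, per-object channel
overlap, masking of one channel by the other's foreground, and simple
greedy frame-to-frame linking.  Object tables are pandas DataFrames with
physical (micrometre) centroids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ShapeMismatchError
from .segmentation import BinaryMask
from .volume_io import ChannelPairVolume

__all__ = [
    "ObjectTable",
    "label_components",
    "object_overlap",
    "mask_green_over_red",
    "link_objects",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}

TABLE_COLUMNS = [
    "label_id", "t", "centroid_z_um", "centroid_y_um", "centroid_x_um",
    "volume_vox", "volume_um3", "mean_red", "mean_green",
    "overlap_fraction", "track_id",
]


@dataclass
class ObjectTable:
    """Labeled components of one timepoint: table + label volume."""

    table: pd.DataFrame
    labels: np.ndarray
    voxel_size_um: tuple[float, float, float]
    t: int = 0

    @property
    def n_objects(self) -> int:
        return len(self.table)


def label_components(
    mask: BinaryMask | np.ndarray,
    voxel_size_um: tuple[float, float, float],
    connectivity: int = 26,
    intensity_red: Optional[np.ndarray] = None,
    intensity_green: Optional[np.ndarray] = None,
    t: int = 0,
) -> ObjectTable:
    """Connected components of a 3D mask under 6/18/26-connectivity.

    Centroids are reported in physical micrometres (voxel centers at
    ``(i + 0.5) * d``).  Mean per-channel intensities are filled when the
    intensity volumes are given.  An empty mask gives an empty table.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    raw = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if raw.ndim != 3:
        raise ValueError("label_components expects a 3D mask")
    labels, n = ndimage.label(raw, structure=_STRUCTURES[connectivity])
    dz, dy, dx = voxel_size_um
    voxel_volume = dz * dy * dx
    rows = []
    if n:
        ids = np.arange(1, n + 1)
        volumes = ndimage.sum_labels(raw, labels, ids).astype(int)
        centroids = ndimage.center_of_mass(raw, labels, ids)
        mean_r = (
            ndimage.mean(intensity_red, labels, ids)
            if intensity_red is not None else [float("nan")] * n
        )
        mean_g = (
            ndimage.mean(intensity_green, labels, ids)
            if intensity_green is not None else [float("nan")] * n
        )
        for i, vol, c, mr, mg in zip(ids, volumes, centroids, mean_r, mean_g):
            rows.append({
                "label_id": int(i),
                "t": t,
                "centroid_z_um": (c[0] + 0.5) * dz,
                "centroid_y_um": (c[1] + 0.5) * dy,
                "centroid_x_um": (c[2] + 0.5) * dx,
                "volume_vox": int(vol),
                "volume_um3": vol * voxel_volume,
                "mean_red": float(mr),
                "mean_green": float(mg),
                "overlap_fraction": float("nan"),
                "track_id": pd.NA,
            })
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return ObjectTable(table, labels, tuple(voxel_size_um), t=t)


def object_overlap(
    table_red: ObjectTable,
    table_green: ObjectTable,
    mask_red: BinaryMask | np.ndarray,
    mask_green: BinaryMask | np.ndarray,
) -> tuple[ObjectTable, ObjectTable]:
    """Per-object overlap with the other channel's foreground mask.

    For each red object, ``overlap_fraction = |object ∩ mask_green| /
    |object|``; symmetric for green objects.  Returns new tables with the
    column filled.
    """
    mr = mask_red.mask if isinstance(mask_red, BinaryMask) else np.asarray(mask_red, bool)
    mg = mask_green.mask if isinstance(mask_green, BinaryMask) else np.asarray(mask_green, bool)
    if mr.shape != mg.shape or table_red.labels.shape != mr.shape:
        raise ShapeMismatchError(
            f"mask shapes differ: red {mr.shape}, green {mg.shape}, "
            f"labels {table_red.labels.shape}"
        )

    def _fill(table: ObjectTable, other_mask: np.ndarray) -> ObjectTable:
        df = table.table.copy()
        if len(df):
            ids = df["label_id"].to_numpy()
            inter = ndimage.sum_labels(
                other_mask.astype(np.float64), table.labels, ids
            )
            df["overlap_fraction"] = inter / df["volume_vox"].to_numpy()
        return ObjectTable(df, table.labels, table.voxel_size_um, t=table.t)

    return _fill(table_red, mg), _fill(table_green, mr)


def mask_green_over_red(
    pair: ChannelPairVolume, mask_green: BinaryMask | np.ndarray
) -> tuple[ChannelPairVolume, dict]:
    """Retain red intensity only where the green foreground mask is true.

    The summary reports the intensity-weighted fraction of red signal
    retained (1.0 for an all-true mask, 0.0 for an empty one).
    """
    mg = mask_green.mask if isinstance(mask_green, BinaryMask) else np.asarray(mask_green, bool)
    if mg.shape != pair.red.shape:
        raise ShapeMismatchError(
            f"mask shape {mg.shape} != volume shape {pair.red.shape}"
        )
    masked_red = np.where(mg, pair.red, 0.0)
    total = float(np.sum(pair.red))
    retained = float(np.sum(masked_red)) / total if total > 0 else float("nan")
    masked = ChannelPairVolume(masked_red, pair.green.copy(), pair.voxel_size_um)
    return masked, {"retained_red_fraction": retained}


def link_objects(
    tables: Sequence[ObjectTable], max_step_um: float
) -> pd.DataFrame:
    """Greedy nearest-centroid linking between consecutive frames.

    Candidate links are sorted by (distance, previous label id, current
    label id) and accepted greedily while both endpoints are unmatched and
    the distance does not exceed ``max_step_um``; unmatched objects start
    new tracks.  Deterministic given the input order.  Returns the
    concatenated table with ``track_id`` filled.
    """
    if len(tables) < 2:
        raise ValueError("link_objects needs at least 2 timepoints")
    frames = []
    next_track = 0
    prev_tracks: dict[int, int] = {}  # label_id (prev frame) -> track_id
    for fi, tab in enumerate(tables):
        df = tab.table.copy()
        df["t"] = tab.t if tab.t is not None else fi
        cents = df[["centroid_z_um", "centroid_y_um", "centroid_x_um"]].to_numpy(float)
        labels = df["label_id"].to_numpy()
        assignment: dict[int, int] = {}
        if fi == 0 or not prev_tracks:
            for lab in labels:
                assignment[int(lab)] = next_track
                next_track += 1
        else:
            prev_df = frames[-1]
            prev_cents = prev_df[
                ["centroid_z_um", "centroid_y_um", "centroid_x_um"]
            ].to_numpy(float)
            prev_labels = prev_df["label_id"].to_numpy()
            candidates = []
            for pi, plab in enumerate(prev_labels):
                d = np.linalg.norm(cents - prev_cents[pi], axis=1)
                for ci, clab in enumerate(labels):
                    if d[ci] <= max_step_um:
                        candidates.append((float(d[ci]), int(plab), int(clab)))
            candidates.sort()
            used_prev: set[int] = set()
            for dist, plab, clab in candidates:
                if plab in used_prev or clab in assignment:
                    continue
                assignment[clab] = prev_tracks[plab]
                used_prev.add(plab)
            for lab in labels:
                if int(lab) not in assignment:
                    assignment[int(lab)] = next_track
                    next_track += 1
        df["track_id"] = [assignment[int(l)] for l in labels]
        prev_tracks = {int(l): assignment[int(l)] for l in labels}
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
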
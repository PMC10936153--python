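"""Colocalization coefficients per image and per timepoint.

The per-image pipeline segments each channel with its channel-specific
procedure (Otsu for green; 3-class multi-Otsu + opening for red), builds a
voxel region from the two foreground masks (by default their intersection,
i.e. the overlapping red-and-green voxels), and computes Pearson's
correlation coefficient over that region together with the Manders split
coefficients and the mask-overlap (Jaccard) index.

Degenerate inputs (constant channels, empty regions, zero-variance
regions) yield a QC-flagged result instead of an exception so that batch
runs over many images complete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import DegenerateInputError, EmptyRegionError, ShapeMismatchError
from .segmentation import BinaryMask, segment_green, segment_red
from .volume_io import ChannelPairVolume

__all__ = [
    "AnalysisConfig",
    "ColocResult",
    "TimeSeriesResult",
    "pearson_cc",
    "manders",
    "mask_overlap",
    "coloc_image",
    "coloc_timeseries",
]

REGION_MODES = ("intersection", "union", "whole")


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the per-image colocalization pipeline."""

    bins: int = 256
    red_classes: int = 3
    open_radius: int = 1
    apply_opening: bool = True
    region_mode: str = "intersection"

    def __post_init__(self) -> None:
        if self.region_mode not in REGION_MODES:
            raise ValueError(
                f"region_mode must be one of {REGION_MODES}, got {self.region_mode!r}"
            )


@dataclass
class ColocResult:
    """Per-image (or per-timepoint) colocalization coefficients.

    ``pcc`` is NaN (with ``qc_fail``) when the region is empty or has zero
    variance in either channel.  ``overlap`` is the Jaccard index of the two
    foreground masks.
    """

    image_id: str
    t: Optional[int]
    pcc: float
    m1: float
    m2: float
    overlap: float
    threshold_green: float
    threshold_red_low: float
    threshold_red_high: float
    n_region_voxels: int
    region_mode: str
    qc_fail: bool = False
    qc_reason: str = ""

    def to_row(self) -> dict:
        return {
            "image_id": self.image_id,
            "t": self.t,
            "pcc": self.pcc,
            "m1": self.m1,
            "m2": self.m2,
            "overlap": self.overlap,
            "threshold_green": self.threshold_green,
            "threshold_red_low": self.threshold_red_low,
            "threshold_red_high": self.threshold_red_high,
            "n_region_voxels": self.n_region_voxels,
            "region_mode": self.region_mode,
            "qc_fail": self.qc_fail,
            "qc_reason": self.qc_reason,
        }


@dataclass
class TimeSeriesResult:
    """Ordered per-timepoint results plus the sign of the PCC-vs-t trend."""

    results: list[ColocResult]
    pcc_slope: float
    trend: str  # "decreasing" | "increasing" | "flat" | "undefined"

    @property
    def pcc_values(self) -> np.ndarray:
        return np.array([r.pcc for r in self.results], dtype=float)


def pearson_cc(red: np.ndarray, green: np.ndarray, region: BinaryMask | np.ndarray) -> float:
    """Pearson correlation of the two channels over the region's voxels.

    Standard two-pass formula ``sum((R-Rbar)(G-Gbar)) /
    sqrt(sum((R-Rbar)^2) * sum((G-Gbar)^2))``.  Raises
    :class:`EmptyRegionError` for an empty region; returns NaN when either
    channel has zero variance within the region (the caller sets a QC flag).
    """
    mask = region.mask if isinstance(region, BinaryMask) else np.asarray(region, bool)
    red = np.asarray(red)
    green = np.asarray(green)
    if red.shape != green.shape or mask.shape != red.shape:
        raise ShapeMismatchError(
            f"shapes differ: red {red.shape}, green {green.shape}, region {mask.shape}"
        )
    r = red[mask].astype(np.float64)
    if r.size == 0:
        raise EmptyRegionError("correlation region contains no voxels")
    g = green[mask].astype(np.float64)
    dr = r - r.mean()
    dg = g - g.mean()
    denom = math.sqrt(float(dr @ dr) * float(dg @ dg))
    if denom == 0.0:
        return float("nan")
    return float(dr @ dg) / denom


def manders(
    red: np.ndarray,
    green: np.ndarray,
    mask_red: BinaryMask | np.ndarray,
    mask_green: BinaryMask | np.ndarray,
) -> tuple[float, float]:
    """Manders split coefficients.

    ``m1`` = fraction of red intensity (within the red mask) that lies in
    the green mask; ``m2`` symmetric for green.  Raises ``ValueError`` when
    a channel carries no intensity inside its own mask.
    """
    mr = mask_red.mask if isinstance(mask_red, BinaryMask) else np.asarray(mask_red, bool)
    mg = mask_green.mask if isinstance(mask_green, BinaryMask) else np.asarray(mask_green, bool)
    red = np.asarray(red, dtype=np.float64)
    green = np.asarray(green, dtype=np.float64)
    red_total = float(red[mr].sum())
    green_total = float(green[mg].sum())
    if red_total <= 0.0 or green_total <= 0.0:
        raise ValueError("Manders coefficients undefined: zero channel intensity in mask")
    both = mr & mg
    m1 = float(red[both].sum()) / red_total
    m2 = float(green[both].sum()) / green_total
    return m1, m2


def mask_overlap(mask_red, mask_green) -> float:
    """Jaccard index |intersection| / |union| of the two foreground masks."""
    mr = mask_red.mask if isinstance(mask_red, BinaryMask) else np.asarray(mask_red, bool)
    mg = mask_green.mask if isinstance(mask_green, BinaryMask) else np.asarray(mask_green, bool)
    union = int(np.count_nonzero(mr | mg))
    if union == 0:
        return float("nan")
    return int(np.count_nonzero(mr & mg)) / union


def _qc_result(image_id, t, region_mode, reason, **kw) -> ColocResult:
    nan = float("nan")
    defaults = dict(
        pcc=nan, m1=nan, m2=nan, overlap=nan,
        threshold_green=nan, threshold_red_low=nan, threshold_red_high=nan,
        n_region_voxels=0,
    )
    defaults.update(kw)
    return ColocResult(
        image_id=image_id, t=t, region_mode=region_mode,
        qc_fail=True, qc_reason=reason, **defaults,
    )


def coloc_image(
    pair: ChannelPairVolume,
    config: AnalysisConfig = AnalysisConfig(),
    image_id: str = "image",
    t: Optional[int] = None,
) -> ColocResult:
    """Full single-image colocalization workflow.

    Segments both channels, builds the region per ``config.region_mode``
    (default: intersection of the two masks — the overlapping red-and-green
    voxels), and computes PCC, Manders M1/M2 and mask overlap with full
    provenance.  Degenerate segmentation or an empty region yields a
    QC-failed result rather than an exception.
    """
    if pair.has_time:
        raise ValueError("coloc_image expects a single timepoint; use coloc_timeseries")
    try:
        green_mask = segment_green(pair.green, bins=config.bins)
        red_mask = segment_red(
            pair.red,
            bins=config.bins,
            n_classes=config.red_classes,
            open_radius=config.open_radius,
            apply_opening=config.apply_opening,
        )
    except DegenerateInputError as exc:
        return _qc_result(image_id, t, config.region_mode, f"degenerate segmentation: {exc}")

    thr_g = green_mask.thresholds.thresholds[0]
    thr_r_low, thr_r_high = red_mask.thresholds.thresholds

    if config.region_mode == "intersection":
        region = red_mask.mask & green_mask.mask
    elif config.region_mode == "union":
        region = red_mask.mask | green_mask.mask
    else:
        region = np.ones(pair.red.shape, dtype=bool)
    n_region = int(np.count_nonzero(region))

    common = dict(
        threshold_green=thr_g,
        threshold_red_low=thr_r_low,
        threshold_red_high=thr_r_high,
        n_region_voxels=n_region,
    )
    overlap = mask_overlap(red_mask, green_mask)
    if n_region == 0:
        return _qc_result(
            image_id, t, config.region_mode, "empty region", overlap=overlap, **common
        )
    pcc = pearson_cc(pair.red, pair.green, region)
    try:
        m1, m2 = manders(pair.red, pair.green, red_mask, green_mask)
    except ValueError:
        m1 = m2 = float("nan")
    qc_fail = math.isnan(pcc)
    return ColocResult(
        image_id=image_id, t=t, pcc=pcc, m1=m1, m2=m2, overlap=overlap,
        region_mode=config.region_mode, qc_fail=qc_fail,
        qc_reason="zero variance in region" if qc_fail else "",
        **common,
    )


def coloc_timeseries(
    pair4d: ChannelPairVolume,
    config: AnalysisConfig = AnalysisConfig(),
    image_id: str = "series",
) -> TimeSeriesResult:
    """Per-timepoint colocalization plus the sign of the PCC-vs-t slope.

    Individual timepoints may be QC-failed; the series is still returned.
    The trend is the sign of the least-squares slope of PCC against t over
    the QC-passing timepoints ("undefined" with fewer than two).
    """
    if not pair4d.has_time or pair4d.n_timepoints < 2:
        raise ValueError("coloc_timeseries needs a 4D pair with T >= 2")
    results = [
        coloc_image(pair4d.frame(t), config, image_id=image_id, t=t)
        for t in range(pair4d.n_timepoints)
    ]
    ts = np.array([r.t for r in results if not math.isnan(r.pcc)], dtype=float)
    ps = np.array([r.pcc for r in results if not math.isnan(r.pcc)], dtype=float)
    if ts.size < 2:
        return TimeSeriesResult(results, float("nan"), "undefined")
    slope = float(np.polyfit(ts, ps, 1)[0])
    trend = "flat" if slope == 0.0 else ("increasing" if slope > 0 else "decreasing")
    return TimeSeriesResult(results, slope, trend)
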
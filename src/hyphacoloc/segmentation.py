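"""Channel-specific foreground extraction.

The two channels are segmented differently: the green channel uses a
two-class Otsu threshold, while the red channel — whose diffuse cytosolic
background is brighter and noisier — uses a three-class multi-Otsu
threshold (top class = foreground) followed by a binary morphological
opening that removes sub-element specks.

Thresholds are searched exhaustively over histogram bin centers by
maximizing the between-class variance; ties are broken toward the smallest
threshold (lexicographically smallest tuple for multi-Otsu) so results are
deterministic across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError

__all__ = [
    "ThresholdResult",
    "BinaryMask",
    "otsu_threshold",
    "multi_otsu_thresholds",
    "morphological_opening",
    "segment_green",
    "segment_red",
]


@dataclass(frozen=True)
class ThresholdResult:
    """Thresholds from a (multi-)Otsu search.

    ``thresholds`` is strictly ascending, with one value for the two-class
    Otsu and two for the three-class multi-Otsu.  Foreground is defined as
    intensity strictly greater than the relevant threshold.
    """

    thresholds: tuple[float, ...]
    n_classes: int
    histogram_bins: int

    def __post_init__(self) -> None:
        if list(self.thresholds) != sorted(self.thresholds) or len(
            set(self.thresholds)
        ) != len(self.thresholds):
            raise ValueError(f"thresholds not strictly ascending: {self.thresholds}")


@dataclass
class BinaryMask:
    """Boolean foreground mask together with its provenance."""

    mask: np.ndarray
    source_channel: str  # "red" | "green"
    provenance: str  # "otsu" | "multi_otsu" | "opened"
    thresholds: Optional[ThresholdResult] = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


def _histogram(volume: np.ndarray, bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Histogram counts and bin centers over [min, max] with equal-width bins."""
    v = np.asarray(volume).ravel()
    vmin, vmax = float(v.min()), float(v.max())
    counts, edges = np.histogram(v, bins=bins, range=(vmin, vmax))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts.astype(np.float64), centers


def otsu_threshold(volume: np.ndarray, bins: int = 256) -> ThresholdResult:
    """Two-class Otsu threshold of a volume's binned intensity histogram.

    Candidates are the bin centers; the candidate maximizing the
    between-class variance ``w0*w1*(mu0-mu1)**2`` wins, with ties resolved
    to the smallest candidate.  Raises :class:`DegenerateInputError` for
    volumes with fewer than two distinct intensities.
    """
    v = np.asarray(volume)
    if v.size == 0 or np.unique(v).size < 2:
        raise DegenerateInputError(
            "Otsu thresholding needs at least 2 distinct intensity values"
        )
    counts, centers = _histogram(v, bins)
    total = counts.sum()
    p = counts / total
    w0 = np.cumsum(p)
    m = np.cumsum(p * centers)
    mu_total = m[-1]
    w1 = 1.0 - w0
    # between-class variance for split after bin k (classes <=k / >k)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m / w0
        mu1 = (mu_total - m) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.where(valid, sigma_b, -np.inf)
    if not np.any(np.isfinite(sigma_b)):
        raise DegenerateInputError("histogram collapses to a single bin")
    k = int(np.argmax(sigma_b))  # argmax returns the first (= smallest) maximum
    return ThresholdResult((float(centers[k]),), 2, bins)


def multi_otsu_thresholds(
    volume: np.ndarray, n_classes: int = 3, bins: int = 256
) -> ThresholdResult:
    """Multi-class Otsu thresholds (currently 3 classes: two cut values).

    Searches all ascending bin-center pairs for the maximal between-class
    variance ``sum_i w_i * (mu_i - mu_T)**2``; ties resolve to the
    lexicographically smallest pair.
    """
    if n_classes != 3:
        raise NotImplementedError("only the 3-class multi-Otsu is supported")
    v = np.asarray(volume)
    if v.size == 0 or np.unique(v).size < n_classes:
        raise DegenerateInputError(
            f"multi-Otsu with {n_classes} classes needs at least {n_classes} "
            "distinct intensity values"
        )
    counts, centers = _histogram(v, bins)
    if np.count_nonzero(counts) < n_classes:
        raise DegenerateInputError(
            f"histogram has fewer than {n_classes} occupied bins"
        )
    total = counts.sum()
    p = counts / total
    cw = np.concatenate([[0.0], np.cumsum(p)])
    cm = np.concatenate([[0.0], np.cumsum(p * centers)])
    mu_total = cm[-1]
    nbins = len(centers)

    best = -np.inf
    best_pair: tuple[int, int] | None = None
    for k1 in range(nbins - 2):
        w0 = cw[k1 + 1]
        if w0 <= 0.0:
            continue
        m0 = cm[k1 + 1]
        k2 = np.arange(k1 + 1, nbins - 1)
        w1 = cw[k2 + 1] - w0
        w2 = 1.0 - cw[k2 + 1]
        m1 = cm[k2 + 1] - m0
        m2 = mu_total - cm[k2 + 1]
        ok = (w1 > 0.0) & (w2 > 0.0)
        if not np.any(ok):
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            sigma_b = (
                w0 * (m0 / w0 - mu_total) ** 2
                + w1 * (m1 / w1 - mu_total) ** 2
                + w2 * (m2 / w2 - mu_total) ** 2
            )
        sigma_b = np.where(ok, sigma_b, -np.inf)
        j = int(np.argmax(sigma_b))
        if sigma_b[j] > best:  # strict: keeps the lexicographically smallest pair
            best = float(sigma_b[j])
            best_pair = (k1, int(k2[j]))
    if best_pair is None:
        raise DegenerateInputError("no valid 3-class split of the histogram")
    t1, t2 = centers[best_pair[0]], centers[best_pair[1]]
    return ThresholdResult((float(t1), float(t2)), 3, bins)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def morphological_opening(mask, se_radius_vox: int = 1):
    """Binary opening (erosion then dilation) with a 6-connected 3D cross.

    ``se_radius_vox`` iterations of erosion/dilation are applied, which is
    equivalent to using the cross dilated to that radius.  The operation is
    anti-extensive (result is a subset of the input) and idempotent.  Accepts
    either a raw boolean array or a :class:`BinaryMask`, returning the same
    type (with provenance ``opened``).
    """
    if se_radius_vox < 1:
        raise ValueError("se_radius_vox must be >= 1")
    raw = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    opened = ndimage.binary_opening(
        raw, structure=_STRUCTURES[6], iterations=se_radius_vox
    )
    if isinstance(mask, BinaryMask):
        return BinaryMask(opened, mask.source_channel, "opened", mask.thresholds)
    return opened


def segment_green(volume: np.ndarray, bins: int = 256) -> BinaryMask:
    """Green-channel foreground: single Otsu threshold, no morphology."""
    thr = otsu_threshold(volume, bins=bins)
    return BinaryMask(np.asarray(volume) > thr.thresholds[0], "green", "otsu", thr)


def segment_red(
    volume: np.ndarray,
    bins: int = 256,
    n_classes: int = 3,
    open_radius: int = 1,
    apply_opening: bool = True,
) -> BinaryMask:
    """Red-channel foreground: 3-class multi-Otsu top class, then opening.

    The middle class absorbs the brighter diffuse cytosolic background; the
    foreground is the highest-intensity class (intensity > upper threshold).
    """
    thr = multi_otsu_thresholds(volume, n_classes=n_classes, bins=bins)
    mask = BinaryMask(
        np.asarray(volume) > thr.thresholds[-1], "red", "multi_otsu", thr
    )
    if apply_opening:
        mask = morphological_opening(mask, se_radius_vox=open_radius)
    return mask
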
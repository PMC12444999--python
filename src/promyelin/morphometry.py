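"""Quantification of pseudocolored micrographs.

Height-pseudocolored SEM images of microsphere networks map elevation to
hue: red-orange (0-60 deg) marks elevated microspheres, yellow-green
(60-180 deg) interfacial zones and cyan-blue (180-300 deg) the surrounding
matrix.  This module segments such images by hue range, computes area
fractions (globally and inside electrode-centred circular regions of
interest) and estimates the box-counting fractal dimension of region
boundaries as a roughness measure.

Near-gray pixels carry no meaningful hue, so pixels below a saturation or
value floor are left unassigned; hues outside all configured bands (the
default bands cover only 0-300 deg) are unassigned as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Tuple

import numpy as np
from skimage import color, util

__all__ = [
    "DEFAULT_HUE_RANGES",
    "SegmentedImage",
    "FractalEstimate",
    "segment_by_hue",
    "box_counting_dimension",
    "roi_stats",
]

#: The three-region pseudocolor scheme (degrees, half-open intervals).
DEFAULT_HUE_RANGES: Dict[str, Tuple[float, float]] = {
    "microsphere": (0.0, 60.0),
    "interface": (60.0, 180.0),
    "matrix": (180.0, 300.0),
}

UNASSIGNED = 0  # label id reserved for unassigned pixels


@dataclass(frozen=True)
class SegmentedImage:
    """Per-pixel region labels with area fractions and a boundary mask."""

    labels: np.ndarray  # int label image; 0 = unassigned
    region_ids: Dict[str, int]  # region name -> label id (>= 1)
    fractions: Dict[str, float]  # area fraction per region (excl. unassigned)
    boundary_mask: np.ndarray  # pixels 4-adjacent to a different label

    def mask(self, region: str) -> np.ndarray:
        return self.labels == self.region_ids[region]

    @property
    def unassigned_fraction(self) -> float:
        return float(np.mean(self.labels == UNASSIGNED))


@dataclass(frozen=True)
class FractalEstimate:
    dimension: float
    box_sizes: np.ndarray  # px
    counts: np.ndarray  # occupied boxes per size
    fit_r2: float


def _validate_ranges(ranges: Mapping[str, Tuple[float, float]]) -> None:
    intervals = []
    for name, (lo, hi) in ranges.items():
        if not (0.0 <= lo < hi <= 360.0):
            raise ValueError(f"hue range for {name!r} must satisfy 0 <= lo < hi <= 360")
        intervals.append((lo, hi, name))
    intervals.sort()
    for (lo1, hi1, n1), (lo2, hi2, n2) in zip(intervals, intervals[1:]):
        if lo2 < hi1:
            raise ValueError(f"hue ranges for {n1!r} and {n2!r} overlap")


def segment_by_hue(
    image: np.ndarray,
    ranges: Mapping[str, Tuple[float, float]] = DEFAULT_HUE_RANGES,
    sat_floor: float = 0.1,
    val_floor: float = 0.1,
) -> SegmentedImage:
    """Segment an RGB raster into labelled regions by hue interval.

    Parameters
    ----------
    image : (H, W, 3) array, uint8 or float in [0, 1]
    ranges : mapping region name -> [hue_lo, hue_hi) in degrees
        Intervals must not overlap.  Pixels whose hue falls in no interval,
        or whose saturation/value is below the floors, are unassigned.
    """
    _validate_ranges(ranges)
    img = util.img_as_float(np.asarray(image))
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    hsv = color.rgb2hsv(img)
    hue = hsv[..., 0] * 360.0
    usable = (hsv[..., 1] >= sat_floor) & (hsv[..., 2] >= val_floor)

    labels = np.zeros(img.shape[:2], dtype=np.int32)
    region_ids: Dict[str, int] = {}
    for k, (name, (lo, hi)) in enumerate(ranges.items(), start=1):
        region_ids[name] = k
        labels[usable & (hue >= lo) & (hue < hi)] = k

    total = labels.size
    fractions = {
        name: float(np.count_nonzero(labels == k) / total)
        for name, k in region_ids.items()
    }

    boundary = np.zeros_like(labels, dtype=bool)
    boundary[:-1, :] |= labels[:-1, :] != labels[1:, :]
    boundary[1:, :] |= labels[1:, :] != labels[:-1, :]
    boundary[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    boundary[:, 1:] |= labels[:, 1:] != labels[:, :-1]

    return SegmentedImage(
        labels=labels, region_ids=region_ids,
        fractions=fractions, boundary_mask=boundary,
    )


def box_counting_dimension(mask: np.ndarray) -> FractalEstimate:
    """Box-counting dimension of a boolean raster.

    Counts occupied boxes over dyadic box sizes from 2 px up to
    ``min(shape) // 4`` and fits the least-squares slope of
    ``log N`` versus ``log(1/s)``.  The count sequence is non-increasing in
    box size by construction; ``fit_r2`` exposes the quality of the log-log
    fit so unreliable estimates are visible.
    """
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not m.any():
        raise ValueError("mask is empty")
    max_size = min(m.shape) // 4
    if max_size < 2:
        raise ValueError("mask too small for box counting (need min(shape) >= 8)")
    sizes, counts = [], []
    s = 2
    while s <= max_size:
        ph = (-m.shape[0]) % s
        pw = (-m.shape[1]) % s
        p = np.pad(m, ((0, ph), (0, pw)))
        occupied = (
            p.reshape(p.shape[0] // s, s, p.shape[1] // s, s)
            .any(axis=(1, 3))
            .sum()
        )
        sizes.append(s)
        counts.append(int(occupied))
        s *= 2
    sizes_arr = np.array(sizes, dtype=float)
    counts_arr = np.array(counts, dtype=float)
    x = np.log(1.0 / sizes_arr)
    y = np.log(counts_arr)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FractalEstimate(
        dimension=float(slope), box_sizes=sizes_arr.astype(int),
        counts=counts_arr.astype(int), fit_r2=r2,
    )


def roi_stats(
    seg: SegmentedImage,
    center: Tuple[float, float],
    radius: float,
) -> Dict[str, float]:
    """Area fractions within a circular region of interest.

    ``center`` is (row, col) in pixels; pixels with Euclidean distance
    <= ``radius`` from the centre (and inside the image) form the ROI.
    Fractions are computed over the ROI pixel count, so they include an
    implicit unassigned remainder just like the global fractions.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    h, w = seg.labels.shape
    rows, cols = np.ogrid[:h, :w]
    dist2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    roi = dist2 <= radius ** 2
    n_roi = int(np.count_nonzero(roi))
    if n_roi == 0:
        raise ValueError("ROI lies entirely outside the image")
    lab = seg.labels[roi]
    return {
        name: float(np.count_nonzero(lab == k) / n_roi)
        for name, k in seg.region_ids.items()
    }
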
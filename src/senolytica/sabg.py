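"""Quantification of senescence-associated β-galactosidase (SABG) staining.

SABG activity at pH 6.0 hydrolyzes X-Gal into an insoluble blue precipitate;
in brightfield RGB images of stained cells the positive regions appear as
blue-hued, high-saturation clusters on a bright background.  The
quantification converts the image into a hue/saturation/brightness (HSB)
stack, thresholds each slice, combines the overlapping parts of the three
masks (per-pixel conjunction), and detects connected clusters on the
combined mask; each cluster's "intensity" is its mean value in the
saturation plane.

Reported per-field metrics: cluster count, mean positive area, and the
percentage of SABG-positive cells over total cells.

The numeric thresholds used in published analyses of this kind are rarely
stated; the defaults here (hue 170–280° for the cyan–blue reaction product,
saturation ≥ 0.25, brightness 0.15–0.95 to exclude near-black debris and
blown-out background) are calibratable package choices, exposed in full.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv
from skimage.measure import label as cc_label

from .errors import UndefinedPercentageError
from .iohub import RGBImage
from .nucleiseg import LabeledMask, _measure, _relabel_raster_order

__all__ = [
    "HSBStack",
    "HSBThresholds",
    "SABGReport",
    "rgb_to_hsb",
    "detect_clusters",
    "cluster_intensity",
    "sabg_metrics",
]


@dataclass
class HSBStack:
    """Hue (degrees, [0, 360)), saturation and brightness ([0, 1]) planes.

    Zero-saturation pixels have hue fixed at 0 by convention.
    """

    hue: np.ndarray
    saturation: np.ndarray
    brightness: np.ndarray

    def __post_init__(self) -> None:
        planes = [np.asarray(p, dtype=float) for p in
                  (self.hue, self.saturation, self.brightness)]
        if len({p.shape for p in planes}) != 1:
            raise ValueError("H, S, B planes must share dimensions")
        if planes[0].min() < 0 or planes[0].max() >= 360:
            raise ValueError("hue must lie in [0, 360)")
        for name, p in zip(("saturation", "brightness"), planes[1:]):
            if p.min() < 0 or p.max() > 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        self.hue, self.saturation, self.brightness = planes


@dataclass
class HSBThresholds:
    """Per-slice threshold windows; the hue window may wrap past 360°."""

    hue_range: tuple[float, float] = (170.0, 280.0)
    sat_min: float = 0.25
    bright_range: tuple[float, float] = (0.15, 0.95)

    def __post_init__(self) -> None:
        lo, hi = self.hue_range
        if not (0 <= lo < 360 and 0 <= hi < 360):
            raise ValueError("hue bounds must lie in [0, 360)")
        if not (0 <= self.sat_min <= 1):
            raise ValueError("sat_min must lie in [0, 1]")
        blo, bhi = self.bright_range
        if not (0 <= blo <= bhi <= 1):
            raise ValueError("bright_range must be ordered within [0, 1]")


@dataclass
class SABGReport:
    """Per-field SABG metrics plus the per-cluster table."""

    n_clusters: int
    mean_positive_area_px: float
    mean_positive_area_um2: float | None
    percent_positive_cells: float
    approximate_percentage: bool
    clusters: pd.DataFrame  # label, area, saturation_intensity


def rgb_to_hsb(image: RGBImage) -> HSBStack:
    """Standard hexcone HSB conversion of an RGB image.

    ``B = max(R,G,B)``, ``S = (max − min)/max`` (0 where max = 0), hue by
    the piecewise sector formula with degrees in [0, 360).
    """
    hsv = rgb2hsv(image.as_array())
    hue = hsv[..., 0] * 360.0
    hue[hue >= 360.0] = 0.0
    return HSBStack(hue=hue, saturation=hsv[..., 1], brightness=hsv[..., 2])


def _hue_mask(hue: np.ndarray, hue_range: tuple[float, float]) -> np.ndarray:
    lo, hi = hue_range
    if lo <= hi:
        return (hue >= lo) & (hue <= hi)
    return (hue >= lo) | (hue <= hi)  # window wraps through 0°


def slice_masks(
    stack: HSBStack, thr: HSBThresholds
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-slice boolean masks (hue window, saturation floor, brightness band)."""
    mask_h = _hue_mask(stack.hue, thr.hue_range)
    mask_s = stack.saturation >= thr.sat_min
    mask_b = (stack.brightness >= thr.bright_range[0]) & (
        stack.brightness <= thr.bright_range[1]
    )
    return mask_h, mask_s, mask_b


def detect_clusters(
    stack: HSBStack,
    thr: HSBThresholds | None = None,
    min_cluster_area: float = 20.0,
) -> LabeledMask:
    """Detect SABG clusters as connected components of the combined mask.

    The combined mask is the per-pixel conjunction (the overlapping part) of
    the three slice masks, so it is a subset of each individual mask.
    Components (8-connectivity) with area ≥ ``min_cluster_area`` px² are
    labeled in raster order.
    """
    thr = thr or HSBThresholds()
    mask_h, mask_s, mask_b = slice_masks(stack, thr)
    combined = mask_h & mask_s & mask_b
    labels = cc_label(combined, connectivity=2)
    if labels.max():
        areas = np.bincount(labels.ravel())
        small = areas < min_cluster_area
        small[0] = False
        labels[small[labels]] = 0
        labels = _relabel_raster_order(labels.astype(np.int32))
    return LabeledMask(
        labels=labels, objects=_measure(labels, stack.saturation)
    )


def cluster_intensity(mask: LabeledMask, stack: HSBStack) -> pd.DataFrame:
    """Mean saturation per cluster — the macro's "intensity" readout.

    Returns a table ``(label, saturation_intensity)``; an empty mask gives
    an empty table.
    """
    if mask.labels.shape != stack.saturation.shape:
        raise ValueError("mask and HSB stack dimensions differ")
    if mask.n_objects == 0:
        return pd.DataFrame(columns=["label", "saturation_intensity"])
    sums = np.bincount(
        mask.labels.ravel(), weights=stack.saturation.ravel(),
        minlength=mask.n_objects + 1,
    )
    counts = np.bincount(mask.labels.ravel(), minlength=mask.n_objects + 1)
    labels = np.arange(1, mask.n_objects + 1)
    return pd.DataFrame(
        {"label": labels, "saturation_intensity": sums[1:] / counts[1:]}
    )


def sabg_metrics(
    mask: LabeledMask,
    stack: HSBStack,
    cell_centroids: np.ndarray | list | None = None,
    total_cells: int | None = None,
    assign_radius: float = 15.0,
    pixel_size: float | None = None,
) -> SABGReport:
    """Per-field SABG report: cluster count, mean area, % positive cells.

    Exactly one of ``cell_centroids`` / ``total_cells`` must be given.  With
    centroids, a cell is positive iff at least one cluster pixel lies within
    ``assign_radius`` of its centroid.  With only a total count the
    percentage is approximated as ``min(n_clusters, total) / total`` and
    flagged as approximate.
    """
    if (cell_centroids is None) == (total_cells is None):
        raise ValueError("provide exactly one of cell_centroids / total_cells")

    n_clusters = mask.n_objects
    areas = mask.objects["area"].to_numpy(dtype=float) if n_clusters else np.array([])
    mean_area = float(areas.mean()) if n_clusters else 0.0

    if cell_centroids is not None:
        centroids = np.asarray(cell_centroids, dtype=float).reshape(-1, 2)
        total = len(centroids)
        if total == 0:
            raise UndefinedPercentageError("no cells given; percentage undefined")
        positive = 0
        cluster_pixels = np.argwhere(mask.labels > 0)
        if len(cluster_pixels):
            from scipy.spatial import cKDTree

            tree = cKDTree(cluster_pixels)
            dists, _ = tree.query(centroids)
            positive = int(np.sum(dists <= assign_radius))
        percent = 100.0 * positive / total
        approximate = False
    else:
        if total_cells == 0:
            raise UndefinedPercentageError("total_cells is 0; percentage undefined")
        percent = 100.0 * min(n_clusters, total_cells) / total_cells
        approximate = True

    intensities = cluster_intensity(mask, stack)
    clusters = mask.objects[["label", "area"]].merge(intensities, on="label") \
        if n_clusters else pd.DataFrame(columns=["label", "area", "saturation_intensity"])
    return SABGReport(
        n_clusters=n_clusters,
        mean_positive_area_px=mean_area,
        mean_positive_area_um2=(
            mean_area * pixel_size**2 if pixel_size is not None else None
        ),
        percent_positive_cells=percent,
        approximate_percentage=approximate,
        clusters=clusters,
    )
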
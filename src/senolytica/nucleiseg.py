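"""Segmentation and counting of fluorescently labeled nuclei.

The senolytic co-culture assay counts H2B-GFP (quiescent) and H2B-RFP
(senescent) nuclei per field; a differential drop in the senescent count is
the senolytic signature.  Because the histone-fusion labels are confined to
the nucleus, simple intensity segmentation suffices: Gaussian smoothing, a
global threshold (Otsu by default — parameter-free and invariant under
uniform intensity rescaling), an area filter, and an optional
distance-transform watershed to split touching nuclei.

Objects are labeled consecutively in raster-scan order (top-left first) so
results are deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label, regionprops_table
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .errors import ChannelError, DegenerateThresholdError
from .iohub import FieldImage

logger = logging.getLogger("senolytica.nucleiseg")

__all__ = ["SegmentationParams", "LabeledMask", "segment_nuclei", "count_field"]


@dataclass
class SegmentationParams:
    """Knobs of the nuclear segmentation pipeline.

    ``min_area``/``max_area`` (px²) bound accepted object sizes: the default
    minimum is the area of a disk at half the quiescent nucleus radius and
    the maximum 10× the senescent nucleus area, rejecting debris and merged
    clumps symmetrically.  ``watershed_h`` is the h-maxima depth (in
    distance-transform units) used to seed the split of touching nuclei.

    ``min_otsu_contrast`` guards Otsu against signal-free planes, where the
    threshold would otherwise bisect the read noise: the threshold must
    exceed the plane median by this many robust (MAD-based) standard
    deviations or the plane is declared empty.
    """

    smoothing_sigma: float = 1.0
    threshold_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float = 0.0
    min_area: float = math.pi * 3.0**2
    max_area: float = 10.0 * math.pi * 9.0**2
    split_touching: bool = False
    watershed_h: float = 1.0
    min_otsu_contrast: float = 5.0

    def __post_init__(self) -> None:
        if not (0 < self.min_area < self.max_area):
            raise ValueError("need 0 < min_area < max_area")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")


@dataclass
class LabeledMask:
    """Integer-labeled segmentation with per-object measurements.

    ``labels`` uses 0 for background and consecutive integers 1..N for
    objects; ``objects`` has exactly N rows with columns
    ``label, area, centroid_row, centroid_col, mean_intensity,
    equivalent_diameter``.
    """

    labels: np.ndarray
    objects: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        n = int(self.labels.max()) if self.labels.size else 0
        present = np.unique(self.labels)
        present = present[present > 0]
        if n and not np.array_equal(present, np.arange(1, n + 1)):
            raise ValueError("labels must be consecutive 1..N")
        if len(self.objects) != n:
            raise ValueError(f"object table has {len(self.objects)} rows for {n} labels")

    @property
    def n_objects(self) -> int:
        return len(self.objects)


def _measure(labels: np.ndarray, intensity: np.ndarray) -> pd.DataFrame:
    if labels.max() == 0:
        return pd.DataFrame(
            columns=[
                "label", "area", "centroid_row", "centroid_col",
                "mean_intensity", "equivalent_diameter",
            ]
        )
    props = regionprops_table(
        labels,
        intensity_image=intensity,
        properties=(
            "label", "area", "centroid", "intensity_mean", "equivalent_diameter_area",
        ),
    )
    table = pd.DataFrame(props).rename(
        columns={
            "centroid-0": "centroid_row",
            "centroid-1": "centroid_col",
            "intensity_mean": "mean_intensity",
            "equivalent_diameter_area": "equivalent_diameter",
        }
    )
    return table.sort_values("label").reset_index(drop=True)


def _relabel_raster_order(labels: np.ndarray) -> np.ndarray:
    """Renumber objects by first pixel occurrence in raster-scan order."""
    flat = labels.ravel()
    nonzero = flat[flat > 0]
    if nonzero.size == 0:
        return labels
    _, first_idx = np.unique(flat, return_index=True)
    order = [(idx, lab) for idx, lab in zip(first_idx, flat[first_idx]) if lab > 0]
    order.sort()
    mapping = np.zeros(int(flat.max()) + 1, dtype=labels.dtype)
    for new, (_, old) in enumerate(order, start=1):
        mapping[old] = new
    return mapping[labels]


def segment_nuclei(
    plane: np.ndarray,
    params: SegmentationParams | None = None,
    field_name: str = "",
) -> LabeledMask:
    """Segment one fluorescence plane into labeled nuclei.

    Pipeline: Gaussian smoothing → global threshold (Otsu or fixed) →
    connected components (8-connectivity) → area filter → optional
    distance-transform watershed split seeded at h-maxima → consecutive
    relabeling in raster order.

    Raises :class:`DegenerateThresholdError` for a constant plane in Otsu
    mode, naming the offending field.
    """
    params = params or SegmentationParams()
    plane = np.asarray(plane, dtype=float)
    if not np.all(np.isfinite(plane)) or plane.min() < 0:
        raise ValueError("plane must be finite and non-negative")

    smoothed = gaussian(plane, sigma=params.smoothing_sigma, preserve_range=True) \
        if params.smoothing_sigma > 0 else plane
    if params.threshold_method == "otsu":
        if np.ptp(smoothed) == 0:
            raise DegenerateThresholdError(
                f"constant plane{f' in field {field_name!r}' if field_name else ''}: "
                "Otsu threshold undefined"
            )
        thr = threshold_otsu(smoothed)
        median = np.median(smoothed)
        robust_sd = 1.4826 * np.median(np.abs(smoothed - median))
        if robust_sd > 0 and (thr - median) < params.min_otsu_contrast * robust_sd:
            # no real foreground: Otsu is bisecting noise
            logger.info(
                "plane%s has no signal above background; 0 objects",
                f" {field_name!r}" if field_name else "",
            )
            empty = np.zeros_like(plane, dtype=np.int32)
            return LabeledMask(labels=empty, objects=_measure(empty, plane))
    else:
        thr = params.fixed_threshold
    mask = smoothed > thr

    labels = cc_label(mask, connectivity=2)
    if labels.max():
        areas = np.bincount(labels.ravel())
        bad = (areas < params.min_area) | (areas > params.max_area)
        bad[0] = False
        mask &= ~bad[labels]
        labels = cc_label(mask, connectivity=2)

    if params.split_touching and labels.max():
        dist = ndi.distance_transform_edt(mask)
        seeds = cc_label(h_maxima(dist, params.watershed_h), connectivity=2)
        if seeds.max():
            labels = watershed(-dist, markers=seeds, mask=mask)
            # re-apply the area filter to split fragments
            areas = np.bincount(labels.ravel())
            bad = (areas < params.min_area) | (areas > params.max_area)
            bad[0] = False
            labels[bad[labels]] = 0

    labels = _relabel_raster_order(labels.astype(np.int32))
    return LabeledMask(labels=labels, objects=_measure(labels, plane))


def count_field(
    field: FieldImage,
    channels: list[str] | None = None,
    params: SegmentationParams | dict[str, SegmentationParams] | None = None,
    double_positive_distance: float = 5.0,
) -> tuple[dict[str, int], dict[str, LabeledMask], pd.DataFrame]:
    """Segment and count nuclei in each requested channel of a field.

    Returns per-channel counts, the labeled masks, and a table of
    double-positive pairs: objects detected in both the GFP and RFP channels
    whose centroids lie within ``double_positive_distance`` pixels.  The
    dual-label design assumes disjoint populations, so coincident detections
    are reported rather than silently assigned to one channel — they remain
    counted in both channels and flagged.
    """
    channels = channels or ["GFP", "RFP"]
    masks: dict[str, LabeledMask] = {}
    counts: dict[str, int] = {}
    for name in channels:
        if name not in field.channels:
            raise ChannelError(
                f"channel {name!r} missing from field {field.field_id!r}"
            )
        chan_params = params.get(name) if isinstance(params, dict) else params
        try:
            masks[name] = segment_nuclei(
                field.channels[name], chan_params, field_name=f"{field.field_id}/{name}"
            )
        except DegenerateThresholdError:
            # a channel with no signal at all counts zero
            size = field.channels[name].shape
            masks[name] = LabeledMask(
                labels=np.zeros(size, dtype=np.int32),
                objects=_measure(np.zeros(size, dtype=np.int32), field.channels[name]),
            )
        counts[name] = masks[name].n_objects

    pairs = []
    if "GFP" in masks and "RFP" in masks:
        gfp, rfp = masks["GFP"].objects, masks["RFP"].objects
        if len(gfp) and len(rfp):
            tree = cKDTree(rfp[["centroid_row", "centroid_col"]].to_numpy())
            dists, idx = tree.query(gfp[["centroid_row", "centroid_col"]].to_numpy())
            hit = dists <= double_positive_distance
            for g_row, r_idx, dist in zip(
                gfp.loc[hit, "label"], np.asarray(idx)[hit], np.asarray(dists)[hit]
            ):
                pairs.append(
                    {
                        "gfp_label": int(g_row),
                        "rfp_label": int(rfp.iloc[r_idx]["label"]),
                        "distance_px": float(dist),
                    }
                )
    double_positive = pd.DataFrame(
        pairs, columns=["gfp_label", "rfp_label", "distance_px"]
    )
    if len(double_positive):
        logger.warning(
            "field %s: %d double-positive object(s) detected",
            field.field_id, len(double_positive),
        )
    return counts, masks, double_positive
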
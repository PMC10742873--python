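"""Synthetic inputs with known ground truth for every pipeline stage.

Real screens of this kind image co-cultures of quiescent cells carrying
nuclear H2B-GFP and senescent cells carrying H2B-RFP; senescence brings
nuclear enlargement and a broad cytoplasmic autofluorescence (lipofuscin)
signal that can mask cytoplasmic probes.  The simulators here emulate those
features at the level the downstream readouts need — object counts, areas,
hues, emission spectra and event mixtures — with planted parameters recorded
in a :class:`GroundTruth` so recovery can be scored exactly.

Every simulator is a pure function of its configuration and an explicit
integer seed: identical inputs give bit-identical outputs.

Deliberately not modeled: chromatin texture, optical PSFs, cell-cycle or
SASP dynamics.  Nuclei are Gaussian-edged disks because counting and area
recovery do not need texture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf
from skimage.color import hsv2rgb

from .errors import PlacementError
from .iohub import FieldImage, RGBImage, SpectralStack, wavelength_axis
from .spectral import ROI, ROISet

__all__ = [
    "CocultureSimConfig",
    "GroundTruth",
    "simulate_coculture_field",
    "simulate_senolysis_experiment",
    "senolysis_assay_table",
    "simulate_sabg_field",
    "simulate_spectral_stack",
    "simulate_flow_events",
]

_MAX_PLACEMENT_TRIES = 2000


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass
class CocultureSimConfig:
    """Parameters of a simulated 1:1 co-culture field.

    Defaults model a field where senescent nuclei are 1.5× the radius of
    quiescent nuclei (the enlargement is qualitative in real data; the ratio
    is a free simulation parameter) and senescent cells carry a diffuse
    cytoplasmic autofluorescence halo recorded in a separate ``autofluor``
    channel.  ``autofluor_bleed`` optionally adds a fraction of that halo
    into named fluorophore channels, reproducing the masking problem that
    motivates nucleus-restricted labeling.
    """

    field_size: int = 512
    n_quiescent: int = 80
    n_senescent: int = 80
    nucleus_radius_quiescent: float = 6.0
    nucleus_radius_senescent: float = 9.0
    nucleus_intensity: float = 1000.0
    intensity_cv: float = 0.10
    autofluor_amplitude: float = 200.0
    background_level: float = 100.0
    noise_sd: float = 10.0
    edge_sigma: float = 1.0
    placement_margin: float = 5.0
    allow_touching: bool = False
    autofluor_bleed: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleus_radius_quiescent <= 0 or self.nucleus_radius_senescent <= 0:
            raise ValueError("nucleus radii must be positive")
        if self.nucleus_radius_senescent < self.nucleus_radius_quiescent:
            raise ValueError("senescent radius must be >= quiescent radius")
        if self.n_quiescent < 0 or self.n_senescent < 0:
            raise ValueError("object counts must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.field_size < 8:
            raise ValueError("field_size too small")


@dataclass
class GroundTruth:
    """Planted objects and parameters of one simulated dataset.

    ``objects`` is a list of per-object records (center, radius, label, …);
    ``params`` echoes the resolved configuration; ``extra`` holds
    stage-specific truths (replicate counts, population labels, …).
    """

    objects: list[dict] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def count(self, label: str) -> int:
        return sum(1 for obj in self.objects if obj.get("label") == label)

    def to_json(self) -> dict:
        def _clean(value):
            if isinstance(value, np.ndarray):
                return value.tolist()
            if isinstance(value, (np.integer,)):
                return int(value)
            if isinstance(value, (np.floating,)):
                return float(value)
            if isinstance(value, dict):
                return {k: _clean(v) for k, v in value.items()}
            if isinstance(value, (list, tuple)):
                return [_clean(v) for v in value]
            return value

        return _clean(
            {"objects": self.objects, "params": self.params,
             "seed": self.seed, "extra": self.extra}
        )


# ---------------------------------------------------------------------------
# placement and rendering primitives
# ---------------------------------------------------------------------------

def _place_centers(
    rng: np.random.Generator,
    radii: Sequence[float],
    field_size: int,
    allow_touching: bool,
    margin_pad: float = 1.0,
    separation_margin: float = 0.0,
) -> np.ndarray:
    """Rejection-sample centers; non-touching means center distance > r_i + r_j.

    ``separation_margin`` adds clearance beyond the sum of radii so that
    soft (blurred) object edges stay separable after thresholding.
    """
    centers: list[tuple[float, float]] = []
    placed_radii: list[float] = []
    for r in radii:
        lo, hi = r + margin_pad, field_size - r - margin_pad
        if hi <= lo:
            raise PlacementError(f"radius {r} does not fit in field {field_size}")
        for _ in range(_MAX_PLACEMENT_TRIES):
            cand = rng.uniform(lo, hi, size=2)
            if allow_touching or not centers:
                ok = True
            else:
                existing = np.asarray(centers)
                dists = np.hypot(*(existing - cand).T)
                ok = bool(
                    np.all(dists > np.asarray(placed_radii) + r + separation_margin)
                )
            if ok:
                centers.append(tuple(cand))
                placed_radii.append(r)
                break
        else:
            raise PlacementError(
                f"could not place {len(radii)} non-touching objects of radius "
                f"~{r} in a {field_size}px field after {_MAX_PLACEMENT_TRIES} tries"
            )
    return np.asarray(centers).reshape(-1, 2)


def _render_disk(
    plane: np.ndarray, center: tuple[float, float], radius: float,
    amplitude: float, edge_sigma: float,
) -> None:
    """Add a Gaussian-edged disk: amplitude × Φ-style soft step at the rim."""
    r0, c0 = center
    pad = int(math.ceil(radius + 4 * edge_sigma + 2))
    rlo, rhi = max(0, int(r0) - pad), min(plane.shape[0], int(r0) + pad + 1)
    clo, chi = max(0, int(c0) - pad), min(plane.shape[1], int(c0) + pad + 1)
    rows = np.arange(rlo, rhi)[:, None]
    cols = np.arange(clo, chi)[None, :]
    dist = np.hypot(rows - r0, cols - c0)
    profile = 0.5 * (1.0 + erf((radius - dist) / (math.sqrt(2.0) * max(edge_sigma, 1e-6))))
    plane[rlo:rhi, clo:chi] += amplitude * profile


def _render_halo(
    plane: np.ndarray, center: tuple[float, float], sigma: float, amplitude: float,
) -> None:
    """Add a broad Gaussian blob (diffuse cytoplasmic autofluorescence)."""
    r0, c0 = center
    pad = int(math.ceil(4 * sigma))
    rlo, rhi = max(0, int(r0) - pad), min(plane.shape[0], int(r0) + pad + 1)
    clo, chi = max(0, int(c0) - pad), min(plane.shape[1], int(c0) + pad + 1)
    rows = np.arange(rlo, rhi)[:, None]
    cols = np.arange(clo, chi)[None, :]
    d2 = (rows - r0) ** 2 + (cols - c0) ** 2
    plane[rlo:rhi, clo:chi] += amplitude * np.exp(-d2 / (2.0 * sigma**2))


# ---------------------------------------------------------------------------
# co-culture fields
# ---------------------------------------------------------------------------

def simulate_coculture_field(
    config: CocultureSimConfig,
    field_id: str = "sim",
    condition: str = "",
) -> tuple[FieldImage, GroundTruth]:
    """Render one dual-label co-culture field.

    The GFP channel holds ``n_quiescent`` Gaussian-edged disks, the RFP
    channel ``n_senescent`` larger disks; each senescent cell adds a diffuse
    halo to the ``autofluor`` channel (with optional bleed-through into the
    fluorophore channels).  Gaussian read noise is added on top of a flat
    background and clipped at zero.
    """
    rng = np.random.default_rng(config.seed)
    size = config.field_size
    radii = (
        [config.nucleus_radius_quiescent] * config.n_quiescent
        + [config.nucleus_radius_senescent] * config.n_senescent
    )
    labels = ["GFP"] * config.n_quiescent + ["RFP"] * config.n_senescent
    centers = _place_centers(
        rng, radii, size, config.allow_touching,
        separation_margin=config.placement_margin,
    )

    planes = {
        "GFP": np.zeros((size, size)),
        "RFP": np.zeros((size, size)),
        "autofluor": np.zeros((size, size)),
    }
    objects: list[dict] = []
    for (center, radius, label) in zip(centers, radii, labels):
        intensity = config.nucleus_intensity * max(
            0.1, 1.0 + config.intensity_cv * rng.standard_normal()
        )
        _render_disk(planes[label], tuple(center), radius, intensity, config.edge_sigma)
        if label == "RFP" and config.autofluor_amplitude > 0:
            _render_halo(
                planes["autofluor"], tuple(center),
                sigma=2.5 * radius, amplitude=config.autofluor_amplitude,
            )
        objects.append(
            {
                "center": [float(center[0]), float(center[1])],
                "radius": float(radius),
                "label": label,
                "intensity": float(intensity),
            }
        )

    for name, frac in config.autofluor_bleed.items():
        planes[name] = planes[name] + frac * planes["autofluor"]

    channels = {}
    for name, plane in planes.items():
        noisy = plane + config.background_level \
            + config.noise_sd * rng.standard_normal(plane.shape)
        channels[name] = np.clip(noisy, 0.0, None)

    truth = GroundTruth(objects=objects, params=asdict(config), seed=config.seed)
    return (
        FieldImage(channels=channels, field_id=field_id, condition=condition),
        truth,
    )


# ---------------------------------------------------------------------------
# senolysis experiments
# ---------------------------------------------------------------------------

def simulate_senolysis_experiment(
    base: CocultureSimConfig,
    survival_gfp: float,
    survival_rfp: float,
    n_replicates: int,
    seed: int,
    well_cv: float = 0.10,
    vehicle_name: str = "DMSO",
    treated_name: str = "treated",
    render: bool = True,
) -> tuple[dict[str, list[FieldImage]], GroundTruth]:
    """Simulate a vehicle-vs-treated senolysis experiment.

    Each replicate well seeds the configured counts jittered by a well-level
    multiplicative factor (CV ``well_cv``); in treated wells every cell then
    survives an independent Bernoulli draw with the channel's survival
    fraction.  Replicate-level seeded and surviving counts are recorded in
    ``GroundTruth.extra["wells"]``.  With ``render=False`` only counts are
    drawn (the images list is empty) — sufficient for statistical power
    studies on the scoring pipeline.
    """
    if not (0.0 <= survival_gfp <= 1.0 and 0.0 <= survival_rfp <= 1.0):
        raise ValueError("survival fractions must lie in [0, 1]")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    survival = {"GFP": survival_gfp, "RFP": survival_rfp}
    nominal = {"GFP": base.n_quiescent, "RFP": base.n_senescent}

    wells: list[dict] = []
    images: dict[str, list[FieldImage]] = {vehicle_name: [], treated_name: []}
    for condition in (vehicle_name, treated_name):
        for rep in range(n_replicates):
            counts: dict[str, int] = {}
            for channel in ("GFP", "RFP"):
                factor = max(0.0, 1.0 + well_cv * rng.standard_normal())
                seeded = int(round(nominal[channel] * factor))
                if condition == treated_name:
                    surviving = int(rng.binomial(seeded, survival[channel])) if seeded else 0
                else:
                    surviving = seeded
                counts[channel] = surviving
            well = {
                "well_id": f"{condition}_r{rep}",
                "condition": condition,
                "replicate": rep,
                "counts": counts,
            }
            wells.append(well)
            if render:
                cfg = CocultureSimConfig(
                    **{
                        **asdict(base),
                        "n_quiescent": counts["GFP"],
                        "n_senescent": counts["RFP"],
                        "seed": int(rng.integers(0, 2**31 - 1)),
                    }
                )
                img, _ = simulate_coculture_field(
                    cfg, field_id=well["well_id"], condition=condition
                )
                images[condition].append(img)

    truth = GroundTruth(
        params={
            **asdict(base),
            "survival_gfp": survival_gfp,
            "survival_rfp": survival_rfp,
            "well_cv": well_cv,
            "n_replicates": n_replicates,
        },
        seed=seed,
        extra={"wells": wells, "vehicle": vehicle_name, "treated": treated_name},
    )
    return images, truth


def senolysis_assay_table(truth: GroundTruth) -> pd.DataFrame:
    """Ground-truth well counts as a long-format assay table.

    Columns: ``well_id, condition, replicate, channel, count`` — the input
    contract of the scoring module.
    """
    rows = []
    for well in truth.extra["wells"]:
        for channel, count in well["counts"].items():
            rows.append(
                {
                    "well_id": well["well_id"],
                    "condition": well["condition"],
                    "replicate": well["replicate"],
                    "channel": channel,
                    "count": count,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SABG brightfield fields
# ---------------------------------------------------------------------------

def simulate_sabg_field(
    n_clusters: int,
    cluster_radius: float = 8.0,
    cluster_hue: float = 240.0,
    total_cells: int = 40,
    seed: int = 0,
    field_size: int = 384,
    cluster_saturation: float = 0.8,
    cluster_brightness: float = 0.6,
    background_brightness: float = 0.92,
    noise_sd: float = 0.008,
    min_separation_factor: float = 3.0,
    edge_sigma: float = 0.8,
) -> tuple[RGBImage, GroundTruth]:
    """Render an X-Gal-stained brightfield field.

    A near-white background carries ``n_clusters`` blue-hued, high-saturation
    blobs (the histochemical reaction product); each cluster marks one
    positive cell among ``total_cells`` simulated cell centroids.  Ground
    truth records cluster centers, per-cluster hard-disk pixel areas, all
    cell centroids, and which cells are positive.
    """
    if not (0.0 <= cluster_hue < 360.0):
        raise ValueError("cluster_hue must be in [0, 360)")
    if n_clusters > total_cells:
        raise ValueError("n_clusters cannot exceed total_cells")
    rng = np.random.default_rng(seed)
    size = field_size
    sep_radius = min_separation_factor * cluster_radius / 2.0
    centers = _place_centers(
        rng, [sep_radius] * n_clusters, size, allow_touching=False
    ) if n_clusters else np.empty((0, 2))

    rows = np.arange(size)[:, None]
    cols = np.arange(size)[None, :]
    alpha = np.zeros((size, size))
    areas = []
    for center in centers:
        dist = np.hypot(rows - center[0], cols - center[1])
        areas.append(int(np.sum(dist <= cluster_radius)))
        profile = 0.5 * (
            1.0 + erf((cluster_radius - dist) / (math.sqrt(2.0) * edge_sigma))
        )
        alpha = np.maximum(alpha, profile)

    color = hsv2rgb(
        np.array([[[cluster_hue / 360.0, cluster_saturation, cluster_brightness]]])
    )[0, 0]
    bg = np.full((size, size, 3), background_brightness)
    image = bg * (1.0 - alpha[..., None]) + color[None, None, :] * alpha[..., None]
    image = np.clip(image + noise_sd * rng.standard_normal(image.shape), 0.0, 1.0)

    # remaining (negative) cell centroids, kept clear of the stained clusters
    # so the planted positive fraction is unambiguous
    n_neg = total_cells - n_clusters
    clearance = 2.0 * min_separation_factor * cluster_radius
    neg_list: list[np.ndarray] = []
    for _ in range(n_neg):
        for _try in range(_MAX_PLACEMENT_TRIES):
            cand = rng.uniform(cluster_radius, size - cluster_radius, size=2)
            if len(centers) == 0 or np.all(
                np.hypot(*(centers - cand).T) > clearance
            ):
                neg_list.append(cand)
                break
        else:
            raise PlacementError(
                f"could not place {n_neg} negative cells clear of clusters"
            )
    neg_centers = np.asarray(neg_list).reshape(-1, 2)
    cell_centroids = np.vstack([centers, neg_centers]) if total_cells else np.empty((0, 2))

    objects = [
        {
            "center": [float(c[0]), float(c[1])],
            "radius": float(cluster_radius),
            "label": "cluster",
            "area_px": areas[i],
            "hue": float(cluster_hue),
            "saturation": float(cluster_saturation),
        }
        for i, c in enumerate(centers)
    ]
    truth = GroundTruth(
        objects=objects,
        params={
            "n_clusters": n_clusters,
            "cluster_radius": cluster_radius,
            "cluster_hue": cluster_hue,
            "total_cells": total_cells,
            "field_size": field_size,
        },
        seed=seed,
        extra={
            "cell_centroids": cell_centroids.tolist(),
            "positive_cells": list(range(n_clusters)),
        },
    )
    return RGBImage.from_array(image), truth


# ---------------------------------------------------------------------------
# spectral stacks
# ---------------------------------------------------------------------------

def simulate_spectral_stack(
    compartment_profiles: Mapping[str, tuple[float, float, float]],
    n_channels: int = 32,
    wl_range: tuple[float, float] = (404.0, 644.0),
    seed: int = 0,
    field_size: int = 192,
    n_cells: int = 4,
    nucleus_radius: float = 10.0,
    cytoplasm_radius: float = 22.0,
    background_level: float = 5.0,
    noise_sd: float = 1.0,
) -> tuple[SpectralStack, ROISet]:
    """Render a lambda stack with Gaussian-in-wavelength compartment emission.

    ``compartment_profiles`` maps ``"nuclear"`` / ``"cytoplasmic"`` to a
    ``(peak_nm, width_nm, amplitude)`` triple; each plane is the sum over
    compartments of (spatial mask × Gaussian amplitude at that wavelength)
    plus background and read noise.  Returns matching nuclear and
    cytoplasmic ROIs (the cytoplasm is an annulus around each nucleus).
    """
    if n_channels < 2:
        raise ValueError("n_channels must be >= 2")
    wavelengths = wavelength_axis(wl_range[0], wl_range[1], n_channels)
    for name, (peak, width, _amp) in compartment_profiles.items():
        if not (wl_range[0] <= peak <= wl_range[1]):
            raise ValueError(f"{name}: peak {peak} nm outside range {wl_range}")
        if width <= 0:
            raise ValueError(f"{name}: width must be positive")

    rng = np.random.default_rng(seed)
    size = field_size
    centers = _place_centers(
        rng, [cytoplasm_radius + 2] * n_cells, size, allow_touching=False
    )
    rows = np.arange(size)[:, None]
    cols = np.arange(size)[None, :]
    nuclear_mask = np.zeros((size, size), dtype=bool)
    cyto_mask = np.zeros((size, size), dtype=bool)
    for center in centers:
        dist = np.hypot(rows - center[0], cols - center[1])
        nuclear_mask |= dist <= nucleus_radius
        cyto_mask |= (dist > nucleus_radius) & (dist <= cytoplasm_radius)

    masks = {"nuclear": nuclear_mask, "cytoplasmic": cyto_mask}
    planes = []
    for wl in wavelengths:
        plane = np.full((size, size), background_level, dtype=float)
        for name, (peak, width, amp) in compartment_profiles.items():
            if name not in masks:
                raise ValueError(f"unknown compartment {name!r}")
            gain = amp * math.exp(-((wl - peak) ** 2) / (2.0 * width**2))
            plane += gain * masks[name]
        plane += noise_sd * rng.standard_normal((size, size))
        planes.append(np.clip(plane, 0.0, None))

    stack = SpectralStack(planes=planes, wavelengths=wavelengths)
    rois = ROISet(
        rois=[
            ROI(roi_id="nuc", compartment="nuclear", mask=nuclear_mask),
            ROI(roi_id="cyt", compartment="cytoplasmic", mask=cyto_mask),
        ]
    )
    return stack, rois


# ---------------------------------------------------------------------------
# flow events
# ---------------------------------------------------------------------------

def simulate_flow_events(
    n_events: int,
    frac_gfp: float,
    frac_rfp: float,
    separation: float = 2.0,
    seed: int = 0,
    log_negative_mean: float = 1.5,
    log_sd: float = 0.25,
    dapi_log_mean_intact: float = 3.0,
    dapi_log_mean_debris: float = 1.0,
    dapi_log_sd: float = 0.2,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a flow-cytometry event table of isolated nuclei plus debris.

    GFP⁺ and RFP⁺ populations are log-normal in their positive channel,
    ``separation`` log10 units above the negative cluster; the remainder
    (``1 − frac_gfp − frac_rfp``) is double-negative debris with low DAPI.
    Intact nuclei carry high DAPI intensity.  True population labels are
    recorded in ``GroundTruth.extra["labels"]``.
    """
    if frac_gfp < 0 or frac_rfp < 0 or frac_gfp + frac_rfp > 1.0 + 1e-12:
        raise ValueError("population fractions must be non-negative and sum to <= 1")
    if separation <= 0:
        raise ValueError("separation must be positive")
    rng = np.random.default_rng(seed)
    labels = rng.choice(
        ["gfp_pos", "rfp_pos", "debris"],
        size=n_events,
        p=[frac_gfp, frac_rfp, max(0.0, 1.0 - frac_gfp - frac_rfp)],
    )
    neg, pos = log_negative_mean, log_negative_mean + separation
    log_gfp = np.where(labels == "gfp_pos", pos, neg) + log_sd * rng.standard_normal(n_events)
    log_rfp = np.where(labels == "rfp_pos", pos, neg) + log_sd * rng.standard_normal(n_events)
    log_dapi = np.where(
        labels == "debris", dapi_log_mean_debris, dapi_log_mean_intact
    ) + dapi_log_sd * rng.standard_normal(n_events)

    table = pd.DataFrame(
        {
            "event_id": np.arange(n_events),
            "gfp": 10.0 ** log_gfp,
            "rfp": 10.0 ** log_rfp,
            "dapi": 10.0 ** log_dapi,
        }
    )
    truth = GroundTruth(
        params={
            "n_events": n_events,
            "frac_gfp": frac_gfp,
            "frac_rfp": frac_rfp,
            "separation": separation,
            "log_negative_mean": log_negative_mean,
            "log_sd": log_sd,
        },
        seed=seed,
        extra={"labels": labels.tolist()},
    )
    return table, truth
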
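"""Per-ROI emission spectra from lambda stacks.

Senescent cells accumulate lipofuscin, an intrinsically fluorescent pigment
concentrated in the cytoplasm.  Exciting unlabeled cells at 405 nm and
recording emission in narrow wavelength windows (a lambda stack) lets the
autofluorescence spectrum be profiled per compartment: mean fluorescence
intensity (MFI) over a nuclear or cytoplasmic region of interest, one value
per emission channel.  The headline comparison is cytoplasmic-vs-nuclear
contrast between senescent and control cells.

ROIs are supplied, not auto-segmented (they are drawn manually in practice);
:func:`cytoplasmic_ring` derives a cytoplasmic annulus from a nuclear mask
as a convenience.  No spectral unmixing is performed — raw MFI only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.morphology import dilation, disk

from .errors import EmptyROIError, GroupingError
from .iohub import SpectralStack

__all__ = [
    "ROI",
    "ROISet",
    "SpectrumProfile",
    "roi_spectrum",
    "peak_band",
    "compare_compartments",
    "cytoplasmic_ring",
    "profiles_to_table",
]


@dataclass
class ROI:
    """A named region of interest with a compartment label."""

    roi_id: str
    compartment: str  # "nuclear" | "cytoplasmic" | "other"
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2D")
        if not self.mask.any():
            raise EmptyROIError(f"ROI {self.roi_id!r} is empty")


@dataclass
class ROISet:
    rois: list[ROI] = field(default_factory=list)

    def by_compartment(self, compartment: str) -> list[ROI]:
        return [r for r in self.rois if r.compartment == compartment]

    def __iter__(self):
        return iter(self.rois)


@dataclass
class SpectrumProfile:
    """Per-wavelength MFI of one ROI."""

    roi_id: str
    compartment: str
    wavelengths: np.ndarray
    mfi: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.mfi = np.asarray(self.mfi, dtype=float)
        if self.mfi.shape != self.wavelengths.shape:
            raise ValueError("mfi and wavelengths must have equal length")
        if not np.all(np.isfinite(self.mfi)):
            raise ValueError("MFI values must be finite")


def roi_spectrum(
    stack: SpectralStack,
    roi: ROI | np.ndarray,
    condition: str = "",
) -> SpectrumProfile:
    """Mean intensity of each spectral plane over the ROI pixels.

    ``mfi[k]`` is the mean of plane ``k`` restricted to the ROI, so the
    operation is linear in the stack and depends only on pixels inside
    the mask.
    """
    if isinstance(roi, np.ndarray):
        roi = ROI(roi_id="roi", compartment="other", mask=roi)
    first = stack.planes[0]
    if roi.mask.shape != first.shape:
        raise ValueError(
            f"ROI shape {roi.mask.shape} does not match stack planes {first.shape}"
        )
    flat = roi.mask.ravel()
    mfi = np.array([plane.ravel()[flat].mean() for plane in stack.planes])
    return SpectrumProfile(
        roi_id=roi.roi_id,
        compartment=roi.compartment,
        wavelengths=stack.wavelengths,
        mfi=mfi,
        condition=condition,
    )


def peak_band(
    profile: SpectrumProfile,
    fraction: float = 0.5,
    baseline: float | None = None,
) -> tuple[float, float] | None:
    """Contiguous wavelength interval around the spectral peak.

    Returns the interval of grid wavelengths, containing the argmax, where
    ``mfi − baseline ≥ fraction × (max − baseline)``.  ``baseline`` defaults
    to ``min(mfi)``.  With ``fraction=0.5`` this is the discrete full width
    at half maximum.  A flat spectrum has no peak and returns ``None``.

    Note the band criterion is a convention of this implementation; reported
    peak bands in the literature rarely define one operationally.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    mfi = profile.mfi
    base = float(mfi.min()) if baseline is None else float(baseline)
    height = float(mfi.max()) - base
    if height <= 0:
        return None
    k = int(np.argmax(mfi))
    above = (mfi - base) >= fraction * height - 1e-12
    lo = k
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = k
    while hi < len(mfi) - 1 and above[hi + 1]:
        hi += 1
    return (float(profile.wavelengths[lo]), float(profile.wavelengths[hi]))


def compare_compartments(
    profiles: list[SpectrumProfile],
    senescent: str = "senescent",
    control: str = "control",
    exceedance_ratio: float = 2.0,
) -> tuple[pd.DataFrame, dict]:
    """Per-wavelength nuclear-vs-cytoplasmic contrast between two conditions.

    For every wavelength the table reports the group-mean MFI of each
    (condition, compartment) cell, the senescent − control difference per
    compartment, and whether the cytoplasmic difference exceeds
    ``exceedance_ratio ×`` the absolute nuclear difference.  The summary
    gives the contiguous exceedance interval containing the largest
    cytoplasmic difference (``None`` if no channel qualifies).
    """
    groups: dict[tuple[str, str], list[np.ndarray]] = {}
    wavelengths = None
    for p in profiles:
        if wavelengths is None:
            wavelengths = p.wavelengths
        elif not np.array_equal(wavelengths, p.wavelengths):
            raise ValueError("all profiles must share one wavelength axis")
        groups.setdefault((p.condition, p.compartment), []).append(p.mfi)
    for cond in (senescent, control):
        for comp in ("nuclear", "cytoplasmic"):
            if (cond, comp) not in groups:
                raise GroupingError(f"no profiles for condition={cond!r}, compartment={comp!r}")

    mean = {key: np.mean(vals, axis=0) for key, vals in groups.items()}
    diff_cyto = mean[(senescent, "cytoplasmic")] - mean[(control, "cytoplasmic")]
    diff_nuc = mean[(senescent, "nuclear")] - mean[(control, "nuclear")]
    exceeds = (diff_cyto > 0) & (diff_cyto > exceedance_ratio * np.abs(diff_nuc))

    table = pd.DataFrame(
        {
            "wavelength_nm": wavelengths,
            f"mfi_{senescent}_cytoplasmic": mean[(senescent, "cytoplasmic")],
            f"mfi_{control}_cytoplasmic": mean[(control, "cytoplasmic")],
            f"mfi_{senescent}_nuclear": mean[(senescent, "nuclear")],
            f"mfi_{control}_nuclear": mean[(control, "nuclear")],
            "diff_cytoplasmic": diff_cyto,
            "diff_nuclear": diff_nuc,
            "cytoplasmic_exceeds": exceeds,
        }
    )

    interval = None
    if exceeds.any():
        k = int(np.argmax(np.where(exceeds, diff_cyto, -np.inf)))
        lo = k
        while lo > 0 and exceeds[lo - 1]:
            lo -= 1
        hi = k
        while hi < len(exceeds) - 1 and exceeds[hi + 1]:
            hi += 1
        interval = (float(wavelengths[lo]), float(wavelengths[hi]))
    summary = {
        "exceedance_interval_nm": interval,
        "exceedance_ratio": exceedance_ratio,
        "max_cytoplasmic_difference": float(diff_cyto.max()),
        "max_abs_nuclear_difference": float(np.abs(diff_nuc).max()),
    }
    return table, summary


def cytoplasmic_ring(
    nuclear_mask: np.ndarray, ring_width: int = 8
) -> np.ndarray:
    """Cytoplasmic annulus: dilation of the nuclear mask minus the nucleus."""
    nuclear_mask = np.asarray(nuclear_mask, dtype=bool)
    if ring_width < 1:
        raise ValueError("ring_width must be >= 1")
    dilated = dilation(nuclear_mask, footprint=disk(ring_width))
    return dilated & ~nuclear_mask


def profiles_to_table(profiles: list[SpectrumProfile]) -> pd.DataFrame:
    """Long-format table: roi_id, compartment, condition, wavelength_nm, mfi."""
    rows = []
    for p in profiles:
        for wl, value in zip(p.wavelengths, p.mfi):
            rows.append(
                {
                    "roi_id": p.roi_id,
                    "compartment": p.compartment,
                    "condition": p.condition,
                    "wavelength_nm": float(wl),
                    "mfi": float(value),
                }
            )
    return pd.DataFrame(rows)
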
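"""Readers and writers for the image and table formats the toolkit touches.

Supported formats are deliberately plain: grayscale single/multi-page TIFF for
fluorescence fields and spectral (lambda) stacks, PNG or TIFF for RGB
brightfield images, RFC-4180 CSV for flow-event and result tables, and JSON
for configuration and plate layouts.  Proprietary microscope containers
(ND2, CZI) and binary FCS files are out of scope; convert upstream.

Pixel coordinates are 0-based ``(row, col)`` with the origin at the top-left,
matching TIFF raster order.  Integer TIFF data are kept in their native depth;
conversion to ``[0, 1]`` floats happens only where an operation requires it.

Every file read or written emits one structured log line with dimensions and
a CRC32 checksum, so screening-scale runs keep provenance.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import (
    ChannelMappingError,
    FormatError,
    SchemaError,
    WavelengthAxisError,
)

logger = logging.getLogger("senolytica.iohub")

__all__ = [
    "FieldImage",
    "RGBImage",
    "SpectralStack",
    "PlateLayout",
    "read_field",
    "write_field",
    "read_rgb_image",
    "write_rgb_image",
    "read_spectral_stack",
    "write_spectral_stack",
    "read_event_table",
    "write_table",
    "read_plate_layout",
]


def _log_io(verb: str, path: Path, arr: np.ndarray) -> None:
    checksum = zlib.crc32(np.ascontiguousarray(arr).tobytes())
    logger.info(
        "%s path=%s shape=%s dtype=%s crc32=%08x",
        verb, path, "x".join(map(str, arr.shape)), arr.dtype, checksum,
    )


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FieldImage:
    """One microscopy field: named channel planes plus pixel metadata.

    Parameters
    ----------
    channels
        Mapping of channel name (e.g. ``"GFP"``, ``"RFP"``, ``"autofluor"``)
        to a 2D non-negative intensity plane in arbitrary units.
    pixel_size
        Micrometers per pixel, if known.
    field_id, condition
        Free-text identifiers (e.g. condition ``"DMSO"`` or ``"navitoclax"``).
    """

    channels: dict[str, np.ndarray]
    pixel_size: float | None = None
    field_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("FieldImage requires at least one channel")
        shapes = {name: np.asarray(p).shape for name, p in self.channels.items()}
        first = next(iter(shapes.values()))
        if len(first) != 2:
            raise ValueError("channel planes must be 2D")
        for name, shape in shapes.items():
            if shape != first:
                raise ValueError(
                    f"channel {name!r} shape {shape} != {first}"
                )
        for name, plane in self.channels.items():
            plane = np.asarray(plane)
            if not np.all(np.isfinite(plane)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if plane.min() < 0:
                raise ValueError(f"channel {name!r} contains negative intensities")
            self.channels[name] = plane

    @property
    def height(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def width(self) -> int:
        return next(iter(self.channels.values())).shape[1]

    def channel(self, name: str) -> np.ndarray:
        from .errors import ChannelError

        if name not in self.channels:
            raise ChannelError(
                f"channel {name!r} not in field {self.field_id!r}; "
                f"have {sorted(self.channels)}"
            )
        return self.channels[name]


@dataclass
class RGBImage:
    """RGB brightfield image with planes scaled to ``[0, 1]``."""

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray

    def __post_init__(self) -> None:
        planes = [np.asarray(p, dtype=float) for p in (self.red, self.green, self.blue)]
        if len({p.shape for p in planes}) != 1 or planes[0].ndim != 2:
            raise ValueError("R, G, B planes must be 2D and share dimensions")
        for p in planes:
            if not np.all(np.isfinite(p)) or p.min() < 0 or p.max() > 1:
                raise ValueError("RGB planes must be finite and within [0, 1]")
        self.red, self.green, self.blue = planes

    @property
    def height(self) -> int:
        return self.red.shape[0]

    @property
    def width(self) -> int:
        return self.red.shape[1]

    def as_array(self) -> np.ndarray:
        """Stack to an ``(H, W, 3)`` float array."""
        return np.dstack([self.red, self.green, self.blue])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "RGBImage":
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 3 or arr.shape[2] < 3:
            raise ValueError("expected an (H, W, 3) array")
        return cls(arr[..., 0], arr[..., 1], arr[..., 2])


@dataclass
class SpectralStack:
    """Ordered emission-wavelength planes (a lambda stack).

    ``planes[k]`` records emission in the window centered at
    ``wavelengths[k]`` nanometers; ``excitation`` is the laser line in nm.
    """

    planes: list[np.ndarray]
    wavelengths: np.ndarray
    excitation: float = 405.0
    axis_convention: str = "evenly-spaced endpoints"

    def __post_init__(self) -> None:
        self.planes = [np.asarray(p) for p in self.planes]
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if len(self.planes) != len(self.wavelengths):
            raise WavelengthAxisError(
                f"{len(self.planes)} planes but {len(self.wavelengths)} wavelengths"
            )
        if len(self.wavelengths) and np.any(np.diff(self.wavelengths) <= 0):
            raise WavelengthAxisError("wavelengths must be strictly increasing")
        if len({p.shape for p in self.planes}) > 1:
            raise ValueError("all planes must share dimensions")

    def __len__(self) -> int:
        return len(self.planes)

    def as_array(self) -> np.ndarray:
        """Stack to ``(n_channels, H, W)``."""
        return np.stack(self.planes, axis=0)


@dataclass
class PlateLayout:
    """Well → condition map with file references for a screening plate."""

    wells: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [w["well_id"] for w in self.wells]
        if len(ids) != len(set(ids)):
            raise ValueError("well_ids must be unique")


# ---------------------------------------------------------------------------
# field images
# ---------------------------------------------------------------------------

def read_field(
    path: str | Path,
    channel_map: Mapping[int, str],
    pixel_size: float | None = None,
    field_id: str = "",
    condition: str = "",
) -> FieldImage:
    """Read a single- or multi-page grayscale TIFF into a :class:`FieldImage`.

    ``channel_map`` assigns a channel name to each page index, e.g.
    ``{0: "GFP", 1: "RFP"}``.  Page indices must exist in the file.
    """
    path = Path(path)
    try:
        pages = tifffile.imread(path)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise FormatError(f"{path}: expected grayscale pages, got shape {pages.shape}")
    n = pages.shape[0]
    bad = [i for i in channel_map if not (0 <= i < n)]
    if bad:
        raise ChannelMappingError(
            f"{path}: channel map indices {bad} out of range for {n} page(s)"
        )
    channels = {name: pages[i] for i, name in channel_map.items()}
    _log_io("read_field", path, pages)
    return FieldImage(
        channels=channels,
        pixel_size=pixel_size,
        field_id=field_id or path.stem,
        condition=condition,
    )


def write_field(
    field_image: FieldImage,
    path: str | Path,
    channel_order: Sequence[str] | None = None,
) -> list[str]:
    """Write a field as a multi-page grayscale TIFF; returns the page order."""
    path = Path(path)
    order = list(channel_order) if channel_order else sorted(field_image.channels)
    stack = np.stack([field_image.channels[name] for name in order])
    tifffile.imwrite(path, stack, photometric="minisblack")
    _log_io("write_field", path, stack)
    return order


# ---------------------------------------------------------------------------
# RGB brightfield
# ---------------------------------------------------------------------------

def read_rgb_image(path: str | Path) -> RGBImage:
    """Read an RGB brightfield image (PNG or TIFF), scaling to ``[0, 1]``."""
    path = Path(path)
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise FormatError(f"{path}: expected an RGB image, got shape {arr.shape}")
    arr = arr[..., :3]
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    _log_io("read_rgb", path, arr)
    return RGBImage.from_array(arr)


def write_rgb_image(image: RGBImage, path: str | Path) -> None:
    """Write an RGB image as 8-bit PNG or TIFF by extension."""
    path = Path(path)
    arr8 = np.round(image.as_array() * 255).astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr8)
    else:
        iio.imwrite(path, arr8)
    _log_io("write_rgb", path, arr8)


# ---------------------------------------------------------------------------
# spectral stacks
# ---------------------------------------------------------------------------

def wavelength_axis(start: float, stop: float, count: int) -> np.ndarray:
    """Evenly spaced inclusive wavelength grid, e.g. (404, 644, 32).

    The per-channel bandwidth of the detector is not encoded; the evenly
    spaced axis is a convention recorded in the stack metadata.
    """
    if count < 2 or stop <= start:
        raise WavelengthAxisError(f"invalid wavelength spec ({start}, {stop}, {count})")
    return np.linspace(start, stop, count)


def read_spectral_stack(
    path: str | Path,
    wavelengths: Sequence[float] | tuple[float, float, int],
    excitation: float = 405.0,
) -> SpectralStack:
    """Read a multi-page TIFF lambda stack.

    ``wavelengths`` is either an explicit list of emission centers (nm), one
    per page, or a ``(start, stop, count)`` spec expanded to an evenly spaced
    inclusive grid — e.g. ``(404, 644, 32)`` gives centers 404…644 nm in
    steps of 240/31 ≈ 7.74 nm.
    """
    path = Path(path)
    try:
        pages = tifffile.imread(path)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if pages.ndim == 2:
        pages = pages[None]
    if isinstance(wavelengths, tuple) and len(wavelengths) == 3 \
            and isinstance(wavelengths[2], (int, np.integer)):
        axis = wavelength_axis(*wavelengths)
    else:
        axis = np.asarray(wavelengths, dtype=float)
    if len(axis) != pages.shape[0]:
        raise WavelengthAxisError(
            f"{path}: {pages.shape[0]} page(s) but {len(axis)} wavelength(s)"
        )
    order = np.argsort(axis)
    _log_io("read_spectral_stack", path, pages)
    return SpectralStack(
        planes=[pages[i] for i in order],
        wavelengths=axis[order],
        excitation=excitation,
    )


def write_spectral_stack(stack: SpectralStack, path: str | Path) -> None:
    path = Path(path)
    arr = stack.as_array()
    tifffile.imwrite(path, arr, photometric="minisblack")
    _log_io("write_spectral_stack", path, arr)


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

def read_event_table(
    path: str | Path,
    gfp_col: str = "gfp",
    rfp_col: str = "rfp",
    dapi_col: str = "dapi",
    id_col: str = "event_id",
) -> pd.DataFrame:
    """Read a flow-cytometry event table from CSV.

    Requires GFP, RFP and DAPI intensity columns (names configurable).
    Rows with non-numeric intensities are dropped and the count is logged.
    Returns a DataFrame with canonical columns ``event_id, gfp, rfp, dapi``.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot read CSV {path}: {exc}") from exc
    missing = [c for c in (gfp_col, rfp_col, dapi_col) if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    table = pd.DataFrame(
        {
            "event_id": raw[id_col] if id_col in raw.columns else np.arange(len(raw)),
            "gfp": pd.to_numeric(raw[gfp_col], errors="coerce"),
            "rfp": pd.to_numeric(raw[rfp_col], errors="coerce"),
            "dapi": pd.to_numeric(raw[dapi_col], errors="coerce"),
        }
    )
    n_bad = int(table[["gfp", "rfp", "dapi"]].isna().any(axis=1).sum())
    if n_bad:
        logger.warning("%s: dropped %d non-numeric event row(s)", path, n_bad)
        table = table.dropna(subset=["gfp", "rfp", "dapi"])
    if table.empty:
        logger.warning("%s: event table has 0 rows", path)
    logger.info("read_event_table path=%s rows=%d", path, len(table))
    return table.reset_index(drop=True)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as RFC-4180 CSV with a header row."""
    path = Path(path)
    table.to_csv(path, index=False)
    logger.info("write_table path=%s rows=%d cols=%d", path, len(table), table.shape[1])


# ---------------------------------------------------------------------------
# plate layouts
# ---------------------------------------------------------------------------

def read_plate_layout(path: str | Path, check_files: bool = True) -> PlateLayout:
    """Load a JSON plate layout: list of well records with file references."""
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read layout {path}: {exc}") from exc
    wells = data["wells"] if isinstance(data, dict) else data
    for well in wells:
        for key in ("well_id", "condition"):
            if key not in well:
                raise SchemaError(f"{path}: well record missing {key!r}")
        if check_files:
            for ref in well.get("files", []):
                ref_path = (path.parent / ref).resolve()
                if not ref_path.exists():
                    raise FormatError(f"{path}: referenced file missing: {ref}")
    return PlateLayout(wells=list(wells))
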
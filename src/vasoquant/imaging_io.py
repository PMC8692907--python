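"""Image/volume containers with physical spacing, TIFF I/O and depth projection.

The native acquisition unit is a 3D intensity volume scanned on a regular
grid: the depth axis is the first array axis and the lateral axes are
(y, x) in row-major order, matching multi-page TIFF page order.  All
intensity processing is done in floating point regardless of the on-disk
bit depth, so downstream intensity sums cannot overflow.

Spacing metadata (the scan step size, in µm) is supplied by the caller —
typically from a config file or CLI flag — rather than parsed from TIFF
resolution tags, which are rarely reliable in microscopy exports.  When a
file does carry resolution tags they are checked and a warning is logged
on mismatch.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "VolumeScan",
    "RasterImage",
    "read_volume",
    "write_volume",
    "read_image",
    "write_image",
    "compute_mip",
    "read_spacing_sidecar",
]


def _check_intensities(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite intensities")
    if np.any(arr < 0):
        raise ValueError(f"{name} contains negative intensities")


@dataclass
class VolumeScan:
    """A 3D intensity volume with per-axis physical spacing.

    Parameters
    ----------
    voxels : ndarray, shape (depth, y, x)
        Non-negative intensities in arbitrary units.
    lateral_spacing_um : float
        In-plane grid pitch (the scan step size), µm.
    axial_spacing_um : float
        Depth pitch, µm.
    meta : dict
        Free-form acquisition annotations.
    """

    voxels: np.ndarray
    lateral_spacing_um: float
    axial_spacing_um: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"voxels must be 3D (depth, y, x); got ndim={self.voxels.ndim}"
            )
        if min(self.voxels.shape) < 1:
            raise ValueError("all volume extents must be >= 1")
        _check_intensities(self.voxels, "voxels")
        if not (self.lateral_spacing_um > 0 and self.axial_spacing_um > 0):
            raise ValueError("spacings must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class RasterImage:
    """A 2D intensity image with pixel size and a processing-stage tag.

    ``stage`` distinguishes raw images (valid for intensity-sum metrics
    such as Hb content) from contrast-enhanced ones (valid for
    segmentation).
    """

    pixels: np.ndarray
    pixel_size_um: float
    stage: str = "raw"

    _STAGES = ("raw", "enhanced")

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D; got ndim={self.pixels.ndim}")
        if min(self.pixels.shape) < 1:
            raise ValueError("both image extents must be >= 1")
        _check_intensities(self.pixels, "pixels")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be strictly positive")
        if self.stage not in self._STAGES:
            raise ValueError(f"stage must be one of {self._STAGES}; got {self.stage!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_mm2(self) -> float:
        """Total imaged area in mm² (rows · cols · pixel_size²)."""
        rows, cols = self.pixels.shape
        return rows * cols * self.pixel_size_um**2 / 1e6


def _load_pages(path: Path) -> np.ndarray:
    """Read a single- or multi-page grayscale TIFF as (depth, y, x)."""
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
    if not pages:
        raise ValueError(f"{path}: TIFF contains no pages")
    shapes = {p.shape for p in pages}
    for p in pages:
        if p.ndim != 2:
            raise ValueError(
                f"{path}: non-grayscale page of shape {p.shape}; "
                "only single-channel 2D pages are supported"
            )
    if len(shapes) > 1:
        raise ValueError(f"{path}: inconsistent page shapes {sorted(shapes)}")
    return np.stack(pages, axis=0)


def _warn_on_tag_mismatch(path: Path, expected_um: float) -> None:
    """Compare TIFF XResolution tag (if any) against caller-supplied spacing."""
    try:
        with tifffile.TiffFile(path) as tif:
            tags = tif.pages[0].tags
            if "XResolution" not in tags or "ResolutionUnit" not in tags:
                return
            num, den = tags["XResolution"].value
            unit = tags["ResolutionUnit"].value
        if den == 0 or num == 0:
            return
        # ResolutionUnit 3 = cm: pixels/cm -> µm/pixel
        if int(unit) == 3:
            tag_um = 1e4 * den / num
            if abs(tag_um - expected_um) / expected_um > 0.01:
                logger.warning(
                    "%s: TIFF resolution tag implies %.3g µm/px but "
                    "%.3g µm/px was supplied; using the supplied value",
                    path, tag_um, expected_um,
                )
    except Exception:  # tag parsing is best-effort only
        pass


def read_volume(
    path: str | Path,
    lateral_spacing_um: float,
    axial_spacing_um: float,
    meta: dict[str, Any] | None = None,
) -> VolumeScan:
    """Read a grayscale TIFF stack as a :class:`VolumeScan`.

    A single-page TIFF is treated as a depth-1 volume.  Page order maps
    to depth order.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"volume file not found: {path}")
    voxels = _load_pages(path)
    _warn_on_tag_mismatch(path, lateral_spacing_um)
    return VolumeScan(
        voxels=voxels,
        lateral_spacing_um=lateral_spacing_um,
        axial_spacing_um=axial_spacing_um,
        meta=dict(meta or {}),
    )


def write_volume(path: str | Path, volume: VolumeScan) -> None:
    """Write a volume as a multi-page float32 grayscale TIFF."""
    tifffile.imwrite(
        Path(path), volume.voxels.astype(np.float32), photometric="minisblack"
    )


def read_image(path: str | Path, pixel_size_um: float, stage: str = "raw") -> RasterImage:
    """Read a 2D grayscale image (TIFF or PNG) as a :class:`RasterImage`."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"image file not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = _load_pages(path)
        if arr.shape[0] != 1:
            raise ValueError(f"{path}: expected a single-page 2D image")
        arr = arr[0]
    else:
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:
            if arr.shape[2] not in (1, 2):  # allow trivial gray+alpha
                raise ValueError(f"{path}: non-grayscale image of shape {arr.shape}")
            arr = arr[..., 0]
    return RasterImage(pixels=arr, pixel_size_um=pixel_size_um, stage=stage)


def write_image(path: str | Path, image: RasterImage) -> None:
    """Write a 2D image as a float32 grayscale TIFF."""
    tifffile.imwrite(
        Path(path), image.pixels.astype(np.float32), photometric="minisblack"
    )


def read_spacing_sidecar(path: str | Path) -> dict[str, float]:
    """Read lateral/axial spacing from a JSON or YAML sidecar file.

    The sidecar must contain ``lateral_spacing_um`` and may contain
    ``axial_spacing_um``.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yml", ".yaml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if "lateral_spacing_um" not in data:
        raise KeyError(f"{path}: sidecar missing 'lateral_spacing_um'")
    return {k: float(v) for k, v in data.items() if k.endswith("_um")}


def compute_mip(volume: VolumeScan) -> RasterImage:
    """Maximum intensity projection along the depth axis.

    Pixel (i, j) of the output is the per-column depth maximum
    max_d voxels[d, i, j]; the result inherits the lateral spacing and
    is tagged ``raw``.
    """
    return RasterImage(
        pixels=volume.voxels.max(axis=0),
        pixel_size_um=volume.lateral_spacing_um,
        stage="raw",
    )
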
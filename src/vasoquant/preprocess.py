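"""Contrast enhancement of projection images and raw-intensity Hb content.

Hemoglobin content is deliberately computed on the *raw* (unenhanced)
image: contrast-limited adaptive histogram equalization (CLAHE) and
smoothing redistribute intensity and would bias any intensity-sum
metric, so :func:`hb_content` rejects enhanced inputs outright.

The enhancement chain for segmentation is CLAHE (tile-wise dynamic-range
adjustment with a clip limit) followed by Gaussian smoothing whose scale
is given in physical units, so scans at different pixel pitches are
smoothed comparably.  The output is rescaled to [0, 1], which makes
global (Otsu) thresholds comparable across inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure

from vasoquant.imaging_io import RasterImage

__all__ = ["EnhanceParams", "hb_content", "enhance", "smooth"]


@dataclass
class EnhanceParams:
    """Parameters of the contrast-enhancement stage.

    Attributes
    ----------
    clahe_tile : int
        Number of CLAHE tiles per image side (>= 1).
    clahe_clip : float
        CLAHE clip limit in (0, 1]; 1 disables clipping.
    smooth_sigma_um : float or None
        Gaussian smoothing scale in µm (>= 0).  ``None`` means one pixel's
        physical size, the default for a minimal anti-quantization blur.
    """

    clahe_tile: int = 8
    clahe_clip: float = 0.01
    smooth_sigma_um: float | None = None

    def __post_init__(self) -> None:
        if int(self.clahe_tile) != self.clahe_tile or self.clahe_tile < 1:
            raise ValueError("clahe_tile must be an integer >= 1")
        self.clahe_tile = int(self.clahe_tile)
        if not (0 < self.clahe_clip <= 1):
            raise ValueError("clahe_clip must be in (0, 1]")
        if self.smooth_sigma_um is not None and self.smooth_sigma_um < 0:
            raise ValueError("smooth_sigma_um must be >= 0")


def hb_content(raw: RasterImage) -> float:
    """Hemoglobin content: sum of raw intensities per imaged area (a.u./mm²).

    Raises
    ------
    ValueError
        If the image is enhanced — the metric is defined on raw data only.
    """
    if raw.stage != "raw":
        raise ValueError(
            "hb_content requires a raw image; got stage="
            f"{raw.stage!r} (intensity sums on enhanced images are biased "
            "by contrast adjustment)"
        )
    return float(raw.pixels.sum() / raw.area_mm2)


def smooth(image: RasterImage, sigma_um: float) -> RasterImage:
    """Gaussian smoothing with the scale given in physical units.

    ``sigma_px = sigma_um / pixel_size_um``; the stage tag is preserved.
    Total intensity is conserved up to boundary truncation, which is
    below 1% when the image carries a zero margin of at least 4·sigma_px.
    """
    if sigma_um < 0:
        raise ValueError("sigma_um must be >= 0")
    sigma_px = sigma_um / image.pixel_size_um
    out = ndimage.gaussian_filter(image.pixels, sigma=sigma_px) if sigma_px > 0 else image.pixels
    return RasterImage(
        pixels=np.clip(out, 0.0, None),
        pixel_size_um=image.pixel_size_um,
        stage=image.stage,
    )


def enhance(raw: RasterImage, params: EnhanceParams | None = None) -> RasterImage:
    """CLAHE + Gaussian smoothing; output rescaled to [0, 1], stage 'enhanced'.

    The smoothing sigma is converted from µm to pixels as
    ``sigma_px = smooth_sigma_um / pixel_size_um``.
    """
    if raw.stage != "raw":
        raise ValueError(f"enhance expects a raw image; got stage={raw.stage!r}")
    if params is None:
        params = EnhanceParams()

    img = raw.pixels
    lo, hi = float(img.min()), float(img.max())
    if hi > lo:
        norm = (img - lo) / (hi - lo)
        rows, cols = img.shape
        kernel = (
            max(1, rows // params.clahe_tile),
            max(1, cols // params.clahe_tile),
        )
        out = exposure.equalize_adapthist(
            norm, kernel_size=kernel, clip_limit=params.clahe_clip, nbins=256
        )
    else:
        # constant image: no dynamic range to adjust; rescale convention
        # maps it to zero
        out = np.zeros_like(img)

    sigma_um = (
        raw.pixel_size_um if params.smooth_sigma_um is None else params.smooth_sigma_um
    )
    sigma_px = sigma_um / raw.pixel_size_um
    if sigma_px > 0:
        out = ndimage.gaussian_filter(out, sigma=sigma_px)

    out = np.clip(out, 0.0, None)
    peak = out.max()
    if peak > 0:
        out = out / peak
    return RasterImage(pixels=out, pixel_size_um=raw.pixel_size_um, stage="enhanced")
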
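"""Per-plate, per-channel flat-field (illumination) estimation and correction.

The illumination function is the pixelwise mean of every image of one
channel across one plate, smoothed with a large square median filter
(default 100×100 px) so that cellular structure averages out and only the
persistent shading pattern of the optics remains. Raw images are corrected
by division.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import rank
from skimage.morphology import footprint_rectangle

__all__ = ["IlluminationFunction", "compute_illumination", "apply_correction"]

#: Relative floor applied before division so a zero-background estimate can
#: never produce infinities.
POSITIVE_FLOOR_FRACTION = 1e-6


@dataclass
class IlluminationFunction:
    channel: str
    image: np.ndarray  # strictly positive, same shape as the raw images
    plate: str = ""
    n_images_averaged: int = 0


def _median_smooth(image: np.ndarray, size: int) -> np.ndarray:
    """Square sliding-window median with reflective padding.

    Even window sizes use the floor-centered convention: the window around
    pixel i spans [i - size//2, i + size//2 - 1] on each axis. The image is
    quantized to 8 bits over its range for the sliding-histogram filter;
    for the smooth fields this stage sees, the quantization error
    (≤ range/255 per pixel) is far below the accuracy of the flat-field
    estimate itself.
    """
    if size < 1:
        raise ValueError("median filter size must be >= 1")
    if size == 1:
        return image.astype(np.float64, copy=True)
    lo, hi = float(image.min()), float(image.max())
    if hi - lo <= 0:
        return image.astype(np.float64, copy=True)
    pad = size // 2
    padded = np.pad(image.astype(np.float64), pad, mode="reflect")
    quant = np.round((padded - lo) / (hi - lo) * 255.0).astype(np.uint8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank filters warn on large footprints
        med = rank.median(quant, footprint_rectangle((size, size)))
    # even window sizes: floor-centered span [i - size//2, i + size//2 - 1];
    # the median of an even pixel count is the upper-middle order statistic
    med = med[pad:pad + image.shape[0], pad:pad + image.shape[1]]
    return lo + med.astype(np.float64) * (hi - lo) / 255.0


def compute_illumination(
    images: list[np.ndarray] | tuple[np.ndarray, ...],
    median_filter_size_px: int = 100,
    channel: str = "",
    plate: str = "",
) -> IlluminationFunction:
    """Estimate the illumination function from all images of one plate/channel."""
    images = list(images)
    if not images:
        raise ValueError("compute_illumination needs at least one image")
    shape = images[0].shape
    bad = [i for i, im in enumerate(images) if im.shape != shape]
    if bad:
        raise ValueError(
            f"images {bad} have shapes "
            f"{[images[i].shape for i in bad]} != {shape}"
        )
    mean = np.mean(np.stack([im.astype(np.float64) for im in images]), axis=0)
    smooth = _median_smooth(mean, median_filter_size_px)
    floor = POSITIVE_FLOOR_FRACTION * max(float(smooth.max()), 1e-300)
    smooth = np.clip(smooth, max(floor, np.finfo(np.float64).tiny), None)
    return IlluminationFunction(
        channel=channel, image=smooth, plate=plate, n_images_averaged=len(images)
    )


def apply_correction(image: np.ndarray, illum: IlluminationFunction) -> np.ndarray:
    """Divide a raw image by its plate/channel illumination function."""
    if image.shape != illum.image.shape:
        raise ValueError(
            f"image shape {image.shape} != illumination shape {illum.image.shape}"
        )
    return image.astype(np.float64) / illum.image
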
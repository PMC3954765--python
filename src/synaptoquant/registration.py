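"""Mutual-information translational registration of puncta channels.

The Psd95 and Gphn channels are aligned to the Syn1 channel by exhaustive
search over integer (row, col) shifts, maximizing the mutual information
(MI) of the joint intensity histogram computed on the overlapping region.
Integer-pixel precision is sufficient here: downstream synapse pairing is
object-overlap based and tolerates sub-pixel residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ShiftEstimate", "mutual_information", "estimate_shift", "apply_shift"]


@dataclass
class ShiftEstimate:
    """The correction shift for one moving channel of one site.

    ``shift`` is the (row, col) translation that, applied to the moving
    image with :func:`apply_shift`, best aligns it to the reference. A
    channel misaligned by (dr, dc) therefore gets the estimate (-dr, -dc).
    """

    channel: str
    shift: tuple[int, int]
    mi_bits: float
    radius_px: int
    at_boundary: bool = False


def _bin_indices(image: np.ndarray, n_bins: int) -> np.ndarray | None:
    """Equal-width bin index per pixel over the image's min–max range.

    Returns None for a constant image (degenerate marginal).
    """
    img = image.astype(np.float64)
    lo, hi = float(img.min()), float(img.max())
    if hi - lo <= 0:
        return None
    idx = ((img - lo) * (n_bins / (hi - lo))).astype(np.int32)
    np.clip(idx, 0, n_bins - 1, out=idx)
    return idx


def _mi_from_joint(joint: np.ndarray) -> float:
    """MI in bits from a 2-D joint count table; empty cells contribute 0."""
    n = joint.sum()
    if n == 0:
        return 0.0
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pxy[nz] * np.log2(pxy[nz] / (px @ py)[nz])
    return float(max(terms.sum(), 0.0))


def mutual_information(a: np.ndarray, b: np.ndarray, n_bins: int = 64) -> float:
    """Mutual information of two images' intensities, in bits.

    Histogram estimator with ``n_bins`` equal-width bins per marginal
    spanning each image's observed min–max. A constant image on either side
    yields 0 by convention (with a warning): a degenerate marginal carries
    no alignment information.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    ia, ib = _bin_indices(a, n_bins), _bin_indices(b, n_bins)
    if ia is None or ib is None:
        warnings.warn("constant image: mutual information defined as 0")
        return 0.0
    joint = np.bincount(
        ia.ravel() * n_bins + ib.ravel(), minlength=n_bins * n_bins
    ).reshape(n_bins, n_bins)
    return _mi_from_joint(joint)


def estimate_shift(
    moving: np.ndarray,
    reference: np.ndarray,
    radius_px: int = 10,
    n_bins: int = 64,
    channel: str = "",
) -> ShiftEstimate:
    """Exhaustive integer-shift MI maximization within ±radius_px.

    MI is evaluated on the overlapping region only; ties are broken by the
    smallest Euclidean shift magnitude, then row-major order. For the
    search, pixels are binned once over each full image's min–max range
    (re-binning per overlap window would make the objective depend on the
    crop, not just the alignment). An optimum on the search boundary is
    flagged: the true misalignment may exceed the radius.
    """
    if moving.shape != reference.shape:
        raise ValueError(f"shape mismatch: {moving.shape} vs {reference.shape}")
    if radius_px < 0:
        raise ValueError("radius_px must be >= 0")
    h, w = reference.shape
    if radius_px > min(h, w) // 2:
        raise ValueError(
            f"search radius {radius_px} exceeds half the image size {(h, w)}"
        )
    im = _bin_indices(moving, n_bins)
    ir = _bin_indices(reference, n_bins)
    if im is None or ir is None:
        warnings.warn("constant image: shift defaults to (0, 0) with MI 0")
        return ShiftEstimate(channel, (0, 0), 0.0, radius_px, at_boundary=False)

    ir_scaled = ir * n_bins  # precomputed joint-histogram index contribution
    best: tuple[float, float, int, int] | None = None  # (-mi, mag2, dr, dc)
    best_mi = -1.0
    for dr in range(-radius_px, radius_px + 1):
        for dc in range(-radius_px, radius_px + 1):
            # moving shifted by (dr, dc): shifted[r, c] = moving[r-dr, c-dc]
            r0, r1 = max(0, dr), min(h, h + dr)
            c0, c1 = max(0, dc), min(w, w + dc)
            idx = ir_scaled[r0:r1, c0:c1] + im[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
            joint = np.bincount(
                idx.ravel(), minlength=n_bins * n_bins
            ).reshape(n_bins, n_bins)
            mi = _mi_from_joint(joint)
            key = (-mi, float(dr * dr + dc * dc), dr, dc)
            if best is None or key < best:
                best = key
                best_mi = mi
    assert best is not None
    dr, dc = best[2], best[3]
    return ShiftEstimate(
        channel=channel,
        shift=(dr, dc),
        mi_bits=best_mi,
        radius_px=radius_px,
        at_boundary=(abs(dr) == radius_px or abs(dc) == radius_px) and radius_px > 0,
    )


def apply_shift(
    image: np.ndarray,
    shift: ShiftEstimate | tuple[int, int],
    fill: float = 0.0,
) -> np.ndarray:
    """Integer translation, filling exposed borders with ``fill`` (default 0).

    Pipelines that threshold the shifted image afterwards should pass a
    background-level fill (e.g. the image median): a zero strip next to
    non-zero background is an artificial edge that a top-hat filter would
    otherwise happily enhance.
    """
    dr, dc = shift.shift if isinstance(shift, ShiftEstimate) else shift
    dr, dc = int(dr), int(dc)
    out = np.full_like(image, fill)
    h, w = image.shape
    out[max(0, dr):min(h, h + dr), max(0, dc):min(w, w + dc)] = image[
        max(0, -dr):min(h, h - dr), max(0, -dc):min(w, w - dc)
    ]
    return out
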
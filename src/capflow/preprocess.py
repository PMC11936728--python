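"""Image-stack preprocessing ahead of segmentation and stall analysis.

Mirrors the standard macro chain applied to two-photon angiogram and
plaque stacks: per-slice mean equalization (bleaching correction),
percentile contrast normalization, rolling-ball background subtraction,
3-D median filtering, and maximum-intensity projection over a z-range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.restoration import rolling_ball

__all__ = [
    "ImageStack",
    "equalize_slice_means",
    "normalize_contrast",
    "subtract_background",
    "median3d",
    "mip",
]


@dataclass
class ImageStack:
    """A 3-D intensity stack (z, y, x) with physical voxel size in µm."""

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("stack must be a non-empty 3-D array (z, y, x)")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")

    def with_data(self, data: np.ndarray) -> "ImageStack":
        return ImageStack(data=data, voxel_size_um=self.voxel_size_um)


def _as_stack(stack) -> tuple[np.ndarray, bool]:
    if isinstance(stack, ImageStack):
        return stack.data, True
    return np.asarray(stack), False


def _wrap(result: np.ndarray, stack, was_stack: bool):
    return stack.with_data(result) if was_stack else result


def equalize_slice_means(stack):
    """Scale every slice so its mean matches the first slice's mean.

    Multiplicative per-slice correction for photobleaching along z; the
    first slice is the reference.
    """
    data, was_stack = _as_stack(stack)
    means = data.reshape(data.shape[0], -1).mean(axis=1, dtype=float)
    if np.any(~np.isfinite(means)):
        raise ValueError("slice means must be finite")
    if np.any(means == 0):
        raise ValueError("cannot equalize: a slice has zero mean")
    scale = means[0] / means
    out = data.astype(float) * scale[:, None, None]
    return _wrap(out, stack, was_stack)


def normalize_contrast(stack, saturated_fraction: float = 0.004):
    """Percentile contrast stretch saturating ``saturated_fraction`` pixels.

    The lower/upper percentiles (half the fraction in each tail) are
    mapped to the output range — [0, 1] for float input, the dtype range
    for integers — and values beyond them are clipped.  A constant image
    is returned unchanged with a warning.
    """
    if not 0 <= saturated_fraction < 0.5:
        raise ValueError("saturated_fraction must be in [0, 0.5)")
    data, was_stack = _as_stack(stack)
    lo_q = 100.0 * saturated_fraction / 2.0
    lo, hi = np.percentile(data, [lo_q, 100.0 - lo_q])
    if hi == lo:
        warnings.warn("constant image: contrast normalization is a no-op")
        return _wrap(data.astype(float), stack, was_stack)
    if np.issubdtype(data.dtype, np.integer):
        out_lo = float(np.iinfo(data.dtype).min)
        out_hi = float(np.iinfo(data.dtype).max)
    else:
        out_lo, out_hi = 0.0, 1.0
    out = (data.astype(float) - lo) / (hi - lo)
    out = np.clip(out, 0.0, 1.0) * (out_hi - out_lo) + out_lo
    return _wrap(out, stack, was_stack)


def subtract_background(stack, rolling_ball_radius: float = 50):
    """Rolling-ball background subtraction, slice by slice.

    Estimates a smooth background per slice with a ball structuring
    element of the given pixel radius and subtracts it; output is
    clipped at zero.  A radius exceeding the in-plane extent degrades to
    a warned no-op.
    """
    if rolling_ball_radius < 1:
        raise ValueError("radius must be >= 1 pixel")
    data, was_stack = _as_stack(stack)
    if rolling_ball_radius > max(data.shape[1], data.shape[2]):
        warnings.warn("rolling-ball radius exceeds image extent: no-op")
        return _wrap(data.astype(float), stack, was_stack)
    out = np.empty(data.shape, dtype=float)
    for z in range(data.shape[0]):
        sl = data[z].astype(float)
        bg = rolling_ball(sl, radius=rolling_ball_radius)
        out[z] = np.clip(sl - bg, 0.0, None)
    return _wrap(out, stack, was_stack)


def median3d(stack, radii: tuple[int, int, int] = (2, 2, 2)):
    """3-D median filter over a (2rz+1, 2ry+1, 2rx+1) box, reflect edges."""
    if any(r < 0 for r in radii):
        raise ValueError("radii must be >= 0")
    data, was_stack = _as_stack(stack)
    size = tuple(2 * r + 1 for r in radii)
    out = ndimage.median_filter(data, size=size, mode="reflect")
    return _wrap(out, stack, was_stack)


def mip(stack, z_range: tuple[int, int] | None = None) -> np.ndarray:
    """Maximum-intensity projection over the half-open slice range [z0, z1)."""
    data, _ = _as_stack(stack)
    if z_range is None:
        z_range = (0, data.shape[0])
    z0, z1 = z_range
    if not 0 <= z0 < z1 <= data.shape[0]:
        raise ValueError(f"invalid z range {z_range} for {data.shape[0]} slices")
    return data[z0:z1].max(axis=0)
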
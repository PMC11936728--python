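"""Vascular morphometrics, plaque quantification, and validation metrics.

Operates downstream of an external segmentation: a binary vessel volume
with its centerline skeleton (per-segment labels) yields per-segment
diameter statistics via the Euclidean distance transform, tortuosity,
length density and blood volume fraction; a binary plaque mask yields
per-object volumes, count density and burden; predicted/reference mask
pairs yield Dice/precision/recall; and voxel counts convert to region
volumes.  All distances are physical (anisotropic voxel sizes in µm).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SegMetrics",
    "segment_diameters",
    "diameter_limit_um",
    "filter_capillaries",
    "tortuosity",
    "polyline_length",
    "length_density",
    "blood_volume_fraction",
    "plaque_quantify",
    "segmentation_metrics",
    "region_volume",
    "relative_sd_increase",
]

#: Capillary cut-off used with 1.15 µm pixels: 8 px -> 9.2 µm.
CAPILLARY_DIAMETER_LIMIT_UM = 9.2


@dataclass(frozen=True)
class SegMetrics:
    """Voxel-overlap validation of a predicted segmentation."""

    dsc: float
    precision: float
    recall: float


def segment_diameters(
    binary_volume: np.ndarray,
    skeleton_labels: np.ndarray,
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> pd.DataFrame:
    """Per-segment diameter mean and SD from skeleton-to-boundary distances.

    For every skeleton voxel the Euclidean distance (physical units) to
    the nearest background voxel is taken from the anisotropic distance
    transform of the vessel mask.  Per segment, diameter = 2 x mean
    distance and the SD is computed from the same distances (also on
    the diameter scale, i.e. 2 x SD of the distances).
    """
    binary_volume = np.asarray(binary_volume).astype(bool)
    skeleton_labels = np.asarray(skeleton_labels)
    if skeleton_labels.shape != binary_volume.shape:
        raise ValueError("skeleton and volume shapes differ")
    if np.any(skeleton_labels.astype(bool) & ~binary_volume):
        raise ValueError("skeleton must lie inside the vessel mask")
    edt = ndimage.distance_transform_edt(
        binary_volume, sampling=voxel_size_um
    )
    rows = []
    for seg_id in np.unique(skeleton_labels):
        if seg_id == 0:
            continue
        dists = edt[skeleton_labels == seg_id]
        if dists.size == 0:
            warnings.warn(f"segment {seg_id} has no skeleton voxels; skipped")
            continue
        rows.append(
            {
                "segment_id": int(seg_id),
                "n_skeleton_voxels": int(dists.size),
                "diameter_um": 2.0 * float(dists.mean()),
                "diameter_sd_um": 2.0 * float(dists.std()),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "segment_id", "n_skeleton_voxels", "diameter_um", "diameter_sd_um",
        ],
    )
    if len(out):
        out["diameter_cov"] = out["diameter_sd_um"] / out["diameter_um"]
    else:
        out["diameter_cov"] = pd.Series(dtype=float)
    return out


def diameter_limit_um(n_pixels: float, pixel_size_um: float) -> float:
    """Convert a pixel-unit diameter cut-off to µm (8 px at 1.15 -> 9.2)."""
    if n_pixels <= 0 or pixel_size_um <= 0:
        raise ValueError("pixel count and size must be positive")
    return n_pixels * pixel_size_um


def filter_capillaries(
    table: pd.DataFrame,
    max_diameter_um: float = CAPILLARY_DIAMETER_LIMIT_UM,
) -> pd.DataFrame:
    """Keep segments with mean diameter <= the capillary cut-off.

    Records the before/after counts in ``DataFrame.attrs``.
    """
    kept = table[table["diameter_um"] <= max_diameter_um].copy()
    kept.attrs["n_before"] = len(table)
    kept.attrs["n_after"] = len(kept)
    kept.attrs["max_diameter_um"] = max_diameter_um
    return kept


def polyline_length(points: np.ndarray) -> float:
    """Arc length of a polyline given as an (n, d) coordinate array."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("polyline needs at least 2 points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def tortuosity(points: np.ndarray) -> float:
    """Segment arc length over endpoint chord length (>= 1, straight = 1)."""
    pts = np.asarray(points, dtype=float)
    arc = polyline_length(pts)
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    if chord == 0:
        raise ValueError("closed loop: endpoints coincide, tortuosity undefined")
    return arc / chord


def length_density(
    table: pd.DataFrame, analyzed_volume_uL: float,
    length_column: str = "length_um",
) -> float:
    """Total capillary length (µm) per analyzed volume (µL)."""
    if analyzed_volume_uL <= 0:
        raise ValueError("analyzed volume must be positive")
    if len(table) == 0:
        return 0.0
    return float(table[length_column].sum()) / analyzed_volume_uL


def blood_volume_fraction(
    binary_volume: np.ndarray,
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
    analyzed_volume_um3: float | None = None,
) -> float:
    """Fraction of the analyzed volume occupied by vessel voxels."""
    binary_volume = np.asarray(binary_volume).astype(bool)
    voxel_vol = float(np.prod(voxel_size_um))
    if analyzed_volume_um3 is None:
        analyzed_volume_um3 = binary_volume.size * voxel_vol
    if analyzed_volume_um3 <= 0:
        raise ValueError("analyzed volume must be positive")
    return binary_volume.sum() * voxel_vol / analyzed_volume_um3


#: Default plaque size-class edges, µm³ (configuration, not measured).
DEFAULT_PLAQUE_CLASS_EDGES_UM3 = (500.0, 2000.0, 10000.0)
PLAQUE_CLASS_NAMES = ("very small", "small", "medium", "large")


def plaque_quantify(
    plaque_mask: np.ndarray,
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
    size_class_edges_um3: tuple[float, ...] = DEFAULT_PLAQUE_CLASS_EDGES_UM3,
) -> pd.DataFrame:
    """Count and measure amyloid plaques as 26-connected 3-D objects.

    Per object: voxel count, physical volume (µm³) and a size class cut
    at ``size_class_edges_um3``.  Totals (count, count per mm³, burden
    as % of analyzed voxels) are stored in ``DataFrame.attrs``.
    """
    mask = np.asarray(plaque_mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("plaque mask must be 3-D")
    voxel_vol = float(np.prod(voxel_size_um))
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labels, n = ndimage.label(mask, structure=structure)
    counts = np.bincount(labels.ravel())[1:]
    volumes = counts * voxel_vol
    edges = list(size_class_edges_um3)
    classes = [
        PLAQUE_CLASS_NAMES[int(np.searchsorted(edges, v, side="right"))]
        for v in volumes
    ]
    table = pd.DataFrame(
        {
            "object_id": np.arange(1, n + 1),
            "n_voxels": counts,
            "volume_um3": volumes,
            "size_class": pd.Categorical(
                classes, categories=list(PLAQUE_CLASS_NAMES)
            ),
        }
    )
    analyzed_um3 = mask.size * voxel_vol
    table.attrs["n_objects"] = int(n)
    table.attrs["count_per_mm3"] = n / (analyzed_um3 * 1e-9)
    table.attrs["burden_pct"] = 100.0 * mask.sum() / mask.size
    table.attrs["analyzed_volume_um3"] = analyzed_um3
    return table


def segmentation_metrics(
    predicted: np.ndarray, truth: np.ndarray
) -> SegMetrics:
    """Dice, precision and recall between binary masks.

    Two empty masks agree perfectly by convention (all metrics 1.0).
    """
    pred = np.asarray(predicted).astype(bool)
    ref = np.asarray(truth).astype(bool)
    if pred.shape != ref.shape:
        raise ValueError("masks must share a shape")
    tp = int(np.sum(pred & ref))
    fp = int(np.sum(pred & ~ref))
    fn = int(np.sum(~pred & ref))
    if tp + fp + fn == 0:
        return SegMetrics(dsc=1.0, precision=1.0, recall=1.0)
    dsc = 2 * tp / (2 * tp + fp + fn)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return SegMetrics(dsc=dsc, precision=precision, recall=recall)


def region_volume(
    n_voxels: int, voxel_dims_um: tuple[float, float, float]
) -> float:
    """Region volume in mm³ from a voxel count and nominal voxel size."""
    if n_voxels < 0:
        raise ValueError("voxel count must be >= 0")
    if any(d <= 0 for d in voxel_dims_um):
        raise ValueError("voxel dimensions must be positive")
    return n_voxels * float(np.prod(voxel_dims_um)) * 1e-9


def relative_sd_increase(sd_ref: float, sd_test: float) -> float:
    """Percent increase of a test SD over a reference SD."""
    if sd_ref <= 0:
        raise ValueError("reference SD must be positive")
    return (sd_test - sd_ref) / sd_ref * 100.0
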
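"""Single-capillary line-scan analysis: RBC velocity, cell flux, diameter.

A line scan repeatedly samples a short path at millisecond rate and
stacks the samples into a space-time image (rows = successive lines in
time, columns = position).  With plasma fluorescently labelled, red
blood cells appear as dark streaks:

* on an **axial** path (along the lumen) a moving cell traces a slanted
  streak whose slope encodes its velocity; the streak angle is found per
  time window as the Radon-projection angle of maximal variance;
* on a **transverse** path (across the lumen) a passing cell darkens the
  lumen for a short epoch; flux is the rate of dark epochs, and the
  lumen's spatial profile in cell-free lines gives the diameter as the
  full width at half maximum (FWHM).

All quantities are computed in sliding windows (150 ms long, stepped by
50 ms for velocity) and summarized as means and coefficients of
variation; linear density is mean flux over mean velocity (cells/mm).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import radon

__all__ = [
    "LinescanRecord",
    "FlowEstimates",
    "radon_velocity",
    "cell_flux",
    "cell_presence",
    "fwhm_diameter",
    "summarize_flow",
    "profile_fwhm",
]

WINDOW_MS = 150.0
STEP_MS = 50.0


@dataclass
class LinescanRecord:
    """Space-time image plus the scan geometry needed to calibrate it."""

    image: np.ndarray
    pixel_size_um: float
    line_period_ms: float
    path: str  # "axial" | "transverse"

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("line-scan image must be 2-D (time x space)")
        if self.pixel_size_um <= 0 or self.line_period_ms <= 0:
            raise ValueError("pixel size and line period must be positive")
        if self.path not in ("axial", "transverse"):
            raise ValueError("path must be 'axial' or 'transverse'")

    @property
    def n_lines(self) -> int:
        return self.image.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_lines * self.line_period_ms / 1000.0


@dataclass
class FlowEstimates:
    """Windowed flow estimates for one capillary with their summaries."""

    velocity_mm_s: np.ndarray
    flux_cells_s: np.ndarray
    diameter_um: np.ndarray
    mean_velocity_mm_s: float
    mean_flux_cells_s: float
    mean_diameter_um: float
    velocity_cov: float
    flux_cov: float
    diameter_cov: float
    linear_density_cells_mm: float


def _window_slices(n_lines: int, window_lines: int, step_lines: int):
    starts = range(0, n_lines - window_lines + 1, step_lines)
    return [slice(s, s + window_lines) for s in starts]


def _streak_angle(window: np.ndarray, coarse_step_deg: float = 1.0):
    """Angle (degrees from vertical, in (-90, 90)) of maximal Radon variance.

    Coarse scan, fine 0.1 deg re-scan around the peak, then parabolic
    interpolation of the variance maximum.  Returns (angle, confidence)
    where confidence is the ratio of peak to mean projection variance —
    near 1 for windows without streak contrast.
    """
    w = window - window.mean()
    if w.std() < 1e-12:
        return 0.0, 0.0

    def variances(thetas):
        with warnings.catch_warnings():
            # zero-mean windows trip skimage's reconstruction-circle
            # warning; projections are still exact for our use.
            warnings.simplefilter("ignore", UserWarning)
            sino = radon(w, theta=thetas)
        return sino.var(axis=0)

    coarse = np.arange(-89.0, 89.0 + 1e-9, coarse_step_deg)
    v = variances(coarse)
    i = int(np.argmax(v))
    confidence = float(v[i] / v.mean()) if v.mean() > 0 else 0.0
    # integer-scaled offsets keep the coarse angle itself exactly on
    # the fine grid (0.0 stays 0.0 for vertical streaks)
    fine = coarse[i] + np.arange(-15, 16) * 0.1
    fine = fine[(fine > -90.0) & (fine < 90.0)]
    vf = variances(fine)
    j = int(np.argmax(vf))
    theta = fine[j]
    if 0 < j < len(fine) - 1:  # parabolic vertex through the 3 top samples
        y0, y1, y2 = vf[j - 1], vf[j], vf[j + 1]
        denom = y0 - 2 * y1 + y2
        # refine only when the neighbor asymmetry exceeds float noise,
        # so symmetric peaks (e.g. vertical streaks) stay on-grid
        if denom < 0 and abs(y0 - y2) > 1e-9 * abs(y1):
            theta += 0.5 * (y0 - y2) / denom * 0.1
    # the parabolic vertex carries no information below ~1e-3 of the
    # fine grid step; quantize so symmetric peaks resolve exactly
    theta = round(theta, 4)
    return float(theta), confidence


def radon_velocity(
    record: LinescanRecord,
    window_ms: float = WINDOW_MS,
    step_ms: float = STEP_MS,
    min_confidence: float = 1.5,
):
    """RBC velocity per window from the streak angle of an axial scan.

    The space-time image is Radon-transformed per window over a fine
    angle grid; the angle maximizing projection variance is the streak
    direction.  A streak advancing s pixels per line corresponds to
    velocity s * pixel_size / line_period (µm/ms == mm/s).  Windows
    without streak contrast (peak/mean variance below
    ``min_confidence``) are returned as NaN.

    Returns
    -------
    velocities : ndarray, mm/s, NaN where invalid
    times_s : ndarray, window start times
    """
    if record.path != "axial":
        raise ValueError("velocity requires an axial line-scan record")
    window_lines = int(round(window_ms / record.line_period_ms))
    step_lines = max(1, int(round(step_ms / record.line_period_ms)))
    if window_lines < 10:
        raise ValueError("window must span at least 10 lines")
    if window_lines > record.n_lines:
        raise ValueError("window longer than the record")
    slices = _window_slices(record.n_lines, window_lines, step_lines)
    velocities = np.full(len(slices), np.nan)
    times = np.array(
        [s.start * record.line_period_ms / 1000.0 for s in slices]
    )
    scale = record.pixel_size_um / record.line_period_ms  # mm/s per px/line
    for k, sl in enumerate(slices):
        theta, conf = _streak_angle(record.image[sl])
        if conf < min_confidence:
            continue
        # rows are time: a streak rotated to vertical at angle theta
        # moves tan(theta) pixels per line.
        velocities[k] = scale * math.tan(math.radians(theta))
    if np.isnan(velocities).all():
        warnings.warn("no window had sufficient streak contrast")
    return velocities, times


def _two_means(x: np.ndarray, max_iter: int = 100):
    """Deterministic 2-means on a 1-D sample, centers seeded at min/max."""
    c0, c1 = float(x.min()), float(x.max())
    if c0 == c1:
        return c0, c1, np.zeros(x.size, dtype=bool)
    for _ in range(max_iter):
        dark = np.abs(x - c0) <= np.abs(x - c1)
        n0, n1 = dark.sum(), (~dark).sum()
        if n0 == 0 or n1 == 0:
            break
        new0, new1 = float(x[dark].mean()), float(x[~dark].mean())
        if new0 == c0 and new1 == c1:
            break
        c0, c1 = new0, new1
    return c0, c1, dark


def cell_presence(
    record: LinescanRecord, min_separation_ratio: float = 4.0
):
    """Per-line boolean mask of RBC presence in a transverse scan.

    The per-line mean lumen intensity is split into two classes by
    deterministic 2-means (centers seeded at the min and max); the dark
    class is "cell present".  If the class separation is below
    ``min_separation_ratio`` times the pooled within-class SD, the
    record is treated as unimodal: no cells, low confidence.

    Returns (mask, confident) where ``confident`` is False for the
    unimodal case.
    """
    if record.path != "transverse":
        raise ValueError("cell detection requires a transverse record")
    line_means = record.image.mean(axis=1)
    c0, c1, dark = _two_means(line_means)
    if c0 == c1:
        return np.zeros(record.n_lines, dtype=bool), False
    within = np.sqrt(
        np.mean(
            np.concatenate(
                [
                    (line_means[dark] - c0) ** 2,
                    (line_means[~dark] - c1) ** 2,
                ]
            )
        )
    )
    if within > 0 and (c1 - c0) / within < min_separation_ratio:
        return np.zeros(record.n_lines, dtype=bool), False
    return dark, True


def cell_flux(
    record: LinescanRecord,
    window_ms: float = WINDOW_MS,
    min_separation_ratio: float = 4.0,
):
    """Cell flux (cells/s) per window and overall from a transverse scan.

    Flux counts absent-to-present transitions of the clustered cell mask
    per unit time.  Windows are non-overlapping ``window_ms`` intervals.

    Returns
    -------
    flux_series : ndarray, cells/s per window
    overall_flux : float, transitions over the whole record / duration
    mask : per-line cell-presence mask
    confident : False when the intensity distribution was unimodal
    """
    mask, confident = cell_presence(record, min_separation_ratio)
    arrivals = np.flatnonzero(np.diff(mask.astype(np.int8)) == 1) + 1
    if mask.size and mask[0]:
        arrivals = np.concatenate(([0], arrivals))
    overall = arrivals.size / record.duration_s
    window_lines = max(1, int(round(window_ms / record.line_period_ms)))
    n_windows = record.n_lines // window_lines
    flux = np.zeros(n_windows)
    window_s = window_lines * record.line_period_ms / 1000.0
    for k in range(n_windows):
        lo, hi = k * window_lines, (k + 1) * window_lines
        flux[k] = ((arrivals >= lo) & (arrivals < hi)).sum() / window_s
    return flux, float(overall), mask, confident


def profile_fwhm(
    profile: np.ndarray,
    pixel_size_um: float = 1.0,
    baseline_fraction: float = 0.1,
) -> float:
    """FWHM of a 1-D intensity profile, µm, by linear interpolation.

    Baseline is the median of the outermost ``baseline_fraction`` of
    columns on each side; the width is measured at baseline + half of
    (max - baseline), interpolating between samples at each crossing.
    """
    p = np.asarray(profile, dtype=float)
    if p.size < 3:
        raise ValueError("profile too short")
    k = max(1, int(round(baseline_fraction * p.size)))
    baseline = float(np.median(np.concatenate([p[:k], p[-k:]])))
    peak_idx = int(np.argmax(p))
    peak = p[peak_idx]
    if peak <= baseline:
        raise ValueError("flat profile: no peak above baseline")
    half = baseline + 0.5 * (peak - baseline)

    def cross(idx_range, rising):
        for i in idx_range:
            a, b = p[i], p[i + 1]
            if (a < half <= b) if rising else (a >= half > b):
                return i + (half - a) / (b - a)
        return None

    left = cross(range(peak_idx - 1, -1, -1), rising=True)
    right = cross(range(peak_idx, p.size - 1), rising=False)
    if left is None:
        left = 0.0
    if right is None:
        right = float(p.size - 1)
    return (right - left) * pixel_size_um


def fwhm_diameter(
    record: LinescanRecord,
    cell_frames: np.ndarray,
    window_ms: float = WINDOW_MS,
):
    """Capillary diameter per window from cell-free transverse profiles.

    Lines flagged in ``cell_frames`` (RBC present) are discarded; the
    remaining lines in each non-overlapping 150 ms window are averaged
    into a spatial profile whose FWHM, in µm, is the diameter estimate.
    Windows fully occupied by cells yield NaN.
    """
    if record.path != "transverse":
        raise ValueError("diameter requires a transverse record")
    cell_frames = np.asarray(cell_frames, dtype=bool)
    if cell_frames.shape != (record.n_lines,):
        raise ValueError("cell mask must have one entry per line")
    window_lines = max(1, int(round(window_ms / record.line_period_ms)))
    n_windows = record.n_lines // window_lines
    diameters = np.full(n_windows, np.nan)
    for k in range(n_windows):
        sl = slice(k * window_lines, (k + 1) * window_lines)
        free = ~cell_frames[sl]
        if not free.any():
            continue
        profile = record.image[sl][free].mean(axis=0)
        try:
            diameters[k] = profile_fwhm(profile, record.pixel_size_um)
        except ValueError:
            continue
    return diameters


def summarize_flow(
    velocity_mm_s,
    flux_cells_s,
    diameter_um,
) -> FlowEstimates:
    """Summaries over valid (non-NaN) windows: means, COVs, linear density.

    COV is SD/mean per quantity; linear density is mean flux divided by
    mean velocity, in cells per mm of capillary.  Zero mean velocity
    leaves the linear density NaN.
    """

    def summarize(x):
        x = np.asarray(x, dtype=float)
        valid = x[~np.isnan(x)]
        if valid.size == 0:
            raise ValueError("no valid windows to summarize")
        mean = float(valid.mean())
        cov = float(valid.std(ddof=1) / mean) if valid.size > 1 and mean else 0.0
        return x, mean, cov

    v, v_mean, v_cov = summarize(velocity_mm_s)
    f, f_mean, f_cov = summarize(flux_cells_s)
    d, d_mean, d_cov = summarize(diameter_um)
    if v_mean == 0:
        warnings.warn("zero mean velocity: linear density undefined")
        density = float("nan")
    else:
        density = f_mean / abs(v_mean)
    return FlowEstimates(
        velocity_mm_s=v,
        flux_cells_s=f,
        diameter_um=d,
        mean_velocity_mm_s=v_mean,
        mean_flux_cells_s=f_mean,
        mean_diameter_um=d_mean,
        velocity_cov=v_cov,
        flux_cov=f_cov,
        diameter_cov=d_cov,
        linear_density_cells_mm=density,
    )
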
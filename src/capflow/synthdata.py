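"""Synthetic data generators with known ground truth for every stage.

Each generator emulates the statistical structure the corresponding
analysis stage assumes — not the optics of the instruments:

* angiogram volume time series in which stalled capillary segments drop
  to background intensity for whole frames (OCT-A signal needs moving
  scatterers);
* space-time line-scan images in which red cells are dark streaks in
  bright, plasma-labelled lumen (axial: slanted streaks; transverse:
  dark epochs);
* bolus dilution curve pairs where the venous curve is the arterial
  curve convolved with an f-scaled, delayed gamma transport density,
  plus a recirculation plateau so post-bolus normalization is defined;
* single-exponential photon-decay histograms with Poisson noise scaled
  by the number of averaged sweeps;
* binary vessel volumes rasterized from centerline specs with known
  radii, lengths and tortuosity, plus spherical plaque masks.

Every generator is deterministic given its parameters and seed; one
top-level seed can be split into independent per-generator streams with
:func:`spawn_rngs`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist
from skimage.draw import line as draw_line

from .dilution import DilutionCurvePair, convolve_transport
from .linescan import LinescanRecord
from .oximetry import PhosphorescenceDecay

__all__ = [
    "StallGroundTruth",
    "FlowGroundTruth",
    "TransportGroundTruth",
    "DecayGroundTruth",
    "SegmentSpec",
    "PlaqueSpec",
    "VolumeGroundTruth",
    "BolusShape",
    "spawn_rngs",
    "rasterize_stallogram",
    "random_stall_truth",
    "make_stall_series",
    "make_linescan",
    "make_bolus_pair",
    "make_decay",
    "make_vessel_volume",
]


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Split one top-level seed into ``n`` independent generator streams."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# stall series


@dataclass
class StallGroundTruth:
    """Stall events on a grid of segments x acquisition volumes.

    ``events`` are (segment index, start volume, duration in volumes);
    overlapping events on one segment merge when rasterized.  Defaults
    follow the standard recording: 60 volumes of 8.5 s each.
    """

    n_segments: int
    n_volumes: int = 60
    events: list[tuple[int, int, int]] = field(default_factory=list)
    frame_duration_s: float = 8.5

    def __post_init__(self) -> None:
        for seg, start, dur in self.events:
            if not 0 <= seg < self.n_segments:
                raise ValueError(f"segment index {seg} out of range")
            if dur < 1:
                raise ValueError("event durations must be >= 1 volume")
            if start < 0 or start + dur > self.n_volumes:
                raise ValueError("event extends outside the recording")


def rasterize_stallogram(truth: StallGroundTruth) -> np.ndarray:
    """Full binary (n_segments x n_volumes) raster of the event list.

    Overlapping events on the same segment merge into one run.
    """
    m = np.zeros((truth.n_segments, truth.n_volumes), dtype=np.int8)
    for seg, start, dur in truth.events:
        m[seg, start : start + dur] = 1
    return m


def random_stall_truth(
    n_segments: int,
    n_volumes: int = 60,
    stall_probability: float = 0.1,
    mean_duration_frames: float = 2.0,
    rng: np.random.Generator | int = 0,
    frame_duration_s: float = 8.5,
) -> StallGroundTruth:
    """Random event list: each segment stalls with ``stall_probability``.

    Stalling segments get 1-3 events with geometric durations (mean
    ``mean_duration_frames``, clipped to the recording).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    events = []
    p_geom = min(1.0, 1.0 / mean_duration_frames)
    for seg in range(n_segments):
        if rng.random() >= stall_probability:
            continue
        for _ in range(rng.integers(1, 4)):
            dur = int(min(rng.geometric(p_geom), n_volumes))
            start = int(rng.integers(0, n_volumes - dur + 1))
            events.append((seg, start, dur))
    return StallGroundTruth(
        n_segments=n_segments,
        n_volumes=n_volumes,
        events=events,
        frame_duration_s=frame_duration_s,
    )


def make_stall_series(
    truth: StallGroundTruth,
    snr: float = 5.0,
    seed: int = 0,
    n_z: int = 4,
    cell_px: int = 12,
):
    """Render an angiogram volume time series with stalling segments.

    Segments are short line segments placed on a non-overlapping grid
    (one per ``cell_px`` x ``cell_px`` tile, replicated over ``n_z``
    slices).  Flowing segments have unit intensity; a stalled frame
    multiplies the segment's intensity by zero before additive Gaussian
    noise of SD 1/snr is applied (frame-resolution stalls only — the
    acquisition integrates a whole volume).

    Returns
    -------
    series : ndarray, (n_volumes, n_z, y, x)
    labels : ndarray, (n_z, y, x) int segment labels (0 = background)
    stallogram : ndarray, the rasterized ground-truth event matrix
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    grid = math.ceil(math.sqrt(truth.n_segments))
    side = grid * cell_px
    plane = np.zeros((side, side), dtype=np.int32)
    seg_len = cell_px - 4
    for idx in range(truth.n_segments):
        gy, gx = divmod(idx, grid)
        y0 = gy * cell_px + 2
        x0 = gx * cell_px + 2
        angle = rng.uniform(0, np.pi)
        dy = int(round(seg_len * math.sin(angle) / 2))
        dx = int(round(seg_len * math.cos(angle) / 2))
        cy, cx = y0 + seg_len // 2, x0 + seg_len // 2
        rr, cc = draw_line(cy - dy, cx - dx, cy + dy, cx + dx)
        plane[rr, cc] = idx + 1
    labels = np.broadcast_to(plane, (n_z, side, side)).copy()

    stallogram = rasterize_stallogram(truth)
    series = np.empty((truth.n_volumes, n_z, side, side), dtype=np.float32)
    seg_mask = labels > 0
    for v in range(truth.n_volumes):
        frame = np.zeros((n_z, side, side), dtype=np.float32)
        flowing = np.flatnonzero(stallogram[:, v] == 0) + 1
        frame[np.isin(labels, flowing) & seg_mask] = 1.0
        frame += rng.normal(0.0, 1.0 / snr, size=frame.shape).astype(np.float32)
        series[v] = frame
    return series, labels, stallogram


# ---------------------------------------------------------------------------
# line scans


@dataclass
class FlowGroundTruth:
    """Single-capillary flow state emulated by the line-scan generator."""

    velocity_mm_s: float = 1.0
    flux_cells_s: float = 80.0
    diameter_um: float = 5.0
    line_period_ms: float = 1.0
    pixel_size_um: float = 0.23
    duration_s: float = 5.0
    cell_length_um: float = 6.0  # typical RBC long axis

    def __post_init__(self) -> None:
        for name in (
            "velocity_mm_s", "flux_cells_s", "diameter_um",
            "line_period_ms", "pixel_size_um", "duration_s",
            "cell_length_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def occupancy(self) -> float:
        """Fraction of the capillary length occupied by cells."""
        return self.flux_cells_s * self.cell_length_um / (
            self.velocity_mm_s * 1000.0
        )


def _arrival_times(truth: FlowGroundTruth, rng, t_lo, t_hi, exact_count=False):
    """Jittered regular arrivals that keep cells non-overlapping."""
    occupancy = truth.occupancy
    if occupancy >= 0.95:
        raise ValueError(
            f"flux {truth.flux_cells_s}/s is inconsistent with velocity "
            f"{truth.velocity_mm_s} mm/s and {truth.cell_length_um} µm "
            f"cells (occupancy {occupancy:.2f})"
        )
    headway = 1.0 / truth.flux_cells_s
    jitter = 0.5 * max(0.0, (1.0 - occupancy)) * 0.6
    if exact_count:
        n = int(round(truth.flux_cells_s * (t_hi - t_lo)))
        base = t_lo + (np.arange(n) + 0.5) * (t_hi - t_lo) / max(n, 1)
    else:
        base = np.arange(t_lo + 0.5 * headway, t_hi, headway)
    return base + rng.uniform(-jitter, jitter, size=base.size) * headway


def make_linescan(
    truth: FlowGroundTruth,
    noise_sd: float = 0.1,
    seed: int = 0,
    path: str = "axial",
    scan_length_um: float = 30.0,
    cell_contrast: float = 0.2,
    background: float = 0.05,
    invert_polarity: bool = False,
) -> LinescanRecord:
    """Render a space-time line-scan image for one capillary.

    Axial path: plasma-bright lumen along the whole scan, cells as dark
    streaks advancing ``velocity/(pixel_size/line_period)`` pixels per
    line.  Transverse path: bright lumen of width ``diameter`` flanked
    by dark tissue; a passing cell darkens the lumen for
    cell_length/velocity seconds; epochs are non-overlapping and their
    count over the record equals round(flux x duration).  Additive
    Gaussian noise of SD ``noise_sd`` (in units of the plasma level).
    ``invert_polarity`` renders bright cells in dark plasma instead.
    """
    rng = np.random.default_rng(seed)
    n_lines = int(round(truth.duration_s * 1000.0 / truth.line_period_ms))
    v_um_ms = truth.velocity_mm_s  # mm/s == µm/ms
    cell_hw_px = truth.cell_length_um / 2.0 / truth.pixel_size_um

    if path == "axial":
        n_px = int(round(scan_length_um / truth.pixel_size_um))
        img = np.ones((n_lines, n_px), dtype=float)
        transit_s = (scan_length_um + truth.cell_length_um) / (v_um_ms * 1000)
        t0s = _arrival_times(
            truth, rng, -transit_s, truth.duration_s + transit_s
        )
        lines = np.arange(n_lines)
        t_line = lines * truth.line_period_ms / 1000.0
        for t0 in t0s:
            # cell center position along the scan, µm, per line
            x_um = (t_line - t0) * v_um_ms * 1000.0
            inside = (x_um > -truth.cell_length_um) & (
                x_um < scan_length_um + truth.cell_length_um
            )
            for r in lines[inside]:
                c = x_um[r] / truth.pixel_size_um
                lo = max(0, int(math.ceil(c - cell_hw_px)))
                hi = min(n_px, int(math.floor(c + cell_hw_px)) + 1)
                if lo < hi:
                    img[r, lo:hi] = cell_contrast
    elif path == "transverse":
        margin_um = truth.diameter_um
        n_px = int(round((truth.diameter_um + 2 * margin_um) / truth.pixel_size_um))
        x_um = (np.arange(n_px) + 0.5) * truth.pixel_size_um
        center = (truth.diameter_um + 2 * margin_um) / 2.0
        lumen = np.abs(x_um - center) <= truth.diameter_um / 2.0
        img = np.full((n_lines, n_px), background, dtype=float)
        img[:, lumen] = 1.0
        epoch_s = truth.cell_length_um / (v_um_ms * 1000.0)
        t0s = _arrival_times(truth, rng, 0.0, truth.duration_s, exact_count=True)
        t_line = np.arange(n_lines) * truth.line_period_ms / 1000.0
        for t0 in t0s:
            occupied = (t_line >= t0) & (t_line < t0 + epoch_s)
            img[np.ix_(occupied, lumen)] = cell_contrast
    else:
        raise ValueError("path must be 'axial' or 'transverse'")

    if invert_polarity:
        img = img.max() + img.min() - img
    img += rng.normal(0.0, noise_sd, size=img.shape)
    return LinescanRecord(
        image=img,
        pixel_size_um=truth.pixel_size_um,
        line_period_ms=truth.line_period_ms,
        path=path,
    )


# ---------------------------------------------------------------------------
# bolus dilution curves


@dataclass
class TransportGroundTruth:
    """Gamma transport function parameters behind a synthetic bolus pair."""

    alpha: float = 4.0
    beta: float = 0.5
    f: float = 1.0
    delay_s: float = 0.0
    noise_sd: float = 0.0
    sampling_hz: float = 6.98

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0 or self.f < 0:
            raise ValueError("alpha, beta must be > 0 and f >= 0")
        if self.sampling_hz < 2:
            raise ValueError("sampling rate must be >= 2 Hz")

    @property
    def mtt_s(self) -> float:
        return self.alpha * self.beta

    @property
    def cth_s(self) -> float:
        return math.sqrt(self.alpha) * self.beta


@dataclass
class BolusShape:
    """Shape of the synthetic arterial input: a gamma-variate bolus that
    arrives ``arrival_s`` after scan start plus a recirculation plateau
    (scaled gamma CDF) that post-bolus normalization can latch onto."""

    arrival_s: float = 7.0
    shape: float = 3.0
    scale_s: float = 0.35
    amplitude: float = 8.0
    plateau: float = 1.0
    duration_s: float = 30.0


def make_bolus_pair(
    truth: TransportGroundTruth,
    aif: BolusShape | None = None,
    seed: int = 0,
    snr: float | None = None,
) -> DilutionCurvePair:
    """Synthesize an AIF/VOF pair linked by a gamma transport function.

    The VOF is the AIF convolved with the f-scaled gamma density of the
    ground truth, shifted by its delay.  When ``snr`` is given it
    overrides ``truth.noise_sd`` with (VOF peak)/snr.  The attached fit
    window is the 10 s curve-matching region starting at bolus arrival.
    """
    aif = aif or BolusShape()
    if truth.mtt_s + truth.delay_s > aif.duration_s - aif.arrival_s:
        raise ValueError("transit time longer than the simulated record")
    rng = np.random.default_rng(seed)
    dt = 1.0 / truth.sampling_hz
    t = np.arange(0.0, aif.duration_s, dt)
    rel = t - aif.arrival_s
    aif_curve = aif.amplitude * gamma_dist.pdf(
        rel, a=aif.shape, scale=aif.scale_s
    ) + aif.plateau * gamma_dist.cdf(rel, a=aif.shape, scale=aif.scale_s)
    vof_curve = convolve_transport(
        aif_curve, dt, truth.alpha, truth.beta, truth.f, truth.delay_s
    )
    noise_sd = truth.noise_sd
    if snr is not None:
        noise_sd = float(vof_curve.max()) / snr
    if noise_sd > 0:
        aif_curve = aif_curve + rng.normal(0, noise_sd, t.size)
        vof_curve = vof_curve + rng.normal(0, noise_sd, t.size)
    window = (aif.arrival_s, min(aif.arrival_s + 10.0, t[-1]))
    return DilutionCurvePair(
        time_s=t, aif=aif_curve, vof=vof_curve, fit_window_s=window
    )


# ---------------------------------------------------------------------------
# phosphorescence decays


@dataclass
class DecayGroundTruth:
    """Single-exponential decay behind a synthetic photon histogram.

    ``amplitude`` and ``background`` are expected counts per bin per
    sweep; averaging ``n_sweeps`` sweeps scales the Poisson noise down
    by sqrt(n_sweeps), emulating the ~15,000-decay averaging used at
    acquisition.
    """

    tau_us: float = 30.0
    amplitude: float = 0.5
    background: float = 0.02
    n_sweeps: int = 15000

    def __post_init__(self) -> None:
        if self.tau_us <= 0:
            raise ValueError("tau must be positive")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")


def make_decay(
    truth: DecayGroundTruth,
    seed: int = 0,
    span_us: float = 290.0,
    bin_us: float = 1.0,
    poisson: bool = True,
) -> PhosphorescenceDecay:
    """Averaged photon-decay histogram over the collection window.

    Expected counts follow amplitude·exp(-t/tau) + background; the
    returned counts are Poisson draws summed over ``n_sweeps`` sweeps
    divided by the sweep count.  A collection window shorter than tau
    triggers a warning (the lifetime is then poorly constrained).
    """
    if span_us < truth.tau_us:
        warnings.warn("collection window shorter than tau")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, span_us, bin_us) + bin_us / 2.0
    expected = truth.amplitude * np.exp(-t / truth.tau_us) + truth.background
    if poisson:
        counts = rng.poisson(expected * truth.n_sweeps) / truth.n_sweeps
    else:
        counts = expected.copy()
    return PhosphorescenceDecay(t_us=t, counts=counts, n_sweeps=truth.n_sweeps)


# ---------------------------------------------------------------------------
# vessel volumes and plaques


@dataclass
class SegmentSpec:
    """One vessel segment: centerline control points and its radius.

    ``points`` are (n, 3) voxel coordinates in (z, y, x) order; the
    radius is in µm (scalar, constant along the segment).
    """

    points: np.ndarray
    radius_um: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (n, 3) in (z, y, x) order")
        if self.radius_um <= 0:
            raise ValueError("radius must be positive")


@dataclass
class PlaqueSpec:
    """A spherical plaque: center (z, y, x) voxels and radius in µm."""

    center: tuple[float, float, float]
    radius_um: float


@dataclass
class VolumeGroundTruth:
    """Specs rasterized by :func:`make_vessel_volume`."""

    shape: tuple[int, int, int] = (40, 64, 64)
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    segments: list[SegmentSpec] = field(default_factory=list)
    plaques: list[PlaqueSpec] = field(default_factory=list)


def _densify(points: np.ndarray, step: float = 0.25) -> np.ndarray:
    """Linear interpolation of a polyline at ~``step``-voxel spacing."""
    out = [points[0]]
    for a, b in zip(points[:-1], points[1:]):
        n = max(1, int(math.ceil(np.linalg.norm(b - a) / step)))
        for k in range(1, n + 1):
            out.append(a + (b - a) * k / n)
    return np.asarray(out)


def make_vessel_volume(truth: VolumeGroundTruth, seed: int = 0):
    """Rasterize tubular segments and spherical plaques with known truth.

    Returns
    -------
    binary : bool ndarray, vessel mask
    skeleton : int ndarray, centerline voxels labelled per segment
    plaque_mask : bool ndarray
    table : DataFrame with analytic diameter, length, tortuosity and
        volume per segment (µm-based, from the specs, not the raster)
    """
    shape = truth.shape
    vz, vy, vx = truth.voxel_size_um
    binary = np.zeros(shape, dtype=bool)
    skeleton = np.zeros(shape, dtype=np.int32)
    claimed = np.zeros(shape, dtype=np.int32)
    rows = []
    zz = np.arange(shape[0]) * vz
    yy = np.arange(shape[1]) * vy
    xx = np.arange(shape[2]) * vx
    for idx, spec in enumerate(truth.segments, start=1):
        pts = _densify(spec.points)
        if (pts < 0).any() or (pts >= np.asarray(shape)).any():
            raise ValueError(f"segment {idx} leaves the volume")
        seg_mask = np.zeros(shape, dtype=bool)
        r = spec.radius_um
        for p in pts:
            p_um = p * np.array([vz, vy, vx])
            z0, z1 = np.searchsorted(zz, [p_um[0] - r, p_um[0] + r + vz])
            y0, y1 = np.searchsorted(yy, [p_um[1] - r, p_um[1] + r + vy])
            x0, x1 = np.searchsorted(xx, [p_um[2] - r, p_um[2] + r + vx])
            sub = (
                (zz[z0:z1, None, None] - p_um[0]) ** 2
                + (yy[None, y0:y1, None] - p_um[1]) ** 2
                + (xx[None, None, x0:x1] - p_um[2]) ** 2
            ) <= r * r
            seg_mask[z0:z1, y0:y1, x0:x1] |= sub
        if (claimed[seg_mask] > 0).any():
            warnings.warn(f"segment {idx} intersects another segment")
        claimed[seg_mask] = idx
        binary |= seg_mask
        ski = np.clip(np.round(pts).astype(int), 0, np.asarray(shape) - 1)
        skeleton[ski[:, 0], ski[:, 1], ski[:, 2]] = idx
        pts_um = spec.points * np.array([vz, vy, vx])
        arc = float(np.linalg.norm(np.diff(pts_um, axis=0), axis=1).sum())
        chord = float(np.linalg.norm(pts_um[-1] - pts_um[0]))
        rows.append(
            {
                "segment_id": idx,
                "diameter_um": 2.0 * r,
                "length_um": arc,
                "tortuosity": arc / chord if chord > 0 else float("nan"),
                "volume_um3": math.pi * r * r * arc,
            }
        )
    plaque_mask = np.zeros(shape, dtype=bool)
    for spec in truth.plaques:
        c_um = np.asarray(spec.center) * np.array([vz, vy, vx])
        r = spec.radius_um
        sub = (
            (zz[:, None, None] - c_um[0]) ** 2
            + (yy[None, :, None] - c_um[1]) ** 2
            + (xx[None, None, :] - c_um[2]) ** 2
        ) <= r * r
        plaque_mask |= sub
    table = pd.DataFrame(
        rows,
        columns=[
            "segment_id", "diameter_um", "length_um", "tortuosity",
            "volume_um3",
        ],
    )
    return binary, skeleton, plaque_mask, table
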
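"""Capillary stall detection and statistics from OCT-A time series.

OCT angiography signal requires moving scatterers, so a capillary whose
red cells halt disappears from the angiogram for as long as the stall
lasts.  Given a time series of angiogram volumes and a mask labelling
capillary segments, this module extracts per-segment intensity time
courses, flags stalled frames with a reproducible relative-threshold
rule, assembles the stall-o-gram (binary segment x volume raster), and
computes the summary statistics used to compare groups: total stalls,
incidence rate, point prevalence, and cumulative stall time.

Stalls shorter than one acquisition volume (8.5 s by default) are
invisible by construction; events separated by a single flowing frame
are counted as distinct events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StallOGram",
    "StallMetrics",
    "segment_timecourses",
    "detect_stalls",
    "stall_metrics",
    "stall_duration_distribution",
]

#: Acquisition time of one angiogram volume, seconds.
DEFAULT_FRAME_DURATION_S = 8.5


@dataclass
class StallOGram:
    """Binary raster of stall state per stalling segment per volume.

    Rows are segments that stalled at least once; ``segment_ids`` maps
    rows back to mask labels.  ``n_segments_examined`` counts every
    segment inspected, including those that never stalled.
    """

    matrix: np.ndarray
    n_segments_examined: int
    segment_ids: np.ndarray | None = None
    frame_duration_s: float = DEFAULT_FRAME_DURATION_S

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("stall-o-gram matrix must be 2-D")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("stall-o-gram entries must be 0 or 1")
        self.matrix = self.matrix.astype(np.int8)
        if self.matrix.shape[0] and not self.matrix.any(axis=1).all():
            raise ValueError("every row must contain at least one stall")
        if self.n_segments_examined < self.matrix.shape[0]:
            raise ValueError("examined count smaller than stalling rows")
        if self.segment_ids is None:
            self.segment_ids = np.arange(self.matrix.shape[0])
        else:
            self.segment_ids = np.asarray(self.segment_ids)

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[1]

    @property
    def total_scan_time_s(self) -> float:
        return self.n_volumes * self.frame_duration_s


@dataclass(frozen=True)
class StallMetrics:
    """The four stall statistics plus the raw-count prevalence variant."""

    total_stalls: int
    incidence_pct: float
    prevalence_pct: float
    prevalence_count: float
    cumulative_stall_time_pct: np.ndarray
    pooled_cumulative_stall_time_pct: float
    total_scan_time_s: float


def segment_timecourses(series: np.ndarray, labels: np.ndarray):
    """Mean intensity of each labelled segment in each volume.

    Parameters
    ----------
    series : ndarray
        Angiogram time series, (n_volumes, z, y, x) or (n_volumes, y, x)
        for a projected series.
    labels : ndarray
        Integer label image matching the spatial shape of one volume;
        0 is background.

    Returns
    -------
    timecourses : ndarray, (n_segments, n_volumes)
    segment_ids : ndarray of the corresponding label values
    """
    series = np.asarray(series)
    labels = np.asarray(labels)
    if labels.shape != series.shape[1:]:
        raise ValueError("label mask must match the series' spatial shape")
    ids = np.unique(labels)
    ids = ids[ids != 0]
    if ids.size == 0:
        raise ValueError("label mask contains no segments")
    flat_labels = labels.ravel()
    n_vol = series.shape[0]
    counts = np.bincount(flat_labels, minlength=ids.max() + 1)
    tc = np.empty((ids.size, n_vol), dtype=float)
    for v in range(n_vol):
        sums = np.bincount(
            flat_labels, weights=series[v].ravel(), minlength=ids.max() + 1
        )
        tc[:, v] = sums[ids] / counts[ids]
    return tc, ids


def detect_stalls(
    timecourses: np.ndarray,
    segment_ids: np.ndarray | None = None,
    method: str = "relative-threshold",
    threshold: float = 0.5,
    noise_floor: float | None = None,
    frame_duration_s: float = DEFAULT_FRAME_DURATION_S,
) -> StallOGram:
    """Flag stalled frames and assemble the stall-o-gram.

    A frame is stalled when the segment's mean intensity drops below
    ``threshold`` times that segment's median across all volumes — the
    reproducible stand-in for rater inspection of the image series.
    Segments whose median sits at the noise floor carry no perfusion
    signal and are excluded (with a warning) from the examined count.
    Rows that never stall are dropped from the matrix but still counted
    in ``n_segments_examined``.
    """
    if method != "relative-threshold":
        raise ValueError(f"unknown detection method: {method!r}")
    tc = np.asarray(timecourses, dtype=float)
    if tc.ndim != 2 or tc.shape[1] < 2:
        raise ValueError("need a 2-D time-course matrix with >= 2 volumes")
    if segment_ids is None:
        segment_ids = np.arange(tc.shape[0])
    medians = np.median(tc, axis=1)
    valid = np.ones(tc.shape[0], dtype=bool)
    if noise_floor is not None:
        valid = medians > noise_floor
        if not valid.all():
            warnings.warn(
                f"excluding {int((~valid).sum())} segment(s) with median "
                "intensity at the noise floor"
            )
    stalled = tc < threshold * medians[:, None]
    stalled &= valid[:, None]
    rows = stalled.any(axis=1)
    return StallOGram(
        matrix=stalled[rows].astype(np.int8),
        n_segments_examined=int(valid.sum()),
        segment_ids=np.asarray(segment_ids)[rows],
        frame_duration_s=frame_duration_s,
    )


def stall_metrics(stallogram: StallOGram) -> StallMetrics:
    """Compute the summary stall statistics from a stall-o-gram.

    * total stalls — number of segments with at least one stalled frame;
    * incidence — stalling segments / segments examined, %;
    * prevalence — average per volume of stalled segments / examined, %
      (also returned as a raw mean count per volume);
    * cumulative stall time — stalled frames / total volumes per
      stalling segment, %, plus the pooled mean over stalling segments.
    """
    if stallogram.n_segments_examined == 0:
        raise ValueError("no segments were examined")
    m = stallogram.matrix
    n_examined = stallogram.n_segments_examined
    total = m.shape[0]
    incidence = 100.0 * total / n_examined
    per_volume = m.sum(axis=0) if total else np.zeros(m.shape[1])
    prevalence_count = float(per_volume.mean()) if m.shape[1] else 0.0
    prevalence = 100.0 * prevalence_count / n_examined
    per_segment = m.sum(axis=1)
    cumulative = 100.0 * per_segment / m.shape[1] if total else np.empty(0)
    pooled = float(cumulative.mean()) if total else 0.0
    return StallMetrics(
        total_stalls=int(total),
        incidence_pct=float(incidence),
        prevalence_pct=float(prevalence),
        prevalence_count=prevalence_count,
        cumulative_stall_time_pct=np.asarray(cumulative, dtype=float),
        pooled_cumulative_stall_time_pct=pooled,
        total_scan_time_s=stallogram.total_scan_time_s,
    )


def stall_duration_distribution(stallogram: StallOGram) -> pd.DataFrame:
    """Run-length table of stall events.

    Each maximal run of consecutive stalled frames within a row is one
    event; a single flowing frame separates events.  Durations are
    reported in frames and in seconds (frames x frame duration).
    """
    records = []
    for row_idx, row in enumerate(stallogram.matrix):
        padded = np.concatenate(([0], row, [0]))
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for s, e in zip(starts, ends):
            records.append(
                {
                    "segment_id": stallogram.segment_ids[row_idx],
                    "start_volume": int(s),
                    "duration_frames": int(e - s),
                    "duration_s": (e - s) * stallogram.frame_duration_s,
                }
            )
    return pd.DataFrame(
        records,
        columns=["segment_id", "start_volume", "duration_frames", "duration_s"],
    )
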
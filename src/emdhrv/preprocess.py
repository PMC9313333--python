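"""Artifact screening and tachogram resampling.

Outlier RR intervals (movement artifacts, ectopic beats) are removed by
the 3-standard-deviation rule: any interval farther than 3 SD from the
record mean is deleted in a single pass, with mean and SD taken over the
full input record.  Surviving beats keep their original absolute times,
so the deleted beats leave gaps that the interpolation bridges.

The evenly sampled HRV signal ("tachogram") used by all spectral and
EMD analysis is a natural cubic spline through (beat time, RR) knots,
evaluated on a uniform 8 Hz grid spanning the knot range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import DataError
from .records import RRSeries

__all__ = ["Tachogram", "OutlierReport", "remove_outliers", "resample_tachogram"]

DEFAULT_FS = 8.0
SD_MULTIPLIER = 3.0


@dataclass
class Tachogram:
    """Uniformly resampled HRV signal x(t)."""

    fs: float
    t: np.ndarray  # uniform sample times, s
    x: np.ndarray  # interpolated RR value at t, ms

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.t.shape != self.x.shape:
            raise DataError("tachogram t and x must have equal length")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class OutlierReport:
    removed_indices: list
    n_removed: int
    mean_ms: float
    sd_ms: float


def remove_outliers(rr: RRSeries, sd_multiplier: float = SD_MULTIPLIER):
    """Delete intervals outside ``sd_multiplier`` SDs of the record mean.

    Returns ``(cleaned, report)``.  The cleaned series is marked
    ``gapped``: surviving beats retain their absolute beat times and the
    spline later bridges the holes, preserving true elapsed time for
    segmentation.
    """
    if len(rr) < 4:
        raise DataError(
            f"outlier screening needs >= 4 intervals, got {len(rr)} "
            f"({rr.subject_id}/{rr.condition})"
        )
    mean = float(np.mean(rr.rr_ms))
    sd = float(np.std(rr.rr_ms, ddof=1))
    keep = np.abs(rr.rr_ms - mean) <= sd_multiplier * sd
    removed = np.flatnonzero(~keep)
    report = OutlierReport(
        removed_indices=[int(i) for i in removed],
        n_removed=int(removed.size),
        mean_ms=mean,
        sd_ms=sd,
    )
    if removed.size == 0:
        return rr, report
    if keep.sum() < 2:
        raise DataError(
            f"outlier screening removed nearly all beats of "
            f"{rr.subject_id}/{rr.condition}; record is degenerate"
        )
    cleaned = rr.with_intervals(
        rr.rr_ms[keep],
        beat_time_s=rr.beat_time_s[keep],
        gapped=True,
        outliers_removed=report.n_removed,
    )
    return cleaned, report


def resample_tachogram(rr: RRSeries, fs: float = DEFAULT_FS) -> Tachogram:
    """Natural cubic spline through (beat time, RR), sampled at ``fs`` Hz.

    The grid starts at the first beat time and never extrapolates past
    the last beat.
    """
    if len(rr) < 4:
        raise DataError(
            f"cubic-spline resampling needs >= 4 beats, got {len(rr)} "
            f"({rr.subject_id}/{rr.condition})"
        )
    spline = CubicSpline(rr.beat_time_s, rr.rr_ms, bc_type="natural")
    t0, t1 = float(rr.beat_time_s[0]), float(rr.beat_time_s[-1])
    n = int(np.floor((t1 - t0) * fs)) + 1
    t = t0 + np.arange(n) / fs
    return Tachogram(fs=fs, t=t, x=spline(t))
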
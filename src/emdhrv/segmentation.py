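"""Ultra-short-term windowing of 5-min RR records.

Windows of 1/2/3 min are cut at three positions — first, middle, last —
relative to the record span T:

    first  : [0, d)
    middle : [(T-d)/2, (T+d)/2)
    last   : [T-d, T]

An interval belongs to the window that contains its *end* time (the
beat time).  Windows are half-open on the right except when the right
edge coincides with the record end, which is closed so that a full-span
window reproduces the record exactly.

The lowest-mean-HR selection rule picks, among the three positional
windows of the rest record, the one with the lowest average heart rate
(sympathetic activation is weakest there); the paired stress record is
cut at the matched position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, ParameterError
from .records import Cohort, RRSeries, REST, STRESS

__all__ = [
    "SegmentSpec",
    "POSITIONS",
    "cut_segment",
    "select_lowest_hr_segment",
    "build_ultra_short_dataset",
]

POSITIONS = ("first", "middle", "last")
DURATIONS_S = (60.0, 120.0, 180.0)

_END_TOL_S = 1e-9


@dataclass(frozen=True)
class SegmentSpec:
    """Windowing recipe: a position (or lowest-HR selection) and a duration."""

    position: str = "first"
    duration_s: float = 180.0
    selection: str = "fixed_position"  # or "lowest_hr"

    def __post_init__(self):
        if self.position not in POSITIONS:
            raise ParameterError(f"position must be one of {POSITIONS}")
        if self.selection not in ("fixed_position", "lowest_hr"):
            raise ParameterError("selection must be fixed_position or lowest_hr")
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be positive")


def _window(position: str, T: float, d: float):
    if position == "first":
        return 0.0, d
    if position == "middle":
        return (T - d) / 2.0, (T + d) / 2.0
    if position == "last":
        return T - d, T
    raise ParameterError(f"unknown position {position!r}")


def cut_segment(rr: RRSeries, position: str, duration_s: float) -> RRSeries:
    """Extract the positional window as a new RRSeries.

    Beat times in the result are kept at their original absolute values;
    the window bounds are recorded in the segment metadata.
    """
    T = rr.span_s
    if T < duration_s:
        raise DataError(
            f"record {rr.subject_id}/{rr.condition} spans {T:.1f} s, "
            f"shorter than the requested {duration_s:.0f} s window"
        )
    w0, w1 = _window(position, T, duration_s)
    t = rr.beat_time_s
    closed_right = w1 >= T - _END_TOL_S
    if closed_right:
        keep = (t >= w0 - _END_TOL_S) & (t <= w1 + _END_TOL_S)
    else:
        keep = (t >= w0 - _END_TOL_S) & (t < w1 - _END_TOL_S)
    if keep.sum() < 2:
        raise DataError(
            f"window {position}/{duration_s:.0f}s of {rr.subject_id}/"
            f"{rr.condition} contains fewer than 2 beats"
        )
    return rr.with_intervals(
        rr.rr_ms[keep],
        beat_time_s=t[keep],
        gapped=True,  # cumulative sums no longer anchor at the window start
        segment={"position": position, "duration_s": duration_s,
                 "window": [w0, w1]},
    )


def select_lowest_hr_segment(rr: RRSeries, duration_s: float):
    """Among the three positional windows, return ``(segment, position)``
    with the lowest mean HR; ties (within 1e-6 beats/min, far below any
    physiological difference) go to the earliest position."""
    best = None
    for position in POSITIONS:
        seg = cut_segment(rr, position, duration_s)
        hr = seg.mean_hr_bpm
        if best is None or hr < best[0] - 1e-6:
            best = (hr, seg, position)
    return best[1], best[2]


def build_ultra_short_dataset(cohort: Cohort, spec: SegmentSpec,
                              rest: str = REST, stress: str = STRESS,
                              lowest_hr_state: str = REST) -> Cohort:
    """Cut every subject's rest and stress records per ``spec``.

    fixed_position: both states cut at the same position/duration.
    lowest_hr: the record of ``lowest_hr_state`` contributes its
    lowest-mean-HR window and the paired record is cut at the matched
    position.  The wording of the pairing rule admits either state as
    the driver; rest is the default and the choice is logged in the
    cohort metadata.
    """
    cohort.require_paired(rest, stress)
    out = Cohort(metadata={**cohort.metadata, "segment_spec": spec.__dict__,
                           "lowest_hr_state": lowest_hr_state})
    if lowest_hr_state not in (rest, stress):
        raise ParameterError(
            f"lowest_hr_state must be {rest!r} or {stress!r}")
    for subject in cohort.subjects():
        records = {c: cohort.get(subject, c) for c in (rest, stress)}
        if spec.selection == "lowest_hr":
            driver_seg, position = select_lowest_hr_segment(
                records[lowest_hr_state], spec.duration_s)
            other = stress if lowest_hr_state == rest else rest
            out.add(driver_seg)
            out.add(cut_segment(records[other], position, spec.duration_s))
        else:
            for condition in (rest, stress):
                out.add(cut_segment(records[condition], spec.position,
                                    spec.duration_s))
    return out
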
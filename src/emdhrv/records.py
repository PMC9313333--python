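"""Core record containers: RR-interval series and cohorts.

An :class:`RRSeries` is the raw unit of analysis — one subject in one
condition, as an ordered sequence of RR (inter-beat) intervals in
milliseconds.  Beat times are the cumulative interval sums in seconds;
when a series has had beats removed (artifact screening) the surviving
beats keep their original absolute times, so ``beat_time_s`` is stored
explicitly rather than recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .errors import DataError

__all__ = ["RRSeries", "Cohort"]

REST = "rest"
STRESS = "stress"

# Max tolerated drift (ms) between supplied beat times and cumulative RR sums
# before the two are declared inconsistent.
_BEAT_TIME_TOL_MS = 1.0


@dataclass
class RRSeries:
    """A subject-condition sequence of RR intervals.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    condition : str
        Condition label, canonically ``"rest"`` or ``"stress"``.
    rr_ms : ndarray
        Ordered RR intervals in milliseconds, all positive, length >= 2.
    beat_time_s : ndarray, optional
        Absolute time of each beat (the *end* of each interval) in
        seconds.  Derived as ``cumsum(rr_ms)/1000`` when omitted.  If
        supplied it must agree with the cumulative sums to within 1 ms
        per step unless the series is marked ``gapped`` (beats removed).
    gapped : bool
        True when beats have been deleted so cumulative sums no longer
        reproduce the beat times.
    meta : dict
        Free-form provenance (segment window, generator parameters, ...).
    """

    subject_id: str
    condition: str
    rr_ms: np.ndarray
    beat_time_s: np.ndarray | None = None
    gapped: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if self.rr_ms.ndim != 1 or self.rr_ms.size < 2:
            raise DataError(
                f"RRSeries {self.subject_id}/{self.condition}: need >= 2 intervals, "
                f"got {self.rr_ms.size}"
            )
        if np.any(self.rr_ms <= 0) or not np.all(np.isfinite(self.rr_ms)):
            raise DataError(
                f"RRSeries {self.subject_id}/{self.condition}: RR intervals must be "
                "finite and positive"
            )
        cumulative = np.cumsum(self.rr_ms) / 1000.0
        if self.beat_time_s is None:
            self.beat_time_s = cumulative
        else:
            self.beat_time_s = np.asarray(self.beat_time_s, dtype=float)
            if self.beat_time_s.shape != self.rr_ms.shape:
                raise DataError("beat_time_s and rr_ms must have equal length")
            if np.any(np.diff(self.beat_time_s) <= 0):
                raise DataError("beat_time_s must be strictly increasing")
            if not self.gapped:
                drift_ms = np.max(
                    np.abs((self.beat_time_s - self.beat_time_s[0])
                           - (cumulative - cumulative[0])) * 1000.0
                )
                if drift_ms > _BEAT_TIME_TOL_MS:
                    raise DataError(
                        f"RRSeries {self.subject_id}/{self.condition}: beat times "
                        f"disagree with cumulative RR sums by {drift_ms:.3f} ms"
                    )

    def __len__(self) -> int:
        return int(self.rr_ms.size)

    @property
    def span_s(self) -> float:
        """Elapsed time covered by the record, from start (t=0 reference
        of the first interval) to the final beat."""
        return float(self.beat_time_s[-1])

    @property
    def mean_hr_bpm(self) -> float:
        return 60000.0 / float(np.mean(self.rr_ms))

    def with_intervals(self, rr_ms, beat_time_s=None, gapped=None, **meta) -> "RRSeries":
        """Copy of this series with new interval data, merged metadata."""
        return RRSeries(
            subject_id=self.subject_id,
            condition=self.condition,
            rr_ms=np.asarray(rr_ms, dtype=float),
            beat_time_s=None if beat_time_s is None else np.asarray(beat_time_s, float),
            gapped=self.gapped if gapped is None else gapped,
            meta={**self.meta, **meta},
        )


@dataclass
class Cohort:
    """Collection of RR records keyed by (subject_id, condition)."""

    records: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def add(self, series: RRSeries) -> None:
        key = (series.subject_id, series.condition)
        if key in self.records:
            raise DataError(f"duplicate record for {key}")
        self.records[key] = series

    def get(self, subject_id: str, condition: str) -> RRSeries:
        try:
            return self.records[(subject_id, condition)]
        except KeyError:
            raise DataError(f"no record for ({subject_id}, {condition})") from None

    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for subject_id, _ in self.records:
            seen.setdefault(subject_id, None)
        return list(seen)

    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, condition in self.records:
            seen.setdefault(condition, None)
        return list(seen)

    def __iter__(self) -> Iterator[RRSeries]:
        return iter(self.records.values())

    def __len__(self) -> int:
        return len(self.records)

    def require_paired(self, rest: str = REST, stress: str = STRESS) -> None:
        """Raise unless every subject has both a rest and a stress record."""
        for subject in self.subjects():
            for condition in (rest, stress):
                if (subject, condition) not in self.records:
                    raise DataError(
                        f"subject {subject} is missing a '{condition}' record"
                    )
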
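"""Ultra-short vs short-term surrogacy of the IMF energy features.

For each state and each ultra-short duration, every feature is computed
on the first window of that duration and on the full record; the Pearson
correlation of the two across subjects says whether the shortened
feature can stand in for its 5-min value (the conventional validity
bar is r > 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .features import ENERGY_SURROGATES
from .pipeline import extract_feature_table
from .records import Cohort
from .segmentation import SegmentSpec, build_ultra_short_dataset

__all__ = ["DurationGrid", "duration_correlation"]


@dataclass(frozen=True)
class DurationGrid:
    durations_s: tuple = (60.0, 120.0, 180.0)
    reference_s: float = 300.0
    threshold_r: float = 0.7

    def __post_init__(self):
        if any(d >= self.reference_s for d in self.durations_s):
            raise DataError("ultra-short durations must be below the reference")


def duration_correlation(cohort: Cohort, feature_names=None,
                         grid: DurationGrid = DurationGrid(),
                         position: str = "first",
                         extract=None) -> pd.DataFrame:
    """Pearson r between ultra-short and full-length feature values.

    Returns a tidy frame with columns feature, duration_s, condition, r,
    surrogate_valid (r > threshold).  Zero-variance features yield an
    NaN sentinel, never a spurious r.  Outlier screening runs once on
    the full records before windowing.
    """
    feature_names = list(feature_names or ENERGY_SURROGATES)
    cohort.require_paired()
    if extract is None:
        from .pipeline import clean_cohort

        cohort = clean_cohort(cohort)
        extract = lambda c: extract_feature_table(c, screen=False)  # noqa: E731
    reference = extract(cohort).sort_values(["subject_id", "condition"])
    rows = []
    for duration in grid.durations_s:
        spec = SegmentSpec(position=position, duration_s=duration)
        segments = build_ultra_short_dataset(cohort, spec)
        short = extract(segments).sort_values(["subject_id", "condition"])
        for condition in reference["condition"].unique():
            ref_c = reference[reference["condition"] == condition]
            short_c = short[short["condition"] == condition]
            if not (ref_c["subject_id"].to_numpy() == short_c["subject_id"].to_numpy()).all():
                raise DataError("subject alignment failed between durations")
            for feature in feature_names:
                a = ref_c[feature].to_numpy(float)
                b = short_c[feature].to_numpy(float)
                ok = np.isfinite(a) & np.isfinite(b)
                if ok.sum() < 3 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
                    r = float("nan")
                else:
                    r = float(stats.pearsonr(a[ok], b[ok])[0])
                rows.append({
                    "feature": feature,
                    "duration_s": duration,
                    "condition": condition,
                    "r": r,
                    "surrogate_valid": bool(r > grid.threshold_r)
                    if np.isfinite(r) else False,
                })
    return pd.DataFrame(rows)
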
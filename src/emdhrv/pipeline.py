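"""Cohort-level feature extraction: RR records to feature tables.

For every record: screen outlier intervals (3 SD rule), fit the 8 Hz
cubic-spline tachogram, decompose into IMF1-3 + residual, and compute
the 26-feature vector.  The G-pNNx threshold is derived once from the
cohort's rest records and shared by all rows.  Band powers (the
frequency-domain references the IMF energies stand in for) are appended
on request for surrogate-correlation analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .emd import SiftConfig, decompose
from .features import (
    EntropyParams,
    FEATURE_NAMES,
    band_power,
    extract_all,
    gpnnx_threshold,
)
from .preprocess import DEFAULT_FS, SD_MULTIPLIER, remove_outliers, resample_tachogram
from .records import Cohort, RRSeries, REST

__all__ = ["extract_record_features", "extract_feature_table", "cohort_gpnnx",
           "clean_cohort"]

KEY_COLUMNS = ["subject_id", "condition"]
BAND_COLUMNS = ["lf_power", "hf_power", "lf_hf_ratio"]


def clean_cohort(cohort: Cohort, sd_multiplier: float = SD_MULTIPLIER) -> Cohort:
    """Outlier-screen every full record once, before any segmentation."""
    out = Cohort(metadata={**cohort.metadata, "screened": True})
    for series in cohort:
        cleaned, _ = remove_outliers(series, sd_multiplier)
        out.add(cleaned)
    return out


def cohort_gpnnx(cohort: Cohort, rest: str = REST, alpha: float = 0.05,
                 screen: bool = True) -> float:
    """G-pNNx threshold from the cohort's rest records (after outlier
    screening, unless the cohort is already screened)."""
    rest_records = []
    for series in cohort:
        if series.condition == rest:
            if screen:
                series, _ = remove_outliers(series)
            rest_records.append(series)
    return gpnnx_threshold(rest_records, alpha=alpha)


def extract_record_features(series: RRSeries, gpnnx_x: float,
                            entropy_params: EntropyParams = EntropyParams(),
                            sift_config: SiftConfig = SiftConfig(),
                            fs: float = DEFAULT_FS,
                            sd_multiplier: float = SD_MULTIPLIER,
                            include_band_power: bool = False,
                            screen: bool = True) -> dict:
    """Full preprocessing + EMD + 26-feature extraction for one record.

    ``screen=False`` skips outlier removal — used for segments cut from
    records that were already screened in full.
    """
    if screen:
        cleaned, _ = remove_outliers(series, sd_multiplier)
    else:
        cleaned = series
    tach = resample_tachogram(cleaned, fs)
    imfset = decompose(tach, sift_config,
                       label=f"{series.subject_id}/{series.condition}")
    row = {
        "subject_id": series.subject_id,
        "condition": series.condition,
        **extract_all(cleaned, imfset, entropy_params, gpnnx_x),
    }
    if include_band_power:
        bp = band_power(tach)
        row["lf_power"] = bp.lf_power
        row["hf_power"] = bp.hf_power
        row["lf_hf_ratio"] = bp.lf_hf_ratio
    segment = series.meta.get("segment")
    if segment:
        row["segment_position"] = segment["position"]
        row["segment_duration_s"] = segment["duration_s"]
    return row


def extract_feature_table(cohort: Cohort,
                          entropy_params: EntropyParams = EntropyParams(),
                          sift_config: SiftConfig = SiftConfig(),
                          gpnnx_x: float | None = None,
                          fs: float = DEFAULT_FS,
                          sd_multiplier: float = SD_MULTIPLIER,
                          include_band_power: bool = False,
                          screen: bool = True) -> pd.DataFrame:
    """Feature table over all records of a cohort.

    Columns: subject_id, condition, the 26 features in canonical order,
    then optional band powers and segment provenance.  ``gpnnx_x`` is
    derived from the cohort's rest records when not supplied.  Pass
    ``screen=False`` for cohorts of segments cut from already-screened
    records.
    """
    if gpnnx_x is None:
        gpnnx_x = cohort_gpnnx(cohort, alpha=0.05, screen=screen)
    rows = [
        extract_record_features(
            series, gpnnx_x, entropy_params, sift_config,
            fs=fs, sd_multiplier=sd_multiplier,
            include_band_power=include_band_power, screen=screen,
        )
        for series in cohort
    ]
    table = pd.DataFrame(rows)
    ordered = KEY_COLUMNS + FEATURE_NAMES
    extras = [c for c in table.columns if c not in ordered]
    table = table[ordered + extras]
    table.attrs["gpnnx_x"] = gpnnx_x
    return table
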
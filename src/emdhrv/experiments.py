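"""Replicated cohort-level experiments.

These compose the full pipeline into the study-level analyses: the
IMF-energy/band-power surrogacy check across autonomic balances, the
label-permutation null for the classifier, and the stress-adaptation
segment-ordering comparison (does the first window of a stress record —
where sympathetic activation is freshest — classify better than the
last, once heart rate has partly adapted back toward baseline?).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .classify import SVMConfig, losocv, sweep_feature_counts
from .features import surrogate_correlation
from .pipeline import clean_cohort, extract_feature_table
from .segmentation import SegmentSpec, build_ultra_short_dataset
from .simulate import CohortSpec, make_cohort, make_ratio_grid_cohort

__all__ = [
    "surrogacy_grid_correlations",
    "permutation_null_accuracy",
    "adaptation_ordering",
]


def surrogacy_grid_correlations(n_records: int = 60, seed: int = 0):
    """Pearson correlations of the IMF-energy surrogates against Welch
    band powers over a cohort spanning a wide grid of LF/HF modulation
    balances.  Returns the (r, labels) pair of
    :func:`emdhrv.features.surrogate_correlation`."""
    cohort = make_ratio_grid_cohort(n_records=n_records, seed=seed)
    table = extract_feature_table(cohort, include_band_power=True)
    return surrogate_correlation(table)


def permutation_null_accuracy(table: pd.DataFrame, n_permutations: int = 20,
                              seed: int = 0,
                              svm: SVMConfig = SVMConfig()) -> pd.DataFrame:
    """LOSOCV accuracy under random label permutation.

    Shuffling the rest/stress labels destroys the class structure, so
    the mean accuracy over permutations estimates the chance level of
    the whole pipeline (ranking + scaling + SVM) — a leak or optimistic
    bias would push it above 50%.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_permutations):
        shuffled = table.copy()
        shuffled["condition"] = rng.permutation(shuffled["condition"].values)
        outcome = losocv(shuffled, ranking_mode="global", svm=svm)
        rows.append({"permutation": i, "accuracy": outcome.metrics.accuracy})
    return pd.DataFrame(rows)


def adaptation_ordering(n_replicates: int = 20, n_subjects: int = 14,
                        duration_s: float = 180.0, seed: int = 0,
                        stress_drift: float = -0.08,
                        svm: SVMConfig = SVMConfig()) -> pd.DataFrame:
    """First- vs last-window classification accuracy over replicates.

    Each replicate draws a fresh cohort whose stress records carry
    ``stress_drift`` (fractional HR change over the record; negative
    models adaptation).  Both positional windows are classified with the
    full feature-count sweep; the returned frame holds one row per
    replicate with ``first_accuracy`` and ``last_accuracy``.  With
    ``stress_drift=0`` the comparison is a null experiment.
    """
    rows = []
    for r in range(n_replicates):
        base = CohortSpec(n_subjects=n_subjects, seed=seed + 1000 * r)
        spec = replace(base, stress=replace(base.stress, drift=stress_drift))
        cohort = clean_cohort(make_cohort(spec))
        accuracies = {}
        for position in ("first", "last"):
            segments = build_ultra_short_dataset(
                cohort, SegmentSpec(position=position, duration_s=duration_s))
            table = extract_feature_table(segments, screen=False)
            report = sweep_feature_counts(table, svm)
            accuracies[position] = report.best.metrics.accuracy
        rows.append({"replicate": r,
                     "first_accuracy": accuracies["first"],
                     "last_accuracy": accuracies["last"]})
    return pd.DataFrame(rows)
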
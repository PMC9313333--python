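"""The 26-feature HRV vector and its reference frequency-domain powers.

Feature families
----------------
* time domain on the raw RR sequence: HR, SDNN, RMSSD, pNN30, pNN50 and
  G-pNNx (a pNNx whose threshold x is derived from a rest cohort);
* tachogram-level nonlinear/energy: permutation entropy (PmEn), sample
  entropy (SpEn) and signal energy;
* per-IMF entropies (SpEn_IMF1..3, PmEn_IMF1..3);
* IMF energy features — surrogates of the spectral band powers:
  Energy_IMF1 tracks HF (0.15-0.4 Hz) power, Energy_(IMF2+IMF3) tracks
  LF (0.04-0.15 Hz) power, and their ratio/normalised forms track the
  LF/HF balance, resting on Parseval's identity between time-domain
  energy and integrated spectral power;
* per-IMF time-domain: SDNN_IMF1..3, RMSSD_IMF1..3 (the SDNN/RMSSD
  formulas applied to the uniformly sampled IMF values).

``FEATURE_NAMES`` fixes the canonical column order used by feature
tables (the ranked order reported for this feature set).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import welch
from scipy.spatial import cKDTree

from .emd import IMFSet
from .errors import DataError, ParameterError
from .preprocess import Tachogram
from .records import RRSeries

__all__ = [
    "FEATURE_NAMES",
    "EntropyParams",
    "BandPower",
    "sdnn",
    "rmssd",
    "pnnx",
    "gpnnx_threshold",
    "perm_entropy",
    "sample_entropy",
    "energy",
    "energy_features",
    "imf_time_features",
    "band_power",
    "extract_all",
    "surrogate_correlation",
    "hopkins_label",
]

#: canonical feature order (descending discriminative rank for this set)
FEATURE_NAMES = [
    "Energy",
    "SDNN",
    "Energy_(IMF2+IMF3)",
    "SpEn_IMF3",
    "RMSSD_IMF3",
    "Energy_IMF1",
    "SDNN_IMF3",
    "HR",
    "SDNN_IMF2",
    "RMSSD_IMF2",
    "RMSSD",
    "RMSSD_IMF1",
    "SDNN_IMF1",
    "SpEn",
    "G-pNNx",
    "PmEn_IMF3",
    "pNN50",
    "pNN30",
    "SpEn_IMF2",
    "Energy_IMF23/IMF1",
    "Energy_IMF1/IMF123",
    "Energy_IMF23/IMF123",
    "PmEn",
    "PmEn_IMF1",
    "PmEn_IMF2",
    "SpEn_IMF1",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


@dataclass(frozen=True)
class EntropyParams:
    """Entropy settings.

    pe_m : ordinal pattern length for permutation entropy (4; valid for
        series longer than 5*m!)
    pe_tau : embedding delay (1..4; 4 is the Nyquist-limited maximum at
        the 8 Hz tachogram rate)
    se_m : sample-entropy embedding dimension (2)
    se_r_coeff : sample-entropy tolerance as a multiple of the series SD
    """

    pe_m: int = 4
    pe_tau: int = 1
    se_m: int = 2
    se_r_coeff: float = 0.2

    def __post_init__(self):
        if not 1 <= self.pe_tau <= 4:
            raise ParameterError("pe_tau must lie in 1..4")
        if self.pe_m < 2:
            raise ParameterError("pe_m must be >= 2")


@dataclass
class BandPower:
    """Welch spectral power in the LF and HF bands (ms^2) and their ratio."""

    lf_power: float
    hf_power: float

    @property
    def lf_hf_ratio(self) -> float:
        if self.hf_power == 0:
            return math.nan
        return self.lf_power / self.hf_power


# ---------------------------------------------------------------- time domain

def sdnn(rr_ms) -> float:
    """Sample standard deviation of the RR intervals (ms), divisor N-1."""
    x = _as_rr(rr_ms)
    if x.size < 2:
        raise DataError("SDNN needs >= 2 intervals")
    return float(np.std(x, ddof=1))


def rmssd(rr_ms) -> float:
    """Root mean square of successive RR differences (ms)."""
    x = _as_rr(rr_ms)
    if x.size < 2:
        raise DataError("RMSSD needs >= 2 intervals")
    d = np.diff(x)
    return float(np.sqrt(np.mean(d**2)))


def pnnx(rr_ms, x_ms: float) -> float:
    """Percentage of successive RR differences strictly greater than x (ms)."""
    x = _as_rr(rr_ms)
    if x.size < 2:
        raise DataError("pNNx needs >= 2 intervals")
    if x_ms < 0:
        raise ParameterError("pNNx threshold must be >= 0")
    d = np.abs(np.diff(x))
    return float(100.0 * np.count_nonzero(d > x_ms) / d.size)


def gpnnx_threshold(rest_records, alpha: float = 0.05) -> float:
    """Cohort-derived pNNx threshold x (ms) from rest records.

    Each rest record contributes its median absolute successive RR
    difference; the cross-subject distribution of these summaries is
    tested for normality (Kolmogorov-Smirnov against a normal with the
    sample's mean/SD).  If normality holds at ``alpha`` the mean is
    returned, otherwise the median — the robust choice for the skewed
    distributions young, healthy cohorts typically show.
    """
    summaries = []
    for rr in rest_records:
        x = rr.rr_ms if isinstance(rr, RRSeries) else np.asarray(rr, float)
        if x.size < 2:
            raise DataError("each rest record needs >= 2 intervals")
        summaries.append(float(np.median(np.abs(np.diff(x)))))
    if len(summaries) < 3:
        raise DataError("G-pNNx threshold needs >= 3 rest records")
    values = np.asarray(summaries)
    mean, sd = float(np.mean(values)), float(np.std(values, ddof=1))
    if sd == 0:
        return mean
    _, p = stats.kstest(values, "norm", args=(mean, sd))
    return mean if p >= alpha else float(np.median(values))


# ------------------------------------------------------------------ entropies

def perm_entropy(series, m: int = 4, tau: int = 1) -> float:
    """Permutation entropy (nats): Shannon entropy of ordinal-pattern
    frequencies in delay-``tau`` embeddings of length ``m``.

    Requires ``len(series) >= 5 * m!`` so every pattern can be sampled;
    ties are broken by time order (stable argsort).
    """
    x = np.asarray(series, dtype=float)
    required = 5 * math.factorial(m)
    if x.size < required:
        raise DataError(
            f"permutation entropy with m={m} needs length >= {required}, "
            f"got {x.size}"
        )
    if tau < 1:
        raise ParameterError("tau must be >= 1")
    n_vec = x.size - (m - 1) * tau
    if n_vec < 1:
        raise DataError("series too short for the requested delay")
    idx = np.arange(n_vec)[:, None] + tau * np.arange(m)[None, :]
    patterns = np.argsort(x[idx], axis=1, kind="stable")
    # encode each ordinal pattern as an integer key
    keys = (patterns * (m ** np.arange(m))).sum(axis=1)
    _, counts = np.unique(keys, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def sample_entropy(series, m: int = 2, r_coeff: float = 0.2) -> float:
    """Sample entropy (nats): -ln(A/B) with B/A the counts of template
    pairs matching at length m / m+1 within Chebyshev tolerance
    r = r_coeff * SD(series); self-matches excluded.

    Returns NaN (undefined-entropy sentinel) when no template pairs
    match at either length.
    """
    x = np.asarray(series, dtype=float)
    if x.size < m + 2:
        raise DataError(f"sample entropy needs length >= {m + 2}")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise DataError("sample entropy undefined for a constant series")
    r = r_coeff * sd
    n_templates = x.size - m  # both passes use N-m templates (Richman-Moorman)
    b = _template_matches(x, m, r, n_templates)
    a = _template_matches(x, m + 1, r, n_templates)
    if b == 0 or a == 0:
        return math.nan
    return float(-np.log(a / b))


def _template_matches(x, m: int, r: float, n: int) -> int:
    """Number of ordered template pairs (i != j) among the first ``n``
    length-``m`` windows within Chebyshev distance r."""
    emb = np.lib.stride_tricks.sliding_window_view(x, m)[:n]
    tree = cKDTree(emb)
    pairs = tree.count_neighbors(tree, r, p=np.inf)
    return int(pairs - n)  # drop self-pairs; ordered count


# ------------------------------------------------------------------- energies

def energy(series) -> float:
    """Signal energy sum(x[n]^2) (ms^2 for RR-derived signals)."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise DataError("energy of an empty series is undefined")
    return float(np.sum(x**2))


def energy_features(imfset: IMFSet) -> dict:
    """The five IMF energy features.

    E1 = energy(IMF1); E23 = energy(IMF2) + energy(IMF3).  The ratio
    E23/E1 is the LF/HF-balance surrogate; the normalised pair uses
    E123 = E1 + E23 (IMF1-3 only) and always sums to 1.
    """
    if len(imfset.imfs) < 3:
        raise DataError("energy features need >= 3 IMFs")
    e1 = energy(imfset.imfs[0])
    e23 = energy(imfset.imfs[1]) + energy(imfset.imfs[2])
    e123 = e1 + e23
    ratio = e23 / e1 if e1 > 0 else math.nan
    return {
        "Energy_IMF1": e1,
        "Energy_(IMF2+IMF3)": e23,
        "Energy_IMF23/IMF1": ratio,
        "Energy_IMF1/IMF123": e1 / e123 if e123 > 0 else math.nan,
        "Energy_IMF23/IMF123": e23 / e123 if e123 > 0 else math.nan,
    }


def imf_time_features(imfset: IMFSet) -> dict:
    """SDNN and RMSSD formulas applied to each IMF's sample values."""
    if len(imfset.imfs) < 3:
        raise DataError("IMF time features need >= 3 IMFs")
    out = {}
    for k in (1, 2, 3):
        mode = imfset.imfs[k - 1]
        out[f"SDNN_IMF{k}"] = float(np.std(mode, ddof=1))
        out[f"RMSSD_IMF{k}"] = float(np.sqrt(np.mean(np.diff(mode) ** 2)))
    return out


def band_power(tachogram: Tachogram, nperseg_s: float = 64.0) -> BandPower:
    """LF/HF band powers of the mean-removed tachogram (Welch, Hann
    windows of ``nperseg_s`` seconds, 50% overlap; trapezoidal band
    integration).  Requires >= 60 s of signal."""
    if tachogram.duration_s < 60.0:
        raise DataError("band power needs a tachogram of >= 60 s")
    x = tachogram.x - np.mean(tachogram.x)
    nperseg = min(int(nperseg_s * tachogram.fs), x.size)
    f, pxx = welch(x, fs=tachogram.fs, window="hann", nperseg=nperseg,
                   noverlap=nperseg // 2, detrend=False)
    return BandPower(
        lf_power=_band_integral(f, pxx, *LF_BAND),
        hf_power=_band_integral(f, pxx, HF_BAND[0], HF_BAND[1], closed_right=True),
    )


def _band_integral(f, pxx, lo, hi, closed_right: bool = False) -> float:
    mask = (f >= lo) & ((f <= hi) if closed_right else (f < hi))
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(pxx[mask], f[mask]))


# ------------------------------------------------------------ full extraction

def extract_all(rr: RRSeries, imfset: IMFSet,
                entropy_params: EntropyParams = EntropyParams(),
                gpnnx_x: float = 30.0) -> dict:
    """Compute the full 26-entry feature vector for one record.

    Entropies and energy are computed on the 8 Hz tachogram (the signal
    EMD decomposes) and on its IMFs; time-domain features on the raw RR
    sequence.  ``gpnnx_x`` is the cohort-derived G-pNNx threshold.
    Returns a dict in canonical :data:`FEATURE_NAMES` order.
    """
    tach_x = imfset.reconstruct()
    centred = tach_x - np.mean(tach_x)
    ep = entropy_params
    values = {
        "HR": 60000.0 / float(np.mean(rr.rr_ms)),
        "SDNN": sdnn(rr.rr_ms),
        "RMSSD": rmssd(rr.rr_ms),
        "pNN30": pnnx(rr.rr_ms, 30.0),
        "pNN50": pnnx(rr.rr_ms, 50.0),
        "G-pNNx": pnnx(rr.rr_ms, gpnnx_x),
        "PmEn": perm_entropy(tach_x, ep.pe_m, ep.pe_tau),
        "SpEn": sample_entropy(tach_x, ep.se_m, ep.se_r_coeff),
        "Energy": energy(centred),
    }
    for k in (1, 2, 3):
        mode = imfset.imfs[k - 1]
        values[f"PmEn_IMF{k}"] = perm_entropy(mode, ep.pe_m, ep.pe_tau)
        values[f"SpEn_IMF{k}"] = sample_entropy(mode, ep.se_m, ep.se_r_coeff)
    values.update(energy_features(imfset))
    values.update(imf_time_features(imfset))
    return {name: values[name] for name in FEATURE_NAMES}


# ------------------------------------------------------- surrogate validation

_HOPKINS = [
    (0.1, "trivial"),
    (0.3, "small"),
    (0.5, "moderate"),
    (0.7, "large"),
    (0.9, "very large"),
    (1.0 + 1e-12, "nearly perfect"),
]


def hopkins_label(r: float) -> str:
    """Qualitative magnitude label for a Pearson correlation."""
    if math.isnan(r):
        return "undefined"
    a = abs(r)
    for upper, label in _HOPKINS:
        if a < upper or upper > 1.0:
            return label
    return "nearly perfect"


ENERGY_SURROGATES = ["Energy_IMF1", "Energy_(IMF2+IMF3)", "Energy_IMF23/IMF1"]
BAND_REFERENCES = ["hf_power", "lf_power", "lf_hf_ratio"]


def surrogate_correlation(table):
    """3x3 Pearson correlations between the IMF energy features and the
    reference band powers, with qualitative magnitude labels.

    ``table`` is a DataFrame holding the three energy-feature columns
    and the three band-power columns across >= 10 records.  Returns
    ``(r_matrix, label_matrix)`` as DataFrames (energy features on rows,
    band references on columns).  Zero-variance columns give NaN.
    """
    import pandas as pd

    if len(table) < 10:
        raise DataError("surrogate correlation needs >= 10 records")
    r = pd.DataFrame(index=ENERGY_SURROGATES, columns=BAND_REFERENCES, dtype=float)
    for feat in ENERGY_SURROGATES:
        for ref in BAND_REFERENCES:
            a = table[feat].to_numpy(float)
            b = table[ref].to_numpy(float)
            ok = np.isfinite(a) & np.isfinite(b)
            if np.std(a[ok]) == 0 or np.std(b[ok]) == 0 or ok.sum() < 3:
                r.loc[feat, ref] = math.nan
            else:
                r.loc[feat, ref] = float(stats.pearsonr(a[ok], b[ok])[0])
    labels = r.map(hopkins_label)
    return r, labels


def _as_rr(rr_ms) -> np.ndarray:
    if isinstance(rr_ms, RRSeries):
        return rr_ms.rr_ms
    return np.asarray(rr_ms, dtype=float)
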
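"""Empirical mode decomposition by sifting.

EMD splits a non-stationary signal into intrinsic mode functions (IMFs)
ordered fast to slow.  An IMF must satisfy two conditions: the numbers
of extrema and zero crossings agree to within one, and the mean of the
upper (maxima) and lower (minima) cubic-spline envelopes is everywhere
(numerically) zero.  Sifting repeatedly subtracts the envelope mean
until a Cauchy-type criterion

    SD = sum((h_prev - h)^2) / sum(h_prev^2) < sd_threshold

is met.  Each accepted IMF is subtracted from the running residual and
the process repeats until ``max_imfs`` modes are extracted or the
residual has too few extrema to sift.

The tachogram's large DC level (~800 ms) is removed before
decomposition and carried separately, so envelopes and energies are not
dominated by the offset; reconstruction adds it back.

Boundary effects are suppressed by mirroring a configurable number of
extrema about each end of the signal before envelope fitting.
"""

from __future__ import annotations

import math

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import DataError, DecompositionError
from .preprocess import Tachogram

__all__ = [
    "SiftConfig",
    "IMFSet",
    "find_extrema",
    "is_imf",
    "sift",
    "decompose",
    "zero_crossing_count",
    "mean_frequency",
]


@dataclass(frozen=True)
class SiftConfig:
    """Sifting controls.

    sd_threshold : Cauchy stop criterion (classic value 0.2)
    max_sift_iters : hard cap on sifting passes per IMF
    max_imfs : modes to extract (the feature set needs IMF1-3)
    boundary : number of extrema mirrored at each end
    imf_tolerance : envelope-mean tolerance in :func:`is_imf`,
        as a fraction of the candidate's range
    """

    sd_threshold: float = 0.2
    max_sift_iters: int = 100
    max_imfs: int = 3
    boundary: int = 2
    imf_tolerance: float = 0.05

    def __post_init__(self):
        if self.sd_threshold <= 0:
            raise DataError("sd_threshold must be positive")
        if self.max_imfs < 3:
            raise DataError("max_imfs must be >= 3 (feature set needs IMF1-3)")


@dataclass
class IMFSet:
    """Ordered IMFs plus residual (and the removed mean) of one tachogram."""

    imfs: list  # of ndarray, fast to slow
    residual: np.ndarray
    mean: float
    t: np.ndarray
    fs: float

    @property
    def source_length(self) -> int:
        return int(self.residual.size)

    def reconstruct(self) -> np.ndarray:
        """Sum of IMFs + residual + mean; equals the source signal."""
        out = self.residual + self.mean
        for imf in self.imfs:
            out = out + imf
        return out

    def tachogram(self) -> Tachogram:
        return Tachogram(fs=self.fs, t=self.t, x=self.reconstruct())

    def to_frame(self):
        """Tabular view (t, imf1.., residual) for CSV export/inspection."""
        import pandas as pd

        data = {"t": self.t}
        for k, mode in enumerate(self.imfs, start=1):
            data[f"imf{k}"] = mode
        data["residual"] = self.residual
        return pd.DataFrame(data)


def find_extrema(signal):
    """Strict local maxima/minima indices and the zero-crossing count.

    Plateaus (runs of equal samples) flanked by opposite slopes count as
    one extremum at the plateau midpoint.  Zero crossings are sign
    changes of the signal, exact zeros attaching to the preceding sign.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 3:
        raise DataError("extrema detection needs a signal of length >= 3")
    d = np.diff(x)
    nz = np.flatnonzero(d != 0)
    if nz.size < 2:
        return np.array([], dtype=int), np.array([], dtype=int), _zero_crossings(x)
    s = np.sign(d[nz])
    peak = np.flatnonzero((s[:-1] > 0) & (s[1:] < 0))
    trough = np.flatnonzero((s[:-1] < 0) & (s[1:] > 0))
    maxima = (nz[peak] + 1 + nz[peak + 1]) // 2
    minima = (nz[trough] + 1 + nz[trough + 1]) // 2
    return maxima.astype(int), minima.astype(int), _zero_crossings(x)


def _zero_crossings(x) -> int:
    s = np.sign(x)
    # exact zeros take the preceding sign (leading zeros the following one)
    nz = np.flatnonzero(s != 0)
    if nz.size == 0:
        return 0
    filled = s[nz]
    return int(np.count_nonzero(filled[1:] != filled[:-1]))


def _envelope(x, idx, depth: int):
    """Cubic-spline envelope through the extrema ``idx``, with ``depth``
    extrema mirrored about each end of the signal."""
    n = x.size
    t = idx.astype(float)
    v = x[idx]
    k = max(1, min(depth, t.size))
    tt = np.concatenate([-t[:k][::-1], t, 2.0 * (n - 1) - t[-k:][::-1]])
    vv = np.concatenate([v[:k][::-1], v, v[-k:][::-1]])
    tt, unique_idx = np.unique(tt, return_index=True)
    vv = vv[unique_idx]
    spline = CubicSpline(tt, vv)
    return spline(np.arange(n, dtype=float))


def envelope_mean(signal, boundary: int = 2):
    """Mean of upper and lower envelopes, or None if the signal has
    fewer than two maxima or two minima."""
    x = np.asarray(signal, dtype=float)
    maxima, minima, _ = find_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        return None
    upper = _envelope(x, maxima, boundary)
    lower = _envelope(x, minima, boundary)
    return 0.5 * (upper + lower)


def is_imf(candidate, tolerance: float = 0.05, boundary: int = 2) -> bool:
    """Check the two IMF conditions.

    True iff ``|#extrema - #zero_crossings| <= 1`` and the envelope mean
    never exceeds ``tolerance`` times the candidate's range (exact zero
    is unattainable on a finite grid).
    """
    x = np.asarray(candidate, dtype=float)
    rng = float(np.max(x) - np.min(x))
    if rng == 0:
        return False
    maxima, minima, zc = find_extrema(x)
    n_extrema = maxima.size + minima.size
    if abs(n_extrema - zc) > 1:
        return False
    mean = envelope_mean(x, boundary)
    if mean is None:
        return False
    return bool(np.max(np.abs(mean)) <= tolerance * rng)


def sift(signal, config: SiftConfig = SiftConfig()):
    """Extract one IMF candidate by iterative envelope-mean subtraction.

    Sifting stops at the first pass where the Cauchy criterion holds
    *and* the candidate satisfies both IMF conditions (extrema vs zero
    crossings within one; envelope mean within tolerance).  Neither IMF
    condition is monotone in the iteration count, so the Cauchy test
    alone can stop one pass short of a valid mode.

    Returns the sifted mode, or None when the signal has too few
    extrema to define envelopes (residual is monotone/constant) — the
    caller terminates the decomposition.
    """
    h = np.asarray(signal, dtype=float).copy()
    sd = math.inf
    for _ in range(config.max_sift_iters):
        maxima, minima, zc = find_extrema(h)
        if maxima.size < 1 or minima.size < 1:
            # degraded to a monotone-like signal mid-sift
            return None if np.allclose(h, signal) else h
        mean = 0.5 * (_envelope(h, maxima, config.boundary)
                      + _envelope(h, minima, config.boundary))
        span = float(np.max(h) - np.min(h))
        if (sd < config.sd_threshold
                and abs(maxima.size + minima.size - zc) <= 1
                and np.max(np.abs(mean)) <= config.imf_tolerance * span):
            break
        denom = float(np.sum(h**2))
        h_new = h - mean
        sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
        h = h_new
    return h


def decompose(tachogram: Tachogram, config: SiftConfig = SiftConfig(),
              label: str = "record") -> IMFSet:
    """Full EMD of a tachogram into ``config.max_imfs`` IMFs + residual.

    The signal mean is removed first and tracked in the set, so
    ``sum(IMFs) + residual + mean`` reconstructs the input exactly (up
    to floating-point error).  Raises :class:`DecompositionError` when
    fewer than three IMFs can be extracted, since the feature set
    requires IMF1-3.
    """
    x = np.asarray(tachogram.x, dtype=float)
    if x.size < 32:
        raise DataError(
            f"EMD needs >= 32 samples, got {x.size} ({label})"
        )
    mean = float(np.mean(x))
    residual = x - mean
    imfs: list[np.ndarray] = []
    while len(imfs) < config.max_imfs:
        maxima, minima, _ = find_extrema(residual)
        # standard termination: sifting needs >= 3 extrema (>= 1 per side;
        # mirroring supplies the envelope knots at the boundary)
        if maxima.size + minima.size < 3 or maxima.size < 1 or minima.size < 1:
            break
        mode = sift(residual, config)
        if mode is None:
            break
        imfs.append(mode)
        residual = residual - mode
    if len(imfs) < 3:
        raise DecompositionError(
            f"only {len(imfs)} IMFs extractable from {label}; "
            "the feature set requires IMF1-3"
        )
    return IMFSet(imfs=imfs, residual=residual, mean=mean,
                  t=np.asarray(tachogram.t, float), fs=tachogram.fs)


def zero_crossing_count(signal) -> int:
    return _zero_crossings(np.asarray(signal, dtype=float))


def mean_frequency(signal, fs: float) -> float:
    """Zero-crossing estimate of a mode's mean frequency in Hz
    (crossings per second / 2)."""
    x = np.asarray(signal, dtype=float)
    duration = (x.size - 1) / fs
    if duration <= 0:
        raise DataError("signal too short for a frequency estimate")
    return _zero_crossings(x) / (2.0 * duration)
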
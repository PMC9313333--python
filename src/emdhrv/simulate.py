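"""Synthetic RR-interval cohorts from an IPFM beat generator.

The integral pulse frequency modulation (IPFM) model drives a beat
emitter with an instantaneous rate

    m(t) = (hr0/60) * (1 + drift*t/T) *
           (1 + a_lf*sin(2*pi*f_lf*t + phi1) + a_hf*sin(2*pi*f_hf*t + phi2) + eps(t))

in beats/s; a beat fires whenever the integral of m crosses the next
integer.  The LF (~0.10 Hz) and HF (~0.25 Hz) sinusoids emulate
sympathetic/baroreflex and respiratory sinus arrhythmia modulation, the
linear ``drift`` term emulates within-record heart-rate adaptation, and
eps(t) is low-pass-filtered broadband modulation noise (cutoff 0.4 Hz so
its power stays inside the physiological analysis band).

Stress templates default to a higher mean heart rate, halved HF
modulation (vagal withdrawal) and a negative drift (adaptation as the
stressor continues); rest templates are stationary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import ParameterError
from .records import Cohort, RRSeries, REST, STRESS

__all__ = [
    "IPFMParams",
    "CohortSpec",
    "ipfm_rr",
    "inject_artifacts",
    "make_cohort",
    "make_ratio_grid_cohort",
]

#: integration grid for the IPFM rate signal (Hz); linear interpolation of
#: the cumulative integral on this grid gives sub-ms beat-time accuracy
_GRID_FS = 100.0


@dataclass(frozen=True)
class IPFMParams:
    """Generating parameters for one IPFM record.

    hr0 : mean heart rate, beats/min
    a_lf, a_hf : relative LF/HF modulation amplitudes (dimensionless)
    f_lf, f_hf : modulation frequencies, Hz
    noise_sd : RMS of the broadband relative modulation noise
    drift : linear fractional HR change start->end (-0.10 = falls 10%)
    duration_s : record length, s
    seed : RNG seed for phases and noise
    """

    hr0: float = 70.0
    a_lf: float = 0.03
    f_lf: float = 0.10
    a_hf: float = 0.06
    f_hf: float = 0.25
    # broadband modulation noise: real RR series carry substantial
    # non-sinusoidal variability at all scales; 3% RMS keeps every
    # 1-min window rich enough to support three intrinsic modes
    noise_sd: float = 0.03
    drift: float = 0.0
    duration_s: float = 300.0
    seed: int = 0

    def validate(self) -> None:
        if self.hr0 <= 0:
            raise ParameterError(f"hr0 must be positive, got {self.hr0}")
        if min(self.a_lf, self.a_hf, self.noise_sd) < 0:
            raise ParameterError("modulation amplitudes must be non-negative")
        if not self.a_lf + self.a_hf + self.noise_sd < 1.0:
            raise ParameterError(
                "a_lf + a_hf + noise_sd must stay below 1 so the modulation "
                "envelope cannot drive the rate negative"
            )
        if not (0.04 <= self.f_lf < 0.15):
            raise ParameterError(f"f_lf must lie in [0.04, 0.15), got {self.f_lf}")
        if not (0.15 <= self.f_hf <= 0.4):
            raise ParameterError(f"f_hf must lie in [0.15, 0.4], got {self.f_hf}")
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a paired rest/stress synthetic cohort."""

    n_subjects: int = 50
    rest: IPFMParams = field(default_factory=lambda: IPFMParams())
    stress: IPFMParams = field(
        # +15 bpm, halved HF modulation, adaptation drift
        default_factory=lambda: IPFMParams(hr0=85.0, a_lf=0.03, a_hf=0.03, drift=-0.08)
    )
    # resting HR across young adults spreads ~10 bpm about ~70 (≈15%
    # relative); the same relative jitter is applied to each parameter
    between_subject_sd: float = 0.15
    # stress reactivity differs between people at least as much as the
    # mean response itself (some subjects barely respond); an extra
    # independent jitter on the stress record's parameters keeps the
    # two classes overlapping instead of trivially separable
    reactivity_sd: float = 0.25
    artifact_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ParameterError("n_subjects must be >= 2")
        if not 0.0 <= self.artifact_rate <= 0.2:
            raise ParameterError("artifact_rate must lie in [0, 0.2]")
        if self.between_subject_sd < 0 or self.reactivity_sd < 0:
            raise ParameterError("jitter SDs must be >= 0")
        self.rest.validate()
        self.stress.validate()


def _modulation_noise(n: int, fs: float, noise_sd: float, rng: np.random.Generator):
    """Band-limited 1/f modulation noise with RMS ``noise_sd``.

    Real RR variability carries a 1/f-like broadband floor under the LF
    and HF peaks; the noise spectrum here is 1/f inside [0.03, 0.4] Hz.
    Variability below 0.03 Hz is left to the explicit ``drift`` term —
    slower components act as pure trend inside the 1-min analysis
    windows and cannot be resolved there anyway.
    """
    if noise_sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    weight = np.zeros_like(f)
    band = (f >= 0.03) & (f <= 0.4)
    weight[band] = f[band] ** -0.5
    eps = np.fft.irfft(spectrum * weight, n)
    rms = np.sqrt(np.mean(eps**2))
    return eps * (noise_sd / rms)


def ipfm_rr(params: IPFMParams, subject_id: str = "sim", condition: str = REST) -> RRSeries:
    """Generate one RR record from the IPFM model.

    Beat times are the crossings of the cumulative rate integral through
    successive integers, located by linear interpolation on a 100 Hz
    grid; RR_k = t_k - t_{k-1} in ms.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    phi1, phi2 = rng.uniform(0, 2 * np.pi, size=2)
    t = np.arange(0.0, params.duration_s + 1.0 / _GRID_FS, 1.0 / _GRID_FS)
    eps = _modulation_noise(t.size, _GRID_FS, params.noise_sd, rng)
    envelope = (
        1.0
        + params.a_lf * np.sin(2 * np.pi * params.f_lf * t + phi1)
        + params.a_hf * np.sin(2 * np.pi * params.f_hf * t + phi2)
        + eps
    )
    rate = (params.hr0 / 60.0) * (1.0 + params.drift * t / params.duration_s) * envelope
    if np.any(rate <= 0):
        raise ParameterError("modulation envelope drove the IPFM rate non-positive")
    integral = cumulative_trapezoid(rate, t, initial=0.0)
    n_beats = int(np.floor(integral[-1]))
    if n_beats < 3:
        raise ParameterError("record too short: fewer than 3 beats generated")
    # integral is strictly increasing (rate > 0), so interp is well defined
    beat_times = np.interp(np.arange(1, n_beats + 1, dtype=float), integral, t)
    rr_ms = np.diff(beat_times) * 1000.0
    return RRSeries(
        subject_id=subject_id,
        condition=condition,
        rr_ms=rr_ms,
        meta={"ipfm": asdict(params)},
    )


def inject_artifacts(rr: RRSeries, rate: float, seed: int):
    """Corrupt ``floor(rate*N)`` randomly chosen intervals with ectopic patterns.

    Half of the corruptions (rounded up) are spikes — the interval is
    replaced by 2.4x the local (11-beat) mean, emulating a missed beat —
    and the rest are halvings, emulating an ectopic premature beat.

    Returns ``(corrupted_series, corrupted_indices)``; the index list
    carries the pattern type in the series metadata.
    """
    if not 0.0 <= rate <= 0.2:
        raise ParameterError("artifact rate must lie in [0, 0.2]")
    n = len(rr)
    n_corrupt = int(np.floor(rate * n))
    if n_corrupt == 0:
        return rr.with_intervals(rr.rr_ms.copy()), []
    rng = np.random.default_rng(seed)
    indices = np.sort(rng.choice(n, size=n_corrupt, replace=False))
    corrupted = rr.rr_ms.copy()
    kinds = []
    for j, idx in enumerate(indices):
        lo, hi = max(0, idx - 5), min(n, idx + 6)
        local_mean = float(np.mean(rr.rr_ms[lo:hi]))
        if j % 2 == 0:
            corrupted[idx] = 2.4 * local_mean  # spike (missed beat)
            kinds.append("spike")
        else:
            corrupted[idx] = corrupted[idx] / 2.0  # premature beat
            kinds.append("half")
    out = rr.with_intervals(
        corrupted,
        artifact_indices=[int(i) for i in indices],
        artifact_kinds=kinds,
    )
    return out, [int(i) for i in indices]


def _jitter(params: IPFMParams, factors: dict, seed: int) -> IPFMParams:
    return replace(
        params,
        hr0=params.hr0 * factors["hr0"],
        a_lf=params.a_lf * factors["a_lf"],
        a_hf=params.a_hf * factors["a_hf"],
        noise_sd=params.noise_sd * factors["noise_sd"],
        drift=params.drift * factors["drift"],
        seed=seed,
    )


def make_cohort(spec: CohortSpec) -> Cohort:
    """Generate a paired rest/stress cohort from subject-jittered templates.

    Each subject draws one multiplicative trait factor per parameter
    (``1 + N(0, between_subject_sd)``, clipped to [0.5, 1.5]) shared
    between their rest and stress records; the stress record draws an
    additional independent reactivity factor per parameter
    (``1 + N(0, reactivity_sd)``) so the magnitude of the stress
    response varies between subjects.  Record-level RNG seeds are
    spawned deterministically from ``spec.seed``.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    subject_seqs = root.spawn(spec.n_subjects)
    cohort = Cohort(metadata={"spec": _spec_dict(spec)})
    truth = {}
    param_names = ("hr0", "a_lf", "a_hf", "noise_sd", "drift")
    for i, seq in enumerate(subject_seqs):
        subject_id = f"S{i + 1:03d}"
        child = seq.spawn(3)
        rng = np.random.default_rng(child[0])
        trait = {
            name: float(np.clip(1.0 + spec.between_subject_sd * rng.standard_normal(), 0.5, 1.5))
            for name in param_names
        }
        reactivity = {
            name: float(np.clip(1.0 + spec.reactivity_sd * rng.standard_normal(), 0.4, 1.6))
            for name in param_names
        }
        truth[subject_id] = {}
        for condition, template, seq_cond in (
            (REST, spec.rest, child[1]),
            (STRESS, spec.stress, child[2]),
        ):
            record_seed = int(seq_cond.generate_state(1)[0] % (2**31 - 1))
            factors = trait
            if condition == STRESS:
                factors = {n: trait[n] * reactivity[n] for n in param_names}
            params = _jitter(template, factors, record_seed)
            params.validate()
            series = ipfm_rr(params, subject_id=subject_id, condition=condition)
            if spec.artifact_rate > 0:
                series, _ = inject_artifacts(series, spec.artifact_rate, record_seed + 1)
            cohort.add(series)
            truth[subject_id][condition] = asdict(params)
    cohort.metadata["true_params"] = truth
    return cohort


def _spec_dict(spec: CohortSpec) -> dict:
    d = asdict(spec)
    return d


def make_ratio_grid_cohort(n_records: int = 60, seed: int = 0,
                           duration_s: float = 300.0) -> Cohort:
    """One record per subject spanning a wide grid of LF/HF modulation
    amplitudes, for validating the IMF-energy surrogates against
    spectral band powers across autonomic balances.

    Amplitudes are log-uniform and independent — a_lf in [0.015, 0.06],
    a_hf in [0.025, 0.08] — so the LF/HF balance varies over ~12x,
    covering the rest-like (HF-dominant) through stress-like
    (LF-dominant) range.  The HF lower bound keeps the respiratory
    modulation steep enough (a_hf*f_hf > a_lf*f_lf) to create its own
    tachogram extrema: below that, EMD is structurally blind to the HF
    tone — a regime real sinus arrhythmia does not occupy.
    """
    if n_records < 10:
        raise ParameterError("ratio-grid cohort needs >= 10 records")
    root = np.random.SeedSequence(seed)
    cohort = Cohort(metadata={"kind": "ratio_grid", "seed": seed})
    for i, seq in enumerate(root.spawn(n_records)):
        rng = np.random.default_rng(seq)
        params = IPFMParams(
            hr0=float(rng.uniform(60.0, 90.0)),
            a_lf=float(np.exp(rng.uniform(np.log(0.015), np.log(0.06)))),
            a_hf=float(np.exp(rng.uniform(np.log(0.025), np.log(0.08)))),
            noise_sd=0.01,
            duration_s=duration_s,
            seed=int(seq.generate_state(1)[0] % (2**31 - 1)),
        )
        cohort.add(ipfm_rr(params, subject_id=f"G{i + 1:03d}", condition=REST))
    return cohort
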
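# Methods

`emdhrv` assesses acute mental stress from short (5-min) and
ultra-short (1–3-min) heart-rate-variability records.  Its core idea is
that the energies of the first intrinsic mode functions of the RR
tachogram are time-domain surrogates of the LF/HF spectral band powers,
which are unreliable on records shorter than ~4 min.  This note
documents the model, the numerical choices, and what the synthetic
cohorts do and do not establish.

## Pipeline

1. **Artifact screening.** RR intervals farther than 3 SD from the
   record mean are deleted in a single pass (mean and SD computed once,
   over the full record, before any windowing).  Surviving beats keep
   their original absolute times; the spline below bridges the gaps, so
   elapsed time — which segmentation depends on — is preserved.
   Screening is deliberately non-iterative: re-screening a cleaned
   record is only asserted to be a no-op on the test fixtures, not
   guaranteed in general.
2. **Tachogram.** A natural cubic spline through (beat time, RR)
   interpolates the irregular beat series; it is evaluated on a uniform
   8 Hz grid spanning the knot range (no extrapolation).  Natural
   boundary conditions are the least-assumptive standard choice.
3. **EMD.** The tachogram, minus its mean (a ~800 ms DC level that
   would otherwise dominate envelopes and energies; it is carried
   separately and restored on reconstruction), is sifted into IMF1–3
   plus a residual.  Completeness (`sum(IMFs) + residual + mean ==
   input`) holds to float precision by construction and is asserted on
   every decomposition in the tests.
4. **Features.** 26 per record (below).
5. **Relief-F ranking, linear-SVM LOSOCV.** Features are ranked per
   training fold (default) or once globally, z-scored with
   training-fold statistics, and classified with a linear SVM; each
   cross-validation fold holds out all records of one subject.

## EMD numerical choices

* **Sifting stop.** Cauchy criterion `sum((h_prev-h)^2)/sum(h_prev^2)
  < 0.2` (the classical threshold), *combined with* the two IMF
  conditions: |#extrema − #zero crossings| ≤ 1 and envelope mean within
  5% of the candidate's range.  Neither IMF condition is monotone in
  the sift count, so the Cauchy test alone can stop one pass short of a
  valid mode; requiring all three makes every accepted mode a bona fide
  IMF at the configured tolerance.  Hard cap: 100 passes.
* **Envelopes.** Cubic splines through the maxima (upper) and minima
  (lower), with 2 extrema mirrored about each end of the signal to
  suppress boundary swings.
* **Termination.** Decomposition continues while the residual has at
  least 3 extrema with at least one maximum and one minimum (the
  standard rule; mirroring supplies the boundary envelope knots even
  for a single interior extremum per side).  Fewer than 3 extractable
  IMFs raises an explicit shortfall error naming the record, because
  the feature set needs IMF1–3.
* **Extrema.** Strict local extrema; plateaus flanked by opposite
  slopes count once, at the plateau midpoint.  Zero crossings are sign
  changes with exact zeros attached to the preceding sign.
* **Tolerance sensitivity.** IMF energies are mildly sensitive to the
  stop rule and boundary depth; both are exposed in `SiftConfig` rather
  than hard-coded.

## The 26 features

| family | features | units |
|---|---|---|
| time domain | HR, SDNN, RMSSD, pNN30, pNN50, G-pNNx | bpm, ms, % |
| tachogram nonlinear/energy | PmEn, SpEn, Energy | nats, ms² |
| per-IMF entropy | PmEn_IMF1..3, SpEn_IMF1..3 | nats |
| IMF energy | Energy_IMF1, Energy_(IMF2+IMF3), Energy_IMF23/IMF1, Energy_IMF1/IMF123, Energy_IMF23/IMF123 | ms², ratios |
| per-IMF time domain | SDNN_IMF1..3, RMSSD_IMF1..3 | ms |

* SDNN is the sample SD (divisor N−1); RMSSD divides the summed squared
  successive differences by their count (N−1 differences); pNNx uses a
  strict `>` on |successive difference| vs x.
* **G-pNNx** derives its threshold x from the cohort's rest records:
  each record contributes its *median absolute successive RR
  difference*; the cross-subject distribution of these summaries is
  tested for normality (Kolmogorov–Smirnov against a normal with the
  sample's own mean/SD, α = 0.05) and x is the mean if normality holds,
  else the median.  The per-subject-summary construction is an
  interpretation — the alternative (pooling all successive differences)
  is defensible too — and is called out here because the choice changes
  x on skewed cohorts.
* **Entropies** are computed on the 8 Hz tachogram and its IMFs, not
  the raw RR list: the resampled series is what EMD decomposes, and the
  Nyquist argument bounding the permutation-entropy delay (τ ≤ 4 at
  8 Hz) only makes sense there.  Permutation entropy uses ordinal
  patterns of length m = 4 (valid for series of ≥ 5·4! = 120 samples,
  i.e. any window ≥ 15 s at 8 Hz), delay τ = 1 for the feature vector
  (τ is configurable 1–4; one feature slot means one τ, and 1 is the
  field default), natural logarithm, ties broken by time order.
  Sample entropy uses m = 2, Chebyshev distance, tolerance
  r = 0.2 × SD of the analysed series (segment-local, sample SD with
  ddof = 1), self-matches excluded, both template passes truncated to
  N−m vectors; an undefined result (no matches) propagates as NaN,
  never as 0.
* **Energies** are plain sums of squares.  The raw-signal "Energy"
  feature removes the tachogram mean first; IMFs are zero-mean by
  construction.  By Parseval's identity these equal integrated spectral
  power, which is what licenses reading Energy_IMF1 as an HF-band and
  Energy_(IMF2+IMF3) as an LF-band surrogate.  The normalised pair uses
  E123 = E1 + E23 (IMFs 1–3 only) and sums to 1 exactly.
* **Reference band powers** (for validating the surrogates, not part
  of the 26): Welch periodogram of the mean-removed tachogram, 64-s
  Hann windows, 50% overlap — long enough to resolve 0.04 Hz while
  averaging ≥ 8 windows over 5 min — integrated over LF [0.04, 0.15)
  and HF [0.15, 0.4] Hz by the trapezoid rule.
* HR = 60000 / mean(RR) in beats/min.

## Segmentation

Windows of 60/120/180 s are cut at three positions of the record span
T: first [0, d), middle [(T−d)/2, (T+d)/2), last [T−d, T].  An interval
belongs to the window containing its end time; windows are half-open on
the right except at the record end (closed there, so a full-span window
is the identity).  The lowest-mean-HR rule picks the rest record's
calmest window and cuts the paired stress record at the matched
position; the source sentence for this rule is ambiguous about which
state drives the choice, so both behaviours exist and the rest-driven
one is the default.  Outlier screening always runs on the full 5-min
record before windowing; segments are never re-screened.

## Relief-F

Deterministic two-class variant: every sample is visited, k = 10
nearest hits and misses (Manhattan distance on min-max-scaled
features), weight update ±diff/(n·k).  Weights are computed once per
training fold; "sequential removal of the lowest weight" with a fixed
weight vector is equivalent to sorting, so the ranking is a sort.
Per-fold ranking is the leakage-clean default; the global-ranking mode
exists to mirror analyses that rank on all data before
cross-validation, and both are reported when relevant.

## Classification

Linear SVM (sklearn `SVC(kernel="linear")`, C = 1), z-scoring per
training fold, stress as the positive class for precision/recall.
Undefined metrics (zero denominators) are NaN sentinels.  The
feature-count sweep runs LOSOCV at every count 1..26 of the ranked
order; the best count is the accuracy argmax with ties to the smaller
count.

## The synthetic cohort generator

No real recordings ship with the package, so an integral pulse
frequency modulation (IPFM) generator produces rest/stress cohorts with
the structure the method assumes.  Beats fire when the integral of

    m(t) = (hr0/60) · (1 + drift·t/T) ·
           (1 + a_lf sin(2π f_lf t + φ₁) + a_hf sin(2π f_hf t + φ₂) + ε(t))

crosses successive integers (integration on a 100 Hz grid, crossings by
linear interpolation — sub-ms beat accuracy).  Defaults:

* rest: hr0 = 70 bpm, a_lf = 0.03 at 0.10 Hz, a_hf = 0.06 at 0.25 Hz
  (respiratory sinus arrhythmia dominant at rest), drift 0;
* stress: hr0 = 85 bpm (+15), a_hf halved to 0.03 (vagal withdrawal),
  a_lf unchanged (so LF/HF balance rises), drift = −0.08 (heart rate
  adapts back toward baseline as the stressor continues);
* ε(t): band-limited 1/f noise over [0.03, 0.4] Hz, RMS 3%.  Real RR
  series carry a 1/f broadband floor under the LF/HF peaks; without it,
  1-min windows often contain no third oscillatory mode at all and EMD
  cannot deliver IMF3, which never happens on real data.  Variability
  below 0.03 Hz is left to the explicit drift term (slower components
  are pure trend inside a 1-min window).
* between-subject structure: one multiplicative trait factor per
  parameter and subject (SD 15%, about the spread of resting HR in
  young adults), shared by both records; plus an independent
  *reactivity* factor (SD 25%) on the stress record's parameters,
  because the magnitude of the autonomic stress response varies between
  people at least as much as its mean — without it the two classes are
  unrealistically separable and every classification experiment
  saturates at 100%.
* ectopic artifacts: a configurable fraction of intervals is replaced
  by spikes (2.4× the local 11-beat mean, emulating missed beats) or
  halvings (premature beats), with the corrupted indices reported so
  detector sensitivity can be measured.

Everything is driven by spawned `SeedSequence` streams: identical specs
give byte-identical cohorts.

**What the generator does not emulate:** real respiratory frequency
wander (the HF modulation is a fixed tone), circadian/posture trends,
true ectopy morphology, measurement jitter of R-peak detection, and any
coupling between HR level and variability amplitude.  Passing tests on
these cohorts therefore show that the pipeline recovers the structure
the model encodes — band-separated modulation, adaptation drift,
overlapping classes — not that accuracies measured on any human cohort
are reproduced.  Cohort-specific quantities (a concrete G-pNNx
threshold, a concrete accuracy percentage) depend on the recordings
they were derived from and carry no reference values here by
construction.

## Validation experiments and problem sizes

* **Band-power surrogacy**: 60 single-state records spanning
  log-uniform LF/HF modulation amplitudes (0.015–0.08 each,
  independent); Pearson r between IMF energies and Welch band powers.
* **Duration surrogacy**: each energy feature computed on the first
  60/120/180-s window vs the full 300 s, correlated across the default
  cohort's subjects per state; the conventional validity bar is
  r > 0.7.
* **Adaptation ordering**: 20 replicate cohorts of 14 subjects; first-
  vs last-window (180 s) LOSOCV accuracy with stress drift −0.08, and a
  zero-drift null arm checked with a sign test.  Replicate counts and
  cohort sizes were chosen so each experiment finishes in minutes while
  leaving the comparisons well inside their noise budgets.
* **Permutation null**: 20 label shuffles of the default feature table;
  the pipeline's mean accuracy must sit at chance (50%), which also
  functions as a leakage alarm.

## Known limitations

* EMD mode mixing: with closely spaced tones or strong noise, LF
  content can split across IMF2/IMF3 — this is why the slow-band
  surrogate uses their *sum*.
* The G-pNNx construction is one reading of an ambiguous procedure (see
  above).
* The 3-SD outlier rule is applied once per record; heavily corrupted
  records (> ~10% artifacts) inflate the SD and lower sensitivity.
* Sample entropy on 1-min windows is occasionally undefined (NaN
  sentinel) at low variability; downstream consumers must handle the
  sentinel rather than assume completeness.
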
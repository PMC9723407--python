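# Methods

This note documents the analysis pipeline implemented by `nremscope`: what
each stage computes, the parameter defaults and their rationale, the design
of the synthetic validation harness, and the numerical engineering choices.

## Scope and data model

The package analyzes non-REM sleep EEG microstructure from standard
polysomnography: two central channels (C3, C4) referenced to the
contralateral mastoid (A2, A1), a 30-s epoch hypnogram, and an
epoch-by-channel artifact annotation. All signal quantities are in
microvolts; "non-REM" throughout means N2 + SWS (N1 is excluded from all
signal analyses). R&K-scored hypnograms are accepted; stages 3 and 4 are
merged into SWS on read.

Processing chain per subject:

1. contralateral-mastoid re-referencing (C3−A2, C4−A1);
2. zero-phase 35 Hz low-pass (cosine-squared roll-off to 45 Hz) and
   resampling to 100 Hz;
3. channel-level artifact rule: a channel is excluded when strictly more
   than 20% of its non-REM epochs are flagged; otherwise its usable epochs
   are the unflagged non-REM epochs;
4. Welch spectrum and fast-spindle peak per channel;
5. spindle and slow-wave detection per channel in the usable epochs;
6. slow-wave/spindle coupling per channel;
7. sleep-architecture metrics from the hypnogram;
8. behavioral (finger-tapping) and clinical (HAMD) scoring when provided.

Events and coupling are detected per channel; subject-level values average
the two per-channel summaries. The subject spectrum is the mean of the
channel spectra.

## Spectral analysis

Welch power spectra use Hann-tapered 5-s intervals advancing in 1-s steps
*within* usable 30-s epochs (26 intervals per epoch; intervals never
straddle an epoch boundary, so excluded epochs cannot leak samples). At
100 Hz this gives a 0.2 Hz frequency grid, reported over 0.6–30 Hz. Power
is one-sided per-bin power in µV² with window power normalization: an
on-grid sine of amplitude A contributes A²/2 to its bin.

Group spectra are compared on dB-transformed values, `10·log10(power + 1)`
(the +1 offset keeps zero power at 0 dB), with a per-bin label-permutation
Welch t-test and the unbiased p estimator `(1 + k)/(n_perm + 1)`. The dB
domain was chosen for the group tests because spectral power is
approximately log-normal across subjects; the permutation machinery is
distribution-free either way, but dB keeps the t statistics well scaled.
No multiple-comparison correction is applied across bins, by design.

The individual fast-spindle peak (surrogate for visual peak scoring) is the
largest local maximum, inside 12–15 Hz, of the dB spectrum after removing a
linear trend fitted over 9–17 Hz. A peak is *confident* when its detrended
residual exceeds 0.5 dB; non-confident subjects are re-run with the group
average of the confident peaks (two-pass cohort procedure), clipped to
12–15 Hz.

## Spindle detection

| parameter | default | rationale |
|---|---|---|
| detection band | peak ± 1.0 Hz | individualized fast-spindle band |
| band-pass | Butterworth magnitude, order 4, zero phase | no phase distortion of event timing |
| envelope | RMS in 0.2-s sliding window | standard envelope smoothing |
| threshold | 1.5 × SD of band-passed signal over usable epochs | amplitude-relative criterion |
| merge gap | < 0.1 s | reunites envelope dips within one spindle |
| duration | 0.5–2.0 s | spindle duration window |
| amplitude | max − min of 10–16 Hz-filtered signal inside the event | fixed sigma band keeps amplitudes comparable across subjects with different detection bands |
| frequency | zero crossings / 2 / duration | cycle counting |

Zero-crossing frequency counting quantizes to half cycles, which bounds the
per-event frequency error at roughly 1/(2·duration) ≈ 0.2 Hz — this is the
dominant term in the observed ~0.22 Hz mean absolute error and is inherent
to the counting estimator, not noise.

## Slow-wave detection

Band-pass 0.3–1.5 Hz (order 3, zero phase), then delineation by
positive-to-negative zero crossings: a candidate is the span between two
consecutive down-crossings containing exactly one up-crossing, with
interpolated-crossing duration in 0.9–2.0 s (the 0.5–1.11 Hz class).
Candidates must lie entirely inside usable epochs (epoch-granular: every
epoch the candidate touches must be usable). Two *relative* amplitude
criteria then apply, per channel and night: |trough| ≥ 1.25 × mean candidate
|trough|, and trough-to-peak amplitude ≥ 1.25 × mean candidate amplitude.
Per-event frequency is defined as 1/duration exactly.

Because the amplitude criteria are relative to the candidate population,
the detector is only well-posed when large target waves sit on top of a
population of smaller candidate waves — which real non-REM sleep always
provides. The synthetic generator reproduces this structure explicitly
(see below).

## Slow-wave/spindle coupling

A spindle couples to a slow wave when its time marker falls in the window
from the SW trough (down state) to the SW end (next down-crossing). The
marker is the spindle's smoothed-envelope peak by default (`onset` and
`midpoint` are available); the envelope peak is the natural marker because
the generator places, and physiology times, the spindle's energy maximum
relative to the down state. Each spindle couples at most once, to the SW
with the earliest trough among those whose windows contain it. Delay =
marker time − trough time; *delay dispersion* — the subject-level SD (n−1)
of delays — is the primary coupling-accuracy index.

Known small bias: on noisy signals the detected trough sample shifts
slightly, producing a mean delay bias of about −0.011 s in the validation
harness, well inside the ±0.02 s recovery tolerance. It is a property of
trough localization under noise, not of the coupling assignment.

## Architecture, behavior, statistics

Sleep architecture: TST = N1+N2+SWS+REM epoch time; all stage percentages,
*including WASO*, use TST as denominator — an unconventional but deliberate
choice so the entire metric row shares one scale. WASO counts Wake epochs
between sleep onset and the last sleep epoch. Movement/unscored epochs count
toward neither TST nor WASO. Latencies are measured from sleep onset (first
epoch of any sleep stage; a first-N2 rule is available).

Tapping: 12 training runs + 3 morning test runs; training effect = mean of
last three training runs − run 1; consolidation = test mean − last-three
mean; absolute and relative variants, the relative one being the group
default. Clinical response: ≥ 50% HAMD reduction from baseline to day 28
(the boundary case counts as response).

Group statistics: single-pass 3-SD outlier removal against the pooled
two-group mean (unpaired designs only), Welch t (independent) or paired t,
two-tailed, plus a JZS Bayes factor with Cauchy prior scale r = 0.5
computed by adaptive quadrature over the inverse-gamma(1/2, 1/2) mixing
variable. An independent oracle (direct noncentral-t likelihood integrated
over the Cauchy effect prior) cross-checks the quadrature to ~1e-11
relative error. Pearson correlations and a moderation OLS
(y ~ x + m + x·m) complete the layer. No multiple-comparison correction.

## Synthetic generator

The generator produces everything the pipeline consumes, with a complete
ground-truth log of every injection (realized, sample-aligned onsets,
amplitudes, frequencies, and coupling delays — post-truncation sample
moments, not nominal parameters, are the recovery targets).

* **Hypnogram**: first-order Markov chain over {Wake, N1, N2, SWS, REM} at
  30-s resolution, starting in Wake. No explicit ultradian cycling — cycle
  realism is a non-goal for detector validation.
* **Background**: 1/f Gaussian noise (exponent 1.0), synthesized in the
  frequency domain, scaled per stage (6 µV RMS in sleep stages, 10 µV in
  Wake/Movement). The stochastic background is **high-passed below 2 Hz**:
  sub-cutoff activity belongs to the slow-wave class under test, so leaving
  it in the noise would constitute unlabeled events of exactly that class
  and make precision against the injection log ill-defined. Slow activity
  is instead modeled explicitly: large logged target SWs plus a logged
  population of small background waves (kind `bg_sw`, trough −10…−4 µV,
  2 per non-REM epoch) that give the relative amplitude criterion the
  candidate floor it is designed against. Background RMS is stationary
  across sleep stages because stage differences in real EEG are dominated
  by the oscillatory classes, which are injected explicitly.
* **Spindles**: Hann-enveloped sinusoids at a per-subject center frequency
  (13.5 ± 0.3 Hz across subjects, clipped to 12.2–14.8), 60 µV peak-to-peak
  at the envelope maximum, 0.9–1.5 s.
* **Slow waves**: one biphasic sine period, trough (at T/4) before peak
  (at 3T/4), so positive-to-negative zero-crossing delineation holds
  exactly and 1/duration is the exact event frequency. Targets: trough
  −90…−60 µV, peak 30…60 µV, duration 1.1–1.4 s.
* **Coupling**: a configured fraction of spindles is placed with envelope
  peak at SW trough + delay, delay ~ Normal(0.35 s, 0.10 s) truncated to
  [0, 0.75·T]. Group effects are multiplicative (delay-SD, SW amplitude,
  spindle density/amplitude) or additive (overnight gain, HAMD shift).
* **Mastoids**: independent 1 µV noise channels constructed so that
  contralateral re-referencing reproduces the constructed C3/C4 exactly.
* **Determinism**: all randomness flows from one seed through
  `numpy.random.SeedSequence` spawning; identical configs give
  byte-identical recordings and logs.

The default noise regime is a *clean validation regime*: band SNR is well
above the detectability floor. The recovery harnesses therefore validate
detector and pipeline correctness against known truth; they do not estimate
performance on noisy clinical recordings, where sensitivity/precision
depend on SNR and scorer criteria.

## Validation harnesses

`nremscope.validation` regenerates seeded synthetic data and scores the
pipeline against the logs:

* `event_recovery` — sensitivity/precision (greedy best-overlap matching,
  ≥ 0.25 s), amplitude and frequency errors, over seeded 8-h nights.
* `coupling_recovery` — detected delay mean/SD vs the realized injected
  sample moments.
* `spectral_type_i`, `welch_type_i` — empirical type-I error of the
  permutation spectral test (pooled over bins) and the Welch t-test under
  simulated nulls. The permutation harness uses 199 permutations per
  replicate (the p estimator is unbiased at any permutation count; the
  pipeline default for real analyses remains 10,000).
* `bf10_grid_check` — Bayes-factor quadrature vs the noncentral-t oracle
  over a (t, n) grid.
* `dispersion_group_power` — the end-to-end replication: control vs
  patient cohorts (n = 20/20) with the patient delay-SD multiplied by 1.5,
  at reduced night length (2 h), full pipeline per subject, Welch t on the
  per-subject delay dispersions. The **null arm reuses the same runs**:
  control groups from two different replicates form an exact null pair
  (identical generating process, independent seed streams), likewise
  patient–patient; pairing disjoint replicates yields as many independent
  null tests as replicates at no extra simulation cost. Reduced problem
  sizes (240-epoch nights, denser events: 1.0/epoch each, coupled fraction
  0.7, no artifacts) keep per-subject dispersion estimates stable at 2-h
  length; these are harness conditions, chosen up front, not tuned values.

## Numerical engineering

* **Zero-phase filtering** is done in the frequency domain with real,
  symmetric magnitude responses (exactly zero phase): a raised-cosine
  low-pass for preprocessing and the analytic Butterworth magnitude
  |H| = 1/√(1+s^2n), s = (f²−lo·hi)/(f·(hi−lo)), for detection bands.
  Signals are reflect-padded (4 periods of the low band edge) so ringing
  decays inside the padding. A per-channel `ZeroPhaseFilterBank` caches one
  forward FFT and pays one inverse FFT per band; at 100 Hz the
  preprocessing low-pass is composed into the bank's responses (responses
  multiply in the frequency domain), which removes a full FFT round trip
  per channel.
* **FFT lengths** are rounded up to `odd · 2^k` with odd ∈ {1,3,5,9,15,
  25,27,45}: these radix-2-dominated lengths run measurably faster in
  pocketfft than the nearest 5-smooth length (~35% on 8-h channels).
* **Precision policy**: the signal path is float32 end to end — 16-bit EDF
  quantization dominates any float32 rounding — while numerically fragile
  accumulations upcast to float64: Welch across-interval means, envelope
  SDs, slow-wave candidate means, and the permutation test throughout (its
  E[x²]−E[x]² variance form cancels catastrophically in single precision).
* **Throughput**: one 8-h, 2-channel subject analyzes in ≈ 1.3 s; the
  2-h cohort subjects in the power replication in ≈ 0.2 s, putting the
  100-replicate end-to-end power study at ≈ 14 min on one CPU.
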
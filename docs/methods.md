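# Methods

This note documents the models, algorithmic conventions and design choices
behind `lowsuite`, in the spirit of a package methods appendix. It explains
what each stage computes, why the defaults are what they are, and what the
synthetic validation does and does not establish about real recordings.

## Event detection

### Interictal discharges

A discharge candidate is a span where two multiplicative envelope thresholds
hold simultaneously: the Hilbert envelope of the 20–80 Hz band-passed signal
exceeds 3.5× its channel mean, and the envelope of the raw signal exceeds 4×
its channel mean. Each contiguous span yields one candidate at the raw
absolute peak. Candidates on contacts of the same anatomical region within
±0.3 s are deduplicated greedily by descending absolute amplitude, removing
volume-conducted duplicates. Because both thresholds are proportional to
per-channel means, detection is invariant to channel gain, and means are
computed over unmasked samples only, so artifact masks cannot bias the
thresholds.

All filtering in the package is zero-phase (second-order Butterworth applied
forward and backward via `sosfiltfilt`). The zero-phase choice preserves
trough and peak latencies, on which every downstream peri-event window
depends; the price is an effective doubling of the filter order, which is
immaterial for threshold detectors.

The original clinical procedure added manual curation of candidates. This
implementation is the automated rule only — a known fidelity gap on real
data, irrelevant for the artifact-free synthetic scenario.

### Local wake slow waves

Candidates are *half-waves*: spans between consecutive zero-crossings of the
0.5–4 Hz filtered signal with durations of 0.25–1 s inclusive (i.e. 0.5–2 Hz
oscillatory frequency). A zero-crossing time is the first sample of the new
sign. Three filters then apply, in order:

1. **Post-discharge exclusion.** Candidates whose onset lies in
   `(t_IED, t_IED + 1 s]` for any discharge detected in the same region are
   discarded — detected slow waves must not be post-discharge waves.
2. **Amplitude gate.** Within each channel and each polarity, the
   nearest-rank 90th percentile of absolute extremum amplitude is computed
   over the surviving candidates, and only candidates *strictly above* it
   are retained. Gating per polarity keeps negative- and positive-wave
   detection symmetric; nearest-rank with strict inequality retains exactly
   the top decile for distinct amplitudes. Groups with fewer than 10
   candidates are skipped with a warning.
3. **Features.** Amplitude is the polarity-matched extremum of the filtered
   signal in the 1 s window after onset; slope is amplitude divided by the
   post-onset extremum delay; frequency is `1/(2·(zc₂ − zc₁))`. Absolute
   amplitude and slope are normalized to [0, 1] by each patient's maximum.

Polarity naming follows the down-state convention: under a common reference,
the down-state wave (nSW) has a *positive* extracellular LFP extremum
(hyperpolarized, silent neurons). A `nsw_positive_lfp` flag flips the mapping
for inverted display conventions.

A consequence worth knowing: the band-pass filter shortens a half-wave
slightly (edge lobes pull the crossings inward, ~10–15% for a 0.4 s
half-sine), so detected durations and the derived frequencies are biased
slightly high relative to the planted kernel. This is a property of every
zero-crossing detector built on a causal-band filter, not of this
implementation; tests assert duration validity rather than sample-exact
round-trips.

### Rates

Event rates are events per second per electrode. When requested, the rate is
refractory-corrected: the union of the 1 s spans following each discharge is
subtracted from the denominator (union, so overlapping spans are not double
counted). The discharge-corrected wave rate is the product of the wave rate
and the discharge rate, used to compare cohorts whose discharge burden
differs.

## Spectral estimation

- **Welch.** 4 s Hamming segments, 50% overlap. Band power is the mean PSD
  over the band, natural-log transformed where the analysis calls for log
  power. Total Welch power matches the signal variance (Parseval) within 5%.
- **Multitaper.** Event-locked high-gamma (45–130 Hz) power uses DPSS tapers
  with a 10 Hz half-bandwidth — wide because the windows of interest are
  short (0.1–0.315 s); the taper count is `max(⌊2·NW − 1⌋, 1)`. The estimate
  is scaled so that band power equals the variance of band-limited noise
  (units µV²). The down-state window is −0.15 to 0.165 s around the trough
  (the zero-crossings of the average wave); baselines are −2.9 to −0.2 s and
  0.2 to 2.9 s. Positive-wave and discharge analyses are *not* baseline
  corrected, because their baselines contain genuine power changes.
- **Morlet.** Seven-cycle wavelets over 1.5–130 Hz on ±3 s epochs. The
  t-statistic map is a one-sample t across events of log baseline-corrected
  power per pixel (the conversion is not standardized in the literature;
  this is the package's definition, and under null epochs the map is
  approximately standard normal). A useful identity under MNE's wavelet
  normalization: mean wavelet power integrated over frequency and divided by
  the sampling rate estimates the one-sided PSD integral, so
  `morlet_band_variance` returns band variance directly and cross-checks the
  multitaper scale within 20%.
- **Control times.** Matched null event times are drawn uniformly over
  admissible time — the recording minus exclusion intervals (±3 s around
  real events, artifact spans) and an edge margin — with 2× as many controls
  for wave analyses and 1× for discharge analyses; the firing analysis uses
  5× for a stabler baseline.

## Coupling and unit firing

The peri-stimulus time histogram counts modulated events in lag bins around
each index event, converts to a rate, convolves with a unit-area 0.5 s
Hanning kernel (area is conserved: the histogram is computed on a window
extended by the kernel half-width), and normalizes by the number of index
events and electrodes. Significance uses the simplest exchangeable null —
re-drawing index times uniformly over admissible time, preserving their
count — with 5000 replicates; per 0.1 s bin, the two-sided add-one
percentile p is FDR-adjusted across bins of the window of interest (±1 s for
wave pairs, 0–2 s for discharges after waves, whose rate is structurally
zero in the second before a wave). The long-term test fits a least-squares
slope to the discharge rate over 0–60 s after each wave, per patient, and
applies a one-sample Wilcoxon test across patients.

Unit firing traces convolve the spike train with a unit-area Gaussian kernel
of 0.2 s total support (σ = 0.2/6 s, truncated ±3σ; the parameterization is
ambiguous in the field, so σ is exposed). Peri-event matrices are normalized
by the across-epoch mean (±3 s epochs), making all statistics invariant to
global rate scaling. Units below 2 Hz mean rate are discarded (strictly
below; both whole-recording and baseline-window criteria are supported). The
time-resolved bootstrap compares per-patient mean rates at 10 Hz resolution
against control-locked rates, building the null by switching condition
labels within patients 5000 times, two-tailed add-one percentile p, BH-FDR
across the 21 bins of ±1 s.

**Discreteness caveat.** With n patients the label-switching null has only
2ⁿ distinct patterns, so the two-sided add-one p cannot fall below ~2¹⁻ⁿ·2.
At n = 8 the floor is ~1/64; after BH correction across 21 bins, a q < 0.05
rejection then requires at least seven floor-level bins, which a ~0.4 s
down-state cannot span. Window-level decisions (the p at the a-priori trough
bin) are therefore the appropriate rejection rule at small n, and the
per-bin p is verified to be calibrated under the null.

## Mixed models and estimation statistics

All trend analyses share one model: a common slope with per-patient random
intercepts, fit by REML (`statsmodels` MixedLM), Wald p for the slope.

- **Wave features before discharges.** Normalized slope and amplitude are
  regressed on the negated time to the next same-region discharge (so a
  positive β means growth as the discharge approaches), with time since
  recording start as a fixed nuisance covariate (the fuller random-effects
  structure is not identifiable from the available description) and
  Bonferroni–Holm correction across the two features.
- **High-gamma ramp.** For each patient, T* is the largest whole second such
  that at least half the discharges have a preceding inter-discharge gap
  ≥ T* (equivalently the ⌈n/2⌉-th largest gap, floored); discharges with gap
  ≥ T* are analyzed in 1 s multitaper windows tiling the T* seconds before
  the discharge (with a 0.1 s guard before the sharp transient), log
  high-gamma power regressed on bin time. Patients with T* < 2 s are
  excluded.
- **Delay effect.** Log high-gamma power in ±0.05 s around each discharge is
  regressed on the delay since the last wave trough on the same channel
  (region scope selectable); discharges with no prior wave are dropped and
  counted.
- **Behavior.** Per-trial rates are events-in-span over trial duration.
  Reaction time in retrieval trials is regressed on the wave rate with the
  discharge rate as covariate, plus an accurate-trials-only refit; accuracy
  effects are paired tests of per-patient mean rates in high- vs
  low-accuracy trials per phase and event kind.

Paired estimation statistics report the mean paired difference with a BCa
bootstrap 95% CI and a sign-flip permutation p (exhaustive enumeration for
n ≤ 14, which includes the identity permutation and therefore never returns
p = 0; Monte Carlo with add-one correction above that).

The PRV index is read with patient-wide totals:
`PRV = Σₙ (iedₙ/swₙ − Σied/Σsw)²`. This is the only reading under which
exact proportionality of per-electrode rates gives PRV = 0, which is the
index's purpose (testing whether wave-rate variability across electrodes
merely tracks discharge-rate variability). Electrodes with zero wave rate
are excluded with a warning; a single electrode gives 0 identically.

## The synthetic generator

The generator is first-class, tested code. It plants, per channel:

- **Background** — broadband 1/f^α noise (spectral synthesis, α = 1,
  rms 20 µV, 0.15 Hz acquisition-like high-pass) plus a fast-delta/low-theta
  band (3–6 Hz, rms 17.5 µV) and a narrow alpha rhythm (9.7 Hz, rms 6 µV).
  The theta term is what makes the background *wake-like*: hippocampal wake
  LFP is theta-dominated, and its short half-waves fall below the 0.25 s
  duration floor, which controls how many background candidates compete in
  the amplitude gate. The alpha term provides the alpha-peak feature used in
  vigilance checks.
- **Slow waves** — half-sine half-waves (analytically known crossings,
  amplitude and slope), amplitude N(150, 25²) µV, half-duration
  N(0.385, 0.08²) s truncated to [0.25, 1] (median frequency 1.3 Hz), both
  polarities at 50/50, 10% of events as trains of three alternating
  half-waves, renewal process at 0.108 events/s with a 2.5 s dead time so
  plants stay isolated. Wave events are vetoed near same-region discharges
  so ground truth matches the detector's exclusion semantics. Optional
  drift knobs scale amplitude/slope toward the next discharge.
- **Discharges** — Ricker (Mexican-hat) sharp component, width 0.05 s
  (spectral peak ≈ 36 Hz, dominant energy inside the 20–80 Hz detection
  band), peak 220 µV ≈ 8× the composite background rms, followed by a half-
  sine after-wave of opposite sign (40 µV, 0.5 s) — the after-wave exists
  precisely so the post-discharge exclusion and the amplitude-decay control
  have something to reject; Poisson-like renewal at 0.01/s.
- **High-gamma carrier** — 45–130 Hz noise (rms 5 µV) whose envelope is
  multiplied by (1 − s) inside wave spans (default s = 0.5, power ratio
  0.25), whose log power ramps linearly over the 60 s before each discharge
  (default 0.015 log(µV²)/s ≈ 1 log unit per 66.5 s), and whose power around
  each discharge scales as exp(g·delay-since-last-wave) (g = 2·10⁻³
  log(µV²)/s); the discharge kernel amplitude carries the same delay factor
  so that measured discharge power is log-linear in delay.
- **Spikes** — inhomogeneous Poisson trains (3 units, 3–8 Hz) thinned by
  (1 − s) inside wave spans, default s = 0.3.
- **Trials** — 27 encoding trials (6 s) and 27 retrieval trials (2–6 s);
  retrieval RT = 1.5 + 0.56·(within-trial wave rate) + N(0, 0.3²) s;
  accuracy is high with probability 0.85 − 5·(within-trial discharge rate),
  clipped to [0.05, 0.95].

One master seed fans out to per-component child streams
(`numpy.random.SeedSequence`), so outputs are byte-identical across runs and
platforms.

### The committed calibrated scenario

The default configuration (3 hippocampal channels × 3600 s at 512 Hz) is
calibrated — once, committed, and not revisited — so that planted half-waves
constitute ≈10% of the duration-valid candidates per channel and polarity.
This is the regime the percentile gate presumes: the planted high-amplitude
waves dominate the top candidate-amplitude decile, so the gate retains
essentially exactly them, and the detected down-state-wave rate lands in the
awake hippocampal regime (≈0.055–0.06 s⁻¹ electrode⁻¹ after refractory
correction, with discharge rate ≈0.01 s⁻¹ electrode⁻¹). The calibration
knobs were the theta rms (which dilutes background candidates) and the wave
event rate; their committed values are the package defaults.

### What the generator does and does not emulate

It reproduces the *statistical structure* each analysis assumes: spectral
background, isolated transients with controlled amplitudes and timing,
multiplicative down-state suppression, log-linear excitability trends,
linear RT coupling, Poisson spiking. It does **not** attempt biophysical
realism: no neural-mass dynamics, no seizures, no artifacts, no propagation
or volume-conduction geometry, no spike-waveform or sorting noise
(spike times are inputs in real use too), and planted waveform kernels are
idealized shapes. Passing the validation suite therefore demonstrates that
the pipeline recovers what it claims from data satisfying its assumptions —
it does not certify detector performance on clinical recordings, where
curation, artifacts and non-stationarity matter.

## Validation design and problem sizes

The end-to-end suite (`tests/test_acceptance.py`) checks, at a fixed seed:

1. **Detector fidelity** on the committed scenario: discharge and wave
   recall/precision ≥ 0.9 against planted truth (±50 ms / ±0.1 s matching).
2. **Down-state recovery power**: over 100 replicated 8-patient cohorts with
   high-gamma suppression 0.5 and firing suppression 0.3, the paired
   high-gamma test and the time-resolved firing bootstrap (judged at the
   a-priori trough bin, see the discreteness caveat) reject at p < 0.05 in
   ≥ 80% of replicates. Cohort sizes (20–50 waves per patient, 3 units,
   ~5 min of signal per patient at 384 Hz for the high-gamma part) are the
   package's validation sizes, chosen to keep the suite fast while leaving
   the tests well-powered.
3. **Null calibration**: with nothing planted, the paired permutation test,
   LMM Wald test, PSTH bootstrap and firing bootstrap all reject at
   0.05 ± 0.02 (per-bin, uncorrected where bins exist; family-wise q
   rejection ≤ 0.07), over 250–600 replicates.
4. **Trend recovery**: the planted wave-amplitude drift (2·10⁻⁵ normalized
   units/s), high-gamma ramp (0.015 log(µV²)/s), delay gain
   (2·10⁻³ log(µV²)/s) and RT coupling (0.56 s²) each fall within 2 standard
   errors of their mixed-model estimate in ≥ 95% of 200 replicates. Note
   that a 2·SE Wald interval has ≈95.4% nominal coverage, so this band sits
   essentially at its own expectation and individual runs fluctuate around
   the threshold by binomial noise (±1.5 percentage points at 200
   replicates).
5. **Oracle equivalence**: PRV, Holm, BH, the percentile gate, half-wave
   extraction and the permutation p agree exactly with independent
   brute-force implementations (exhaustive enumeration up to n = 12).
6. **Spectral sanity**: Parseval within 5%; a planted envelope suppression
   of 0.5 yields a measured in-span/baseline multitaper power ratio of
   0.25 ± 0.05.

`scripts/acceptance.py` recomputes the headline quantities from scratch at a
caller-supplied seed: the corrected wave rate of the committed scenario
(one 3-channel hour), the detected discharge rate on planted single-channel
recordings (forty 3000 s recordings averaged, to keep the Poisson counting
noise of ~30 events per recording from dominating the estimate), and the
proportional-rates PRV.

## Known limitations

- Manual curation steps of the original clinical workflow are not modeled.
- The amplitude-gate percentile scope (per channel and polarity) is one of
  several defensible readings; it is a parameter, and sensitivity to pooling
  across channels or polarities can be tested by calling the gate directly.
- EDF export is not implemented (no writer available in the supported
  dependency set); the HDF5 container is the round-trip format.
- The oscillatory-content control around detected waves is not implemented
  (its definition is not available); wave/delta-power decorrelation can be
  computed from the provided Welch and rate primitives instead.
- Mixed models use a single random-intercept structure; per-patient random
  slopes are not fit.
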
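# Methods

`adreflex` implements a complete, testable analysis for detecting autonomic
dysreflexia (AD) from non-invasive sensors in a rat model of high spinal cord
injury. Because no recordings of this kind are publicly deposited, the package
pairs the analysis with a synthetic-data generator whose construction encodes
the physiology the analysis is designed to detect; every detector and the
classifier are scored against the generator's ground truth, never against
themselves.

## The physiological model

AD is an episodic hypertensive reflex triggered by noxious stimuli below the
lesion (here, colorectal distension, CRD). Its defining signature is a
*sympathovagal cascade*: a burst of sympathetic discharge at trigger onset,
followed tens of seconds later by a compensatory vagal surge with bradycardia,
on top of a systolic blood-pressure (SBP) rise of at least 15 mmHg and a mean
arterial pressure (MAP) rise of at least 10 mmHg.

Four channels are modeled, with the acquisition characteristics of the
experimental rig they emulate:

| channel | rate | units | content |
|---|---|---|---|
| ECG | 10 kHz | mV | template QRS-T complexes at simulated beat times + Gaussian noise |
| skNA | 10 kHz | µV | broadband noise + band-limited (550–950 Hz) burst packets |
| BP (tail cuff) | 1/30 s | mmHg | systolic + diastolic samples; MAP = DBP + (SBP−DBP)/3 |
| skin temperature | 2 Hz | °C | slow drift around 34 °C; recorded but unused, as in practice |

### Beat process

NN intervals follow `nn(t) = µ0·m(t) + slow + g(t)·white`, with the baseline
mean µ0 drawn per animal from 60000/HR, HR ~ N(400, 20²) bpm; `slow` is an
AR(1) component (sd 3 ms, φ = 0.95) and `white` is beat-to-beat jitter
(sd 2 ms). The modulators m(t) (mean multiplier) and g(t) (jitter gain) carry
the class effects:

* **AD (successful CRD)** — a Gaussian vagal bump (width 30 s) starting
  `vagal_lag_s` = 30 s after onset and peaking 90 s after onset lengthens NN by
  up to 15% (`ad_bradycardia_frac`) and triples the jitter
  (`vagal_jitter_gain_ad` = 3), raising RMSSD and pnn5.
* **Startle** — NN shortened 10% (tachycardia) and jitter doubled during the
  stimulus minute, tapering exponentially (τ = 15 s) afterwards.
* **Tail pinch** — jitter halved (vagal inhibition → pnn5 falls), no HR change.

Because the modulators depend on absolute time, which depends on the beats,
beat times are resolved by a short vectorized fixed-point iteration (three
passes; the modulators vary over ~30 s, so convergence is immediate).

### Sympathetic bursts

Burst onsets follow an inhomogeneous Poisson process (thinning algorithm with
a 150 ms dead time): 2 bursts/min at rest, plus a surge for CRD
(20 extra bursts over the stimulus minute) and startle (15) whose rate decays
exponentially from onset (τ = 30 s), so it bleeds into early recovery —
transition windows after the epoch genuinely resemble stimulus windows, as in
real recordings. Tail pinch doubles packet *amplitude* without changing the
rate (`iskna_gain_tailpinch` = 2). A packet is a Hann-windowed two-tone
carrier (550–950 Hz), 0.1–1 s long, amplitude 4 µV × LogNormal(0, 0.3).

### Blood pressure and trial outcome

Each trial ramps SBP/DBP linearly over the stimulus minute and decays
exponentially (τ = 120 s) in recovery, sampled on the 30-s cuff grid with
1.5 mmHg noise. Injected deltas: AD +20/+14 (SBP/DBP, MAP ≈ +16), startle
+7/+1, tail pinch +5/+0.4. A CRD trial "succeeds" with probability
`ad_success_prob` = 0.7; failed trials keep the sympathetic surge but
attenuate the ramp to 20–75% of the 15-mmHg threshold and damp the vagal
response to 30% — they are the realistic negatives the labeling stage must
reject.

### Cohort layout

One recording per animal × trial day (days 7, 9, 11, 14 post-injury): a 60-s
quiet baseline then three CRD trials (1-min stimulus, 10-min recovery) plus,
on a random 75% of days each, one startle and/or one tail-pinch trial, in
seeded random order. The default cohort is 4 animals × 4 days ≈ 2900 windows
of 15 s. The modeling stage reduces these to exactly 2200 windows with an
*event-centered* composition: every window from 1 min before a stimulus onset
to 2.5 min after the stimulus end is kept, and the remainder is padded with
seeded quiet windows. An AD episode and its surroundings span roughly 15–20
windows, so the informative data points cluster around events rather than
spreading uniformly over day-long recordings (most of which is quiet
recovery); the practical consequence is that the non-stimulus class
is rich in transition windows (vagal tails, decaying sympathetic surges,
sub-threshold CRD responses), which is what makes it the hard class.
Four animals rather than a full 13-animal study keeps a complete run at 10 kHz
in the minutes range while leaving every per-window statistic unchanged; the
truth-only mode (`render=False`) simulates a 13-animal cohort in well under a
second for trial-level checks such as the CRD→AD conversion fraction.

### What the generator does *not* emulate

No baroreflex dynamics (BP and HR effects are injected independently), no
motion artifacts or electrode noise beyond stationary Gaussian noise, no ECG
leakage into the skNA channel, no arrhythmias or ectopy beyond what the noise
produces, no anesthesia/restraint stress drift, and no inter-animal
correlation structure. Passing tests therefore demonstrate that the analysis
recovers the cascade *when it is present as modeled*, not that it would
survive every artifact of a real rig.

## Signal conditioning

* ECG band-pass 0.5–100 Hz (2nd-order Butterworth); skNA band-pass
  500–1000 Hz (4th-order) — the standard neuECG band separating nerve spikes
  from cardiac content. All filtering is zero-phase (`sosfiltfilt`) so beat
  and burst timestamps carry no group delay into the 15-s windows. Edge
  padding is set to 6 time constants of the low band edge (minimum 0.2 s):
  with scipy's default padding the 0.5-Hz transient breaks the time-reversal
  symmetry that zero-phase filtering promises.
* R peaks: derivative → squaring → 30-ms moving-window integration → peak
  picking with a 100-ms refractory period and an adaptive threshold (25% of
  the 99th percentile of the integrated energy), then refinement to the local
  ECG maximum within ±20 ms. Tuned for rat rates (~400 bpm); returns an empty,
  flagged series instead of raising when nothing is found.
* NN cleaning: RR intervals deviating more than 20% from an 11-beat centered
  running median are rejected (a standard ectopic-beat filter; the tolerance
  and window are arguments).
* iskNA: moving average of |filtered skNA| over 100 ms. Baseline statistics
  are the median and 1.4826×MAD over stimulus-free segments (robust to the
  bursts themselves).
* Bursts: maximal intervals with iskNA > baseline + 3σ lasting ≥ 50 ms, gaps
  < 100 ms merged, **and** peak ≥ baseline + 5σ. The peak requirement is
  needed because a 100-ms-smoothed noise envelope crosses a 3σ level about
  twice per minute and stays above it for ~50 ms by construction; genuine
  bursts exceed baseline by two orders of magnitude, so the peak gate removes
  essentially all false positives at no sensitivity cost. Both multipliers
  are arguments (`threshold_k`, `peak_k`).

## Features, scaling, labels

Five features on non-overlapping half-open 15-s windows aligned to the
recording start (stride configurable): burst count, mean iskNA (sympathetic);
medianNN, RMSSD, pnn5 (vagal). pnn5 is read as the percentage of *successive
NN differences* exceeding 5 ms — the rat-scale analogue of pNN50; the absolute
intervals are two orders of magnitude larger than 5 ms, so only the
differences reading yields a vagal index. NN features use intervals whose
terminating beat falls in the window; windows with fewer than three NN
intervals are flagged invalid and excluded. An optional extended bank
(time-domain HRV, burst morphology, iskNA quantiles) exists to exercise
chi-squared feature selection; it makes no claim of reproducing any
historical 36-feature inventory.

Normalization is min-max within each (animal, trial-day) group — the scaling a
day's recording session supports in deployment. Because group extrema include
test-day windows, this leaks information across the later split; a
`train-only` mode fits extrema on training windows alone, clips test values to
[0, 1], and reports the fraction of out-of-range test values (the leakage
audit). The same-day mode is the default because it is the protocol being
reproduced.

A window inherits a stimulus label when ≥ 50% of it overlaps the labeled
interval. For startle and tail pinch that interval is the stimulus epoch. For
CRD trials that passed the blood-pressure criteria it is the *AD episode*:
onset through 90 s past the stimulus end — the end of the modeled vagal phase
(30 s lag + 120 s duration) and the span over which pressure, bradycardia and
vagal indices are actually abnormal. Labeling only the 1-min distension epoch
was tried first and proved wrong on its own terms: the windows with the
strongest vagal signature fell *outside* the AD label (the late-epoch window
had 9% recall), which contradicts how the AD event is described and windowed
in this literature (an episode spanning many 15-s windows, with the vagal peak
after the distension). Failed-CRD windows and everything else are `none` —
which is why `none` is the hard class: it contains decaying surges,
post-episode tails and sub-threshold CRD responses.

## AD labeling

A CRD trial is AD when, relative to the mean of cuff samples in the 120 s
before onset, peak SBP within onset→epoch-end+120 s rises ≥ 15 mmHg **and**
peak MAP rises ≥ 10 mmHg (inclusive; an `audit` mode reports the MAP margin
without enforcing it), with two auxiliary checks on by default: at least one
detected burst between onset and the SBP peak, and mean beat-derived HR in the
30–180 s window after onset below the pre-onset mean by more than twice its
standard error. The 120-s peak grace period operationalizes "rapid"; the
2-SE margin operationalizes "significant bradycardia". All thresholds are
fields of `ADCriteria`, and every verdict carries its full criteria breakdown
for threshold-sensitivity audits. Cohort conversion rates are reported with a
Wilson 95% CI.

## Classifier

A five-layer feed-forward network: 5 input features, ReLU hidden layers
(default 32/16/8 — the layer widths are not derivable from any published
rule, so they are config), and one logistic output unit (binary) or one
softmax unit per class (4-way). Data are split 70/15/15 with stratification
(exact split totals; per-class counts within one window of exact). Protocol:
train on the 70%, early-stop on the 15% validation split (patience 20 epochs
on log-loss, best weights restored), report on the 15% test split; stratified
10-fold cross-validation measures stability (each fold re-carves 15% of its
training portion for early stopping). Optimization is scikit-learn's Adam MLP
driven by an explicit `partial_fit` loop, because its built-in early stopping
cannot monitor an external validation set. Binary decisions threshold the AD
probability at 0.5; no class reweighting by default (an optional
seeded-oversampling `class_weight="balanced"` flag exists). Trained weights
freeze into a JSON bundle with a pure-numpy forward pass, so persisted models
are independent of scikit-learn internals.

"Most-confused class" (the structural claim that non-stimulus windows are the
main source of false detections) is operationalized on the pooled CV confusion
matrix as the true class contributing the most *false-positive* errors —
samples predicted as an event class other than their own. Missed detections
(event windows predicted as non-stimulus) are already accounted by per-class
sensitivity, and plain off-diagonal row sums turn out to be uninformative
here: with a sharp label boundary on a smooth physiological signal, the AD and
non-stimulus classes each misclassify roughly one boundary window per trial,
so their total error counts tie to within sampling noise. The false-positive
count is the stable structure: virtually every false alarm originates from a
non-stimulus window (decaying surges, failed-CRD trials), while AD errors are
almost exclusively missed detections.

## Statistics

Welch t-tests (AD vs non-AD, per feature), one-way ANOVA across the three
stimuli with per-stimulus vs-baseline t-tests alongside, all at α = 0.01;
feature selection by chi-squared on quartile-binned features. Outliers are
removed in a single pass per feature per group at |z| > 3 (sample SD,
ddof = 1). No multiple-testing correction is applied; the report carries the
number of tests so a reader can correct externally. With two groups the ANOVA
F equals the squared pooled t statistic, which the suite verifies to 1e-9.

## Numerical and reproducibility choices

* All randomness flows from one integer seed through purpose-split
  `numpy.random.Generator` streams (plan/beats/bursts/noise/BP per recording,
  keyed by animal id and day), so truth-only and fully rendered runs agree
  bit for bit and fixed-seed pipeline reruns produce byte-identical artifacts
  (hashes in `manifest.json`).
* Waveforms are synthesized and filtered in float32 (a day-long 10-kHz
  channel is ~135 MB); recordings are streamed one at a time through the
  pipeline so memory stays flat in cohort size.
* Degenerate cases: constant feature in a scaling group → 0.0 with a warning;
  zero-variance group in outlier removal → nothing removed, warning;
  σ = 0 iskNA baseline → absolute-floor threshold, warning; empty peak list →
  flagged empty beat series, not an exception.
* CSV floats are printed with `%.10g` so float32 samples round-trip exactly.

## Known limitations

* The bradycardia check compares HR means by a 2-SE margin rather than a
  model-based test; it is a deliberately simple surrogate.
* Repeated measures per animal are ignored by the t-test/ANOVA battery (no
  mixed-effects modeling), matching the reproduced analysis plan.
* Tail-cuff sampling every 30 s undersamples fast SBP spikes; near-threshold
  trials can flip label purely through cuff noise. The labeling/truth
  agreement is therefore expected to sit near, not at, 100%.
* No claim is made of reproducing performance figures from animal
  experiments: no recordings of this kind are publicly deposited, so
  classifier quality is assessed against synthetic cohorts whose difficulty
  is set by the generator defaults above.
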
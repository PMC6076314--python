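# Methods

This note documents the models, conventions and numerical choices behind
`gazedecode`, in the spirit of a methods appendix: what is simulated and
why, how each analysis stage is defined, and where the design was
genuinely open.

## 1. The generative model of fixational gaze

One simulated participant is a schedule (sessions × runs × trials) plus
one continuous binocular recording per run at 1000 Hz with channels
`xl, yl, xr, yr` (degrees of visual angle, DVA), `pl, pr` (pupil,
arbitrary units) and per-eye blink masks.  The position signal is the
sum of three classical components of fixational eye movement plus
blinks.

**Microsaccades.**  A Poisson master process at `microsaccade_rate`
(default 1.5 events/s, within the 1–2/s range typical of attempted
fixation) runs over the whole recording, fixation blocks included.
Each event is a ballistic displacement with a raised-cosine velocity
profile — duration uniform on 10–30 ms, amplitude uniform on
0.1–0.5 DVA (0.5 DVA = 30 arcmin, the conventional upper bound for
microsaccades) — whose discrete integral equals the drawn amplitude
exactly (midpoint sampling of the cosine).  An event lands in both eyes
with probability `binocular_correlation` (default 0.9; microsaccades
are strongly conjugate), otherwise in one random eye; binocular events
share direction and amplitude.  Directions follow an axial von Mises
mixture peaked at 0°/180° with concentration `horizontal_bias`
(default 1.0), reproducing the horizontal dominance seen in empirical
microsaccade-direction histograms.

**Drift.**  Drift velocity is an Ornstein–Uhlenbeck process
(correlation time `drift_tau` = 0.2 s) integrated to position,
independent across eyes and axes.  Its standard deviation is set in
closed form so that the mean absolute displacement over one second
equals `drift_speed` (default 0.5 DVA/s): for an OU velocity with
variance σ², Var D(T) = 2σ²τ[T − τ(1 − e^(−T/τ))], and E|D| =
√(2/π)·SD.  A velocity-level model (rather than a per-sample position
random walk) keeps instantaneous velocities in the physiological
~1 DVA/s range; a 1000 Hz position walk with the same 1-s excursion
would carry ~20 DVA/s of white velocity noise, which no
velocity-threshold event detector could operate on.

**Tremor.**  Band-passed Gaussian noise (Butterworth order 4,
`tremor_band` = 30–100 Hz) added to position, RMS `tremor_amplitude`
(default 0.002 DVA ≈ 0.12 arcmin), independent between eyes.

**Fixation leak.**  The slow component (drift plus accumulated saccade
displacements) decays with time constant `fixation_leak_tau` = 5 s,
standing in for the error-correcting role of fixational eye movements so
that 160-s runs remain bounded near the fixation point.  The leak is
weak relative to the 1-s excursion scale; the drift-calibration unit
test disables it to check the closed form exactly.

**Pupil.**  Baseline (default 1000 a.u.) plus low-pass (< 2 Hz)
Gaussian noise of RMS `pupil_noise` (default 10 a.u.), orientation-
independent: empirical trial-average pupil statistics show no
orientation structure under passive viewing.

**Blinks.**  A Poisson process at `blink_rate` (default 8/min) masks
`blink_duration` = 150 ms windows in both eyes, giving ~2% missing
samples.  Masked samples are set to NaN and flagged — present but
unusable until imputed, so a pipeline that skipped imputation would
fail loudly rather than silently.

**The confound (positive control).**  `ConfoundSpec` couples
microsaccade direction to the trial's grating orientation: for an event
falling inside a trial *and* inside an on-phase of the 2 Hz stimulus
flicker (250 ms on / 250 ms off), with probability `coupling_strength`
its direction is redrawn from a concentrated axial von Mises (κ = 20)
around the orientation-locked axis — by default orthogonal to the
grating, the direction hypothesized for apparent-motion-driven
microsaccades.  Flicker gating means roughly half of within-trial
events are eligible.  `coupling_strength = 0` takes the identical code
path as no confound, so the null condition is bit-reproducible, and
under the null no generated channel depends on the orientation labels
at all — labels are exchangeable by construction.

What the generator does **not** emulate: main-sequence
amplitude–velocity relations beyond the amplitude/duration ranges,
saccadic overshoot, microsaccadic inhibition after stimulus onset,
pupillary light/flicker responses, tracker noise models, and any
orientation coupling other than the direction/rate confound.  Passing
null-calibration tests on this generator therefore shows the pipeline
is unbiased under a realistic-statistics null, not that real data
contain no confound.

## 2. Preprocessing

Fixed order: impute → filter → downsample → slice → center.

* Blink imputation replaces flagged samples by the run median of
  unflagged samples per channel — with centered fixation data the
  median *is* the fixation point.  Imputation precedes filtering so the
  filter never sees gaps.
* Low-pass: Butterworth order 5, cutoff 100 Hz, applied
  forward–backward (`sosfiltfilt`) for zero phase; the effective
  magnitude response is squared.  Event timing matters downstream
  (detection, per-timepoint decoding), which makes zero phase the right
  offline choice.
* Downsampling 1000 → 256 Hz uses polyphase resampling at the rational
  factor 32/125 with linear-extension edge padding (the ratio is not an
  integer, so naive decimation is not available).
* Trials are sliced synchronized to the first stimulus onset
  (16 s into the run): 8 abutting tensors of 6 × 4096 per run.
* Centering subtracts the per-run, per-channel median computed over the
  run's trial epochs (fixation blocks excluded — the choice is
  contained in which samples enter `center_runs`), zeroing
  recalibration offsets between runs.

## 3. Microsaccade detection

Velocity is the 5-point moving-average derivative
v[n] = (x[n+2] + x[n+1] − x[n−1] − x[n−2]) / (6Δt), exact for linear
signals, boundaries zeroed.  Per axis the noise scale is the
median-based estimator σ = √(median(v²) − median(v)²), robust to the
saccades themselves; thresholds are η = λσ with λ = 6 (the standard
setting of the velocity-threshold algorithm; configurable).  An event
is a maximal run of samples with (vx/ηx)² + (vy/ηy)² > 1 (elliptic,
combined-axis criterion) lasting **more than** 6 ms — at 256 Hz the
smallest qualifying run is 2 samples (7.8 ms).  Events carry amplitude
and direction from the onset→offset positional displacement and the
peak speed within the run.  Detection runs on preprocessed (filtered,
downsampled, centered) data; thresholds are estimated per trial and per
eye in the feature path, and per run when evaluating recovery against
simulated ground truth.  Monocular detection is the default (per-eye
histograms are wanted downstream); a binocular-coincidence filter is
available but off.

Recovery, measured against injected events (0.2–0.5 DVA, 10–30 ms)
with ±10 ms onset tolerance under default drift/tremor/blinks:
sensitivity ≈ 0.95 with ≈ 0.2 false alarms per second at λ = 6.

## 4. Trial summary features

76 = 2 × (3 + 3 + 16 + 16) per trial, concatenated as
[μ_xl μ_yl μ_pl, μ_xr μ_yr μ_pr, σ (same order), θ_el(16), θ_er(16),
θ_ml(16), θ_mr(16)].

* SDs use the population convention (divide by n).
* Eye-angle occupancy: atan2(y, x) of each centered sample, binned into
  16 half-open 22.5° bins, expressed as percent of trial time.  Samples
  exactly at the origin have no angle and are excluded from the
  denominator (measure zero for continuous data; an all-zero trial
  yields an all-zero histogram).
* Microsaccade-direction histograms are raw event counts (a
  normalized-rate mode exists but is off by default).

## 5. Decoding

All five analyses share leave-one-run-out cross-validation (one fold
per run; 23 runs train / 1 run test at the default design) and
standardization by the training split's mean and SD; zero-SD training
features are divided by 1.  Orientation labels are encoded as the 8
class indices; chance is 12.5%.

* SVMs: `sklearn.svm.SVC`, linear kernel, C = 1, one-vs-one.
* Raw-vector SVM uses all 6 × 4096 = 24576 samples per trial.
* Per-timepoint SVM fits one 6-feature SVM per sample, reporting a
  4096-long accuracy trace (fold-mean) plus per-fold means.
* CNN: conv(6 kernels, 32 samples) → ReLU → maxpool(2,2) →
  conv(16, 16) → ReLU → maxpool(2,2) → conv(120, 8) → ReLU → flatten →
  dense 84 → dense 8 softmax; stride 1, no padding; with 4096-sample
  input the flatten sees 120 × 1001.  Kernel counts/sizes are
  parameters so short sequences can use smaller stacks in tests.
* RNN: 20 LSTM units over the 6-channel sequence (forget-gate bias
  initialized to 1); the final hidden state feeds a dense softmax.
* Training: Adam with α = 0.001, β₁ = 0.9, β₂ = 0.999, batch 32,
  100 epochs, no early stopping; the final-epoch model is evaluated.
  Per-epoch training loss and held-out-fold (validation) cross-entropy
  are recorded; the reference line for no-information data is the
  uniform-classifier loss −ln(1/8) ≈ 2.079.
* The neural-network layers and optimizer are implemented in NumPy
  inside the package (`gazedecode.nnet`), with gradient correctness
  verified against central differences in the test suite.  SVM results
  are exactly reproducible; CNN/RNN results are reproducible given the
  seed up to floating-point reduction order.

## 6. Statistical inference

**Permutation test.**  The decoding function (the *entire*
cross-validated pipeline) is re-run on label permutations; the add-one
estimator p = (1 + #{perm ≥ observed}) / (n_perm + 1) never returns
zero.  When run identities are supplied, labels are permuted *within
runs*.  This choice is deliberate: the experiment randomizes the trial
order independently within each run, so every run contains each
orientation exactly once.  Whole-session permutation destroys that
balance, and under leave-one-run-out CV the unbalanced-null accuracies
fall systematically below chance, which makes the observed (balanced)
accuracy look significant too often — measured on 100 null simulated
participants (6 runs, 200 permutations), whole-session permutation
rejects 15% of the time at α = 0.05, while within-run permutation — an
exact randomization test, since it re-draws labels precisely the way
the schedule does — rejects 3% (conservatism from discreteness of the
accuracy statistic).  Whole-session permutation remains available by
omitting the run ids.

**Group test.**  One-sided Wilcoxon signed-rank of participant
accuracies against chance, zero differences included in the ranking
(Pratt): all |differences| are ranked (average ranks for ties), zero
ranks are then discarded, and the one-sided p is computed from the
exact sign-flip null by dynamic programming over the (doubled, hence
integral) rank sums for n ≤ 25, falling back to the normal
approximation beyond.  All-zero differences give p = 1 by convention.
The smallest attainable p for n participants all above chance is 2⁻ⁿ.

**Multiple comparisons.**  Per-timepoint p-values are Bonferroni
controlled: significance iff p < α/n; the report carries the adjusted
threshold and min-adjusted p.

## 7. Numerical notes

* The digital Butterworth designed by the bilinear transform has
  magnitude (1 + (tan(πf/fs)/tan(πf_c/fs))^(2n))^(−1/2); prewarping
  pins it to the analog response at the cutoff, but near Nyquist they
  diverge (at 150 Hz / fs 1000: 0.105 vs the analog 0.131).  Tests
  check the implemented filter against the digital closed form, and
  against the analog form in the band where warping is negligible.
* The polyphase anti-aliasing FIR has unit DC gain to within design
  ripple (~3 × 10⁻⁵ relative), so constants survive downsampling to
  that accuracy.
* Degenerate inputs fail loudly: all-flagged channels (imputation),
  zero median-based velocity scale (thresholding), fewer than 5 samples
  (velocity), fewer than 2 runs (CV), fewer than 2 rows
  (standardization), empty trials (occupancy).
* Seeds: simulation fans a root `SeedSequence` out to one child per
  run; the CLI derives per-stage seeds from the global seed by a fixed
  byte-hash; all derived integer seeds stay below 2³¹.

## 8. Problem sizes in the test suite and acceptance script

Simulation-heavy checks use the design scales at which their
Monte-Carlo error is informative while keeping the suite fast: chance
calibration averages 20 full-scale null participants (2 × 12 runs
each); type-I calibration uses 100 null participants of 6 runs with
200-permutation tests; detector recovery uses two full 160-s runs
(~900 ground-truth events); the confound positive control uses one
6-run participant at coupling 1.  The acceptance script reports the
grand-mean null accuracy over 40 full-scale participants in percent.
Neural-network unit tests run on short sequences (tens of samples) with
reduced conv stacks, which exercise identical code paths as the
full-size architecture.

## 9. Known limitations

* The generator's realism gaps listed in §1 bound what null-calibration
  results imply about real recordings.
* The LSTM over 4096 timesteps is computationally heavy in pure NumPy;
  an optional temporal-stride parameter exists for exploratory use but
  defaults off, and full-scale network runs are minutes-per-fold rather
  than seconds.
* Exact Wilcoxon inference above n = 25 falls back to the normal
  approximation with Pratt zero handling.
* The per-timepoint analysis fits 4096 SVMs per fold; at the full
  design this is the slowest SVM variant by far.
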
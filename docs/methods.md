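# Methods

This note documents the models, parameter choices, and numerical decisions
behind `dualfiber`, in the spirit of the methods documentation that mature
simulation/analysis packages ship: what the code assumes, why the defaults
are what they are, and what a green test does and does not establish.

## 1. Signal model and processing chain

A dual-color rig records four demodulated fluorescence channels: for each
sensor (fast green / astrocyte, slow red / neuron) one calcium-dependent
signal channel and one calcium-insensitive isosbestic (~405 nm) control.
The processing chain is fixed, in this order:

1. **Polynomial detrend** (default order 2, configurable 0–8) fit by least
   squares over the whole session, per channel. Photobleaching is slow and
   smooth; order 2 captures it without absorbing multi-second transients.
   The fit uses a time axis rescaled to [−1, 1] for conditioning.
2. **Isosbestic subtraction**: `signal − isosbestic`, pointwise. Both
   channels travel the same fiber, so mechanical artifacts appear with the
   same waveform in both and cancel. An optional mode rescales the
   isosbestic by its OLS fit to the signal first (off by default — plain
   subtraction is the documented behavior of the original analysis).
3. **Zero-phase low-pass**: 2nd-order Butterworth at 0.3 Hz applied
   forward–backward. Zero phase preserves event timing, which the
   time-of-peak analyses require. Edge handling uses Gustafsson's method:
   at a cutoff 300× below the sampling rate, reflect-padding leaves
   boundary transients larger than the signals of interest, while the
   Gustafsson initial-condition choice keeps a 5 Hz probe tone below 1%
   residual RMS and shifts a symmetric pulse by exactly 0 samples.
4. **z-scoring**: `z = (F − F0)/σF` with basal statistics from the whole
   corrected session by default (a restricted basal window is
   configurable). Whole-session scaling plus the later per-trial baseline
   subtraction reproduces the two-step normalization of the original
   analysis.

Inputs above 100 Hz are anti-alias decimated to ≤100 Hz first; all
analysis windows are specified in seconds, and results are rate-invariant
well above the 0.3 Hz filter's Nyquist needs.

## 2. Trial extraction and QC

Trials are cut on a fixed relative grid (−8…5 s around sniff initiation,
−5…15 s around looming disc appearance) and the mean of the pre-event
baseline window (−8…−3 s social, −5…0 s looming) is subtracted from the
whole segment. Exclusion rules are applied in a fixed order so each
excluded trial carries exactly one machine-readable reason:

`min_bout` (< 1 s sniffs) → `min_events` (subjects with ≤ 3 qualifying
events) → `baseline_irregularity` (any baseline sample beyond ±0.2 z of
the baseline-window mean; "beyond" is exclusive, so a deviation of exactly
0.2 passes) → `trial_cap` (chronologically first five per subject ×
condition).

Open choices resolved here: the ±0.2 rule is evaluated on every baseline
sample (the stricter any-sample reading) with a window-mean alternative
behind a config switch; the trial cap takes the chronologically first five,
which is deterministic and bias-transparent.

## 3. Per-trial metrics

A *curve* is a maximal run of samples strictly on one side of zero
(samples exactly at zero separate curves). Social trials use the curve
containing t = 0; looming trials the curve with maximal overlap with the
5–8 s full-expansion epoch, ties to the earlier region. Peaks are interior
local maxima of Δz within the curve; a peak is ignored when its height
above the trial minimum is below 5% (social) or 10% (looming) of the
trial's full min-to-max range — the range is deliberately taken over the
whole trial window, matching the graphing convention of the original
tool. Peak ties break to the earliest time. AUC is the signed trapezoidal
integral over the curve (negative curves give negative AUC). The
poststimulus epoch starts strictly after 8 s — the published "8.01 s"
reflects a 100 Hz grid, not a physical constant, and generalizes to the
first sample after 8 s at any rate.

## 4. Coupling

Social pairing is peak-anchored: x = neuron peak Δz, y = astrocyte Δz at
the neuron's time of peak via nearest-sample lookup (both sensors share
one acquisition clock, so interpolation would add nothing). Looming
pairing is epoch-mean: mean z over 5–8 s minus the −5…0 s baseline mean,
per sensor. Points are pooled across animals within a condition and fit by
OLS (slope, intercept, R², two-sided t-based p with n−2 df). Pooling
without a subject random effect replicates the published per-trial
scatter; a hierarchical model is a known limitation, not an option.

## 5. The synthetic world

The generator emulates: channel-specific double-exponential bleach (~1–2%
of the offset, consistent with LED powers chosen for limited
photobleaching); motion bumps injected with the *same* waveform into all
channels; peak-normalized difference-of-exponential transient kernels
(fast sensor rise 0.1 s / decay 0.6 s; slow sensor 0.3 s / 1.5 s — only
the relative ordering matters for tests); white Gaussian channel noise;
and two basal-activity components — sparse spontaneous transients and a
slow basal wander (session-period sinusoids).

**Why basal activity is part of the stated world.** The analysis z-scores
by the whole-session SD. In a world containing only bleach + motion +
noise, that SD *is* the filtered-noise SD, so noise has unit variance in z
units; then the ±0.2 z baseline rule excludes essentially every trial and
a 0.2 z peak cannot be measured to 15%. Real photometry does not look
like that: ongoing population activity, not detector noise, sets the basal
SD, and quiet baselines are far below 1 z locally. The generator
reproduces this by letting spontaneous transients dominate session
variance. They are placed outside the analysis windows of scheduled
events — an idealization that makes ground-truth amplitudes well defined;
its cost is that the simulation cannot probe how overlapping spontaneous
events bias trial metrics (a green recovery test says nothing about that).

**Ground truth in measurement units.** Event amplitudes are specified in
Δz. The generator converts them to raw fluorescence deterministically: a
minimal internal replica of the chain (polynomial fit + Butterworth
filtfilt, written directly against numpy/scipy primitives and independent
of the analysis module) predicts the basal SD of the noiseless session;
the analytic noise bandwidth of the forward–backward filter adds the noise
variance; and the known filter attenuation of each sensor's kernel
pre-compensates the peak (the 0.3 Hz filter passes only ~45% / 77% of the
fast / slow kernel's peak). The astrocyte amplitude is additionally scaled
so that the astrocyte Δz *at the neuron's time of peak* equals
`slope·A + intercept + ε` — i.e. the coupling parameters describe exactly
the peak-anchored quantity the analysis measures. Evoked transients
themselves contribute < ~2% of session variance at default amplitudes and
are ignored in the calibration (a like-sized bias on recovered Δz).

**Defaults** (chosen once, as a realistic 10-min session; amplitudes match
the order of magnitude of published in vivo Δz values, ~0.1–0.5):
100 Hz sampling, 600 s duration, channel offsets ~1–2 a.u., noise SD
0.006 a.u., wander 0.007 a.u./sinusoid at periods 600 and 300 s,
spontaneous rate 0.18 s⁻¹ in allowed gaps at 0.06 a.u., social bouts
1.2–3.5 s. Sniff-bout density (10/600 s, ≥30 s apart) is far below real
scoring (~30/10 min) because the generator rejects events closer than the
kernel support so that each trial has an uncontaminated window; the
simulation therefore cannot exercise overlapping-bout scoring. Looming
sessions carry 6–8 stimuli ≥ 60 s apart; evoked transients start 4.5 s
after disc appearance (during expansion) so the response peaks inside the
5–8 s epoch, scaled per response category (run 1.0, freeze 0.6,
no-response 0).

**What recovery tests establish.** Peak recovery is assessed on the mean
recovered amplitude per level: the slow wander adds a ~0.05–0.1 z
zero-mean per-trial error (any session-variance-dominating component must
wander at least this much over a 10 s trial), which averages out across
trials but sets a per-trial floor. For the coupling-slope recovery the
same x-axis error produces classical regression attenuation, so the
scenario draws true amplitudes U(0.2, 1.2) — a spread comfortably above
the measurement floor; with the paper-scale range 0.15–0.5 the same
pipeline shows visibly attenuated slopes, which is a property of pooled
OLS on noisy x, not a bug.

## 6. Statistics

* Wilcoxon signed-rank vs zero: zeros removed; exact null for n ≤ 25 via
  dynamic programming over doubled midranks (handles ties exactly);
  tie-corrected normal approximation above; two-sided p = 2·min(tails),
  capped at 1.
* Mann–Whitney: exact when min(n) ≤ 8 with no ties, else the
  tie-corrected normal approximation (scipy supplies both branches).
* Variance F test: larger variance over smaller, doubled upper-tail p
  capped at 1 (the two-sided convention of the original analysis tool;
  one- vs two-sided is not stated there, so the tool's convention is
  followed).
* One-way RM ANOVA across baseline / loom / post epoch means (trials as
  subjects), direct sum-of-squares decomposition; pairwise paired-t post
  hocs corrected by the two-stage BKY FDR. Per-trial baseline subtraction
  does not change the within-trial contrasts, so Δz- and z-based epoch
  matrices give identical F.
* Two-stage BKY linear step-up FDR: stage 1 at α′ = α/(1+α) estimates the
  true-null count m0; stage 2 reruns the step-up at α′·m/m0. Q-values are
  the adaptive adjustment p·m0·(1+α)/rank, monotonized and capped, so
  Q ≤ α coincides with stage-2 rejection in the non-degenerate case.
* Two-way ANOVA (sex × familiarity) with type-II sums of squares via
  nested OLS fits — robust to the unbalanced cells these designs produce;
  the original tool's SS type is not stated, type II is this package's
  choice. BKY-corrected pairwise cell comparisons serve as post hocs.
* ROUT outlier removal, mean-only model: median location, RSDR = 68.27th
  percentile of |residuals| × √(N/(N−1)), two-tailed t p-values on
  standardized residuals, largest-residual prefix removed by a linear
  step-up test at rate Q (default 1%).
* A Shapiro–Wilk gate (α = 0.05) reproduces the published decision path
  between t tests and their rank analogues; the selected branch is
  recorded in each result.

Degenerate inputs: constant responses give F = 0 / p = 1 by convention;
zero basal variance, empty groups, all-zero Wilcoxon inputs, and zero
predictor variance raise informative errors rather than returning NaN.

## 7. Known limitations

* Trials are pooled across animals in the coupling regression (no mixed
  effects), as published.
* The generator does not model hemodynamic artifacts, spectral crosstalk
  between sensors, or overlapping sniff bouts.
* Lock-in demodulation is upstream: inputs are assumed demodulated
  per-channel traces.
* The male looming "run" percentage printed in the source results
  (57.78%) is inconsistent with its own printed counts (19/36 = 52.78%);
  the pipeline reports count-derived percentages.
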
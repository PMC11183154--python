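# Methods

## Signal preprocessing

Load force of an airborne object is computed from its mass and measured
acceleration, `LF = m·sqrt((a_z + g)² + a_y²)` with g = 9.81 m/s²; it is
undefined while the object rests on the table, so only the lift phase is
analyzed.  Grip and load forces are low-pass filtered with a 4th-order
Butterworth at 12 Hz; EMG is full-wave rectified, low-pass filtered at
10 Hz (4th-order Butterworth, zero-phase), and decimated from 2000 Hz to
the 200 Hz kinematic rate.  Zero-phase (forward–backward) filtering is
used for all channels so that events stay aligned across modalities; it
applies the magnitude response twice, i.e. the effective attenuation is
that of an 8th-order filter.  The 12 Hz force filter is applied once.

The analyzed window runs from 100 ms before first contact (grip force of
either hand first exceeding 0.1 N) to 100 ms after the beginning of the
stable hold (first sample after the peak of |vertical velocity| at which
it falls below 0.001 m/s).  The "after the peak" rule resolves the
ambiguity of which velocity excursion counts in a single-lift trial.
Trials whose padded window leaves the recording raise a detection error
naming the trial rather than being silently truncated.

Each channel is linearly interpolated onto 500 samples (endpoints
preserved) and 20 samples are dropped from each edge (filter transients),
leaving T = 460.  EMG envelopes are normalized per participant and per
muscle — each channel divided by its maximum over all of that
participant's trials, objects and time points — so that no participant
dominates the decomposition through raw amplitude.  Per-muscle (rather
than across-muscle) normalization prevents one strong muscle from
silencing the others; this granularity is a documented open choice.
Filtered envelopes are clipped at zero (zero-phase filtering of rectified
signals can undershoot slightly), keeping the tensor non-negative by
construction.

Trials are collated into X (12 × 460 × 2 × P × 10) with channels in the
fixed order grip R/L, load R/L, deltoid R/L, ECR R/L, FCR R/L, APB R/L;
object index 0 is the heavy object; participants are sorted by age.  A
single scalar then rescales the four force channels so the mean l2-norm
of force rows in the mode-1 unfolding equals that of the EMG rows; the
scalar is recorded, within-modality ratios are untouched, and the
operation is idempotent.

Indexing is 0-based half-open internally; the 1-based channel labels
appear only in files and reports.  An optional amplitude-outlier screen
(|z| > 8 on any channel) only warns — it never drops trials, because
artifact rejection is a judgment call left to the analyst.

## Decomposition

The non-negative CP model is fitted by block-coordinate HALS: for each
mode in turn, each factor column is updated in closed form against the
matricized-tensor-times-Khatri-Rao product and clipped below at 1e-12.
The epsilon floor (rather than exact zero) matters: a column that hits
exact zero in one mode has a zero diagonal in every other mode's Gram
product and can never re-grow, which silently reduces the model rank.
Each column update is an exact coordinate minimizer, so the squared-error
objective is non-increasing across sweeps; the recorded objective history
is asserted monotone in the tests.

Initialization is entrywise |N(0,1)|, seeded; multi-start fits keep the
best final objective.  Convergence is declared when the relative objective
change drops below 1e-8, capped at 500 sweeps.  VAF uses the population
variance of the vectorized tensor (dividing by N, matching the 1/N in the
MSE); a toy check in the test suite pins this convention (X = [1, 3] with
a zero reconstruction gives VAF = −4).  Rank selection runs candidate
ranks 1..10 with 10 seeded restarts each and returns the smallest rank
whose *mean* VAF reaches 0.6 (ties at the threshold accepted); if none
qualifies, the error carries the full curve.  Reported components are
ordered by descending object-factor column norm after scale fixing, which
makes reports deterministic under the CP permutation ambiguity.
Estimated-to-planted component matching uses Hungarian assignment on the
product-over-modes cosine similarity.

## Synthetic ground truth

The generator plants a rank-R non-negative model with unit-l2 factor
columns, so all components have equal Frobenius energy:

* spatial columns are sparse with *disjoint* channel supports whenever
  M ≥ 2R (each synergy recruits its own muscle/force group).  This keeps
  planted components linearly independent — with overlapping supports the
  all-positive, nearly parallel participant and trial loadings make the
  components close to collinear and the effective rank collapses;
* temporal columns are staggered raised-cosine bumps of fixed relative
  width (0.3 T).  A single profile family keeps per-component variance
  shares comparable: a near-constant profile contributes tensor mean but
  almost no variance and becomes invisible to a VAF criterion;
* object columns are positive and mildly unequal (U(0.8, 1.2));
* the designated participant column separates older from younger adults
  by *exactly* `group_effect_d` pooled standard deviations (both groups
  standardized in-sample before shifting), so planted effect sizes are
  realized, not merely expected.  A corollary: at `group_effect_d = 0`
  the in-sample group means coincide exactly and a group t-test on the
  planted column is conservative (it essentially never rejects) rather
  than calibrated to its nominal level — nominal null calibration is
  instead exercised through the trial-trend test, whose jitter is
  genuinely stochastic;
* the designated trial column adds a linear drift `trial_slope` per trial
  to i.i.d. positive jitter (SD 0.05), clipped at zero.

Noise is additive Gaussian scaled to a target SNR in dB (variance ratio
of clean signal to noise), then the tensor is clipped at zero.  The
realized pre-clipping SNR is recorded; clipping introduces a small
positive bias at low SNR which is measured rather than corrected — the
simplest model that preserves non-negativity.

Dexterity scores are coupled to the designated participant loading by a
Gaussian copula: the loading's ranks are mapped to normal scores, an
independent residual is orthogonalized against them in-sample, and the
mixture `ρ·z + sqrt(1−ρ²)·w` is pushed through a normal marginal
(mean 14, SD 2.5, floored at 1).  In-sample orthogonalization makes the
realized latent correlation equal the requested target exactly; the score
is kept continuous (pin counts would be integers; rounding would blur the
controlled correlation).  Ages are uniform on [18, 29] (younger) and
[60, 85] (older); EMG amplitudes are arbitrary by design, since no
distributional facts about them are available.

Raw-trial synthesis produces a grip-force rise crossing the 0.1 N
threshold at a known sample, a 0.3 m minimum-jerk lift with analytic
velocity/acceleration, a still hold, and Gaussian-noise EMG modulated by
burst envelopes.  Both manipulanda share one kinematic trace (the two
load-force channels coincide); ground-truth first-contact and
stable-onset samples are stored with each trial for window-detection
tests.  What the generator does *not* emulate: motion-capture marker
noise, electromechanical delays, trial-to-trial kinematic variability of
real lifts, EMG crosstalk and baseline wander.  Passing tests therefore
demonstrate correctness of the pipeline's operations and recoverability
of planted structure, not robustness to every artifact of real
recordings.

## Inference

Classification uses a linear SVM (C = 1, no within-fold tuning — with
~29 participants there is no data to tune on) under leave-one-out
cross-validation; predictors are standardized on each training fold,
since unit-norm factor columns have entries of order 1/sqrt(P) and an
unstandardized C = 1 SVM collapses to the majority class.  AUC is
computed from the pooled held-out decision values (single ROC), oriented
so larger values mean "older".  Subset search evaluates every non-empty
factor subset, ranked by AUC then accuracy with deterministic
tie-breaking.  Permutation importance shuffles one column across
participants (others intact) and reports the percentile of the
unpermuted performance in the null distribution, counting ties as half.

Regression is OLS with intercept (two-sided t p-values per coefficient);
group comparisons use the pooled-variance independent t-test (Welch by
flag); correlations are Pearson with optional index-based outlier
exclusion; all multiple comparisons over the R factors use Bonferroni
(α/R).  The Mann-Kendall statistic uses the tie-corrected variance and
continuity-corrected z; an OLS slope over the trial index is reported
alongside as the headline effect size (Theil–Sen would be the robust
alternative; OLS is what the slope summaries refer to).

## Problem sizes and numerical checks

The heavy acceptance-style checks run at the study's spatial layout with
planted rank 4: the full-size VAF check on a 12×460×2×29×10 tensor at
10 dB SNR (best of 10 restarts; a single HALS run takes ~15 s here), and
the rank sweep on a temporally reduced 12×100×2×29×10 tensor with noise
calibrated so the clean signal explains ~65% of total variance — the
smallest-rank-over-60% rule then lands on the planted rank across seeds
(mean VAF ≈ 0.03/0.35/0.57/0.71 for ranks 1–4).  The end-to-end recovery
check plants a strong age effect, d = 2.5: for normal within-group
variation the expected group separability is Φ(d/√2), so 2.5 is the
smallest "strong" effect whose expected AUC (≈0.96) clears the 0.9
acceptance bar by about one sampling standard deviation at n = 13/16 —
a power calculation, not an empirical calibration.

## Known limitations

* HALS converges slowly in its tail on noisy tensors; with the 1e-8
  relative tolerance the 500-sweep cap is usually what stops it.  VAF
  values are stable to ~1e-3 long before that.
* The load-force channels duplicate one kinematic trace in synthetic
  data, so spatial factors cannot dissociate right from left load force
  there.
* CP identifiability requires components that are not collinear; planted
  models use disjoint spatial supports to guarantee this, and real data
  offer no such guarantee.
* The permutation and classification analyses assume exchangeable
  participants; no hierarchical (per-trial) classification is attempted.
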
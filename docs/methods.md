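# Methods

This note documents the models and procedures implemented in `sepsislupi`,
the choices made where the design was genuinely open, and what the
synthetic studies do and do not demonstrate.

## Problem and timeline

An instance is anchored at a time t0 at which a patient's qSOFA score —
the sum of three inclusive criteria, Glasgow Coma Scale ≤ 13, systolic
blood pressure ≤ 100 mmHg, respiratory rate ≥ 22/min — equals 1. The task
is to predict whether the score reaches ≥ 2 at t6 = t0 + 6 h (label +1)
or stays below (label −1). Features observable at or before t0 form the
*regular space*; data from the ten minutes ending at t6 form the
*privileged space*, usable only during training (learning using privileged
information, LUPI).

## Taut-string signal approximation

For a sampled signal f and tube half-width ε > 0, the taut-string
estimate g minimises Σ(g_{i+1} − g_i)² subject to max|f − g| ≤ ε. It is
computed by a linear-time funnel walk over the corridor [f − ε, f + ε]
(the channel shortest-path construction): convex/concave hulls of pending
ceiling and floor contacts are maintained and knots are committed when a
new corridor point forces a bend. A dense QP is never formed, so 5-minute
windows at 240 Hz (72,000 samples) are routine.

Numerical choices:

* **Free endpoints.** The problem definition pins neither end, so both are
  free inside their tube interval; the optimal string then starts and ends
  with zero slope. When an entirely flat string fits, its height is the
  midpoint of the feasible interval (tie-break).
* **Tube exactness.** Corridor bounds are rounded floats; contact values
  are nudged by ulps toward f so max|f − g| ≤ ε holds exactly in measured
  arithmetic. The residual ("noise") is defined as r = f − g, which makes
  reconstruction exact by definition; re-adding introduces at most one
  rounding per sample (bitwise re-addition is unattainable in IEEE
  arithmetic when |f − g| exceeds |f|).
* **Segments and inflections.** A knot is a slope change larger than 1e−9
  (slope units). Line segments are maximal linear pieces; inflection
  segments are interior knots where the slope sign flips. "Power" is mean
  squared amplitude and "total variation" the sum of absolute first
  differences; these conventions are this package's definitions, chosen
  where the literature delegates them to earlier work.

Six features per estimate (segment count, inflection count, TV of noise,
TV of denoised signal, power of denoised signal, power of noise) are
computed at five tube widths (0.0100, 0.1575, 0.3050, 0.4525, 0.6000 mV).

## ECG processing

Lead-II ECG at 240 Hz is filtered with a second-order Butterworth
band-pass (0.5–40 Hz), applied forward–backward (`sosfiltfilt`). The
zero-phase choice preserves QRS morphology; a causal single pass would be
the alternative if streaming operation were required. The 10-minute
regular segment is split into two 5-minute windows, giving a 2×5×6 feature
tensor, flattened window-major. The privileged segment is summarised
unwindowed: a 5×6 taut-string bank (TS-ECG) and seven statistics (SF-ECG):
mean, median, variance (1/n), skewness and Pearson kurtosis (standardised
moments, Gaussian → 3, defined 0 for constant windows), Shannon entropy in
nats over a 64-bin equal-width histogram, and the mean absolute value of
the unnormalised forward FFT.

Signal quality is the fraction of 10-second subwindows flagged by a
configurable heuristic (flat line, rail clipping, out-of-range amplitude);
instances with ≥ 50% flagged subwindows in either segment are rejected
with a reason code. The detector is a stated heuristic — the underlying
cohort rule is not published.

## EHR features

Each time block holds 5 vitals + urine output (numeric), 10 lab ordinals
(0 = not logged, 1–4 increasing severity) and 7 cardiovascular infusion
ordinals (0 = off, 1–3 dose severity): 23 values. The regular vector
spans lookbacks t−16 … t0 (115 values); the privileged vector is the t6
block (23 values). Missing vitals/urine are last-observation-carried-
forward across lookbacks, falling back to configured population defaults;
missing labs/infusions encode as 0. Threshold tables are configuration:
the shipped defaults are clinically plausible (e.g. lactate 2/4/8 mmol/L,
norepinephrine 0.1/0.5 µg/kg/min) but not a canonical published table.
Values exactly on a cut point stay in the milder bin.

## SVM and SVM+

The baseline is a Gaussian-kernel soft-margin SVM (hinge loss, box
constraint C, explicit bias) whose dual is solved by a most-violating-pair
SMO with deterministic first-index tie-breaking.

SVM+ replaces slack variables by a linear function of the privileged
space. With augmented features ([z, 1], bias absorbed) and squared hinge
loss the dual is min ½αᵀ(H + G)α with H = K̃ ∘ (y yᵀ) and the privileged
correction G = K*(γI + C K*)⁻¹, computed in kernelised form (equal to the
explicit-feature form by the push-through identity, and defined for
nonlinear privileged kernels). α is obtained from the one-class-SVM dual
(Σα = νn, 0 ≤ α ≤ 1) by a pairwise SMO. Decision scores are
f(x) = Σ αᵢ yᵢ K̃(xᵢ, x); classes are sign(f), ranking metrics use raw
scores.

Parameter choices:

* ν = 0.5 and γ = 1 by default; both are exposed and optionally
  searchable. Positive rescaling of α leaves the score ranking unchanged,
  so ν mostly sets normalisation. The printed constraint αᵀ1 = 1 from the
  stationarity conditions and the one-class form 1ᵀα = νn differ only by
  such a rescaling; the one-class form is implemented.
* The correction uses γ as printed in the dual (a factor-2 reparametrisation
  of the primal regulariser γ‖w*‖² is absorbed into the hyperparameter).
* The regular kernel is always augmented (+1). The privileged kernel is
  Gaussian by default and **not** augmented: with augmentation K* never
  vanishes (k(0,0) = 1), so identically-zero privileged features would not
  reduce SVM+ to the plain dual. A linear privileged kernel is available
  and is what the vanishing-PI checks use.
* Solver stopping: KKT violation ≤ 1e−8 or 200,000 pairwise updates. The
  tight default keeps the dual objective within 1e−6 of a generic QP
  solution on problems of the tested sizes; both knobs are arguments.

## Evaluation protocol

Each of n_iterations (default 100; the synthetic studies use 20)
repetitions draws a patient-wise split — 20% of patients to test, 20% of
the remainder to validation — so no patient appears in two sets. A grid
over C ∈ {0.1, 1, 10, 100} and kernel scale ∈ {0.5, 1, 2, 4}·√d is ranked
by validation AUROC (ties break toward smaller C, then smaller scale);
the winner is refit on train+validation and scored on test. γ and ν stay
at their defaults during the search. Features are z-scored with
fitting-fold statistics before the Gaussian kernel — mixed-unit features
otherwise collapse the kernel; whether the original analysis scaled is
unstated, and this package's choice is to scale. The F1 threshold is a
raw score of 0 (not tuned). A failed iteration aborts the run; skipping
folds would bias the means. Reported: mean and standard deviation of F1,
sensitivity, specificity, AUROC and AUPRC per PI type ("none" = plain
SVM; TS-ECG / SF-ECG / EHR = SVM+).

## Synthetic cohort

Real cohort data are controlled-access, so the generator emulates the
input structure: 10-minute 240 Hz ECG per anchor, EHR observations at the
five lookbacks plus t6, labels produced strictly by the qSOFA rules on
generated t6 vitals (never assigned directly). Default shapes mirror the
two study cohorts (453 instances at 31.8% positive; 106 at 55.7%).

The ECG is a Gaussian-bump QRS pulse train with beat-interval jitter,
baseline wander and white noise; the class signal lives in beat-interval
variability and noise amplitude (plausible physiology: decompensation
alters heart-rate variability), scaled by `ecg_effect`. EHR vitals follow
a drifting random walk and labs/infusions come from class-tilted severity
distributions, scaled by `ehr_effect`. `pi_informativeness` interpolates
the t6 outcome between an independent coin at the base rate (0) and a
deterministic reflection of the planted class (1).

What the synthetic studies show — and do not. Because the taut-string
noise features concentrate sharply over long windows, even small planted
amplitude differences are almost perfectly detectable: high-separation
configurations saturate AUROC near 1, and the graded response regime sits
at small effect scales (~0.05 at 20-second windows). Passing these studies
demonstrates that the pipeline is wired correctly (no leakage, labels
faithful, effects propagate, null configurations stay at chance); it says
nothing about real ECG morphology, real missingness patterns, or the
attainable accuracy on clinical data.

## Problem sizes used in the shipped studies

The generator's defaults are the emulated study conditions (600-second
segments at 240 Hz). The packaged end-to-end studies and the
reproduction script run 200-patient cohorts for 20 iterations with
120-second segments, and unit tests use 10–60-second segments: segment
length is a pure problem-size parameter here (the planted structure is
per-sample), and the shorter segments keep the studies quick to re-run.

## Known limitations

* Encoding thresholds and the noise detector are plausible defaults, not
  published tables; results on real data will depend on them.
* The synthetic ECG has no P/T waves, arrhythmias, or electrode artifacts;
  the statistical features are exercised, not validated, on it.
* The SMO solvers are dense and O(n²) in memory; cohorts of a few
  thousand instances are the practical ceiling.
* GCS is taken as recorded; the package does not derive it from
  sub-scores, and instances without a recorded qSOFA(t0) = 1 anchor are
  rejected rather than imputed.
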
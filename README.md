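# sepsislupi

Predicting short-term sepsis deterioration from physiological signals with
**learning using privileged information (LUPI)**.

Patients in intensive care whose quick Sequential Organ Failure Assessment
score (qSOFA — one point each for GCS ≤ 13, systolic BP ≤ 100 mmHg,
respiratory rate ≥ 22/min) sits at 1 are at a tipping point: a rise to
≥ 2 within six hours marks substantially increased risk. `sepsislupi`
implements a complete, tested pipeline to predict that transition at time
t0 from the ten minutes of lead-II ECG ending at t0 and routine EHR data
(vitals, labs, infusions, urine output over the preceding 16 hours).

Because the training data are retrospective, the *future* is available for
training cases: signals and EHR from the ten minutes ending at t6 (the
outcome time) form a **privileged space** that regularises training via
the SVM+ classifier but is never needed at prediction time.

The package is intended for methods researchers in clinical ML and
physiological signal processing: it provides the primitives (taut string,
SVM+), the featurization, a synthetic cohort generator that emulates the
data structure of the original study (whose clinical data are
controlled-access), and the repeated patient-wise evaluation protocol.

## What it computes

* **Taut string.** For a signal f and tube width ε, the unique g with
  ‖f − g‖∞ ≤ ε minimising ‖Dg‖₂² = Σ(g_{i+1} − g_i)² — a piecewise-linear
  "string pulled tight" through the ε-tube, computed in O(n) by a funnel
  walk. Six features per estimate (segment count, inflection count, total
  variation and power of the denoised and noise parts) at five ε values
  give a 2×5×6 tensor per 10-minute ECG segment (two 5-minute windows).
* **EHR encoding.** 115-value regular vector over lookbacks
  t−16 … t0 (numeric vitals/urine; labs ordinal 0–4; infusions 0–3) and a
  23-value privileged block at t6.
* **SVM and SVM+.** Gaussian-kernel soft-margin SVM (two-set SMO), and
  SVM+ whose dual is min ½αᵀ(H + G)α with H = K̃∘(yyᵀ) and the privileged
  correction G = K*(γI + CK*)⁻¹, solved as a one-class dual
  (1ᵀα = νn, 0 ≤ α ≤ 1) by pairwise SMO.
* **Evaluation.** 100× repeated patient-wise 80/20 splits with a 20%
  validation carve-out, grid search on validation AUROC, and mean (std)
  F1 / sensitivity / specificity / AUROC / AUPRC per privileged-information
  type (none, TS-ECG, SF-ECG, EHR).

## Worked example

`examples/synthetic_study.py` generates a 60-patient synthetic cohort in
the shape of the study's critically-ill cohort (55.7% positive), extracts
both feature spaces and runs the repeated evaluation:

```
$ python examples/synthetic_study.py
generating 60 patients (positive fraction 0.557, seed 42) ...
cohort: 36 positive / 60 instances
features: ECG 60, EHR 115, privileged TS 30 / SF 7 / EHR 23

ECG in the regular space ('none' = plain SVM, others = SVM+):

metric            f1  sensitivity  specificity        auroc        auprc
pi_type
none     0.84 (0.07)  0.90 (0.11)  0.62 (0.38)  0.89 (0.06)  0.94 (0.03)
ts_ecg   0.87 (0.04)  0.90 (0.11)  0.74 (0.16)  0.88 (0.07)  0.92 (0.07)
```

Each row is one privileged-information type; each cell is the mean (std)
over repeated patient-wise splits. AUROC is the probability that a random
deteriorating patient outranks a random stable one; the synthetic
generator's default effect sizes separate the classes strongly, so these
numbers are far above what real clinical data yield.

`examples/taut_string_demo.py` shows the ε-sweep on one signal, and
`examples/svmplus_vs_svm.py` compares SVM and SVM+ on a toy LUPI task.

## Layout

```
src/sepsislupi/
  taut_string.py      # tube taut string (funnel algorithm) + TS features
  signal_features.py  # Butterworth band-pass, windows, tensors, SF stats
  ehr.py              # ordinal encoders and EHR vector assembly
  labeling.py         # qSOFA, labels, instance construction
  svmplus.py          # kernels, correction matrix G, SMO solvers, SVM/SVM+
  cohort.py           # synthetic patient generator
  pipeline.py         # instance -> feature matrices
  evaluation.py       # splits, grid search, metrics, study reports
examples/             # narrative scripts, one per capability
docs/methods.md       # models, conventions, design choices, limitations
```
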
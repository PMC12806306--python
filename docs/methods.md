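# Methods

## Model

DAE-DSR couples two objectives on one shared encoder. Covariate rows
x ∈ R^p (p = 33 by default: 28 one-hot and 5 standardized numeric columns)
are corrupted with additive Gaussian noise, x̃ = x + ε, ε ~ N(0, σ²) per
cell, and passed through an encoder f (dense 32 → dense 16, rectified). The
decoder g mirrors the encoder (16 → 32 → p) with a **linear** output layer,
since the reconstruction target includes unbounded z-scored columns. The
survival head is a single-hidden-layer network on the 16-dim bottleneck:
dense(16) → batch-norm → ReLU → dropout(0.1) → one linear risk unit h.

The training loss is the weighted sum

    l = α · l_surv + γ · l_recon,   γ = 1 − α,   α = 0.6 by default,

with `l_recon` the mean per-row squared reconstruction error against the
**clean** x (the denoising objective) and `l_surv` the negative Cox partial
log-likelihood under the Breslow tie convention, computed within each
minibatch (risk sets restricted to the batch — standard deep-survival
practice; with batch 256 and n ≈ 800 the within-batch risk sets are close
to the full ones, and a full-batch mode is available by setting
`batch_size ≥ n`). Both terms are averaged — reconstruction over rows, the
partial likelihood over events (`normalize_loss=True`) — so α has a
batch-size-independent meaning.

Under proportional hazards, λ(t|x) = λ₀(t)·e^{h(x)}. After training, the
Breslow estimator on the training set materializes the cumulative baseline
hazard H₀(t) = Σ_{T_i ≤ t} d_i / Σ_{j∈R(T_i)} e^{h_j}, a right-continuous
step function with jumps at event times, and per-subject survival curves
are Ŝ(t|x) = exp(−H₀(t)·e^{h(x)}). At null scores this reduces exactly to
exp(−Nelson–Aalen), which tracks Kaplan–Meier closely (checked to 0.02
sup-norm in the tests).

## Training and model selection

Optimization is Adam (lr 0.01, default β's) over shuffled minibatches of
256 for at most 200 epochs. An 8:2 validation split is carved from the fit
rows when no validation set is passed; a trailing singleton batch is folded
into its predecessor because batch statistics are undefined for one row.
Batches that happen to contain no events contribute only the
reconstruction term. All randomness (initialization, shuffling, corruption,
dropout, validation carve) derives from a single `random_state`, and two
fits with the same seed are bit-identical.

Early stopping (patience 20) watches the **validation Cox loss**, not the
joint loss. This is a deliberate choice: the reconstruction term keeps
decreasing essentially monotonically for hundreds of epochs, so a joint
criterion never registers that the survival head has begun to overfit and
lets the model train far past its best survival epoch — in our experiments
this single choice decided whether DAE-DSR's generalization gap landed
below or far above plain DeepSurv's. The reconstruction term is an
auxiliary regularizer; model selection should target the predictive task,
and doing so also makes the stopping rule symmetric with the DeepSurv
baseline (whose only validation loss is the Cox loss). `early_stopping=
'joint'` restores the joint criterion. The best-epoch parameters (including
batch-norm running statistics) are restored before the baseline hazard is
fitted.

A `two_stage=True` mode trains the autoencoder to convergence first and
then the head on frozen clean latent codes, reflecting the alternative
pretrain-then-predict reading of the architecture; joint training is the
default.

### Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.6 | survival weight in the joint loss (γ = 1 − α) |
| `noise_sd` σ | 0.1 | corruption sd; mild relative to binary/z-scored features |
| `encoder_widths` | (32, 16) | encoder layers, bottleneck last |
| `dropout` | 0.1 | survival-head dropout |
| `batch_size` / `learning_rate` | 256 / 0.01 | Adam minibatch training |
| `max_epochs` / `patience` | 200 / 20 | early-stopping budget |
| `val_fraction` | 0.2 | validation carve (8:2) |

Corruption is additive Gaussian on **all** columns, binary included; a
masking mode (`corruption='mask'`) is provided for comparison but off by
default. σ is applied only during training — inference always encodes the
clean input. The survival head's hidden width is 16 (one hidden layer; a
two-hidden-layer variant of the risk network exists only in the DeepSurv
baseline, which uses widths 32 and 16 on the raw covariates).

## Baselines

The linear Cox model is fit by Newton–Raphson on the same Breslow partial
likelihood (suffix-sum formulation for S₀/S₁/S₂), with a small ridge
(1e-6) stabilizing separation and collinearity and step-halving guarding
each Newton step. Because it is an independent implementation of the same
likelihood, it doubles as an oracle for the deep models' loss machinery;
the suite additionally cross-checks it against an established survival
library. DeepSurv is the identical training loop with α = 1, no encoder
and no corruption, on the raw covariates.

## Evaluation

Concordance follows the risk-score orientation: a pair (i, j) is
comparable iff T_i < T_j and the earlier subject's event was observed, and
concordant iff h_i > h_j; tied scores get half credit; counting is
integer-exact before the final division. The censoring distribution Ĝ is
the Kaplan–Meier product-limit estimator with the censoring indicator as
the event. The IPCW Brier score at horizon t weighs past observed events
by 1/Ĝ(T_i) — evaluated exactly at T_i by default, with a left-limit
option matching some references — and still-at-risk subjects by 1/Ĝ(t).
The default Brier grid is 100 points from 0 to the 90th percentile of the
observed times, avoiding the Ĝ → 0 tail; the integrated Brier score is the
trapezoid integral normalized by the grid span.

## Synthetic registry generator

The generator emulates the shape of a sparse trial-registry extract:
n = 819 rows, 28 Bernoulli(1 − 0.85) binary covariates, 5 standard-normal
numeric covariates. Event times are exponential with rate
λ₀·exp(x·β + ε_i), λ₀ = 1/500 per day (a Weibull shape parameter
generalizes this; default shape 1), with subject-level latent noise
ε_i ~ N(0, noise_sd²) controlling the achievable (Bayes) concordance;
censoring is administrative, Uniform(0, censor_max = 2000 days);
missingness is injected completely at random (rate 0.05) into covariate
cells only, and the pre-missingness matrix is retained so the true risk
x·β stays computable as an evaluation ceiling. The default effect vector
has a few strong binary effects (1.0, −0.8, 0.6, 0.5, −0.4), modest
numeric effects (0.4, −0.3, 0.2) and a long tail of nulls — a handful of
design features driving termination, the rest noise. Times are continuous
to avoid artificial ties; `round_days=True` enables tie stress-testing.

What the generator does **not** model: covariate dependence (real one-hot
blocks are mutually exclusive; here binaries are independent), informative
censoring, and any nonlinearity in the true hazard (except in dedicated
interaction scenarios constructed in the tests). Passing tests therefore
demonstrate correctness of the machinery and the qualitative
regularization behavior, not performance on real registry data.

Named study conditions live in `daedsr.scenarios`: `registry_scale`
(the default above), `easy` (three strong effects, no latent noise, light
censoring — models should approach the Bayes ceiling), and
`single_binary` (one balanced covariate with log-hazard 1 and ~20%
censoring — the parameter-recovery condition; censor_max = 1500 gives the
~20% analytically, from P(censor) = E[min(T_exp, U)] arithmetic).

## Preprocessing

Order (leakage-free): exact-duplicate removal on the full table → random
80/20 train/test split → fit on the training rows only (drop columns with
missing fraction **strictly** above 0.8; KNN imputation with k = 5 on
nan-Euclidean distances, binary columns rounded back to {0,1}; per-column
z-scoring of numeric columns, population sd; min-max available) → apply
the fitted state unchanged to the test rows (imputation neighbors come
from the training rows) → SMOTE on the training rows only. The survival
variant of SMOTE interpolates the event-minority rows: each synthetic row
is x_i + u·(x_nn − x_i) with u ~ U(0,1) and x_nn one of the k = 5 nearest
minority neighbors, the synthetic `time` interpolated with the same u, and
the synthetic `event` set to the minority label — keeping (x, T) jointly
plausible under smoothness. The minority class is whichever event value is
rarer in the data at hand.

## Numerical choices and degenerate inputs

Log-sum-exp in the partial likelihood is max-shifted; tied event times
share the full risk set (Breslow; Efron not implemented). Weight
initialization is uniform fan-in scaling. Zero-variance numeric columns,
all-censored batches, singleton minority classes, columns left entirely
missing, and unfitted-model prediction all raise explicit errors;
non-finite training loss aborts with the epoch/batch location. The
experiment runner evaluates every model through the same metric code path
and records per-model failures without aborting the run.

## Problem sizes

The shipped study conditions are desk-scale by design: registry-scale
comparisons use n = 819 with 7 replicate seeds, ceiling-tracking n = 2000
with 5 seeds, recovery n = 2000 with 10 seeds. The full test suite and the
acceptance script each complete in well under a minute of CPU time at
these sizes; medians across seeds replace any single-run number because
single-seed neural results are seed-sensitive.

## Known limitations

The C-index orientation and the exact-time Ĝ(T_i) convention are
documented choices where the field has competing conventions (flags expose
the alternatives). Minibatch risk sets are an approximation to the full
partial likelihood. Feature importance by retrain-without-column measures
a feature's marginal value to the *pipeline*, not a causal effect, and is
noisy at registry scale — medians across seeds are reported for that
reason. No uncertainty quantification is attached to the C-index or Brier
estimates.
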
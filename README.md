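# daedsr

Deep survival regression with a denoising autoencoder (DAE-DSR) for
predicting time-to-termination of clinical trials from sparse registry
covariates, together with the two standard comparison models — a linear Cox
proportional-hazards fit and a plain DeepSurv network — censoring-aware
evaluation, and a synthetic registry generator with known
proportional-hazards ground truth.

## The problem

Registry extracts of clinical trials (one row per trial, ~33 covariates,
mostly one-hot encodings of design features such as randomization,
blinding, intervention allocation, sponsor class and planned sample size)
are small and extremely sparse. A deep Cox model (DeepSurv) trained on such
features overfits: training concordance exceeds test concordance by a wide
margin. DAE-DSR addresses this by learning the risk score on the latent
code of a denoising autoencoder, trained **jointly** with the survival
objective:

```
l  =  α · l_DeepSurv  +  γ · l_DAE ,      γ = 1 − α  (default α = 0.6)
```

where, for corrupted input x̃ = x + ε (Gaussian, sd σ),

* `l_DAE = mean_i ‖x_i − g_θ(f_θ(x̃_i))‖²` — reconstruction of the **clean**
  row from the corrupted one through an encoder f (widths 32 → 16) and a
  mirrored decoder g;
* `l_DeepSurv` — the negative Cox partial log-likelihood with the Breslow
  convention for ties, `−Σ_{i:E_i=1}[ h_i − log Σ_{j∈R(T_i)} e^{h_j} ]`,
  of the risk scores `h = head(f_θ(x̃))` from a single-hidden-layer network
  (batch-norm, ReLU, dropout 0.1) on the 16-dim bottleneck.

Survival curves come from the Breslow baseline-hazard estimator,
`Ŝ(t|x) = exp(−H₀(t)·e^{h(x)})`; evaluation uses Harrell's concordance
index and the IPCW (inverse-probability-of-censoring-weighted) Brier score
with a Kaplan–Meier estimate of the censoring distribution.

## Worked example

```python
import numpy as np
from daedsr import (DaeDsrSurvival, GeneratorConfig, generate_registry,
                    concordance_index, make_survival_target)
from daedsr.preprocess import RegistryPreprocessor, smote_balance, split_train_test

table = generate_registry(GeneratorConfig(n_trials=819, seed=1))   # 819 x 33
train_raw, test_raw = split_train_test(table, 0.8, seed=1)          # 655 / 164
prep  = RegistryPreprocessor().fit(train_raw)                       # impute + z-score
train, test = prep.train_table_, prep.transform(test_raw)
x, e, t = smote_balance(train.covariates, train.event, train.time, seed=1)

model = DaeDsrSurvival(alpha=0.6, noise_sd=0.1, random_state=1)
model.fit(x, make_survival_target(t, e))

c_train = concordance_index(model.predict(train.covariates), train.time, train.event)
c_test  = concordance_index(model.predict(test.covariates),  test.time,  test.event)
print(f"train C = {c_train.c_index:.3f}   test C = {c_test.c_index:.3f}")
```

```
train C = 0.700   test C = 0.627
```

A concordance of 1.0 would mean every comparable pair of trials is ranked
correctly (higher predicted risk ↔ earlier completion); 0.5 is random. On
this synthetic registry the latent noise level caps the achievable
(Bayes) concordance well below 1; the point of DAE-DSR is that its
train−test gap stays at or below plain DeepSurv's on the same data.

The same pipeline is scriptable:

```sh
daedsr simulate  --out registry.csv --seed 1
daedsr preprocess --in registry.csv --out clean.csv --test-out test.csv
daedsr train     --model daedsr --in clean.csv --out model/
daedsr evaluate  --model model/ --test test.csv --out metrics.json
daedsr benchmark --config experiment.yaml --out results/
```

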
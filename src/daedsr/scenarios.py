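"""Canonical synthetic study conditions used by the benchmark suite.

Three named scenarios cover the evaluation spectrum:

* ``registry_scale`` — the realistic condition: registry-sized sample
  (819 trials), 33 covariates with heavy one-hot sparsity (0.85), moderate
  latent noise, right censoring, injected missingness.
* ``easy`` — three strong covariates, no latent noise, light censoring and
  a large sample; fitted models should approach the generator's
  Bayes-optimal concordance here.
* ``single_binary`` — one balanced binary covariate with log-hazard 1 and
  roughly 20% administrative censoring; the parameter-recovery condition
  for the linear Cox baseline.
"""

from __future__ import annotations

import numpy as np

from .datagen import GeneratorConfig


def registry_scale_config(**overrides) -> GeneratorConfig:
    """The default registry-emulating condition (819 x 33, sparsity 0.85)."""
    return GeneratorConfig(**overrides)


def easy_config(n_trials: int = 2000, **overrides) -> GeneratorConfig:
    """Three strong covariates, no latent noise, light censoring."""
    beta = np.zeros(33)
    beta[0], beta[1], beta[28] = 2.0, -1.5, 1.0
    params = dict(
        n_trials=n_trials,
        noise_sd=0.0,
        missing_rate=0.0,
        censor_max=6000.0,
        true_coefficients=beta,
    )
    params.update(overrides)
    return GeneratorConfig(**params)


def single_binary_config(n_trials: int = 2000, beta: float = 1.0, **overrides) -> GeneratorConfig:
    """One balanced binary covariate; ~20% censoring at the default rate."""
    params = dict(
        n_trials=n_trials,
        n_binary=1,
        n_numeric=0,
        sparsity=0.5,
        true_coefficients=[beta],
        noise_sd=0.0,
        missing_rate=0.0,
        censor_max=1500.0,
    )
    params.update(overrides)
    return GeneratorConfig(**params)
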
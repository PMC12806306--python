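"""Denoising autoencoder: corruption process, encoder/decoder, and the
mean-squared reconstruction loss.

The encoder maps the p-dimensional covariate vector through two rectified
hidden layers (default widths 32 then 16) to a latent code y; the decoder
mirrors it back (16 -> 32 -> p) with a linear output layer so reconstructions
of z-scored columns are unbounded.  During training the encoder sees a
corrupted input x~ (additive Gaussian noise by default) while the
reconstruction target stays the clean x — the denoising objective that
forces robust latent features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import Dense, ReLU, Sequential


@dataclass
class CorruptedBatch:
    """A noised covariate matrix together with the noise level used."""

    x_tilde: np.ndarray
    sigma: float


def corrupt(
    x: np.ndarray,
    sigma: float,
    rng: np.random.Generator | int | None = None,
    mode: str = "gaussian",
) -> CorruptedBatch:
    """Corrupt ``x`` for denoising training.

    ``mode='gaussian'`` adds i.i.d. Normal(0, sigma^2) per cell; ``mode='mask'``
    zeroes each cell independently with probability ``sigma`` (salt-and-pepper
    style masking, provided for comparison).  ``sigma=0`` returns ``x``
    unchanged.  Deterministic given the generator state.
    """
    if sigma < 0:
        raise ValueError("noise level must be non-negative")
    x = np.asarray(x, dtype=float)
    if sigma == 0.0:
        return CorruptedBatch(x.copy(), 0.0)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if mode == "gaussian":
        x_tilde = x + rng.normal(0.0, sigma, size=x.shape)
    elif mode == "mask":
        x_tilde = np.where(rng.random(x.shape) < sigma, 0.0, x)
    else:
        raise ValueError(f"unknown corruption mode '{mode}'")
    return CorruptedBatch(x_tilde, sigma)


def reconstruction_loss(x: np.ndarray, x_prime: np.ndarray) -> float:
    """Mean over rows of the squared Euclidean reconstruction error
    ||x - x'||^2."""
    x = np.asarray(x, dtype=float)
    x_prime = np.asarray(x_prime, dtype=float)
    if x.shape != x_prime.shape:
        raise ValueError("x and x' must have the same shape")
    return float(((x - x_prime) ** 2).sum(axis=1).mean())


def reconstruction_loss_grad(x: np.ndarray, x_prime: np.ndarray) -> np.ndarray:
    """Gradient of :func:`reconstruction_loss` with respect to ``x_prime``."""
    n = x.shape[0]
    return 2.0 * (x_prime - x) / n


class Autoencoder:
    """Encoder/decoder pair sized for sparse registry covariates.

    Parameters
    ----------
    input_dim : covariate dimension p.
    encoder_widths : hidden widths ending in the bottleneck (default (32, 16)).
    rng : generator (or seed) for the fan-in uniform weight initialization.
    """

    def __init__(
        self,
        input_dim: int,
        encoder_widths: tuple[int, ...] = (32, 16),
        rng: np.random.Generator | int | None = None,
    ):
        if any(w <= 0 for w in encoder_widths):
            raise ValueError("encoder widths must be positive")
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.input_dim = input_dim
        self.encoder_widths = tuple(encoder_widths)
        self.latent_dim = encoder_widths[-1]

        enc_layers: list = []
        d = input_dim
        for w in encoder_widths:
            enc_layers += [Dense(d, w, rng), ReLU()]
            d = w
        self.encoder = Sequential(enc_layers)

        dec_layers: list = []
        for w in reversed(self.encoder_widths[:-1]):
            dec_layers += [Dense(d, w, rng), ReLU()]
            d = w
        dec_layers += [Dense(d, input_dim, rng)]  # linear output for MSE targets
        self.decoder = Sequential(dec_layers)

    def encode(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[1] != self.input_dim:
            raise ValueError(
                f"expected {self.input_dim} input columns, got {x.shape[1]}"
            )
        return self.encoder.forward(x, training)

    def decode(self, y: np.ndarray, training: bool = False) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if y.shape[1] != self.latent_dim:
            raise ValueError(f"expected {self.latent_dim} latent columns")
        return self.decoder.forward(y, training)

    def params(self):
        return self.encoder.params() + self.decoder.params()

    def grads(self):
        return self.encoder.grads() + self.decoder.grads()

    def zero_grad(self):
        self.encoder.zero_grad()
        self.decoder.zero_grad()
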
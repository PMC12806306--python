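"""Joint DAE-DSR model and the plain DeepSurv network, as scikit-learn-style
estimators.

``DaeDsrSurvival`` trains a denoising autoencoder and a deep Cox head
jointly under the weighted loss

    l = alpha * l_surv + gamma * l_recon,        gamma = 1 - alpha

where ``l_surv`` is the Breslow negative partial log-likelihood of the risk
scores computed on the latent code of the *corrupted* input, and ``l_recon``
is the mean squared reconstruction error against the *clean* input.  At
``alpha = 1`` the model degenerates to DeepSurv-on-latent; at ``alpha = 0``
to a pure denoising autoencoder.  ``DeepSurv`` is the comparison model: the
same Cox head machinery on the raw covariates, no encoder, no corruption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from ._nn import Adam, BatchNorm, Dense, Dropout, ReLU, Sequential
from .dae import Autoencoder, corrupt, reconstruction_loss, reconstruction_loss_grad
from .survival import (
    SurvivalHead,
    breslow_baseline,
    cox_nll_breslow,
    cox_nll_breslow_with_grad,
    predict_survival,
)
from .util import check_survival_y


@dataclass
class LossWeights:
    """Weights of the joint objective; ``gamma`` defaults to ``1 - alpha``
    (``beta`` is an accepted alias for ``gamma``)."""

    alpha: float = 0.6
    gamma: float | None = None

    def __init__(self, alpha: float = 0.6, gamma: float | None = None, beta: float | None = None):
        if gamma is not None and beta is not None and gamma != beta:
            raise ValueError("gamma and its alias beta disagree")
        self.alpha = float(alpha)
        self.gamma = float(beta if gamma is None and beta is not None else (1.0 - alpha if gamma is None else gamma))
        if not 0.0 <= self.alpha <= 1.0 or self.gamma < 0:
            raise ValueError("alpha must lie in [0, 1] and gamma must be non-negative")
        if abs(self.alpha + self.gamma - 1.0) > 1e-9:
            raise ValueError("alpha + gamma must equal 1")

    @property
    def beta(self) -> float:
        return self.gamma


def joint_loss(l_recon: float, l_surv: float, w: LossWeights) -> float:
    """Weighted linear combination ``alpha * l_surv + gamma * l_recon``."""
    if not (np.isfinite(l_recon) and np.isfinite(l_surv)):
        raise ValueError("component losses must be finite")
    return w.alpha * l_surv + w.gamma * l_recon


def _batch_slices(n: int, batch_size: int, rng: np.random.Generator):
    """Shuffled minibatch index arrays; a trailing singleton is folded into
    the previous batch (batch-norm needs >= 2 rows)."""
    perm = rng.permutation(n)
    starts = list(range(0, n, batch_size))
    batches = [perm[s : s + batch_size] for s in starts]
    if len(batches) > 1 and len(batches[-1]) == 1:
        batches[-2] = np.concatenate([batches[-2], batches[-1]])
        batches.pop()
    return batches


def _collect_state(nets) -> list[np.ndarray]:
    state = [p.copy() for net in nets for p in net.params()]
    for net in nets:
        for layer in _layers_of(net):
            if isinstance(layer, BatchNorm):
                state += [layer.running_mean.copy(), layer.running_var.copy()]
    return state


def _restore_state(nets, state: list[np.ndarray]) -> None:
    k = 0
    for net in nets:
        for p in net.params():
            p[...] = state[k]
            k += 1
    for net in nets:
        for layer in _layers_of(net):
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = state[k]
                layer.running_var[...] = state[k + 1]
                k += 2


def _layers_of(net):
    return net.layers if isinstance(net, Sequential) else (
        net.encoder.layers + net.decoder.layers
        if isinstance(net, Autoencoder)
        else net.net.layers
    )


def _carve_validation(n, times, events, val_fraction, rng):
    """Split fit rows into train/validation (default 8:2), making sure both
    sides keep at least one event."""
    perm = rng.permutation(n)
    n_val = max(1, int(np.floor(val_fraction * n)))
    if n_val >= n:
        raise ValueError("validation fraction leaves no training rows")
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if events[val_idx].sum() == 0 or events[tr_idx].sum() == 0:
        short, other = (
            (val_idx, tr_idx) if events[val_idx].sum() == 0 else (tr_idx, val_idx)
        )
        donors = other[events[other] == 1]
        if len(donors) < 2:
            raise ValueError("too few events to form a validation split")
        swap_in = donors[0]
        swap_out = short[0]
        short[0] = swap_in
        other[np.flatnonzero(other == swap_in)[0]] = swap_out
    return tr_idx, val_idx


class _DeepCoxBase(BaseEstimator):
    """Shared prediction surface for the fitted deep survival models."""

    def predict(self, X) -> np.ndarray:
        """Risk scores h(x); higher means earlier predicted completion."""
        self._check_fitted()
        return self._risk(np.asarray(X, dtype=float))

    def predict_survival_function(self, X, times=None):
        """Per-subject survival curves from the fitted Breslow baseline."""
        self._check_fitted()
        if self.baseline_hazard_ is None:
            raise ValueError("model has no fitted baseline hazard")
        if times is None:
            grid = self.baseline_hazard_.event_times
            times = np.concatenate([[0.0], grid])
        return predict_survival(self.baseline_hazard_, self.predict(X), times)

    def score(self, X, y) -> float:
        """Harrell's C on (X, y) — higher is better, for model selection."""
        from .evaluation import concordance_index

        times, events = check_survival_y(y)
        return concordance_index(self.predict(X), times, events).c_index

    def _check_fitted(self):
        if not hasattr(self, "baseline_hazard_"):
            raise ValueError("estimator is not fitted")


class DaeDsrSurvival(_DeepCoxBase):
    """Denoising-autoencoder deep survival regression (DAE-DSR).

    Parameters
    ----------
    alpha : weight of the survival loss term in [0, 1]; the reconstruction
        term gets ``1 - alpha``.  Default 0.6.
    noise_sd : sd of the additive Gaussian input corruption (default 0.1;
        covariates are z-scored or binary, so this is a mild corruption).
    corruption : 'gaussian' (default) or 'mask'.
    encoder_widths : encoder hidden widths ending in the bottleneck
        (default (32, 16)).
    head_hidden : width of the survival head's single hidden layer.
    dropout, batch_norm : survival-head regularization (defaults 0.1, True).
    batch_size, learning_rate, max_epochs, patience : Adam training loop
        controls (defaults 256, 0.01, 200, 20); early stopping watches the
        validation joint loss.
    val_fraction : fraction of fit rows carved off for early stopping when
        no validation set is passed (default 0.2, i.e. an 8:2 split).
    two_stage : train the autoencoder first and the head second on frozen
        latent features, instead of jointly.
    early_stopping : which validation loss the patience watches: 'surv'
        (default) stops on the validation Cox loss — the model-selection
        task loss, symmetric with the DeepSurv baseline — while 'joint'
        stops on the full weighted objective (whose reconstruction term
        keeps decreasing long after the survival head starts overfitting).
    normalize_loss : divide the Cox loss by the batch event count so alpha
        keeps a consistent meaning across batch sizes (default True).
    random_state : seed for initialization, shuffling, corruption, dropout.
    """

    def __init__(
        self,
        alpha: float = 0.6,
        noise_sd: float = 0.1,
        corruption: str = "gaussian",
        encoder_widths: tuple[int, ...] = (32, 16),
        head_hidden: int = 16,
        dropout: float = 0.1,
        batch_norm: bool = True,
        batch_size: int = 256,
        learning_rate: float = 0.01,
        max_epochs: int = 200,
        patience: int = 20,
        val_fraction: float = 0.2,
        two_stage: bool = False,
        early_stopping: str = "surv",
        normalize_loss: bool = True,
        random_state: int | None = None,
    ):
        self.alpha = alpha
        self.noise_sd = noise_sd
        self.corruption = corruption
        self.encoder_widths = encoder_widths
        self.head_hidden = head_hidden
        self.dropout = dropout
        self.batch_norm = batch_norm
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.two_stage = two_stage
        self.early_stopping = early_stopping
        self.normalize_loss = normalize_loss
        self.random_state = random_state

    # -- construction ---------------------------------------------------
    def _init_networks(self, p: int, init_seed: int, dropout_seed: int):
        self.autoencoder_ = Autoencoder(
            p, tuple(self.encoder_widths), rng=np.random.default_rng(init_seed)
        )
        self.head_ = SurvivalHead(
            self.autoencoder_.latent_dim,
            self.head_hidden,
            self.dropout,
            self.batch_norm,
            rng=np.random.default_rng(dropout_seed),
        )

    # -- training -------------------------------------------------------
    def fit(self, X, y, validation_data=None):
        X = np.asarray(X, dtype=float)
        times, events = check_survival_y(y)
        if np.isnan(X).any():
            raise ValueError("fit requires imputed (no-missing) covariates")
        if events.sum() == 0:
            raise ValueError("training data has no events")
        if self.early_stopping not in ("surv", "joint"):
            raise ValueError("early_stopping must be 'surv' or 'joint'")
        n, p = X.shape
        self.n_features_in_ = p
        w = LossWeights(alpha=self.alpha)
        self.loss_weights_ = w

        rng = np.random.default_rng(self.random_state)
        init_seed, drop_seed, shuffle_seed, noise_seed, split_seed = rng.integers(
            0, 2**31, size=5
        )
        self._init_networks(p, init_seed, drop_seed)

        if validation_data is not None:
            X_val = np.asarray(validation_data[0], dtype=float)
            t_val, e_val = check_survival_y(validation_data[1])
            X_tr, t_tr, e_tr = X, times, events
        else:
            tr_idx, val_idx = _carve_validation(
                n, times, events, self.val_fraction, np.random.default_rng(split_seed)
            )
            X_tr, t_tr, e_tr = X[tr_idx], times[tr_idx], events[tr_idx]
            X_val, t_val, e_val = X[val_idx], times[val_idx], events[val_idx]

        shuffle_rng = np.random.default_rng(shuffle_seed)
        noise_rng = np.random.default_rng(noise_seed)

        if self.two_stage:
            self._fit_two_stage(X_tr, t_tr, e_tr, X_val, t_val, e_val, w, shuffle_rng, noise_rng)
        else:
            self._fit_joint(X_tr, t_tr, e_tr, X_val, t_val, e_val, w, shuffle_rng, noise_rng)

        # refit the baseline hazard with the frozen encoder on clean inputs
        scores = self._risk(X)
        self.baseline_hazard_ = breslow_baseline(scores, times, events)
        return self

    def _fit_joint(self, X_tr, t_tr, e_tr, X_val, t_val, e_val, w, shuffle_rng, noise_rng):
        ae, head = self.autoencoder_, self.head_
        opt = Adam(ae.params() + head.params(), ae.grads() + head.grads(), lr=self.learning_rate)
        best_val, best_state, stall = np.inf, None, 0
        self.history_ = []
        for epoch in range(self.max_epochs):
            epoch_losses = []
            for b, idx in enumerate(_batch_slices(len(X_tr), self.batch_size, shuffle_rng)):
                xb, tb, eb = X_tr[idx], t_tr[idx], e_tr[idx]
                ae.zero_grad()
                head.zero_grad()
                x_tilde = corrupt(xb, self.noise_sd, noise_rng, self.corruption).x_tilde
                yb = ae.encoder.forward(x_tilde, training=True)
                x_prime = ae.decoder.forward(yb, training=True)
                l_recon = reconstruction_loss(xb, x_prime)
                sb = head.forward(yb, training=True).ravel()
                if eb.sum() > 0:
                    l_surv, g_s = cox_nll_breslow_with_grad(
                        sb, tb, eb, normalize=self.normalize_loss
                    )
                else:  # no event in batch: only the reconstruction term acts
                    l_surv, g_s = 0.0, np.zeros_like(sb)
                loss = joint_loss(l_recon, l_surv, w)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged (non-finite loss) at epoch {epoch}, batch {b}"
                    )
                g_y_head = head.net.backward(w.alpha * g_s[:, None])
                g_y_dec = ae.decoder.backward(
                    w.gamma * reconstruction_loss_grad(xb, x_prime)
                )
                ae.encoder.backward(g_y_head + g_y_dec)
                opt.step()
                epoch_losses.append(loss)

            val_loss, val_recon, val_surv = self._validation_losses(
                X_val, t_val, e_val, w
            )
            self.history_.append(
                {
                    "epoch": epoch,
                    "train_loss": float(np.mean(epoch_losses)),
                    "val_loss": val_loss,
                    "val_recon": val_recon,
                    "val_surv": val_surv,
                }
            )
            watched = val_surv if self.early_stopping == "surv" else val_loss
            if watched < best_val - 1e-12:
                best_val, stall = watched, 0
                best_state = _collect_state([ae, head])
            else:
                stall += 1
                if stall >= self.patience:
                    break
        if best_state is not None:
            _restore_state([ae, head], best_state)

    def _fit_two_stage(self, X_tr, t_tr, e_tr, X_val, t_val, e_val, w, shuffle_rng, noise_rng):
        ae, head = self.autoencoder_, self.head_
        # stage 1: denoising autoencoder alone
        opt = Adam(ae.params(), ae.grads(), lr=self.learning_rate)
        best_val, best_state, stall = np.inf, None, 0
        self.history_ = []
        for epoch in range(self.max_epochs):
            for idx in _batch_slices(len(X_tr), self.batch_size, shuffle_rng):
                xb = X_tr[idx]
                ae.zero_grad()
                x_tilde = corrupt(xb, self.noise_sd, noise_rng, self.corruption).x_tilde
                x_prime = ae.decoder.forward(
                    ae.encoder.forward(x_tilde, training=True), training=True
                )
                ae.encoder.backward(
                    ae.decoder.backward(reconstruction_loss_grad(xb, x_prime))
                )
                opt.step()
            val_recon = reconstruction_loss(
                X_val, ae.decode(ae.encode(X_val))
            )
            self.history_.append({"epoch": epoch, "stage": 1, "val_recon": val_recon})
            if val_recon < best_val - 1e-12:
                best_val, stall = val_recon, 0
                best_state = _collect_state([ae])
            else:
                stall += 1
                if stall >= self.patience:
                    break
        if best_state is not None:
            _restore_state([ae], best_state)
        # stage 2: survival head on frozen clean latent features
        z_tr, z_val = ae.encode(X_tr), ae.encode(X_val)
        opt = Adam(head.params(), head.grads(), lr=self.learning_rate)
        best_val, best_state, stall = np.inf, None, 0
        for epoch in range(self.max_epochs):
            for idx in _batch_slices(len(z_tr), self.batch_size, shuffle_rng):
                if e_tr[idx].sum() == 0:
                    continue
                head.zero_grad()
                sb = head.forward(z_tr[idx], training=True).ravel()
                _, g_s = cox_nll_breslow_with_grad(
                    sb, t_tr[idx], e_tr[idx], normalize=self.normalize_loss
                )
                head.net.backward(g_s[:, None])
                opt.step()
            val_surv = cox_nll_breslow(
                head.risk_score(z_val), t_val, e_val, normalize=self.normalize_loss
            )
            self.history_.append({"epoch": epoch, "stage": 2, "val_surv": val_surv})
            if val_surv < best_val - 1e-12:
                best_val, stall = val_surv, 0
                best_state = _collect_state([head])
            else:
                stall += 1
                if stall >= self.patience:
                    break
        if best_state is not None:
            _restore_state([head], best_state)

    def _validation_losses(self, X_val, t_val, e_val, w):
        y_val = self.autoencoder_.encode(X_val)
        l_recon = reconstruction_loss(X_val, self.autoencoder_.decode(y_val))
        l_surv = cox_nll_breslow(
            self.head_.risk_score(y_val), t_val, e_val, normalize=self.normalize_loss
        )
        return joint_loss(l_recon, l_surv, w), l_recon, l_surv

    # -- inference ------------------------------------------------------
    def transform(self, X) -> np.ndarray:
        """Clean (uncorrupted) latent features, evaluation mode."""
        if not hasattr(self, "autoencoder_"):
            raise ValueError("estimator is not fitted")
        return self.autoencoder_.encode(np.asarray(X, dtype=float))

    def _risk(self, X) -> np.ndarray:
        return self.head_.risk_score(self.autoencoder_.encode(X))


class DeepSurv(_DeepCoxBase):
    """Deep Cox proportional-hazards network on raw covariates.

    Two rectified hidden layers (default widths 32 and 16, each with batch
    normalization and dropout), one linear risk unit, trained on the Breslow
    negative partial log-likelihood — the comparison model for DAE-DSR: no
    encoder, no input corruption.
    """

    def __init__(
        self,
        hidden_widths: tuple[int, ...] = (32, 16),
        dropout: float = 0.1,
        batch_norm: bool = True,
        batch_size: int = 256,
        learning_rate: float = 0.01,
        max_epochs: int = 200,
        patience: int = 20,
        val_fraction: float = 0.2,
        normalize_loss: bool = True,
        random_state: int | None = None,
    ):
        self.hidden_widths = hidden_widths
        self.dropout = dropout
        self.batch_norm = batch_norm
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.normalize_loss = normalize_loss
        self.random_state = random_state

    def _init_networks(self, p: int, init_seed: int, dropout_seed: int):
        rng = np.random.default_rng(init_seed)
        drop_rng = np.random.default_rng(dropout_seed)
        layers: list = []
        d = p
        for wdt in self.hidden_widths:
            layers.append(Dense(d, wdt, rng))
            if self.batch_norm:
                layers.append(BatchNorm(wdt))
            layers += [ReLU(), Dropout(self.dropout, drop_rng)]
            d = wdt
        layers.append(Dense(d, 1, rng))
        self.net_ = Sequential(layers)

    def fit(self, X, y, validation_data=None):
        X = np.asarray(X, dtype=float)
        times, events = check_survival_y(y)
        if np.isnan(X).any():
            raise ValueError("fit requires imputed (no-missing) covariates")
        if events.sum() == 0:
            raise ValueError("training data has no events")
        n, p = X.shape
        self.n_features_in_ = p

        rng = np.random.default_rng(self.random_state)
        init_seed, drop_seed, shuffle_seed, split_seed = rng.integers(0, 2**31, size=4)
        self._init_networks(p, init_seed, drop_seed)

        if validation_data is not None:
            X_val = np.asarray(validation_data[0], dtype=float)
            t_val, e_val = check_survival_y(validation_data[1])
            X_tr, t_tr, e_tr = X, times, events
        else:
            tr_idx, val_idx = _carve_validation(
                n, times, events, self.val_fraction, np.random.default_rng(split_seed)
            )
            X_tr, t_tr, e_tr = X[tr_idx], times[tr_idx], events[tr_idx]
            X_val, t_val, e_val = X[val_idx], times[val_idx], events[val_idx]

        shuffle_rng = np.random.default_rng(shuffle_seed)
        opt = Adam(self.net_.params(), self.net_.grads(), lr=self.learning_rate)
        best_val, best_state, stall = np.inf, None, 0
        self.history_ = []
        for epoch in range(self.max_epochs):
            epoch_losses = []
            for b, idx in enumerate(_batch_slices(len(X_tr), self.batch_size, shuffle_rng)):
                if e_tr[idx].sum() == 0:
                    continue
                self.net_.zero_grad()
                sb = self.net_.forward(X_tr[idx], training=True).ravel()
                loss, g_s = cox_nll_breslow_with_grad(
                    sb, t_tr[idx], e_tr[idx], normalize=self.normalize_loss
                )
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged (non-finite loss) at epoch {epoch}, batch {b}"
                    )
                self.net_.backward(g_s[:, None])
                opt.step()
                epoch_losses.append(loss)
            val_loss = cox_nll_breslow(
                self._risk(X_val), t_val, e_val, normalize=self.normalize_loss
            )
            self.history_.append(
                {
                    "epoch": epoch,
                    "train_loss": float(np.mean(epoch_losses)) if epoch_losses else np.nan,
                    "val_loss": val_loss,
                }
            )
            if val_loss < best_val - 1e-12:
                best_val, stall = val_loss, 0
                best_state = _collect_state([self.net_])
            else:
                stall += 1
                if stall >= self.patience:
                    break
        if best_state is not None:
            _restore_state([self.net_], best_state)

        self.baseline_hazard_ = breslow_baseline(self._risk(X), times, events)
        return self

    def _risk(self, X) -> np.ndarray:
        return self.net_.forward(np.asarray(X, dtype=float), training=False).ravel()
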
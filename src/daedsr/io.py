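"""Checkpoint persistence: binary weight archive (.npz) plus a JSON
metadata sidecar recording the estimator class, hyperparameters, and the
fitted Breslow baseline."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ._nn import BatchNorm
from .baselines import CoxPHNewton
from .models import DaeDsrSurvival, DeepSurv
from .survival import BaselineHazard

_CLASSES = {c.__name__: c for c in (DaeDsrSurvival, DeepSurv, CoxPHNewton)}


def _networks(model):
    if isinstance(model, DaeDsrSurvival):
        return [model.autoencoder_, model.head_]
    if isinstance(model, DeepSurv):
        return [model.net_]
    return []


def _bn_layers(model):
    from .models import _layers_of

    return [
        layer
        for net in _networks(model)
        for layer in _layers_of(net)
        if isinstance(layer, BatchNorm)
    ]


def save_model(model, out_dir) -> Path:
    """Write ``weights.npz`` and ``model.json`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {}
    if isinstance(model, CoxPHNewton):
        arrays["coef"] = model.coef_
    else:
        for i, p in enumerate([p for net in _networks(model) for p in net.params()]):
            arrays[f"param_{i}"] = p
        for i, bn in enumerate(_bn_layers(model)):
            arrays[f"bn_mean_{i}"] = bn.running_mean
            arrays[f"bn_var_{i}"] = bn.running_var
    arrays["baseline_times"] = model.baseline_hazard_.event_times
    arrays["baseline_cumulative"] = model.baseline_hazard_.cumulative
    np.savez(out / "weights.npz", **arrays)

    meta = {
        "class": type(model).__name__,
        "params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in model.get_params().items()
        },
        "n_features_in": int(model.n_features_in_),
    }
    (out / "model.json").write_text(json.dumps(meta, indent=2) + "\n")
    return out


def load_model(model_dir):
    """Reconstruct a fitted estimator from :func:`save_model` output."""
    d = Path(model_dir)
    meta = json.loads((d / "model.json").read_text())
    cls = _CLASSES[meta["class"]]
    params = {
        k: (tuple(v) if isinstance(v, list) else v) for k, v in meta["params"].items()
    }
    model = cls(**params)
    arrays = np.load(d / "weights.npz")
    p = meta["n_features_in"]
    model.n_features_in_ = p
    if cls is CoxPHNewton:
        model.coef_ = arrays["coef"]
    else:
        model._init_networks(p, 0, 0)
        flat = [q for net in _networks(model) for q in net.params()]
        for i, q in enumerate(flat):
            q[...] = arrays[f"param_{i}"]
        for i, bn in enumerate(_bn_layers(model)):
            bn.running_mean[...] = arrays[f"bn_mean_{i}"]
            bn.running_var[...] = arrays[f"bn_var_{i}"]
    model.baseline_hazard_ = BaselineHazard(
        event_times=arrays["baseline_times"], cumulative=arrays["baseline_cumulative"]
    )
    return model
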
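"""Deep belief network classifier built from stacked RBMs.

A restricted Boltzmann machine (RBM) is a bipartite energy-based model
over binary visible and hidden units with energy

    E(v, h) = -a'v - b'h - v'Wh

Stacking RBMs and training them greedily — each layer by contrastive
divergence (CD) on the hidden-probability transform of its predecessor —
yields a deep belief network.  Fine-tuning uses the up-down (wake-sleep)
procedure: the *wake* pass runs the recognition (bottom-up) weights and
fits the generative (top-down) weights to reconstruct each layer; the
*sleep* pass runs the generative weights and fits the recognition weights
to invert them; the top RBM is refreshed by CD with the class labels
concatenated to its visible layer.  A softmax head over the top-layer
hidden probabilities is trained jointly (with dropout) by the Adamax rule,
and its cross-entropy gradient is also propagated into the recognition
weights so that supervised fine-tuning actually reduces the training error
the greedy phase leaves behind.

Real-valued feature vectors are min-max scaled to [0, 1] and treated as
Bernoulli probabilities by the first layer.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np

from . import _nn
from .adamax import AdamaxOptimizer
from .errors import ParameterError, StructuralError

__all__ = [
    "RBMLayer",
    "DBNModel",
    "TrainConfig",
    "rbm_energy",
    "prop_up",
    "prop_down",
    "cd_update",
    "greedy_pretrain",
    "up_down_finetune",
    "predict",
    "build_model",
]


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


@dataclass
class RBMLayer:
    """One RBM: weights W (visible x hidden), visible bias a, hidden bias b."""

    W: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        if self.W.shape != (self.a.size, self.b.size):
            raise StructuralError(
                f"RBM shapes inconsistent: W {self.W.shape}, a {self.a.size}, b {self.b.size}"
            )

    @property
    def n_visible(self) -> int:
        return self.a.size

    @property
    def n_hidden(self) -> int:
        return self.b.size

    def copy(self) -> "RBMLayer":
        return RBMLayer(self.W.copy(), self.a.copy(), self.b.copy())


def prop_up(layer: RBMLayer, v: np.ndarray) -> np.ndarray:
    """p(h=1 | v), rows = samples."""
    return _sigmoid(np.atleast_2d(v) @ layer.W + layer.b)


def prop_down(layer: RBMLayer, h: np.ndarray) -> np.ndarray:
    """p(v=1 | h), rows = samples."""
    return _sigmoid(np.atleast_2d(h) @ layer.W.T + layer.a)


def rbm_energy(layer: RBMLayer, v: np.ndarray, h: np.ndarray) -> float:
    """Joint energy E(v, h); lower energy means higher unnormalized probability."""
    v = np.asarray(v, dtype=np.float64).ravel()
    h = np.asarray(h, dtype=np.float64).ravel()
    if v.size != layer.n_visible or h.size != layer.n_hidden:
        raise StructuralError(
            f"state sizes ({v.size}, {h.size}) do not match RBM "
            f"({layer.n_visible}, {layer.n_hidden})"
        )
    return float(-layer.a @ v - layer.b @ h - v @ layer.W @ h)


def cd_update(layer: RBMLayer, batch: np.ndarray, k: int = 1, lr: float = 0.01,
              rng: np.random.Generator | None = None) -> RBMLayer:
    """One CD-k gradient step on a batch; returns a new layer.

    Positive statistics come from the data, negative statistics from k
    alternating Gibbs samples (hidden states sampled, final statistics
    taken on probabilities, the usual CD recipe).
    """
    if k < 1:
        raise ParameterError("cd steps k must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    batch = np.atleast_2d(np.asarray(batch, dtype=np.float64))
    if batch.shape[1] != layer.n_visible:
        raise StructuralError(
            f"batch width {batch.shape[1]} != visible size {layer.n_visible}"
        )
    n = batch.shape[0]
    ph0 = prop_up(layer, batch)
    h = (rng.random(ph0.shape) < ph0).astype(np.float64)
    for _ in range(k):
        pv = prop_down(layer, h)
        v = (rng.random(pv.shape) < pv).astype(np.float64)
        ph = prop_up(layer, v)
        h = (rng.random(ph.shape) < ph).astype(np.float64)
    dW = (batch.T @ ph0 - v.T @ ph) / n
    da = (batch - v).mean(axis=0)
    db = (ph0 - ph).mean(axis=0)
    return RBMLayer(layer.W + lr * dW, layer.a + lr * da, layer.b + lr * db)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (reference defaults: learning rate 0.01,
    dropout 0.5, batch size 5, 50 epochs)."""

    cd_steps: int = 1
    epochs: int = 50
    batch_size: int = 5
    learning_rate: float = 0.01
    dropout: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.cd_steps < 1 or self.epochs < 0 or self.batch_size < 1 \
                or self.learning_rate <= 0:
            raise ParameterError("invalid training configuration")


@dataclass
class DBNModel:
    """Stacked RBM layers plus a linear softmax head over the top layer."""

    layers: list[RBMLayer]
    head_W: np.ndarray
    head_b: np.ndarray
    label_W: np.ndarray | None = None   # label pathway into the top RBM (wake phase)
    label_a: np.ndarray | None = None
    input_min: np.ndarray | None = None  # min-max scaling learned from training data
    input_range: np.ndarray | None = None
    pretrained: bool = False

    def __post_init__(self):
        for lo, hi in zip(self.layers[:-1], self.layers[1:]):
            if lo.n_hidden != hi.n_visible:
                raise StructuralError("consecutive RBM layer shapes do not chain")
        if self.head_W.shape[0] != self.layers[-1].n_hidden:
            raise StructuralError("head width does not match top hidden layer")

    @property
    def layer_sizes(self) -> list[int]:
        return [self.layers[0].n_visible] + [l.n_hidden for l in self.layers]

    def copy(self) -> "DBNModel":
        return copy.deepcopy(self)


def build_model(layer_sizes: list[int], n_classes: int = 2, seed: int = 0,
                scale: float = 0.1) -> DBNModel:
    """Fresh model with small Gaussian weights and zero biases."""
    if len(layer_sizes) < 2:
        raise ParameterError("need at least one RBM layer")
    rng = np.random.default_rng(seed)
    layers = [
        RBMLayer(scale * rng.standard_normal((nv, nh)), np.zeros(nv), np.zeros(nh))
        for nv, nh in zip(layer_sizes[:-1], layer_sizes[1:])
    ]
    head_W = scale * rng.standard_normal((layer_sizes[-1], n_classes))
    head_b = np.zeros(n_classes)
    label_W = scale * rng.standard_normal((n_classes, layer_sizes[-1]))
    label_a = np.zeros(n_classes)
    return DBNModel(layers, head_W, head_b, label_W, label_a)


def scale_features(model: DBNModel, x: np.ndarray, fit: bool = False) -> np.ndarray:
    """Min-max scale features to [0, 1] using (optionally fitting) the model's stats."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if fit or model.input_min is None:
        model.input_min = x.min(axis=0)
        rng_ = x.max(axis=0) - model.input_min
        model.input_range = np.where(rng_ > 0, rng_, 1.0)
    return np.clip((x - model.input_min) / model.input_range, 0.0, 1.0)


def _up_pass(model: DBNModel, v: np.ndarray) -> list[np.ndarray]:
    """Mean-field bottom-up pass; returns activations per layer (incl. input)."""
    acts = [v]
    for layer in model.layers:
        acts.append(prop_up(layer, acts[-1]))
    return acts


def greedy_pretrain(model: DBNModel, data: np.ndarray, config: TrainConfig) -> DBNModel:
    """Layer-wise CD pretraining; returns a trained copy of the model.

    Layer 1 is trained on the data, each subsequent layer on the hidden
    probabilities of its (already trained) predecessor.
    """
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    if data.shape[1] != model.layers[0].n_visible:
        raise StructuralError(
            f"data width {data.shape[1]} != first visible size "
            f"{model.layers[0].n_visible}"
        )
    model = model.copy()
    if config.epochs == 0:
        return model
    rng = np.random.default_rng(config.seed)
    level = data
    for li, layer in enumerate(model.layers):
        for _ in range(config.epochs):
            order = rng.permutation(level.shape[0])
            for start in range(0, level.shape[0], config.batch_size):
                batch = level[order[start:start + config.batch_size]]
                layer = cd_update(layer, batch, config.cd_steps,
                                  config.learning_rate, rng)
        model.layers[li] = layer
        level = prop_up(layer, level)
    model.pretrained = True
    return model


def up_down_finetune(model: DBNModel, data: np.ndarray, labels: np.ndarray,
                     config: TrainConfig, n_classes: int = 2,
                     log: list | None = None) -> DBNModel:
    """Wake-sleep fine-tuning plus joint discriminative head training.

    Returns a fine-tuned copy.  Per epoch and minibatch:

    1. wake: sample states bottom-up through the recognition weights and
       fit per-layer generative weights (delta rule) to reconstruct;
    2. top CD: contrastive-divergence refresh of the top RBM with the
       one-hot labels concatenated to its visible layer;
    3. sleep: sample top-down through the generative weights and fit the
       recognition weights to invert the generative model;
    4. discriminative: softmax head over top-layer probabilities (dropout
       on its input), trained with Adamax; the cross-entropy gradient is
       backpropagated into the recognition weights.

    An unpretrained model is accepted but flagged in ``log``.
    """
    model = model.copy()
    if config.epochs == 0:
        return model
    if not model.pretrained and log is not None:
        log.append({"warning": "fine-tuning an unpretrained model"})
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    labels = np.asarray(labels, dtype=np.int64)
    rng = np.random.default_rng(config.seed)
    onehot = np.eye(n_classes)[labels]

    # untied generative copies of every non-top layer
    gen = [layer.copy() for layer in model.layers[:-1]]
    if model.label_W is None:
        model.label_W = 0.01 * rng.standard_normal((n_classes, model.layers[-1].n_hidden))
        model.label_a = np.zeros(n_classes)

    disc_params = {"head_W": model.head_W, "head_b": model.head_b}
    for li, layer in enumerate(model.layers):
        disc_params[f"W{li}"] = layer.W
        disc_params[f"b{li}"] = layer.b
    opt = AdamaxOptimizer(disc_params, lr=config.learning_rate)
    lr = config.learning_rate
    # generative (wake/sleep/top-CD) refinement runs at a tenth of the
    # supervised rate so it regularizes rather than overrides the
    # discriminative signal
    gen_lr = 0.1 * lr
    n = data.shape[0]

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch, y = data[idx], onehot[idx]
            bs = len(idx)

            # --- wake: recognition samples, generative updates
            states = [batch]
            for layer in model.layers[:-1]:
                p = prop_up(layer, states[-1])
                states.append((rng.random(p.shape) < p).astype(np.float64))
            for li, g in enumerate(gen):
                recon = prop_down(g, states[li + 1])
                g.W += gen_lr * (states[li] - recon).T @ states[li + 1] / bs
                g.a += gen_lr * (states[li] - recon).mean(axis=0)

            # --- top RBM: CD-k on [top input, labels], updated in place
            top = model.layers[-1]
            w_aug = np.vstack([top.W, model.label_W])
            a_aug = np.concatenate([top.a, model.label_a])
            aug = RBMLayer(w_aug, a_aug, top.b.copy())
            aug_batch = np.hstack([states[-1], y])
            aug = cd_update(aug, aug_batch, config.cd_steps, gen_lr, rng)
            nv = top.n_visible
            top.W[...] = aug.W[:nv]
            top.a[...] = aug.a[:nv]
            top.b[...] = aug.b
            model.label_W[...] = aug.W[nv:]
            model.label_a[...] = aug.a[nv:]

            # --- sleep: generative samples, recognition updates
            ph_top = prop_up(model.layers[-1], states[-1])
            h_top = (rng.random(ph_top.shape) < ph_top).astype(np.float64)
            sleep_states = [h_top]  # start of the top-down chain
            pv = prop_down(model.layers[-1], h_top)
            sleep_states.insert(0, (rng.random(pv.shape) < pv).astype(np.float64))
            for g in reversed(gen):
                pv = prop_down(g, sleep_states[0])
                sleep_states.insert(0, (rng.random(pv.shape) < pv).astype(np.float64))
            for li, layer in enumerate(model.layers):
                v_gen, h_gen = sleep_states[li], sleep_states[li + 1]
                p = prop_up(layer, v_gen)
                layer.W += gen_lr * v_gen.T @ (h_gen - p) / bs
                layer.b += gen_lr * (h_gen - p).mean(axis=0)

            # --- discriminative pass (mean-field, dropout on head input)
            acts = _up_pass(model, batch)
            topact = acts[-1]
            if config.dropout > 0:
                mask = (rng.random(topact.shape) >= config.dropout) / (1 - config.dropout)
            else:
                mask = np.ones_like(topact)
            logits = (topact * mask) @ disc_params["head_W"] + disc_params["head_b"]
            loss, glog = _nn.softmax_xent(logits, labels[idx])
            epoch_loss += loss * bs
            grads = {
                "head_W": (topact * mask).T @ glog,
                "head_b": glog.sum(axis=0),
            }
            gact = (glog @ disc_params["head_W"].T) * mask
            for li in reversed(range(len(model.layers))):
                pre = gact * acts[li + 1] * (1 - acts[li + 1])  # sigmoid'
                grads[f"W{li}"] = acts[li].T @ pre
                grads[f"b{li}"] = pre.sum(axis=0)
                gact = pre @ disc_params[f"W{li}"].T
            opt.step(disc_params, grads)
        if log is not None:
            preds, _ = predict(model, data, scaled=True)
            from .aoa import fitness_error_rate

            log.append({
                "epoch": epoch + 1,
                "loss": epoch_loss / n,
                "train_error_rate": fitness_error_rate(preds, labels),
            })
    model.head_W = disc_params["head_W"]
    model.head_b = disc_params["head_b"]
    return model


def predict(model: DBNModel, features: np.ndarray, scaled: bool = False):
    """Class labels and softmax scores (rows sum to 1).

    ``scaled=True`` skips min-max scaling (input already in [0, 1]).
    """
    x = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if x.shape[1] != model.layers[0].n_visible:
        raise StructuralError(
            f"feature width {x.shape[1]} != model input {model.layers[0].n_visible}"
        )
    if not scaled:
        x = scale_features(model, x)
    acts = _up_pass(model, x)
    scores = _nn.softmax(acts[-1] @ model.head_W + model.head_b)
    return scores.argmax(axis=1), scores
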
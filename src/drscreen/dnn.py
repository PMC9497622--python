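"""Fully-connected deep network for binary classification, in NumPy.

Architecture: a 10-wide input, five hidden blocks of widths
1024/512/256/128/64 — each block a dense layer with ReLU, dropout(0.5),
then batch normalization — and a single sigmoid output unit.  Trained with
binary cross-entropy and Adam.

Batch normalization follows the usual inference convention: running mean
and variance are tracked with momentum during training (running <-
momentum * running + (1 - momentum) * batch) and used at prediction time;
the per-channel scale/shift (gamma, beta) are trainable, the running
statistics are not.  Dropout is "inverted" (activations scaled by 1/keep
at train time) so inference needs no rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DnnSpec",
    "TrainConfig",
    "DnnModel",
    "build_dnn",
    "count_parameters",
    "train_dnn",
    "predict_score",
]


@dataclass
class DnnSpec:
    """Layer widths and block structure of the network."""

    input_width: int = 10
    hidden_widths: tuple[int, ...] = (1024, 512, 256, 128, 64)
    dropout: float = 0.5


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults are the published configuration)."""

    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 100
    dropout: float = 0.5
    bn_momentum: float = 0.95
    bn_epsilon: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.bn_epsilon) <= 0:
            raise ValueError("learning_rate, batch_size and bn_epsilon must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


class _Block:
    """One hidden block: dense -> ReLU -> dropout -> batch norm."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He initialization for ReLU layers
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gamma = np.ones(n_out)
        self.beta = np.zeros(n_out)
        self.run_mean = np.zeros(n_out)
        self.run_var = np.ones(n_out)
        self.width = n_out

    def params(self):
        return [self.w, self.b, self.gamma, self.beta]


class DnnModel:
    """Parameter container plus forward/backward passes."""

    def __init__(self, spec: DnnSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        widths = (spec.input_width,) + tuple(spec.hidden_widths)
        self.blocks = [_Block(widths[k], widths[k + 1], rng) for k in range(len(spec.hidden_widths))]
        n_last = widths[-1]
        # Glorot for the sigmoid output unit
        self.w_out = rng.normal(0.0, np.sqrt(1.0 / n_last), size=(n_last, 1))
        self.b_out = np.zeros(1)
        self.history: dict[str, list[float]] = {"loss": [], "accuracy": []}

    # ---- forward -------------------------------------------------------
    def forward(self, x, training=False, dropout_rng=None, config: TrainConfig | None = None):
        """Return output logits; in training mode also return a backprop cache."""
        cfg = config or TrainConfig()
        cache = []
        h = np.asarray(x, dtype=float)
        for blk in self.blocks:
            z = h @ blk.w + blk.b
            a = np.maximum(z, 0.0)
            if training and cfg.dropout > 0:
                keep = 1.0 - cfg.dropout
                mask = (dropout_rng.random(a.shape) < keep) / keep
                d = a * mask
            else:
                mask = None
                d = a
            if training:
                mu = d.mean(axis=0)
                var = d.var(axis=0)
                blk.run_mean = cfg.bn_momentum * blk.run_mean + (1 - cfg.bn_momentum) * mu
                blk.run_var = cfg.bn_momentum * blk.run_var + (1 - cfg.bn_momentum) * var
            else:
                mu, var = blk.run_mean, blk.run_var
            inv_sd = 1.0 / np.sqrt(var + cfg.bn_epsilon)
            xhat = (d - mu) * inv_sd
            out = blk.gamma * xhat + blk.beta
            cache.append((h, z, mask, d, mu, inv_sd, xhat))
            h = out
        logits = h @ self.w_out + self.b_out
        if training:
            return logits, (cache, h)
        return logits

    # ---- backward ------------------------------------------------------
    def backward(self, dlogits, cache_pack):
        """Gradients of the loss w.r.t. every trainable parameter."""
        cache, h_last = cache_pack
        grads = {}
        grads["w_out"] = h_last.T @ dlogits
        grads["b_out"] = dlogits.sum(axis=0)
        dh = dlogits @ self.w_out.T
        m = dlogits.shape[0]
        for k in reversed(range(len(self.blocks))):
            blk = self.blocks[k]
            h_in, z, mask, d, mu, inv_sd, xhat = cache[k]
            dgamma = (dh * xhat).sum(axis=0)
            dbeta = dh.sum(axis=0)
            dxhat = dh * blk.gamma
            # batch-norm backward over the batch dimension
            dd = inv_sd / m * (
                m * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
            )
            da = dd * mask if mask is not None else dd
            dz = da * (z > 0)
            grads[f"w_{k}"] = h_in.T @ dz
            grads[f"b_{k}"] = dz.sum(axis=0)
            grads[f"gamma_{k}"] = dgamma
            grads[f"beta_{k}"] = dbeta
            dh = dz @ blk.w.T
        return grads

    def named_params(self):
        out = {}
        for k, blk in enumerate(self.blocks):
            out[f"w_{k}"] = blk.w
            out[f"b_{k}"] = blk.b
            out[f"gamma_{k}"] = blk.gamma
            out[f"beta_{k}"] = blk.beta
        out["w_out"] = self.w_out
        out["b_out"] = self.b_out
        return out

    def state_dict(self):
        state = self.named_params().copy()
        for k, blk in enumerate(self.blocks):
            state[f"run_mean_{k}"] = blk.run_mean
            state[f"run_var_{k}"] = blk.run_var
        return state

    def load_state_dict(self, state):
        for k, blk in enumerate(self.blocks):
            blk.w = state[f"w_{k}"]
            blk.b = state[f"b_{k}"]
            blk.gamma = state[f"gamma_{k}"]
            blk.beta = state[f"beta_{k}"]
            blk.run_mean = state[f"run_mean_{k}"]
            blk.run_var = state[f"run_var_{k}"]
        self.w_out = state["w_out"]
        self.b_out = state["b_out"]


def build_dnn(spec: DnnSpec | None = None, seed: int = 0) -> DnnModel:
    """Construct an untrained network from a layer spec."""
    return DnnModel(spec or DnnSpec(), seed=seed)


def count_parameters(model: DnnModel | DnnSpec):
    """Per-layer and total parameter counts, in closed form.

    A dense layer from ``n_in`` to ``n_out`` has ``n_in * n_out + n_out``
    parameters; a batch-norm layer over ``w`` channels has ``4 * w`` (gamma
    and beta trainable, running mean/variance not); dropout has none.

    Returns ``(layers, total, trainable)`` where ``layers`` is a list of
    ``(name, n_params, n_trainable)`` rows in network order.
    """
    spec = model.spec if isinstance(model, DnnModel) else model
    widths = (spec.input_width,) + tuple(spec.hidden_widths)
    layers = [("input", 0, 0)]
    for k in range(len(spec.hidden_widths)):
        n_in, n_out = widths[k], widths[k + 1]
        dense = n_in * n_out + n_out
        layers.append((f"dense_{k + 1}", dense, dense))
        layers.append((f"dropout_{k + 1}", 0, 0))
        layers.append((f"batch_normalization_{k + 1}", 4 * n_out, 2 * n_out))
    out = widths[-1] * 1 + 1
    layers.append((f"dense_{len(spec.hidden_widths) + 1}_output", out, out))
    total = sum(n for _, n, _ in layers)
    trainable = sum(t for _, _, t in layers)
    return layers, total, trainable


def _bce_from_logits(logits, y):
    """Numerically stable mean binary cross-entropy and its logit gradient."""
    z = logits.ravel()
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    p = 1.0 / (1.0 + np.exp(-z))
    dlogits = ((p - y) / z.size).reshape(-1, 1)
    return loss, dlogits, p


def train_dnn(model: DnnModel, x, y, config: TrainConfig | None = None) -> DnnModel:
    """Mini-batch Adam training with binary cross-entropy.

    ``y`` holds {0, 1} labels.  The history records the mean per-batch
    training loss and the full-set (inference-mode) accuracy per epoch.
    Raises RuntimeError if the loss becomes non-finite.
    """
    cfg = config or TrainConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(cfg.seed)
    params = model.named_params()
    adam_m = {k: np.zeros_like(v) for k, v in params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    n = x.shape[0]
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            logits, cache = model.forward(xb, training=True, dropout_rng=rng, config=cfg)
            loss, dlogits, _ = _bce_from_logits(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged: non-finite loss at step {step}")
            grads = model.backward(dlogits, cache)
            step += 1
            for key, p in params.items():
                g = grads[key]
                adam_m[key] = beta1 * adam_m[key] + (1 - beta1) * g
                adam_v[key] = beta2 * adam_v[key] + (1 - beta2) * g * g
                m_hat = adam_m[key] / (1 - beta1 ** step)
                v_hat = adam_v[key] / (1 - beta2 ** step)
                p -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
            epoch_losses.append(loss)
        scores = predict_score(model, x, config=cfg)
        acc = float(np.mean((scores >= 0.5) == (y == 1)))
        model.history["loss"].append(float(np.mean(epoch_losses)))
        model.history["accuracy"].append(acc)
    return model


def predict_score(model: DnnModel, x, config: TrainConfig | None = None) -> np.ndarray:
    """Sigmoid class scores in [0, 1] (inference mode: no dropout, running BN)."""
    logits = model.forward(np.asarray(x, dtype=float), training=False, config=config)
    return (1.0 / (1.0 + np.exp(-logits))).ravel()
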
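"""From-scratch LSTM binary classifier (NumPy forward, BPTT, Adam).

Architecture: a single LSTM layer (default 128 hidden units) reads the
feature tensor, a dropout layer (default rate 0.25) regularises the final
hidden state, and a 1-unit dense layer with sigmoid activation produces the
anticancer-peptide probability.  Training minimises binary cross-entropy
with the Adam optimizer; all randomness (weight initialisation, dropout
masks, batch shuffling) derives from a single seed, so runs are exactly
reproducible.

The gate equations are the classical ones: with z_t = [h_{t−1}, x_t],

    f_t = σ(W_f·z_t + b_f)          (forget gate)
    i_t = σ(W_i·z_t + b_i)          (input gate)
    C̃_t = tanh(W_c·z_t + b_c)       (candidate cell state)
    C_t = f_t ∗ C_{t−1} + i_t ∗ C̃_t
    o_t = σ(W_o·z_t + b_o)          (output gate)
    h_t = o_t ∗ tanh(C_t)

where σ(x) = 1/(1+e^{−x}) and ∗ is the element-wise product.

The conjoined 483-dim feature vectors are pre-pooled (not a residue-level
time series), so the default tensor layout feeds them as a single timestep
of width 483 (``one_step``); a ``per_feature`` layout (483 timesteps of
width 1) is available for experimentation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

logger = logging.getLogger(__name__)

GATES = ("i", "f", "c", "o")
LAYOUTS = ("one_step", "per_feature")


@dataclass
class LSTMConfig:
    """Hyperparameters of the LSTM classifier.

    ``hidden_units`` is the size of the LSTM layer (the model's only
    layer-size parameter); ``tensor_layout`` controls how flat feature
    vectors are reshaped into the 3-axis input tensor; ``threshold`` turns
    scores into hard labels.
    """

    hidden_units: int = 128
    dropout_rate: float = 0.25
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 0.001
    seed: int = 0
    tensor_layout: str = "one_step"
    threshold: float = 0.5

    def __post_init__(self):
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.tensor_layout not in LAYOUTS:
            raise ValueError(f"tensor_layout must be one of {LAYOUTS}")


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function σ(x) = 1/(1+e^{−x})."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def make_lstm_tensor(features, layout: str = "one_step") -> np.ndarray:
    """Reshape a 2D feature matrix (or FeatureVector collection) into the
    3-axis tensor the LSTM consumes.

    ``one_step`` → shape (n, 1, d): one timestep with d channels.
    ``per_feature`` → shape (n, d, 1): d timesteps of width 1.
    The reshape is lossless: flattening recovers the 2D matrix exactly.
    """
    if layout not in LAYOUTS:
        raise ValueError(f"layout must be one of {LAYOUTS}")
    if isinstance(features, np.ndarray):
        X = np.asarray(features, dtype=float)
        if X.ndim != 2:
            raise ValueError(f"expected a 2D matrix, got shape {X.shape}")
    else:
        rows = [np.asarray(f.values, dtype=float) for f in features]
        widths = {r.shape[0] for r in rows}
        if len(widths) != 1:
            raise ValueError(f"feature vectors have mixed lengths: {sorted(widths)}")
        X = np.vstack(rows)
    n, d = X.shape
    if layout == "one_step":
        return X.reshape(n, 1, d)
    return X.reshape(n, d, 1)


def init_params(input_dim: int, hidden_units: int, rng: np.random.Generator) -> dict:
    """Glorot-uniform gate weights over [h, x]; forget-gate bias starts at 1."""
    H, D = hidden_units, input_dim
    params: dict[str, np.ndarray] = {}
    limit = np.sqrt(6.0 / (H + D + H))
    for g in GATES:
        params[f"W_{g}"] = rng.uniform(-limit, limit, size=(H, H + D))
        params[f"b_{g}"] = np.zeros(H)
    params["b_f"] = np.ones(H)  # bias the forget gate open at the start
    out_limit = np.sqrt(6.0 / (H + 1))
    params["w_out"] = rng.uniform(-out_limit, out_limit, size=H)
    params["b_out"] = np.zeros(())
    return params


def lstm_cell_step(
    params: dict,
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell step on a batch: returns (h_t, C_t).

    Accepts 1D vectors (a single sample) or 2D (batch, dim) arrays.
    """
    single = x_t.ndim == 1
    x = np.atleast_2d(x_t)
    h = np.atleast_2d(h_prev)
    c = np.atleast_2d(c_prev)
    if h.shape[1] != params["W_i"].shape[0]:
        raise ValueError(
            f"hidden state width {h.shape[1]} does not match "
            f"weights ({params['W_i'].shape[0]})"
        )
    if h.shape[1] + x.shape[1] != params["W_i"].shape[1]:
        raise ValueError(
            f"input width {x.shape[1]} does not match weights "
            f"(expected {params['W_i'].shape[1] - h.shape[1]})"
        )
    z = np.concatenate([h, x], axis=1)
    i_t = sigmoid(z @ params["W_i"].T + params["b_i"])
    f_t = sigmoid(z @ params["W_f"].T + params["b_f"])
    g_t = np.tanh(z @ params["W_c"].T + params["b_c"])
    o_t = sigmoid(z @ params["W_o"].T + params["b_o"])
    c_t = f_t * c + i_t * g_t
    h_t = o_t * np.tanh(c_t)
    if single:
        return h_t[0], c_t[0]
    return h_t, c_t


def _forward(params: dict, X3: np.ndarray):
    """Run the LSTM over all timesteps; returns (h_T, caches)."""
    n, T, _ = X3.shape
    H = params["W_i"].shape[0]
    h = np.zeros((n, H))
    c = np.zeros((n, H))
    caches = []
    for t in range(T):
        x = X3[:, t, :]
        z = np.concatenate([h, x], axis=1)
        i_t = sigmoid(z @ params["W_i"].T + params["b_i"])
        f_t = sigmoid(z @ params["W_f"].T + params["b_f"])
        g_t = np.tanh(z @ params["W_c"].T + params["b_c"])
        o_t = sigmoid(z @ params["W_o"].T + params["b_o"])
        c_new = f_t * c + i_t * g_t
        tanh_c = np.tanh(c_new)
        h_new = o_t * tanh_c
        caches.append((z, i_t, f_t, g_t, o_t, c, tanh_c))
        h, c = h_new, c_new
    return h, caches


def _backward(params: dict, caches, dh_T: np.ndarray) -> dict:
    """BPTT from a gradient on the final hidden state back through time."""
    H = params["W_i"].shape[0]
    grads = {k: np.zeros_like(v) for k, v in params.items()
             if k not in ("w_out", "b_out")}
    dh = dh_T
    dc = np.zeros_like(dh)
    for z, i_t, f_t, g_t, o_t, c_prev, tanh_c in reversed(caches):
        do = dh * tanh_c
        dc = dc + dh * o_t * (1.0 - tanh_c**2)
        df = dc * c_prev
        di = dc * g_t
        dg = dc * i_t
        da = {
            "i": di * i_t * (1.0 - i_t),
            "f": df * f_t * (1.0 - f_t),
            "c": dg * (1.0 - g_t**2),
            "o": do * o_t * (1.0 - o_t),
        }
        dz = np.zeros_like(z)
        for g in GATES:
            grads[f"W_{g}"] += da[g].T @ z
            grads[f"b_{g}"] += da[g].sum(axis=0)
            dz += da[g] @ params[f"W_{g}"]
        dh = dz[:, :H]
        dc = dc * f_t
    return grads


def binary_cross_entropy(y: np.ndarray, p: np.ndarray) -> float:
    """Mean log loss −[(1−t)·log(1−p) + t·log(p)] with clipped probabilities."""
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-np.mean((1.0 - y) * np.log(1.0 - p) + y * np.log(p)))


class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class LSTMResults:
    """Fitted LSTM classifier: parameters, config, history, prediction.

    Obtained from :meth:`LSTMClassifier.fit` or :func:`load_model`.
    Prediction is deterministic (dropout is disabled outside training) and
    a persisted-and-reloaded model reproduces scores bit-identically.
    """

    def __init__(self, params: dict, config: LSTMConfig,
                 feature_length: int, training_history: list[float]):
        self.params = params
        self.config = config
        self.feature_length = feature_length
        self.training_history = list(training_history)

    @property
    def n_parameters(self) -> int:
        return int(sum(np.size(v) for v in self.params.values()))

    def _as_tensor(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = make_lstm_tensor(X, self.config.tensor_layout)
        if X.ndim != 3:
            raise ValueError(f"expected a 2D matrix or 3-axis tensor, got {X.shape}")
        expected = (
            (1, self.feature_length)
            if self.config.tensor_layout == "one_step"
            else (self.feature_length, 1)
        )
        if X.shape[1:] != expected:
            raise ValueError(
                f"tensor shape {X.shape[1:]} does not match the model's "
                f"layout {self.config.tensor_layout} / feature length "
                f"{self.feature_length} (expected {expected})"
            )
        return X

    def predict_scores(self, X) -> np.ndarray:
        """Sigmoid scores in [0, 1], one per row."""
        X3 = self._as_tensor(X)
        h, _ = _forward(self.params, X3)
        return sigmoid(h @ self.params["w_out"] + self.params["b_out"])

    def predict(self, X) -> np.ndarray:
        """Hard labels: score ≥ threshold → 1."""
        return (self.predict_scores(X) >= self.config.threshold).astype(int)

    def save(self, path) -> None:
        """Persist weights + config + feature contract to one .npz archive."""
        meta = json.dumps(
            {"config": asdict(self.config),
             "feature_length": self.feature_length,
             "training_history": self.training_history}
        )
        np.savez(path, __meta__=np.array(meta), **self.params)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "LSTM peptide classifier",
            "=" * 47,
            f"{'hidden units':<24}{cfg.hidden_units}",
            f"{'dropout rate':<24}{cfg.dropout_rate}",
            f"{'tensor layout':<24}{cfg.tensor_layout}",
            f"{'feature length':<24}{self.feature_length}",
            f"{'trainable parameters':<24}{self.n_parameters}",
            f"{'epochs':<24}{cfg.epochs}",
            f"{'batch size':<24}{cfg.batch_size}",
            f"{'learning rate':<24}{cfg.learning_rate}",
            f"{'seed':<24}{cfg.seed}",
        ]
        if self.training_history:
            lines.append(
                f"{'final training loss':<24}{self.training_history[-1]:.6f}"
            )
        return "\n".join(lines)


def load_model(path) -> LSTMResults:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        params = {k: archive[k] for k in archive.files if k != "__meta__"}
    return LSTMResults(
        params,
        LSTMConfig(**meta["config"]),
        meta["feature_length"],
        meta["training_history"],
    )


class LSTMClassifier:
    """LSTM binary classifier model; ``fit`` returns :class:`LSTMResults`.

    Accepts either the 3-axis tensor from :func:`make_lstm_tensor` or a
    flat 2D feature matrix (reshaped internally per the configured layout).
    """

    def __init__(self, config: LSTMConfig | None = None, **kwargs):
        if config is None:
            config = LSTMConfig(**kwargs)
        elif kwargs:
            raise TypeError("pass either a config object or keyword overrides")
        self.config = config

    @property
    def parameters(self) -> dict:
        return asdict(self.config)

    def fit(self, X, y) -> LSTMResults:
        cfg = self.config
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X3 = make_lstm_tensor(X, cfg.tensor_layout)
        elif X.ndim == 3:
            X3 = X
        else:
            raise ValueError(f"expected 2D or 3-axis input, got shape {X.shape}")
        y = np.asarray(y, dtype=float).ravel()
        if X3.shape[0] != y.shape[0]:
            raise ValueError(
                f"{X3.shape[0]} samples but {y.shape[0]} labels"
            )
        classes = np.unique(y)
        if not np.array_equal(classes, [0.0, 1.0]):
            raise ValueError(
                f"training labels must contain both classes 0 and 1, got {classes}"
            )
        n, T, width = X3.shape
        feature_length = T * width
        input_dim = X3.shape[2]
        rng = np.random.default_rng(cfg.seed)
        params = init_params(input_dim, cfg.hidden_units, rng)
        optimizer = _Adam(params, cfg.learning_rate)
        history: list[float] = []
        keep = 1.0 - cfg.dropout_rate
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = X3[idx], y[idx]
                h, caches = _forward(params, xb)
                if cfg.dropout_rate > 0.0:
                    mask = (rng.random(h.shape) < keep) / keep
                    h_drop = h * mask
                else:
                    mask = None
                    h_drop = h
                logits = h_drop @ params["w_out"] + params["b_out"]
                p = sigmoid(logits)
                loss = binary_cross_entropy(yb, p)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at epoch {epoch + 1} "
                        f"(batch starting {start}); lower the learning rate"
                    )
                epoch_loss += loss * len(idx)
                # d(BCE)/d(logit) = p − t, averaged over the batch
                dlogits = (p - yb) / len(idx)
                grads = {
                    "w_out": h_drop.T @ dlogits,
                    "b_out": np.asarray(dlogits.sum()),
                }
                dh = np.outer(dlogits, params["w_out"])
                if mask is not None:
                    dh = dh * mask
                grads.update(_backward(params, caches, dh))
                optimizer.step(params, grads)
            history.append(epoch_loss / n)
        return LSTMResults(params, cfg, feature_length, history)
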
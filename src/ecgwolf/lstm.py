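"""LSTM classification head, implemented directly from the gate equations.

The cell computes, with ``z_t = [h_{t-1}, x_t]`` (hidden state first):

    i_t = sigmoid(W_i z_t + b_i)          input gate
    f_t = sigmoid(W_f z_t + b_f)          forget gate
    g_t = tanh(W_c z_t + b_c)             candidate cell state
    C_t = f_t * C_{t-1} + i_t * g_t       cell state update
    o_t = sigmoid(W_o z_t + b_o)          output gate
    h_t = o_t * tanh(C_t)                 hidden state

followed by dropout on the last hidden state, a dense layer to the class
logits, and a numerically stable softmax ``P(y_k|x) = exp(O_k)/sum exp(O_n)``.

Training uses categorical cross-entropy, Adam (default learning rate 0.01),
L2 regularization on the weight matrices (factor 0.001), He-normal weight
initialization, mini-batches of 100, at most 30 epochs with early stopping
after 6 validation checks without improvement, and gradient clipping at
global norm 1.0 as a safeguard against divergence at the high learning rate.
Selected feature vectors are fed as length-1 sequences (static mode); a raw
sample-window sequence mode is available for true temporal input.

Everything is NumPy; a run is a pure function of (data, config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TrainingError
from .features import FeatureMatrix

__all__ = [
    "LSTMParams",
    "LSTMState",
    "TrainConfig",
    "TrainedClassifier",
    "lstm_cell_step",
    "softmax",
    "to_sequences",
    "segments_to_sequences",
    "train",
    "predict",
]

_GATES = ("W_i", "W_f", "W_c", "W_o")
_BIASES = ("b_i", "b_f", "b_c", "b_o")


@dataclass
class LSTMParams:
    """All weights of the single-layer LSTM plus the dense output head.

    Gate matrices have shape ``(hidden, hidden + input)`` and act on the
    concatenation ``[h, x]``; ``W_out`` maps the final hidden state to the
    class logits.
    """

    W_i: np.ndarray
    W_f: np.ndarray
    W_c: np.ndarray
    W_o: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray
    W_out: np.ndarray
    b_out: np.ndarray

    def __post_init__(self):
        H, HD = self.W_i.shape
        for name in _GATES:
            if getattr(self, name).shape != (H, HD):
                raise ValueError(f"{name} shape mismatch")
        for name in _BIASES:
            if getattr(self, name).shape != (H,):
                raise ValueError(f"{name} shape mismatch")
        if self.W_out.shape[1] != H or self.b_out.shape != (self.W_out.shape[0],):
            raise ValueError("output head shape mismatch")
        for name in _GATES + _BIASES + ("W_out", "b_out"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite entries")

    @property
    def hidden_size(self) -> int:
        return self.W_i.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_i.shape[1] - self.W_i.shape[0]

    @property
    def n_classes(self) -> int:
        return self.W_out.shape[0]

    def arrays(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n) for n in _GATES + _BIASES + ("W_out", "b_out")}

    def copy(self) -> "LSTMParams":
        return LSTMParams(**{k: v.copy() for k, v in self.arrays().items()})


@dataclass
class LSTMState:
    """Hidden state ``h`` and cell state ``c`` of one LSTM cell."""

    h: np.ndarray
    c: np.ndarray


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.01
    batch_size: int = 100
    epochs: int = 30
    l2: float = 0.001
    dropout: float = 0.2
    hidden_size: int = 50
    seed: int = 0
    early_stop_patience: int = 6
    clip_norm: float = 1.0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("learning_rate, batch_size, epochs must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class TrainedClassifier:
    params: LSTMParams
    feature_names: list[str]
    class_labels: np.ndarray
    training_history: list[dict] = field(default_factory=list)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def lstm_cell_step(x: np.ndarray, state: LSTMState, p: LSTMParams) -> LSTMState:
    """One cell step on a single sample (1-D input vector)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (p.input_size,):
        raise ValueError(
            f"input of shape {x.shape} does not match input size {p.input_size}"
        )
    if state.h.shape != (p.hidden_size,) or state.c.shape != (p.hidden_size,):
        raise ValueError("state shape does not match hidden size")
    z = np.concatenate([state.h, x])
    i = _sigmoid(p.W_i @ z + p.b_i)
    f = _sigmoid(p.W_f @ z + p.b_f)
    g = np.tanh(p.W_c @ z + p.b_c)
    c = f * state.c + i * g
    o = _sigmoid(p.W_o @ z + p.b_o)
    h = o * np.tanh(c)
    return LSTMState(h=h, c=c)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Stable softmax along the last axis; sums to 1 and preserves order."""
    logits = np.asarray(logits, dtype=float)
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def to_sequences(fm: FeatureMatrix, mask) -> tuple[np.ndarray, np.ndarray]:
    """Restrict columns to the mask and shape each row as a length-1
    sequence: ``(n, 1, popcount)`` plus the label vector."""
    bits = np.asarray(getattr(mask, "bits", mask), dtype=bool)
    if bits.sum() < 1:
        raise ValueError("empty feature mask")
    if bits.size != fm.n_features:
        raise ValueError("mask length does not match feature count")
    X = fm.values[:, bits]
    return X[:, None, :], fm.labels.copy()


def segments_to_sequences(segments) -> tuple[np.ndarray, np.ndarray]:
    """Raw-window sequence mode: each segment's samples become a sequence of
    scalar timesteps, ``(n, W, 1)``."""
    X = np.stack([s.samples for s in segments])[:, :, None]
    y = np.array([s.label for s in segments], dtype=int)
    return X, y


# ---------------------------------------------------------------------------
# training internals
# ---------------------------------------------------------------------------

def init_params(input_size: int, hidden_size: int, n_classes: int,
                rng: np.random.Generator) -> LSTMParams:
    """He-normal weights (std sqrt(2 / fan_in)); zero biases except the
    forget-gate bias, initialized to 1 so early training does not forget."""
    HD = hidden_size + input_size

    def he(shape, fan_in):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

    return LSTMParams(
        W_i=he((hidden_size, HD), HD), W_f=he((hidden_size, HD), HD),
        W_c=he((hidden_size, HD), HD), W_o=he((hidden_size, HD), HD),
        b_i=np.zeros(hidden_size), b_f=np.ones(hidden_size),
        b_c=np.zeros(hidden_size), b_o=np.zeros(hidden_size),
        W_out=he((n_classes, hidden_size), hidden_size),
        b_out=np.zeros(n_classes),
    )


def _forward(X: np.ndarray, p: LSTMParams):
    """Batched forward pass over (B, T, D); returns last hidden state and
    the per-step cache needed for backpropagation through time."""
    B, T, _ = X.shape
    H = p.hidden_size
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    cache = []
    for t in range(T):
        z = np.concatenate([h, X[:, t, :]], axis=1)
        i = _sigmoid(z @ p.W_i.T + p.b_i)
        f = _sigmoid(z @ p.W_f.T + p.b_f)
        g = np.tanh(z @ p.W_c.T + p.b_c)
        o = _sigmoid(z @ p.W_o.T + p.b_o)
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        cache.append((z, i, f, g, o, c, tanh_c))
        h, c = h_new, c_new
    return h, cache


def _loss_and_grads(X, y_idx, p: LSTMParams, l2: float,
                    drop_mask: np.ndarray | None):
    """Cross-entropy loss (+ L2/2 * ||W||^2 on weight matrices) and exact
    gradients via backpropagation through time."""
    B = X.shape[0]
    H = p.hidden_size
    h_last, cache = _forward(X, p)
    hd = h_last * drop_mask if drop_mask is not None else h_last
    logits = hd @ p.W_out.T + p.b_out
    probs = softmax(logits)
    data_loss = -np.mean(np.log(probs[np.arange(B), y_idx] + 1e-300))
    reg = 0.5 * l2 * sum(
        float(np.sum(getattr(p, n) ** 2)) for n in _GATES + ("W_out",)
    )
    loss = data_loss + reg

    dlogits = probs.copy()
    dlogits[np.arange(B), y_idx] -= 1.0
    dlogits /= B
    grads = {n: np.zeros_like(getattr(p, n)) for n in p.arrays()}
    grads["W_out"] = dlogits.T @ hd + l2 * p.W_out
    grads["b_out"] = dlogits.sum(axis=0)
    dhd = dlogits @ p.W_out
    dh = dhd * drop_mask if drop_mask is not None else dhd
    dc = np.zeros((B, H))
    for t in range(len(cache) - 1, -1, -1):
        z, i, f, g, o, c_prev, tanh_c = cache[t]
        do = dh * tanh_c
        dct = dc + dh * o * (1.0 - tanh_c ** 2)
        di = dct * g
        dg = dct * i
        df = dct * c_prev
        dc = dct * f
        dai = di * i * (1.0 - i)
        daf = df * f * (1.0 - f)
        dag = dg * (1.0 - g ** 2)
        dao = do * o * (1.0 - o)
        grads["W_i"] += dai.T @ z
        grads["W_f"] += daf.T @ z
        grads["W_c"] += dag.T @ z
        grads["W_o"] += dao.T @ z
        grads["b_i"] += dai.sum(axis=0)
        grads["b_f"] += daf.sum(axis=0)
        grads["b_c"] += dag.sum(axis=0)
        grads["b_o"] += dao.sum(axis=0)
        dz = dai @ p.W_i + daf @ p.W_f + dag @ p.W_c + dao @ p.W_o
        dh = dz[:, :H]
    for n in _GATES:
        grads[n] += l2 * getattr(p, n)
    return loss, grads


class Adam:
    """Adam optimizer over a dict of named arrays."""

    def __init__(self, shapes: dict[str, tuple], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {n: np.zeros(s) for n, s in shapes.items()}
        self.v = {n: np.zeros(s) for n, s in shapes.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for n, g in grads.items():
            self.m[n] = self.beta1 * self.m[n] + (1 - self.beta1) * g
            self.v[n] = self.beta2 * self.v[n] + (1 - self.beta2) * g * g
            params[n] -= self.lr * (self.m[n] / b1t) / (
                np.sqrt(self.v[n] / b2t) + self.eps
            )


def clip_gradients(grads: dict[str, np.ndarray], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``;
    returns the pre-clip norm."""
    total = float(np.sqrt(sum(np.sum(g * g) for g in grads.values())))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale
    return total


def evaluate_loss(X, y_idx, p: LSTMParams, l2: float = 0.0) -> float:
    """Loss without dropout (inference mode)."""
    loss, _ = _loss_and_grads(X, y_idx, p, l2, None)
    return loss


def train(seqs: np.ndarray, labels: np.ndarray, cfg: TrainConfig,
          val_seqs: np.ndarray, val_labels: np.ndarray,
          feature_names: list[str] | None = None) -> TrainedClassifier:
    """Train the LSTM head on labeled sequences.

    One validation check per epoch; training stops after
    ``cfg.early_stop_patience`` consecutive checks without a validation-loss
    improvement, and the parameters from the best check are restored.
    Raises :class:`TrainingError` if the loss diverges.
    """
    seqs = np.asarray(seqs, dtype=float)
    labels = np.asarray(labels)
    class_labels = np.unique(labels)
    if class_labels.size < 2:
        raise ValueError("training requires at least 2 classes")
    if val_seqs is None or len(val_seqs) == 0:
        raise ValueError("a nonempty validation set is required")
    lab_to_idx = {c: k for k, c in enumerate(class_labels)}
    y = np.array([lab_to_idx[c] for c in labels])
    y_val = np.array([lab_to_idx[c] for c in val_labels])
    val_seqs = np.asarray(val_seqs, dtype=float)

    rng = np.random.default_rng(cfg.seed)
    D = seqs.shape[2]
    p = init_params(D, cfg.hidden_size, class_labels.size, rng)
    arrays = p.arrays()
    opt = Adam({n: a.shape for n, a in arrays.items()}, lr=cfg.learning_rate)

    n = seqs.shape[0]
    history: list[dict] = []
    best_val = np.inf
    best_params = p.copy()
    checks_without_improvement = 0
    keep_prob = 1.0 - cfg.dropout
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            Xb, yb = seqs[idx], y[idx]
            if cfg.dropout > 0:
                drop = (rng.random((Xb.shape[0], cfg.hidden_size))
                        < keep_prob) / keep_prob
            else:
                drop = None
            loss, grads = _loss_and_grads(Xb, yb, p, cfg.l2, drop)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"training diverged (non-finite loss) at epoch {epoch}",
                    epoch=epoch,
                )
            clip_gradients(grads, cfg.clip_norm)
            opt.step(arrays, grads)
            epoch_losses.append(loss)
        val_loss = evaluate_loss(val_seqs, y_val, p, cfg.l2)
        val_probs = softmax(_forward(val_seqs, p)[0] @ p.W_out.T + p.b_out)
        val_acc = float(np.mean(val_probs.argmax(axis=1) == y_val))
        train_loss = evaluate_loss(seqs, y, p, cfg.l2)
        history.append({"epoch": epoch, "batch_loss": float(np.mean(epoch_losses)),
                        "train_loss": float(train_loss),
                        "val_loss": float(val_loss), "val_acc": val_acc})
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = p.copy()
            checks_without_improvement = 0
        else:
            checks_without_improvement += 1
            if checks_without_improvement >= cfg.early_stop_patience:
                break
    return TrainedClassifier(
        params=best_params,
        feature_names=feature_names or [f"x{i}" for i in range(D)],
        class_labels=class_labels,
        training_history=history,
    )


def predict(model: TrainedClassifier,
            seqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class labels and class-probability rows for each sequence; dropout is
    inactive, so repeat calls are identical."""
    seqs = np.asarray(seqs, dtype=float)
    p = model.params
    if seqs.ndim != 3 or seqs.shape[2] != p.input_size:
        raise ValueError(
            f"sequence feature dimension {seqs.shape[-1] if seqs.ndim == 3 else '?'}"
            f" does not match model input size {p.input_size}"
        )
    h_last, _ = _forward(seqs, p)
    probs = softmax(h_last @ p.W_out.T + p.b_out)
    return model.class_labels[probs.argmax(axis=1)], probs
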
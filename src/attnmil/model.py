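"""Attention-based MIL classifier: scoring, pooling, loss, and training.

The model scores each patch embedding h_k with a two-layer attention
network, s_k = wᵀ tanh(V h_k), normalizes the scores with a softmax to
attention weights α_k, pools the bag to a slide vector z = Σ_k α_k h_k,
and classifies with a single affine head followed by a sigmoid,
p = σ(uᵀ z + b).  Training minimizes a class-weighted binary
cross-entropy (weights N/(2·N_class), which exactly rebalance the two
classes) by plain stochastic gradient descent, one bag per step, with L2
weight decay and early stopping on the validation loss.

Gradients are derived analytically (closed-form backpropagation through
the softmax-attention pooling); a finite-difference check pins them in
the test suite.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import TrainingError, ValidationError
from .io import FeatureBag

EPS = 1e-7  # probability clipping for loss evaluation


@dataclass
class MilModelParams:
    """Learnable parameters: attention matrix V (L x d), attention vector
    w (L,), and the affine head u (d,), b (scalar)."""

    V: np.ndarray
    w: np.ndarray
    u: np.ndarray
    b: float

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=np.float64)
        self.w = np.asarray(self.w, dtype=np.float64)
        self.u = np.asarray(self.u, dtype=np.float64)
        self.b = float(self.b)

    @property
    def L(self) -> int:
        return int(self.V.shape[0])

    @property
    def d(self) -> int:
        return int(self.V.shape[1])

    def copy(self) -> "MilModelParams":
        return MilModelParams(self.V.copy(), self.w.copy(), self.u.copy(), self.b)

    # -- flat-vector view, used by the finite-difference gradient check --

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.V.ravel(), self.w, self.u, [self.b]])

    @classmethod
    def from_vector(cls, vec: np.ndarray, L: int, d: int) -> "MilModelParams":
        vec = np.asarray(vec, dtype=np.float64)
        V = vec[: L * d].reshape(L, d)
        w = vec[L * d : L * d + L]
        u = vec[L * d + L : L * d + L + d]
        return cls(V, w, u, float(vec[-1]))


def init_params(d: int, L: int, rng: np.random.Generator) -> MilModelParams:
    """Uniform initialization in ±1/sqrt(fan_in)."""
    return MilModelParams(
        V=rng.uniform(-1, 1, size=(L, d)) / np.sqrt(d),
        w=rng.uniform(-1, 1, size=L) / np.sqrt(L),
        u=rng.uniform(-1, 1, size=d) / np.sqrt(d),
        b=0.0,
    )


@dataclass(frozen=True)
class ClassWeights:
    """Rebalancing weights: w_class = N / (2 · N_class), so that
    w_pcr·n_pcr = w_nonpcr·n_nonpcr = N/2 exactly."""

    w_pcr: float
    w_nonpcr: float
    n_pcr: int
    n_nonpcr: int

    @property
    def n_total(self) -> int:
        return self.n_pcr + self.n_nonpcr


def class_weights(n_pcr: int, n_nonpcr: int) -> ClassWeights:
    if n_pcr < 1 or n_nonpcr < 1:
        raise ValidationError(
            f"both classes need at least one member (got n_pcr={n_pcr}, n_nonpcr={n_nonpcr})"
        )
    n = n_pcr + n_nonpcr
    return ClassWeights(w_pcr=n / (2 * n_pcr), w_nonpcr=n / (2 * n_nonpcr), n_pcr=n_pcr, n_nonpcr=n_nonpcr)


def attention_scores(features: np.ndarray, params: MilModelParams) -> np.ndarray:
    """Softmax-normalized attention weights α over the bag's patches.

    α_k = softmax_k( wᵀ tanh(V h_k) ), computed with the max-subtracted
    stable softmax.  Output order matches patch order.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[0] < 1:
        raise ValidationError("features must be a nonempty N x d matrix")
    if not np.all(np.isfinite(features)):
        raise ValidationError("features contain non-finite values")
    if features.shape[1] != params.d:
        raise ValidationError(f"feature dim {features.shape[1]} != model dim {params.d}")
    scores = np.tanh(features @ params.V.T) @ params.w
    scores = scores - scores.max()
    e = np.exp(scores)
    return e / e.sum()


def attention_pool(features: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Bag-level representation z = Σ_k α_k h_k."""
    features = np.asarray(features, dtype=np.float64)
    alpha = np.asarray(alpha, dtype=np.float64)
    if alpha.ndim != 1 or len(alpha) != features.shape[0]:
        raise ValidationError(
            f"alpha length {alpha.shape} does not match {features.shape[0]} patches"
        )
    if np.any(alpha < 0) or not np.isclose(alpha.sum(), 1.0, atol=1e-6):
        raise ValidationError("alpha must lie on the probability simplex")
    return alpha @ features


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


def predict_bag(bag: FeatureBag | np.ndarray, params: MilModelParams) -> float:
    """Slide-level pCR probability p = σ(uᵀ z + b); permutation-invariant."""
    features = bag.features if isinstance(bag, FeatureBag) else np.asarray(bag)
    alpha = attention_scores(features, params)
    z = attention_pool(features, alpha)
    return float(_sigmoid(float(params.u @ z + params.b)))


def weighted_bce(
    y: Sequence[int] | np.ndarray,
    p: Sequence[float] | np.ndarray,
    cw: ClassWeights,
    eps: float = EPS,
) -> float:
    """Class-weighted binary cross-entropy, averaged over the batch:

    L = -(1/B) Σ_k [ w_pcr · y_k log p_k + w_nonpcr · (1-y_k) log(1-p_k) ]

    Probabilities are clipped to [eps, 1-eps].  Reduces to plain BCE when
    both weights are 1.
    """
    y = np.asarray(y, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if y.size == 0:
        raise ValidationError("batch must be nonempty")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValidationError("labels must be 0 or 1")
    p = np.clip(p, eps, 1.0 - eps)
    terms = cw.w_pcr * y * np.log(p) + cw.w_nonpcr * (1.0 - y) * np.log(1.0 - p)
    return float(-terms.mean())


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol: SGD over single-bag batches with weight
    decay and patience-based early stopping on validation loss."""

    learning_rate: float = 0.0001
    weight_decay: float = 0.001
    max_epochs: int = 1024
    patience: int = 50
    L: int = 256
    seed: int = 0
    jitter_magnitude: float = 0.0

    def validate(self) -> None:
        if self.learning_rate < 0 or self.weight_decay < 0 or self.jitter_magnitude < 0:
            raise ValidationError("rates and magnitudes must be >= 0")
        if self.max_epochs < 1 or self.patience < 1:
            raise ValidationError("max_epochs and patience must be >= 1")
        if self.patience > self.max_epochs:
            raise ValidationError("patience must be <= max_epochs")
        if self.L < 1:
            raise ValidationError("attention width L must be >= 1")


@dataclass
class TrainResult:
    params: MilModelParams
    epochs_run: int
    best_val_loss: float
    loss_history: dict[str, list[float]] = field(default_factory=lambda: {"train": [], "val": []})


def _bag_loss_and_grads(
    features: np.ndarray, y: int, params: MilModelParams, cw: ClassWeights
) -> tuple[float, MilModelParams]:
    """Loss and analytic gradients of the weighted BCE for a single bag
    (data term only; weight decay is added by the caller)."""
    t = np.tanh(features @ params.V.T)            # N x L
    s = t @ params.w                              # N
    s = s - s.max()
    e = np.exp(s)
    alpha = e / e.sum()
    z = alpha @ features                          # d
    logit = float(params.u @ z + params.b)
    p = _sigmoid(logit)
    c = cw.w_pcr if y == 1 else cw.w_nonpcr
    pc = min(max(p, EPS), 1.0 - EPS)
    loss = -c * (y * np.log(pc) + (1 - y) * np.log(1.0 - pc))

    dlogit = c * (p - y)
    du = dlogit * z
    db = dlogit
    dalpha = dlogit * (features @ params.u)       # N
    ds = alpha * (dalpha - float(alpha @ dalpha))
    dw = t.T @ ds
    dV = (ds[:, None] * (1.0 - t * t) * params.w[None, :]).T @ features
    return float(loss), MilModelParams(dV, dw, du, float(db))


def full_objective(
    params: MilModelParams,
    bags: Sequence[np.ndarray],
    labels: Sequence[int],
    cw: ClassWeights,
    weight_decay: float,
) -> float:
    """Mean weighted BCE over bags plus the L2 penalty (wd/2)·‖θ‖².
    This is the exact objective whose gradient SGD follows; exposed for
    gradient checking."""
    preds = [predict_bag(f, params) for f in bags]
    data = weighted_bce(np.asarray(labels), np.asarray(preds), cw)
    theta = params.to_vector()
    return data + 0.5 * weight_decay * float(theta @ theta)


def full_objective_grad(
    params: MilModelParams,
    bags: Sequence[np.ndarray],
    labels: Sequence[int],
    cw: ClassWeights,
    weight_decay: float,
) -> np.ndarray:
    """Analytic gradient of :func:`full_objective`, flattened."""
    acc = np.zeros_like(params.to_vector())
    for f, y in zip(bags, labels):
        _, g = _bag_loss_and_grads(np.asarray(f, dtype=np.float64), int(y), params, cw)
        acc += g.to_vector()
    acc /= len(bags)
    acc += weight_decay * params.to_vector()
    return acc


def _mean_val_loss(bags: Sequence[FeatureBag], params: MilModelParams, cw: ClassWeights) -> float:
    preds = np.array([predict_bag(b, params) for b in bags])
    labels = np.array([b.label for b in bags])
    return weighted_bce(labels, preds, cw)


def train_model(
    train_bags: Sequence[FeatureBag],
    val_bags: Sequence[FeatureBag],
    cfg: TrainConfig,
) -> TrainResult:
    """Train by SGD (batch = one bag), returning the parameters from the
    epoch with minimum validation loss.

    Class weights come from the training split only.  Bag order is
    reshuffled every epoch from ``cfg.seed``.  A strictly lower validation
    loss resets patience; ties do not.  Optional feature-space jitter is
    redrawn per bag per epoch when ``cfg.jitter_magnitude > 0``.
    """
    cfg.validate()
    if not train_bags or not val_bags:
        raise ValidationError("train and validation splits must both be nonempty")
    dims = {b.dim for b in list(train_bags) + list(val_bags)}
    if len(dims) != 1:
        raise ValidationError(f"inconsistent feature dimensions across splits: {sorted(dims)}")
    labels = [b.label for b in train_bags]
    if any(l is None for l in labels):
        raise ValidationError("all training bags must be labeled")
    cw = class_weights(int(np.sum(labels)), int(len(labels) - np.sum(labels)))

    d = dims.pop()
    rng = np.random.default_rng(cfg.seed)
    params = init_params(d, cfg.L, rng)

    best = params.copy()
    best_val = np.inf
    since_improvement = 0
    history: dict[str, list[float]] = {"train": [], "val": []}
    epochs_run = 0

    from .synthetic import feature_jitter  # local import: avoids a cycle

    for epoch in range(1, cfg.max_epochs + 1):
        epochs_run = epoch
        order = rng.permutation(len(train_bags))
        epoch_losses = []
        for idx in order:
            bag = train_bags[idx]
            if cfg.jitter_magnitude > 0:
                bag = feature_jitter(bag, cfg.jitter_magnitude, int(rng.integers(0, 2**31 - 1)))
            features = bag.features.astype(np.float64)
            loss, g = _bag_loss_and_grads(features, int(bag.label), params, cw)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            lr, wd = cfg.learning_rate, cfg.weight_decay
            params.V -= lr * (g.V + wd * params.V)
            params.w -= lr * (g.w + wd * params.w)
            params.u -= lr * (g.u + wd * params.u)
            params.b -= lr * (g.b + wd * params.b)
            epoch_losses.append(loss)

        val_loss = _mean_val_loss(val_bags, params, cw)
        if not np.isfinite(val_loss):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}")
        history["train"].append(float(np.mean(epoch_losses)))
        history["val"].append(val_loss)

        if val_loss < best_val:
            best_val = val_loss
            best = params.copy()
            since_improvement = 0
        else:
            since_improvement += 1
            if since_improvement >= cfg.patience:
                break

    return TrainResult(params=best, epochs_run=epochs_run, best_val_loss=float(best_val), loss_history=history)


def save_checkpoint(result: TrainResult, cfg: TrainConfig, path: str | Path) -> Path:
    """Single-archive checkpoint: arrays for V, w, u plus a JSON header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    p = result.params
    header = {
        "schema_version": 1,
        "d": p.d,
        "L": p.L,
        "b": p.b,
        "best_val_loss": result.best_val_loss,
        "epochs_run": result.epochs_run,
        "train_config": {
            "learning_rate": cfg.learning_rate,
            "weight_decay": cfg.weight_decay,
            "max_epochs": cfg.max_epochs,
            "patience": cfg.patience,
            "L": cfg.L,
            "seed": cfg.seed,
            "jitter_magnitude": cfg.jitter_magnitude,
        },
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("header.json", json.dumps(header, sort_keys=True))
        for name, arr in (("V", p.V), ("w", p.w), ("u", p.u)):
            rows = np.atleast_2d(arr)
            text = "\n".join(",".join(repr(float(v)) for v in row) for row in rows)
            zf.writestr(f"{name}.csv", text)
    return path


def load_checkpoint(path: str | Path) -> MilModelParams:
    with zipfile.ZipFile(path) as zf:
        header = json.loads(zf.read("header.json"))
        arrays = {}
        for name in ("V", "w", "u"):
            text = zf.read(f"{name}.csv").decode()
            arrays[name] = np.array([[float(v) for v in line.split(",")] for line in text.splitlines()])
    V = arrays["V"].reshape(header["L"], header["d"])
    return MilModelParams(V=V, w=arrays["w"].ravel(), u=arrays["u"].ravel(), b=header["b"])
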
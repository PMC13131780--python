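"""Training objective and optimization for the segmentation network.

Class-weighted voxel-wise cross-entropy (mean over voxels, weights normalized
to mean 1 so the learning-rate scale is weight-invariant), Adam, and
global-norm gradient clipping.  A fixed seed governs initialization, window
shuffling and dropout, making runs bit-reproducible.  Checkpoints written
after each epoch carry the model and optimizer state, the loss history, the
best validation record, and a snapshot of the full configuration.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .nn.autograd import Tensor
from .network import ModelConfig, SwinUNet3D

__all__ = [
    "TrainConfig",
    "Adam",
    "clip_gradients",
    "weighted_cross_entropy",
    "class_weights_from_counts",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 2
    batch_size: int = 2
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    grad_clip_norm: float = 1.0
    class_weights: tuple[float, ...] | None = None  # None -> corpus inverse frequency
    seed: int = 0

    def __post_init__(self):
        if self.grad_clip_norm <= 0:
            raise ValueError("grad_clip_norm must be positive")
        if self.class_weights is not None:
            w = np.asarray(self.class_weights, dtype=float)
            if (w < 0).any() or not (w > 0).any():
                raise ValueError("class weights must be >= 0 with at least one > 0")


class Adam:
    """Standard Adam with bias correction over a parameter list."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v}

    def load_state(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(a) for a in state["m"]]
        self.v = [np.asarray(a) for a in state["v"]]


def clip_gradients(grads: list[np.ndarray], clip_norm: float) -> list[np.ndarray]:
    """Rescale so the global L2 norm is at most ``clip_norm``.

    Direction is preserved; gradients already inside the ball are unchanged.
    """
    if clip_norm <= 0:
        raise ValueError("clip threshold must be positive")
    total = float(np.sqrt(sum(float((g**2).sum()) for g in grads)))
    if total <= clip_norm or total == 0.0:
        return grads
    scale = clip_norm / total
    return [g * scale for g in grads]


def class_weights_from_counts(counts, num_classes: int | None = None) -> np.ndarray:
    """Inverse-frequency class weights, normalized to mean 1.

    w_k proportional to N_total / (K * max(N_k, 1)); the max guard keeps
    absent classes finite.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 1 or (counts < 0).any():
        raise ValueError("counts must be a 1D non-negative vector")
    if num_classes is not None and len(counts) != num_classes:
        raise ValueError(f"expected {num_classes} counts, got {len(counts)}")
    total = counts.sum()
    if total == 0:
        raise ValueError("all class counts are zero")
    k = len(counts)
    w = total / (k * np.maximum(counts, 1.0))
    return w / w.mean()


def weighted_cross_entropy(logits: Tensor, labels: np.ndarray,
                           weights: np.ndarray) -> Tensor:
    """Mean class-weighted cross-entropy over voxels.

    ``logits`` is (B, K, D, H, W) (or (K, ...)); ``labels`` matches the
    spatial shape with integer classes in [0, K).
    """
    if logits.ndim == 4:
        logits = logits.reshape((1,) + logits.shape)
    k = logits.shape[1]
    labels = np.asarray(labels).reshape(-1)
    if labels.size and (labels.min() < 0 or labels.max() >= k):
        raise ValueError(f"labels must lie in [0, {k}), got range "
                         f"[{labels.min()}, {labels.max()}]")
    weights = np.asarray(weights, dtype=np.float64)
    if len(weights) != k:
        raise ValueError(f"need {k} class weights, got {len(weights)}")
    flat = logits.transpose(0, 2, 3, 4, 1).reshape(-1, k)
    return flat.cross_entropy(labels, weights)


@dataclasses.dataclass
class TrainReport:
    loss_history: list[float]
    epoch_losses: list[float]
    val_history: list[float | None]
    best_val: float | None
    best_epoch: int | None
    checkpoints: list[str]


def _iterate_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def corpus_class_weights(labels: list[np.ndarray], num_classes: int) -> np.ndarray:
    counts = np.zeros(num_classes, dtype=np.int64)
    for lab in labels:
        counts += np.bincount(np.asarray(lab).reshape(-1), minlength=num_classes)
    return class_weights_from_counts(counts, num_classes)


def train(
    model: SwinUNet3D,
    inputs: list[np.ndarray],
    labels: list[np.ndarray],
    cfg: TrainConfig,
    val_inputs: list[np.ndarray] | None = None,
    val_labels: list[np.ndarray] | None = None,
    out_dir=None,
    log=None,
) -> TrainReport:
    """Optimize the model on (feature window, label window) pairs.

    Windows are (C, w, w, w) float inputs and (w, w, w) integer labels.
    Checkpoints are written per epoch when ``out_dir`` is given.
    """
    if not inputs or len(inputs) != len(labels):
        raise ValueError("need a non-empty, equal-length input/label set")
    k = model.config.num_classes
    if cfg.class_weights is not None:
        weights = np.asarray(cfg.class_weights, dtype=np.float64)
        weights = weights / weights.mean()
    else:
        weights = corpus_class_weights(labels, k)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), cfg.learning_rate, cfg.beta1, cfg.beta2, cfg.eps)
    report = TrainReport([], [], [], None, None, [])
    for epoch in range(cfg.epochs):
        epoch_losses = []
        for batch in _iterate_batches(len(inputs), cfg.batch_size, rng):
            x = np.stack([inputs[i] for i in batch])
            y = np.stack([labels[i] for i in batch])
            opt.zero_grad()
            logits = model.forward(x, rng=rng, training=True)
            loss = weighted_cross_entropy(logits, y, weights)
            loss.backward()
            params = opt.params
            grads = clip_gradients([p.grad for p in params], cfg.grad_clip_norm)
            for p, g in zip(params, grads):
                p.grad = g
            opt.step()
            value = float(loss.data)
            epoch_losses.append(value)
            report.loss_history.append(value)
        mean_loss = float(np.mean(epoch_losses))
        report.epoch_losses.append(mean_loss)
        val = None
        if val_inputs:
            val_losses = []
            for x, y in zip(val_inputs, val_labels):
                logits = model.forward(x[None])
                val_losses.append(float(weighted_cross_entropy(logits, y[None], weights).data))
            val = float(np.mean(val_losses))
            if report.best_val is None or val < report.best_val:
                report.best_val, report.best_epoch = val, epoch
        report.val_history.append(val)
        if log:
            log(f"epoch {epoch + 1}/{cfg.epochs}: train loss {mean_loss:.4f}"
                + (f", val loss {val:.4f}" if val is not None else ""))
        if out_dir is not None:
            Path(out_dir).mkdir(parents=True, exist_ok=True)
            path = Path(out_dir) / f"checkpoint_epoch{epoch + 1:03d}.npz"
            save_checkpoint(path, model, opt, cfg, report, epoch)
            report.checkpoints.append(str(path))
    return report


def save_checkpoint(path, model: SwinUNet3D, opt: Adam, cfg: TrainConfig,
                    report: TrainReport, epoch: int) -> None:
    """Self-describing archive: weights, optimizer state, history, config."""
    state = model.state_dict()
    names = sorted(state)
    meta = {
        "epoch": epoch,
        "param_names": names,
        "model_config": dataclasses.asdict(model.config),
        "train_config": dataclasses.asdict(cfg),
        "loss_history": report.loss_history,
        "epoch_losses": report.epoch_losses,
        "val_history": report.val_history,
        "best_val": report.best_val,
        "best_epoch": report.best_epoch,
    }
    arrays = {f"param_{i}": state[n] for i, n in enumerate(names)}
    arrays.update({f"adam_m_{i}": m for i, m in enumerate(opt.state()["m"])})
    arrays.update({f"adam_v_{i}": v for i, v in enumerate(opt.state()["v"])})
    arrays["adam_t"] = np.int64(opt.t)
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path, seed: int = 0):
    """Rebuild (model, train config, metadata) from a checkpoint archive."""
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta_json"]).decode())
        model_cfg = ModelConfig(
            **{k: tuple(v) if isinstance(v, list) else v
               for k, v in meta["model_config"].items()}
        )
        model = SwinUNet3D(model_cfg, seed=seed)
        names = meta["param_names"]
        model.load_state_dict({n: npz[f"param_{i}"] for i, n in enumerate(names)})
        train_cfg = TrainConfig(
            **{k: tuple(v) if isinstance(v, list) else v
               for k, v in meta["train_config"].items()}
        )
        opt = Adam(model.parameters(), train_cfg.learning_rate,
                   train_cfg.beta1, train_cfg.beta2, train_cfg.eps)
        opt.load_state({
            "t": int(npz["adam_t"]),
            "m": [npz[f"adam_m_{i}"] for i in range(len(names))],
            "v": [npz[f"adam_v_{i}"] for i in range(len(names))],
        })
    return model, opt, train_cfg, meta
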
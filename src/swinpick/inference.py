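"""Patch-wise inference: softmax posteriors, confidence threshold, argmax.

Each window's logits become per-voxel posteriors; voxels whose maximum
posterior falls below the confidence threshold are assigned background (0),
suppressing uncertain predictions.  Window predictions keep their placement
metadata so they stitch back into a full-size label volume exactly.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .gridding import stitch
from .io import GridBundle, Volume
from .network import SwinUNet3D

__all__ = ["InferConfig", "predict_window", "predict_bundles", "predict_volume"]


@dataclasses.dataclass
class InferConfig:
    """``conf_threshold`` in [0, 1]; class 0 is background.

    In ``binary`` mode (two classes) the foreground posterior p1 is
    thresholded directly instead of the max-posterior rule.
    """

    conf_threshold: float = 0.5
    binary: bool = False

    def __post_init__(self):
        if not 0.0 <= self.conf_threshold <= 1.0:
            raise ValueError(f"confidence threshold must be in [0, 1], got {self.conf_threshold}")


def _softmax(z: np.ndarray, axis: int) -> np.ndarray:
    e = np.exp(z - z.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def labels_from_logits(logits: np.ndarray, cfg: InferConfig) -> np.ndarray:
    """(K, D, H, W) logits -> integer label grid with confidence suppression."""
    return labels_from_posteriors(_softmax(np.asarray(logits, dtype=np.float64), axis=0), cfg)


def labels_from_posteriors(post: np.ndarray, cfg: InferConfig) -> np.ndarray:
    if cfg.binary:
        if post.shape[0] != 2:
            raise ValueError(f"binary mode needs 2 classes, got {post.shape[0]}")
        return (post[1] >= cfg.conf_threshold).astype(np.int64)
    labels = post.argmax(axis=0).astype(np.int64)
    labels[post.max(axis=0) < cfg.conf_threshold] = 0
    return labels


def posterior_window(model: SwinUNet3D, x: np.ndarray) -> np.ndarray:
    """Per-voxel class posteriors (K, D, H, W) for one feature window."""
    logits = model.forward(x[None] if x.ndim == 4 else x).data[0]
    return _softmax(logits.astype(np.float64), axis=0)


def predict_window(model: SwinUNet3D, x: np.ndarray,
                   cfg: InferConfig | None = None) -> np.ndarray:
    """Segment one feature window (C, w, w, w) into an integer label grid."""
    cfg = cfg or InferConfig()
    logits = model.forward(x[None] if x.ndim == 4 else x).data[0]
    return labels_from_logits(logits, cfg)


def predict_bundles(model: SwinUNet3D, bundles: list[GridBundle],
                    cfg: InferConfig | None = None, log=None) -> list[GridBundle]:
    """Predict every feature bundle, preserving placement metadata."""
    cfg = cfg or InferConfig()
    out = []
    for idx, b in enumerate(bundles):
        labels = predict_window(model, b.grid, cfg)
        out.append(dataclasses.replace(b, grid=labels))
        if log and (idx + 1) % 10 == 0:
            log(f"predicted {idx + 1}/{len(bundles)} windows")
    return out


def predict_volume(model: SwinUNet3D, bundles: list[GridBundle],
                   cfg: InferConfig | None = None, log=None) -> Volume:
    """Predict all windows of a volume and stitch the full label volume."""
    return stitch(predict_bundles(model, bundles, cfg, log=log))
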
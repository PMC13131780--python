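"""From dense label volumes to particle coordinates, and their evaluation.

Post-processing: per predicted class, connected components under
18-connectivity (face + edge neighbours), removal of components below a
minimum voxel count, and unweighted centroid extraction.  Evaluation:
one-to-one Hungarian assignment between predicted and reference centroids
under a distance cutoff ``d_max`` (default 5 voxels); pairs within the cutoff
are true positives, the rest of the predictions are false positives and the
rest of the references false negatives.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .io import Volume, particle_table

__all__ = [
    "Component",
    "ComponentSet",
    "MatchResult",
    "connected_components",
    "size_filter",
    "centroids",
    "hungarian_match",
    "metrics_from_counts",
    "extract_particles",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclasses.dataclass
class Component:
    class_id: int
    size: int
    centroid: tuple[float, float, float]  # canonical (z, y, x) voxel indices


@dataclasses.dataclass
class ComponentSet:
    components: list[Component]

    def sizes(self) -> list[int]:
        return [c.size for c in self.components]


@dataclasses.dataclass
class MatchResult:
    """Detection counts, matched pairs, and the derived ratios.

    ``precision``/``recall``/``f1``/``miss_rate`` are ``None`` when their
    denominator is zero (undefined, never reported as 0), and ``ad`` (mean
    Euclidean distance over matched pairs, voxels) is ``None`` at TP = 0.
    """

    tp: int
    fp: int
    fn: int
    matched_pairs: list[tuple[int, int, float]]
    precision: float | None
    recall: float | None
    f1: float | None
    miss_rate: float | None
    ad: float | None

    def to_dict(self) -> dict:
        # MH (multiple hits) cannot occur under one-to-one assignment and is
        # reported as the structural 0 for comparability with count tables
        return {
            "TP": self.tp, "FP": self.fp, "FN": self.fn, "MH": 0,
            "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "miss_rate": self.miss_rate, "AD": self.ad,
        }


def connected_components(labels: Volume, connectivity: int = 18) -> ComponentSet:
    """Per-class connected components of an integer label volume."""
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}, got {connectivity}")
    data = labels.data
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError("label volume must be integer-valued")
    structure = _STRUCTURES[connectivity]
    out: list[Component] = []
    for class_id in np.unique(data):
        class_id = int(class_id)
        if class_id <= 0:
            continue
        lab, n = ndimage.label(data == class_id, structure=structure)
        if n == 0:
            continue
        idx = np.arange(1, n + 1)
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, idx)
        cents = ndimage.center_of_mass(np.ones_like(lab), lab, idx)
        for size, cent in zip(sizes, cents):
            out.append(Component(class_id, int(size), tuple(float(c) for c in cent)))
    return ComponentSet(out)


def size_filter(cs: ComponentSet, min_size: int = 5) -> ComponentSet:
    """Keep components with at least ``min_size`` voxels (inclusive bound)."""
    if min_size < 0:
        raise ValueError(f"min_size must be >= 0, got {min_size}")
    return ComponentSet([c for c in cs.components if c.size >= min_size])


def centroids(cs: ComponentSet) -> pd.DataFrame:
    """Particle table of component centroids, converted to (x, y, z) order."""
    rows = [
        (c.class_id, c.centroid[2], c.centroid[1], c.centroid[0]) for c in cs.components
    ]
    return particle_table(rows)


def extract_particles(
    labels: Volume, min_size: int = 5, connectivity: int = 18
) -> pd.DataFrame:
    """Full post-processing chain: components -> size filter -> centroids."""
    return centroids(size_filter(connected_components(labels, connectivity), min_size))


def _match_coords(pred: np.ndarray, gt: np.ndarray, d_max: float) -> list[tuple[int, int, float]]:
    if len(pred) == 0 or len(gt) == 0:
        return []
    diff = pred[:, None, :] - gt[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    invalid = 1e6 * d_max
    cost = np.where(dist > d_max, invalid, dist)
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(r), int(c), float(dist[r, c]))
        for r, c in zip(rows, cols)
        if dist[r, c] <= d_max
    ]


def hungarian_match(
    pred: pd.DataFrame,
    gt: pd.DataFrame,
    d_max: float = 5.0,
    per_class: bool = False,
) -> MatchResult:
    """Score predicted centroids against reference centroids.

    Euclidean distances above ``d_max`` are invalidated (set to a large
    constant) before solving the assignment; invalid assignments do not count
    as matches.  With ``per_class`` the assignment is restricted to equal
    class IDs (multiclass evaluation); otherwise coordinates are pooled
    (binary evaluation).
    """
    if d_max <= 0:
        raise ValueError(f"d_max must be positive, got {d_max}")
    pairs: list[tuple[int, int, float]] = []
    if per_class:
        classes = sorted(set(pred["class_id"]) | set(gt["class_id"]))
        for class_id in classes:
            p_idx = np.flatnonzero((pred["class_id"] == class_id).to_numpy())
            g_idx = np.flatnonzero((gt["class_id"] == class_id).to_numpy())
            sub = _match_coords(
                pred.iloc[p_idx][["x", "y", "z"]].to_numpy(float),
                gt.iloc[g_idx][["x", "y", "z"]].to_numpy(float),
                d_max,
            )
            pairs.extend((int(p_idx[r]), int(g_idx[c]), d) for r, c, d in sub)
    else:
        pairs = _match_coords(
            pred[["x", "y", "z"]].to_numpy(float), gt[["x", "y", "z"]].to_numpy(float), d_max
        )
    tp = len(pairs)
    fp = len(pred) - tp
    fn = len(gt) - tp
    precision, recall, f1, miss = metrics_from_counts(tp, fp, fn)
    ad = float(np.mean([d for _, _, d in pairs])) if pairs else None
    return MatchResult(tp, fp, fn, pairs, precision, recall, f1, miss, ad)


def metrics_from_counts(tp: int, fp: int, fn: int):
    """(precision, recall, f1, miss_rate) from detection counts.

    Ratios with zero denominators are undefined and returned as ``None``.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    elif precision is None or recall is None:
        f1 = None
    else:
        f1 = None if math.isclose(precision + recall, 0.0) else 0.0
    miss_rate = None if recall is None else 1.0 - recall
    return precision, recall, f1, miss_rate
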
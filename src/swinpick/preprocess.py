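"""Tomogram standardization and label construction.

Tomograms from heterogeneous sources are brought onto a common footing before
feature extraction: trilinear resampling to an isotropic target voxel size,
percentile normalization into [0, 1], dataset-specific z-offset correction of
centroid annotations, and remapping of per-dataset class IDs into one unified
multiclass space (with membranes/vesicles dropped to background).  Mask
remapping is purely value substitution — the occupancy (true 3D shape) of
every labelled instance is preserved, never replaced by synthetic spheres.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import PARTICLE_COLUMNS, Volume

__all__ = [
    "NormalizationParams",
    "ClassMap",
    "OffsetRule",
    "DegenerateVolumeError",
    "ClassMappingError",
    "resample_isotropic",
    "percentile_normalize",
    "align_coordinates",
    "remap_class_mask",
    "binarize_mask",
]


class DegenerateVolumeError(ValueError):
    """Raised when a volume cannot be normalized (reference percentile <= 0)."""


class ClassMappingError(ValueError):
    """Raised when a mask contains class IDs absent from the mapping."""


@dataclasses.dataclass
class NormalizationParams:
    """Percentile scaling followed by clipping into [clip_lo, clip_hi].

    ``nonzero_only`` restricts the percentile to nonzero voxels, for
    reconstructions carrying zero padding slabs; default uses all finite
    voxels.
    """

    percentile: float = 95.0
    clip_lo: float = 0.0
    clip_hi: float = 1.0
    nonzero_only: bool = False

    def __post_init__(self):
        if not 0.0 < self.percentile <= 100.0:
            raise ValueError(f"percentile must be in (0, 100], got {self.percentile}")


@dataclasses.dataclass
class ClassMap:
    """Per-dataset remapping of original class IDs into the unified ID space.

    ``mapping`` sends original IDs to unified IDs in {0..K}; IDs listed in
    ``excluded_ids`` (vesicles, membranes, ...) are dropped to background 0.
    """

    mapping: dict[int, int]
    excluded_ids: frozenset[int] = frozenset()

    def __post_init__(self):
        self.mapping = {int(k): int(v) for k, v in self.mapping.items()}
        self.excluded_ids = frozenset(int(i) for i in self.excluded_ids)
        if any(v < 0 for v in self.mapping.values()):
            raise ValueError("unified class ids must be >= 0")

    def lookup(self) -> dict[int, int]:
        table = {i: 0 for i in self.excluded_ids}
        table.update(self.mapping)
        table.setdefault(0, 0)
        return table

    @classmethod
    def from_file(cls, path, dataset: str) -> "ClassMap":
        """Load a dataset's mapping from a YAML/JSON file.

        Layout: ``{<dataset>: {orig_id: unified_id, ...}, excluded: [ids]}``;
        ``excluded`` may also live inside the dataset section.
        """
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if dataset not in doc:
            raise ValueError(f"{path}: no class map for dataset {dataset!r}")
        section = dict(doc[dataset])
        excluded = set(section.pop("excluded", [])) | set(doc.get("excluded", []))
        return cls(mapping=section, excluded_ids=frozenset(excluded))


@dataclasses.dataclass
class OffsetRule:
    """Dataset tag -> integer z offset (voxels) applied to coordinates.

    SHREC reconstructions are taller than their ground-truth model volume, so
    annotation z must be shifted into reconstruction coordinates (+156 for
    SHREC2020, +166 for SHREC2021); other sources need no correction.
    """

    offsets: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"SHREC2020": 156, "SHREC2021": 166}
    )
    default: int | None = None

    def offset_for(self, dataset: str) -> int:
        if dataset in self.offsets:
            return int(self.offsets[dataset])
        if self.default is not None:
            return int(self.default)
        raise ValueError(f"unknown dataset tag {dataset!r}; known: {sorted(self.offsets)}")


def resample_isotropic(v: Volume, target: float) -> Volume:
    """Trilinearly resample onto an isotropic grid of ``target`` A per voxel.

    Output dimension along each axis is ``round(dim * voxel/target)``;
    sampling outside the source grid clamps to the edge.  A volume already at
    the target spacing is returned unchanged (exact identity).
    """
    if target <= 0:
        raise ValueError(f"target voxel size must be positive, got {target}")
    sx, sy, sz = v.voxel_size
    scale = np.array([sz, sy, sx]) / target  # canonical (z, y, x) order
    if np.allclose(scale, 1.0):
        return Volume(v.data.copy(), (target, target, target), v.origin, v.axis_map)
    out_shape = tuple(int(round(d * s)) for d, s in zip(v.data.shape, scale))
    if min(out_shape) < 1:
        raise ValueError(f"target spacing {target} collapses the volume to {out_shape}")
    # Output index -> input index in each axis: i_in = i_out * target / voxel.
    grids = np.meshgrid(
        *[np.arange(n, dtype=np.float64) / s for n, s in zip(out_shape, scale)],
        indexing="ij",
    )
    data = ndimage.map_coordinates(
        v.data.astype(np.float32), np.stack(grids), order=1, mode="nearest"
    )
    return Volume(data, (target, target, target), v.origin, v.axis_map)


def percentile_normalize(v: Volume, params: NormalizationParams | None = None) -> Volume:
    """Scale by the reference percentile of the density, then clip to [0, 1]."""
    params = params or NormalizationParams()
    data = v.data.astype(np.float64)
    ref = data[data != 0] if params.nonzero_only else data[np.isfinite(data)]
    if ref.size == 0:
        raise DegenerateVolumeError("no informative voxels to normalize against")
    p = float(np.percentile(ref, params.percentile))
    if p <= 0:
        raise DegenerateVolumeError(
            f"reference percentile p{params.percentile:g} = {p:g} is not positive"
        )
    out = np.clip(data / p, params.clip_lo, params.clip_hi).astype(np.float32)
    return v.with_data(out)


def align_coordinates(table: pd.DataFrame, rule: OffsetRule, dataset: str) -> pd.DataFrame:
    """Apply the dataset's z offset to the coordinate table (x, y untouched)."""
    offset = rule.offset_for(dataset)
    out = table.copy()
    out["z"] = out["z"].astype(np.float64) + offset
    return out[PARTICLE_COLUMNS]


def remap_class_mask(mask: Volume, cm: ClassMap) -> Volume:
    """Substitute voxel class IDs per the mapping; excluded IDs become 0.

    Value substitution only: instance occupancy shapes are untouched.
    """
    data = mask.data
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValueError("class mask must be integer-valued")
        data = np.round(data).astype(np.int64)
    table = cm.lookup()
    present = np.unique(data)
    unmapped = sorted(int(i) for i in present if int(i) not in table)
    if unmapped:
        raise ClassMappingError(f"mask contains unmapped class ids {unmapped}")
    lut_size = int(present.max()) + 1 if present.size else 1
    lut = np.zeros(lut_size, dtype=np.int64)
    for orig, unified in table.items():
        if 0 <= orig < lut_size:
            lut[orig] = unified
    return mask.with_data(lut[data])


def binarize_mask(mask: Volume) -> Volume:
    """Collapse all particle classes to foreground 1; background stays 0."""
    data = mask.data
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError("mask must be integer-valued")
    return mask.with_data((data > 0).astype(np.int64))
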
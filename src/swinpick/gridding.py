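"""Windowing of volumes into context-padded cubes and exact stitching back.

Volumes are tiled by disjoint cubic *cores* (default 48^3) on a core-stride
lattice; each training/inference window adds a fixed context margin (default
8 voxels per face) around its core, zero-padded where the window leaves the
volume.  Because cores are disjoint and exhaustive, stitching the core
regions of predicted windows back into a full-size volume is write-once and
exact.  The default geometry gives 64^3 windows; any core/pad combination is
accepted as long as the window stays divisible by 16 (the encoder's total
downscale factor).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .features import FeatureStack
from .io import GridBundle, Volume

__all__ = ["GridSpec", "split_volume", "filter_nonzero", "stitch", "StitchError"]


class StitchError(ValueError):
    """Raised when bundle cores do not tile the source volume exactly."""


@dataclasses.dataclass
class GridSpec:
    """Core/pad geometry: window = core + 2 * pad."""

    core: int = 48
    pad: int = 8

    def __post_init__(self):
        if self.core <= 0 or self.pad < 0:
            raise ValueError(f"need core > 0 and pad >= 0, got core={self.core} pad={self.pad}")
        if self.window % 16 != 0:
            raise ValueError(
                f"window {self.window} (= core + 2*pad) must be divisible by 16 "
                "to pass the 4-stage downscaling"
            )

    @property
    def window(self) -> int:
        return self.core + 2 * self.pad


def _as_array_and_meta(v):
    if isinstance(v, Volume):
        return v.data[None], v.voxel_size, v.origin, v.axis_map, False
    if isinstance(v, FeatureStack):
        return v.channels, v.voxel_size, v.origin, v.axis_map, True
    raise TypeError(f"expected Volume or FeatureStack, got {type(v).__name__}")


def split_volume(v, spec: GridSpec | None = None) -> list[GridBundle]:
    """Cut a volume (or feature stack) into padded windows covering it.

    Returns ``prod(ceil(dim / core))`` bundles whose disjoint cores tile the
    volume; boundary bundles record truncated extents.
    """
    spec = spec or GridSpec()
    arr, voxel_size, origin, axis_map, channelled = _as_array_and_meta(v)
    shape = arr.shape[1:]
    w, c, p = spec.window, spec.core, spec.pad
    bundles = []
    counts = [math.ceil(d / c) for d in shape]
    for bi in range(counts[0]):
        for bj in range(counts[1]):
            for bk in range(counts[2]):
                offs = (bi * c, bj * c, bk * c)
                exts = tuple(min(c, d - o) for o, d in zip(offs, shape))
                window = np.zeros((arr.shape[0], w, w, w), dtype=arr.dtype)
                # window voxel 0 sits at source index off - pad
                src_lo = [o - p for o in offs]
                src_hi = [lo + w for lo in src_lo]
                cut_lo = [max(lo, 0) for lo in src_lo]
                cut_hi = [min(hi, d) for hi, d in zip(src_hi, shape)]
                dst_lo = [cl - lo for cl, lo in zip(cut_lo, src_lo)]
                dst_hi = [dl + (ch - cl) for dl, cl, ch in zip(dst_lo, cut_lo, cut_hi)]
                window[
                    :, dst_lo[0] : dst_hi[0], dst_lo[1] : dst_hi[1], dst_lo[2] : dst_hi[2]
                ] = arr[:, cut_lo[0] : cut_hi[0], cut_lo[1] : cut_hi[1], cut_lo[2] : cut_hi[2]]
                bundles.append(
                    GridBundle(
                        grid=window if channelled else window[0],
                        placement=offs,
                        extents=exts,
                        pad=p,
                        source_shape=tuple(shape),
                        voxel_size=voxel_size,
                        origin=origin,
                        axis_map=axis_map,
                    )
                )
    return bundles


def filter_nonzero(
    pairs: list[tuple[GridBundle, GridBundle]]
) -> list[tuple[GridBundle, GridBundle]]:
    """Drop (input, mask) window pairs whose mask window is entirely background.

    Training-time only: tomograms are mostly empty, and background-only cubes
    waste computation and bias the class balance.  Inference must keep every
    window so the stitched prediction covers the full volume.
    """
    kept = []
    for inp, mask in pairs:
        if inp.placement != mask.placement or inp.source_shape != mask.source_shape:
            raise ValueError(
                f"unpaired bundles: input at {inp.placement}, mask at {mask.placement}"
            )
        if mask.grid.max() > 0:
            kept.append((inp, mask))
    return kept


def stitch(bundles: list[GridBundle]) -> Volume:
    """Reassemble a full-size volume from the core regions of its windows.

    Only the central, non-padded core of each window is written, at its
    recorded placement; every output voxel must be written exactly once.
    """
    if not bundles:
        raise StitchError("no bundles to stitch")
    ref = bundles[0]
    shape = ref.source_shape
    out = np.zeros(shape, dtype=ref.grid.dtype)
    written = np.zeros(shape, dtype=bool)
    for b in bundles:
        if b.source_shape != shape:
            raise StitchError(f"bundle source shapes differ: {b.source_shape} vs {shape}")
        if b.grid.ndim != 3:
            raise StitchError("stitching expects single-channel (label) bundles")
        i, j, k = b.placement
        di, dj, dk = b.extents
        region = (slice(i, i + di), slice(j, j + dj), slice(k, k + dk))
        if written[region].any():
            raise StitchError(f"overlapping cores at placement {b.placement}")
        out[region] = b.core()
        written[region] = True
    if not written.all():
        raise StitchError("bundle cores do not cover the full volume")
    return Volume(out, ref.voxel_size, ref.origin, ref.axis_map)
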
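"""Derived 3D feature volumes and the 4-channel network input stack.

Three complementary feature maps are computed on the full normalized tomogram
(so window borders see true context) and stacked with the density itself:

* multi-scale difference-of-Gaussians, keeping at each voxel the signed
  response of the scale with maximum absolute magnitude (blobness),
* Sobel gradient magnitude in intensity per Angstrom (edge strength),
* multi-scale white/black morphological top-hat, combined by voxel-wise
  maximum (local contrast against slowly varying background).

Channel order of the stack is fixed:
``[normalized density, gradient magnitude, combined top-hat, DoG-max]``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .io import Volume

__all__ = [
    "FeatureConfig",
    "FeatureStack",
    "dog_max",
    "sobel_gradient_magnitude",
    "tophat_multiscale",
    "build_feature_stack",
    "percentile_clip",
]

#: Boundary handling for all filters: replicate the edge voxel.
_BOUNDARY = "nearest"


@dataclasses.dataclass
class FeatureConfig:
    """Shared scale set and numeric options for the derived feature maps.

    ``scales`` are structuring radii / Gaussian sigmas in voxels; ``k`` is the
    DoG sigma ratio (sqrt(2) approximates the scale-normalized Laplacian);
    ``scale_normalize`` multiplies each DoG response by s^2 to balance blob
    sizes; top-hat responses are harmonized across scales by an s^(1/2)
    multiplier.  ``clip_percentiles=None`` disables the final outlier clip.
    """

    scales: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)
    k: float = float(np.sqrt(2.0))
    scale_normalize: bool = True
    clip_percentiles: tuple[float, float] | None = (0.01, 99.99)
    tophat_scale_power: float = 0.5

    def __post_init__(self):
        scales = tuple(float(s) for s in self.scales)
        if not scales:
            raise ValueError("scale set must be non-empty")
        if any(s <= 0 for s in scales) or any(b <= a for a, b in zip(scales, scales[1:])):
            raise ValueError(f"scales must be positive and strictly increasing, got {scales}")
        if self.k <= 1:
            raise ValueError(f"DoG sigma ratio k must exceed 1, got {self.k}")
        self.scales = scales


@dataclasses.dataclass
class FeatureStack:
    """The 4-channel input tensor, channel-first, sharing the volume metadata."""

    channels: np.ndarray  # (4, D, H, W)
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]
    axis_map: tuple[int, int, int]

    def __post_init__(self):
        if self.channels.ndim != 4 or self.channels.shape[0] != 4:
            raise ValueError(f"feature stack must be (4, D, H, W), got {self.channels.shape}")

    @property
    def shape(self):
        return self.channels.shape


def percentile_clip(data: np.ndarray, percentiles: tuple[float, float] | None) -> np.ndarray:
    """Clip to the [lo, hi] percentile interval of the data (no-op if None)."""
    if percentiles is None:
        return data
    lo, hi = np.percentile(data, percentiles)
    return np.clip(data, lo, hi)


def dog_max(v: Volume, cfg: FeatureConfig | None = None) -> Volume:
    """Signed multi-scale DoG response at the scale of maximum |response|."""
    cfg = cfg or FeatureConfig()
    data = v.data.astype(np.float32)
    best = np.zeros_like(data)
    best_abs = np.full_like(data, -1.0)
    for s in cfg.scales:
        low = ndimage.gaussian_filter(data, sigma=cfg.k * s, mode=_BOUNDARY)
        high = ndimage.gaussian_filter(data, sigma=s, mode=_BOUNDARY)
        resp = low - high
        if cfg.scale_normalize:
            resp = resp * np.float32(s * s)
        mag = np.abs(resp)
        take = mag > best_abs
        best = np.where(take, resp, best)
        best_abs = np.where(take, mag, best_abs)
    return v.with_data(percentile_clip(best, cfg.clip_percentiles).astype(np.float32))


def sobel_gradient_magnitude(v: Volume) -> Volume:
    """3D Sobel gradient magnitude in intensity per Angstrom.

    The kernel is the (-1, 0, 1) derivative stencil combined with (1, 2, 1)
    smoothing on both orthogonal axes, divided by 32 so a unit-slope ramp
    (per voxel) responds with exactly 1; each component is then divided by
    the voxel size along its axis to express gradients per Angstrom.
    """
    data = v.data.astype(np.float32)
    sx, sy, sz = v.voxel_size
    sq = np.zeros(data.shape, dtype=np.float64)
    for axis, spacing in ((0, sz), (1, sy), (2, sx)):  # canonical (z, y, x)
        g = ndimage.sobel(data, axis=axis, mode=_BOUNDARY) / (32.0 * spacing)
        sq += g.astype(np.float64) ** 2
    return v.with_data(np.sqrt(sq).astype(np.float32))


def tophat_multiscale(
    v: Volume, cfg: FeatureConfig | None = None
) -> tuple[Volume, Volume, Volume]:
    """Multi-scale white/black top-hat maps and their voxel-wise combination.

    Per scale s the white top-hat I - opening(I) (bright detail) and black
    top-hat closing(I) - I (dark detail) are computed with a discrete ball of
    radius s, weighted by s^(1/2), and aggregated across scales by voxel-wise
    maximum; the combined map is max(white, black).
    """
    cfg = cfg or FeatureConfig()
    data = v.data.astype(np.float32)
    white = np.zeros_like(data)
    black = np.zeros_like(data)
    for s in cfg.scales:
        footprint = ball(int(round(s)))
        weight = np.float32(s ** cfg.tophat_scale_power)
        white = np.maximum(
            white, weight * ndimage.white_tophat(data, footprint=footprint, mode=_BOUNDARY)
        )
        black = np.maximum(
            black, weight * ndimage.black_tophat(data, footprint=footprint, mode=_BOUNDARY)
        )
    combined = np.maximum(white, black)
    clip = cfg.clip_percentiles
    return (
        v.with_data(percentile_clip(white, clip).astype(np.float32)),
        v.with_data(percentile_clip(black, clip).astype(np.float32)),
        v.with_data(percentile_clip(combined, clip).astype(np.float32)),
    )


def build_feature_stack(v_norm: Volume, cfg: FeatureConfig | None = None) -> FeatureStack:
    """Assemble the fixed-order 4-channel input from a normalized tomogram."""
    cfg = cfg or FeatureConfig()
    grad = sobel_gradient_magnitude(v_norm)
    _, _, tophat = tophat_multiscale(v_norm, cfg)
    dog = dog_max(v_norm, cfg)
    channels = np.stack(
        [v_norm.data.astype(np.float32), grad.data, tophat.data, dog.data], axis=0
    )
    return FeatureStack(channels, v_norm.voxel_size, v_norm.origin, v_norm.axis_map)
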
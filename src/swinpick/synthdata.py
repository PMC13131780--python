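"""Synthetic tomograms with known particle positions, masks, and noise.

The simulator emulates the on-disk triplet a picking pipeline consumes: a
density volume containing particles of several size classes at known
centroids, the matching occupancy label mask, and the centroid coordinate
table.  Particles are solid spheres by default (their voxel occupancy is then
exactly the label mask, as in occupancy-preserving supervision) or isotropic
Gaussian blobs for softer contrast; additive Gaussian noise sets the SNR
regime, and an optional Fourier-space wedge reproduces the z-elongation
artifact of limited-tilt reconstruction.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import Volume, particle_table

__all__ = ["ParticleClass", "SimConfig", "PlacementError", "simulate", "apply_missing_wedge"]


class PlacementError(RuntimeError):
    """Raised when the min-distance packing cannot be satisfied."""


@dataclasses.dataclass
class ParticleClass:
    class_id: int
    radius: float  # voxels
    amplitude: float
    count: int

    def __post_init__(self):
        if self.class_id < 1:
            raise ValueError("particle class ids start at 1 (0 is background)")
        if self.radius <= 0 or self.count < 0:
            raise ValueError("radius must be positive and count non-negative")


@dataclasses.dataclass
class SimConfig:
    """Generation settings; the seed fixes the full output bit-exactly.

    Defaults give the easy regime (unit-amplitude spheres in unit-sigma
    noise, SNR ~ 1) used for smoke tests; raise ``noise_sigma`` towards ~3
    for the sub-0.1 SNR stress regime of real tomograms.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 1.0
    classes: tuple[ParticleClass, ...] = (
        ParticleClass(1, 3.0, 1.0, 10),
        ParticleClass(2, 5.0, 1.0, 6),
    )
    noise_sigma: float = 1.0
    min_distance: float = 14.0
    gaussian_profile: bool = False
    missing_wedge_half_angle: float | None = None
    seed: int = 0
    max_attempts: int = 10_000

    def __post_init__(self):
        if self.min_distance < 0:
            raise ValueError("min_distance must be >= 0")


def _place_centers(cfg: SimConfig, rng: np.random.Generator) -> list[tuple[int, np.ndarray]]:
    """Rejection-sample particle centers honouring the min pairwise distance."""
    centers: list[tuple[int, np.ndarray]] = []
    shape = np.asarray(cfg.shape, dtype=float)
    for pc in cfg.classes:
        margin = pc.radius + 1.0
        lo, hi = margin, shape - margin
        if np.any(hi <= lo):
            raise PlacementError(f"volume {cfg.shape} too small for radius {pc.radius}")
        for _ in range(pc.count):
            for _ in range(cfg.max_attempts):
                cand = rng.uniform(lo, hi)
                if all(
                    np.linalg.norm(cand - c) >= cfg.min_distance for _, c in centers
                ):
                    centers.append((pc.class_id, cand))
                    break
            else:
                raise PlacementError(
                    f"could not place {pc.count} particles of class {pc.class_id} "
                    f"at min distance {cfg.min_distance} in {cfg.max_attempts} attempts"
                )
    return centers


def simulate(cfg: SimConfig | None = None):
    """Generate (density Volume, mask Volume, truth particle table).

    The mask labels exactly the voxels within each particle's radius of its
    center with the particle's class id; the density is the sum of particle
    kernels plus i.i.d. Gaussian noise.  Coordinates in the truth table are
    (x, y, z) voxel positions of the planted centers.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    by_radius = {pc.class_id: pc for pc in cfg.classes}
    centers = _place_centers(cfg, rng)

    density = np.zeros(cfg.shape, dtype=np.float32)
    mask = np.zeros(cfg.shape, dtype=np.int64)
    zz, yy, xx = np.meshgrid(*[np.arange(n) for n in cfg.shape], indexing="ij")
    rows = []
    for class_id, center in centers:
        pc = by_radius[class_id]
        r2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
        inside = r2 <= pc.radius**2
        mask[inside] = class_id
        if cfg.gaussian_profile:
            density += (pc.amplitude * np.exp(-r2 / (2 * (pc.radius / 2) ** 2))).astype(
                np.float32
            )
        else:
            density[inside] += np.float32(pc.amplitude)
        # canonical (z, y, x) center -> (x, y, z) coordinate columns
        rows.append((class_id, center[2], center[1], center[0]))
    if cfg.noise_sigma > 0:
        density = density + rng.normal(0.0, cfg.noise_sigma, cfg.shape).astype(np.float32)
    vs = (cfg.voxel_size,) * 3
    density_v = Volume(density, vs)
    if cfg.missing_wedge_half_angle is not None:
        density_v = apply_missing_wedge(density_v, cfg.missing_wedge_half_angle)
    return density_v, Volume(mask, vs), particle_table(rows)


def apply_missing_wedge(v: Volume, half_angle: float) -> Volume:
    """Zero Fourier coefficients inside the missing wedge (tilt axis y).

    A limited tilt range of +/- ``half_angle`` degrees about the y axis leaves
    unsampled the Fourier region where the angle from the x-y plane toward z,
    measured in the x-z plane, exceeds ``half_angle``.
    """
    if not 0 < half_angle < 90:
        raise ValueError(f"half angle must be in (0, 90) degrees, got {half_angle}")
    data = v.data.astype(np.float64)
    kz = np.fft.fftfreq(data.shape[0])[:, None, None]
    kx = np.fft.fftfreq(data.shape[2])[None, None, :]
    angle = np.degrees(np.arctan2(np.abs(kz), np.abs(kx)))
    wedge = angle > half_angle
    spectrum = np.fft.fftn(data)
    spectrum[np.broadcast_to(wedge, spectrum.shape)] = 0.0
    out = np.fft.ifftn(spectrum).real.astype(np.float32)
    return v.with_data(out)
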
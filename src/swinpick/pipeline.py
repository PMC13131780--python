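"""End-to-end wiring of the stages, plus the reduced CPU benchmark.

Two reference experiments are defined here and shared by the test suite, the
command line, and the reproduction script:

* :func:`oracle_roundtrip` — the zero-noise consistency check: simulate,
  normalize, grid the ground-truth occupancy mask as if it were a perfect
  segmentation, stitch, extract components and centroids, and match against
  the planted centers.  Every center must be recovered essentially exactly;
  this validates the deterministic plumbing around the network.

* :func:`reduced_benchmark` — a small Swin U-Net (hidden 16, stage depths
  (2, 2, 2, 2), 32^3 windows) trained from scratch on a handful of simulated
  64^3 tomograms and evaluated on held-out simulations by pooled Hungarian
  matching at a 5-voxel cutoff.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .detection import MatchResult, extract_particles, hungarian_match, metrics_from_counts
from .features import FeatureConfig, FeatureStack, build_feature_stack
from .gridding import GridSpec, filter_nonzero, split_volume, stitch
from .io import Volume
from .network import ModelConfig, SwinUNet3D
from .preprocess import NormalizationParams, percentile_normalize
from .synthdata import ParticleClass, SimConfig, simulate
from .training import TrainConfig, load_checkpoint, train

__all__ = [
    "featurize",
    "training_windows",
    "oracle_roundtrip",
    "reduced_benchmark",
    "ReducedBenchmarkResult",
]


def featurize(density: Volume, norm: NormalizationParams | None = None,
              feat: FeatureConfig | None = None) -> FeatureStack:
    """Percentile-normalize a tomogram and build its 4-channel stack."""
    return build_feature_stack(percentile_normalize(density, norm), feat)


def training_windows(stack: FeatureStack, mask: Volume,
                     spec: GridSpec) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Paired, background-filtered (feature window, label window) arrays."""
    pairs = filter_nonzero(list(zip(split_volume(stack, spec), split_volume(mask, spec))))
    inputs = [inp.grid.astype(np.float32) for inp, _ in pairs]
    labels = [m.grid.astype(np.int64) for _, m in pairs]
    return inputs, labels


def oracle_roundtrip(seed: int = 0, shape=(64, 64, 64),
                     spec: GridSpec | None = None) -> tuple[MatchResult, object]:
    """Zero-noise pipeline identity check with the mask as oracle segmentation."""
    spec = spec or GridSpec(core=24, pad=4)
    cfg = SimConfig(shape=shape, noise_sigma=0.0, seed=seed)
    density, mask, truth = simulate(cfg)
    # noiseless density is mostly zero, so normalize against nonzero voxels
    featurize(density, NormalizationParams(nonzero_only=True))
    stitched = stitch(split_volume(mask, spec))
    assert np.array_equal(stitched.data, mask.data)
    pred = extract_particles(stitched, min_size=5, connectivity=18)
    return hungarian_match(pred, truth, d_max=5.0, per_class=True), truth


@dataclasses.dataclass
class ReducedBenchmarkResult:
    match: MatchResult
    per_volume: list[MatchResult]
    train_report: object
    n_train_windows: int
    conf_threshold: float
    min_size: int
    selected_epoch: int
    model: SwinUNet3D


def _default_sim(seed: int) -> SimConfig:
    return SimConfig(
        shape=(64, 64, 64),
        classes=(ParticleClass(1, 3.0, 1.0, 10), ParticleClass(2, 5.0, 1.0, 6)),
        noise_sigma=1.0,
        seed=seed,
    )


def _volume_posteriors(model, stack: FeatureStack, spec: GridSpec):
    """(bundle, per-voxel posterior) pairs for every window of a volume."""
    from .inference import posterior_window

    return [(b, posterior_window(model, b.grid)) for b in split_volume(stack, spec)]


def _detect(posts, conf_threshold: float, min_size: int) -> object:
    from .inference import InferConfig, labels_from_posteriors

    cfg = InferConfig(conf_threshold=conf_threshold)
    labelled = [
        dataclasses.replace(b, grid=labels_from_posteriors(p, cfg)) for b, p in posts
    ]
    return extract_particles(stitch(labelled), min_size=min_size, connectivity=18)


def reduced_benchmark(
    seed: int = 0,
    n_train: int = 6,
    n_val: int = 1,
    n_test: int = 2,
    epochs: int = 20,
    candidate_every: int = 4,
    learning_rate: float = 1e-3,
    conf_grid: tuple[float, ...] = (0.5, 0.8, 0.95),
    min_size_grid: tuple[int, ...] = (30, 60),
    log=None,
) -> ReducedBenchmarkResult:
    """Train the reduced model on simulations and score held-out volumes.

    The reduced preset keeps the full architecture (4 merge/expand stages,
    alternating regular/shifted window attention, additive skips) at widths
    small enough for a single CPU; windows are 32^3 (24-voxel cores with
    4-voxel context).  The three free post-training choices — which epoch's
    checkpoint to deploy, the confidence threshold, and the component size
    filter — are selected on a validation simulation (early-stopping-style:
    every ``candidate_every``-th checkpoint is scored on the validation
    volume over the tau/min-size grid, and the best combination wins).
    Test volumes are then scored untouched, pooled, by Hungarian matching
    at d_max = 5 voxels.
    """
    import tempfile

    rng = np.random.default_rng(seed)
    spec = GridSpec(core=24, pad=4)
    feat = FeatureConfig()

    train_inputs: list[np.ndarray] = []
    train_labels: list[np.ndarray] = []
    sims = [_default_sim(int(rng.integers(2**31))) for _ in range(n_train + n_val + n_test)]
    for sim in sims[:n_train]:
        density, mask, _ = simulate(sim)
        inputs, labels = training_windows(featurize(density, feat=feat), mask, spec)
        train_inputs.extend(inputs)
        train_labels.extend(labels)
    if log:
        log(f"training on {len(train_inputs)} windows from {n_train} volumes")

    model = SwinUNet3D(
        ModelConfig.reduced(num_classes=3), seed=int(rng.integers(2**31))
    )
    cfg = TrainConfig(
        epochs=epochs,
        batch_size=2,
        learning_rate=learning_rate,
        grad_clip_norm=1.0,
        seed=int(rng.integers(2**31)),
    )

    val_sims = sims[n_train : n_train + n_val]
    val_data = []
    for sim in val_sims:
        density, _, truth = simulate(sim)
        val_data.append((featurize(density, feat=feat), truth))

    with tempfile.TemporaryDirectory() as ckpt_dir:
        report = train(model, train_inputs, train_labels, cfg, out_dir=ckpt_dir, log=log)
        candidates = sorted(
            {e for e in range(candidate_every, epochs + 1, candidate_every)} | {epochs}
        )
        # lexicographic selection: validation F1, then the latest epoch
        # (no evidence of degradation among ties), then higher tau (trust
        # model confidence over size filtering: confident cores also
        # separate touching particles), then the smaller min_size
        best = None
        for epoch in candidates:
            cand_model, _, _, _ = load_checkpoint(
                Path(ckpt_dir) / f"checkpoint_epoch{epoch:03d}.npz"
            )
            val_posts = [
                (_volume_posteriors(cand_model, stack, spec), truth)
                for stack, truth in val_data
            ]
            for tau in conf_grid:
                for min_size in min_size_grid:
                    tp = fp = fn = 0
                    for posts, truth in val_posts:
                        m = hungarian_match(
                            _detect(posts, tau, min_size), truth, d_max=5.0
                        )
                        tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
                    f1 = metrics_from_counts(tp, fp, fn)[2]
                    key = (-1.0 if f1 is None else f1, epoch, tau, -min_size)
                    if best is None or key > best[0]:
                        best = (key, cand_model)
        (val_f1, sel_epoch, tau, neg_ms), model = best
        min_size = -neg_ms
    if log:
        log(f"selected epoch {sel_epoch}, tau={tau}, min_size={min_size} "
            f"(validation F1={val_f1:.3f})")

    per_volume: list[MatchResult] = []
    tp = fp = fn = 0
    distances: list[float] = []
    for sim in sims[n_train + n_val :]:
        density, _, truth = simulate(sim)
        posts = _volume_posteriors(model, featurize(density, feat=feat), spec)
        match = hungarian_match(_detect(posts, tau, min_size), truth, d_max=5.0)
        per_volume.append(match)
        tp, fp, fn = tp + match.tp, fp + match.fp, fn + match.fn
        distances.extend(d for _, _, d in match.matched_pairs)
        if log:
            log(f"held-out volume: TP={match.tp} FP={match.fp} FN={match.fn} "
                f"F1={match.f1 if match.f1 is None else round(match.f1, 3)}")
    precision, recall, f1, miss = metrics_from_counts(tp, fp, fn)
    pooled = MatchResult(
        tp, fp, fn, [], precision, recall, f1, miss,
        float(np.mean(distances)) if distances else None,
    )
    return ReducedBenchmarkResult(
        pooled, per_volume, report, len(train_inputs), tau, min_size, sel_epoch, model
    )
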
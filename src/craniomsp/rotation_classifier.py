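"""Rotation-angle classification: label codec, preprocessing and the 3D CNN.

Two independent 21-class classifiers — one for the coronal-plane angle, one
for the transverse-plane angle — predict which member of the
-5..5 deg (0.5-deg step) grid a skull volume was rotated by.  Preprocessing
resizes the volume in-plane with nearest-neighbor interpolation and keeps a
single quarter sub-cube (left-anterior, full z extent): for a bilaterally
symmetric skull the discarded quarters carry no extra information, and the
crop quarters the input voxel count.

The network is a fixed stack of 3D conv / batch-norm / ReLU blocks with
interleaved max pooling (kernel sizes 1, 5, 7, 5, 5, 1; filter counts 3, 8,
16, 32, 64, 128; poolings 5, 5, 3, 2 stride 2 plus a final average pool),
followed by fully connected layers of 25, 50 and ``n_labels`` units with
softmax output, trained with Adam.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import NamedTuple
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from . import _nn
from .phantom import AngleGrid, RotationDataset
from .volume_io import Volume

__all__ = [
    "AngleLabel",
    "ClassifierConfig",
    "angle_to_label",
    "label_to_angle",
    "preprocess",
    "MaterializedDataset",
    "materialize_dataset",
    "build_classifier",
    "train_classifier",
    "predict_plane_angle",
    "predict_angles",
    "TrainedRotationClassifier",
    "save_classifier",
    "load_classifier",
]

PLANES = ("coronal", "transverse")


@dataclass(frozen=True)
class AngleLabel:
    """One of the discrete rotation offsets of an anatomical plane."""

    plane: str
    index: int
    degrees: float

    def __post_init__(self) -> None:
        if self.plane not in PLANES:
            raise ValueError(f"plane must be one of {PLANES}, got {self.plane!r}")


@dataclass(frozen=True)
class ClassifierConfig:
    """Preprocessing + training configuration for one plane's classifier.

    ``input_side`` is the in-plane size after nearest-neighbor resizing
    (128 reproduces the original design; 32 is the desk-scale default);
    ``resize_z`` also resizes the z axis to ``input_side`` (otherwise z is
    kept native; native z must then equal ``input_side``).  The desk-scale
    ``batch_size`` of 24 keeps the optimizer step count comparable to the
    reference setup (mini-batch 128 on a ~40k-sample dataset); Adam with a
    cosine learning-rate decay drives training.
    """

    input_side: int = 32
    n_labels: int = 21
    batch_size: int = 24
    learning_rate: float = 3e-3
    optimizer_name: str = "adam"
    lr_schedule: str = "cosine"
    epochs: int = 20
    seed: int = 0
    resize_z: bool = True
    holdout_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.n_labels < 2:
            raise ValueError("n_labels must be >= 2")
        if self.input_side < 8:
            raise ValueError(
                "input_side must be >= 8 to survive the stride-2 pooling "
                "stack (quarter crop halves it twice more)"
            )
        if self.optimizer_name.lower() != "adam":
            raise ValueError("only the Adam optimizer is implemented")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError("lr_schedule must be 'cosine' or 'constant'")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")


def angle_to_label(
    degrees: float, grid: AngleGrid = AngleGrid(), plane: str = "coronal"
) -> AngleLabel:
    """Exact grid angle -> class index; off-grid angles are an error."""
    idx = (degrees - grid.min_deg) / grid.step_deg
    if not np.isfinite(idx) or abs(idx - round(idx)) > 1e-9:
        raise ValueError(f"{degrees} deg is not on the grid {grid}")
    i = int(round(idx))
    if not 0 <= i < len(grid):
        raise ValueError(f"{degrees} deg outside grid range {grid}")
    return AngleLabel(plane=plane, index=i, degrees=float(degrees))


def label_to_angle(index: int, grid: AngleGrid = AngleGrid()) -> float:
    if not 0 <= index < len(grid):
        raise ValueError(f"label index {index} outside [0, {len(grid) - 1}]")
    return float(grid.min_deg + grid.step_deg * index)


def _nn_resize_1d(n_in: int, n_out: int) -> np.ndarray:
    # voxel-center aligned nearest-neighbor source indices
    return np.minimum(
        ((np.arange(n_out) + 0.5) * n_in / n_out).astype(int), n_in - 1
    )


def preprocess(
    volume: Volume, config: ClassifierConfig = ClassifierConfig()
) -> Volume:
    """Nearest-neighbor resize, then crop the left-anterior quarter.

    The in-plane (x, y) grid is resized to ``input_side`` squared; z is
    resized to ``input_side`` when ``resize_z`` else kept native.  The kept
    quarter is x < mid, y >= mid with full z extent.  Nearest-neighbor
    interpolation preserves binarity.
    """
    nx, ny, nz = volume.shape
    if nx < 2 or ny < 2:
        raise ValueError(f"in-plane size {nx}x{ny} too small to quarter")
    side = config.input_side
    ix = _nn_resize_1d(nx, side)
    iy = _nn_resize_1d(ny, side)
    iz = _nn_resize_1d(nz, side) if config.resize_z else np.arange(nz)
    data = volume.data[np.ix_(ix, iy, iz)]
    half = side // 2
    quarter = data[:half, half:, :]
    sx = volume.spacing[0] * nx / side
    sy = volume.spacing[1] * ny / side
    sz = volume.spacing[2] * nz / side if config.resize_z else volume.spacing[2]
    return Volume(quarter, (sx, sy, sz), volume.origin)


def build_classifier(
    config: ClassifierConfig, rng: np.random.Generator | None = None
) -> _nn.Sequential:
    """The fixed conv/pool stack; deterministic given a seeded generator."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    blocks: list[_nn.Layer] = []

    def conv_block(cin, cout, k):
        blocks.extend([
            _nn.Conv3d(cin, cout, k, rng),
            _nn.BatchNorm(cout),
            _nn.ReLU(),
        ])

    conv_block(1, 3, 1)
    blocks.append(_nn.MaxPool3d(5, 2))
    conv_block(3, 8, 5)
    blocks.append(_nn.MaxPool3d(5, 2))
    conv_block(8, 16, 7)
    blocks.append(_nn.MaxPool3d(3, 2))
    conv_block(16, 32, 5)
    blocks.append(_nn.MaxPool3d(2, 2))
    conv_block(32, 64, 5)
    blocks.append(_nn.AvgPool3d(2, 2))
    conv_block(64, 128, 1)
    blocks.append(_nn.Flatten())

    # feature width after global collapse of the spatial axes
    shape = _feature_shape(config)
    fin = 128 * int(np.prod(shape))
    blocks.extend([
        _nn.Dense(fin, 25, rng), _nn.ReLU(),
        _nn.Dense(25, 50, rng), _nn.ReLU(),
        _nn.Dense(50, config.n_labels, rng),
    ])
    return _nn.Sequential(blocks)


def _feature_shape(config: ClassifierConfig) -> tuple[int, int, int]:
    # with resize_z=False the native z extent must equal input_side so the
    # fully connected width is known at build time (validated when training)
    half = config.input_side // 2
    dims = [half, half, config.input_side]
    for _ in range(5):  # five stride-2 'same' poolings: ceil(n / 2) each
        dims = [-(-n // 2) for n in dims]
    return tuple(dims)


@dataclass
class TrainedRotationClassifier:
    model: _nn.Sequential
    config: ClassifierConfig
    plane: str
    grid: AngleGrid
    accuracy_history: list[float]

    @property
    def holdout_accuracy(self) -> float:
        return self.accuracy_history[-1] if self.accuracy_history else float("nan")


class MaterializedDataset(NamedTuple):
    """Preprocessed sample tensor plus per-sample angle labels."""

    X: np.ndarray  # (N, 1, x, y, z)
    coronal_deg: np.ndarray
    transverse_deg: np.ndarray


def materialize_dataset(dataset, config: ClassifierConfig) -> MaterializedDataset:
    """Preprocess a rotation dataset once; reusable across both planes."""
    return MaterializedDataset(*_materialize(dataset, config))


def _materialize(dataset, config: ClassifierConfig):
    """Preprocess every sample into a compact (N, 1, x, y, z) array."""
    if isinstance(dataset, MaterializedDataset):
        return dataset
    samples = list(dataset) if not isinstance(dataset, RotationDataset) else dataset
    n = len(samples)
    first = preprocess(samples[0].volume, config)
    dtype = np.uint8 if first.data.dtype == np.uint8 else np.float32
    X = np.empty((n, 1) + first.shape, dtype=dtype)
    cor = np.empty(n)
    tra = np.empty(n)
    for i in range(n):
        s = samples[i]
        X[i, 0] = preprocess(s.volume, config).data
        cor[i], tra[i] = s.coronal_deg, s.transverse_deg
    return X, cor, tra


def _forward_batches(model, X, batch: int = 256) -> np.ndarray:
    outs = []
    for i in range(0, len(X), batch):
        outs.append(model.forward(X[i:i + batch].astype(np.float32), train=False))
    return np.concatenate(outs, axis=0)


def train_classifier(
    model: _nn.Sequential,
    dataset,
    plane: str,
    config: ClassifierConfig,
    grid: AngleGrid = AngleGrid(),
    verbose: bool = False,
):
    """Train one plane's classifier on rotation samples.

    The model sees the plane-specific label only (the coronal classifier
    trains on coronal angles and vice versa).  A stratified 90/10
    train/holdout split with a fixed seed makes runs reproducible; the
    returned history holds the held-out accuracy after each epoch.
    """
    if plane not in PLANES:
        raise ValueError(f"plane must be one of {PLANES}")
    X, cor, tra = _materialize(dataset, config)
    degs = cor if plane == "coronal" else tra
    labels = np.array([angle_to_label(d, grid, plane).index for d in degs])
    if len(np.unique(labels)) < 2:
        raise ValueError("dataset contains a single class; cannot train")
    idx_tr, idx_te = train_test_split(
        np.arange(len(X)),
        test_size=config.holdout_fraction,
        random_state=config.seed,
        stratify=labels,
    )
    rng = np.random.default_rng(config.seed + 1)
    opt = _nn.Adam(model.params(), lr=config.learning_rate)
    # BN population-statistics passes: a light subset tracks progress
    # between epochs; the final epoch gets the full-accuracy calibration
    calib_light = idx_tr[:1024]
    calib_full = idx_tr[:2048]
    steps_per_epoch = -(-len(idx_tr) // config.batch_size)
    n_steps = config.epochs * steps_per_epoch
    step = 0
    history: list[float] = []
    for epoch in range(config.epochs):
        perm = rng.permutation(idx_tr)
        for i in range(0, len(perm), config.batch_size):
            if config.lr_schedule == "cosine":
                opt.lr = config.learning_rate * 0.5 * (
                    1.0 + np.cos(np.pi * step / n_steps)
                )
            step += 1
            sel = perm[i:i + config.batch_size]
            logits = model.forward(X[sel].astype(np.float32), train=True)
            _, dlogits = _nn.softmax_cross_entropy(logits, labels[sel])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
        # small-batch training leaves BN running statistics noisy; replace
        # them with population statistics before evaluating
        calib = calib_full if epoch == config.epochs - 1 else calib_light
        _nn.recalibrate_batchnorm(
            model,
            (X[calib[i:i + 256]].astype(np.float32)
             for i in range(0, len(calib), 256)),
        )
        pred = _forward_batches(model, X[idx_te]).argmax(axis=1)
        acc = float((pred == labels[idx_te]).mean())
        history.append(acc)
        if verbose:
            print(f"[{plane}] epoch {epoch + 1}/{config.epochs} "
                  f"holdout accuracy {acc:.4f}", flush=True)
    return TrainedRotationClassifier(model, config, plane, grid, history)


def _decode(logits: np.ndarray, grid: AngleGrid) -> float:
    """Argmax with ties broken toward the smaller |angle|, then smaller index."""
    scores = logits.ravel()
    best = scores.max()
    cand = np.flatnonzero(scores == best)
    angles = grid.angles[cand]
    order = np.lexsort((cand, np.abs(angles)))
    return float(angles[order[0]])


def predict_plane_angle(
    trained: TrainedRotationClassifier, volume: Volume
) -> float:
    x = preprocess(volume, trained.config).data.astype(np.float32)
    logits = trained.model.forward(x[None, None], train=False)
    return _decode(logits, trained.grid)


def predict_angles(
    coronal: TrainedRotationClassifier,
    transverse: TrainedRotationClassifier,
    volume: Volume,
) -> tuple[float, float]:
    """(coronal_deg, transverse_deg) from the two plane-specific models."""
    if coronal.plane != "coronal" or transverse.plane != "transverse":
        raise ValueError("models must be (coronal, transverse) in that order")
    return (
        predict_plane_angle(coronal, volume),
        predict_plane_angle(transverse, volume),
    )


def _layer_state(model: _nn.Sequential) -> list[np.ndarray]:
    arrays: list[np.ndarray] = []
    for lay in model.layers:
        arrays.extend(p.val for p in lay.params())
        if isinstance(lay, _nn.BatchNorm):
            arrays.extend([lay.run_mean, lay.run_var])
    return arrays


def _load_layer_state(model: _nn.Sequential, arrays: list[np.ndarray]) -> None:
    it = iter(arrays)
    for lay in model.layers:
        for p in lay.params():
            p.val = np.asarray(next(it), dtype=np.float32)
        if isinstance(lay, _nn.BatchNorm):
            lay.run_mean = np.asarray(next(it), dtype=np.float32)
            lay.run_var = np.asarray(next(it), dtype=np.float32)


def save_classifier(trained: TrainedRotationClassifier, path) -> None:
    path = Path(path)
    meta = {
        "config": asdict(trained.config),
        "plane": trained.plane,
        "grid": [trained.grid.min_deg, trained.grid.max_deg, trained.grid.step_deg],
        "accuracy_history": trained.accuracy_history,
    }
    arrays = {f"arr_{i}": a for i, a in enumerate(_layer_state(trained.model))}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_classifier(path) -> TrainedRotationClassifier:
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        arrays = [z[f"arr_{i}"] for i in range(len(z.files) - 1)]
    config = ClassifierConfig(**meta["config"])
    model = build_classifier(config)
    _load_layer_state(model, arrays)
    return TrainedRotationClassifier(
        model, config, meta["plane"], AngleGrid(*meta["grid"]),
        list(meta["accuracy_history"]),
    )
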
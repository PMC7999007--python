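"""3D U-Net skull segmentation, trainable at desk scale.

Encoder-decoder with skip concatenations: each encoder level applies a
conv / batch-norm / ReLU block (cubic kernels, filter count doubling per
level from ``first_encoder_filters``) followed by 2x max pooling; the
decoder mirrors it with nearest-neighbor upsampling, concatenation of the
matching encoder features, and a conv block; a final 1-voxel convolution
yields voxelwise 2-class logits.  Training minimizes voxelwise softmax
cross-entropy with Adam on randomly sampled patches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import _nn
from .volume_io import Volume

__all__ = [
    "UNetConfig",
    "UNet3d",
    "build_unet",
    "train_segmenter",
    "segment",
    "TrainedSegmenter",
    "save_segmenter",
    "load_segmenter",
]


@dataclass(frozen=True)
class UNetConfig:
    """Architecture and training parameters of the skull segmenter.

    Defaults follow the reference parameterization (Adam, encoder depth 4,
    filter size 5, 6 first-encoder filters, 4 patches per image, initial
    learning rate 1e-2) except ``batch_size``, whose reference value of 128
    targets large-memory GPU training; the desk default of 2 patches per
    optimizer step fits CPU memory.  ``patch_size`` is clamped to the
    training volumes and rounded down to a multiple of 2**encoder_depth.
    """

    encoder_depth: int = 4
    filter_size: int = 5
    first_encoder_filters: int = 6
    patches_per_image: int = 4
    patch_size: int = 64
    batch_size: int = 2
    learning_rate: float = 1e-2
    optimizer_name: str = "adam"
    epochs: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("encoder_depth", "filter_size", "first_encoder_filters",
                     "patches_per_image", "patch_size", "batch_size", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.filter_size % 2 == 0:
            raise ValueError("filter_size must be odd ('same' padding)")
        if self.optimizer_name.lower() != "adam":
            raise ValueError("only the Adam optimizer is implemented")


def _conv_block(cin, cout, k, rng):
    return _nn.Sequential([
        _nn.Conv3d(cin, cout, k, rng),
        _nn.BatchNorm(cout),
        _nn.ReLU(),
    ])


class UNet3d(_nn.Layer):
    """U-shaped encoder-decoder; input spatial dims must be multiples of
    2**encoder_depth."""

    def __init__(self, config: UNetConfig, rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng(config.seed)
        self.config = config
        d, k, f = config.encoder_depth, config.filter_size, config.first_encoder_filters
        self.encoders = [_conv_block(1 if i == 0 else f * 2 ** (i - 1),
                                     f * 2**i, k, rng) for i in range(d)]
        self.pools = [_nn.MaxPool3d(2, 2) for _ in range(d)]
        self.bridge = _conv_block(f * 2 ** (d - 1), f * 2**d, k, rng)
        # decoders applied deepest-first
        self.ups = [_nn.Upsample3d(2) for _ in range(d)]
        self.decoders = [
            _conv_block(f * 2**i + f * 2 ** (i + 1), f * 2**i, k, rng)
            for i in reversed(range(d))
        ]
        self.head = _nn.Conv3d(f, 2, 1, rng)

    # -- Layer protocol -----------------------------------------------------
    def params(self):
        mods = self.encoders + [self.bridge] + self.decoders + [self.head]
        return [p for m in mods for p in m.params()]

    def _check_shape(self, shape) -> None:
        m = 2**self.config.encoder_depth
        if any(s % m != 0 or s < m for s in shape):
            raise ValueError(
                f"input spatial shape {tuple(shape)} must have every "
                f"dimension a positive multiple of 2**encoder_depth = {m} "
                f"(minimum valid size {m} per axis)"
            )

    def forward(self, x, train=False):
        self._check_shape(x.shape[2:])
        skips = []
        for enc, pool in zip(self.encoders, self.pools):
            x = enc.forward(x, train=train)
            skips.append(x)
            x = pool.forward(x, train=train)
        x = self.bridge.forward(x, train=train)
        for up, dec, skip in zip(self.ups, self.decoders, reversed(skips)):
            x = up.forward(x, train=train)
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x, train=train)
        if train:
            self._skip_channels = [s.shape[1] for s in skips]
        return self.head.forward(x, train=train)

    def backward(self, dout):
        d = self.head.backward(dout)
        dskips = [None] * len(self.encoders)
        # decoders were applied deepest (level D-1) first
        levels = list(reversed(range(len(self.encoders))))
        for up, dec, lvl in zip(reversed(self.ups), reversed(self.decoders),
                                reversed(levels)):
            dcat = dec.backward(d)
            ch = self._skip_channels[lvl]
            dskips[lvl] = dcat[:, :ch]
            d = up.backward(dcat[:, ch:])
        d = self.bridge.backward(d)
        for lvl in reversed(range(len(self.encoders))):
            d = self.pools[lvl].backward(d)
            d = d + dskips[lvl]
            d = self.encoders[lvl].backward(d)
        return d

    def flat_layers(self):
        mods = self.encoders + [self.bridge] + self.decoders
        out = [lay for m in mods for lay in m.layers]
        out.append(self.head)
        return out

    def n_params(self) -> int:
        return sum(p.val.size for p in self.params())


def build_unet(config: UNetConfig, input_shape=None) -> UNet3d:
    """Construct the U-Net; optionally validate an intended input shape."""
    net = UNet3d(config)
    if input_shape is not None:
        net._check_shape(input_shape)
    return net


@dataclass
class TrainedSegmenter:
    model: UNet3d
    config: UNetConfig
    loss_history: list[float]


def _patch_side(config: UNetConfig, shape) -> int:
    m = 2**config.encoder_depth
    side = min(config.patch_size, min(shape))
    side -= side % m
    if side < m:
        raise ValueError(
            f"volumes of shape {tuple(shape)} are too small for encoder "
            f"depth {config.encoder_depth} (need >= {m} per axis)"
        )
    return side


def train_segmenter(
    model: UNet3d,
    pairs: list[tuple[Volume, Volume]],
    config: UNetConfig,
    verbose: bool = False,
) -> TrainedSegmenter:
    """Train on (graylevel, mask) volume pairs; returns per-epoch mean loss.

    Each epoch draws ``patches_per_image`` random patches per volume and
    steps Adam on mini-batches of ``batch_size`` patches.  Deterministic
    given ``config.seed``.
    """
    if len(pairs) == 0:
        raise ValueError("empty training set")
    for g, m in pairs:
        if g.shape != m.shape:
            raise ValueError("gray/mask shape mismatch in training pair")
        if not m.is_mask():
            raise ValueError("training targets must be binary masks")
    rng = np.random.default_rng(config.seed)
    opt = _nn.Adam(model.params(), lr=config.learning_rate)
    side = _patch_side(config, np.min([g.shape for g, _ in pairs], axis=0))
    history: list[float] = []
    for epoch in range(config.epochs):
        xs, ys = [], []
        for g, m in pairs:
            for _ in range(config.patches_per_image):
                corner = [rng.integers(0, s - side + 1) for s in g.shape]
                sl = tuple(slice(c, c + side) for c in corner)
                xs.append(g.data[sl])
                ys.append(m.data[sl])
        order = rng.permutation(len(xs))
        losses = []
        for i in range(0, len(order), config.batch_size):
            sel = order[i:i + config.batch_size]
            xb = np.stack([xs[j] for j in sel]).astype(np.float32)[:, None]
            yb = np.stack([ys[j] for j in sel]).astype(np.int64)
            logits = model.forward(xb, train=True)
            flat = logits.transpose(0, 2, 3, 4, 1).reshape(-1, 2)
            loss, dflat = _nn.softmax_cross_entropy(flat, yb.ravel())
            dlogits = dflat.reshape(
                logits.shape[0], *logits.shape[2:], 2
            ).transpose(0, 4, 1, 2, 3)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
        if verbose:
            print(f"[unet] epoch {epoch + 1}/{config.epochs} "
                  f"loss {history[-1]:.4f}")
    return TrainedSegmenter(model, config, history)


def segment(trained: TrainedSegmenter, volume: Volume) -> Volume:
    """Voxelwise argmax segmentation; same grid and spacing as the input.

    Inputs whose dimensions are not multiples of 2**encoder_depth are
    zero-padded for the forward pass and cropped back.
    """
    m = 2**trained.config.encoder_depth
    shape = np.asarray(volume.shape)
    padded = (np.ceil(shape / m).astype(int) * m)
    pad = [(0, int(p - s)) for p, s in zip(padded, shape)]
    x = np.pad(volume.data.astype(np.float32), pad)[None, None]
    logits = trained.model.forward(x, train=False)
    mask = logits[0].argmax(axis=0).astype(np.uint8)
    sl = tuple(slice(0, int(s)) for s in shape)
    return volume.copy_with(mask[sl])


def save_segmenter(trained: TrainedSegmenter, path) -> None:
    arrays = []
    for lay in trained.model.flat_layers():
        arrays.extend(p.val for p in lay.params())
        if isinstance(lay, _nn.BatchNorm):
            arrays.extend([lay.run_mean, lay.run_var])
    meta = {"config": asdict(trained.config),
            "loss_history": trained.loss_history}
    np.savez(Path(path), meta=json.dumps(meta),
             **{f"arr_{i}": a for i, a in enumerate(arrays)})


def load_segmenter(path) -> TrainedSegmenter:
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        arrays = [z[f"arr_{i}"] for i in range(len(z.files) - 1)]
    config = UNetConfig(**meta["config"])
    model = UNet3d(config)
    it = iter(arrays)
    for lay in model.flat_layers():
        for p in lay.params():
            p.val = np.asarray(next(it), dtype=np.float32)
        if isinstance(lay, _nn.BatchNorm):
            lay.run_mean = np.asarray(next(it), dtype=np.float32)
            lay.run_var = np.asarray(next(it), dtype=np.float32)
    return TrainedSegmenter(model, config, list(meta["loss_history"]))
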
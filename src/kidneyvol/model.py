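"""2.5D encoder--decoder segmentation network, training loop and inference.

The architecture is a U-Net-style encoder--decoder over three-slice (2.5D)
inputs: an encoder of residual convolution blocks (VGG-like channel widths,
2x max-pooling after every stage), a bottleneck block, and a mirrored decoder
with nearest-neighbour upsampling and long skip concatenations from each
encoder stage. Short ResNet-style additive skips sit inside every block. The
head is a 1x1 convolution to two classes (background, kidney); class scores
become labels by argmax and the softmax foreground probability is retained
for station fusion.

The full-scale widths mirror an 11-layer VGG encoder (64, 128, 256, 512, 512
with five 2x downsamplings -> factor 32); ``width_multiplier`` scales all
widths down for CPU-scale runs. Training follows an iteration-based loop:
batch size one, pixel-wise cross-entropy, Adam, a step learning-rate schedule
(constant, then dropped once by a fixed factor), and online elastic
augmentation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .image import LabelVolume, VolumeImage
from .preprocess import SliceStack, build_stack, elastic_augment, normalize_station, unpad

__all__ = [
    "NetworkSpec",
    "TrainingConfig",
    "UNet2p5D",
    "build_network",
    "train",
    "predict_station",
    "save_checkpoint",
    "load_checkpoint",
    "load_encoder_weights",
]

FULL_SCALE_WIDTHS = (64, 128, 256, 512, 512)


@dataclass
class NetworkSpec:
    """Architecture hyper-parameters.

    ``downsampling_factor`` is derived: 2 ** number of pooling stages, one
    pool per encoder stage. Output spatial dims always equal input dims.
    """

    encoder_widths: tuple[int, ...] = FULL_SCALE_WIDTHS
    width_multiplier: float = 1.0
    in_channels: int = 3
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.encoder_widths) < 2:
            raise ValueError("need at least 2 encoder stages")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")

    @property
    def widths(self) -> tuple[int, ...]:
        return tuple(max(2, int(round(w * self.width_multiplier))) for w in self.encoder_widths)

    @property
    def downsampling_factor(self) -> int:
        return 2 ** len(self.encoder_widths)


@dataclass
class TrainingConfig:
    """Iteration-based training settings (defaults: full-scale protocol)."""

    iterations: int = 80_000
    lr: float = 1e-4
    lr_drop_iteration: int = 60_000
    lr_drop_factor: float = 10.0
    batch_size: int = 1
    seed: int = 0
    drop_ends: int = 2
    augment: dict | None = field(
        default_factory=lambda: {"amplitude_px": 10.0, "grid_points": 4, "smooth_sigma": 4.0}
    )
    checkpoint_every: int = 0  # 0 = only at the end

    def __post_init__(self) -> None:
        if not self.lr_drop_iteration < self.iterations:
            raise ValueError("lr_drop_iteration must be < iterations")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def lr_at(self, iteration: int) -> float:
        """Step schedule: lr until the drop iteration, then lr/drop_factor."""
        return self.lr if iteration < self.lr_drop_iteration else self.lr / self.lr_drop_factor

    @classmethod
    def desk_scale(cls, **overrides) -> "TrainingConfig":
        """Shortened CPU protocol: 2k iterations, proportionally hotter lr.

        The elastic-deformation amplitude is scaled to the coarse desk-scale
        voxels (3 px at ~4.5 mm/px keeps warps anatomically plausible).
        """
        base = dict(
            iterations=2000,
            lr=3e-4,
            lr_drop_iteration=1500,
            augment={"amplitude_px": 3.0, "grid_points": 4, "smooth_sigma": 4.0},
        )
        base.update(overrides)
        return cls(**base)


class UNet2p5D:
    """The assembled network; forward/backward walk an explicit layer graph."""

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        w = spec.widths
        self.enc_blocks = []
        cin = spec.in_channels
        for width in w:
            self.enc_blocks.append(nn.ResBlock(cin, width, rng))
            cin = width
        self.pools = [nn.MaxPool2() for _ in w]
        self.bottleneck = nn.ResBlock(w[-1], w[-1], rng)
        self.ups = [nn.Upsample2() for _ in w]
        self.dec_blocks = []
        cin = w[-1]
        for width in reversed(w):
            self.dec_blocks.append(nn.ResBlock(cin + width, width, rng))
            cin = width
        self.head = nn.Conv2d(w[0], spec.n_classes, k=1, rng=rng)
        self.trained = False

    # -- parameter plumbing ------------------------------------------------
    def _layers(self):
        out = []
        for block in [*self.enc_blocks, self.bottleneck, *self.dec_blocks]:
            out.extend(block.children)
        out.append(self.head)
        return out

    def param_slots(self):
        return [(layer, name) for layer in self._layers() for name in layer.params]

    def n_parameters(self) -> int:
        return sum(layer.params[n].size for layer, n in self.param_slots())

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        f = self.spec.downsampling_factor
        H, W = x.shape[:2]
        if H % f or W % f:
            raise ValueError(f"input dims {H}x{W} not divisible by downsampling factor {f}")
        skips = []
        h = x.astype(np.float32)
        for block, pool in zip(self.enc_blocks, self.pools):
            h = block.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        self._skip_channels = [s.shape[-1] for s in skips]
        for up, block, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            h = up.forward(h)
            h = np.concatenate([h, skip], axis=-1)
            h = block.forward(h)
        return self.head.forward(h)

    def backward(self, dout: np.ndarray) -> None:
        d = self.head.backward(dout)
        dskips = []
        for up, block, ch in zip(
            reversed(self.ups), reversed(self.dec_blocks), self._skip_channels
        ):
            d = block.backward(d)
            d, dskip = d[..., : d.shape[-1] - ch], d[..., d.shape[-1] - ch :]
            dskips.append(dskip)
            d = up.backward(d)
        d = self.bottleneck.backward(d)
        # dskips were collected shallow-first; encoder unwinds deepest-first
        for block, pool, dskip in zip(
            reversed(self.enc_blocks), reversed(self.pools), reversed(dskips)
        ):
            d = pool.backward(d)
            d = block.backward(d + dskip)

    def predict_slice(self, stack: SliceStack) -> np.ndarray:
        """Foreground probability map for one padded stack (padding kept)."""
        logits = self.forward(stack.pixels)
        return nn.softmax(logits)[..., 1]


def build_network(spec: NetworkSpec) -> UNet2p5D:
    """Instantiate the network for a spec; weights are He-initialized."""
    return UNet2p5D(spec)


def train(model: UNet2p5D, training_set, cfg: TrainingConfig):
    """Train on a list of ``(SliceStack, label2d)`` samples.

    Samples are drawn uniformly with replacement, each optionally warped by a
    fresh elastic deformation; the loss trace and learning-rate trace are
    returned alongside the model. Deterministic for a fixed seed.
    """
    samples = list(training_set)
    if not samples:
        raise ValueError("empty training set")
    for _, label in samples:
        if not np.isin(np.unique(label), (0, 1)).all():
            raise ValueError("labels must be binary")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.param_slots(), lr=cfg.lr)
    loss_trace, lr_trace = [], []
    for it in range(cfg.iterations):
        opt.lr = cfg.lr_at(it)
        stack, label = samples[int(rng.integers(len(samples)))]
        if cfg.augment:
            stack, label = elastic_augment(stack, label, cfg.augment, rng)
        logits = model.forward(stack.pixels)
        loss, dlogits = nn.softmax_cross_entropy(logits, label.astype(np.int64))
        model.backward(dlogits)
        opt.step()
        loss_trace.append(loss)
        lr_trace.append(opt.lr)
    model.trained = True
    return model, {"loss": np.asarray(loss_trace), "lr": np.asarray(lr_trace)}


def predict_station(model: UNet2p5D, station: VolumeImage, clip_fraction: float = 0.01):
    """Segment every slice of a station and restack to a label volume.

    Returns ``(labels, probabilities)`` as :class:`LabelVolume` objects
    aligned voxel-for-voxel with the input station. The station is
    normalized, each slice stacked with its periodic neighbours, padded to
    the network's downsampling multiple, forwarded, softmaxed, unpadded and
    argmaxed.
    """
    if not getattr(model, "trained", False):
        raise RuntimeError("model has not been trained or loaded from a checkpoint")
    norm = normalize_station(station, clip_fraction)
    S = norm.data.shape[2]
    f = model.spec.downsampling_factor
    prob = np.empty(norm.data.shape, dtype=np.float32)
    for i in range(S):
        stack = build_stack(norm, i, pad_multiple=f)
        p = model.predict_slice(stack)
        prob[:, :, i] = unpad(p, stack.pad_spec)
    labels = (prob >= 0.5).astype(np.uint8)
    return (
        LabelVolume(labels, station.spacing_mm, station.origin_mm),
        LabelVolume(prob, station.spacing_mm, station.origin_mm),
    )


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(model: UNet2p5D, path: str | Path) -> None:
    arrays = {}
    for i, layer in enumerate(model._layers()):
        for name, value in layer.params.items():
            arrays[f"{i}.{name}"] = value
    spec = asdict(model.spec)
    spec["encoder_widths"] = list(spec["encoder_widths"])
    np.savez(path, __spec__=np.frombuffer(json.dumps(spec).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> UNet2p5D:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such checkpoint: {path}")
    with np.load(path) as data:
        spec_dict = json.loads(bytes(data["__spec__"]).decode())
        spec_dict["encoder_widths"] = tuple(spec_dict["encoder_widths"])
        model = UNet2p5D(NetworkSpec(**spec_dict))
        for i, layer in enumerate(model._layers()):
            for name in layer.params:
                stored = data[f"{i}.{name}"]
                if stored.shape != layer.params[name].shape:
                    raise ValueError(
                        f"checkpoint shape mismatch at layer {i} param {name}: "
                        f"{stored.shape} vs {layer.params[name].shape}"
                    )
                layer.params[name] = stored.copy()
    model.trained = True
    return model


def load_encoder_weights(model: UNet2p5D, path: str | Path) -> UNet2p5D:
    """Initialize only the encoder blocks from a checkpoint file.

    The decoder and head keep their current weights. A hook for externally
    pre-trained encoders; shape mismatches are errors.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such weight file: {path}")
    donor = load_checkpoint(path)
    if len(donor.enc_blocks) != len(model.enc_blocks):
        raise ValueError("encoder depth mismatch")
    for ours, theirs in zip(model.enc_blocks, donor.enc_blocks):
        for a, b in zip(ours.children, theirs.children):
            for name in a.params:
                if a.params[name].shape != b.params[name].shape:
                    raise ValueError(
                        f"encoder shape mismatch: {a.params[name].shape} vs {b.params[name].shape}"
                    )
                a.params[name] = b.params[name].copy()
    return model
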
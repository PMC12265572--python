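"""A small configurable 3D encoder--decoder regression network.

The network is deliberately modest: its job is to exercise the training
objective end-to-end at desk scale, standing in for the larger U-net-style
label-free models used in production virtual staining.  Architecture:
``depth`` encoder levels (two 3x3x3 convolutions + ReLU, 2x average pooling),
a bottleneck block, and a mirrored decoder (2x nearest-neighbour upsampling,
channel-reducing convolution, additive skip connection, one convolution +
ReLU), closed by a linear 1x1x1 output convolution.  Channel width doubles
per level from ``base_channels``.

Every spatial dimension of a processed patch must be divisible by
``2 ** depth``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ._autodiff import Tensor, avg_pool3d, conv3d, upsample_nearest3d
from .errors import ValidationError

__all__ = ["BackboneConfig", "Backbone", "build_backbone", "predict_volume",
           "save_checkpoint", "load_checkpoint"]

CHECKPOINT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class BackboneConfig:
    depth: int = 2
    base_channels: int = 8
    input_channels: int = 1
    output_channels: int = 1

    def __post_init__(self):
        if self.depth < 1 or self.base_channels < 1:
            raise ValidationError("depth and base_channels must be positive")
        if self.input_channels < 1 or self.output_channels < 1:
            raise ValidationError("channel counts must be positive")

    @property
    def min_input_size(self) -> int:
        """Smallest admissible spatial extent (divisibility by 2**depth)."""
        return 2**self.depth


def _he_conv(rng: np.random.Generator, c_out: int, c_in: int, k: int) -> Tensor:
    fan_in = c_in * k**3
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k, k))
    return Tensor(w, requires_grad=True)


class Backbone:
    """Shape-preserving Volume3D -> Volume3D regression network."""

    def __init__(self, config: BackboneConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        ch = [config.base_channels * 2**i for i in range(config.depth + 1)]
        self._names: list[str] = []
        self._params: dict[str, Tensor] = {}

        def add(name: str, t: Tensor) -> None:
            self._names.append(name)
            self._params[name] = t

        c_prev = config.input_channels
        for i in range(config.depth):
            add(f"enc{i}_w1", _he_conv(rng, ch[i], c_prev, 3))
            add(f"enc{i}_b1", Tensor(np.zeros(ch[i]), requires_grad=True))
            add(f"enc{i}_w2", _he_conv(rng, ch[i], ch[i], 3))
            add(f"enc{i}_b2", Tensor(np.zeros(ch[i]), requires_grad=True))
            c_prev = ch[i]
        add("bott_w1", _he_conv(rng, ch[-1], c_prev, 3))
        add("bott_b1", Tensor(np.zeros(ch[-1]), requires_grad=True))
        add("bott_w2", _he_conv(rng, ch[-1], ch[-1], 3))
        add("bott_b2", Tensor(np.zeros(ch[-1]), requires_grad=True))
        for i in reversed(range(config.depth)):
            add(f"dec{i}_wr", _he_conv(rng, ch[i], ch[i + 1], 3))
            add(f"dec{i}_br", Tensor(np.zeros(ch[i]), requires_grad=True))
            add(f"dec{i}_w", _he_conv(rng, ch[i], ch[i], 3))
            add(f"dec{i}_b", Tensor(np.zeros(ch[i]), requires_grad=True))
        add("out_w", _he_conv(rng, config.output_channels, ch[0], 1))
        add("out_b", Tensor(np.zeros(config.output_channels), requires_grad=True))

    # -- parameter plumbing ----------------------------------------------

    def parameters(self) -> list[Tensor]:
        return [self._params[n] for n in self._names]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: self._params[n].data.copy() for n in self._names}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for n in self._names:
            if n not in state:
                raise ValidationError(f"checkpoint missing parameter {n!r}")
            if state[n].shape != self._params[n].data.shape:
                raise ValidationError(f"checkpoint parameter {n!r} has wrong shape")
            self._params[n].data = np.asarray(state[n], dtype=np.float64).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- forward ----------------------------------------------------------

    def _check_shape(self, shape) -> None:
        div = 2**self.config.depth
        if any(s % div != 0 for s in shape):
            raise ValidationError(
                f"patch spatial dims {tuple(shape)} must each be divisible by "
                f"2**depth = {div}"
            )

    def forward(self, x: Tensor) -> Tensor:
        """x: (N, C_in, Z, Y, X) Tensor; returns (N, C_out, Z, Y, X)."""
        if x.ndim != 5:
            raise ValidationError(f"expected 5D (N, C, Z, Y, X) input, got ndim={x.ndim}")
        self._check_shape(x.shape[2:])
        P = self._params
        skips = []
        h = x
        for i in range(self.config.depth):
            h = conv3d(h, P[f"enc{i}_w1"], P[f"enc{i}_b1"]).relu()
            h = conv3d(h, P[f"enc{i}_w2"], P[f"enc{i}_b2"]).relu()
            skips.append(h)
            h = avg_pool3d(h)
        h = conv3d(h, P["bott_w1"], P["bott_b1"]).relu()
        h = conv3d(h, P["bott_w2"], P["bott_b2"]).relu()
        for i in reversed(range(self.config.depth)):
            h = upsample_nearest3d(h)
            h = conv3d(h, P[f"dec{i}_wr"], P[f"dec{i}_br"]).relu()
            h = h + skips[i]
            h = conv3d(h, P[f"dec{i}_w"], P[f"dec{i}_b"]).relu()
        return conv3d(h, P["out_w"], P["out_b"])

    def predict_patch(self, patch: np.ndarray) -> np.ndarray:
        """Forward a single (Z, Y, X) patch without building a gradient tape."""
        x = Tensor(np.asarray(patch, dtype=np.float64)[None, None])
        return self.forward(x).data[0, 0]


def build_backbone(config: BackboneConfig | None = None, seed: int = 0) -> Backbone:
    """Construct a backbone; identical seeds yield identical initial weights."""
    return Backbone(config or BackboneConfig(), seed=seed)


# -- tiled inference -------------------------------------------------------


def _tile_starts(extent: int, patch: int, stride: int) -> list[int]:
    if extent <= patch:
        return [0]
    starts = list(range(0, extent - patch + 1, stride))
    if starts[-1] != extent - patch:
        starts.append(extent - patch)
    return starts


def predict_volume(
    model: Backbone,
    volume: np.ndarray,
    patch_size: int = 32,
    overlap: int = 8,
    clip_range: tuple[float, float] | None = (0.0, 1.0),
) -> np.ndarray:
    """Full-volume prediction assembled from overlapping tiles.

    Tiles are blended with a separable tapered (Hann-based, floored) weight
    window and the accumulated weights normalized away, so single-tile
    regions reproduce the direct forward pass exactly and overlaps blend
    linearly.  Volumes smaller than a tile are reflect-padded up to one tile.

    The network output is linear; because predictions are normalized
    fluorescence intensities, the assembled volume is clamped to
    ``clip_range`` (default the valid intensity range [0, 1]; pass None to
    disable).
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ValidationError(f"expected a 3D volume, got ndim={volume.ndim}")
    if overlap >= patch_size:
        raise ValidationError(f"overlap ({overlap}) must be < patch_size ({patch_size})")
    div = 2**model.config.depth
    if patch_size % div:
        raise ValidationError(f"patch_size {patch_size} must be divisible by 2**depth = {div}")

    orig_shape = volume.shape
    pad = [(0, max(patch_size - s, 0)) for s in orig_shape]
    if any(p[1] for p in pad):
        volume = np.pad(volume, pad, mode="reflect")

    stride = patch_size - overlap
    w1 = np.hanning(patch_size)
    w1 = np.maximum(w1, 1e-3)
    weight = w1[:, None, None] * w1[None, :, None] * w1[None, None, :]

    out = np.zeros_like(volume)
    acc = np.zeros_like(volume)
    for z0 in _tile_starts(volume.shape[0], patch_size, stride):
        for y0 in _tile_starts(volume.shape[1], patch_size, stride):
            for x0 in _tile_starts(volume.shape[2], patch_size, stride):
                sl = (
                    slice(z0, z0 + patch_size),
                    slice(y0, y0 + patch_size),
                    slice(x0, x0 + patch_size),
                )
                pred = model.predict_patch(volume[sl])
                out[sl] += pred * weight
                acc[sl] += weight
    out /= acc
    out = out[tuple(slice(0, s) for s in orig_shape)]
    if clip_range is not None:
        out = np.clip(out, clip_range[0], clip_range[1])
    return out


# -- checkpointing ---------------------------------------------------------


def save_checkpoint(
    path,
    model: Backbone,
    normalization: dict | None = None,
    extra: dict | None = None,
) -> None:
    """Single-file checkpoint: weights + config + normalization parameters."""
    meta = {
        "schema_version": CHECKPOINT_SCHEMA_VERSION,
        "config": asdict(model.config),
        "normalization": normalization or {},
        "extra": extra or {},
    }
    np.savez(path, __meta__=np.array(json.dumps(meta)), **model.state_dict())


def load_checkpoint(path) -> tuple[Backbone, dict]:
    """Load a checkpoint; returns the model and its metadata dict."""
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        if meta.get("schema_version") != CHECKPOINT_SCHEMA_VERSION:
            raise ValidationError(
                f"unsupported checkpoint schema {meta.get('schema_version')}"
            )
        state = {k: npz[k] for k in npz.files if k != "__meta__"}
    model = Backbone(BackboneConfig(**meta["config"]))
    model.load_state_dict(state)
    return model, meta
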
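"""Encoder and head architectures.

The feature extractor is a 1-D residual network in the pre-activation (V2)
style: a strided stem convolution, residual stages with channel doubling and
stride-2 downsampling, global average pooling, and a final linear map to a
fixed ``feature_dim`` embedding per 10-s window. ``depth=18`` counts the
weighted layers (stem + 16 stage convolutions + final linear); the ``tiny``
preset (depth 8, feature_dim 64) trains end-to-end on a CPU in well under
two minutes on fixture-sized corpora and is the default for tests.

On top of the embedding sit three interchangeable heads — three stacked
fully-connected layers with or without ReLU between them, or a small 1-D
U-Net run along the feature axis — plus a 2-logit linear classifier used for
the downstream gait / non-gait decision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from ._nn import (BatchNorm1d, Conv1d, Linear, Module, ReLU, Sequential,
                  Tensor, Upsample1d, concat, no_grad, param_checksum, relu)
from .preprocess import WINDOW_SAMPLES, Window

# (channels per stage, blocks per stage, stride per stage)
_ARCH = {
    18: ((32, 64, 128, 256), (2, 2, 2, 2), (1, 2, 2, 2)),
    8: ((8, 16, 32), (1, 1, 1), (1, 2, 2)),
}


@dataclass
class EncoderConfig:
    depth: int = 18
    in_channels: int = 3
    feature_dim: int = 1024
    frozen: bool = False

    def __post_init__(self):
        if self.depth not in _ARCH:
            raise ValueError(f"depth must be one of {sorted(_ARCH)}")
        if self.feature_dim <= 0:
            raise ValueError("feature_dim must be positive")

    @classmethod
    def tiny(cls, feature_dim: int = 64, frozen: bool = False) -> "EncoderConfig":
        return cls(depth=8, feature_dim=feature_dim, frozen=frozen)


@dataclass
class HeadConfig:
    variant: Literal["fc_linear", "fc_relu", "unet"] = "fc_relu"
    hidden_dims: Sequence[int] = (512, 256, 128)
    out_dim: int = 128

    def __post_init__(self):
        self.hidden_dims = tuple(self.hidden_dims)
        if self.variant in ("fc_linear", "fc_relu"):
            if len(self.hidden_dims) != 3:
                raise ValueError("fc heads have exactly three fully-connected layers")
            if self.hidden_dims[-1] != self.out_dim:
                raise ValueError("last hidden dim must equal out_dim")

    @classmethod
    def tiny(cls, variant: str = "fc_relu", out_dim: int = 32) -> "HeadConfig":
        return cls(variant=variant, hidden_dims=(64, 48, out_dim), out_dim=out_dim)


class _ResBlockV2(Module):
    def __init__(self, in_ch: int, out_ch: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.bn1 = BatchNorm1d(in_ch)
        self.conv1 = Conv1d(in_ch, out_ch, 3, rng, stride=stride, padding=1)
        self.bn2 = BatchNorm1d(out_ch)
        self.conv2 = Conv1d(out_ch, out_ch, 3, rng, stride=1, padding=1)
        self.proj = (Conv1d(in_ch, out_ch, 1, rng, stride=stride, padding=0)
                     if stride != 1 or in_ch != out_ch else None)

    def forward(self, x: Tensor) -> Tensor:
        h = relu(self.bn1(x))
        y = self.conv2(relu(self.bn2(self.conv1(h))))
        skip = self.proj(h) if self.proj is not None else x
        return y + skip


class Encoder(Module):
    """Windows (N, 3, 300) -> embeddings (N, feature_dim)."""

    def __init__(self, config: EncoderConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        channels, blocks, strides = _ARCH[config.depth]
        self.stem = Conv1d(config.in_channels, channels[0], 5, rng,
                           stride=2, padding=2)
        stages: list[Module] = []
        in_ch = channels[0]
        for ch, n_blocks, stride in zip(channels, blocks, strides):
            for b in range(n_blocks):
                stages.append(_ResBlockV2(in_ch, ch, stride if b == 0 else 1, rng))
                in_ch = ch
        self.stages = Sequential(*stages)
        self.final_bn = BatchNorm1d(in_ch)
        self.fc = Linear(in_ch, config.feature_dim, rng)
        if config.frozen:
            self.freeze()

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 3 or x.shape[1:] != (self.config.in_channels, WINDOW_SAMPLES):
            raise ValueError(
                f"expected (N, {self.config.in_channels}, {WINDOW_SAMPLES}) input")
        h = self.stages(self.stem(x))
        h = relu(self.final_bn(h))
        return self.fc(h.mean(axis=2))


class _FcHead(Module):
    def __init__(self, in_dim: int, config: HeadConfig, rng: np.random.Generator):
        super().__init__()
        self.nonlinear = config.variant == "fc_relu"
        dims = [in_dim, *config.hidden_dims]
        self.fc1 = Linear(dims[0], dims[1], rng)
        self.fc2 = Linear(dims[1], dims[2], rng)
        self.fc3 = Linear(dims[2], dims[3], rng)

    def forward(self, z: Tensor) -> Tensor:
        h = self.fc1(z)
        if self.nonlinear:
            h = relu(h)
        h = self.fc2(h)
        if self.nonlinear:
            h = relu(h)
        return self.fc3(h)


class _UnetHead(Module):
    """1-D encoder-decoder with a skip connection, run along the feature axis.

    The embedding is treated as a single-channel sequence, downsampled twice,
    upsampled back with a skip concatenation, globally pooled and projected
    to ``out_dim``.
    """

    def __init__(self, in_dim: int, config: HeadConfig, rng: np.random.Generator):
        super().__init__()
        if in_dim % 4 != 0:
            raise ValueError("unet head needs feature_dim divisible by 4")
        self.in_dim = in_dim
        self.down1 = Conv1d(1, 4, 3, rng, stride=2, padding=1)
        self.down2 = Conv1d(4, 8, 3, rng, stride=2, padding=1)
        self.up1 = Upsample1d(2)
        self.upconv1 = Conv1d(8, 4, 3, rng, stride=1, padding=1)
        self.up2 = Upsample1d(2)
        self.upconv2 = Conv1d(8, 4, 3, rng, stride=1, padding=1)  # 4 + 4 skip
        self.out = Linear(4, config.out_dim, rng)

    def forward(self, z: Tensor) -> Tensor:
        x = z.reshape(z.shape[0], 1, self.in_dim)
        d1 = relu(self.down1(x))                 # (N, 4, D/2)
        d2 = relu(self.down2(d1))                # (N, 8, D/4)
        u1 = relu(self.upconv1(self.up1(d2)))    # (N, 4, D/2)
        u2 = relu(self.upconv2(concat([u1, d1], axis=1)))
        return self.out(u2.mean(axis=2))


def build_head(config: HeadConfig, in_dim: int, seed: int = 0) -> Module:
    rng = np.random.default_rng(seed)
    if config.variant in ("fc_linear", "fc_relu"):
        return _FcHead(in_dim, config, rng)
    if config.variant == "unet":
        return _UnetHead(in_dim, config, rng)
    raise ValueError(f"unknown head variant {config.variant!r}")


class GaitClassifier(Module):
    """Linear layer producing a (gait, non-gait) logit pair per window."""

    def __init__(self, in_dim: int, seed: int = 0):
        super().__init__()
        self.linear = Linear(in_dim, 2, np.random.default_rng(seed))

    def forward(self, z: Tensor) -> Tensor:
        return self.linear(z)


class GaitModel(Module):
    """encoder -> head -> 2-logit classifier; the fine-tuned gait detector."""

    def __init__(self, encoder: Encoder, head: Module, head_out_dim: int,
                 seed: int = 0):
        super().__init__()
        self.encoder = encoder
        self.head = head
        self.classifier = GaitClassifier(head_out_dim, seed=seed)

    def forward(self, x: Tensor) -> Tensor:
        return self.classifier(self.head(self.encoder(x)))


def softmax_probabilities(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _stack_windows(windows) -> np.ndarray:
    arrs = [w.samples if isinstance(w, Window) else np.asarray(w, np.float32)
            for w in windows]
    x = np.stack(arrs).astype(np.float32)
    if x.ndim != 3 or x.shape[1:] != (3, WINDOW_SAMPLES):
        raise ValueError(f"windows must be (3, {WINDOW_SAMPLES})")
    return x


def encode(windows, encoder: Encoder, batch_size: int = 256) -> np.ndarray:
    """Embed windows in inference mode; (N, feature_dim) float32."""
    x = _stack_windows(windows)
    encoder.eval()
    out = []
    with no_grad():
        for lo in range(0, x.shape[0], batch_size):
            out.append(encoder(Tensor(x[lo:lo + batch_size])).data)
    return np.concatenate(out)


def head_forward(z: np.ndarray, head: Module, batch_size: int = 1024) -> np.ndarray:
    z = np.asarray(z, dtype=np.float32)
    head.eval()
    out = []
    with no_grad():
        for lo in range(0, z.shape[0], batch_size):
            out.append(head(Tensor(z[lo:lo + batch_size])).data)
    return np.concatenate(out)


def classify(z: np.ndarray, classifier: GaitClassifier) -> np.ndarray:
    """Per-window (gait, non-gait) logits from head-space embeddings."""
    z = np.asarray(z, dtype=np.float32)
    classifier.eval()
    with no_grad():
        return classifier(Tensor(z)).data


# ---------------------------------------------------------------------------
# checkpoints: named-parameter container + embedded architecture manifest


def save_checkpoint(path, modules: dict[str, Module], manifest: dict) -> None:
    arrays = {}
    for mod_name, module in modules.items():
        for key, value in module.state_dict().items():
            arrays[f"{mod_name}:{key}"] = value
    np.savez(path, __manifest__=np.frombuffer(
        json.dumps(manifest).encode(), dtype=np.uint8), **arrays)


def read_checkpoint(path) -> tuple[dict[str, dict[str, np.ndarray]], dict]:
    with np.load(path) as data:
        manifest = json.loads(bytes(data["__manifest__"]).decode())
        states: dict[str, dict[str, np.ndarray]] = {}
        for key in data.files:
            if key == "__manifest__":
                continue
            mod_name, param = key.split(":", 1)
            states.setdefault(mod_name, {})[param] = data[key]
    return states, manifest


def load_pretrained_encoder(path, encoder: Encoder | None = None,
                            partial: bool = False) -> Encoder:
    """Load encoder weights from a checkpoint, with mismatch diagnostics.

    Without ``partial``, any missing/unexpected/mismatched parameter raises
    and names the offending keys; with ``partial=True`` the intersection is
    loaded (a head-only checkpoint then leaves the encoder untouched).
    """
    states, manifest = read_checkpoint(path)
    if encoder is None:
        cfg = EncoderConfig(**manifest["encoder_config"])
        encoder = Encoder(cfg, seed=0)
    enc_state = states.get("encoder", {})
    if partial:
        encoder.load_state_dict(
            {k: v for k, v in enc_state.items()}, strict=False)
    else:
        encoder.load_state_dict(enc_state, strict=True)
    return encoder


def encoder_checksum(encoder: Module) -> str:
    return param_checksum(encoder)
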
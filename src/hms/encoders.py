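"""Shared CNN encoder template with task-specific heads.

One encoder skeleton serves every component: pre-processing, a backbone
from a small registered family, and global average pooling into an
embedding ``z`` of dimension ``d``.  Task differences live entirely in
lightweight heads on ``z``: a 4-logit multi-label sigmoid head for parent
screening, a K-class softmax head for staging (AMD K=5, DR K=4), and an
L2-normalized projection head for contrastive cross-modal alignment.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor
from .types import ImageSample

__all__ = ["EncoderConfig", "TinyEncoder", "build_encoder", "encode",
           "adapt_grayscale_weights", "ParentHead", "StagingHead",
           "ProjectionHead", "softmax", "save_checkpoint", "load_checkpoint",
           "BACKBONES"]

_NORM_EPS = 1e-12


@dataclass
class EncoderConfig:
    backbone: str = "tiny"
    embedding_dim: int = 64
    input_channels: int = 1

    def __post_init__(self):
        if self.embedding_dim <= 0:
            raise ValueError("embedding_dim must be positive")


class TinyEncoder(nn.Module):
    """3 conv blocks (conv-norm-relu-pool) -> global pooling -> linear to d.

    The readout concatenates global average and global max pooling: the
    average term carries layer/texture statistics while the max term keeps
    small focal lesions (a few bright or dark pixels) from being diluted
    over the spatial grid.
    """

    widths = (8, 16, 64)

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        c_in = config.input_channels
        blocks = []
        for w in self.widths:
            blocks += [nn.Conv2d(c_in, w, 3, padding=1, rng=rng),
                       nn.BatchNorm2d(w), nn.ReLU(), nn.MaxPool2d(2)]
            c_in = w
        self.backbone = nn.Sequential(*blocks)
        self.fc = nn.Linear(2 * self.widths[-1], config.embedding_dim, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.backbone(x)
        n, c = h.shape[0], h.shape[1]
        flat = h.reshape(n, c, -1)
        z = Tensor.concatenate([flat.mean(axis=2), flat.max(axis=2)], axis=1)
        return self.fc(z)


class WideEncoder(TinyEncoder):
    """Same template, wider channels; exercises the pluggable-family slot."""

    widths = (24, 48, 96)


BACKBONES = {"tiny": TinyEncoder, "wide": WideEncoder}


def build_encoder(config: EncoderConfig,
                  rng: np.random.Generator | None = None) -> TinyEncoder:
    if config.backbone not in BACKBONES:
        raise KeyError(f"unknown backbone {config.backbone!r}; "
                       f"registered: {sorted(BACKBONES)}")
    return BACKBONES[config.backbone](config, rng or np.random.default_rng(0))


def encode(images, encoder: nn.Module, batch_size: int = 256) -> np.ndarray:
    """Embed images (ImageSample list or (N,1,H,W) array) in inference mode.

    Deterministic: batchnorm uses running statistics, no stochastic layers.
    """
    if isinstance(images, ImageSample):
        images = [images]
    if isinstance(images, list):
        from .types import stack_pixels
        x = stack_pixels(images)
    else:
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
    cfg = encoder.config
    if x.shape[1] != cfg.input_channels:
        raise ValueError(f"expected {cfg.input_channels} channel(s), got {x.shape[1]}")
    encoder.eval()
    outs = []
    with nn.no_grad():
        for i in range(0, len(x), batch_size):
            outs.append(encoder(Tensor(x[i:i + batch_size])).data)
    return np.concatenate(outs, axis=0)


def adapt_grayscale_weights(first_layer_weights: np.ndarray) -> np.ndarray:
    """Collapse an RGB first-conv kernel to grayscale by channel averaging.

    A gray image then produces exactly the response the original layer
    gives to that image replicated across RGB (linearity of convolution).
    """
    w = np.asarray(first_layer_weights)
    if w.ndim != 4 or w.shape[1] != 3:
        raise ValueError("expected kernel of shape (out, 3, kh, kw)")
    return w.mean(axis=1, keepdims=True)


class ParentHead(nn.Module):
    """4 independent logits (NORM, AMD, DR, DME); sigmoid for probabilities."""

    def __init__(self, d: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.fc = nn.Linear(d, 4, rng=rng)

    def forward(self, z: Tensor) -> Tensor:
        return self.fc(z)

    def probabilities(self, z) -> np.ndarray:
        with nn.no_grad():
            return self.fc(Tensor(z)).sigmoid().data


def softmax(logits: Tensor, axis: int = -1) -> Tensor:
    logits = Tensor(logits) if not isinstance(logits, Tensor) else logits
    shifted = logits - Tensor(logits.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


class StagingHead(nn.Module):
    """Softmax head over K stages (K=5 for AMD, K=4 for DR)."""

    def __init__(self, d: int, K: int, rng: np.random.Generator | None = None):
        super().__init__()
        if K <= 1:
            raise ValueError("staging requires K >= 2")
        self.K = K
        self.fc = nn.Linear(d, K, rng=rng)

    def forward(self, z: Tensor) -> Tensor:
        return self.fc(z)            # logits

    def probabilities(self, z) -> np.ndarray:
        with nn.no_grad():
            return softmax(self.fc(Tensor(z))).data


class ProjectionHead(nn.Module):
    """2-layer MLP with intermediate normalization, then L2 normalization."""

    def __init__(self, d: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.fc1 = nn.Linear(d, d, rng=rng)
        self.fc2 = nn.Linear(d, d, rng=rng)

    def forward(self, z: Tensor) -> Tensor:
        h = self.fc1(z)
        # feature standardization in place of batch-coupled normalization
        mu = h.mean(axis=-1, keepdims=True)
        sd = (((h - mu) ** 2).mean(axis=-1, keepdims=True) + _NORM_EPS) ** 0.5
        h = ((h - mu) / sd).relu()
        out = self.fc2(h)
        norm = ((out**2).sum(axis=-1, keepdims=True) + _NORM_EPS) ** 0.5
        return out / norm


def save_checkpoint(path, modules: dict[str, nn.Module],
                    encoder_config: EncoderConfig | None = None):
    """Serialize named modules into one NPZ plus a JSON config sidecar."""
    path = Path(path)
    state = {}
    for name, module in modules.items():
        for k, v in module.state_dict().items():
            state[f"{name}::{k}"] = v
    np.savez(path, **state)
    if encoder_config is not None:
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(asdict(encoder_config), indent=2))


def load_checkpoint(path, modules: dict[str, nn.Module]):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing checkpoint: {path}")
    data = np.load(path)
    for name, module in modules.items():
        state = {k.split("::", 1)[1]: data[k] for k in data.files
                 if k.startswith(name + "::")}
        if not state:
            raise KeyError(f"checkpoint {path} lacks component {name!r}")
        module.load_state_dict(state)
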
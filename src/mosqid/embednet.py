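"""The embedding network: backbone -> 64-d embedder -> 20-d classifier head.

Two backbone families are provided. ``residual34`` is the classic 34
parameter-layer residual network (basic blocks [3, 4, 6, 3], projection
shortcuts excluded from the census) whose 1000-wide output layer feeds the
embedder, as in the original identification system. ``smallcnn`` is a
~100k-parameter 4-block CNN for 32x32 inputs, the default at desk scale
where residual-34 training on one CPU is impractical.

Embeddings are L2-normalised at the embedder output, so Euclidean ranking
and cosine ranking agree; the retrieval stage relies on this. The classifier
head maps the 64-d embedding to ``n_out`` logits (default 20, which must be
at least the number of trained classes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "BackboneConfig", "EmbeddingModel", "build_model", "embed_images",
    "classify_logits", "preprocess", "parameter_layer_census",
    "save_checkpoint", "load_checkpoint",
]

RESIDUAL34_BLOCKS = (3, 4, 6, 3)


@dataclass(frozen=True)
class BackboneConfig:
    family: str = "smallcnn"                  # {"residual34", "smallcnn"}
    input_resolution: tuple[int, int] = (32, 32)
    init: str = "random"                      # pretrained weights optional, never required
    channels: tuple[int, ...] = (16, 32, 64, 128)   # smallcnn widths
    feature_width: int = 1000                 # residual34 output-layer width

    def __post_init__(self):
        if self.family not in ("residual34", "smallcnn"):
            raise ValueError(f"unknown backbone family {self.family!r}")


def _default_resolution(family: str) -> tuple[int, int]:
    return (224, 224) if family == "residual34" else (32, 32)


class _BasicBlock(nn.Module):
    def __init__(self, c_in: int, c_out: int, stride: int, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(c_in, c_out, 3, rng, stride=stride, padding=1)
        self.bn1 = nn.BatchNorm2d(c_out)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, rng, padding=1)
        self.bn2 = nn.BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.proj = nn.Conv2d(c_in, c_out, 1, rng, stride=stride,
                                  is_projection=True)
            self.proj_bn = nn.BatchNorm2d(c_out)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        shortcut = x if self.proj is None else self.proj_bn(self.proj(x))
        return (out + shortcut).relu()


def _build_residual34(cfg: BackboneConfig, rng) -> nn.Module:
    layers: list[nn.Module] = [
        nn.Conv2d(3, 64, 7, rng, stride=2, padding=3),
        nn.BatchNorm2d(64), nn.ReLU(), nn.MaxPool2d(2),
    ]
    c_in = 64
    for stage, n_blocks in enumerate(RESIDUAL34_BLOCKS):
        c_out = 64 * 2 ** stage
        for b in range(n_blocks):
            stride = 2 if (stage > 0 and b == 0) else 1
            layers.append(_BasicBlock(c_in, c_out, stride, rng))
            c_in = c_out
    layers += [nn.GlobalAvgPool(), nn.Linear(c_in, cfg.feature_width, rng),
               nn.ReLU()]
    return nn.Sequential(*layers)


def _build_smallcnn(cfg: BackboneConfig, rng) -> nn.Module:
    # conv blocks halve the spatial dims; the final map is flattened rather
    # than pooled away so the embedder keeps coarse spatial structure
    layers: list[nn.Module] = []
    c_in = 3
    for c_out in cfg.channels:
        layers += [nn.Conv2d(c_in, c_out, 3, rng, padding=1),
                   nn.BatchNorm2d(c_out), nn.ReLU(), nn.MaxPool2d(2)]
        c_in = c_out
    layers.append(nn.Flatten())
    return nn.Sequential(*layers)


def smallcnn_feature_width(cfg: BackboneConfig) -> int:
    h, w = cfg.input_resolution
    f = 2 ** len(cfg.channels)
    if h % f or w % f:
        raise ValueError(f"input resolution {cfg.input_resolution} not "
                         f"divisible by total pooling factor {f}")
    return cfg.channels[-1] * (h // f) * (w // f)


class EmbeddingModel(nn.Module):
    """Backbone features -> unit-norm 64-d embedding -> n_out logits."""

    def __init__(self, config: BackboneConfig, embed_dim: int, n_out: int,
                 seed: int = 0, vocabulary: list[str] | None = None):
        super().__init__()
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE1]))
        self.config = config
        self.embed_dim, self.n_out = embed_dim, n_out
        self.vocabulary = list(vocabulary) if vocabulary else []
        self.backbone = (_build_residual34(config, rng)
                         if config.family == "residual34"
                         else _build_smallcnn(config, rng))
        feat = (config.feature_width if config.family == "residual34"
                else smallcnn_feature_width(config))
        self.embedder = nn.Linear(feat, embed_dim, rng)
        self.classifier = nn.Linear(embed_dim, n_out, rng)

    # parameter groups for per-part learning rates
    def parameter_groups(self) -> dict[str, list[Tensor]]:
        return {
            "backbone": self.backbone.parameters(),
            "embedder": self.embedder.parameters(),
            "classifier": self.classifier.parameters(),
        }

    def embed(self, x: Tensor) -> Tensor:
        h, w = self.config.input_resolution
        if x.shape[2:] != (h, w):
            raise ValueError(
                f"expected {h}x{w} input, got {x.shape[2]}x{x.shape[3]}")
        feats = self.backbone(x)
        e = self.embedder(feats)
        norm = (e * e).sum(axis=1, keepdims=True).sqrt() + 1e-12
        return e / norm

    def logits(self, embeddings: Tensor) -> Tensor:
        if embeddings.shape[1] != self.embed_dim:
            raise ValueError(f"expected {self.embed_dim}-d embeddings, "
                             f"got {embeddings.shape[1]}-d")
        return self.classifier(embeddings)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        e = self.embed(x)
        return e, self.logits(e)


def build_model(config: BackboneConfig, embed_dim: int = 64, n_out: int = 20,
                n_classes: int | None = None, seed: int = 0,
                vocabulary: list[str] | None = None) -> EmbeddingModel:
    if embed_dim <= 0 or n_out <= 0:
        raise ValueError("dimensions must be positive")
    if vocabulary is not None and n_classes is None:
        n_classes = len(vocabulary)
    if n_classes is not None and n_out < n_classes:
        raise ValueError(
            f"classifier width {n_out} < number of classes {n_classes}")
    return EmbeddingModel(config, embed_dim, n_out, seed=seed,
                          vocabulary=vocabulary)


def preprocess(images: np.ndarray | list[np.ndarray]) -> Tensor:
    """uint8 HWC image(s) -> float NCHW tensor scaled to [-1, 1]."""
    arr = np.stack([np.asarray(im) for im in images]) \
        if isinstance(images, (list, tuple)) else np.asarray(images)
    if arr.ndim == 3:
        arr = arr[None]
    x = arr.astype(np.float64) / 255.0
    return Tensor(np.transpose((x - 0.5) / 0.5, (0, 3, 1, 2)))


def embed_images(model: EmbeddingModel, images) -> np.ndarray:
    """Eval-mode embeddings for a batch of uint8 images; (n, 64) unit-norm."""
    was_training = model.training
    model.eval()
    try:
        out = model.embed(preprocess(images)).data
    finally:
        if was_training:
            model.train()
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite embedding values")
    return out


def classify_logits(model: EmbeddingModel, embeddings: np.ndarray) -> np.ndarray:
    return model.logits(Tensor(np.asarray(embeddings, dtype=np.float64))).data


def parameter_layer_census(model: EmbeddingModel) -> int:
    """Count weight-bearing layers on the backbone's main path.

    Convolutions and fully connected layers count; batch-norm, pooling and
    projection shortcuts do not. A residual-34 backbone censuses to exactly
    34 (stem + 2x(3+4+6+3) block convolutions + the final 1000-wide layer).
    """
    n = 0
    for m in model.backbone.modules():
        if isinstance(m, nn.Conv2d) and not m.is_projection:
            n += 1
        elif isinstance(m, nn.Linear):
            n += 1
    return n


# ---------------------------------------------------------------- checkpoints

def save_checkpoint(model: EmbeddingModel, path: str | Path) -> None:
    """Single-file weights (.npz) + JSON sidecar with the architecture."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"param/{k}": p.data for k, p in model.named_parameters()}
    arrays.update({f"buffer/{k}": b for k, b in model.buffers()})
    np.savez(path, **arrays)
    sidecar = {
        "family": model.config.family,
        "input_resolution": list(model.config.input_resolution),
        "channels": list(model.config.channels),
        "feature_width": model.config.feature_width,
        "embed_dim": model.embed_dim,
        "n_out": model.n_out,
        "vocabulary": model.vocabulary,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path: str | Path) -> EmbeddingModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    cfg = BackboneConfig(family=sidecar["family"],
                         input_resolution=tuple(sidecar["input_resolution"]),
                         channels=tuple(sidecar["channels"]),
                         feature_width=sidecar["feature_width"])
    model = EmbeddingModel(cfg, sidecar["embed_dim"], sidecar["n_out"],
                           vocabulary=sidecar["vocabulary"])
    data = np.load(path)
    params = dict(model.named_parameters())
    stored = {k[len("param/"):]: data[k] for k in data.files
              if k.startswith("param/")}
    if set(stored) != set(params):
        raise ValueError(
            f"checkpoint/architecture mismatch for family {cfg.family!r}: "
            f"parameter sets differ")
    for k, p in params.items():
        if p.data.shape != stored[k].shape:
            raise ValueError(f"shape mismatch for {k}: "
                             f"{stored[k].shape} vs {p.data.shape}")
        p.data = stored[k].astype(np.float64)
    buffers = dict(model.buffers())
    for k in data.files:
        if k.startswith("buffer/"):
            name = k[len("buffer/"):]
            buffers[name][...] = data[k]
    return model


def restore_into(model: EmbeddingModel, path: str | Path) -> None:
    """Load checkpoint weights into an existing compatible model."""
    loaded = load_checkpoint(path)
    if loaded.config.family != model.config.family:
        raise ValueError(f"family mismatch: checkpoint is "
                         f"{loaded.config.family!r}, model is "
                         f"{model.config.family!r}")
    if loaded.embed_dim != model.embed_dim:
        raise ValueError("embed_dim mismatch")
    for (_, dst), (_, src) in zip(model.named_parameters(),
                                  loaded.named_parameters()):
        dst.data = src.data.copy()
    for (_, dst), (_, src) in zip(model.buffers(), loaded.buffers()):
        dst[...] = src
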
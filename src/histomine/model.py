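"""Backbones, partial fine-tuning freeze policy, prediction, ensembling.

Two architectures share one interface: ``efficientnet_b1`` (the canonical
B1 layout — stem, 7 MBConv stages with depths [2,3,3,4,4,5,2], top conv
to 1280 features — used for transfer learning and parameter accounting)
and ``tiny_cnn`` (a small batch-norm-bearing ConvNet for desk-scale
training and tests).  Both are fully convolutional with global average
pooling and a single-logit sigmoid head, so tiles can be fed at native
size or mean-pooled to a configured input size.

The partial freeze policy marks exactly the batch-normalisation affine
parameters (scale γ, offset β) and the final classification layer
(weights + bias) trainable and freezes everything else; on
EfficientNetB1 that leaves 62,048 BN parameters + 1,281 head parameters
= 63,329 trainable scalars.  BN running statistics still update in
training mode but are buffers, not trainable parameters.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _nn
from ._nn import (Adam, BatchNorm2d, Conv2d, Dense, GlobalAvgPool, MBConv,
                  Module, ReLU, Sequential, Swish)
from .errors import ModelError

FREEZE_PARTIAL = "partial_bn_affine_plus_head"
FREEZE_NONE = "none"

#: EfficientNet-B1 stage table: (kernel, stride, expand_ratio, cout, repeats).
#: B1 applies depth coefficient 1.1 to B0's repeats [1,2,2,3,3,4,1] -> ceil.
EFFICIENTNET_B1_STAGES = [
    (3, 1, 1, 16, 2),
    (3, 2, 6, 24, 3),
    (5, 2, 6, 40, 3),
    (3, 2, 6, 80, 4),
    (5, 1, 6, 112, 4),
    (5, 2, 6, 192, 5),
    (3, 1, 6, 320, 2),
]
EFFICIENTNET_STEM_CHANNELS = 32
EFFICIENTNET_TOP_CHANNELS = 1280


@dataclass
class BackboneConfig:
    """Model construction options."""

    architecture: str = "tiny_cnn"  # efficientnet_b1 | tiny_cnn
    input_size: int | None = None  # None: feed tiles at native size
    pretrained_source: str | None = None  # checkpoint path or None
    freeze_policy: str = FREEZE_NONE
    seed: int = 0


class Model:
    """Backbone + global average pool + single-logit sigmoid head."""

    def __init__(self, architecture: str, backbone: Module, head: Dense,
                 input_size: int | None = None, freeze_policy: str = FREEZE_NONE):
        self.architecture = architecture
        self.backbone = backbone
        self.gap = GlobalAvgPool()
        self.head = head
        self.input_size = input_size
        self.freeze_policy = freeze_policy

    # -- parameter access ---------------------------------------------------
    def params(self) -> list[_nn.Param]:
        return self.backbone.params() + self.head.params()

    def bn_modules(self) -> list[BatchNorm2d]:
        return [m for m in self.backbone.modules() if isinstance(m, BatchNorm2d)]

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """NCHW float batch -> per-tile probability vector in (0,1)."""
        feats = self.backbone(x, train=train)
        logits = self.head(self.gap(feats, train=train), train=train)
        self._logits = logits
        return 1.0 / (1.0 + np.exp(-logits[:, 0]))

    def backward_from_logit_grad(self, dlogit: np.ndarray) -> None:
        """Backpropagate d(loss)/d(logit) (shape (n,)) through the network."""
        d = self.head.backward(dlogit[:, None].astype(self._logits.dtype))
        self.backbone.backward(self.gap.backward(d))

    # -- preprocessing ------------------------------------------------------
    def preprocess(self, tiles: np.ndarray) -> np.ndarray:
        """uint8 NHWC tile batch -> float32 NCHW in [0,1], resized to input_size."""
        if tiles.ndim != 4 or tiles.shape[-1] != 3:
            raise ModelError(f"expected NxHxWx3 tile batch, got shape {tiles.shape}")
        x = tiles.astype(np.float32) / 255.0
        if self.input_size is not None and tiles.shape[1] != self.input_size:
            h = tiles.shape[1]
            if h % self.input_size == 0 and tiles.shape[2] % self.input_size == 0:
                f = h // self.input_size
                n, _, w, c = x.shape
                x = x.reshape(n, self.input_size, f, self.input_size, f, c).mean(axis=(2, 4))
            else:
                from skimage.transform import resize
                x = np.stack([
                    resize(t, (self.input_size, self.input_size, 3),
                           preserve_range=True, anti_aliasing=True)
                    for t in x]).astype(np.float32)
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))

    def predict(self, tiles: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Deterministic inference (running BN statistics, no dropout)."""
        out = []
        for i in range(0, len(tiles), batch_size):
            x = self.preprocess(tiles[i:i + batch_size])
            out.append(self.forward(x, train=False))
        return np.concatenate(out)

    # -- checkpointing ------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {}
        for p in self.params():
            if p.name in arrays:
                raise ModelError(f"duplicate parameter name {p.name}")
            arrays["p:" + p.name] = p.value
        for i, bn in enumerate(self.bn_modules()):
            arrays[f"b:{i}:mean"] = bn.running_mean
            arrays[f"b:{i}:var"] = bn.running_var
        return arrays

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for p in self.params():
            key = "p:" + p.name
            if key not in arrays:
                raise ModelError(f"checkpoint missing parameter {p.name}")
            if arrays[key].shape != p.value.shape:
                raise ModelError(
                    f"checkpoint shape mismatch for {p.name}: "
                    f"{arrays[key].shape} vs {p.value.shape}")
            p.value = arrays[key].astype(p.value.dtype).copy()
            p.grad = np.zeros_like(p.value)
        for i, bn in enumerate(self.bn_modules()):
            bn.running_mean = arrays[f"b:{i}:mean"].astype(bn.running_mean.dtype).copy()
            bn.running_var = arrays[f"b:{i}:var"].astype(bn.running_var.dtype).copy()

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_arrays().items()}


def _build_tiny_cnn(rng: np.random.Generator) -> tuple[Module, Dense]:
    """3-stage strided ConvNet (3->8->16->32 channels) with BN after each conv."""
    layers = []
    cin = 3
    for i, cout in enumerate((8, 16, 32)):
        layers += [
            Conv2d(cin, cout, 3, stride=2, rng=rng, name=f"conv{i}"),
            BatchNorm2d(cout, name=f"bn{i}"),
            ReLU(),
        ]
        cin = cout
    head = Dense(32, 1, rng=rng, name="head")
    return Sequential(*layers), head


def _build_efficientnet_b1(rng: np.random.Generator) -> tuple[Module, Dense]:
    layers: list[Module] = [
        Conv2d(3, EFFICIENTNET_STEM_CHANNELS, 3, stride=2, rng=rng, name="stem"),
        BatchNorm2d(EFFICIENTNET_STEM_CHANNELS, name="stem_bn"),
        Swish(),
    ]
    cin = EFFICIENTNET_STEM_CHANNELS
    bidx = 0
    for k, stride, expand, cout, repeats in EFFICIENTNET_B1_STAGES:
        for r in range(repeats):
            layers.append(MBConv(cin, cout, k, stride if r == 0 else 1, expand,
                                 rng=rng, name=f"block{bidx}"))
            cin = cout
            bidx += 1
    layers += [
        Conv2d(cin, EFFICIENTNET_TOP_CHANNELS, 1, rng=rng, name="top"),
        BatchNorm2d(EFFICIENTNET_TOP_CHANNELS, name="top_bn"),
        Swish(),
    ]
    head = Dense(EFFICIENTNET_TOP_CHANNELS, 1, rng=rng, name="head")
    return Sequential(*layers), head


_BUILDERS = {"tiny_cnn": _build_tiny_cnn, "efficientnet_b1": _build_efficientnet_b1}


def build_model(config: BackboneConfig) -> Model:
    """Construct a backbone, optionally load a checkpoint, apply the freeze policy."""
    if config.architecture not in _BUILDERS:
        raise ModelError(f"unsupported architecture {config.architecture!r}; "
                         f"choose from {sorted(_BUILDERS)}")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    backbone, head = _BUILDERS[config.architecture](rng)
    model = Model(config.architecture, backbone, head,
                  input_size=config.input_size, freeze_policy=config.freeze_policy)
    src = config.pretrained_source
    if src == "imagenet":
        raise ModelError(
            "ImageNet weights are not bundled with this package; export them to a "
            "checkpoint file and pass its path as pretrained_source")
    if src not in (None, "", "none"):
        ckpt = Path(src)
        if not ckpt.exists():
            raise ModelError(f"pretrained checkpoint not found: {ckpt}")
        loaded = load_checkpoint(ckpt)
        if loaded.architecture != config.architecture:
            raise ModelError(
                f"checkpoint architecture {loaded.architecture!r} does not match "
                f"requested {config.architecture!r}")
        model.load_state_arrays(loaded.state_arrays())
    apply_freeze_policy(model, config.freeze_policy)
    return model


def apply_freeze_policy(model: Model, policy: str) -> Model:
    """Mark trainable parameters in place.

    partial_bn_affine_plus_head: exactly {BN γ, BN β, head weight, head
    bias} are trainable, everything else frozen.  none: all trainable.
    """
    if policy == FREEZE_NONE:
        for p in model.params():
            p.trainable = True
    elif policy == FREEZE_PARTIAL:
        bns = model.bn_modules()
        if not bns:
            raise ModelError(
                f"freeze policy {policy!r} requires batch-normalisation layers; "
                f"{model.architecture} has none")
        for p in model.params():
            p.trainable = False
        for bn in bns:
            bn.gamma.trainable = True
            bn.beta.trainable = True
        model.head.w.trainable = True
        if model.head.b is not None:
            model.head.b.trainable = True
    else:
        raise ModelError(f"unknown freeze policy {policy!r}")
    model.freeze_policy = policy
    return model


def count_trainable_params(model: Model) -> int:
    """Total scalar entries over all trainable parameter tensors."""
    return sum(p.size for p in model.params() if p.trainable)


def count_total_params(model: Model) -> int:
    return sum(p.size for p in model.params())


def predict_tiles(model: Model, tiles: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Per-tile probabilities, order-preserving, deterministic in inference mode."""
    if len(tiles) == 0:
        raise ModelError("empty tile batch")
    return model.predict(tiles, batch_size=batch_size)


@dataclass
class EnsembleSpec:
    """>= 2 checkpoint paths sharing one input contract."""

    members: list[Path] = field(default_factory=list)

    def __post_init__(self):
        if len(self.members) < 2:
            raise ModelError("an ensemble needs at least 2 members")


def ensemble_predict(models: list[Model], tiles: np.ndarray,
                     batch_size: int = 256) -> np.ndarray:
    """Arithmetic mean of member tile probabilities."""
    if len(models) < 2:
        raise ModelError("an ensemble needs at least 2 members")
    preds = [predict_tiles(m, tiles, batch_size=batch_size) for m in models]
    return np.mean(preds, axis=0)


def load_ensemble(spec: EnsembleSpec) -> list[Model]:
    out = []
    for path in spec.members:
        try:
            out.append(load_checkpoint(path))
        except Exception as exc:
            raise ModelError(f"ensemble member {path}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Checkpoint files: .npz weights + .json sidecar

def save_checkpoint(model: Model, path: str | Path,
                    training_config: dict | None = None) -> None:
    path = Path(path)
    arrays = model.state_arrays()
    np.savez(path.with_suffix(".npz"), **arrays)
    cfg_hash = ""
    if training_config is not None:
        blob = json.dumps(training_config, sort_keys=True).encode()
        cfg_hash = hashlib.sha256(blob).hexdigest()[:16]
    sidecar = {
        "architecture": model.architecture,
        "freeze_policy": model.freeze_policy,
        "input_size": model.input_size,
        "training_config_hash": cfg_hash,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> Model:
    path = Path(path)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    sidecar_path = npz_path.with_suffix(".json")
    if not npz_path.exists():
        raise ModelError(f"checkpoint not found: {npz_path}")
    if not sidecar_path.exists():
        raise ModelError(f"checkpoint sidecar not found: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    cfg = BackboneConfig(architecture=meta["architecture"],
                         input_size=meta.get("input_size"),
                         freeze_policy=meta.get("freeze_policy", FREEZE_NONE))
    if cfg.architecture not in _BUILDERS:
        raise ModelError(f"checkpoint {path}: unknown architecture {cfg.architecture!r}")
    rng = np.random.default_rng(0)
    backbone, head = _BUILDERS[cfg.architecture](rng)
    model = Model(cfg.architecture, backbone, head, input_size=cfg.input_size,
                  freeze_policy=cfg.freeze_policy)
    with np.load(npz_path) as data:
        model.load_state_arrays({k: data[k] for k in data.files})
    apply_freeze_policy(model, cfg.freeze_policy)
    return model


def make_optimizer(model: Model, beta1: float = 0.9, beta2: float = 0.999) -> Adam:
    return Adam(model.params(), beta1=beta1, beta2=beta2)
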
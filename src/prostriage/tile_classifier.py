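"""Trainable tile scorer: tile raster -> (p_indolent, p_aggressive).

The two heads are independent sigmoids — a tile may score high on both,
which is what produces double-label slide calls downstream; benign is the
absence of both. Training minimizes mean binary cross-entropy over the
unmasked (tile, head) pairs of a batch with an Adam optimizer
(lr 0.001, beta1 0.9, beta2 0.999 by default).

Backbones are pluggable through a small registry. The built-in ``tinyconv``
backbone is a compact convolutional network (two 3x3 conv + batch-norm +
ReLU + pool stages, global average pooling, a 2-unit linear head) written
directly on numpy with explicit forward/backward passes, so it trains in
seconds on one CPU and its batch-normalization affine parameters are
individually addressable. That addressability is what the partial
fine-tuning policy needs: under ``policy="partial"`` only the
batch-normalization scale/shift parameters and the final classification
layer are trainable, everything else stays frozen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "OptimizerConfig",
    "TileBatch",
    "TileClassifier",
    "ConfigurationError",
    "DegenerateBatchError",
    "InputError",
    "BACKBONES",
    "build_classifier",
    "partial_finetune_setup",
    "train_step",
    "predict_tiles",
    "save_checkpoint",
    "load_checkpoint",
]

HEADS = ("indolent", "aggressive")
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


class ConfigurationError(ValueError):
    """Backbone cannot support the requested parameter policy."""


class DegenerateBatchError(ValueError):
    """A batch with no unmasked (tile, head) pair cannot produce a loss."""


class InputError(ValueError):
    """Tile rasters do not match the classifier's expected input."""


@dataclass(frozen=True)
class OptimizerConfig:
    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7


# ---------------------------------------------------------------------------
# layers (NHWC layout, float64)


class _Conv3x3:
    """3x3 same-padding convolution without bias (bias is absorbed by BN)."""

    def __init__(self, name: str, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (9 * c_in))
        self.name = name
        self.weight = rng.normal(0.0, scale, size=(3, 3, c_in, c_out))
        self.grad_weight = np.zeros_like(self.weight)

    def params(self):
        return {f"{self.name}.weight": (self.weight, self.grad_weight)}

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, _ = x.shape
        self._x_pad = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        out = np.zeros((n, h, w, self.weight.shape[3]))
        for di in range(3):
            for dj in range(3):
                out += self._x_pad[:, di : di + h, dj : dj + w, :] @ self.weight[di, dj]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, _ = dout.shape
        dx_pad = np.zeros_like(self._x_pad)
        self.grad_weight[...] = 0.0
        for di in range(3):
            for dj in range(3):
                patch = self._x_pad[:, di : di + h, dj : dj + w, :]
                self.grad_weight[di, dj] = np.tensordot(patch, dout, axes=([0, 1, 2], [0, 1, 2]))
                dx_pad[:, di : di + h, dj : dj + w, :] += dout @ self.weight[di, dj].T
        return dx_pad[:, 1:-1, 1:-1, :]


class _BatchNorm:
    """Per-channel batch normalization with affine scale/shift."""

    def __init__(self, name: str, channels: int):
        self.name = name
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.grad_gamma = np.zeros(channels)
        self.grad_beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def params(self):
        return {
            f"{self.name}.gamma": (self.gamma, self.grad_gamma),
            f"{self.name}.beta": (self.beta, self.grad_beta),
        }

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - _BN_MOMENTUM) * self.running_mean + _BN_MOMENTUM * mean
            self.running_var = (1 - _BN_MOMENTUM) * self.running_var + _BN_MOMENTUM * var
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + _BN_EPS)
        self._xhat = (x - mean) * self._istd
        self._training = training
        self._m = int(np.prod([x.shape[a] for a in axes]))
        return self.gamma * self._xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes = tuple(range(dout.ndim - 1))
        self.grad_gamma[...] = (dout * self._xhat).sum(axis=axes)
        self.grad_beta[...] = dout.sum(axis=axes)
        dxhat = dout * self.gamma
        if not self._training:
            return dxhat * self._istd
        m = self._m
        return (
            self._istd
            / m
            * (m * dxhat - dxhat.sum(axis=axes) - self._xhat * (dxhat * self._xhat).sum(axis=axes))
        )


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _AvgPool:
    """Non-overlapping k x k average pooling (spatial dims must divide by k)."""

    def __init__(self, k: int):
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        k = self.k
        self._in_shape = x.shape
        return x.reshape(n, h // k, k, w // k, k, c).mean(axis=(2, 4))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        k = self.k
        d = dout / (k * k)
        return np.broadcast_to(
            d[:, :, None, :, None, :], (n, h // k, k, w // k, k, c)
        ).reshape(n, h, w, c)


class _GlobalAvgPool:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        return np.broadcast_to(dout[:, None, None, :] / (h * w), self._in_shape).copy()


class _Dense:
    def __init__(self, name: str, c_in: int, c_out: int, rng: np.random.Generator):
        self.name = name
        self.weight = rng.normal(0.0, 1.0 / np.sqrt(c_in), size=(c_in, c_out))
        self.bias = np.zeros(c_out)
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)

    def params(self):
        return {
            f"{self.name}.weight": (self.weight, self.grad_weight),
            f"{self.name}.bias": (self.bias, self.grad_bias),
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight + self.bias

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grad_weight[...] = self._x.T @ dout
        self.grad_bias[...] = dout.sum(axis=0)
        return dout @ self.weight.T


class TinyConvBackbone:
    """Two-stage conv/BN/ReLU/pool network over a 32x32 working resolution.

    Inputs of side 32*f (f integer) are first mean-pooled by f so the same
    parameters serve 128-px test tiles and 512-px production tiles.
    """

    id = "tinyconv"

    def __init__(self, rng: np.random.Generator, channels: tuple[int, int] = (8, 16)):
        c1, c2 = channels
        self.conv1 = _Conv3x3("conv1", 3, c1, rng)
        self.bn1 = _BatchNorm("bn1", c1)
        self.relu1 = _ReLU()
        self.pool1 = _AvgPool(2)
        self.conv2 = _Conv3x3("conv2", c1, c2, rng)
        self.bn2 = _BatchNorm("bn2", c2)
        self.relu2 = _ReLU()
        self.pool2 = _AvgPool(2)
        self.gap = _GlobalAvgPool()
        self.head = _Dense("head", c2, len(HEADS), rng)
        self._param_layers = [self.conv1, self.bn1, self.conv2, self.bn2, self.head]

    # -- parameter bookkeeping ------------------------------------------------
    def named_params(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for layer in self._param_layers:
            out.update(layer.params())
        return out

    def norm_affine_names(self) -> list[str]:
        return [n for n in self.named_params() if ".gamma" in n or ".beta" in n]

    def head_names(self) -> list[str]:
        return [n for n in self.named_params() if n.startswith("head.")]

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: value.copy() for name, (value, _) in self.named_params().items()}
        for bn in (self.bn1, self.bn2):
            state[f"{bn.name}.running_mean"] = bn.running_mean.copy()
            state[f"{bn.name}.running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, (value, _) in self.named_params().items():
            value[...] = state[name]
        for bn in (self.bn1, self.bn2):
            bn.running_mean = state[f"{bn.name}.running_mean"].copy()
            bn.running_var = state[f"{bn.name}.running_var"].copy()

    # -- forward/backward -----------------------------------------------------
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        side = x.shape[1]
        if side % 32:
            raise InputError(f"tile side {side} is not a multiple of 32")
        factor = side // 32
        if factor > 1:
            self._pre_pool = _AvgPool(factor)
            x = self._pre_pool.forward(x)
        else:
            self._pre_pool = None
        h = self.conv1.forward(x)
        h = self.bn1.forward(h, training)
        h = self.relu1.forward(h)
        h = self.pool1.forward(h)
        h = self.conv2.forward(h)
        h = self.bn2.forward(h, training)
        h = self.relu2.forward(h)
        h = self.pool2.forward(h)
        h = self.gap.forward(h)
        return self.head.forward(h)  # logits, shape (n, 2)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        d = self.gap.backward(d)
        d = self.pool2.backward(d)
        d = self.relu2.backward(d)
        d = self.bn2.backward(d)
        d = self.conv2.backward(d)
        d = self.pool1.backward(d)
        d = self.relu1.backward(d)
        d = self.bn1.backward(d)
        self.conv1.backward(d)


BACKBONES: dict[str, Callable[[np.random.Generator], TinyConvBackbone]] = {
    "tinyconv": TinyConvBackbone,
}


# ---------------------------------------------------------------------------
# public containers


@dataclass
class TileBatch:
    """A batch of tile rasters with per-head weak labels.

    ``labels`` is (n, 2) in {0, 1}; ``mask`` is (n, 2) boolean, True where
    the (tile, head) pair is supervised. Masked pairs contribute neither
    loss nor gradient.
    """

    tiles: np.ndarray
    labels: np.ndarray
    mask: np.ndarray
    source_slide_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tiles = np.asarray(self.tiles)
        self.labels = np.asarray(self.labels, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = len(self.tiles)
        if self.labels.shape != (n, 2) or self.mask.shape != (n, 2):
            raise InputError("labels and mask must have shape (n_tiles, 2)")
        if self.source_slide_ids and len(self.source_slide_ids) != n:
            raise InputError("source_slide_ids length must match tiles")
        if n and not self.mask.any():
            raise DegenerateBatchError("batch has no unmasked (tile, head) pair")

    def __len__(self) -> int:
        return len(self.tiles)


class TileClassifier:
    """Two-head tile scorer with a pluggable backbone and trainable-policy."""

    def __init__(self, backbone_id: str = "tinyconv", input_size: int = 512,
                 trainable_policy: str = "all", seed: int = 0):
        if backbone_id not in BACKBONES:
            raise ConfigurationError(f"unknown backbone {backbone_id!r}")
        if trainable_policy not in ("all", "partial"):
            raise ConfigurationError(f"unknown policy {trainable_policy!r}")
        self.backbone_id = backbone_id
        self.input_size = int(input_size)
        self.trainable_policy = trainable_policy
        self.seed = int(seed)
        self.backbone = BACKBONES[backbone_id](np.random.default_rng(seed))
        self._adam_state: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._adam_t = 0
        self._adam_config: OptimizerConfig | None = None

    # -- persistence ----------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return self.backbone.state_dict()

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.backbone.load_state_dict(state)

    # -- inference ------------------------------------------------------------
    def _check_tiles(self, tiles: np.ndarray) -> np.ndarray:
        tiles = np.asarray(tiles)
        if tiles.ndim != 4 or tiles.shape[3] != 3:
            raise InputError("tiles must be an (n, h, w, 3) array")
        if tiles.shape[1] != self.input_size or tiles.shape[2] != self.input_size:
            raise InputError(
                f"tile size {tiles.shape[1]}x{tiles.shape[2]} does not match "
                f"classifier input {self.input_size}"
            )
        return tiles.astype(np.float64) / 255.0

    def predict_logits(self, tiles: np.ndarray, training: bool = False) -> np.ndarray:
        x = self._check_tiles(tiles)
        return self.backbone.forward(x, training=training)


def build_classifier(backbone_id: str = "tinyconv", input_size: int = 512,
                     trainable_policy: str = "all", seed: int = 0) -> TileClassifier:
    return TileClassifier(backbone_id, input_size, trainable_policy, seed)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def partial_finetune_setup(classifier: TileClassifier) -> dict[str, bool]:
    """Trainable-parameter descriptor for the classifier's policy.

    Under ``partial``, exactly the normalization affine parameters and the
    final classification layer are trainable; under ``all``, everything.
    """
    backbone = classifier.backbone
    names = list(backbone.named_params())
    if classifier.trainable_policy == "all":
        return {name: True for name in names}
    affine = set(backbone.norm_affine_names())
    if not affine:
        raise ConfigurationError(
            f"backbone {classifier.backbone_id!r} exposes no normalization affine "
            "parameters; partial fine-tuning is not applicable"
        )
    trainable = affine | set(backbone.head_names())
    return {name: name in trainable for name in names}


def train_step(
    classifier: TileClassifier,
    batch: TileBatch,
    optimizer_config: OptimizerConfig = OptimizerConfig(),
) -> float:
    """One Adam step on mean masked binary cross-entropy; returns the loss."""
    if len(batch) == 0 or not batch.mask.any():
        raise DegenerateBatchError("cannot train on a batch with no unmasked pairs")
    descriptor = partial_finetune_setup(classifier)
    logits = classifier.predict_logits(batch.tiles, training=True)
    probs = _sigmoid(logits)
    eps = 1e-15
    p = np.clip(probs, eps, 1 - eps)
    y, m = batch.labels, batch.mask
    n_pairs = int(m.sum())
    loss = float(-(m * (y * np.log(p) + (1 - y) * np.log(1 - p))).sum() / n_pairs)
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite training loss")
    dlogits = np.where(m, probs - y, 0.0) / n_pairs
    classifier.backbone.backward(dlogits)

    cfg = optimizer_config
    if classifier._adam_config != cfg:
        classifier._adam_state = {}
        classifier._adam_t = 0
        classifier._adam_config = cfg
    classifier._adam_t += 1
    t = classifier._adam_t
    for name, (value, grad) in classifier.backbone.named_params().items():
        if not descriptor[name]:
            continue
        if name not in classifier._adam_state:
            classifier._adam_state[name] = (np.zeros_like(value), np.zeros_like(value))
        m1, m2 = classifier._adam_state[name]
        m1 *= cfg.beta1
        m1 += (1 - cfg.beta1) * grad
        m2 *= cfg.beta2
        m2 += (1 - cfg.beta2) * grad**2
        m1_hat = m1 / (1 - cfg.beta1**t)
        m2_hat = m2 / (1 - cfg.beta2**t)
        value -= cfg.lr * m1_hat / (np.sqrt(m2_hat) + cfg.eps)
    return loss


def predict_tiles(
    classifier: TileClassifier, tiles: Sequence[np.ndarray] | np.ndarray, chunk: int = 256
) -> np.ndarray:
    """Per-tile (p_indolent, p_aggressive) in input order; eval-mode, chunked."""
    tiles = np.asarray(tiles)
    if tiles.size == 0:
        return np.zeros((0, 2))
    out = []
    for start in range(0, len(tiles), chunk):
        logits = classifier.predict_logits(tiles[start : start + chunk], training=False)
        out.append(_sigmoid(logits))
    return np.concatenate(out, axis=0)


def save_checkpoint(classifier: TileClassifier, path: str | Path) -> Path:
    """Write parameters plus metadata to a .npz archive."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = json.dumps(
        {
            "format_version": 1,
            "backbone_id": classifier.backbone_id,
            "input_size": classifier.input_size,
            "trainable_policy": classifier.trainable_policy,
            "seed": classifier.seed,
        }
    )
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **classifier.state_dict())
    return path


def load_checkpoint(path: str | Path) -> TileClassifier:
    path = Path(path)
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    clf = TileClassifier(
        backbone_id=meta["backbone_id"],
        input_size=meta["input_size"],
        trainable_policy=meta["trainable_policy"],
        seed=meta["seed"],
    )
    clf.load_state_dict(state)
    return clf
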
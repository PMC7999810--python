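"""3D U-Net for patch-wise infarct segmentation: architecture, Dice loss, training.

The network is the classic encoder-decoder with skip connections, built for
cubic patches (e.g. 64x64x64x1 in, 64x64x64x2 out). Each level applies two
3x3x3 convolutions, each followed by ReLU and batch normalization; channel
counts double at every downsampling (2x2x2 max pool). The bridge applies two
convolutions and a 2x2x2 up-convolution; each decoder level up-convolves,
concatenates the matching encoder feature map, and applies two convolutions.
Dropout follows the second convolution block of every encoder and decoder
level. A final 1x1x1 convolution maps to two channels (background / lesion)
with a per-voxel softmax. Training minimises the soft Dice loss with Adam.

Implemented directly on the NumPy layer library in :mod:`infarctseg.nn`; all
randomness (weight init, shuffling, dropout) is keyed to ``config.seed``, so
a run is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .errors import InputError, ParameterError, ShapeError
from .patching import PatchSet
from .volumes import BinaryMask

__all__ = [
    "UNetConfig",
    "ModelHandle",
    "build_unet3d",
    "dice_loss",
    "train",
    "predict_patches",
    "save_model",
    "load_model",
]


@dataclass
class UNetConfig:
    """Architecture and training hyperparameters.

    Defaults follow the reference training setup: batch size 16, dropout 0.2,
    learning rate 0.001, 20 epochs, Adam, Dice loss. ``depth``/``base_filters``
    default to standard U-Net proportions for 64-voxel patches.
    """

    depth: int = 4
    base_filters: int = 16
    dropout_rate: float = 0.2
    batch_size: int = 16
    learning_rate: float = 0.001
    epochs: int = 20
    optimizer_name: str = "adam"
    loss_name: str = "dice"
    seed: int = 0
    patch_size: int = 64
    dice_smooth: float = 1.0

    def __post_init__(self):
        if self.depth < 1:
            raise ParameterError("depth must be >= 1")
        if self.base_filters < 1:
            raise ParameterError("base_filters must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ParameterError("dropout_rate must be in [0, 1)")
        if self.batch_size < 1 or self.epochs < 0 or self.learning_rate <= 0:
            raise ParameterError("invalid batch_size/epochs/learning_rate")
        if self.optimizer_name.lower() != "adam":
            raise ParameterError(f"unsupported optimizer: {self.optimizer_name}")
        if self.loss_name.lower() != "dice":
            raise ParameterError(f"unsupported loss: {self.loss_name}")
        if self.patch_size % (2 ** self.depth) != 0:
            raise ParameterError(
                f"patch edge {self.patch_size} not divisible by 2^depth = {2 ** self.depth}"
            )


class _ConvBlock:
    """(Conv3 -> ReLU -> BN) x 2."""

    def __init__(self, c_in: int, c_out: int, rng):
        self.layers = [
            nn.Conv3d(c_in, c_out, 3, rng),
            nn.ReLU(),
            nn.BatchNorm3d(c_out),
            nn.Conv3d(c_out, c_out, 3, rng),
            nn.ReLU(),
            nn.BatchNorm3d(c_out),
        ]

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class _UNet3D:
    """The wired network; holds every layer and the shared dropout generator."""

    def __init__(self, config: UNetConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        d, bf = config.depth, config.base_filters
        self.enc_blocks, self.enc_drops, self.pools = [], [], []
        c_in = 1
        for i in range(d):
            c_out = bf * 2 ** i
            self.enc_blocks.append(_ConvBlock(c_in, c_out, rng))
            self.enc_drops.append(nn.Dropout(config.dropout_rate))
            self.pools.append(nn.MaxPool3d())
            c_in = c_out
        self.bridge = _ConvBlock(c_in, bf * 2 ** d, rng)
        self.upconvs, self.dec_blocks, self.dec_drops = [], [], []
        c_prev = bf * 2 ** d
        for i in reversed(range(d)):
            c_out = bf * 2 ** i
            self.upconvs.append(nn.ConvTranspose3d(c_prev, c_out, rng))
            self.dec_blocks.append(_ConvBlock(2 * c_out, c_out, rng))
            self.dec_drops.append(nn.Dropout(config.dropout_rate))
            c_prev = c_out
        self.head = nn.Conv3d(bf, 2, 1, rng)
        # background-prior bias: start near the all-background solution so the
        # Dice denominator (sum of foreground probabilities) is small and
        # gradients on the rare lesion class are not drowned out
        self.head.b[:] = (2.0, -2.0)
        self.dropout_rng = np.random.default_rng(config.seed + 1)
        for drop in self.enc_drops + self.dec_drops:
            drop.rng = self.dropout_rng

    def _all_layers(self):
        layers = []
        for blk in self.enc_blocks:
            layers += blk.layers
        layers += self.bridge.layers
        layers += self.upconvs
        for blk in self.dec_blocks:
            layers += blk.layers
        layers.append(self.head)
        return layers

    def parameters(self):
        return [p for layer in self._all_layers() for p in layer.params]

    def gradients(self):
        return [g for layer in self._all_layers() for g in layer.grads]

    def zero_grad(self):
        for layer in self._all_layers():
            layer.zero_grad()

    def state(self) -> list[np.ndarray]:
        out = []
        for layer in self._all_layers():
            out += layer.params + layer.buffers
        return out

    def load_state(self, arrays: list[np.ndarray]):
        slots = []
        for layer in self._all_layers():
            slots += layer.params + layer.buffers
        if len(slots) != len(arrays):
            raise InputError(f"checkpoint has {len(arrays)} arrays, model expects {len(slots)}")
        for slot, arr in zip(slots, arrays):
            if slot.shape != arr.shape:
                raise ShapeError(f"checkpoint array {arr.shape} != model slot {slot.shape}")
            slot[...] = arr

    def forward_logits(self, x: np.ndarray, training: bool) -> np.ndarray:
        d = self.config.depth
        skips = []
        h = x
        for i in range(d):
            h = self.enc_blocks[i].forward(h, training)
            h = self.enc_drops[i].forward(h, training)
            skips.append(h)
            h = self.pools[i].forward(h, training)
        h = self.bridge.forward(h, training)
        self._skip_channels = []
        for j, i in enumerate(reversed(range(d))):
            h = self.upconvs[j].forward(h, training)
            skip = skips[i]
            self._skip_channels.append(h.shape[1])
            h = np.concatenate([skip, h], axis=1)
            h = self.dec_blocks[j].forward(h, training)
            h = self.dec_drops[j].forward(h, training)
        return self.head.forward(h, training)

    def backward(self, g_logits: np.ndarray):
        d = self.config.depth
        g = self.head.backward(g_logits)
        skip_grads = [None] * d
        for j in reversed(range(d)):
            i = d - 1 - j  # encoder level that fed this decoder step
            g = self.dec_drops[j].backward(g)
            g = self.dec_blocks[j].backward(g)
            c_up = self._skip_channels[j]
            g_skip, g_up = g[:, :-c_up], g[:, -c_up:]
            skip_grads[i] = g_skip
            g = self.upconvs[j].backward(np.ascontiguousarray(g_up))
        g = self.bridge.backward(g)
        for i in reversed(range(d)):
            g = self.pools[i].backward(g)
            g = g + skip_grads[i]
            g = self.enc_drops[i].backward(g)
            g = self.enc_blocks[i].backward(g)
        return g


@dataclass
class ModelHandle:
    """Opaque trained-model handle: network, config, per-epoch loss history."""

    net: _UNet3D = field(repr=False)
    config: UNetConfig
    history: list[dict] = field(default_factory=list)

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        """Softmax class probabilities for a (B, D, H, W) or (D, H, W) patch array."""
        x = np.asarray(patches, dtype=nn.DTYPE)
        squeeze = x.ndim == 3
        if squeeze:
            x = x[None]
        if x.ndim != 4:
            raise ShapeError(f"expected (B, D, H, W) patches, got shape {x.shape}")
        logits = self.net.forward_logits(x[:, None], training=False)
        p = _softmax_channels(logits)
        return p[0] if squeeze else p


def _softmax_channels(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_unet3d(config: UNetConfig | None = None) -> ModelHandle:
    """Construct an untrained 3D U-Net from a configuration (weights seeded)."""
    config = config or UNetConfig()
    return ModelHandle(net=_UNet3D(config), config=config, history=[])


def dice_loss(probabilities: np.ndarray, target, smooth: float = 1.0) -> float:
    """Soft Dice loss 1 - (2*sum(p*t) + eps) / (sum(p) + sum(t) + eps).

    ``probabilities`` is the per-voxel foreground probability grid; ``target``
    a binary mask of the same shape. For hard probabilities and eps = 0 this
    is exactly 1 - DSC.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    t = np.asarray(target.data if isinstance(target, BinaryMask) else target, dtype=np.float64)
    if p.shape != t.shape:
        raise ShapeError(f"probabilities {p.shape} vs target {t.shape}")
    if np.any(np.isnan(p)) or np.any(np.isnan(t)):
        raise InputError("NaN in dice_loss input")
    if p.min() < 0 or p.max() > 1:
        raise InputError("probabilities must lie in [0, 1]")
    num = 2.0 * (p * t).sum() + smooth
    den = p.sum() + t.sum() + smooth
    return float(1.0 - num / den)


def _dice_loss_and_grad(p1: np.ndarray, t: np.ndarray, smooth: float):
    """Soft Dice over the whole batch; returns (loss, dL/dp1)."""
    num = 2.0 * (p1 * t).sum() + smooth
    den = p1.sum() + t.sum() + smooth
    loss = 1.0 - num / den
    dp1 = -(2.0 * t * den - num) / den ** 2
    return float(loss), dp1.astype(nn.DTYPE)


def _prepare_pairs(pairs) -> tuple[np.ndarray, np.ndarray]:
    """Accepts (PatchSet, PatchSet) pairs or explicit (image, mask) array pairs."""
    xs, ts = [], []
    for img, msk in pairs:
        if isinstance(img, PatchSet):
            mask_by_serial = {rid: patch for rid, patch in msk.patches}
            for rid, patch in img.patches:
                xs.append(np.asarray(patch, dtype=nn.DTYPE))
                m = mask_by_serial.get(rid)
                if m is None:  # mask patch pruned on the image side only
                    m = np.zeros_like(patch)
                ts.append(np.asarray(m, dtype=nn.DTYPE))
        else:
            xs.append(np.asarray(img, dtype=nn.DTYPE))
            ts.append(np.asarray(msk.data if isinstance(msk, BinaryMask) else msk, dtype=nn.DTYPE))
    if not xs:
        raise InputError("no training patches")
    return np.stack(xs), np.stack(ts)


def _epoch_eval_loss(net: _UNet3D, x: np.ndarray, t: np.ndarray, batch: int, smooth: float) -> float:
    losses = []
    for s in range(0, len(x), batch):
        p = _softmax_channels(net.forward_logits(x[s : s + batch, None], training=False))
        loss, _ = _dice_loss_and_grad(p[:, 1], t[s : s + batch], smooth)
        losses.append(loss)
    return float(np.mean(losses))


def train(model: ModelHandle, train_pairs, val_pairs=None, config: UNetConfig | None = None) -> ModelHandle:
    """Mini-batch Adam training with soft Dice loss.

    ``train_pairs``/``val_pairs`` are sequences of (image PatchSet, mask
    PatchSet) pairs, or of raw (patch, mask-patch) array pairs. History
    records mean training and validation loss per epoch; the weights of the
    epoch with the lowest validation loss are restored at the end (final
    weights are kept when there is no validation set). ``epochs = 0`` returns
    the model unchanged with empty history.
    """
    config = config or model.config
    net = model.net
    x_train, t_train = _prepare_pairs(train_pairs)
    if x_train.shape[1:] != (config.patch_size,) * 3:
        raise ShapeError(
            f"training patches {x_train.shape[1:]} != configured patch size {(config.patch_size,) * 3}"
        )
    has_val = bool(val_pairs)
    if has_val:
        x_val, t_val = _prepare_pairs(val_pairs)
    if config.epochs == 0:
        model.history = []
        return model

    rng = np.random.default_rng(config.seed + 2)
    opt = nn.Adam(net.parameters(), lr=config.learning_rate)
    history: list[dict] = []
    best_val = np.inf
    best_state: list[np.ndarray] | None = None

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(x_train))
        epoch_losses = []
        for s in range(0, len(order), config.batch_size):
            idx = order[s : s + config.batch_size]
            xb, tb = x_train[idx], t_train[idx]
            net.zero_grad()
            logits = net.forward_logits(xb[:, None], training=True)
            p = _softmax_channels(logits)
            loss, dp1 = _dice_loss_and_grad(p[:, 1], tb, config.dice_smooth)
            # softmax backward for the 2-channel case collapses to +/- one grad
            g1 = dp1 * p[:, 1] * p[:, 0]
            g_logits = np.stack([-g1, g1], axis=1).astype(nn.DTYPE)
            net.backward(g_logits)
            opt.step(net.gradients())
            epoch_losses.append(loss)
        record = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}
        if has_val:
            val_loss = _epoch_eval_loss(net, x_val, t_val, config.batch_size, config.dice_smooth)
            record["val_loss"] = val_loss
            if val_loss < best_val:
                best_val = val_loss
                best_state = [a.copy() for a in net.state()]
        else:
            record["val_loss"] = float("nan")
        history.append(record)

    if best_state is not None:
        net.load_state(best_state)
    model.history = history
    return model


def predict_patches(model: ModelHandle, patches: PatchSet) -> list[tuple[str, np.ndarray]]:
    """Segment every retained patch: argmax over the two softmax channels.

    Returns (reference_id, {0,1} label grid) pairs in patch order. Inference
    is deterministic (dropout disabled, running batch-norm statistics).
    """
    out = []
    p_edge = model.config.patch_size
    batch = model.config.batch_size
    items = patches.patches
    for s in range(0, len(items), batch):
        chunk = items[s : s + batch]
        arr = np.stack([np.asarray(patch, dtype=nn.DTYPE) for _, patch in chunk])
        if arr.shape[1:] != (p_edge,) * 3:
            raise ShapeError(f"patch shape {arr.shape[1:]} != model patch size {(p_edge,) * 3}")
        proba = model.predict_proba(arr)
        labels = np.argmax(proba, axis=1).astype(np.uint8)
        out += [(rid, lab) for (rid, _), lab in zip(chunk, labels)]
    return out


def save_model(model: ModelHandle, path) -> None:
    """Checkpoint: .npz of all weights/buffers + JSON sidecar (config, history)."""
    path = Path(path)
    arrays = {f"arr_{i}": a for i, a in enumerate(model.net.state())}
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {"config": asdict(model.config), "history": model.history}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_model(path) -> ModelHandle:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = UNetConfig(**sidecar["config"])
    model = build_unet3d(config)
    with np.load(path.with_suffix(".npz")) as data:
        arrays = [data[f"arr_{i}"] for i in range(len(data.files))]
    model.net.load_state(arrays)
    model.history = sidecar["history"]
    return model
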
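"""3D residual UNet for voxel classification of cocoon CT volumes.

The segmenter is an encoder-decoder with skip connections.  Each depth is a
residual unit of two 3x3x3 convolutions, each followed by batch
normalization and a parametric rectified linear activation, with an identity
(or 1x1x1 projection) shortcut around the pair.  Downsampling uses stride-2
convolution at every depth after the first, so the default 5-depth network
with 16/32/64/128/256 filters takes a 96^3 patch down to 6^3 at the
bottleneck; upsampling uses stride-matched transposed convolutions, and the
decoder concatenates the encoder feature maps at the same depth.  The head
is a 1x1x1 convolution to one score per class (background, healthy cocoon,
parasitoid cocoon), trained with a soft-Dice loss over the foreground
classes and Adam.

Whole volumes are segmented by sliding-window inference with Gaussian patch
blending, since training operates on patches but counting needs the full
volume.
"""

from __future__ import annotations

import copy
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .preprocessing import (AugmentationParams, ClipWindow, clip_normalize,
                            sample_patches)


@dataclass
class ModelSpec:
    """Architecture hyperparameters.

    The default mirrors the production configuration: 5 depths with 16, 32,
    64, 128 and 256 filters, stride 2 everywhere, two convolutions per depth
    with residual shortcuts, batch norm and PReLU, softmax over 3 classes.
    """

    depths: int = 5
    filters_per_depth: tuple[int, ...] = (16, 32, 64, 128, 256)
    downsample_stride: int = 2
    convs_per_depth: int = 2
    n_classes: int = 3
    input_channels: int = 1

    def __post_init__(self) -> None:
        if len(self.filters_per_depth) != self.depths:
            raise ValueError("filters_per_depth length must equal depths")
        if any(b <= a for a, b in zip(self.filters_per_depth, self.filters_per_depth[1:])):
            raise ValueError("filters_per_depth must be strictly increasing")

    @classmethod
    def tiny(cls) -> "ModelSpec":
        """Reduced profile (3 depths, 8/16/32 filters) for CPU-scale runs."""
        return cls(depths=3, filters_per_depth=(8, 16, 32))


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    epochs: int = 100
    batch_size: int = 2
    patches_per_volume: int = 4
    seed: int = 0
    patch_size: int = 96
    clip_window: ClipWindow = field(default_factory=ClipWindow)
    foreground_bias: float = 0.5
    augmentation: AugmentationParams | None = None
    dice_smooth: float = 1e-5
    include_background: bool = False
    val_interval: int = 1
    val_overlap: float = 0.0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


class _ResidualUnit:
    """conv-BN-PReLU twice, plus an identity/projection shortcut."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, rng: np.random.Generator):
        self.conv1 = nn.Conv3d(in_ch, out_ch, 3, stride, rng=rng)
        self.bn1 = nn.BatchNorm3d(out_ch)
        self.act1 = nn.PReLU(out_ch)
        self.conv2 = nn.Conv3d(out_ch, out_ch, 3, 1, rng=rng)
        self.bn2 = nn.BatchNorm3d(out_ch)
        self.act2 = nn.PReLU(out_ch)
        if in_ch != out_ch or stride != 1:
            self.proj = nn.Conv3d(in_ch, out_ch, 1, stride, padding=0, rng=rng)
        else:
            self.proj = None

    def layers(self):
        out = [self.conv1, self.bn1, self.act1, self.conv2, self.bn2, self.act2]
        if self.proj is not None:
            out.append(self.proj)
        return out

    def forward(self, x, training=False):
        y = self.conv1.forward(x, training)
        y = self.bn1.forward(y, training)
        y = self.act1.forward(y, training)
        y = self.conv2.forward(y, training)
        y = self.bn2.forward(y, training)
        y = self.act2.forward(y, training)
        r = x if self.proj is None else self.proj.forward(x, training)
        return y + r

    def backward(self, dy):
        d = self.act2.backward(dy)
        d = self.bn2.backward(d)
        d = self.conv2.backward(d)
        d = self.act1.backward(d)
        d = self.bn1.backward(d)
        d = self.conv1.backward(d)
        if self.proj is None:
            return d + dy
        return d + self.proj.backward(dy)


class ResidualUNet3D:
    """The assembled network; see the module docstring for the layout."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        f = spec.filters_per_depth
        s = spec.downsample_stride
        self.encoders = [_ResidualUnit(spec.input_channels, f[0], 1, rng)]
        for i in range(1, spec.depths):
            self.encoders.append(_ResidualUnit(f[i - 1], f[i], s, rng))
        self.upconvs = []
        self.decoders = []
        for i in range(spec.depths - 2, -1, -1):
            self.upconvs.append(nn.ConvTranspose3d(f[i + 1], f[i], kernel=s, rng=rng))
            self.decoders.append(_ResidualUnit(2 * f[i], f[i], 1, rng))
        self.head = nn.Conv3d(f[0], spec.n_classes, 1, 1, padding=0, rng=rng)
        self._skip_grads = None

    # -- plumbing ---------------------------------------------------------
    def _units(self):
        for enc in self.encoders:
            yield from enc.layers()
        for up, dec in zip(self.upconvs, self.decoders):
            yield up
            yield from dec.layers()
        yield self.head

    def params(self) -> list[nn.Param]:
        out = []
        for layer in self._units():
            out.extend(layer.params())
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(p.val.size for p in self.params()))

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, p in enumerate(self.params()):
            state[f"param_{i:04d}"] = p.val
        bns = [l for l in self._units() if isinstance(l, nn.BatchNorm3d)]
        for i, bn in enumerate(bns):
            state[f"bn_{i:04d}_mean"] = bn.running_mean
            state[f"bn_{i:04d}_var"] = bn.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.val = np.array(state[f"param_{i:04d}"], dtype=nn.DTYPE)
            p.grad = np.zeros_like(p.val)
        bns = [l for l in self._units() if isinstance(l, nn.BatchNorm3d)]
        for i, bn in enumerate(bns):
            bn.running_mean = np.array(state[f"bn_{i:04d}_mean"], dtype=nn.DTYPE)
            bn.running_var = np.array(state[f"bn_{i:04d}_var"], dtype=nn.DTYPE)

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """(N, 1, D, H, W) -> (N, n_classes, D, H, W) logits."""
        skips = []
        for i, enc in enumerate(self.encoders):
            x = enc.forward(x, training)
            if i < self.spec.depths - 1:
                skips.append(x)
        for up, dec in zip(self.upconvs, self.decoders):
            x = up.forward(x, training)
            skip = skips.pop()
            x = np.concatenate([x, skip], axis=1)
            x = dec.forward(x, training)
        return self.head.forward(x, training)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        skip_grads = []
        # decoders were applied shallow-last; walk them in reverse of forward
        for up, dec in zip(self.upconvs[::-1], self.decoders[::-1]):
            d = dec.backward(d)
            c = up.out_ch
            d_up, d_skip = d[:, :c], d[:, c:]
            skip_grads.append(d_skip)
            d = up.backward(np.ascontiguousarray(d_up))
        # backward walked decoders shallowest-first, so skip_grads[i] is the
        # gradient arriving at encoder depth i's output via its skip
        d = self.encoders[-1].backward(d)
        for i in range(self.spec.depths - 2, -1, -1):
            d = d + skip_grads[i]
            d = self.encoders[i].backward(d)

    def predict_proba_patch(self, patch: np.ndarray) -> np.ndarray:
        """Softmax probabilities for one normalized (D, H, W) patch."""
        logits = self.forward(patch[None, None].astype(nn.DTYPE), training=False)
        return nn.softmax(logits)[0]


def build_model(spec: ModelSpec | None = None, seed: int = 0) -> ResidualUNet3D:
    return ResidualUNet3D(spec or ModelSpec(), seed=seed)


dice_loss = nn.dice_loss


def foreground_dice(pred_labels: np.ndarray, true_labels: np.ndarray) -> float:
    """Dice of the foreground union (any cocoon class vs background)."""
    p = pred_labels > 0
    g = true_labels > 0
    denom = p.sum() + g.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, g).sum() / denom)


def train(model: ResidualUNet3D, train_volumes, val_volumes, config: TrainConfig):
    """Train on (HU volume, label volume) pairs; returns (model, log).

    Per epoch, ``patches_per_volume`` foreground-biased patches are drawn
    from every training volume, optionally augmented, and optimized in
    mini-batches with Adam.  Validation foreground Dice is computed every
    ``val_interval`` epochs by tiled whole-volume prediction, and the
    best-validation checkpoint is restored at the end.
    """
    if not train_volumes:
        raise ValueError("at least one training volume required")
    if not any((lab > 0).any() for _, lab in train_volumes):
        raise ValueError("training volumes contain no foreground labels")
    rng = np.random.default_rng(config.seed)
    norm_train = [(clip_normalize(img, config.clip_window), lab) for img, lab in train_volumes]
    opt = nn.Adam(model.params(), lr=config.learning_rate, weight_decay=config.weight_decay)
    log = []
    best = {"dice": -1.0, "state": None, "epoch": 0}
    for epoch in range(1, config.epochs + 1):
        pairs = []
        for img, lab in norm_train:
            pairs.extend(sample_patches(img, lab, size=config.patch_size,
                                        n_patches=config.patches_per_volume,
                                        foreground_bias=config.foreground_bias, rng=rng))
        if config.augmentation is not None:
            from .preprocessing import augment
            pairs = [augment(p, config.augmentation, rng) for p in pairs]
        order = rng.permutation(len(pairs))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [pairs[i] for i in order[start:start + config.batch_size]]
            x = np.stack([p.image for p in batch])[:, None].astype(nn.DTYPE)
            y = np.stack([p.labels for p in batch]).astype(np.int64)
            logits = model.forward(x, training=True)
            loss, dlogits = nn.softmax_dice_loss(
                logits, y, model.spec.n_classes,
                smooth=config.dice_smooth, include_background=config.include_background)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}")
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_dice": None}
        if val_volumes and epoch % config.val_interval == 0:
            dices = []
            for img, lab in val_volumes:
                probs = predict_volume(model, img, config.clip_window,
                                       patch_size=config.patch_size,
                                       overlap=config.val_overlap)
                pred = probs.argmax(axis=0)
                dices.append(foreground_dice(pred, lab))
            entry["val_dice"] = float(np.mean(dices))
            if entry["val_dice"] > best["dice"]:
                best = {"dice": entry["val_dice"],
                        "state": copy.deepcopy(model.state_dict()), "epoch": epoch}
        log.append(entry)
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    return model, log


def _gaussian_importance(patch_size: int) -> np.ndarray:
    coords = np.arange(patch_size) - (patch_size - 1) / 2.0
    sigma = patch_size / 8.0
    g = np.exp(-0.5 * (coords / sigma) ** 2)
    w = g[:, None, None] * g[None, :, None] * g[None, None, :]
    return (w / w.max()).astype(np.float32) + 1e-6


def predict_volume(model: ResidualUNet3D, volume: np.ndarray,
                   window: ClipWindow = ClipWindow(), patch_size: int = 96,
                   overlap: float = 0.25) -> np.ndarray:
    """Sliding-window softmax prediction for a whole HU volume.

    Overlapping patch predictions are blended with a Gaussian importance
    map; the result is renormalized per voxel so class probabilities sum to
    one.  Volumes smaller than the patch are padded with the window floor
    and cropped back.
    """
    img = clip_normalize(volume, window)
    orig_shape = img.shape
    pads = [(0, max(patch_size - s, 0)) for s in img.shape]
    if any(p[1] for p in pads):
        img = np.pad(img, pads, constant_values=0.0)
    shape = img.shape
    stride = max(1, int(round(patch_size * (1.0 - overlap))))
    starts = []
    for s in shape:
        pos = list(range(0, s - patch_size + 1, stride))
        if pos[-1] != s - patch_size:
            pos.append(s - patch_size)
        starts.append(pos)
    acc = np.zeros((model.spec.n_classes,) + shape, dtype=np.float64)
    wsum = np.zeros(shape, dtype=np.float64)
    w = _gaussian_importance(patch_size)
    for z0 in starts[0]:
        for y0 in starts[1]:
            for x0 in starts[2]:
                sl = (slice(z0, z0 + patch_size), slice(y0, y0 + patch_size),
                      slice(x0, x0 + patch_size))
                probs = model.predict_proba_patch(img[sl])
                acc[(slice(None),) + sl] += probs * w
                wsum[sl] += w
    acc /= wsum
    acc = acc[:, :orig_shape[0], :orig_shape[1], :orig_shape[2]]
    acc /= acc.sum(axis=0, keepdims=True)
    return acc.astype(np.float32)


# -- checkpointing --------------------------------------------------------

def save_checkpoint(path: str | os.PathLike, model: ResidualUNet3D,
                    config: TrainConfig | None = None) -> None:
    """Write weights (.npz) plus a JSON sidecar embedding the full ModelSpec
    and TrainConfig, so inference never guesses the architecture."""
    path = os.fspath(path)
    np.savez(path if path.endswith(".npz") else path + ".npz", **model.state_dict())
    sidecar = {"model_spec": asdict(model.spec)}
    if config is not None:
        cfg = asdict(config)
        cfg["clip_window"] = {"lower": config.clip_window.lower,
                              "upper": config.clip_window.upper}
        sidecar["train_config"] = cfg
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)


def load_checkpoint(path: str | os.PathLike) -> ResidualUNet3D:
    path = os.fspath(path)
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json") as fh:
        sidecar = json.load(fh)
    ms = sidecar["model_spec"]
    ms["filters_per_depth"] = tuple(ms["filters_per_depth"])
    model = ResidualUNet3D(ModelSpec(**ms))
    with np.load(base + ".npz") as npz:
        model.load_state_dict({k: npz[k] for k in npz.files})
    return model
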
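"""Intensity preprocessing, patch sampling and augmentation.

Raw CT volumes are clipped to a fixed Hounsfield window (default -1000..600,
spanning air through silk, tissue and the plastic box) and rescaled to
[0, 1].  Training operates on cubic patches (default 96 voxels per edge)
sampled with a configurable bias toward patches that contain foreground,
since a packed-box scan is mostly air.  Augmentation applies the same random
rigid/zoom transform to image and labels (labels via nearest neighbour) and
intensity perturbations to the image only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class ClipWindow:
    """HU clipping window; the default spans -1000 to 600 HU."""

    lower: float = -1000.0
    upper: float = 600.0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"invalid clip window [{self.lower}, {self.upper}]")


@dataclass
class PatchPair:
    """A normalized image patch and its integer label patch (same shape)."""

    image: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        if self.image.shape != self.labels.shape:
            raise ValueError("image and labels must share a shape")

    @property
    def size(self) -> int:
        return self.image.shape[0]


@dataclass
class AugmentationParams:
    """Magnitudes for the random transforms.

    The transform family is rotation, flipping and zooming along all axes
    plus Gaussian noise and smoothing on the image; magnitudes are package
    defaults (see methods note) and fully configurable.
    """

    rotation_range: float = 15.0  # degrees, per axis pair
    flip_probability: float = 0.5  # per axis
    zoom_range: tuple[float, float] = (0.9, 1.1)
    noise_sd_range: tuple[float, float] = (0.0, 0.05)  # normalized intensity units
    smoothing_sigma_range: tuple[float, float] = (0.0, 1.0)  # voxels

    def __post_init__(self) -> None:
        if self.zoom_range[0] > self.zoom_range[1]:
            raise ValueError("zoom range min > max")
        if not 0.0 <= self.flip_probability <= 1.0:
            raise ValueError("flip probability must be in [0, 1]")


def clip_normalize(volume: np.ndarray, window: ClipWindow = ClipWindow()) -> np.ndarray:
    """Clip to the HU window and rescale linearly so lower -> 0 and upper -> 1."""
    volume = np.asarray(volume)
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains non-finite voxels")
    clipped = np.clip(volume, window.lower, window.upper)
    return ((clipped - window.lower) / (window.upper - window.lower)).astype(np.float32)


def _pad_to(volume: np.ndarray, size: int, value: float = 0.0) -> np.ndarray:
    pads = []
    for s in volume.shape:
        short = max(size - s, 0)
        pads.append((short // 2, short - short // 2))
    if any(p != (0, 0) for p in pads):
        volume = np.pad(volume, pads, constant_values=value)
    return volume


def sample_patches(image: np.ndarray, labels: np.ndarray, size: int = 96,
                   n_patches: int = 1, foreground_bias: float = 0.5,
                   rng: np.random.Generator | None = None) -> list[PatchPair]:
    """Sample ``n_patches`` aligned image/label patches of edge ``size``.

    A fraction ``foreground_bias`` of the patches is centred near a randomly
    chosen foreground voxel (when any exists), the rest are uniform.  Volumes
    smaller than the patch are padded symmetrically with background.
    """
    if n_patches <= 0:
        raise ValueError("n_patches must be positive")
    rng = rng or np.random.default_rng()
    image = _pad_to(image, size)
    labels = _pad_to(labels, size)
    fg = np.argwhere(labels > 0)
    shape = np.asarray(image.shape)
    max_corner = shape - size
    n_fg = int(np.ceil(foreground_bias * n_patches)) if fg.size else 0
    out = []
    for i in range(n_patches):
        want_fg = i < n_fg
        if want_fg:
            voxel = fg[rng.integers(len(fg))]
            lo = voxel - rng.integers(0, size, size=3)
            corner = np.clip(lo, 0, max_corner)
        else:
            corner = np.array([rng.integers(0, m + 1) for m in max_corner])
        sl = tuple(slice(int(c), int(c) + size) for c in corner)
        out.append(PatchPair(image=image[sl].copy(), labels=labels[sl].copy()))
    return out


def augment(pair: PatchPair, params: AugmentationParams,
            rng: np.random.Generator | None = None) -> PatchPair:
    """Apply one random draw of the augmentation family to a patch pair.

    Spatial transforms (flip, rotation, zoom) act identically on image and
    labels; labels are interpolated nearest-neighbour so no new classes can
    appear (background may, from out-of-field padding).  Noise and smoothing
    perturb the image only.  No-op draws short-circuit, so identity
    parameters return the input unchanged.
    """
    rng = rng or np.random.default_rng()
    img, lab = pair.image, pair.labels

    for ax in range(3):
        if rng.random() < params.flip_probability:
            img = np.flip(img, axis=ax)
            lab = np.flip(lab, axis=ax)

    for axes in ((0, 1), (0, 2), (1, 2)):
        angle = float(rng.uniform(-params.rotation_range, params.rotation_range))
        if abs(angle) > 1e-9:
            img = ndimage.rotate(img, angle, axes=axes, reshape=False, order=1,
                                 mode="constant", cval=0.0)
            lab = ndimage.rotate(lab, angle, axes=axes, reshape=False, order=0,
                                 mode="constant", cval=0)

    zoom = float(rng.uniform(*params.zoom_range))
    if abs(zoom - 1.0) > 1e-9:
        size = pair.image.shape
        img = ndimage.zoom(img, zoom, order=1, mode="constant", cval=0.0)
        lab = ndimage.zoom(lab, zoom, order=0, mode="constant", cval=0)
        img = _crop_or_pad(img, size)
        lab = _crop_or_pad(lab, size)

    sigma = float(rng.uniform(*params.smoothing_sigma_range))
    if sigma > 1e-9:
        img = ndimage.gaussian_filter(img, sigma=sigma)
    noise_sd = float(rng.uniform(*params.noise_sd_range))
    if noise_sd > 1e-12:
        img = img + rng.normal(0.0, noise_sd, size=img.shape).astype(np.float32)

    return PatchPair(image=np.ascontiguousarray(img, dtype=np.float32),
                     labels=np.ascontiguousarray(lab))


def _crop_or_pad(volume: np.ndarray, target: tuple[int, ...]) -> np.ndarray:
    for ax, t in enumerate(target):
        s = volume.shape[ax]
        if s > t:
            start = (s - t) // 2
            volume = np.take(volume, range(start, start + t), axis=ax)
        elif s < t:
            pads = [(0, 0)] * volume.ndim
            short = t - s
            pads[ax] = (short // 2, short - short // 2)
            volume = np.pad(volume, pads, constant_values=0)
    return volume
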
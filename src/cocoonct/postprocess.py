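"""From probability maps to cocoon counts.

The segmenter's softmax output is thresholded (default 0.8) into class
labels, enclosed air cavities in the segmentation are filled (cocoon
interiors are largely air, so genuine cocoons come out hollow), instances
are separated per class — plain connected components, or a distance-
transform watershed that can split touching cocoons — and the surviving
instances are tallied into per-sample counts and a parasitoid rate.

The parasitoid rate is 100 * parasitoid / healthy per sample, displayed with
two decimals (half away from zero).  With no healthy cocoons the rate is
flagged undefined rather than raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import local_maxima, reconstruction
from skimage.segmentation import watershed

FOREGROUND_CLASSES = (1, 2)  # healthy, parasitoid
CLASS_NAMES = {1: "healthy", 2: "parasitoid"}


@dataclass
class PostprocessConfig:
    probability_threshold: float = 0.8
    cavity_min_size: int = 5  # voxels; see fill_cavities for how it is applied
    connectivity: int = 3  # ndimage connectivity rank: 3 = full 26-neighbourhood
    min_instance_volume: int = 27  # 3^3 voxels, suppresses speckle
    instance_method: str = "watershed"  # or "components"
    watershed_h: float = 1.5  # depth (voxels) a distance-map peak must have

    def __post_init__(self) -> None:
        if not 0.0 < self.probability_threshold < 1.0:
            raise ValueError("probability_threshold must be in (0, 1)")
        if self.cavity_min_size < 0:
            raise ValueError("cavity_min_size must be non-negative")
        if self.instance_method not in ("components", "watershed"):
            raise ValueError(f"unknown instance method {self.instance_method!r}")


@dataclass
class CountRecord:
    """Per-sample counting result."""

    sample_id: str
    healthy: int
    parasitoid: int
    rate_undefined: bool = False

    def __post_init__(self) -> None:
        if self.healthy < 0 or self.parasitoid < 0:
            raise ValueError("counts must be non-negative")
        if self.healthy == 0:
            self.rate_undefined = True

    @property
    def parasitoid_rate(self) -> float | None:
        """Raw (unrounded) rate in percent; None when undefined."""
        if self.healthy == 0:
            return None
        return 100.0 * self.parasitoid / self.healthy

    @property
    def parasitoid_rate_display(self) -> float | None:
        r = self.parasitoid_rate
        return None if r is None else round_half_up(r, 2)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero to ``ndigits`` decimals."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def parasitoid_rate(healthy: int, parasitoid: int) -> float | None:
    """Percent parasitized relative to the healthy count, display-rounded.

    Returns None (undefined) when the healthy count is zero.
    """
    if healthy < 0 or parasitoid < 0:
        raise ValueError("counts must be non-negative")
    if healthy == 0:
        return None
    return round_half_up(100.0 * parasitoid / healthy, 2)


def binarize_classes(probs: np.ndarray, config: PostprocessConfig = PostprocessConfig()) -> np.ndarray:
    """Threshold a (C, D, H, W) probability volume into class labels.

    A voxel is foreground only where a foreground class reaches the
    threshold; if both do, the larger probability wins and exact ties go to
    healthy (conservative for the parasitoid rate).
    """
    t = config.probability_threshold
    p1, p2 = probs[1], probs[2]
    labels = np.zeros(probs.shape[1:], dtype=np.uint8)
    labels[p1 >= t] = 1
    labels[(p2 >= t) & (p2 > p1)] = 2
    return labels


def fill_cavities(labels: np.ndarray, config: PostprocessConfig = PostprocessConfig()) -> np.ndarray:
    """Fill enclosed background cavities with the surrounding class.

    Background components that do not reach the volume border are assigned
    the majority class among their touching foreground voxels (all enclosed
    cavities are filled, not only those above ``cavity_min_size``; small
    ones are harmless for counting and filling them keeps the operator
    idempotent).  Background connected to the border is never filled.
    """
    out = labels.copy()
    bg = out == 0
    if not bg.any():
        return out
    # 6-connectivity for background, the complement of 26-connected foreground
    comp, n = ndimage.label(bg, structure=ndimage.generate_binary_structure(3, 1))
    border = np.zeros_like(bg)
    border[0], border[-1] = True, True
    border[:, 0], border[:, -1] = True, True
    border[:, :, 0], border[:, :, -1] = True, True
    border_ids = np.unique(comp[border & bg])
    enclosed = np.setdiff1d(np.arange(1, n + 1), border_ids)
    if enclosed.size == 0:
        return out
    objects = ndimage.find_objects(comp)
    struct = ndimage.generate_binary_structure(3, 3)
    for cid in enclosed:
        sl = objects[cid - 1]
        sl = tuple(slice(max(s.start - 1, 0), min(s.stop + 1, dim))
                   for s, dim in zip(sl, out.shape))
        mask = comp[sl] == cid
        ring = ndimage.binary_dilation(mask, structure=struct) & ~mask
        neighbours = out[sl][ring]
        neighbours = neighbours[neighbours > 0]
        if neighbours.size == 0:
            continue
        counts = np.bincount(neighbours, minlength=3)
        fill_class = 1 if counts[1] >= counts[2] else 2
        out[sl][mask] = fill_class
    return out


def _instances_components(mask: np.ndarray, struct) -> np.ndarray:
    lab, _ = ndimage.label(mask, structure=struct)
    return lab


def _instances_watershed(mask: np.ndarray, struct, h: float) -> np.ndarray:
    """Split a foreground mask into instances by distance-transform watershed.

    Seeds are the regional maxima of the h-reconstruction of the Euclidean
    distance map: peaks separated by saddles shallower than ``h`` merge into
    one plateau (so an isolated convex cocoon, whose discrete distance map
    may carry several equal ridge maxima, yields exactly one seed), while
    two touching cocoons with a neck deeper than ``h`` yield two.
    """
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    dist = ndimage.distance_transform_edt(mask)
    rec = reconstruction(dist - h, dist, method="dilation")
    peaks = local_maxima(rec, connectivity=3) & mask
    markers, n = ndimage.label(peaks, structure=struct)
    if n == 0:
        return _instances_components(mask, struct)
    return watershed(-dist, markers=markers, mask=mask).astype(np.int32)


def count_instances(labels: np.ndarray,
                    config: PostprocessConfig = PostprocessConfig(),
                    sample_id: str = "sample"):
    """Separate instances per class and tally them.

    Returns ``(instance_volume, id_to_class, record)``: instance IDs are
    consecutive across classes, instances smaller than
    ``min_instance_volume`` voxels are discarded as speckle.
    """
    struct = ndimage.generate_binary_structure(3, config.connectivity)
    instance_volume = np.zeros(labels.shape, dtype=np.int32)
    id_to_class: dict[int, int] = {}
    next_id = 1
    tallies = {c: 0 for c in FOREGROUND_CLASSES}
    for c in FOREGROUND_CLASSES:
        mask = labels == c
        if config.instance_method == "watershed":
            lab = _instances_watershed(mask, struct, config.watershed_h)
        else:
            lab = _instances_components(mask, struct)
        n_inst = int(lab.max())
        if n_inst == 0:
            continue
        sizes = np.bincount(lab.ravel(), minlength=n_inst + 1)
        remap = np.zeros(n_inst + 1, dtype=np.int32)
        for inst in range(1, n_inst + 1):
            if sizes[inst] < config.min_instance_volume:
                continue
            remap[inst] = next_id
            id_to_class[next_id] = c
            tallies[c] += 1
            next_id += 1
        instance_volume += remap[lab]
    record = CountRecord(sample_id=sample_id, healthy=tallies[1], parasitoid=tallies[2])
    return instance_volume, id_to_class, record


def count_from_probabilities(probs: np.ndarray,
                             config: PostprocessConfig = PostprocessConfig(),
                             sample_id: str = "sample"):
    """Full postprocessing chain: threshold, fill cavities, count."""
    labels = binarize_classes(probs, config)
    labels = fill_cavities(labels, config)
    return count_instances(labels, config, sample_id=sample_id)
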
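"""Synthetic CT phantoms of packed mason-bee cocoons.

A phantom emulates one compartment of the scanning box: densely packed
ellipsoidal cocoons on an air background.  Each cocoon is a thin silk shell;
a healthy cocoon contains one compact bee body, a parasitized cocoon contains
several small larvae.  Tissue contrast is modelled as per-tissue mean
Hounsfield values, with optional Gaussian blur (scanner point spread) and
additive Gaussian noise applied to the image only.  Every phantom carries an
exact per-cocoon ground truth, playing the role a full manual volumetric
count plays for a real scan.

Packing is by rejection sampling with a bounding-sphere overlap test — cheap
and conservative, so generated cocoons never touch.  Real cocoons do touch;
see the methods note for what that difference means for the tests.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .io import VolumeMeta, write_volume

HEALTHY, PARASITOID = "healthy", "parasitoid"
CLASS_IDS = {HEALTHY: 1, PARASITOID: 2}

#: Default per-tissue mean HU.  The real tissue distributions are unknown;
#: these stand-ins are separable yet all inside the standard clip window.
DEFAULT_HU = {"air": -1000.0, "shell": -400.0, "bee_body": 0.0,
              "larva": -100.0, "box_wall": 100.0}


class PackingError(RuntimeError):
    pass


@dataclass
class CocoonGeometry:
    """One ellipsoidal cocoon: center/semi-axes in voxel units, a rotation
    matrix mapping local to volume axes, and its class label."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    rotation: np.ndarray  # 3x3, local -> volume
    class_label: str

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive")
        if self.class_label not in CLASS_IDS:
            raise ValueError(f"unknown class label {self.class_label!r}")

    @property
    def bounding_radius(self) -> float:
        return float(max(self.semi_axes))

    def to_json(self) -> dict:
        return {
            "center": [round(float(c), 4) for c in self.center],
            "semi_axes": [round(float(a), 4) for a in self.semi_axes],
            "rotation": [[round(float(v), 6) for v in row] for row in self.rotation],
            "class_label": self.class_label,
        }


@dataclass
class PhantomSpec:
    """Generation parameters for one phantom volume.

    Defaults describe a desk-scale compartment: ~300 cocoons with semi-axes
    of roughly 2-8 mm at clinical CT spacing, moderate noise and blur.
    """

    volume_shape: tuple[int, int, int] = (192, 192, 192)
    voxel_spacing: tuple[float, float, float] = (0.8, 0.4, 0.4)  # mm (z, y, x)
    n_cocoons: int = 300
    parasitoid_fraction: float = 0.011  # overall rate observed in the field is ~1%
    semi_axis_range: tuple[tuple[float, float], ...] = ((6.0, 10.0), (4.0, 7.0), (4.0, 7.0))
    hu_model: dict = field(default_factory=lambda: dict(DEFAULT_HU))
    noise_sd: float = 30.0  # HU
    blur_sigma: float = 0.7  # voxels
    seed: int = 0
    min_gap: float = 2.0  # voxels kept free between bounding spheres
    wall_thickness: int = 0  # voxels of box wall lining the volume faces
    shell_fraction: float = 0.12  # shell thickness as fraction of each semi-axis
    content_fraction: float = 0.70  # scale of the interior content region
    larvae_range: tuple[int, int] = (3, 15)
    max_attempts_per_cocoon: int = 200

    def __post_init__(self) -> None:
        if not 0.0 <= self.parasitoid_fraction <= 1.0:
            raise ValueError("parasitoid_fraction must be in [0, 1]")
        if self.n_cocoons < 0:
            raise ValueError("n_cocoons must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for hu in self.hu_model.values():
            if not -1024.0 <= hu <= 3071.0:
                raise ValueError(f"tissue HU {hu} outside the representable CT range")
        if len(self.semi_axis_range) == 2 and np.isscalar(self.semi_axis_range[0]):
            self.semi_axis_range = (tuple(self.semi_axis_range),) * 3


@dataclass
class GroundTruth:
    """Exact per-volume truth: the list of cocoons and the class tallies."""

    instances: list[CocoonGeometry]
    healthy_count: int
    parasitoid_count: int

    @classmethod
    def from_geometries(cls, geoms: list[CocoonGeometry]) -> "GroundTruth":
        h = sum(1 for g in geoms if g.class_label == HEALTHY)
        return cls(instances=list(geoms), healthy_count=h, parasitoid_count=len(geoms) - h)

    def __post_init__(self) -> None:
        assert self.healthy_count + self.parasitoid_count == len(self.instances)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation from a normalized random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def place_cocoons(spec: PhantomSpec, rng: np.random.Generator) -> list[CocoonGeometry]:
    """Pack ``spec.n_cocoons`` non-overlapping ellipsoids into the volume.

    Overlap is tested on bounding spheres with ``spec.min_gap`` clearance, so
    accepted cocoons are strictly separated.  Class labels are assigned so the
    parasitoid tally is exactly round(n * parasitoid_fraction).
    """
    n = spec.n_cocoons
    if n == 0:
        return []
    shape = np.asarray(spec.volume_shape, dtype=float)
    ranges = np.asarray(spec.semi_axis_range, dtype=float)

    n_para = _round_half_up(n * spec.parasitoid_fraction)
    labels = np.array([PARASITOID] * n_para + [HEALTHY] * (n - n_para))
    labels = labels[rng.permutation(n)]

    centers = np.empty((0, 3))
    radii = np.empty(0)
    geoms: list[CocoonGeometry] = []
    for i in range(n):
        placed = False
        for _ in range(spec.max_attempts_per_cocoon):
            semi = rng.uniform(ranges[:, 0], ranges[:, 1])
            r = float(semi.max())
            lo = r + spec.wall_thickness + 0.5
            hi = shape - 1 - lo
            if np.any(hi <= lo):
                break
            center = rng.uniform(lo, hi)
            if centers.size:
                d = np.linalg.norm(centers - center, axis=1)
                if np.any(d < radii + r + spec.min_gap):
                    continue
            centers = np.vstack([centers, center])
            radii = np.append(radii, r)
            geoms.append(CocoonGeometry(center=tuple(center), semi_axes=tuple(semi),
                                        rotation=_random_rotation(rng),
                                        class_label=str(labels[i])))
            placed = True
            break
        if not placed:
            occupied = sum(4.0 / 3.0 * math.pi * rr ** 3 for rr in radii)
            density = occupied / float(np.prod(shape))
            raise PackingError(
                f"failed to place cocoon {i + 1}/{n} after "
                f"{spec.max_attempts_per_cocoon} attempts "
                f"(attempted bounding-sphere density {density:.2f})")
    return geoms


def _local_coords(bbox_grids, center, rotation, semi_axes):
    """Normalized ellipsoid coordinates u for every voxel center in the bbox."""
    dz, dy, dx = (g - c for g, c in zip(bbox_grids, center))
    rt = rotation.T
    u = [rt[k, 0] * dz + rt[k, 1] * dy + rt[k, 2] * dx for k in range(3)]
    return [u[k] / semi_axes[k] for k in range(3)], (dz, dy, dx)


def rasterize(geometries: list[CocoonGeometry], spec: PhantomSpec,
              rng: np.random.Generator | None = None):
    """Render geometries into (HU volume, class-label volume, instance volume).

    The label volume marks every voxel of a cocoon (shell and interior alike)
    with its class; the instance volume assigns consecutive IDs 1..n in input
    order.  Blur and noise act on the HU image only.
    """
    rng = rng or np.random.default_rng(spec.seed)
    hu_model = spec.hu_model
    shape = tuple(int(s) for s in spec.volume_shape)
    hu = np.full(shape, hu_model["air"], dtype=np.float32)
    labels = np.zeros(shape, dtype=np.uint8)
    instances = np.zeros(shape, dtype=np.int32)

    t = spec.wall_thickness
    if t > 0:
        wall = np.zeros(shape, dtype=bool)
        for ax in range(3):
            sl = [slice(None)] * 3
            sl[ax] = slice(0, t)
            wall[tuple(sl)] = True
            sl[ax] = slice(shape[ax] - t, shape[ax])
            wall[tuple(sl)] = True
        hu[wall] = hu_model["box_wall"]

    f_shell_inner = 1.0 - spec.shell_fraction
    f_content = spec.content_fraction
    for idx, geom in enumerate(geometries, start=1):
        semi = np.asarray(geom.semi_axes)
        center = np.asarray(geom.center)
        r = geom.bounding_radius + 1.0
        lo = np.maximum(np.floor(center - r).astype(int), 0)
        hi = np.minimum(np.ceil(center + r).astype(int) + 1, shape)
        if np.any(hi <= lo):
            raise ValueError("cocoon bounding box outside the volume")
        grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        u, _ = _local_coords(grids, center, np.asarray(geom.rotation), semi)
        n2 = u[0] ** 2 + u[1] ** 2 + u[2] ** 2
        full = n2 <= 1.0
        box = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        labels[box][full] = CLASS_IDS[geom.class_label]
        instances[box][full] = idx

        hu_box = hu[box]
        hu_box[full] = hu_model["air"]  # interior between shell and content is air
        shell = full & (n2 >= f_shell_inner ** 2)
        hu_box[shell] = hu_model["shell"]
        if geom.class_label == HEALTHY:
            hu_box[n2 <= f_content ** 2] = hu_model["bee_body"]
        else:
            n_larvae = int(rng.integers(spec.larvae_range[0], spec.larvae_range[1] + 1))
            zz = grids[0] - center[0]
            yy = grids[1] - center[1]
            xx = grids[2] - center[2]
            min_semi = float(semi.min())
            for _ in range(n_larvae):
                lr = rng.uniform(0.10, 0.18) * min_semi
                max_u = max(f_content - lr / min_semi, 0.05)
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                u0 = direction * rng.uniform(0, max_u)
                lc = np.asarray(geom.rotation) @ (u0 * semi)
                d2 = (zz - lc[0]) ** 2 + (yy - lc[1]) ** 2 + (xx - lc[2]) ** 2
                hu_box[d2 <= lr ** 2] = hu_model["larva"]
        hu[box] = hu_box

    if spec.blur_sigma > 0:
        hu = ndimage.gaussian_filter(hu, sigma=spec.blur_sigma)
    if spec.noise_sd > 0:
        hu = hu + rng.normal(0.0, spec.noise_sd, size=hu.shape).astype(np.float32)
    return hu.astype(np.float32), labels, instances


def generate_phantom(spec: PhantomSpec):
    """Convenience wrapper: pack, rasterize and tally one phantom volume."""
    rng = np.random.default_rng(spec.seed)
    geoms = place_cocoons(spec, rng)
    hu, labels, instances = rasterize(geoms, spec, rng)
    return hu, labels, instances, GroundTruth.from_geometries(geoms)


def generate_dataset(template: PhantomSpec, out_dir: str | os.PathLike,
                     n_volumes: int, seed: int,
                     count_range: tuple[int, int] | None = None,
                     n_val: int = 0) -> list[dict]:
    """Write ``n_volumes`` phantoms (image/labels/instances NIfTI + JSON manifest).

    Per-volume seeds derive deterministically from the master seed.  When
    ``count_range`` is given, each volume's cocoon total is drawn uniformly
    from it, mirroring how real rearing compartments vary in fill level.  An
    optional train/validation split of the volume IDs is recorded in a
    dataset-level manifest.
    """
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    master = np.random.SeedSequence(seed)
    children = master.spawn(n_volumes + 1)
    manifests = []
    meta = VolumeMeta(voxel_spacing=template.voxel_spacing,
                      shape=tuple(template.volume_shape), source="synthetic")
    for v in range(n_volumes):
        rng = np.random.default_rng(children[v])
        n = template.n_cocoons
        if count_range is not None:
            n = int(rng.integers(count_range[0], count_range[1] + 1))
        spec = PhantomSpec(**{**asdict_shallow(template), "n_cocoons": n})
        geoms = place_cocoons(spec, rng)
        hu, labels, instances = rasterize(geoms, spec, rng)
        truth = GroundTruth.from_geometries(geoms)
        vid = f"{v:03d}"
        write_volume(os.path.join(out_dir, f"image_{vid}.nii.gz"), hu, meta)
        write_volume(os.path.join(out_dir, f"labels_{vid}.nii.gz"), labels, meta)
        write_volume(os.path.join(out_dir, f"instances_{vid}.nii.gz"), instances, meta)
        manifest = {
            "volume_id": vid,
            "n_cocoons": len(geoms),
            "healthy_count": truth.healthy_count,
            "parasitoid_count": truth.parasitoid_count,
            "instances": [g.to_json() for g in geoms],
        }
        with open(os.path.join(out_dir, f"manifest_{vid}.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        manifests.append(manifest)

    ids = [m["volume_id"] for m in manifests]
    split_rng = np.random.default_rng(children[n_volumes])
    if n_val > 0:
        order = split_rng.permutation(len(ids))
        val_ids = sorted(ids[i] for i in order[:n_val])
        train_ids = sorted(ids[i] for i in order[n_val:])
    else:
        train_ids, val_ids = ids, []
    with open(os.path.join(out_dir, "dataset.json"), "w") as fh:
        json.dump({"volumes": ids, "train": train_ids, "val": val_ids,
                   "seed": seed}, fh, indent=1, sort_keys=True)
    return manifests


def asdict_shallow(spec: PhantomSpec) -> dict:
    d = asdict(spec)
    return d
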
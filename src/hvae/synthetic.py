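"""Seeded synthetic datasets with known class structure and ground-truth
rotations.

Two generators mirror the two supported input kinds: rotated point-cloud
shape classes with positional noise (a stand-in for atomic neighborhoods),
and class-labeled spherical bump images on the Driscoll-Healy grid (a
stand-in for spherical image datasets).  Every dataset is a pure function of
its (spec, seed) pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .rotations import random_rotation
from .tensors import SteerableTensor, TensorSignature
from .transforms import (
    LabeledPointCloud,
    SphericalGridImage,
    ZFTConfig,
    dh_grid,
    zft_point_cloud,
    zft_spherical_image,
)

__all__ = [
    "BumpClassSpec",
    "ShapeClassSpec",
    "SyntheticDataset",
    "default_cloud_specs",
    "default_bump_specs",
    "encode_cloud_dataset",
    "encode_image_dataset",
    "make_cloud_dataset",
    "make_fixture_suite",
    "make_sphere_image_dataset",
]


@dataclass(frozen=True)
class ShapeClassSpec:
    """A point-cloud class: per-channel template points on the unit ball,
    positional noise scale (in template units), and a rotation flag."""

    name: str
    templates: tuple[tuple[str, tuple[tuple[float, float, float], ...]], ...]
    sigma: float = 0.05
    rotate: bool = True

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        pts = self.template_points()
        if len(pts) < 1:
            raise ValueError("template needs at least one point")
        if np.linalg.norm(pts, axis=1).max() > 1 + 1e-12:
            raise ValueError("template points must lie within the unit ball")

    def template_points(self) -> np.ndarray:
        return np.array([p for _, ps in self.templates for p in ps], dtype=float)

    def template_labels(self) -> tuple[str, ...]:
        return tuple(ch for ch, ps in self.templates for _ in ps)


@dataclass(frozen=True)
class BumpClassSpec:
    """A spherical-image class: bump centers (unit vectors), concentration
    kappa, and bump amplitude."""

    name: str
    centers: tuple[tuple[float, float, float], ...]
    kappa: float = 10.0
    amplitude: float = 1.0
    rotate: bool = True


@dataclass
class SyntheticDataset:
    """Samples, class labels, ground-truth rotations, and provenance."""

    samples: list
    labels: np.ndarray
    rotations: np.ndarray
    class_names: tuple[str, ...]
    seed: int
    spec: object = None

    def __len__(self) -> int:
        return len(self.samples)


def _ring(n, radius, z=0.0):
    a = 2 * np.pi * np.arange(n) / n
    return tuple(
        (radius * np.cos(t), radius * np.sin(t), z) for t in a
    )


def _helix(n, radius, pitch):
    a = 1.5 * np.pi * np.arange(n) / (n - 1)
    z = pitch * (np.arange(n) / (n - 1) - 0.5)
    return tuple((radius * np.cos(t), radius * np.sin(t), zz) for t, zz in zip(a, z))


def default_cloud_specs(sigma: float = 0.05) -> list[ShapeClassSpec]:
    """Three structurally distinct classes across the four atom-type channels:
    a planar ring, a helical arc, and a tetrahedral cluster."""
    tetra = ((0.5, 0.5, 0.5), (0.5, -0.5, -0.5), (-0.5, 0.5, -0.5), (-0.5, -0.5, 0.5))
    return [
        ShapeClassSpec(
            "ring",
            (
                ("C", _ring(8, 0.65)),
                ("O", ((0.0, 0.0, 0.3), (0.0, 0.0, -0.3))),
            ),
            sigma=sigma,
        ),
        ShapeClassSpec(
            "helix",
            (
                ("C", _helix(8, 0.45, 0.9)),
                ("N", ((0.0, 0.0, 0.62), (0.0, 0.0, -0.62))),
            ),
            sigma=sigma,
        ),
        ShapeClassSpec(
            "cluster",
            (
                ("C", tetra),
                ("S", ((0.0, 0.0, 0.0),)),
                ("N", ((0.0, 0.0, 0.85),)),
            ),
            sigma=sigma,
        ),
    ]


def make_cloud_dataset(
    specs: list[ShapeClassSpec],
    n_per_class: int,
    seed: int,
    r_max: float = 10.0,
) -> SyntheticDataset:
    """Balanced, seeded point-cloud dataset scaled into the r_max ball.

    Each sample is ``R @ (template + noise)`` rescaled by ``r_max`` (and, if
    the noise pushed any radius above 1, shrunk back onto the unit ball);
    the ground-truth rotation ``R`` is stored.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    samples, labels, rotations = [], [], []
    for ci, spec in enumerate(specs):
        template = spec.template_points()
        chan = spec.template_labels()
        for _ in range(n_per_class):
            pts = template + rng.normal(scale=spec.sigma, size=template.shape)
            R = random_rotation(rng) if spec.rotate else np.eye(3)
            pts = pts @ R.T
            scale = r_max / max(1.0, np.linalg.norm(pts, axis=1).max())
            samples.append(LabeledPointCloud(pts * scale, chan))
            labels.append(ci)
            rotations.append(R)
    return SyntheticDataset(
        samples=samples,
        labels=np.array(labels),
        rotations=np.array(rotations),
        class_names=tuple(s.name for s in specs),
        seed=seed,
        spec=tuple(specs),
    )


def default_bump_specs() -> list[BumpClassSpec]:
    s3 = 1.0 / np.sqrt(3.0)
    return [
        BumpClassSpec("one", ((0.0, 0.0, 1.0),)),
        BumpClassSpec("two", ((0.0, 0.0, 1.0), (1.0, 0.0, 0.0))),
        BumpClassSpec("three", ((s3, s3, s3), (-s3, -s3, s3), (0.0, 0.0, -1.0))),
    ]


def make_sphere_image_dataset(
    classes: list[BumpClassSpec],
    bandwidth: int,
    n_per_class: int,
    seed: int,
) -> SyntheticDataset:
    """Spherical images: sums of von-Mises-Fisher-like bumps at rotated
    class-specific center patterns, sampled on the DH grid."""
    if bandwidth < 8:
        raise ValueError("bandwidth must be >= 8")
    rng = np.random.default_rng(seed)
    theta, phi = dh_grid(bandwidth)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    grid = np.stack(
        [np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp), np.cos(tt)], axis=-1
    )
    samples, labels, rotations = [], [], []
    for ci, spec in enumerate(classes):
        centers = np.asarray(spec.centers, dtype=float)
        centers /= np.linalg.norm(centers, axis=1, keepdims=True)
        for _ in range(n_per_class):
            R = random_rotation(rng) if spec.rotate else np.eye(3)
            img = np.zeros(tt.shape)
            for c in centers @ R.T:
                img += spec.amplitude * np.exp(spec.kappa * (grid @ c - 1.0))
            samples.append(SphericalGridImage(bandwidth, img[None]))
            labels.append(ci)
            rotations.append(R)
    return SyntheticDataset(
        samples=samples,
        labels=np.array(labels),
        rotations=np.array(rotations),
        class_names=tuple(s.name for s in classes),
        seed=seed,
        spec=tuple(classes),
    )


# ---------------------------------------------------------------------------
# Encoding helpers
# ---------------------------------------------------------------------------

def encode_cloud_dataset(
    dataset: SyntheticDataset, cfg: ZFTConfig, normalize: bool = True
) -> SteerableTensor:
    """Batched forward ZFT of a cloud dataset (optionally unit-normalized).

    Normalization divides each sample by its global coefficient norm; the
    cosine reconstruction loss is scale-free, and unit-norm inputs keep the
    mean-squared training loss comparable across samples.
    """
    flats = []
    for cloud in dataset.samples:
        t = zft_point_cloud(cloud, cfg)
        f = t.flatten()
        if normalize:
            f = f / np.linalg.norm(f)
        flats.append(f)
    return SteerableTensor.from_flat(np.stack(flats), cfg.signature())


def encode_image_dataset(
    dataset: SyntheticDataset, L: int, normalize: bool = True
) -> SteerableTensor:
    flats = []
    for img in dataset.samples:
        f = zft_spherical_image(img, L).flatten()
        if normalize:
            f = f / np.linalg.norm(f)
        flats.append(f)
    return SteerableTensor.from_flat(
        np.stack(flats),
        zft_spherical_image(dataset.samples[0], L).signature,
    )


# ---------------------------------------------------------------------------
# Frozen regression fixtures
# ---------------------------------------------------------------------------

_FIXTURE_SIGNATURES = {
    "lmax1": ((0, 2), (1, 2)),
    "lmax4": ((0, 1), (1, 1), (2, 1), (3, 1), (4, 1)),
    "lmax10": tuple((l, 1) for l in range(11)),
}


def make_fixture_suite(seed: int) -> dict:
    """Small frozen (tensor, rotation, rotated-tensor) regression triples.

    Regenerable bit-exactly from the seed; covers maximum degrees 1, 4, 10.
    """
    rng = np.random.default_rng(seed)
    suite = {"seed": int(seed), "cases": {}}
    for name, sig in _FIXTURE_SIGNATURES.items():
        t = SteerableTensor.random(TensorSignature(sig), rng)
        R = random_rotation(rng)
        suite["cases"][name] = {
            "signature": [list(e) for e in sig],
            "tensor": t.flatten().tolist(),
            "rotation": R.tolist(),
            "rotated_tensor": t.rotate(R).flatten().tolist(),
        }
    return suite


def save_fixture_suite(suite: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(suite, fh)


def load_fixture_suite(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
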
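"""Zernike Fourier transform (ZFT): data <-> steerable tensors.

Two input kinds are supported:

* labeled 3D point clouds, for which the forward transform has the closed
  form ``Z_{lmn} = sum_i R_{nl}(r_i / r_max) Y_{lm}(theta_i, phi_i)`` per
  channel (no discretization of space);
* spherical images on the Driscoll-Healy equiangular grid, for which the
  angular transform is computed with the grid's exact quadrature weights and
  a constant radial function.

Channel blocks are ordered channel-major: for each channel label in
``cfg.channels``, the radial indices ``n`` ascend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .so3 import sph_harm_matrix, zernike_radial, zernike_radial_indices
from .tensors import SteerableTensor, TensorSignature

__all__ = [
    "LabeledPointCloud",
    "SphericalGridImage",
    "ZFTConfig",
    "dh_grid",
    "dh_quadrature_weights",
    "inverse_zft_point_density",
    "inverse_zft_spherical_image",
    "zft_point_cloud",
    "zft_spherical_image",
]

DEFAULT_CHANNELS = ("C", "N", "O", "S")


@dataclass
class LabeledPointCloud:
    """Points (N, 3) around the origin with a per-point channel label."""

    points: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size and self.points.shape[-1] != 3:
            raise ValueError("points must be (N, 3)")
        if self.points.size and not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite coordinates")
        self.labels = tuple(self.labels)
        n = 0 if self.points.size == 0 else self.points.shape[0]
        if len(self.labels) != n:
            raise ValueError("one label per point required")

    def __len__(self) -> int:
        return 0 if self.points.size == 0 else self.points.shape[0]

    def rotate(self, rot_matrix: np.ndarray) -> "LabeledPointCloud":
        if len(self) == 0:
            return LabeledPointCloud(self.points, self.labels)
        return LabeledPointCloud(self.points @ np.asarray(rot_matrix).T, self.labels)


@dataclass
class SphericalGridImage:
    """Channels sampled on the Driscoll-Healy grid: values (C, 2 bw, 2 bw)."""

    bandwidth: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[None]
        n = 2 * self.bandwidth
        if self.values.ndim != 3 or self.values.shape[1:] != (n, n):
            raise ValueError(f"values must be (C, {n}, {n}) for bandwidth {self.bandwidth}")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ZFTConfig:
    """Resolution and channel layout of a Zernike Fourier transform.

    ``radial_mode='zernike'`` uses the 3D Zernike radial polynomials with the
    selection rule ``n >= l``, ``n - l`` even, ``n <= N``; ``'constant'``
    uses R = 1 with exactly one radial index per degree (spherical images).
    """

    L: int
    N: int
    r_max: float = 10.0
    radial_mode: str = "zernike"
    channels: tuple[str, ...] = field(default=DEFAULT_CHANNELS)

    def __post_init__(self):
        if self.L < 0 or self.N < 0:
            raise ValueError("L and N must be non-negative")
        if self.radial_mode not in ("zernike", "constant"):
            raise ValueError("radial_mode must be 'zernike' or 'constant'")
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        object.__setattr__(self, "channels", tuple(self.channels))

    def radial_indices(self, l: int) -> list:
        if self.radial_mode == "constant":
            return [None]
        return zernike_radial_indices(l, self.N)

    def signature(self) -> TensorSignature:
        entries = []
        for l in range(self.L + 1):
            n_count = len(self.radial_indices(l))
            if n_count:
                entries.append((l, len(self.channels) * n_count))
        return TensorSignature(tuple(entries))

    def radial_values(self, l: int, r_scaled: np.ndarray) -> np.ndarray:
        """Stack of R_{nl}(r) over the valid n's, shape (n_count, npts)."""
        if self.radial_mode == "constant":
            return np.ones((1,) + np.asarray(r_scaled).shape)
        return np.stack([zernike_radial(n, l, r_scaled) for n in self.radial_indices(l)])


def _spherical_coords(points: np.ndarray):
    r = np.linalg.norm(points, axis=-1)
    z_over_r = np.divide(points[:, 2], r, out=np.zeros_like(r), where=r > 0)
    theta = np.arccos(np.clip(z_over_r, -1, 1))
    theta = np.where(r > 0, theta, 0.0)
    phi = np.mod(np.arctan2(points[:, 1], points[:, 0]), 2 * np.pi)
    return r, theta, phi


def zft_point_cloud(
    cloud: LabeledPointCloud, cfg: ZFTConfig, on_outlier: str = "error"
) -> SteerableTensor:
    """Closed-form forward ZFT of a labeled point cloud (unit point weights).

    Points beyond ``cfg.r_max`` raise by default (``on_outlier='error'``) or
    are dropped with ``on_outlier='drop'``.
    """
    unknown = set(cloud.labels) - set(cfg.channels)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} not in configured channels")
    points, labels = cloud.points, np.asarray(cloud.labels, dtype=object)
    if len(cloud):
        r = np.linalg.norm(points, axis=-1)
        outside = r > cfg.r_max * (1 + 1e-12)
        if np.any(outside):
            if on_outlier == "error":
                raise ValueError(
                    f"{int(outside.sum())} point(s) beyond r_max={cfg.r_max}"
                )
            points, labels = points[~outside], labels[~outside]
    out = SteerableTensor.zeros(cfg.signature())
    if points.size == 0:
        return out
    r, theta, phi = _spherical_coords(points)
    r_scaled = r / cfg.r_max
    masks = {ch: labels == ch for ch in cfg.channels}
    for l in range(cfg.L + 1):
        if l not in out.blocks:
            continue
        Y = sph_harm_matrix(l, theta, phi)  # (npts, 2l+1)
        rad = cfg.radial_values(l, r_scaled)  # (n_count, npts)
        rows = []
        for ch in cfg.channels:
            m = masks[ch]
            if np.any(m):
                rows.append(rad[:, m] @ Y[m])  # (n_count, 2l+1)
            else:
                rows.append(np.zeros((rad.shape[0], 2 * l + 1)))
        out.blocks[l][:] = np.concatenate(rows, axis=0)
    return out


def inverse_zft_point_density(
    t: SteerableTensor, cfg: ZFTConfig, query_points: np.ndarray
) -> np.ndarray:
    """Truncated synthesis of the encoded density at query points.

    Returns an array of shape ``(n_points, n_channels)``.
    """
    if t.signature != cfg.signature():
        raise ValueError("tensor signature does not match the ZFT configuration")
    pts = np.atleast_2d(np.asarray(query_points, dtype=float))
    r, theta, phi = _spherical_coords(pts)
    if np.any(r > cfg.r_max * (1 + 1e-12)):
        raise ValueError("query point beyond r_max")
    n_ch = len(cfg.channels)
    out = np.zeros((pts.shape[0], n_ch))
    for l, block in t.blocks.items():
        Y = sph_harm_matrix(l, theta, phi)  # (npts, 2l+1)
        rad = cfg.radial_values(l, r / cfg.r_max)  # (n_count, npts)
        coeff = block.reshape(n_ch, -1, 2 * l + 1)  # (C, n_count, 2l+1)
        out += np.einsum("cnm,np,pm->pc", coeff, rad, Y)
    return out


# ---------------------------------------------------------------------------
# Driscoll-Healy grid
# ---------------------------------------------------------------------------

def dh_grid(bandwidth: int):
    """Equiangular DH grid angles: theta_j = pi(2j+1)/(4 bw), phi_k = pi k / bw."""
    if bandwidth < 1:
        raise ValueError("bandwidth must be >= 1")
    j = np.arange(2 * bandwidth)
    theta = np.pi * (2 * j + 1) / (4 * bandwidth)
    phi = np.pi * j / bandwidth
    return theta, phi


def dh_quadrature_weights(bandwidth: int) -> np.ndarray:
    """Per-row weights w_j with  integral f dOmega = sum_{jk} w_j f(j, k).

    These are the Driscoll-Healy sampling-theorem weights (including the
    uniform azimuthal factor pi/bw); exact for integrands band-limited below
    the grid bandwidth.
    """
    bw = bandwidth
    theta, _ = dh_grid(bw)
    p = np.arange(bw)
    a = (2.0 / bw) * np.sin(theta)[:, None] * (
        np.sin((2 * p[None, :] + 1) * theta[:, None]) / (2 * p + 1)
    )
    return a.sum(axis=1) * (np.pi / bw)


def zft_spherical_image(img: SphericalGridImage, L: int) -> SteerableTensor:
    """Spherical-harmonic coefficients of a DH-grid image (constant radial)."""
    if L >= img.bandwidth:
        raise ValueError(f"L={L} must be below the grid bandwidth {img.bandwidth}")
    theta, phi = dh_grid(img.bandwidth)
    w = dh_quadrature_weights(img.bandwidth)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    blocks = {}
    for l in range(L + 1):
        Y = sph_harm_matrix(l, tt.ravel(), pp.ravel()).reshape(tt.shape + (2 * l + 1,))
        blocks[l] = np.einsum("j,cjk,jkm->cm", w, img.values, Y)
    return SteerableTensor(blocks)


def inverse_zft_spherical_image(t: SteerableTensor, bandwidth: int) -> SphericalGridImage:
    """Synthesis of a constant-radial steerable tensor on the DH grid."""
    if t.signature.max_degree >= bandwidth:
        raise ValueError("tensor max degree must be below the grid bandwidth")
    theta, phi = dh_grid(bandwidth)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    n_ch = t.signature.channels(t.signature.degrees[0])
    values = np.zeros((n_ch,) + tt.shape)
    for l, block in t.blocks.items():
        if block.shape[-2] != n_ch:
            raise ValueError("all degrees must carry the same channel count")
        Y = sph_harm_matrix(l, tt.ravel(), pp.ravel()).reshape(tt.shape + (2 * l + 1,))
        values += np.einsum("cm,jkm->cjk", block, Y)
    return SphericalGridImage(bandwidth, values)
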
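"""Steerable tensors: per-degree blocks of real Fourier coefficients.

A steerable tensor stores, for each degree ``l``, a real block of shape
``(..., C_l, 2l+1)`` whose last axis transforms under rotation by the real
Wigner-D matrix of that degree.  Leading axes (if any) are batch axes shared
by all blocks.  The flat-vector export order is ascending degree, then
channel, then ``m`` from ``-l`` to ``l``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rotations import as_rotation_matrix
from .so3 import wigner_d_matrix

__all__ = [
    "SteerableTensor",
    "TensorSignature",
    "concatenate_channels",
    "cosine_loss",
    "dot",
    "mse_loss",
]


@dataclass(frozen=True)
class TensorSignature:
    """Ordered (degree, channel-count) pairs describing a steerable tensor."""

    entries: tuple[tuple[int, int], ...]

    def __post_init__(self):
        degrees = [l for l, _ in self.entries]
        if any(l < 0 for l in degrees):
            raise ValueError("degrees must be non-negative")
        if len(set(degrees)) != len(degrees):
            raise ValueError("degrees must be unique")
        if any(c < 1 for _, c in self.entries):
            raise ValueError("channel counts must be >= 1")
        object.__setattr__(self, "entries", tuple((int(l), int(c)) for l, c in self.entries))

    @classmethod
    def of(cls, spec) -> "TensorSignature":
        if isinstance(spec, TensorSignature):
            return spec
        if isinstance(spec, dict):
            return cls(tuple(sorted(spec.items())))
        return cls(tuple(spec))

    @property
    def degrees(self) -> tuple[int, ...]:
        return tuple(l for l, _ in self.entries)

    @property
    def max_degree(self) -> int:
        return max(self.degrees)

    def channels(self, l: int) -> int:
        for deg, c in self.entries:
            if deg == l:
                return c
        raise KeyError(f"degree {l} not in signature")

    @property
    def n_coefficients(self) -> int:
        """Total coefficient count, sum_l C_l (2l+1)."""
        return sum(c * (2 * l + 1) for l, c in self.entries)

    def __iter__(self):
        return iter(self.entries)


class SteerableTensor:
    """Container of per-degree coefficient blocks; see module docstring."""

    def __init__(self, blocks: dict[int, np.ndarray], channel_names=None):
        blocks = {int(l): np.asarray(b, dtype=float) for l, b in blocks.items()}
        entries = []
        batch_shape = None
        for l in sorted(blocks):
            b = blocks[l]
            if b.ndim < 2 or b.shape[-1] != 2 * l + 1:
                raise ValueError(f"degree-{l} block must have last axis of size {2*l+1}")
            if batch_shape is None:
                batch_shape = b.shape[:-2]
            elif b.shape[:-2] != batch_shape:
                raise ValueError("inconsistent batch shapes across degrees")
            if not np.all(np.isfinite(b)):
                raise ValueError(f"non-finite entries in degree-{l} block")
            entries.append((l, b.shape[-2]))
        if not entries:
            raise ValueError("a steerable tensor needs at least one degree block")
        self.blocks = {l: blocks[l] for l in sorted(blocks)}
        self.signature = TensorSignature(tuple(entries))
        self.batch_shape = batch_shape
        self.channel_names = channel_names

    # -- construction -------------------------------------------------------

    @classmethod
    def zeros(cls, signature, batch_shape: tuple = ()) -> "SteerableTensor":
        signature = TensorSignature.of(signature)
        blocks = {
            l: np.zeros(tuple(batch_shape) + (c, 2 * l + 1)) for l, c in signature
        }
        return cls(blocks)

    @classmethod
    def random(cls, signature, rng: np.random.Generator, batch_shape: tuple = ()) -> "SteerableTensor":
        signature = TensorSignature.of(signature)
        blocks = {
            l: rng.normal(size=tuple(batch_shape) + (c, 2 * l + 1)) for l, c in signature
        }
        return cls(blocks)

    # -- group action -------------------------------------------------------

    def rotate(self, rot, d_matrices: dict[int, np.ndarray] | None = None) -> "SteerableTensor":
        """Act with a rotation: each degree block right-multiplied by D^l(R)^T."""
        if d_matrices is None:
            mat = as_rotation_matrix(rot)
            d_matrices = {l: wigner_d_matrix(l, mat) for l in self.signature.degrees}
        blocks = {l: b @ d_matrices[l].T for l, b in self.blocks.items()}
        return SteerableTensor(blocks, channel_names=self.channel_names)

    # -- algebra -------------------------------------------------------------

    def norm(self):
        """Global L2 norm sqrt(dot(t, t)); batched if the tensor is batched."""
        return np.sqrt(dot(self, self))

    def feature_norms(self, l: int) -> np.ndarray:
        """Per-channel L2 norms of the degree-l block, shape (..., C_l)."""
        return np.linalg.norm(self.blocks[l], axis=-1)

    def flatten(self) -> np.ndarray:
        """Flat export: ascending degree, then channel, then m = -l..l."""
        parts = [
            b.reshape(b.shape[:-2] + (-1,)) for _, b in sorted(self.blocks.items())
        ]
        return np.concatenate(parts, axis=-1)

    @classmethod
    def from_flat(cls, flat: np.ndarray, signature) -> "SteerableTensor":
        signature = TensorSignature.of(signature)
        flat = np.asarray(flat, dtype=float)
        if flat.shape[-1] != signature.n_coefficients:
            raise ValueError("flat vector length does not match signature")
        blocks, i = {}, 0
        for l, c in signature:
            w = c * (2 * l + 1)
            blocks[l] = flat[..., i : i + w].reshape(flat.shape[:-1] + (c, 2 * l + 1))
            i += w
        return cls(blocks)

    def __getitem__(self, idx) -> "SteerableTensor":
        """Index into the batch axes."""
        return SteerableTensor({l: b[idx] for l, b in self.blocks.items()},
                               channel_names=self.channel_names)

    def scale(self, factor) -> "SteerableTensor":
        factor = np.asarray(factor, dtype=float)
        f = factor.reshape(factor.shape + (1, 1)) if factor.ndim else factor
        return SteerableTensor({l: b * f for l, b in self.blocks.items()},
                               channel_names=self.channel_names)


def _check_same_signature(t1: SteerableTensor, t2: SteerableTensor) -> None:
    if t1.signature != t2.signature:
        raise ValueError(
            f"signature mismatch: {t1.signature.entries} vs {t2.signature.entries}"
        )


def dot(t1: SteerableTensor, t2: SteerableTensor):
    """Coefficient-wise inner product; rotation-invariant under joint rotation."""
    _check_same_signature(t1, t2)
    total = 0.0
    for l, b1 in t1.blocks.items():
        total = total + np.sum(b1 * t2.blocks[l], axis=(-2, -1))
    return total


def mse_loss(x: SteerableTensor, x_rec: SteerableTensor):
    """Mean squared coefficient error (mean over all coefficients)."""
    _check_same_signature(x, x_rec)
    total = 0.0
    for l, b in x.blocks.items():
        total = total + np.sum((b - x_rec.blocks[l]) ** 2, axis=(-2, -1))
    return total / x.signature.n_coefficients


def cosine_loss(x: SteerableTensor, x_rec: SteerableTensor, per_degree: bool = False):
    """1 - dot(x, x')/(|x| |x'|); in [0, 2], scale- and joint-rotation-invariant.

    With ``per_degree=True`` the normalized dot product is computed within
    each degree block and averaged, weighting every degree equally
    regardless of its coefficient count.
    """
    _check_same_signature(x, x_rec)
    if per_degree:
        out = 0.0
        for l, bx in x.blocks.items():
            by = x_rec.blocks[l]
            num = np.sum(bx * by, axis=(-2, -1))
            nx = np.sqrt(np.sum(bx * bx, axis=(-2, -1)))
            ny = np.sqrt(np.sum(by * by, axis=(-2, -1)))
            if np.any(nx == 0) or np.any(ny == 0):
                raise ValueError("cosine loss is undefined for zero-norm blocks")
            out = out + num / (nx * ny)
        return 1.0 - out / len(x.blocks)
    nx, ny = x.norm(), x_rec.norm()
    if np.any(nx == 0) or np.any(ny == 0):
        raise ValueError("cosine loss is undefined for zero-norm tensors")
    return 1.0 - dot(x, x_rec) / (nx * ny)


def concatenate_channels(ts: list[SteerableTensor]) -> SteerableTensor:
    """Concatenate same-degree features of several tensors along channels."""
    if not ts:
        raise ValueError("need at least one tensor")
    degrees = ts[0].signature.degrees
    for t in ts[1:]:
        if t.signature.degrees != degrees:
            raise ValueError("all tensors must share the same degree set")
    blocks = {
        l: np.concatenate([t.blocks[l] for t in ts], axis=-2) for l in degrees
    }
    return SteerableTensor(blocks)
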
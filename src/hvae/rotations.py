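"""Proper-rotation handling: conversions, validation, Haar sampling.

Convention used throughout the package: intrinsic ZYZ Euler angles
(alpha, beta, gamma), i.e. ``R = Rz(alpha) @ Ry(beta) @ Rz(gamma)``.
Quaternions are scalar-last ``(x, y, z, w)`` as in scipy.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "as_rotation_matrix",
    "euler_zyz",
    "identity_rotation",
    "is_rotation_matrix",
    "random_rotation",
]

_ORTHO_TOL = 1e-10


def is_rotation_matrix(mat: np.ndarray, tol: float = _ORTHO_TOL) -> bool:
    """True if ``mat`` is orthogonal with determinant +1 to tolerance."""
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (3, 3):
        return False
    if not np.allclose(mat @ mat.T, np.eye(3), atol=tol):
        return False
    return bool(abs(np.linalg.det(mat) - 1.0) < max(tol, 1e-9))


def as_rotation_matrix(rot) -> np.ndarray:
    """Coerce a rotation given in any supported representation to a 3x3 matrix.

    Accepts a 3x3 proper-rotation matrix, a unit quaternion ``(x, y, z, w)``,
    a ZYZ Euler-angle triple, or a ``scipy.spatial.transform.Rotation``.
    """
    if isinstance(rot, Rotation):
        return rot.as_matrix()
    arr = np.asarray(rot, dtype=float)
    if arr.shape == (3, 3):
        if not is_rotation_matrix(arr, tol=1e-8):
            raise ValueError("matrix is not a proper rotation (orthogonal, det +1)")
        return arr
    if arr.shape == (4,):
        n = np.linalg.norm(arr)
        if n < 1e-12:
            raise ValueError("zero quaternion")
        return Rotation.from_quat(arr / n).as_matrix()
    if arr.shape == (3,):
        return Rotation.from_euler("ZYZ", arr).as_matrix()
    raise ValueError(f"unrecognized rotation representation with shape {arr.shape}")


def euler_zyz(rot) -> np.ndarray:
    """Intrinsic ZYZ Euler angles (alpha, beta, gamma) of a rotation."""
    mat = as_rotation_matrix(rot)
    return Rotation.from_matrix(mat).as_euler("ZYZ")


def identity_rotation() -> np.ndarray:
    return np.eye(3)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform rotation sampled via a normalized Gaussian quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q).as_matrix()
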
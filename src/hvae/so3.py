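"""Special-function and representation-theory kernel for SO(3).

Real spherical harmonics, 3D Zernike radial polynomials, real Wigner-D
matrices and real-basis Clebsch-Gordan coefficients, all in one consistent
convention:

* Real harmonics are the standard recombination of the complex ones
  (Condon-Shortley phase included), ordered ``m = -l..l``; for ``m > 0``
  ``Y_{lm} = sqrt(2) (-1)^m Re Y_l^m`` and ``Y_{l,-m} = sqrt(2) (-1)^m Im Y_l^m``.
* Wigner-D matrices are defined by ``Y_l(R x) = D^l(R) Y_l(x)`` where
  ``Y_l`` is the length-``2l+1`` vector of real harmonics.  With this
  convention ``D^1(R) = P R P^T`` where ``P`` is the fixed permutation
  mapping Cartesian ``(x, y, z)`` to the harmonic order ``(y, z, x)``.
* Clebsch-Gordan coefficients are computed exactly with rational arithmetic
  (Racah's formula) and conjugated into the real basis; a global unit phase
  per ``(l1, l2, l3)`` makes each coefficient block real.

Degrees are capped at ``MAX_DEGREE = 14`` by default.
"""

from __future__ import annotations

import math
from fractions import Fraction
from functools import lru_cache

import numpy as np
from scipy.special import eval_jacobi, sph_harm_y

from .rotations import as_rotation_matrix, euler_zyz

__all__ = [
    "MAX_DEGREE",
    "CGTable",
    "cartesian_to_harmonic_permutation",
    "cg_table",
    "real_spherical_harmonic",
    "sph_harm_matrix",
    "wigner_d_matrix",
    "wigner_d_stack",
    "zernike_radial",
    "zernike_radial_indices",
]

MAX_DEGREE = 14

# Cartesian (x, y, z) -> real-harmonic order (m = -1, 0, 1) ~ (y, z, x)
_P_CART = np.zeros((3, 3))
_P_CART[0, 1] = _P_CART[1, 2] = _P_CART[2, 0] = 1.0


def cartesian_to_harmonic_permutation() -> np.ndarray:
    """Fixed permutation P with ``D^1(R) = P R P^T``; maps (x,y,z) to (y,z,x)."""
    return _P_CART.copy()


# ---------------------------------------------------------------------------
# Real spherical harmonics
# ---------------------------------------------------------------------------

def real_spherical_harmonic(l: int, m: int, theta, phi):
    """Real spherical harmonic Y_{lm}(theta, phi).

    ``theta`` is the polar (colatitude) angle in [0, pi], ``phi`` the
    azimuthal angle.  Orthonormal on the unit sphere.
    """
    if l < 0:
        raise ValueError(f"degree l must be non-negative, got {l}")
    if abs(m) > l:
        raise ValueError(f"|m| must not exceed l, got m={m}, l={l}")
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if m == 0:
        out = sph_harm_y(l, 0, theta, phi).real
    elif m > 0:
        out = math.sqrt(2.0) * (-1) ** m * sph_harm_y(l, m, theta, phi).real
    else:
        out = math.sqrt(2.0) * (-1) ** m * sph_harm_y(l, -m, theta, phi).imag
    return out if out.shape else float(out)


def sph_harm_matrix(l: int, theta, phi) -> np.ndarray:
    """All real harmonics of degree ``l`` stacked on the last axis.

    Returns an array of shape ``theta.shape + (2l+1,)`` with ``m = -l..l``.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    cols = [real_spherical_harmonic(l, m, theta, phi) for m in range(-l, l + 1)]
    return np.stack([np.atleast_1d(c) for c in cols], axis=-1)


# ---------------------------------------------------------------------------
# 3D Zernike radial polynomials
# ---------------------------------------------------------------------------

def zernike_radial(n: int, l: int, r):
    """3D Zernike radial polynomial R_{nl}(r) on the unit ball.

    Closed form used: ``R_{nl}(r) = sqrt(2n+3) r^l P_k^{(0, l+1/2)}(2 r^2 - 1)``
    with ``k = (n-l)/2`` (Jacobi polynomial), which is orthonormal on [0, 1]
    under weight ``r^2``.  Identically zero when ``n < l`` or ``n - l`` is odd.
    """
    if n < 0 or l < 0:
        raise ValueError("n and l must be non-negative")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > 1 + 1e-12):
        raise ValueError("radius must lie in [0, 1]; rescale by r_max first")
    if n < l or (n - l) % 2 != 0:
        out = np.zeros_like(r)
        return out if out.shape else 0.0
    k = (n - l) // 2
    out = math.sqrt(2 * n + 3) * r**l * eval_jacobi(k, 0.0, l + 0.5, 2.0 * r**2 - 1.0)
    return out if out.shape else float(out)


def zernike_radial_indices(l: int, n_max: int) -> list[int]:
    """Valid radial frequencies for degree ``l`` up to ``n_max`` (selection rule)."""
    return list(range(l, n_max + 1, 2))


# ---------------------------------------------------------------------------
# Wigner-D matrices (real basis)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _real_basis_matrix(l: int) -> np.ndarray:
    """Unitary U with Y_real = U Y_complex (rows/cols ordered m = -l..l)."""
    U = np.zeros((2 * l + 1, 2 * l + 1), dtype=complex)
    U[l, l] = 1.0
    inv_sqrt2 = 1.0 / math.sqrt(2.0)
    for m in range(1, l + 1):
        U[l + m, l + m] = (-1) ** m * inv_sqrt2
        U[l + m, l - m] = inv_sqrt2
        U[l - m, l + m] = (-1) ** m * (-1j) * inv_sqrt2
        U[l - m, l - m] = 1j * inv_sqrt2
    return U


def _wigner_small_d(l: int, beta: float) -> np.ndarray:
    """Wigner's factorial formula for d^l(beta); exact integer prefactors."""
    d = np.zeros((2 * l + 1, 2 * l + 1))
    c, s = math.cos(beta / 2.0), math.sin(beta / 2.0)
    f = math.factorial
    for i, mp in enumerate(range(-l, l + 1)):
        for j, m in enumerate(range(-l, l + 1)):
            pref = math.sqrt(f(l + mp) * f(l - mp) * f(l + m) * f(l - m))
            tot = 0.0
            for k in range(max(0, m - mp), 2 * l + 1):
                a1, a3, a4 = l + m - k, mp - m + k, l - mp - k
                if min(a1, a3, a4) < 0:
                    continue
                term = (-1) ** (mp - m + k) / (f(a1) * f(k) * f(a3) * f(a4))
                tot += term * c ** (2 * l + m - mp - 2 * k) * s ** (mp - m + 2 * k)
            d[i, j] = pref * tot
    return d


def wigner_d_matrix(l: int, rot) -> np.ndarray:
    """Real Wigner-D matrix D^l(R) with ``Y_l(R x) = D^l(R) Y_l(x)``.

    ``rot`` may be a 3x3 matrix, unit quaternion, ZYZ Euler triple, or a
    scipy Rotation.  The result is orthogonal and the map is a group
    homomorphism.
    """
    if l < 0:
        raise ValueError("degree l must be non-negative")
    alpha, beta, gamma = euler_zyz(rot)
    if l == 0:
        return np.ones((1, 1))
    m = np.arange(-l, l + 1)
    d = _wigner_small_d(l, beta)
    Dc = np.exp(-1j * m[:, None] * alpha) * d * np.exp(-1j * m[None, :] * gamma)
    U = _real_basis_matrix(l)
    Dr = U @ Dc.conj() @ U.conj().T
    return np.ascontiguousarray(Dr.real)


def wigner_d_stack(l_max: int, rot) -> dict[int, np.ndarray]:
    """Wigner-D matrices for all degrees 0..l_max for one rotation."""
    mat = as_rotation_matrix(rot)
    return {l: wigner_d_matrix(l, mat) for l in range(l_max + 1)}


# ---------------------------------------------------------------------------
# Clebsch-Gordan coefficients
# ---------------------------------------------------------------------------

def _cg_complex(l1: int, m1: int, l2: int, m2: int, l3: int, m3: int) -> float:
    """<l1 m1 l2 m2 | l3 m3> via Racah's formula with exact rationals."""
    if m3 != m1 + m2 or not abs(l1 - l2) <= l3 <= l1 + l2:
        return 0.0
    f = math.factorial
    pref = Fraction(
        (2 * l3 + 1) * f(l3 + l1 - l2) * f(l3 - l1 + l2) * f(l1 + l2 - l3),
        f(l1 + l2 + l3 + 1),
    ) * (f(l3 + m3) * f(l3 - m3) * f(l1 - m1) * f(l1 + m1) * f(l2 - m2) * f(l2 + m2))
    tot = Fraction(0)
    for k in range(0, l1 + l2 - l3 + 1):
        args = (
            k,
            l1 + l2 - l3 - k,
            l1 - m1 - k,
            l2 + m2 - k,
            l3 - l2 + m1 + k,
            l3 - l1 - m2 + k,
        )
        if min(args) < 0:
            continue
        tot += Fraction((-1) ** k, math.prod(f(a) for a in args))
    return float(tot) * math.sqrt(float(pref))


@lru_cache(maxsize=2048)
def _real_cg_block(l1: int, l2: int, l3: int) -> np.ndarray:
    """Real-basis CG block of shape (2l1+1, 2l2+1, 2l3+1).

    Conjugates the complex tensor into the real basis; the result is purely
    real for even l1+l2+l3 and purely imaginary for odd, so a global unit
    phase yields a real, orthogonality-preserving block.
    """
    C = np.zeros((2 * l1 + 1, 2 * l2 + 1, 2 * l3 + 1))
    for i, m1 in enumerate(range(-l1, l1 + 1)):
        for j, m2 in enumerate(range(-l2, l2 + 1)):
            m3 = m1 + m2
            if abs(m3) <= l3:
                C[i, j, l3 + m3] = _cg_complex(l1, m1, l2, m2, l3, m3)
    U1, U2, U3 = (_real_basis_matrix(l) for l in (l1, l2, l3))
    T = np.einsum("ai,bj,ijk,ck->abc", U1.conj(), U2.conj(), C, U3)
    out = T.real if (l1 + l2 + l3) % 2 == 0 else T.imag
    residual = T.imag if (l1 + l2 + l3) % 2 == 0 else T.real
    assert np.abs(residual).max() < 1e-12
    return np.ascontiguousarray(out)


class CGTable:
    """Precomputed real-basis Clebsch-Gordan coefficients up to ``max_degree``.

    ``table[(l1, l2, l3)]`` is the coefficient block indexed by
    ``(m1, m2, m3)``; triples violating ``|l1-l2| <= l3 <= l1+l2`` are absent.
    """

    def __init__(self, max_degree: int, entries: dict[tuple[int, int, int], np.ndarray]):
        self.max_degree = int(max_degree)
        self.entries = entries

    def __getitem__(self, key: tuple[int, int, int]) -> np.ndarray:
        l1, l2, l3 = key
        if not abs(l1 - l2) <= l3 <= l1 + l2:
            raise KeyError(f"triple {key} violates the triangle inequality")
        if max(key) > self.max_degree:
            raise KeyError(f"triple {key} exceeds max_degree={self.max_degree}")
        return self.entries[key]

    def __contains__(self, key) -> bool:
        return key in self.entries

    def save(self, path) -> None:
        """Serialize to a single .npz archive keyed by 'l1_l2_l3'."""
        arrays = {f"{k[0]}_{k[1]}_{k[2]}": v for k, v in self.entries.items()}
        np.savez(path, max_degree=np.array(self.max_degree), **arrays)

    @classmethod
    def load(cls, path) -> "CGTable":
        with np.load(path) as data:
            max_degree = int(data["max_degree"])
            entries = {}
            for key in data.files:
                if key == "max_degree":
                    continue
                l1, l2, l3 = (int(s) for s in key.split("_"))
                entries[(l1, l2, l3)] = data[key]
        return cls(max_degree, entries)


@lru_cache(maxsize=8)
def cg_table(max_degree: int) -> CGTable:
    """Build (and cache) the real CG table for all degrees <= max_degree."""
    if max_degree < 0:
        raise ValueError("max_degree must be non-negative")
    entries = {}
    for l1 in range(max_degree + 1):
        for l2 in range(max_degree + 1):
            for l3 in range(abs(l1 - l2), min(l1 + l2, max_degree) + 1):
                entries[(l1, l2, l3)] = _real_cg_block(l1, l2, l3)
    return CGTable(max_degree, entries)
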
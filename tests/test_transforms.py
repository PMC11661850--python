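"""Zernike Fourier transform: closed-form point-cloud encoding, spherical
grid quadrature, inverses, and equivariance."""

import math

import numpy as np
import pytest

from hvae.rotations import random_rotation
from hvae.so3 import real_spherical_harmonic, sph_harm_matrix, zernike_radial
from hvae.tensors import SteerableTensor
from hvae.transforms import (
    LabeledPointCloud,
    SphericalGridImage,
    ZFTConfig,
    dh_grid,
    dh_quadrature_weights,
    inverse_zft_point_density,
    inverse_zft_spherical_image,
    zft_point_cloud,
    zft_spherical_image,
)

from .conftest import angles_of

CFG = ZFTConfig(L=4, N=6, r_max=10.0)


def random_cloud(rng, n=10, r_max=10.0):
    pts = rng.normal(size=(n, 3))
    pts *= rng.uniform(0.1, 0.9 * r_max, size=(n, 1)) / np.linalg.norm(pts, axis=1, keepdims=True)
    labels = tuple(rng.choice(["C", "N", "O", "S"], size=n))
    return LabeledPointCloud(pts, labels)


class TestConfiguredSignatures:
    def test_printed_coefficient_tallies(self):
        """The three published encoding sizes follow from signature arithmetic."""
        mnist = ZFTConfig(L=10, N=0, radial_mode="constant", channels=("img",))
        shrec = ZFTConfig(L=14, N=0, radial_mode="constant", channels=tuple("123456"))
        amino = ZFTConfig(L=4, N=20, r_max=10.0)
        assert mnist.signature().n_coefficients == 121
        assert shrec.signature().n_coefficients == 1350
        assert amino.signature().n_coefficients == 940

    def test_constant_mode_single_radial_index(self):
        cfg = ZFTConfig(L=3, N=0, radial_mode="constant", channels=("a",))
        assert all(cfg.radial_indices(l) == [None] for l in range(4))


class TestPointCloudZFT:
    def test_empty_cloud_is_zero_tensor(self):
        t = zft_point_cloud(LabeledPointCloud(np.zeros((0, 3)), ()), CFG)
        assert t.signature == CFG.signature()
        assert all(np.all(b == 0) for b in t.blocks.values())

    def test_single_point_matches_direct_basis_evaluation(self, rng):
        p = np.array([2.0, -1.0, 3.0])
        t = zft_point_cloud(LabeledPointCloud(p[None], ("O",)), CFG)
        theta, phi = angles_of(p)
        r = np.linalg.norm(p) / CFG.r_max
        for l in range(CFG.L + 1):
            block = t.blocks[l].reshape(4, -1, 2 * l + 1)  # (channel, n, m)
            for i_n, n in enumerate(CFG.radial_indices(l)):
                for i_m, m in enumerate(range(-l, l + 1)):
                    expected = zernike_radial(n, l, r) * real_spherical_harmonic(l, m, theta, phi)
                    assert block[2, i_n, i_m] == pytest.approx(expected, abs=1e-12)
            # channels with no points stay exactly zero
            assert np.all(block[[0, 1, 3]] == 0)

    def test_superposition_linearity(self, rng):
        c1, c2 = random_cloud(rng, 5), random_cloud(rng, 7)
        both = LabeledPointCloud(
            np.vstack([c1.points, c2.points]), c1.labels + c2.labels
        )
        t1, t2, tb = (zft_point_cloud(c, CFG) for c in (c1, c2, both))
        for l in tb.blocks:
            assert np.abs(tb.blocks[l] - t1.blocks[l] - t2.blocks[l]).max() < 1e-12

    def test_rotation_equivariance(self, rng):
        for _ in range(10):
            cloud = random_cloud(rng)
            R = random_rotation(rng)
            lhs = zft_point_cloud(cloud.rotate(R), CFG)
            rhs = zft_point_cloud(cloud, CFG).rotate(R)
            for l in lhs.blocks:
                assert np.abs(lhs.blocks[l] - rhs.blocks[l]).max() < 1e-8

    def test_point_outside_ball_rejected_or_dropped(self, rng):
        far = LabeledPointCloud(np.array([[0.0, 0.0, 11.0]]), ("C",))
        with pytest.raises(ValueError):
            zft_point_cloud(far, CFG)
        t = zft_point_cloud(far, CFG, on_outlier="drop")
        assert all(np.all(b == 0) for b in t.blocks.values())

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            zft_point_cloud(LabeledPointCloud(np.array([[1.0, 0, 0]]), ("Zn",)), CFG)


class TestPointDensitySynthesis:
    def test_zero_tensor_gives_zero_density(self, rng):
        t = SteerableTensor.zeros(CFG.signature())
        q = rng.normal(size=(5, 3))
        q = q / np.linalg.norm(q, axis=1, keepdims=True) * 5.0
        assert np.all(inverse_zft_point_density(t, CFG, q) == 0)

    def test_band_limited_round_trip(self, rng):
        """Synthesis built from the truncated basis reprojects to itself.

        The forward transform of the synthesized density is computed by
        quadrature over a dense ball grid and compared to the original
        coefficients (projection of the basis onto itself).
        """
        from scipy.special import roots_legendre

        cfg = ZFTConfig(L=2, N=4, r_max=1.0, channels=("a",))
        t = SteerableTensor.random(cfg.signature(), rng)
        # dense quadrature grid on the ball: GL in radius and cos(theta), uniform phi
        xr, wr = roots_legendre(24)
        r = 0.5 * (xr + 1.0)
        wr = 0.5 * wr
        xc, wc = roots_legendre(24)
        theta = np.arccos(xc)
        phi = 2 * np.pi * np.arange(48) / 48
        rr, tt, pp = np.meshgrid(r, theta, phi, indexing="ij")
        ww = (
            wr[:, None, None] * rr**2 * wc[None, :, None] * (2 * np.pi / 48)
        )
        pts = np.stack(
            [rr * np.sin(tt) * np.cos(pp), rr * np.sin(tt) * np.sin(pp), rr * np.cos(tt)],
            axis=-1,
        ).reshape(-1, 3)
        dens = inverse_zft_point_density(t, cfg, pts)[:, 0].reshape(rr.shape)
        for l in range(cfg.L + 1):
            Y = sph_harm_matrix(l, tt.ravel(), pp.ravel()).reshape(tt.shape + (2 * l + 1,))
            for i_n, n in enumerate(cfg.radial_indices(l)):
                Rn = zernike_radial(n, l, rr.ravel()).reshape(rr.shape)
                proj = np.einsum("rtp,rtp,rtpm->m", ww, dens * Rn, Y)
                assert np.abs(proj - t.blocks[l][i_n]).max() < 1e-8

    def test_peak_approaches_point_as_resolution_grows(self):
        """The synthesized density of a 1-point cloud peaks ever closer to it."""
        p = np.array([0.35, -0.2, 0.4]) * 10.0
        cloud = LabeledPointCloud(p[None], ("C",))
        g = np.linspace(-0.9, 0.9, 25) * 10.0
        gx, gy, gz = np.meshgrid(g, g, g, indexing="ij")
        q = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
        q = q[np.linalg.norm(q, axis=1) <= 10.0]
        errors = []
        for L in (2, 4, 8):
            cfg = ZFTConfig(L=L, N=8, r_max=10.0)
            dens = inverse_zft_point_density(zft_point_cloud(cloud, cfg), cfg, q)[:, 0]
            errors.append(np.linalg.norm(q[np.argmax(dens)] - p))
        assert errors[0] >= errors[1] >= errors[2]
        assert errors[2] < 2.0  # within the grid spacing of the true point

    def test_query_outside_ball_rejected(self, rng):
        t = SteerableTensor.zeros(CFG.signature())
        with pytest.raises(ValueError):
            inverse_zft_point_density(t, CFG, np.array([[0.0, 0.0, 12.0]]))


class TestDriscollHealyGrid:
    def test_quadrature_exact_for_band_limited_integrands(self):
        """DH weights integrate products of harmonics below the bandwidth exactly."""
        bw = 12
        theta, phi = dh_grid(bw)
        w = dh_quadrature_weights(bw)
        tt, pp = np.meshgrid(theta, phi, indexing="ij")
        assert w.sum() * 2 * bw == pytest.approx(4 * np.pi, abs=1e-10)
        feats = []
        for l in range(6):
            Y = sph_harm_matrix(l, tt.ravel(), pp.ravel()).reshape(tt.shape + (2 * l + 1,))
            feats.extend(Y[..., m] for m in range(2 * l + 1))
        F = np.stack(feats)
        gram = np.einsum("j,ajk,bjk->ab", w, F, F)
        assert np.abs(gram - np.eye(len(F))).max() < 1e-10


class TestSphericalImageZFT:
    def test_constant_image_has_only_monopole(self):
        img = SphericalGridImage(12, np.full((1, 24, 24), 3.0))
        t = zft_spherical_image(img, 6)
        assert t.blocks[0][0, 0] == pytest.approx(3.0 * math.sqrt(4 * math.pi), abs=1e-10)
        for l in range(1, 7):
            assert np.abs(t.blocks[l]).max() < 1e-10

    def test_pure_harmonic_image_gives_unit_coefficient(self, rng):
        bw = 12
        theta, phi = dh_grid(bw)
        tt, pp = np.meshgrid(theta, phi, indexing="ij")
        l, m = 3, -2
        Y = sph_harm_matrix(l, tt.ravel(), pp.ravel()).reshape(tt.shape + (2 * l + 1,))
        img = SphericalGridImage(bw, Y[..., l + m][None])
        t = zft_spherical_image(img, 6)
        for lp in range(7):
            expected = np.zeros(2 * lp + 1)
            if lp == l:
                expected[l + m] = 1.0
            assert np.abs(t.blocks[lp][0] - expected).max() < 1e-8

    def test_degree_must_stay_below_bandwidth(self):
        img = SphericalGridImage(8, np.zeros((1, 16, 16)))
        with pytest.raises(ValueError):
            zft_spherical_image(img, 8)

    def test_forward_inverse_identity_on_coefficients(self, rng):
        cfg = ZFTConfig(L=6, N=0, radial_mode="constant", channels=("a", "b"))
        t = SteerableTensor.random(cfg.signature(), rng)
        back = zft_spherical_image(inverse_zft_spherical_image(t, 16), 6)
        for l in t.blocks:
            assert np.abs(back.blocks[l] - t.blocks[l]).max() < 1e-8

    def test_zero_tensor_inverse_is_zero_image(self):
        cfg = ZFTConfig(L=2, N=0, radial_mode="constant", channels=("a",))
        img = inverse_zft_spherical_image(SteerableTensor.zeros(cfg.signature()), 8)
        assert np.all(img.values == 0)

    def test_dipole_tensor_synthesizes_cos_theta(self):
        cfg = ZFTConfig(L=1, N=0, radial_mode="constant", channels=("a",))
        t = SteerableTensor.zeros(cfg.signature())
        t.blocks[1][0, 1] = 1.0  # (l=1, m=0)
        img = inverse_zft_spherical_image(t, 12)
        theta, _ = dh_grid(12)
        expected = math.sqrt(3.0 / (4 * math.pi)) * np.cos(theta)
        assert np.abs(img.values[0] - expected[:, None]).max() < 1e-10

    def test_121_coefficients_for_single_channel_L10(self):
        img = SphericalGridImage(30, np.zeros((1, 60, 60)))
        assert zft_spherical_image(img, 10).signature.n_coefficients == 121
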
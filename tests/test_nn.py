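"""Equivariance and algebraic contracts of the network layers."""

import numpy as np
import pytest

from hvae.nn import (
    BatchNorm,
    CGBlock,
    Linear,
    SignalNorm,
    blocks_signature,
    blocks_to_tensor,
    cg_tensor_product,
    default_paths,
    efficient_tensor_product,
    etp_output_signature,
    tensor_to_blocks,
)
from hvae.rotations import random_rotation
from hvae.so3 import cartesian_to_harmonic_permutation, wigner_d_matrix
from hvae.tensors import SteerableTensor, TensorSignature

SIG = ((0, 2), (1, 2), (2, 2), (3, 2))


def max_block_err(t1, t2):
    return max(np.abs(t1.blocks[l] - t2.blocks[l]).max() for l in t1.blocks)


def apply_layer(layer, t, **kw):
    return blocks_to_tensor(layer(tensor_to_blocks(t), **kw))


class TestLinear:
    def test_identity_and_zero_weights(self, rng):
        t = SteerableTensor.random(SIG, rng, batch_shape=(3,))
        lin = Linear(SIG, {l: c for l, c in SIG}, rng)
        for l in lin.weights:
            lin.weights[l].data = np.eye(lin.weights[l].shape[0])
        assert max_block_err(apply_layer(lin, t), t) < 1e-12
        for l in lin.weights:
            lin.weights[l].data = np.zeros_like(lin.weights[l].data)
        out = apply_layer(lin, t)
        assert all(np.all(b == 0) for b in out.blocks.values())

    def test_equivariance(self, rng):
        t = SteerableTensor.random(SIG, rng, batch_shape=(2,))
        lin = Linear(SIG, 3, rng)
        R = random_rotation(rng)
        assert max_block_err(apply_layer(lin, t.rotate(R)), apply_layer(lin, t).rotate(R)) < 1e-8

    def test_shape_mismatch_rejected(self, rng):
        lin = Linear(SIG, 3, rng)
        bad = SteerableTensor.random(((0, 5), (1, 2), (2, 2), (3, 2)), rng, batch_shape=(1,))
        with pytest.raises(ValueError):
            apply_layer(lin, bad)


class TestCGProduct:
    def test_dot_and_cross_from_vector_couplings(self, table4, rng):
        P = cartesian_to_harmonic_permutation()
        for _ in range(10):
            a, b = rng.normal(size=3), rng.normal(size=3)
            s = cg_tensor_product(P @ a, P @ b, 0, table4)
            assert s[0] * (-np.sqrt(3.0)) == pytest.approx(np.dot(a, b), abs=1e-10)
            v = cg_tensor_product(P @ a, P @ b, 1, table4)
            assert np.abs(v * np.sqrt(2.0) - P @ np.cross(a, b)).max() < 1e-10

    def test_equivariance_over_degrees(self, table8, rng):
        for _ in range(10):
            l1, l2 = rng.integers(0, 4, size=2)
            l3 = rng.integers(abs(l1 - l2), l1 + l2 + 1)
            h1 = rng.normal(size=2 * l1 + 1)
            h2 = rng.normal(size=2 * l2 + 1)
            R = random_rotation(rng)
            lhs = cg_tensor_product(
                wigner_d_matrix(l1, R) @ h1, wigner_d_matrix(l2, R) @ h2, int(l3), table8
            )
            rhs = wigner_d_matrix(l3, R) @ cg_tensor_product(h1, h2, int(l3), table8)
            assert np.abs(lhs - rhs).max() < 1e-8

    def test_triangle_violation_rejected(self, table4, rng):
        with pytest.raises(ValueError):
            cg_tensor_product(rng.normal(size=3), rng.normal(size=3), 3, table4)


class TestETP:
    def test_scalar_only_paths_square_invariants(self, table4, rng):
        blocks = tensor_to_blocks(SteerableTensor.random(((0, 3),), rng, batch_shape=(2,)))
        out = efficient_tensor_product(blocks, [(0, 0, 0)], table4, include_skip=False)
        h0 = blocks[0].data
        c000 = table4[(0, 0, 0)][0, 0, 0]
        assert np.abs(out[0].data - c000 * h0 * h0).max() < 1e-12

    def test_matches_full_bilinear_product_on_kept_paths(self, table4, rng):
        """The channel-wise ETP equals the corresponding slice of the full
        (all-pairs) bilinear CG product computed by brute force."""
        sig = ((0, 2), (1, 2), (2, 2))
        t = SteerableTensor.random(sig, rng, batch_shape=(3,))
        blocks = tensor_to_blocks(t)
        paths = default_paths((0, 1, 2), cap=2)
        out = efficient_tensor_product(blocks, paths, table4, include_skip=False)
        grouped = {}
        for l1, l2, l3 in paths:
            full = np.einsum(
                "bci,bcj,ijk->bck", t.blocks[l1], t.blocks[l2], table4[(l1, l2, l3)]
            )
            grouped.setdefault(l3, []).append(full)
        for l3, parts in grouped.items():
            assert np.abs(out[l3].data - np.concatenate(parts, axis=1)).max() < 1e-12

    def test_output_signature_calculator(self, table4, rng):
        sig = TensorSignature.of(SIG)
        paths = default_paths(sig.degrees, cap=2)
        blocks = tensor_to_blocks(SteerableTensor.random(SIG, rng, batch_shape=(1,)))
        out = efficient_tensor_product(blocks, paths, table4, include_skip=True, cap=2)
        assert blocks_signature(out) == etp_output_signature(sig, paths, True, 2)

    def test_equivariance(self, table8, rng):
        t = SteerableTensor.random(SIG, rng, batch_shape=(2,))
        R = random_rotation(rng)
        paths = default_paths((0, 1, 2, 3), cap=4)
        out = blocks_to_tensor(efficient_tensor_product(tensor_to_blocks(t), paths, table8))
        outR = blocks_to_tensor(
            efficient_tensor_product(tensor_to_blocks(t.rotate(R)), paths, table8)
        )
        assert max_block_err(outR, out.rotate(R)) < 1e-8

    def test_channel_mismatch_rejected(self, table4, rng):
        blocks = tensor_to_blocks(SteerableTensor.random(((0, 2), (1, 3)), rng, batch_shape=(1,)))
        with pytest.raises(ValueError):
            efficient_tensor_product(blocks, [(0, 1, 1)], table4)


class TestNorms:
    def test_batch_norm_unit_norms_after_training_pass(self, rng):
        bn = BatchNorm(SIG)
        t = SteerableTensor.random(SIG, rng, batch_shape=(16,))
        out = apply_layer(bn, t, training=True)
        for l in out.blocks:
            mean_norms = np.linalg.norm(out.blocks[l], axis=-1).mean(axis=0)
            assert np.abs(mean_norms - 1.0).max() < 1e-4

    def test_batch_norm_equivariance(self, rng):
        t = SteerableTensor.random(SIG, rng, batch_shape=(8,))
        R = random_rotation(rng)
        out = apply_layer(BatchNorm(SIG), t, training=True)
        outR = apply_layer(BatchNorm(SIG), t.rotate(R), training=True)
        assert max_block_err(outR, out.rotate(R)) < 1e-8

    def test_batch_norm_eval_uses_running_statistics(self, rng):
        bn = BatchNorm(SIG)
        t = SteerableTensor.random(SIG, rng, batch_shape=(8,))
        apply_layer(bn, t, training=True)
        running = {l: v.copy() for l, v in bn.running.items()}
        out = apply_layer(bn, t.scale(100.0), training=False)
        for l in out.blocks:
            expected = t.blocks[l] * 100.0 / (running[l][None, :, None] + bn.eps)
            assert np.abs(out.blocks[l] - expected).max() < 1e-8

    def test_batch_norm_rejects_empty_and_warns_on_singleton(self, rng):
        bn = BatchNorm(SIG)
        with pytest.raises(ValueError):
            apply_layer(bn, SteerableTensor.random(SIG, rng, batch_shape=(0,)), training=True)
        with pytest.warns(UserWarning):
            apply_layer(bn, SteerableTensor.random(SIG, rng, batch_shape=(1,)), training=True)

    def test_signal_norm_unit_total_norm(self, rng):
        sn = SignalNorm(SIG)
        t = SteerableTensor.random(SIG, rng, batch_shape=(4,))
        out = apply_layer(sn, t)
        for b in range(4):
            total = sum((out.blocks[l][b] ** 2).sum() for l in out.blocks)
            assert total == pytest.approx(1.0, abs=1e-4)

    def test_signal_norm_zero_input_stays_finite(self):
        out = apply_layer(SignalNorm(SIG), SteerableTensor.zeros(SIG, batch_shape=(2,)))
        assert all(np.all(np.isfinite(b)) and np.all(b == 0) for b in out.blocks.values())

    def test_norm_layers_finite_across_magnitudes(self, rng):
        """No overflow/NaN on feature scales spanning 12 orders of magnitude."""
        for scale in (1e-6, 1.0, 1e6):
            t = SteerableTensor.random(SIG, rng, batch_shape=(4,)).scale(scale)
            for out in (
                apply_layer(BatchNorm(SIG), t, training=True),
                apply_layer(SignalNorm(SIG), t),
            ):
                assert all(np.all(np.isfinite(b)) for b in out.blocks.values())

    def test_signal_norm_factor_rotation_invariant(self, rng):
        sn = SignalNorm(SIG)
        t = SteerableTensor.random(SIG, rng, batch_shape=(4,))
        R = random_rotation(rng)
        out, outR = apply_layer(sn, t), apply_layer(sn, t.rotate(R))
        assert max_block_err(outR, out.rotate(R)) < 1e-8


class TestCGBlock:
    def test_end_to_end_equivariance(self, table8, rng):
        t = SteerableTensor.random(SIG, rng, batch_shape=(4,))
        block = CGBlock(SIG, width=3, cap=2, table=table8, rng=rng)
        R = random_rotation(rng)
        out = apply_layer(block, t, training=False)
        outR = apply_layer(block, t.rotate(R), training=False)
        assert max_block_err(outR, out.rotate(R)) < 1e-6

    def test_cap_zero_emits_only_invariants(self, table8, rng):
        block = CGBlock(SIG, width=3, cap=0, table=table8, rng=rng)
        assert block.sig_out.degrees == (0,)

    def test_stacked_blocks_remain_equivariant(self, table8, rng):
        t = SteerableTensor.random(SIG, rng, batch_shape=(3,))
        b1 = CGBlock(SIG, width=3, cap=3, table=table8, rng=rng)
        b2 = CGBlock(b1.sig_out, width=2, cap=1, table=table8, rng=rng)
        R = random_rotation(rng)
        out = apply_layer(b2, apply_layer(b1, t))
        outR = apply_layer(b2, apply_layer(b1, t.rotate(R)))
        assert max_block_err(outR, out.rotate(R)) < 1e-6

    def test_cap_beyond_table_rejected(self, table4, rng):
        with pytest.raises(ValueError):
            CGBlock(SIG, width=2, cap=6, table=table4, rng=rng)

    def test_figure_order_variant_also_equivariant(self, table8, rng):
        t = SteerableTensor.random(SIG, rng, batch_shape=(4,))
        block = CGBlock(
            SIG, width=3, cap=2, table=table8, rng=rng, order=("bn", "etp", "sn", "lin")
        )
        R = random_rotation(rng)
        out = apply_layer(block, t)
        outR = apply_layer(block, t.rotate(R))
        assert max_block_err(outR, out.rotate(R)) < 1e-6
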
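"""The H-(V)AE: an SO(3)-equivariant autoencoder in spherical Fourier space.

The encoder compresses a steerable tensor through Clebsch-Gordan blocks with
decreasing degree caps down to ``l_max = 1``; its final ``l=0`` channels map
linearly to the invariant latent code ``z`` (mean and log-variance in the
variational case) and its final ``l=1`` channels map to two 3-vectors whose
Gram-Schmidt orthonormalization — completed by a cross product — forms the
equivariant frame ``g``.  The decoder receives ``z`` as ``l=0`` channels and
the frame's two defining rows as ``l=1`` channels, and mirrors the encoder
with increasing caps back to the input signature.  Rotating the input leaves
``z`` unchanged and right-multiplies the frame by the inverse rotation; the
whole composition is equivariant by construction.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Node
from .nn import CGBlock, Linear, blocks_signature, tensor_to_blocks
from .so3 import cartesian_to_harmonic_permutation, cg_table
from .tensors import SteerableTensor, TensorSignature

__all__ = ["Frame", "HVAE", "LatentCode", "ModelConfig", "gram_schmidt_frame"]

_LEVI_CIVITA = np.zeros((3, 3, 3))
for _i, _j, _k in [(0, 1, 2), (1, 2, 0), (2, 0, 1)]:
    _LEVI_CIVITA[_i, _j, _k] = 1.0
    _LEVI_CIVITA[_i, _k, _j] = -1.0

_DEGENERATE_TOL = 1e-8
# fixed orthogonal pair added (scaled by 1e-6) to regularize near-collinear input
_FALLBACK_PAIR = (np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]))


@dataclass
class Frame:
    """Proper-rotation matrix whose rows are the learned orthonormal vectors."""

    basis: np.ndarray

    def __post_init__(self):
        self.basis = np.asarray(self.basis, dtype=float)
        if self.basis.shape[-2:] != (3, 3):
            raise ValueError("frame basis must be (..., 3, 3)")
        eye = np.eye(3)
        gram = self.basis @ np.swapaxes(self.basis, -1, -2)
        if not np.allclose(gram, eye, atol=1e-6):
            raise ValueError("frame rows are not orthonormal")
        if not np.allclose(np.linalg.det(self.basis), 1.0, atol=1e-6):
            raise ValueError("frame determinant is not +1")


@dataclass
class LatentCode:
    """Invariant code plus equivariant frame (and the posterior parameters)."""

    z: np.ndarray
    frame: np.ndarray
    mean: np.ndarray | None = None
    log_variance: np.ndarray | None = None


def _gram_schmidt_nodes(v1: Node, v2: Node, regularize: bool = False) -> Node:
    """Batched differentiable Gram-Schmidt; returns frames (B, 3, 3)."""
    if regularize:
        v1 = v1 + 1e-6 * _FALLBACK_PAIR[0][None, :]
        v2 = v2 + 1e-6 * _FALLBACK_PAIR[1][None, :]
    n1 = ad.einsum("bi,bi->b", v1, v1).sqrt()
    if np.any(n1.data < _DEGENERATE_TOL):
        raise ValueError("degenerate frame: first vector has near-zero norm")
    e1 = v1 / n1.reshape(-1, 1)
    proj = ad.einsum("bi,bi->b", e1, v2)
    u2 = v2 - proj.reshape(-1, 1) * e1
    n2 = ad.einsum("bi,bi->b", u2, u2).sqrt()
    if np.any(n2.data < _DEGENERATE_TOL):
        raise ValueError("degenerate frame: second vector is parallel to the first")
    e2 = u2 / n2.reshape(-1, 1)
    e3 = ad.einsum("bi,bj,ijk->bk", e1, e2, _LEVI_CIVITA)
    return ad.stack([e1, e2, e3], axis=1)


def gram_schmidt_frame(v1: np.ndarray, v2: np.ndarray) -> Frame:
    """Orthonormal right-handed frame from two vectors.

    Row 1 is ``v1`` normalized, row 2 the orthonormalized ``v2``, row 3
    their cross product.  Equivariant: ``frame(Rv1, Rv2) = frame(v1, v2) R^T``.
    Near-collinear or near-zero inputs raise a degenerate-frame error.
    """
    v1 = ad.as_node(np.asarray(v1, dtype=float).reshape(1, 3))
    v2 = ad.as_node(np.asarray(v2, dtype=float).reshape(1, 3))
    return Frame(_gram_schmidt_nodes(v1, v2).data[0])


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters of an H-(V)AE.

    ``encoder_caps`` descend to 1 and ``decoder_caps`` ascend back to the
    input's maximum degree; the defaults step one degree per block.
    ``width`` is the channel count each block's linearity maps every degree
    to.  ``condition_size`` invariant conditioning channels are appended to
    both encoder and decoder inputs (0 = no conditioning).
    """

    signature: tuple
    latent_dim: int = 8
    width: int = 8
    variational: bool = False
    condition_size: int = 0
    encoder_caps: tuple[int, ...] | None = None
    decoder_caps: tuple[int, ...] | None = None
    block_order: tuple[str, str, str, str] = ("lin", "etp", "bn", "sn")
    seed: int = 0

    def __post_init__(self):
        sig = TensorSignature.of(self.signature)
        object.__setattr__(self, "signature", sig.entries)
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        L = sig.max_degree
        enc = self.encoder_caps
        dec = self.decoder_caps
        if enc is None:
            enc = tuple(range(L - 1, 0, -1)) or (1,)
        if dec is None:
            dec = tuple(range(2, L + 1)) or (L,)
        if enc[-1] != 1:
            raise ValueError("the final encoder cap must be 1")
        if dec[-1] != L:
            raise ValueError("the final decoder cap must equal the input max degree")
        object.__setattr__(self, "encoder_caps", tuple(int(c) for c in enc))
        object.__setattr__(self, "decoder_caps", tuple(int(c) for c in dec))

    @property
    def input_signature(self) -> TensorSignature:
        return TensorSignature(self.signature)


class HVAE:
    """Holographic (variational) autoencoder over steerable tensors."""

    def __init__(self, config: ModelConfig, table=None):
        self.config = config
        sig_in = config.input_signature
        L = sig_in.max_degree
        max_needed = max(L, max(config.encoder_caps), max(config.decoder_caps))
        self.table = table if table is not None else cg_table(max_needed)
        rng = np.random.default_rng(config.seed)
        self._P = cartesian_to_harmonic_permutation()

        # encoder stack
        entries = dict(sig_in.entries)
        if config.condition_size:
            entries[0] = entries.get(0, 0) + config.condition_size
        sig = TensorSignature.of(entries)
        self.encoder_blocks = []
        for cap in config.encoder_caps:
            block = CGBlock(sig, config.width, cap, self.table, rng, config.block_order)
            self.encoder_blocks.append(block)
            sig = block.sig_out
        z_out = 2 * config.latent_dim if config.variational else config.latent_dim
        self.invariant_head = Linear(sig, {0: z_out}, rng)
        self.frame_head = Linear(sig, {1: 2}, rng)

        # decoder stack
        dec_entries = {0: config.latent_dim + config.condition_size, 1: 2}
        sig = TensorSignature.of(dec_entries)
        self.decoder_blocks = []
        for cap in config.decoder_caps:
            block = CGBlock(sig, config.width, cap, self.table, rng, config.block_order)
            self.decoder_blocks.append(block)
            sig = block.sig_out
        self.output_head = Linear(sig, dict(sig_in.entries), rng)

    # -- parameters ----------------------------------------------------------

    def parameters(self) -> list[Node]:
        params = []
        for block in self.encoder_blocks + self.decoder_blocks:
            params.extend(block.parameters())
        params.extend(self.invariant_head.parameters())
        params.extend(self.frame_head.parameters())
        params.extend(self.output_head.parameters())
        return params

    # -- graph-level passes (autodiff Nodes) ---------------------------------

    def _append_condition(self, blocks, condition, batch: int):
        if self.config.condition_size == 0:
            return blocks
        if condition is None:
            raise ValueError("model expects a conditioning vector")
        cond = ad.as_node(np.broadcast_to(
            np.asarray(condition, dtype=float).reshape(-1, self.config.condition_size),
            (batch, self.config.condition_size),
        )[..., None])
        blocks = dict(blocks)
        blocks[0] = ad.concatenate([blocks[0], cond], axis=1) if 0 in blocks else cond
        return blocks

    def _encode_nodes(self, blocks, condition=None, noise=None, training=False):
        batch = next(iter(blocks.values())).shape[0]
        blocks = self._append_condition(blocks, condition, batch)
        for block in self.encoder_blocks:
            blocks = block(blocks, training=training)
        zraw = self.invariant_head(blocks)[0]  # (B, z or 2z, 1)
        zraw = zraw.reshape(batch, -1)
        vecs = self.frame_head(blocks)[1]  # (B, 2, 3) in the harmonic basis
        v_cart = ad.einsum("ji,brj->bri", self._P, vecs)  # P^T maps back to Cartesian
        frame = _gram_schmidt_nodes(v_cart[:, 0], v_cart[:, 1], regularize=training)
        if not self.config.variational:
            return zraw, None, None, frame
        mean = zraw[:, : self.config.latent_dim]
        log_var = zraw[:, self.config.latent_dim :]
        if noise is None:
            z = mean
        else:
            noise = np.asarray(noise, dtype=float).reshape(batch, self.config.latent_dim)
            z = mean + (log_var * 0.5).exp() * noise
        return z, mean, log_var, frame

    def _decode_nodes(self, z, frame, condition=None, training=False):
        z = ad.as_node(z)
        frame = ad.as_node(frame)
        batch = z.shape[0]
        blocks = {0: z.reshape(batch, -1, 1)}
        blocks = self._append_condition(blocks, condition, batch)
        rows = frame[:, :2, :]  # the two defining rows; row 3 is redundant
        blocks[1] = ad.einsum("ij,brj->bri", self._P, rows)
        for block in self.decoder_blocks:
            blocks = block(blocks, training=training)
        return self.output_head(blocks)

    # -- public numpy API -----------------------------------------------------

    def _as_batch(self, x: SteerableTensor):
        if x.signature != self.config.input_signature:
            raise ValueError("input signature does not match the model")
        batched = len(x.batch_shape) > 0
        return tensor_to_blocks(x), batched

    def encode(self, x: SteerableTensor, condition=None, noise=None) -> LatentCode:
        """Invariant code and equivariant frame of (a batch of) inputs.

        In variational mode ``z = mean + exp(log_var / 2) * noise``; with no
        noise supplied the posterior mean is returned.  Deterministic models
        ignore ``noise`` entirely.
        """
        blocks, batched = self._as_batch(x)
        if not self.config.variational:
            noise = None
        z, mean, log_var, frame = self._encode_nodes(blocks, condition, noise)
        squeeze = (lambda a: a if batched else a[0])
        return LatentCode(
            z=squeeze(z.data),
            frame=squeeze(frame.data),
            mean=None if mean is None else squeeze(mean.data),
            log_variance=None if log_var is None else squeeze(log_var.data),
        )

    def decode(self, code, frame=None, condition=None) -> SteerableTensor:
        """Decode an invariant code and frame back to a steerable tensor."""
        if isinstance(code, LatentCode):
            z, fr = code.z, code.frame
        else:
            z, fr = code, frame
            if fr is None:
                raise ValueError("decode needs a frame")
        if isinstance(fr, Frame):
            fr = fr.basis
        z = np.asarray(z, dtype=float)
        batched = z.ndim > 1
        z2 = z.reshape(-1, z.shape[-1])
        if z2.shape[-1] != self.config.latent_dim:
            raise ValueError(
                f"latent size mismatch: expected {self.config.latent_dim}, got {z2.shape[-1]}"
            )
        fr2 = np.asarray(fr, dtype=float).reshape(-1, 3, 3)
        blocks = self._decode_nodes(z2, fr2, condition)
        arrs = {l: n.data for l, n in blocks.items()}
        if not batched:
            arrs = {l: a[0] for l, a in arrs.items()}
        return SteerableTensor(arrs)

    def reconstruct(self, x: SteerableTensor, condition=None, noise=None) -> SteerableTensor:
        """Encode-then-decode; equivariant end to end."""
        code = self.encode(x, condition=condition, noise=noise)
        return self.decode(code, condition=condition)

    def generate(self, z_sample, frame, condition=None) -> SteerableTensor:
        """Decode a latent-prior sample under a frame of choice."""
        if not self.config.variational:
            raise ValueError("generate requires a variational model")
        if isinstance(frame, Frame):
            frame = frame.basis
        return self.decode(np.asarray(z_sample), frame=frame, condition=condition)

    # -- checkpointing --------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {}
        for i, p in enumerate(self.parameters()):
            arrays[f"param_{i}"] = p.data
        for j, block in enumerate(self.encoder_blocks + self.decoder_blocks):
            bn = block.stages.get("bn")
            if bn is not None:
                for l, v in bn.running.items():
                    arrays[f"running_{j}_{l}"] = v
        return arrays

    def save(self, path) -> None:
        """Self-describing checkpoint: config JSON + parameters + norm state."""
        cfg = {
            "signature": list(map(list, self.config.signature)),
            "latent_dim": self.config.latent_dim,
            "width": self.config.width,
            "variational": self.config.variational,
            "condition_size": self.config.condition_size,
            "encoder_caps": list(self.config.encoder_caps),
            "decoder_caps": list(self.config.decoder_caps),
            "block_order": list(self.config.block_order),
            "seed": self.config.seed,
            "cg_max_degree": self.table.max_degree,
        }
        arrays = self.state_arrays()
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", json.dumps(cfg))
            buf = io.BytesIO()
            np.savez(buf, **arrays)
            zf.writestr("state.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "HVAE":
        with zipfile.ZipFile(path, "r") as zf:
            cfg = json.loads(zf.read("config.json"))
            with np.load(io.BytesIO(zf.read("state.npz"))) as data:
                arrays = {k: data[k] for k in data.files}
        config = ModelConfig(
            signature=tuple(tuple(e) for e in cfg["signature"]),
            latent_dim=cfg["latent_dim"],
            width=cfg["width"],
            variational=cfg["variational"],
            condition_size=cfg["condition_size"],
            encoder_caps=tuple(cfg["encoder_caps"]),
            decoder_caps=tuple(cfg["decoder_caps"]),
            block_order=tuple(cfg["block_order"]),
            seed=cfg["seed"],
        )
        model = cls(config, table=cg_table(cfg["cg_max_degree"]))
        for i, p in enumerate(model.parameters()):
            p.data = arrays[f"param_{i}"]
        for j, block in enumerate(model.encoder_blocks + model.decoder_blocks):
            bn = block.stages.get("bn")
            if bn is not None:
                for l in bn.running:
                    bn.running[l] = arrays[f"running_{j}_{l}"]
        return model
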
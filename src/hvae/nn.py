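"""Equivariant building blocks: degree-wise linearity, efficient
Clebsch-Gordan tensor product, batch norm, signal norm, and the CG block.

Layers operate on *block dicts*: ``{l: Node of shape (B, C_l, 2l+1)}``, the
autodiff view of a batched steerable tensor.  Channels mix freely within a
degree; orders ``m`` only ever transform through Wigner-D or couple through
Clebsch-Gordan coefficients, so every layer is equivariant by construction.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import autodiff as ad
from .autodiff import Node
from .so3 import CGTable
from .tensors import SteerableTensor, TensorSignature

__all__ = [
    "BatchNorm",
    "CGBlock",
    "Linear",
    "SignalNorm",
    "blocks_signature",
    "blocks_to_tensor",
    "cg_tensor_product",
    "default_paths",
    "efficient_tensor_product",
    "etp_output_signature",
    "tensor_to_blocks",
    "validate_paths",
]


def tensor_to_blocks(t: SteerableTensor) -> dict[int, Node]:
    """Lift a (batched) steerable tensor into constant autodiff nodes."""
    blocks = {}
    for l, b in t.blocks.items():
        if b.ndim == 2:
            b = b[None]
        blocks[l] = ad.as_node(b)
    return blocks


def blocks_to_tensor(blocks: dict[int, Node], squeeze: bool = False) -> SteerableTensor:
    arrs = {l: n.data for l, n in blocks.items()}
    if squeeze:
        arrs = {l: a[0] for l, a in arrs.items()}
    return SteerableTensor(arrs)


def blocks_signature(blocks: dict[int, Node]) -> TensorSignature:
    return TensorSignature(tuple((l, blocks[l].shape[-2]) for l in sorted(blocks)))


# ---------------------------------------------------------------------------
# Linearity
# ---------------------------------------------------------------------------

class Linear:
    """Degree-specific linear maps h'_l = W_l h_l (channels mix, orders don't).

    ``out_channels`` is either a single width applied to every degree or a
    ``{degree: channels}`` mapping.  Weights are initialized with variance
    ``1/C_in`` per degree, from the supplied generator.
    """

    def __init__(self, sig_in, out_channels, rng: np.random.Generator):
        sig_in = TensorSignature.of(sig_in)
        if isinstance(out_channels, int):
            out_channels = {l: out_channels for l in sig_in.degrees}
        self.sig_in = sig_in
        self.weights: dict[int, Node] = {}
        for l in sorted(out_channels):
            c_in = sig_in.channels(l)
            w = rng.normal(scale=1.0 / np.sqrt(c_in), size=(out_channels[l], c_in))
            self.weights[l] = Node(w, requires_grad=True)
        self.sig_out = TensorSignature(
            tuple((l, self.weights[l].shape[0]) for l in sorted(self.weights))
        )

    def parameters(self) -> list[Node]:
        return list(self.weights.values())

    def __call__(self, blocks: dict[int, Node]) -> dict[int, Node]:
        out = {}
        for l, w in self.weights.items():
            if l not in blocks:
                raise ValueError(f"input lacks degree {l}")
            if blocks[l].shape[-2] != w.shape[1]:
                raise ValueError(
                    f"degree {l}: expected {w.shape[1]} channels, got {blocks[l].shape[-2]}"
                )
            out[l] = ad.einsum("oc,bcm->bom", w, blocks[l])
        return out


# ---------------------------------------------------------------------------
# Clebsch-Gordan products
# ---------------------------------------------------------------------------

def cg_tensor_product(h1, h2, l3: int, table: CGTable):
    """Couple a degree-l1 and a degree-l2 feature into degree l3.

    ``h1``, ``h2`` are arrays or nodes of shape ``(..., 2l+1)`` (matching
    leading shapes).  Bilinear and equivariant.
    """
    l1 = (np.shape(h1.data if isinstance(h1, Node) else h1)[-1] - 1) // 2
    l2 = (np.shape(h2.data if isinstance(h2, Node) else h2)[-1] - 1) // 2
    if not abs(l1 - l2) <= l3 <= l1 + l2:
        raise ValueError(f"({l1}, {l2}) -> {l3} violates the triangle inequality")
    C = table[(l1, l2, l3)]
    if isinstance(h1, Node) or isinstance(h2, Node):
        flat1, flat2 = ad.as_node(h1), ad.as_node(h2)
        if flat1.ndim == 1:
            return ad.einsum("i,j,ijk->k", flat1, flat2, C)
        if flat1.ndim == 2:
            return ad.einsum("bi,bj,ijk->bk", flat1, flat2, C)
        return ad.einsum("bci,bcj,ijk->bck", flat1, flat2, C)
    return np.einsum("...i,...j,ijk->...k", np.asarray(h1), np.asarray(h2), C)


def validate_paths(paths, cap: int | None = None):
    for l1, l2, l3 in paths:
        if not abs(l1 - l2) <= l3 <= l1 + l2:
            raise ValueError(f"path ({l1},{l2},{l3}) violates the triangle inequality")
        if cap is not None and l3 > cap:
            raise ValueError(f"path ({l1},{l2},{l3}) exceeds the degree cap {cap}")
    return sorted(set(tuple(p) for p in paths))


def default_paths(degrees, cap: int) -> list[tuple[int, int, int]]:
    """Default ETP connectivity: self-couplings plus couplings with l=1.

    Per channel, each degree couples with itself into every allowed output
    degree up to the cap, and — when an l=1 feature exists — with that
    feature into neighboring degrees.  This guarantees paths from every
    degree down to l=0 and from low degrees upward.
    """
    degrees = sorted(set(degrees))
    paths = set()
    for l in degrees:
        for l3 in range(0, min(2 * l, cap) + 1):
            paths.add((l, l, l3))
        if 1 in degrees:
            for l3 in range(abs(l - 1), min(l + 1, cap) + 1):
                paths.add((l, 1, l3))
    return sorted(paths)


def etp_output_signature(
    sig_in, paths, include_skip: bool = True, cap: int | None = None
) -> TensorSignature:
    """Signature of the efficient tensor product as a pure function of inputs."""
    sig_in = TensorSignature.of(sig_in)
    counts: dict[int, int] = {}
    for l1, l2, l3 in validate_paths(paths, cap):
        c = sig_in.channels(l1)
        if sig_in.channels(l2) != c:
            raise ValueError(f"path ({l1},{l2},{l3}): channel counts differ")
        counts[l3] = counts.get(l3, 0) + c
    if include_skip:
        for l, c in sig_in:
            if cap is None or l <= cap:
                counts[l] = counts.get(l, 0) + c
    return TensorSignature(tuple(sorted(counts.items())))


def efficient_tensor_product(
    blocks: dict[int, Node],
    paths,
    table: CGTable,
    include_skip: bool = True,
    cap: int | None = None,
) -> dict[int, Node]:
    """Channel-wise CG tensor products along a restricted set of paths.

    For each path ``(l1, l2, l3)`` every channel c couples ``h_{l1,c}`` with
    ``h_{l2,c}`` into an output channel at degree l3; outputs of all paths
    (and, optionally, the pass-through inputs with ``l <= cap``) are
    concatenated per degree, in path order.
    """
    paths = validate_paths(paths, cap)
    grouped: dict[int, list[Node]] = {}
    for l1, l2, l3 in paths:
        h1, h2 = blocks[l1], blocks[l2]
        if h1.shape[-2] != h2.shape[-2]:
            raise ValueError(f"path ({l1},{l2},{l3}): channel counts differ")
        out = ad.einsum("bci,bcj,ijk->bck", h1, h2, table[(l1, l2, l3)])
        grouped.setdefault(l3, []).append(out)
    if include_skip:
        for l in sorted(blocks):
            if cap is None or l <= cap:
                grouped.setdefault(l, []).append(blocks[l])
    return {
        l: (parts[0] if len(parts) == 1 else ad.concatenate(parts, axis=1))
        for l, parts in sorted(grouped.items())
    }


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

class BatchNorm:
    """Divide each (degree, channel) feature by its batch-averaged norm.

    Feature norms are rotation invariants, so the layer is equivariant.
    Training mode uses the current batch average (and updates running
    statistics with the configured momentum); evaluation mode always uses
    the running statistics.  A batch of one falls back to running
    statistics with a warning.
    """

    def __init__(self, sig, momentum: float = 0.1, eps: float = 1e-6):
        self.sig = TensorSignature.of(sig)
        self.momentum = momentum
        self.eps = eps
        self.running: dict[int, np.ndarray] = {
            l: np.ones(c) for l, c in self.sig
        }

    def parameters(self) -> list[Node]:
        return []

    def __call__(self, blocks: dict[int, Node], training: bool = False) -> dict[int, Node]:
        first = next(iter(blocks.values()))
        batch = first.shape[0]
        if batch == 0:
            raise ValueError("empty batch")
        out = {}
        use_batch_stats = training and batch > 1
        if training and batch == 1:
            warnings.warn("batch of size 1: batch norm falls back to running statistics")
        for l, h in blocks.items():
            if use_batch_stats:
                norms = (ad.einsum("bcm,bcm->bc", h, h) + self.eps**2).sqrt()
                mean_norm = norms.mean(axis=0)  # (C,)
                self.running[l] = (
                    (1 - self.momentum) * self.running[l] + self.momentum * mean_norm.data
                )
                denom = mean_norm.reshape(1, -1, 1)
            else:
                denom = ad.as_node(self.running[l].reshape(1, -1, 1))
            out[l] = h / (denom + self.eps)
        return out


class SignalNorm:
    """Divide the whole tensor by the square root of its total norm.

    The total norm of a sample is the sum of the inner-product (squared L2)
    norms of its (degree, channel) features; after dividing by its square
    root a learned scalar per degree rescales each block.  With unit affine
    factors the output's total norm is exactly 1.
    """

    def __init__(self, sig, eps: float = 1e-6):
        self.sig = TensorSignature.of(sig)
        self.eps = eps
        self.affine: dict[int, Node] = {
            l: Node(np.ones(1), requires_grad=True) for l, _ in self.sig
        }

    def parameters(self) -> list[Node]:
        return list(self.affine.values())

    def __call__(self, blocks: dict[int, Node]) -> dict[int, Node]:
        total = None
        for l, h in blocks.items():
            s = ad.einsum("bcm,bcm->bc", h, h).sum(axis=1)  # (B,)
            total = s if total is None else total + s
        factor = (total + self.eps).sqrt().reshape(-1, 1, 1)
        return {
            l: h / factor * self.affine[l].reshape(1, 1, 1)
            for l, h in blocks.items()
        }


# ---------------------------------------------------------------------------
# Clebsch-Gordan block
# ---------------------------------------------------------------------------

class CGBlock:
    """Lin -> ETP -> BN -> SN (order configurable), all degrees <= cap.

    ``width`` is the common channel count the linearity maps every degree
    to; the channel-wise tensor product requires it to be uniform.
    """

    def __init__(
        self,
        sig_in,
        width: int,
        cap: int,
        table: CGTable,
        rng: np.random.Generator,
        order: tuple[str, ...] = ("lin", "etp", "bn", "sn"),
        paths=None,
        include_skip: bool = True,
    ):
        if sorted(order) != ["bn", "etp", "lin", "sn"]:
            raise ValueError("order must be a permutation of lin, etp, bn, sn")
        sig_in = TensorSignature.of(sig_in)
        if cap > table.max_degree:
            raise ValueError("degree cap exceeds the CG table's max degree")
        self.order = tuple(order)
        self.cap = cap
        self.table = table
        self.include_skip = include_skip
        self.stages: dict[str, object] = {}
        sig = sig_in
        for stage in order:
            if stage == "lin":
                self.stages["lin"] = Linear(sig, width, rng)
                sig = self.stages["lin"].sig_out
            elif stage == "etp":
                self.paths = (
                    validate_paths(paths, cap)
                    if paths is not None
                    else default_paths(sig.degrees, cap)
                )
                sig = etp_output_signature(sig, self.paths, include_skip, cap)
            elif stage == "bn":
                self.stages["bn"] = BatchNorm(sig)
            elif stage == "sn":
                self.stages["sn"] = SignalNorm(sig)
        self.sig_in = sig_in
        self.sig_out = sig

    def parameters(self) -> list[Node]:
        params = []
        for stage in self.order:
            if stage in self.stages:
                params.extend(self.stages[stage].parameters())
        return params

    def __call__(self, blocks: dict[int, Node], training: bool = False) -> dict[int, Node]:
        for stage in self.order:
            if stage == "lin":
                blocks = self.stages["lin"](blocks)
            elif stage == "etp":
                blocks = efficient_tensor_product(
                    blocks, self.paths, self.table, self.include_skip, self.cap
                )
            elif stage == "bn":
                blocks = self.stages["bn"](blocks, training=training)
            elif stage == "sn":
                blocks = self.stages["sn"](blocks)
        return blocks
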
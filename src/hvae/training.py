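"""Loss assembly, optimization loop, and latent-space evaluation metrics.

The total loss is ``alpha * L_rec + beta * D_KL`` with mean-squared
coefficient error for ``L_rec`` (SO(3)-pairwise invariant) and the closed
form KL of a diagonal Gaussian posterior from the standard-normal prior.
``beta = 0`` and ``alpha = 1`` recover the plain autoencoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import v_measure_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from . import autodiff as ad
from .model import HVAE
from .nn import tensor_to_blocks
from .tensors import SteerableTensor, cosine_loss
from .tensors import mse_loss as mse_loss_np

__all__ = [
    "Adam",
    "LossWeights",
    "TrainReport",
    "clustering_metrics",
    "kl_isotropic",
    "kmeans_cluster",
    "latent_classifier_eval",
    "pocket_embedding",
    "total_loss",
    "train",
]


@dataclass(frozen=True)
class LossWeights:
    """Reconstruction weight alpha, KL weight beta, and the beta warm-up.

    ``beta_warmup`` is the fraction of epochs over which beta ramps
    linearly from 0 to its final value (standard KL annealing); 0 disables
    the ramp.
    """

    alpha: float = 1.0
    beta: float = 0.0
    beta_warmup: float = 0.25

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")

    def beta_at(self, epoch: int, n_epochs: int) -> float:
        if self.beta == 0 or self.beta_warmup == 0:
            return self.beta
        ramp = max(1, int(round(self.beta_warmup * n_epochs)))
        return self.beta * min(1.0, (epoch + 1) / ramp)


def kl_isotropic(mean, log_variance) -> float:
    """KL( N(mean, diag exp(log_var)) || N(0, I) ), summed over dimensions.

    Closed form ``0.5 * sum(exp(lv) + mean^2 - 1 - lv)``; non-negative, zero
    iff the posterior equals the prior.  Batched inputs return the batch
    mean.
    """
    mean = np.asarray(mean, dtype=float)
    lv = np.asarray(log_variance, dtype=float)
    per = 0.5 * np.sum(np.exp(lv) + mean**2 - 1.0 - lv, axis=-1)
    return float(np.mean(per))


def total_loss(x: SteerableTensor, x_rec: SteerableTensor, mean, log_variance, w: LossWeights) -> float:
    """alpha * MSE + beta * KL; invariant under joint rotation of (x, x_rec)."""
    rec = float(np.mean(mse_loss_np(x, x_rec)))
    kl = 0.0
    if mean is not None and w.beta > 0:
        kl = kl_isotropic(mean, log_variance)
    return w.alpha * rec + w.beta * kl


class Adam:
    """Standard Adam over a list of autodiff parameter nodes."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


@dataclass
class TrainReport:
    """Per-epoch loss trajectory of a training run."""

    seed: int
    epochs: int = 0
    reconstruction: list[float] = field(default_factory=list)
    kl: list[float] = field(default_factory=list)
    total: list[float] = field(default_factory=list)
    val_cosine: list[float] = field(default_factory=list)
    equivariance_error: float | None = None

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "epochs": self.epochs,
            "reconstruction": self.reconstruction,
            "kl": self.kl,
            "total": self.total,
            "val_cosine": self.val_cosine,
            "equivariance_error": self.equivariance_error,
        }


def _mse_nodes(blocks_x, blocks_rec, n_coeff: int):
    total = None
    for l, bx in blocks_x.items():
        d = blocks_rec[l] - bx
        s = ad.einsum("bcm,bcm->b", d, d)
        total = s if total is None else total + s
    return total.mean() * (1.0 / n_coeff)


def _kl_nodes(mean, log_var):
    per = (log_var.exp() + mean * mean - 1.0 - log_var) * 0.5
    return per.sum(axis=1).mean()


def train(
    model: HVAE,
    data: SteerableTensor,
    weights: LossWeights = LossWeights(),
    *,
    epochs: int = 100,
    batch_size: int = 32,
    lr: float = 1e-3,
    seed: int = 0,
    conditions: np.ndarray | None = None,
    val_data: SteerableTensor | None = None,
    patience: int | None = 20,
) -> TrainReport:
    """Minimize the total loss on a batched steerable-tensor dataset.

    Deterministic for a given seed.  ``val_data`` enables per-epoch cosine
    loss tracking and early stopping with the given patience (in epochs);
    non-finite losses abort with a diagnostic.
    """
    if len(data.batch_shape) != 1:
        raise ValueError("data must be a batched steerable tensor")
    if data.signature != model.config.input_signature:
        raise ValueError("dataset signature does not match the model")
    n = data.batch_shape[0]
    n_coeff = data.signature.n_coefficients
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=lr)
    report = TrainReport(seed=seed)
    best_val, best_age = np.inf, 0
    for epoch in range(epochs):
        order = rng.permutation(n)
        beta = weights.beta_at(epoch, epochs)
        ep_rec, ep_kl, nb = 0.0, 0.0, 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb = data[idx]
            blocks = tensor_to_blocks(xb)
            cond = None if conditions is None else conditions[idx]
            noise = (
                rng.standard_normal((len(idx), model.config.latent_dim))
                if model.config.variational
                else None
            )
            z, mean, log_var, frame = model._encode_nodes(
                blocks, condition=cond, noise=noise, training=True
            )
            rec_blocks = model._decode_nodes(z, frame, condition=cond, training=True)
            rec = _mse_nodes(blocks, rec_blocks, n_coeff)
            loss = rec * weights.alpha
            kl_val = 0.0
            if model.config.variational:
                kl = _kl_nodes(mean, log_var)
                kl_val = float(kl.data)
                if beta > 0:
                    loss = loss + kl * beta
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {start // batch_size}: "
                    f"rec={rec.data}, kl={kl_val}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_rec += float(rec.data)
            ep_kl += kl_val
            nb += 1
        report.reconstruction.append(ep_rec / nb)
        report.kl.append(ep_kl / nb)
        report.total.append(
            weights.alpha * ep_rec / nb + beta * ep_kl / nb
        )
        report.epochs = epoch + 1
        if val_data is not None:
            rec_val = model.reconstruct(val_data)
            vc = float(np.mean(cosine_loss(val_data, rec_val)))
            report.val_cosine.append(vc)
            if patience is not None:
                if vc < best_val - 1e-6:
                    best_val, best_age = vc, 0
                else:
                    best_age += 1
                    if best_age >= patience:
                        break
    # re-verify equivariance of the trained model post hoc
    from .rotations import random_rotation

    x = data[np.asarray([0])]
    R = random_rotation(np.random.default_rng(seed))
    rec, rec_rot = model.reconstruct(x), model.reconstruct(x.rotate(R))
    report.equivariance_error = float(
        max(
            np.abs(rec_rot.blocks[l] - rec.rotate(R).blocks[l]).max()
            for l in rec.blocks
        )
    )
    return report


# ---------------------------------------------------------------------------
# Latent-space evaluation
# ---------------------------------------------------------------------------

def clustering_metrics(labels_true, labels_pred) -> tuple[float, float]:
    """(purity, V-measure) of a clustering against ground-truth classes."""
    labels_true = np.asarray(labels_true)
    labels_pred = np.asarray(labels_pred)
    if labels_true.size == 0:
        raise ValueError("empty input")
    if labels_true.shape != labels_pred.shape:
        raise ValueError("label arrays must have equal length")
    purity = 0
    for k in np.unique(labels_pred):
        members = labels_true[labels_pred == k]
        _, counts = np.unique(members, return_counts=True)
        purity += counts.max()
    return purity / labels_true.size, float(v_measure_score(labels_true, labels_pred))


def kmeans_cluster(embeddings, n_clusters: int, seed: int = 0) -> np.ndarray:
    """K-means assignment of latent embeddings (10 restarts, seeded)."""
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    return km.fit_predict(np.asarray(embeddings, dtype=float))


def latent_classifier_eval(
    train_embeddings,
    train_labels,
    test_embeddings,
    test_labels,
    mode: str = "linear",
    seed: int = 0,
    n_neighbors: int = 5,
    train_ids=None,
    test_ids=None,
) -> float:
    """Held-out accuracy of a classifier on invariant latent descriptors.

    Pipeline: standardize, fit on the training embeddings, evaluate on the
    test embeddings.  Optional sample-id arrays guard against split leakage.
    """
    if train_ids is not None and test_ids is not None:
        shared = set(np.asarray(train_ids).tolist()) & set(np.asarray(test_ids).tolist())
        if shared:
            raise ValueError(f"label leakage: {len(shared)} shared sample ids across splits")
    if mode == "linear":
        clf = LogisticRegression(max_iter=2000, random_state=seed)
    elif mode == "knn":
        clf = KNeighborsClassifier(n_neighbors=n_neighbors)
    else:
        raise ValueError("mode must be 'linear' or 'knn'")
    pipe = make_pipeline(StandardScaler(), clf)
    pipe.fit(np.asarray(train_embeddings, dtype=float), np.asarray(train_labels))
    return float(pipe.score(np.asarray(test_embeddings, dtype=float), np.asarray(test_labels)))


def pocket_embedding(residue_embeddings) -> np.ndarray:
    """Sum of residue-level invariant embeddings: permutation-invariant and
    extensive in the number of residues."""
    arr = np.asarray(residue_embeddings, dtype=float)
    if arr.size == 0:
        raise ValueError("empty embedding list")
    if arr.ndim == 1:
        arr = arr[None]
    return arr.sum(axis=0)
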
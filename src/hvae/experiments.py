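"""End-to-end toy experiments on the bundled synthetic data.

These are the package's reference workflows: generate the default
three-class cloud dataset, encode it with the Zernike Fourier transform,
train an H-(V)AE, and evaluate reconstruction and latent-space structure.
Problem sizes default to a desk-scale setting (a few hundred samples,
L = 4) that trains in minutes on one CPU core.
"""

from __future__ import annotations

import numpy as np

from .model import HVAE, ModelConfig
from .synthetic import default_cloud_specs, encode_cloud_dataset, make_cloud_dataset
from .tensors import SteerableTensor, cosine_loss
from .training import (
    LossWeights,
    clustering_metrics,
    kmeans_cluster,
    latent_classifier_eval,
    train,
)
from .transforms import ZFTConfig

__all__ = ["toy_cloud_experiment", "toy_zft_config"]


def toy_zft_config() -> ZFTConfig:
    """The encoding used by the toy cloud experiments: L=4, N=4, 10-angstrom ball."""
    return ZFTConfig(L=4, N=4, r_max=10.0)


def toy_cloud_experiment(
    seed: int,
    *,
    n_per_class: int = 200,
    sigma: float = 0.05,
    rotate_train: bool = True,
    latent_dim: int = 8,
    width: int = 12,
    epochs: int = 100,
    fine_epochs: int = 25,
    lr: float = 2e-3,
    test_fraction: float = 0.25,
    variational: bool = False,
    beta: float = 0.0,
    evaluate_latent: bool = True,
) -> dict:
    """Train an H-(V)AE on the default synthetic cloud classes.

    The training split optionally uses non-rotated samples
    (``rotate_train=False``); the held-out evaluation split is always
    rotated, so the non-rotated condition probes generalization to unseen
    orientations.  After the main run a short fine-tuning phase at lr/4
    settles the optimum.  Returns the trained model, the held-out cosine
    loss, and (optionally) K-means purity / V-measure and a linear
    classifier accuracy on the invariant latents.
    """
    cfg = toy_zft_config()
    rng = np.random.default_rng(seed)
    train_specs = [
        s.__class__(s.name, s.templates, s.sigma, rotate_train)
        for s in default_cloud_specs(sigma)
    ]
    ds_train = make_cloud_dataset(
        train_specs, n_per_class, seed=int(rng.integers(2**31)), r_max=cfg.r_max
    )
    n_test = max(1, int(test_fraction * n_per_class))
    ds_test = make_cloud_dataset(
        default_cloud_specs(sigma), n_test, seed=int(rng.integers(2**31)), r_max=cfg.r_max
    )
    enc_train = encode_cloud_dataset(ds_train, cfg)
    enc_test = encode_cloud_dataset(ds_test, cfg)

    model_cfg = ModelConfig(
        signature=enc_train.signature.entries,
        latent_dim=latent_dim,
        width=width,
        variational=variational,
        seed=int(rng.integers(2**31)),
    )
    model = HVAE(model_cfg)
    weights = LossWeights(alpha=1.0, beta=beta)
    opt_seed = int(rng.integers(2**31))
    report = train(
        model, enc_train, weights, epochs=epochs, batch_size=32, lr=lr,
        seed=opt_seed, patience=None,
    )
    if fine_epochs:
        report_fine = train(
            model, enc_train, weights, epochs=fine_epochs, batch_size=32, lr=lr / 4,
            seed=opt_seed + 1, patience=None,
        )
        report.reconstruction += report_fine.reconstruction
        report.kl += report_fine.kl
        report.total += report_fine.total
        report.epochs += report_fine.epochs

    rec_test = model.reconstruct(enc_test)
    test_cosine = float(np.mean(cosine_loss(enc_test, rec_test)))
    result = {
        "model": model,
        "report": report,
        "zft_config": cfg,
        "train_tensors": enc_train,
        "test_tensors": enc_test,
        "train_labels": ds_train.labels,
        "test_labels": ds_test.labels,
        "test_cosine_loss": test_cosine,
    }
    if evaluate_latent:
        z_train = model.encode(enc_train).z
        z_test = model.encode(enc_test).z
        k = len(np.unique(ds_test.labels))
        assignments = kmeans_cluster(np.vstack([z_train, z_test]), k, seed=seed)
        labels_all = np.concatenate([ds_train.labels, ds_test.labels])
        purity, vm = clustering_metrics(labels_all, assignments)
        acc = latent_classifier_eval(
            z_train, ds_train.labels, z_test, ds_test.labels, mode="linear", seed=seed
        )
        result.update(
            purity=purity, v_measure=vm, linear_classifier_accuracy=acc,
            z_train=z_train, z_test=z_test,
        )
    return result
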
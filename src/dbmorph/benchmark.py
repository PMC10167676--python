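"""Paired benchmark of classification methods on one synthetic cohort.

One autoencoder is trained once; then, over a set of shared site-stratified
splits, six methods are scored on identical test sets: the latent CNN
(AE+CNN), SVM and random forest on PCA features, SVM and random forest on
flattened latents, and the CNN on raw volumes with no reduction. Sharing
the split plan across methods is what licenses the paired t-test on
per-split accuracies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .autoencoder import encode_batch, train_autoencoder
from .baselines import cnn_no_reduction, fit_baseline, pca_reduce
from .classifier import predict_batch, stratified_split, train_classifier
from .stats import confusion_metrics, roc_auc
from .synthetic import generate_cohort

__all__ = ["benchmark_methods", "run_benchmark", "METHODS"]

METHODS = ("ae_cnn", "pca_svm", "pca_rf", "latent_svm", "latent_rf", "cnn_raw")


def benchmark_methods(
    data: np.ndarray,
    labels,
    sites,
    latents: np.ndarray,
    n_splits: int = 20,
    test_ratio: float = 0.2,
    seed: int = 0,
    variance_retained: float = 0.90,
    cnn_kwargs: dict | None = None,
    methods=METHODS,
) -> pd.DataFrame:
    """Score each method on each shared split; returns one row per
    (method, split) with accuracy/precision/recall."""
    labels = np.asarray(labels).astype(int)
    sites = np.asarray(sites)
    flat_latents = latents.reshape(latents.shape[0], -1)
    kwargs = dict(cnn_kwargs or {})
    rows = []
    for k in range(n_splits):
        split_seed = seed * 100_003 + k
        split = stratified_split(labels, sites, test_ratio=test_ratio,
                                 seed=split_seed)
        y_test = labels[split.test_ids]
        if "ae_cnn" in methods:
            model, _ = train_classifier(latents, labels, split,
                                        seed=split_seed, **kwargs)
            probs = predict_batch(model, latents[split.test_ids])
            m = confusion_metrics(probs, y_test)
            try:
                auc, _ = roc_auc(probs, y_test)
            except ValueError:
                auc = float("nan")
            rows.append({"method": "ae_cnn", "split_id": k, "auc": auc,
                         **_trim(m)})
        if "pca_svm" in methods or "pca_rf" in methods:
            pca_feats, _ = pca_reduce(data, variance_retained,
                                      train_idx=split.train_ids)
        for name, feats, model_kind in (
                ("pca_svm", "pca", "margin_classifier"),
                ("pca_rf", "pca", "tree_ensemble"),
                ("latent_svm", "latent", "margin_classifier"),
                ("latent_rf", "latent", "tree_ensemble")):
            if name not in methods:
                continue
            x = pca_feats if feats == "pca" else flat_latents
            m = fit_baseline(x, labels, split, model_kind, seed=split_seed % (2**31))
            rows.append({"method": name, "split_id": k, **_trim(m)})
        if "cnn_raw" in methods:
            m, _, _ = cnn_no_reduction(data, labels, split, seed=split_seed,
                                       **kwargs)
            rows.append({"method": "cnn_raw", "split_id": k, **_trim(m)})
    return pd.DataFrame(rows)


def _trim(m: dict) -> dict:
    return {"accuracy": m["accuracy"], "precision": m["precision"],
            "recall": m["recall"]}


def run_benchmark(cfg) -> pd.DataFrame:
    """Generate the cohort, train the AE once, and run the full method grid."""
    from .synthetic import default_regions

    regions = (default_regions(tuple(cfg.dims), group_shift=cfg.group_shift)
               if cfg.group_shift is not None else None)
    cohort = generate_cohort(
        n_cases=cfg.n_cases, n_controls=cfg.n_controls, dims=tuple(cfg.dims),
        regions=regions, subject_noise_sd=cfg.subject_noise_sd,
        fwhm_mm=cfg.fwhm_mm, score_effect=cfg.score_effect, seed=cfg.seed)
    data = cohort.volume_array()
    split = stratified_split(cohort, test_ratio=cfg.test_ratio, seed=cfg.seed)
    ae, _ = train_autoencoder(data, split, steps=cfg.ae_steps,
                              learning_rate=cfg.ae_lr,
                              batch_size=cfg.ae_batch_size,
                              latent_channels=cfg.latent_channels,
                              seed=cfg.seed)
    latents = encode_batch(ae, data)
    return benchmark_methods(
        data, cohort.labels, cohort.sites, latents, n_splits=cfg.n_splits,
        test_ratio=cfg.test_ratio, seed=cfg.seed,
        cnn_kwargs={"learning_rate": cfg.cnn_lr,
                    "check_every": cfg.cnn_check_every,
                    "dropout_rate": cfg.cnn_dropout,
                    "max_steps": cfg.cnn_max_steps})
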
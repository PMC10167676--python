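"""Reference methods the AE+CNN approach is compared against.

Four shallow pipelines — PCA or flattened-latent features fed to a
support-vector machine or a random forest at their documented library
defaults — plus a CNN trained directly on the full-dimensional volumes
with no dimensionality reduction. All methods consume the identical
site-stratified split plan so that per-split accuracies can be compared
with a paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from . import nnet
from .autoencoder import LatentGrid, TrainTrace
from .classifier import LatentCNN, SplitPlan, train_classifier
from .stats import confusion_metrics

__all__ = [
    "FeatureVector",
    "pca_reduce",
    "flatten_latent",
    "unflatten_latent",
    "fit_baseline",
    "cnn_no_reduction",
    "build_raw_cnn",
]

BASELINE_MODELS = ("margin_classifier", "tree_ensemble")


@dataclass(frozen=True)
class FeatureVector:
    subject_id: str
    values: np.ndarray
    provenance: str  # pca | flattened_latent | raw_flat


def pca_reduce(volumes, variance_retained: float = 0.90, train_idx=None):
    """SVD-based reduction keeping the smallest component count whose
    cumulative explained variance reaches ``variance_retained``.

    Volumes are flattened to vectors first. The projection is fitted on
    ``train_idx`` rows only (all rows when None) and applied to every volume,
    so no test information leaks into the basis.

    Returns ``(features, basis)`` where ``features`` is (n, k) and ``basis``
    the fitted :class:`sklearn.decomposition.PCA`.
    """
    if not 0.0 < variance_retained <= 1.0:
        raise ValueError("variance_retained must be in (0, 1]")
    x = np.asarray(volumes, dtype=float)
    x = x.reshape(x.shape[0], -1)
    if x.shape[0] < 2:
        raise ValueError("need at least two volumes")
    fit_rows = x if train_idx is None else x[np.asarray(train_idx)]
    if np.allclose(fit_rows.var(axis=0), 0.0):
        raise ValueError("degenerate input: all training volumes identical")
    n_comp = (variance_retained if variance_retained < 1.0
              else min(fit_rows.shape) - 1)
    basis = PCA(n_components=n_comp, svd_solver="full")
    basis.fit(fit_rows)
    return basis.transform(x), basis


def flatten_latent(z: LatentGrid | np.ndarray) -> np.ndarray:
    """Channel-major (C-order) flattening: index = ((c*d + i)*h + j)*w + k."""
    values = z.values if isinstance(z, LatentGrid) else np.asarray(z)
    return values.reshape(-1)


def unflatten_latent(flat: np.ndarray, channels: int, spatial_dims) -> LatentGrid:
    return LatentGrid(np.asarray(flat).reshape(channels, *spatial_dims))


def _make_model(model: str, seed: int):
    # documented library defaults; only the seed is pinned for reproducibility
    if model == "margin_classifier":
        return SVC(random_state=seed)
    if model == "tree_ensemble":
        return RandomForestClassifier(random_state=seed)
    raise ValueError(f"unknown model {model!r}; expected one of {BASELINE_MODELS}")


def fit_baseline(features, labels, split: SplitPlan, model: str,
                 seed: int = 0) -> dict:
    """Train an SVM or random forest at library defaults; test metrics returned.

    The fitted estimator's parameters are included under ``"params"`` so a
    run record pins the exact defaults in effect.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    tr, te = split.train_ids, split.test_ids
    if len(np.unique(y[tr])) < 2:
        raise ValueError("training labels contain a single class")
    est = _make_model(model, seed)
    est.fit(x[tr], y[tr])
    pred = est.predict(x[te])
    metrics = confusion_metrics(pred.astype(float), y[te])
    metrics["method"] = model
    metrics["params"] = est.get_params()
    return metrics


def build_raw_cnn(input_dims, dropout_rate: float = 0.55, seed: int = 0,
                  latent_channels: int = 32) -> LatentCNN:
    """The latent-CNN architecture generalised to full-dimensional input.

    Three extra kernel-2/stride-2 convolution stages (channels 1 -> 8 -> 16
    -> 32, batch-normalised rectifiers) bring the raw volume down to
    latent-grid scale, then the standard classifier head follows.
    """
    from .autoencoder import latent_dims_for
    from .classifier import build_classifier

    dims = tuple(int(d) for d in input_dims)
    reduced = latent_dims_for(dims)
    rng = np.random.default_rng(seed)
    c1, c2 = 8, 16
    front = [
        nnet.HalvingConv3d(1, c1, rng), nnet.BatchNorm(c1, spatial=True), nnet.ReLU(),
        nnet.HalvingConv3d(c1, c2, rng), nnet.BatchNorm(c2, spatial=True), nnet.ReLU(),
        nnet.HalvingConv3d(c2, latent_channels, rng),
        nnet.BatchNorm(latent_channels, spatial=True), nnet.ReLU(),
    ]
    head = build_classifier(reduced, latent_channels=latent_channels,
                            dropout_rate=dropout_rate, seed=seed)
    net = nnet.Sequential(front + head.net.layers)
    return LatentCNN(net=net, latent_dims=dims, latent_channels=1,
                     dropout_rate=dropout_rate, seed=seed)


def cnn_no_reduction(volumes, labels, split: SplitPlan,
                     learning_rate: float = 1e-3, check_every: int = 200,
                     dropout_rate: float = 0.55, batch_size: int = 16,
                     max_steps: int = 4000, seed: int = 0) -> tuple[dict, LatentCNN, TrainTrace]:
    """Train the full-dimensional CNN (no autoencoder) and return test metrics."""
    x = np.asarray(volumes, dtype=float)
    model = build_raw_cnn(x.shape[1:], dropout_rate=dropout_rate, seed=seed)
    model, trace = train_classifier(
        x[:, None], labels, split, learning_rate=learning_rate,
        check_every=check_every, dropout_rate=dropout_rate,
        batch_size=batch_size, max_steps=max_steps, seed=seed, model=model)
    from .classifier import predict_batch
    probs = predict_batch(model, x[split.test_ids][:, None])
    metrics = confusion_metrics(probs, np.asarray(labels)[split.test_ids])
    metrics["method"] = "cnn_no_reduction"
    return metrics, model, trace
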
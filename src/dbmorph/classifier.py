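"""Site-stratified splitting and the supervised CNN on latent grids.

The classifier consumes only the autoencoder's latent grids — site labels
are used for constructing train/test splits but never reach the model, so
classification is site-agnostic by construction. Architecture: one 3D
convolution (kernel 3, stride 2, 24 filters; 15 x 18 x 15 latents map to
7 x 8 x 7 feature maps), a 128-unit fully connected rectifier layer, and a
single output neuron whose logistic sigmoid is the case probability. Batch
normalisation follows each trainable layer with dropout after it (rate
0.5-0.6 by default); neither is active at prediction time. Training uses
Adam on binary cross-entropy with early stopping on held-out loss
divergence, returning the best-held-out-loss checkpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nnet
from .autoencoder import LatentGrid, TrainTrace

__all__ = [
    "SplitPlan",
    "LatentCNN",
    "Prediction",
    "stratified_split",
    "build_classifier",
    "train_classifier",
    "predict_probability",
    "predict_batch",
    "conv_output_dims",
]


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint train/test index sets covering the cohort, plus provenance."""

    train_ids: np.ndarray
    test_ids: np.ndarray
    seed: int
    test_ratio: float

    def __post_init__(self):
        tr = np.asarray(self.train_ids, dtype=int)
        te = np.asarray(self.test_ids, dtype=int)
        if np.intersect1d(tr, te).size:
            raise ValueError("train and test sets overlap")
        object.__setattr__(self, "train_ids", tr)
        object.__setattr__(self, "test_ids", te)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(cohort_or_labels, sites=None, test_ratio: float = 0.2,
                     seed: int = 0, per_site_ratio: dict | None = None) -> SplitPlan:
    """Site-by-group stratified train/test split.

    Each (site, group) stratum contributes round-half-up(ratio * stratum size)
    test members; the totals are then adjusted by at most one subject per
    stratum (seeded, largest-remainder order) so the global test size equals
    ceil(test_ratio * n) — e.g. 39 of 192 at ratio 0.2. ``per_site_ratio``
    overrides the ratio for selected sites (used to balance per-subject test
    appearances across repeated splits).
    """
    if hasattr(cohort_or_labels, "labels"):
        labels = cohort_or_labels.labels
        sites = cohort_or_labels.sites
    else:
        labels = np.asarray(cohort_or_labels)
        sites = np.asarray(sites)
    if not 0.0 < test_ratio < 1.0:
        raise ValueError(f"test_ratio must be in (0, 1), got {test_ratio}")
    n = len(labels)
    rng = np.random.default_rng(seed)

    strata = []
    for site in sorted(set(sites.tolist())):
        ratio = (per_site_ratio or {}).get(site, test_ratio)
        for group in (0, 1):
            idx = np.flatnonzero((sites == site) & (labels == group))
            if idx.size:
                strata.append((idx, ratio))

    global_target = int(np.ceil(test_ratio * n))
    if per_site_ratio:
        global_target = sum(_round_half_up(r * len(idx)) for idx, r in strata)
    test_parts, targets, takes = [], [], []
    for idx, ratio in strata:
        target = ratio * idx.size
        test_parts.append(rng.permutation(idx))
        takes.append(min(_round_half_up(target), idx.size))
        targets.append(target)
    takes = np.asarray(takes, dtype=int)
    targets = np.asarray(targets)
    deficit = global_target - int(takes.sum())
    # adjust one subject at a time, seeded order, preferring moves that keep
    # every stratum within +/-1 of its real-valued target
    while deficit != 0:
        step = 1 if deficit > 0 else -1
        ok = [s for s in range(len(strata))
              if 0 <= takes[s] + step <= len(test_parts[s])
              and abs(takes[s] + step - targets[s]) <= 1.0]
        if not ok:
            ok = [s for s in range(len(strata))
                  if 0 <= takes[s] + step <= len(test_parts[s])]
            if not ok:
                break
            ok = [min(ok, key=lambda s: abs(takes[s] + step - targets[s]))]
        s = ok[int(rng.integers(0, len(ok)))]
        takes[s] += step
        deficit -= step
    test_idx = np.concatenate([p[:k] for p, k in zip(test_parts, takes)])
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    return SplitPlan(train_ids=np.sort(train_idx), test_ids=np.sort(test_idx),
                     seed=seed, test_ratio=test_ratio)


def conv_output_dims(latent_dims, kernel: int = 3, stride: int = 2) -> tuple:
    """Spatial dims after the classifier convolution: floor((d - 3) / 2) + 1."""
    return tuple(nnet.StridedConv3d.out_dim(d, kernel, stride) for d in latent_dims)


@dataclass
class LatentCNN:
    """Classifier network and its architecture metadata."""

    net: nnet.Sequential
    latent_dims: tuple
    latent_channels: int
    dropout_rate: float
    seed: int

    def hyperparams(self) -> dict:
        return {"latent_dims": list(self.latent_dims),
                "latent_channels": self.latent_channels,
                "dropout_rate": self.dropout_rate, "seed": self.seed}


@dataclass(frozen=True)
class Prediction:
    subject_id: str
    probability: float
    hard_label: int

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")


def build_classifier(latent_dims, latent_channels: int = 32,
                     conv_channels: int = 24, hidden_units: int = 128,
                     dropout_rate: float = 0.55, seed: int = 0) -> LatentCNN:
    """One conv stage (24 filters), 128-unit dense stage, single-logit output.

    Batch normalisation after each trainable layer, dropout after each batch
    normalisation; requires every latent spatial dim >= 3.
    """
    latent_dims = tuple(int(d) for d in latent_dims)
    if any(d < 3 for d in latent_dims):
        raise ValueError(f"latent dims {latent_dims} too small for a 3x3x3 kernel")
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError("dropout_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    drop_rng = np.random.default_rng(seed + 10_000)
    out_dims = conv_output_dims(latent_dims)
    flat = conv_channels * int(np.prod(out_dims))
    net = nnet.Sequential([
        nnet.StridedConv3d(latent_channels, conv_channels, rng),
        nnet.BatchNorm(conv_channels, spatial=True),
        nnet.ReLU(),
        nnet.Dropout(dropout_rate, drop_rng),
        nnet.Flatten(),
        nnet.Dense(flat, hidden_units, rng),
        nnet.BatchNorm(hidden_units, spatial=False),
        nnet.ReLU(),
        nnet.Dropout(dropout_rate, drop_rng),
        nnet.Dense(hidden_units, 1, rng, init="glorot"),
    ])
    return LatentCNN(net=net, latent_dims=latent_dims,
                     latent_channels=latent_channels,
                     dropout_rate=dropout_rate, seed=seed)


def _latent_stack(latents) -> np.ndarray:
    if isinstance(latents, (list, tuple)):
        latents = np.stack([z.values if isinstance(z, LatentGrid) else np.asarray(z)
                            for z in latents])
    return np.asarray(latents, dtype=float)


def train_classifier(
    latents,
    labels,
    split: SplitPlan,
    learning_rate: float = 1e-3,
    check_every: int = 200,
    dropout_rate: float = 0.55,
    batch_size: int = 16,
    max_steps: int = 4000,
    patience: int = 5,
    seed: int = 0,
    model: LatentCNN | None = None,
) -> tuple[LatentCNN, TrainTrace]:
    """Train the latent CNN with Adam / binary cross-entropy / early stopping.

    Held-out loss is evaluated every ``check_every`` update steps. Training
    stops early when held-out loss has exceeded its running minimum for
    ``patience`` consecutive checks while train loss is non-increasing (the
    divergence signature of overfitting), or at ``max_steps``. The returned
    parameters are the best-held-out-loss checkpoint seen.
    """
    z = _latent_stack(latents).astype(np.float32)
    y = np.asarray(labels).astype(int)
    tr, te = split.train_ids, split.test_ids
    if len(np.unique(y[tr])) < 2:
        raise ValueError("training labels contain a single class")
    if model is None:
        model = build_classifier(z.shape[2:], latent_channels=z.shape[1],
                                 dropout_rate=dropout_rate, seed=seed)
    for p in model.net.params:
        p.value = p.value.astype(np.float32)
        p.grad = np.zeros_like(p.value)
    rng = np.random.default_rng(seed + 1)
    opt = nnet.Adam(model.net.params, lr=learning_rate)
    trace = TrainTrace()

    def full_loss(idx) -> float:
        total = 0.0
        for i in range(0, len(idx), 64):
            sel = idx[i: i + 64]
            logits = model.net.forward(z[sel], train=False)
            loss, _ = nnet.bce_with_logits(logits, y[sel])
            total += loss * len(sel)
        return total / len(idx)

    best_state = model.net.get_state()
    best_loss = np.inf
    best_step = 0
    bad_checks = 0
    prev_train_check = np.inf
    window: list[float] = []
    for step in range(1, max_steps + 1):
        idx = tr[rng.integers(0, len(tr), size=min(batch_size, len(tr)))]
        opt.zero_grad()
        logits = model.net.forward(z[idx], train=True)
        loss, grad = nnet.bce_with_logits(logits, y[idx])
        model.net.backward(grad.astype(np.float32))
        opt.step()
        window.append(loss)
        if step % check_every == 0 or step == max_steps:
            test_loss = full_loss(te)
            train_loss = float(np.mean(window[-check_every:]))
            trace.record(step, train_loss, test_loss)
            if test_loss < best_loss:
                best_loss = test_loss
                best_state = model.net.get_state()
                best_step = step
                bad_checks = 0
            else:
                bad_checks += 1
            diverging = bad_checks >= patience and train_loss <= prev_train_check
            prev_train_check = train_loss
            if diverging:
                break
    trace.stopping_step = best_step
    model.net.set_state(best_state)
    return model, trace


def predict_batch(model: LatentCNN, latents) -> np.ndarray:
    """Case probabilities for a stack of latents (inference mode, no dropout)."""
    z = _latent_stack(latents)
    logits = model.net.forward(z, train=False)
    return nnet.sigmoid(logits.ravel())


def predict_probability(model: LatentCNN, z, subject_id: str = "",
                        threshold: float = 0.5) -> Prediction:
    """Deterministic case probability for one latent grid."""
    values = z.values if isinstance(z, LatentGrid) else np.asarray(z, dtype=float)
    if values.shape != (model.latent_channels, *model.latent_dims):
        raise ValueError(
            f"latent shape {values.shape} != model "
            f"{(model.latent_channels, *model.latent_dims)}")
    p = float(predict_batch(model, values[None])[0])
    return Prediction(subject_id=subject_id, probability=p,
                      hard_label=int(p >= threshold))
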
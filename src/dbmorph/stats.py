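"""Repeated-split evaluation metrics and post-hoc statistics.

Classification quality is summarised per split by accuracy, precision
(TP / (TP + FP)), recall (TP / (TP + FN)) at threshold 0.5, and rank-based
AUC (the probability that a random case outscores a random control, ties
counting one half). Across repeated site-stratified splits, each subject's
median test-set case probability is collected, and method comparisons use a
paired t-test with a paired Cohen's d. Ordinary least-squares regression and
Pearson correlation (with Fisher-z confidence intervals) support the
post-hoc analyses relating classification probability to behavioural scores
and regional volume measures. p-values are reported unadjusted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve

from .classifier import SplitPlan, predict_batch, stratified_split, train_classifier

__all__ = [
    "confusion_metrics",
    "roc_auc",
    "repeated_splits",
    "paired_accuracy_ttest",
    "ols_regression",
    "pearson_corr",
    "appearance_balanced_ratios",
]


def confusion_metrics(probabilities, labels, threshold: float = 0.5) -> dict:
    """Accuracy, precision, recall from thresholded probabilities.

    Precision is NaN with ``precision_defined=False`` when the classifier
    makes no positive predictions.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {y.shape}")
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    n = tp + fp + fn + tn
    precision_defined = (tp + fp) > 0
    return {
        "accuracy": (tp + tn) / n,
        "precision": tp / (tp + fp) if precision_defined else float("nan"),
        "precision_defined": precision_defined,
        "recall": tp / (tp + fn) if (tp + fn) > 0 else float("nan"),
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
    }


def roc_auc(probabilities, labels) -> tuple[float, pd.DataFrame]:
    """Rank-based AUC and the full ROC curve over all thresholds."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for ROC analysis")
    auc = float(roc_auc_score(y, p))
    fpr, tpr, thr = roc_curve(y, p)
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def appearance_balanced_ratios(sites, n_splits: int, base_ratio: float = 0.2,
                               min_appearances: int = 5,
                               max_appearances: int = 30) -> dict:
    """Per-site test ratios so expected per-subject test appearances over
    ``n_splits`` splits land in [min, max]; larger sites get smaller ratios."""
    lo = min_appearances / n_splits
    hi = max_appearances / n_splits
    sites = np.asarray(sites)
    counts = pd.Series(sites).value_counts()
    scale = counts.median() / counts  # shrink the ratio for larger sites
    return {site: float(np.clip(base_ratio * scale[site], lo, hi))
            for site in counts.index}


def repeated_splits(
    labels,
    sites,
    latents,
    n_splits: int = 100,
    test_ratio: float = 0.2,
    seed: int = 0,
    per_site_ratio: dict | None = None,
    train_kwargs: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retrain the latent CNN from random initialisation on each of
    ``n_splits`` site-stratified splits of frozen latents.

    Returns ``(metrics, subject_summary)``: one metric row per split
    (accuracy, precision, recall, AUC) and one row per subject with the
    number of test appearances and the median test-set case probability.
    """
    if n_splits < 2:
        raise ValueError("n_splits must be >= 2")
    labels = np.asarray(labels).astype(int)
    sites = np.asarray(sites)
    z = np.asarray(latents, dtype=float)
    kwargs = dict(train_kwargs or {})
    rows = []
    probs_per_subject: dict[int, list[float]] = {i: [] for i in range(len(labels))}
    for k in range(n_splits):
        split_seed = seed * 100_003 + k
        split = stratified_split(labels, sites, test_ratio=test_ratio,
                                 seed=split_seed, per_site_ratio=per_site_ratio)
        model, _ = train_classifier(z, labels, split, seed=split_seed, **kwargs)
        p = predict_batch(model, z[split.test_ids])
        m = confusion_metrics(p, labels[split.test_ids])
        try:
            auc, _ = roc_auc(p, labels[split.test_ids])
        except ValueError:
            auc = float("nan")
        rows.append({"split_id": k, "accuracy": m["accuracy"],
                     "precision": m["precision"], "recall": m["recall"],
                     "auc": auc, "n_test": len(split.test_ids)})
        for i, prob in zip(split.test_ids, p):
            probs_per_subject[int(i)].append(float(prob))
    metrics = pd.DataFrame(rows)
    summary = pd.DataFrame({
        "subject_index": np.arange(len(labels)),
        "n_test_appearances": [len(probs_per_subject[i]) for i in range(len(labels))],
        "median_probability": [float(np.median(probs_per_subject[i]))
                               if probs_per_subject[i] else float("nan")
                               for i in range(len(labels))],
        "label": labels,
    })
    return metrics, summary


def paired_accuracy_ttest(acc_a, acc_b) -> dict:
    """Paired t-test of per-split accuracies plus paired Cohen's d.

    Cohen's d = mean(diff) / sd(diff). Zero-variance differences are flagged
    (``degenerate=True``) with NaN t and p.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need equal-length vectors of >= 3 paired values")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd <= 1e-12 * max(1.0, abs(diff.mean())):
        return {"t": float("nan"), "p": float("nan"),
                "cohens_d": 0.0 if np.allclose(diff, 0) else float("inf"),
                "mean_diff": float(diff.mean()), "degenerate": True}
    t, p = sps.ttest_rel(a, b)
    return {"t": float(t), "p": float(p),
            "cohens_d": float(diff.mean() / sd),
            "mean_diff": float(diff.mean()), "degenerate": False}


def ols_regression(response, predictors, names: list[str] | None = None) -> dict:
    """Least-squares fit with intercept; per-coefficient t and p values.

    ``predictors`` is (n, p); categorical site indicators should be one-hot
    encoded by the caller (largest site as reference).
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictors, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations, got n={n}, p={p}")
    design = sm.add_constant(x)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, design).fit()
    coef_names = ["intercept"] + (names if names is not None
                                  else [f"x{i}" for i in range(p)])
    return {"coefficients": dict(zip(coef_names, fit.params)),
            "t_values": dict(zip(coef_names, fit.tvalues)),
            "p_values": dict(zip(coef_names, fit.pvalues)),
            "r_squared": float(fit.rsquared),
            "f_statistic": float(fit.fvalue) if p > 0 else float("nan"),
            "df": (int(fit.df_model), int(fit.df_resid))}


def pearson_corr(x, y) -> dict:
    """Product-moment correlation with two-sided p and Fisher-z 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of >= 3 values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    n = len(x)
    if n > 3 and abs(r) < 1.0:
        zr = np.arctanh(r)
        half = 1.959963984540054 / np.sqrt(n - 3)
        ci = (float(np.tanh(zr - half)), float(np.tanh(zr + half)))
    else:
        ci = (float("nan"), float("nan"))
    return {"r": float(r), "p": float(p), "ci95": ci, "n": n}
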
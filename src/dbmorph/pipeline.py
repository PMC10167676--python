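"""End-to-end orchestration: simulate -> preprocess -> train AE -> encode ->
train CNN -> evaluate -> perturb -> report, driven by one validated config.

Every stage writes its outputs, the seed, and a hash of the configuration
into a run directory, so a run is resumable and any artifact can be traced
to the exact configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import baselines, perturbation, stats
from .autoencoder import (build_autoencoder, encode_batch, save_autoencoder,
                          train_autoencoder)
from .classifier import predict_batch, stratified_split, train_classifier
from .synthetic import generate_cohort
from .volume_io import write_mask, write_volume

logger = logging.getLogger("dbmorph")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All pipeline parameters; validated before any stage runs."""

    out_dir: str = "runs/run"
    seed: int = 0
    dims: tuple = (40, 48, 40)
    n_cases: int = 96
    n_controls: int = 96
    fwhm_mm: float = 8.0
    subject_noise_sd: float = 2.0
    score_effect: float = 6.0
    group_shift: float | None = None  # None -> generator default regions
    latent_channels: int = 32
    ae_steps: int = 2500
    ae_lr: float = 1e-3
    ae_batch_size: int = 16
    cnn_lr: float = 1e-3
    cnn_dropout: float = 0.55
    cnn_check_every: int = 200
    cnn_max_steps: int = 4000
    n_splits: int = 20
    test_ratio: float = 0.2
    n_filters: int = 2000
    filter_extent: tuple = (8, 8, 8)
    roi_threshold: float = 0.25
    perturb_subjects: int | None = None  # None -> all

    def validate(self, classifier: bool = True) -> None:
        if any(d < 8 for d in self.dims):
            raise ValueError(
                f"dims {tuple(self.dims)} too small: three stride-2 halvings "
                "need every dim >= 8")
        latent = tuple(d // 8 for d in self.dims)
        if classifier and any(d < 3 for d in latent):
            raise ValueError(
                f"latent dims {latent} too small for the classifier's 3x3x3 kernel")
        if not 0.0 < self.test_ratio < 1.0:
            raise ValueError("test_ratio must be in (0, 1)")
        if not 0.0 <= self.cnn_dropout < 1.0:
            raise ValueError("cnn_dropout must be in [0, 1)")
        if self.fwhm_mm <= 0:
            raise ValueError("fwhm_mm must be positive")
        if any(e > d for e, d in zip(self.filter_extent, self.dims)):
            raise ValueError("filter extent larger than dims")
        if not 0.0 < self.roi_threshold < 1.0:
            raise ValueError("roi_threshold must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("dims", "filter_extent"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stamp(cfg: RunConfig, path: Path, extra: dict | None = None) -> None:
    record = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    record.update(extra or {})
    path.write_text(json.dumps(record, indent=2, default=str))


def run_pipeline(cfg: RunConfig, write_volumes: bool = False) -> Path:
    """Run every stage; returns the run directory.

    ``write_volumes`` controls whether per-subject NIfTI volumes are saved
    (off by default; they are large and regenerable from the seed).
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run directory: %s (config %s)", out, cfg.config_hash())
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(cfg)))

    # --- simulate -------------------------------------------------------
    logger.info("stage simulate: %d cases / %d controls at dims %s",
                cfg.n_cases, cfg.n_controls, cfg.dims)
    regions = None
    if cfg.group_shift is not None:
        from .synthetic import default_regions
        regions = default_regions(cfg.dims, group_shift=cfg.group_shift)
    cohort = generate_cohort(
        n_cases=cfg.n_cases, n_controls=cfg.n_controls, dims=tuple(cfg.dims),
        regions=regions, subject_noise_sd=cfg.subject_noise_sd,
        fwhm_mm=cfg.fwhm_mm, score_effect=cfg.score_effect, seed=cfg.seed)
    cohort.metadata().to_csv(out / "metadata.csv", index=False)
    truth = [{"center": list(r.center), "radius_voxels": r.radius_voxels,
              "group_shift": r.group_shift, "target_group": r.target_group}
             for r in cohort.truth]
    _stamp(cfg, out / "truth.json", {"regions": truth})
    write_mask(cohort.mask, out / "mask.nii.gz")
    if write_volumes:
        vol_dir = out / "volumes"
        vol_dir.mkdir(exist_ok=True)
        for s, v in zip(cohort.subjects, cohort.volumes):
            write_volume(v, vol_dir / f"{s.subject_id}.nii.gz")
    data = cohort.volume_array()

    # --- train AE + encode ---------------------------------------------
    split = stratified_split(cohort, test_ratio=cfg.test_ratio, seed=cfg.seed)
    logger.info("stage train-ae: %d steps", cfg.ae_steps)
    ae, trace = train_autoencoder(
        data, split, steps=cfg.ae_steps, learning_rate=cfg.ae_lr,
        batch_size=cfg.ae_batch_size, latent_channels=cfg.latent_channels,
        seed=cfg.seed)
    save_autoencoder(ae, out / "autoencoder")
    pd.DataFrame({"step": trace.steps, "train_loss": trace.train_loss,
                  "test_loss": trace.test_loss}).to_csv(
        out / "ae_loss_trace.csv", index=False)
    latents = encode_batch(ae, data)
    np.save(out / "latents.npy", latents)

    # --- train CNN ------------------------------------------------------
    logger.info("stage train-cnn")
    model, cnn_trace = train_classifier(
        latents, cohort.labels, split, learning_rate=cfg.cnn_lr,
        check_every=cfg.cnn_check_every, dropout_rate=cfg.cnn_dropout,
        max_steps=cfg.cnn_max_steps, seed=cfg.seed)
    pd.DataFrame({"step": cnn_trace.steps, "train_loss": cnn_trace.train_loss,
                  "test_loss": cnn_trace.test_loss}).to_csv(
        out / "cnn_loss_trace.csv", index=False)
    probs = predict_batch(model, latents)
    pred = pd.DataFrame({"subject_id": [s.subject_id for s in cohort.subjects],
                         "probability": probs,
                         "label": (probs >= 0.5).astype(int),
                         "in_test": np.isin(np.arange(len(cohort)), split.test_ids)})
    pred.to_csv(out / "predictions.csv", index=False)

    # --- evaluate -------------------------------------------------------
    logger.info("stage evaluate: %d splits", cfg.n_splits)
    metrics, subject_summary = stats.repeated_splits(
        cohort.labels, cohort.sites, latents, n_splits=cfg.n_splits,
        test_ratio=cfg.test_ratio, seed=cfg.seed,
        train_kwargs={"learning_rate": cfg.cnn_lr,
                      "check_every": cfg.cnn_check_every,
                      "dropout_rate": cfg.cnn_dropout,
                      "max_steps": cfg.cnn_max_steps})
    metrics.to_csv(out / "split_metrics.csv", index=False)
    subject_summary.to_csv(out / "subject_probabilities.csv", index=False)

    # --- perturb --------------------------------------------------------
    logger.info("stage perturb: %d filters", cfg.n_filters)
    filters = perturbation.make_filters(
        tuple(cfg.dims), n_filters=cfg.n_filters,
        extent=tuple(cfg.filter_extent), seed=cfg.seed)
    subject_idx = np.arange(len(cohort))
    if cfg.perturb_subjects is not None:
        rng = np.random.default_rng(cfg.seed)
        subject_idx = np.sort(rng.choice(subject_idx, cfg.perturb_subjects,
                                         replace=False))
    maps = []
    for i in subject_idx:
        y_star = float(probs[i])
        maps.append(perturbation.sensitivity_map(
            data[i], y_star, filters, ae, model,
            subject_id=cohort.subjects[i].subject_id))
    case_map, ctrl_map = perturbation.group_importance(
        maps, cohort.labels[subject_idx])
    np.save(out / "case_importance.npy", case_map)
    np.save(out / "control_importance.npy", ctrl_map)
    rois = perturbation.extract_rois(case_map, threshold=cfg.roi_threshold)
    rois += perturbation.extract_rois(-ctrl_map, threshold=cfg.roi_threshold)
    if rois:
        perturbation.roi_table(rois, [data[i] for i in subject_idx]).to_csv(
            out / "rois.csv", index=False)

    # --- report ---------------------------------------------------------
    report = {
        "ae_final_heldout_mse": trace.test_loss[-1],
        "mean_accuracy": float(metrics["accuracy"].mean()),
        "mean_auc": float(metrics["auc"].mean()),
        "mean_precision": float(metrics["precision"].mean()),
        "mean_recall": float(metrics["recall"].mean()),
        "n_rois": len(rois),
    }
    _stamp(cfg, out / "report.json", report)
    logger.info("report: %s", report)
    return out
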
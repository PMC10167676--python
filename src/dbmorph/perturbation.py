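"""Perturbation-based sensitivity maps and region-of-interest extraction.

The importance of each voxel for a subject's classification is estimated by
occlusion with noise: many filters are drawn, each placing a block (8x8x8 by
default) of i.i.d. standard-normal noise at a random in-bounds position; the
perturbed image F = X + K is encoded and classified, and the signed error
e = y* - y (base probability minus perturbed probability) is added to every
voxel the block covered. Dividing the accumulated error by each voxel's
visit count yields the normalised per-subject sensitivity map S. Positive
values mark voxels whose corruption pulls a case's probability down;
negative values mark voxels whose corruption pushes a control's probability
up. Group-mean maps thresholded at a 25-percentage-point probability change
give regions of interest (26-connected components) over which mean Jacobian
values are extracted per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .autoencoder import Autoencoder
from .classifier import LatentCNN, predict_batch
from .nnet import sigmoid
from .volume_io import JacobianVolume

__all__ = [
    "SubsampledFilter",
    "SensitivityMap",
    "RegionOfInterest",
    "make_filters",
    "perturb",
    "classification_error",
    "sensitivity_map",
    "group_importance",
    "extract_rois",
    "roi_mean_jacobian",
    "roi_table",
]


@dataclass(frozen=True)
class SubsampledFilter:
    """A noise block: position, extent, and the standard-normal draws."""

    origin: tuple[int, int, int]
    extent: tuple[int, int, int]
    noise_block: np.ndarray
    filter_id: int = 0

    def __post_init__(self):
        if self.noise_block.shape != tuple(self.extent):
            raise ValueError("noise block shape must equal extent")

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(o, o + e) for o, e in zip(self.origin, self.extent))


@dataclass
class SensitivityMap:
    """Accumulated error field, visit counts, and their normalised ratio."""

    accum: np.ndarray
    visits: np.ndarray
    subject_id: str = ""
    normalized: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.accum.shape != self.visits.shape:
            raise ValueError("accum and visits must share dims")
        self.normalized = np.divide(
            self.accum, self.visits,
            out=np.zeros_like(self.accum), where=self.visits > 0)


@dataclass(frozen=True)
class RegionOfInterest:
    label: int
    voxels: np.ndarray  # boolean grid
    sign: str  # case_important | control_important

    def __post_init__(self):
        if not self.voxels.any():
            raise ValueError("ROI must be non-empty")

    @property
    def size(self) -> int:
        return int(self.voxels.sum())

    @property
    def centroid(self) -> tuple[float, ...]:
        return tuple(float(c) for c in np.argwhere(self.voxels).mean(axis=0))


def make_filters(dims, n_filters: int = 10_000, extent=(8, 8, 8),
                 seed: int = 0) -> list[SubsampledFilter]:
    """Draw filters with origins uniform over all in-bounds block positions."""
    dims = tuple(int(d) for d in dims)
    extent = tuple(int(e) for e in extent)
    if any(e > d for e, d in zip(extent, dims)):
        raise ValueError(f"extent {extent} larger than dims {dims}")
    rng = np.random.default_rng(seed)
    filters = []
    for j in range(n_filters):
        origin = tuple(int(rng.integers(0, d - e + 1))
                       for d, e in zip(dims, extent))
        filters.append(SubsampledFilter(
            origin=origin, extent=extent,
            noise_block=rng.standard_normal(extent), filter_id=j))
    return filters


def perturb(x, k: SubsampledFilter) -> np.ndarray:
    """F = X + K: add the noise block at its origin; everything else unchanged.

    Values are not clipped — the encoder accepts out-of-range inputs.
    """
    voxels = x.voxels if isinstance(x, JacobianVolume) else np.asarray(x, dtype=float)
    sl = k.slices()
    if any(s.stop > d for s, d in zip(sl, voxels.shape)):
        raise ValueError("filter block does not fit in volume dims")
    out = voxels.copy()
    out[sl] += k.noise_block
    return out


def classification_error(y_star: float, y_perturbed: float) -> float:
    """Signed probability change e = y* - y."""
    for v in (y_star, y_perturbed):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"probability {v} outside [0, 1]")
    return y_star - y_perturbed


def sensitivity_map(x, y_star: float, filters, encoder: Autoencoder,
                    classifier: LatentCNN, subject_id: str = "",
                    batch_size: int = 32) -> SensitivityMap:
    """Accumulate per-filter classification errors into a subject's map.

    For each filter: perturb -> encode -> predict -> error; the error is
    added uniformly over the block's voxels and each covered voxel's visit
    count incremented. Filters are evaluated in batches for speed; results
    are independent of the batch size.
    """
    if len(filters) == 0:
        raise ValueError("empty filter list")
    voxels = x.voxels if isinstance(x, JacobianVolume) else np.asarray(x, dtype=float)
    accum = np.zeros(voxels.shape)
    visits = np.zeros(voxels.shape)
    for start in range(0, len(filters), batch_size):
        chunk = filters[start: start + batch_size]
        batch = np.stack([perturb(voxels, k) for k in chunk])
        z = encoder.encoder.forward(batch[:, None], train=False)
        probs = predict_batch(classifier, z)
        for k, y in zip(chunk, probs):
            e = classification_error(y_star, float(y))
            sl = k.slices()
            accum[sl] += e
            visits[sl] += 1
    return SensitivityMap(accum=accum, visits=visits, subject_id=subject_id)


def group_importance(maps: list[SensitivityMap], labels) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise mean of normalised maps per group: (case_mean, control_mean)."""
    labels = np.asarray(labels).astype(int)
    if len(maps) != len(labels):
        raise ValueError("one label per map required")
    case = [m.normalized for m, l in zip(maps, labels) if l == 1]
    ctrl = [m.normalized for m, l in zip(maps, labels) if l == 0]
    if not case or not ctrl:
        raise ValueError("both groups must be non-empty")
    return np.mean(case, axis=0), np.mean(ctrl, axis=0)


def extract_rois(mean_map: np.ndarray, threshold: float = 0.25,
                 min_size: int = 27) -> list[RegionOfInterest]:
    """Threshold |map| >= threshold, label 26-connected components.

    ``threshold`` is in probability-change units (0.25 = a 25-percentage-point
    change in classification probability). Components smaller than
    ``min_size`` voxels are dropped. Sign is taken from the component's mean:
    positive maps mark case-important voxels, negative control-important.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    mask = np.abs(mean_map) >= threshold
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    rois = []
    for lab in range(1, n + 1):
        comp = labeled == lab
        if comp.sum() < min_size:
            continue
        sign = "case_important" if mean_map[comp].mean() >= 0 else "control_important"
        rois.append(RegionOfInterest(label=len(rois) + 1, voxels=comp, sign=sign))
    return rois


def roi_mean_jacobian(volume, roi: RegionOfInterest) -> float:
    """Arithmetic mean of a subject's volume over the ROI voxels."""
    voxels = (volume.voxels if isinstance(volume, JacobianVolume)
              else np.asarray(volume, dtype=float))
    if roi.voxels.shape != voxels.shape:
        raise ValueError("ROI dims must match volume dims")
    return float(voxels[roi.voxels].mean())


def roi_table(rois: list[RegionOfInterest], volumes) -> pd.DataFrame:
    """Per-ROI rows: label, sign, size, centroid, and per-subject mean values."""
    rows = []
    for roi in rois:
        row = {"label": roi.label, "sign": roi.sign, "size": roi.size,
               "centroid": roi.centroid}
        for i, v in enumerate(volumes):
            row[f"mean_sub{i:04d}"] = roi_mean_jacobian(v, roi)
        rows.append(row)
    return pd.DataFrame(rows)
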
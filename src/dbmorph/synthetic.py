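"""Synthetic cohorts of Jacobian-like volumes with planted ground truth.

Real multi-site case-control Jacobian data are consortium-held, so every
downstream stage of this package is exercised on generated cohorts whose
group effects, site structure, and behavioural correlations are planted and
therefore known exactly. A subject's field is built on the log-Jacobian
scale as

    smooth shared background + i.i.d. Gaussian subject noise
    + group_shift inside each effect region (for that region's target group)

then smoothed with the configured FWHM, unit-scaled over the whole cohort,
and masked — the same post-processing chain applied to real data.

Behavioural standard scores (non-word reading WA, real-word reading WID,
passage comprehension PC, rapid naming RAN, verbal comprehension VIQ) are
drawn as ``100 - score_effect * z(region mean intensity) + noise`` with each
score driven by one case-target region, so cases (whose case-target regions
carry a positive volume shift) score below controls and scores correlate
negatively with their driving region's intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import (
    FWHM_TO_SIGMA,
    BrainMask,
    JacobianVolume,
    apply_mask,
    scale_dataset_unit_interval,
)

__all__ = [
    "SCORE_KEYS",
    "EffectRegion",
    "SubjectRecord",
    "Cohort",
    "default_sites",
    "default_regions",
    "ellipsoid_mask",
    "generate_cohort",
    "planted_truth_mask",
    "region_mask",
]

SCORE_KEYS = ("WA", "WID", "PC", "RAN", "VIQ")


@dataclass(frozen=True)
class EffectRegion:
    """A spherical region carrying an additive log-scale mean shift for one group."""

    center: tuple[int, int, int]
    radius_voxels: float
    group_shift: float
    target_group: str = "case"  # "case" or "control"

    def __post_init__(self):
        if self.radius_voxels < 1:
            raise ValueError("radius_voxels must be >= 1")
        if self.target_group not in ("case", "control"):
            raise ValueError("target_group must be 'case' or 'control'")

    def fits(self, dims) -> bool:
        return all(self.radius_voxels <= c and c + self.radius_voxels <= d - 1
                   for c, d in zip(self.center, dims))


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    site: str
    age: float
    sex: str
    scores: dict[str, float]
    total_brain_volume: float

    def __post_init__(self):
        if not self.group or not self.site:
            raise ValueError("group and site must be non-empty")
        if not all(np.isfinite(v) for v in self.scores.values()):
            raise ValueError("scores must be finite")


@dataclass
class Cohort:
    """Subjects, their processed volumes, the mask, and the planted truth."""

    subjects: list[SubjectRecord]
    volumes: list[JacobianVolume]
    mask: BrainMask
    truth: list[EffectRegion] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if len(self.subjects) != len(self.volumes):
            raise ValueError("one volume per subject required")
        dims = {v.dims for v in self.volumes}
        if len(dims) > 1:
            raise ValueError("all volumes must share dims")
        if self.volumes and self.volumes[0].dims != self.mask.dims:
            raise ValueError("mask dims must match volume dims")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def labels(self) -> np.ndarray:
        """1 for cases, 0 for controls."""
        return np.array([1 if s.group == "case" else 0 for s in self.subjects])

    @property
    def sites(self) -> np.ndarray:
        return np.array([s.site for s in self.subjects])

    def volume_array(self) -> np.ndarray:
        """(n_subjects, D, H, W) stacked voxel data."""
        return np.stack([v.voxels for v in self.volumes])

    def metadata(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {"subject_id": s.subject_id, "group": s.group, "site": s.site,
                   "age": s.age, "sex": s.sex,
                   "total_brain_volume": s.total_brain_volume}
            row.update(s.scores)
            rows.append(row)
        return pd.DataFrame(rows)


def default_sites() -> list[dict]:
    """Four research sites; the last is deliberately over-imbalanced
    (many more cases than controls), emulating a common multi-site pathology."""
    return [
        {"site": "siteA", "case_frac": 0.25, "control_frac": 0.30},
        {"site": "siteB", "case_frac": 0.25, "control_frac": 0.32},
        {"site": "siteC", "case_frac": 0.27, "control_frac": 0.34},
        {"site": "siteD", "case_frac": 0.23, "control_frac": 0.04},
    ]


def default_regions(dims, group_shift: float = 0.08) -> list[EffectRegion]:
    """Three case-target and two control-target spheres at fixed fractional
    positions, radius scaled to the grid."""
    d = np.asarray(dims)
    r = max(2.0, round(min(d) / 8))
    at = lambda fx, fy, fz: tuple(int(round(f * (n - 1))) for f, n in
                                  zip((fx, fy, fz), d))
    return [
        EffectRegion(at(0.30, 0.35, 0.40), r, group_shift, "case"),
        EffectRegion(at(0.65, 0.60, 0.55), r, group_shift, "case"),
        EffectRegion(at(0.45, 0.70, 0.35), r, group_shift, "case"),
        EffectRegion(at(0.35, 0.55, 0.65), r, group_shift, "control"),
        EffectRegion(at(0.60, 0.35, 0.60), r, group_shift, "control"),
    ]


def strong_regions(dims, group_shift: float = 0.6,
                   radius_divisor: int = 5) -> list[EffectRegion]:
    """The strong planted-effect condition: spheres large enough to survive
    8 mm smoothing (radius ~ min(dim)/radius_divisor) with a shift of several
    times the smoothed subject-field standard deviation."""
    d = np.asarray(dims)
    r = max(2.0, round(min(d) / radius_divisor))
    at = lambda fx, fy, fz: tuple(int(round(f * (n - 1))) for f, n in
                                  zip((fx, fy, fz), d))
    return [
        EffectRegion(at(0.30, 0.35, 0.40), r, group_shift, "case"),
        EffectRegion(at(0.65, 0.60, 0.55), r, group_shift, "case"),
        EffectRegion(at(0.45, 0.70, 0.35), r, group_shift, "case"),
        EffectRegion(at(0.35, 0.55, 0.65), r, group_shift, "control"),
        EffectRegion(at(0.60, 0.35, 0.60), r, group_shift, "control"),
    ]


def ellipsoid_mask(dims, semi_axis_frac: float = 0.47) -> BrainMask:
    """Brain-like mask: axis-aligned ellipsoid inscribed in the grid."""
    grids = np.meshgrid(*[np.arange(n) for n in dims], indexing="ij")
    r2 = sum(((g - (n - 1) / 2.0) / (semi_axis_frac * n)) ** 2
             for g, n in zip(grids, dims))
    return BrainMask(r2 <= 1.0)


def region_mask(region: EffectRegion, dims) -> np.ndarray:
    """Boolean grid of the discrete ball |x - center| <= radius."""
    grids = np.meshgrid(*[np.arange(n) for n in dims], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, region.center))
    return d2 <= region.radius_voxels ** 2


def planted_truth_mask(cohort: Cohort) -> BrainMask:
    """Binary grid marking every voxel inside any planted effect region."""
    if not cohort.truth:
        raise ValueError("cohort has no effect regions")
    dims = cohort.mask.dims
    m = np.zeros(dims, dtype=bool)
    for region in cohort.truth:
        m |= region_mask(region, dims)
    return BrainMask(m)


def _apportion(total: int, fracs: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment: integer counts matching fractions exactly."""
    raw = fracs / fracs.sum() * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


def generate_cohort(
    n_cases: int = 96,
    n_controls: int = 96,
    dims: tuple[int, int, int] = (40, 48, 40),
    sites: list[dict] | None = None,
    regions: list[EffectRegion] | None = None,
    subject_noise_sd: float = 2.0,
    fwhm_mm: float = 8.0,
    score_effect: float = 6.0,
    seed: int = 0,
    *,
    background_sd: float = 0.25,
    background_fwhm_mm: float = 24.0,
    score_noise_sd: float = 12.0,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    mask: BrainMask | None = None,
) -> Cohort:
    """Generate a case-control cohort with planted regional effects.

    Parameters mirror the study conditions this generator emulates: smoothed,
    log-transformed, unit-scaled Jacobian maps with group-specific regional
    volume effects, per-site sampling imbalance (one over-imbalanced site by
    default), and behavioural scores correlated with the planted regions.
    ``subject_noise_sd`` is the standard deviation of the i.i.d. voxel noise
    *before* smoothing; smoothing shrinks it into a spatially correlated
    subject-specific field.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("counts must be positive")
    if sites is None:
        sites = default_sites()
    if len(sites) == 0:
        raise ValueError("empty site list")
    if regions is None:
        regions = default_regions(dims)
    for region in regions:
        if not region.fits(dims):
            raise ValueError(f"region at {region.center} does not fit in dims {dims}")
    rng = np.random.default_rng(seed)
    if mask is None:
        mask = ellipsoid_mask(dims)

    # site assignment: exact apportionment of requested per-site proportions
    case_counts = _apportion(n_cases, np.array([s["case_frac"] for s in sites]))
    ctrl_counts = _apportion(n_controls, np.array([s["control_frac"] for s in sites]))
    site_names = [s["site"] for s in sites]
    groups = ["case"] * n_cases + ["control"] * n_controls
    site_labels = (
        [name for name, c in zip(site_names, case_counts) for _ in range(c)]
        + [name for name, c in zip(site_names, ctrl_counts) for _ in range(c)]
    )

    sigma = [fwhm_mm / FWHM_TO_SIGMA / s for s in voxel_size_mm]
    bg_sigma = [background_fwhm_mm / FWHM_TO_SIGMA / s for s in voxel_size_mm]
    background = ndimage.gaussian_filter(rng.standard_normal(dims), bg_sigma,
                                         mode="constant")
    bstd = background.std()
    if bstd > 0:
        background *= background_sd / bstd

    shift_fields = {
        "case": np.zeros(dims), "control": np.zeros(dims)}
    for region in regions:
        shift_fields[region.target_group] += (
            region.group_shift * region_mask(region, dims))

    n = n_cases + n_controls
    volumes = []
    for i in range(n):
        raw = (background
               + shift_fields[groups[i]]
               + rng.normal(0.0, subject_noise_sd, size=dims))
        smoothed = ndimage.gaussian_filter(raw, sigma, mode="constant")
        volumes.append(JacobianVolume(smoothed, voxel_size_mm=voxel_size_mm,
                                      subject_id=f"sub{i:04d}", stage="logged"))
    volumes = scale_dataset_unit_interval(volumes, mask)
    volumes = [apply_mask(v, mask) for v in volumes]

    # behavioural scores driven by case-target region mean intensities
    case_regions = [r for r in regions if r.target_group == "case"]
    region_means = {}
    for ridx, region in enumerate(case_regions):
        rm = region_mask(region, dims)
        vals = np.array([float(v.voxels[rm].mean()) for v in volumes])
        sd = vals.std()
        region_means[ridx] = (vals - vals.mean()) / sd if sd > 0 else vals * 0.0

    subjects = []
    for i in range(n):
        scores = {}
        for k, key in enumerate(SCORE_KEYS):
            noise = rng.normal(0.0, score_noise_sd)
            if case_regions:
                z = region_means[k % len(case_regions)][i]
                scores[key] = 100.0 - score_effect * z + noise
            else:
                scores[key] = 100.0 + noise
        tbv = rng.normal(1250.0, 100.0) + (15.0 if groups[i] == "control" else 0.0)
        subjects.append(SubjectRecord(
            subject_id=f"sub{i:04d}", group=groups[i], site=site_labels[i],
            age=float(np.clip(rng.normal(9.86, 1.56), 6.0, 14.0)),
            sex="F" if rng.random() < 0.5 else "M",
            scores=scores, total_brain_volume=tbv))

    return Cohort(subjects=subjects, volumes=volumes, mask=mask,
                  truth=list(regions), seed=seed)
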
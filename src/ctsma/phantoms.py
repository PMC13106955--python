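"""Synthetic trabecular-bone phantoms with known ground truth.

The generator emulates the data a paired MR/CT knee study provides: a
high-resolution MR-like volume in which individual trabeculae are resolved
(voxels 0.234 x 0.234 x 1.5 mm), a degraded CT-like counterpart in which they
are not (0.977 x 0.977 x 1.0 mm, blur + downsample + intensity remap + noise),
two bone compartments ("femur"/"tibia") separated by a joint gap and movable
by independent rigid transforms, anatomical landmarks with exact coordinates,
and a cohort whose per-region morphometry shifts with a latent 3-class
disease grade plus a continuous severity score.

The microstructure model is a thresholded Gaussian random field: white noise
smoothed at a correlation length ``structure_scale`` and binarized at the
quantile that yields the requested bone volume fraction inside each bone
compartment.  This reproduces the interconnected plate/rod statistics of
trabecular bone well enough for morphometry and regression testing while
giving continuous control over BV/TV.  BV/TV here is always the foreground
fraction *within the bone compartments* (the joint gap contains no bone by
construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import RigidTransform, Volume3D, resample_to_grid

__all__ = [
    "PhantomConfig",
    "LabeledVolume",
    "CohortSpec",
    "CohortSubject",
    "generate_microstructure",
    "simulate_ct",
    "apply_bone_misalignment",
    "generate_cohort",
    "OutOfBoundsError",
]

MR_PATCH_SHAPE = (48, 48, 16)
CT_PATCH_SHAPE = (12, 12, 12)
JOINT_GAP_MM = 5.0


class OutOfBoundsError(ValueError):
    """A transform moved a landmark outside the field of view."""


@dataclass
class AffineIntensityMap:
    """Monotone affine MR-to-CT intensity remap, ``v -> scale * v + offset``."""

    scale: float = 0.8
    offset: float = 0.1

    def __call__(self, v):
        return self.scale * v + self.offset


@dataclass
class PhantomConfig:
    grid_shape_mr: tuple[int, int, int] = (128, 128, 40)
    spacing_mr: tuple[float, float, float] = (0.234, 0.234, 1.5)
    spacing_ct: tuple[float, float, float] = (0.977, 0.977, 1.0)
    target_bvtv: float | tuple[float, float] = 0.30  # scalar or (femur, tibia)
    structure_scale: float = 0.35  # mm, correlation length of the random field
    psf_sigma: float = 0.8  # mm, CT point-spread blur
    ct_noise_sd: float = 0.05
    mr_noise_sd: float = 0.03
    intensity_map: AffineIntensityMap = field(default_factory=AffineIntensityMap)
    landmark_margin_mm: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mr) or any(s <= 0 for s in self.spacing_ct):
            raise ValueError("voxel spacing must be strictly positive")
        for b in self.bvtv_per_bone:
            if not 0.0 < b < 1.0:
                raise ValueError(f"target_bvtv must lie in (0, 1), got {b}")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be non-negative")
        if any(n < p for n, p in zip(self.grid_shape_mr, MR_PATCH_SHAPE)):
            raise ValueError(
                f"grid_shape_mr {self.grid_shape_mr} cannot hold a {MR_PATCH_SHAPE} MR patch")

    @property
    def bvtv_per_bone(self) -> tuple[float, float]:
        if np.isscalar(self.target_bvtv):
            return (float(self.target_bvtv), float(self.target_bvtv))
        f, t = self.target_bvtv
        return (float(f), float(t))


@dataclass
class LabeledVolume:
    """A phantom realization: intensity + ground-truth structure + landmarks."""

    intensity: Volume3D
    microstructure: Volume3D  # binary, trabecular bone = 1, MR grid
    bone_labels: Volume3D  # 0 background/gap, 1 femur-like, 2 tibia-like
    landmarks: pd.DataFrame  # columns: name, bone, x_mm, y_mm, z_mm

    def __post_init__(self) -> None:
        for v in (self.microstructure, self.bone_labels):
            if v.shape != self.intensity.shape or v.spacing != self.intensity.spacing:
                raise ValueError("component volumes must share grid and spacing")
        micro = self.microstructure.data.astype(bool)
        if np.any(micro & (self.bone_labels.data == 0)):
            raise ValueError("microstructure must lie inside the bone compartments")
        for _, row in self.landmarks.iterrows():
            if not self.intensity.contains_point([row.x_mm, row.y_mm, row.z_mm]):
                raise ValueError(f"landmark {row['name']} outside volume bounds")

    @property
    def realized_bvtv(self) -> float:
        region = self.bone_labels.data > 0
        return float(self.microstructure.data[region].mean())


def _compartment_labels(shape, spacing, origin) -> np.ndarray:
    """Split the grid into two half-volumes along z with a fixed joint gap."""
    z = origin[2] + np.arange(shape[2]) * spacing[2]
    zc = origin[2] + 0.5 * (shape[2] - 1) * spacing[2]
    labels = np.zeros(shape, dtype=np.int8)
    labels[:, :, z < zc - JOINT_GAP_MM / 2] = 1
    labels[:, :, z > zc + JOINT_GAP_MM / 2] = 2
    return labels


def _corner_landmarks(labels: np.ndarray, spacing, origin, margin_mm: float) -> pd.DataFrame:
    """Landmarks at the corners of each compartment's bounding box, pulled
    inward by ``margin_mm`` so that moderate rigid motions keep them in-FOV."""
    rows = []
    for lab, bone in ((1, "femur"), (2, "tibia")):
        idx = np.nonzero(labels == lab)
        lo = np.array([a.min() for a in idx], dtype=float) * spacing + np.asarray(origin)
        hi = np.array([a.max() for a in idx], dtype=float) * spacing + np.asarray(origin)
        lo2 = np.minimum(lo + margin_mm, (lo + hi) / 2)
        hi2 = np.maximum(hi - margin_mm, (lo + hi) / 2)
        for cx in (lo2[0], hi2[0]):
            for cy in (lo2[1], hi2[1]):
                for cz in (lo2[2], hi2[2]):
                    rows.append({"name": f"{bone}_c{len(rows)}", "bone": bone,
                                 "x_mm": cx, "y_mm": cy, "z_mm": cz})
    return pd.DataFrame(rows)


def generate_microstructure(config: PhantomConfig) -> LabeledVolume:
    """Realize a two-compartment trabecular phantom from a seeded random field.

    The smoothed Gaussian field is thresholded at the per-compartment quantile
    that delivers the requested BV/TV, so the realized bone fraction matches
    the target up to quantile discreteness (well within +/- 0.02).
    """
    shape, spacing = tuple(config.grid_shape_mr), config.spacing_mr
    origin = (0.0, 0.0, 0.0)
    ss = np.random.SeedSequence(config.seed)
    rng_field, rng_mr = [np.random.default_rng(s) for s in ss.spawn(2)]

    sigma_vox = [config.structure_scale / s for s in spacing]
    field3d = ndimage.gaussian_filter(rng_field.standard_normal(shape), sigma_vox)

    labels = _compartment_labels(shape, spacing, origin)
    micro = np.zeros(shape, dtype=np.uint8)
    for lab, bvtv in zip((1, 2), config.bvtv_per_bone):
        region = labels == lab
        thr = np.quantile(field3d[region], 1.0 - bvtv)
        micro[region & (field3d > thr)] = 1

    # MR-like appearance: bone bright against marrow, light smoothing + noise
    mr = ndimage.gaussian_filter(micro.astype(np.float64), 0.5)
    mr += config.mr_noise_sd * rng_mr.standard_normal(shape)

    landmarks = _corner_landmarks(labels, spacing, origin, config.landmark_margin_mm)
    return LabeledVolume(
        intensity=Volume3D(mr, spacing, origin),
        microstructure=Volume3D(micro, spacing, origin),
        bone_labels=Volume3D(labels, spacing, origin),
        landmarks=landmarks,
    )


def simulate_ct(mr: LabeledVolume | Volume3D, config: PhantomConfig) -> Volume3D:
    """Degrade an MR-grid volume into its CT-like counterpart.

    Gaussian blur by the physical point-spread ``psf_sigma``, resampling to
    the CT grid covering the same field of view, monotone intensity remap,
    then additive Gaussian noise.  Origin is preserved so MR and CT live in
    the same physical space.
    """
    vol = mr.intensity if isinstance(mr, LabeledVolume) else mr
    if config.psf_sigma < 0:
        raise ValueError("psf_sigma must be non-negative")
    data = np.asarray(vol.data, dtype=np.float64)
    if config.psf_sigma > 0:
        data = ndimage.gaussian_filter(data, [config.psf_sigma / s for s in vol.spacing])
    blurred = vol.copy_with(data)

    shape_ct = tuple(int(round(e / s)) for e, s in zip(vol.extent_mm, config.spacing_ct))
    reference = Volume3D(np.zeros(shape_ct), config.spacing_ct, vol.origin)
    ct = resample_to_grid(blurred, reference, interpolation="linear")

    ct.data = np.asarray(config.intensity_map(ct.data), dtype=np.float64)
    if config.ct_noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
        ct.data = ct.data + config.ct_noise_sd * rng.standard_normal(ct.shape)
    return ct


def apply_bone_misalignment(vol: LabeledVolume, tf_femur: RigidTransform,
                            tf_tibia: RigidTransform) -> tuple[Volume3D, pd.DataFrame]:
    """Move each bone compartment under its own rigid transform.

    The intensity volume is resampled once per transform and composited by
    nearest-compartment assignment (distance transform in physical units), so
    bone voxels follow their own bone exactly and the gap/background follows
    whichever compartment is closer.  Returns the composited volume and a
    landmark table with both original (``x_mm`` ...) and transformed
    (``xt_mm`` ...) physical coordinates, the exact ground truth for TRE.
    """
    labels = vol.bone_labels.data
    spacing = vol.bone_labels.spacing
    d1 = ndimage.distance_transform_edt(labels != 1, sampling=spacing)
    d2 = ndimage.distance_transform_edt(labels != 2, sampling=spacing)
    femur_region = d1 <= d2

    moved_f = resample_to_grid(vol.intensity, vol.intensity, motion=tf_femur)
    moved_t = resample_to_grid(vol.intensity, vol.intensity, motion=tf_tibia)
    out = vol.intensity.copy_with(np.where(femur_region, moved_f.data, moved_t.data))

    lm = vol.landmarks.copy()
    pts = lm[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    moved = np.empty_like(pts)
    for i, bone in enumerate(lm["bone"]):
        tf = tf_femur if bone == "femur" else tf_tibia
        moved[i] = tf.apply(pts[i])
        if not vol.intensity.contains_point(moved[i]):
            raise OutOfBoundsError(
                f"landmark {lm['name'].iloc[i]} moved outside the field of view")
    lm[["xt_mm", "yt_mm", "zt_mm"]] = moved
    return out, lm


# --- Cohort generation -----------------------------------------------------

@dataclass
class ScoreModel:
    """Continuous severity score: linear in the per-bone BV/TV targets plus
    Gaussian noise (a stand-in for a semi-quantitative MRI severity score)."""

    intercept: float = 12.0
    coef_femur: float = -15.0
    coef_tibia: float = -15.0
    noise_sd: float = 0.3

    def mean(self, bvtv_femur: float, bvtv_tibia: float) -> float:
        return self.intercept + self.coef_femur * bvtv_femur + self.coef_tibia * bvtv_tibia


@dataclass
class CohortSpec:
    n_subjects: int = 24
    class_proportions: tuple[float, float, float] = (0.375, 0.3125, 0.3125)
    # per-class mean BV/TV target (normal / mild / advanced): bone loss with grade
    class_bvtv_means: tuple[float, float, float] = (0.35, 0.28, 0.21)
    class_bvtv_sd: float = 0.01
    score_model: ScoreModel = field(default_factory=ScoreModel)
    # per-subject trabecular scale: thickness varies independently of BV/TV
    structure_scale_range: tuple[float, float] = (0.25, 0.45)
    rot_range_deg: float = 5.0
    trans_range_mm: float = 2.5
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    # optional per-class femur-minus-tibia BV/TV offset (spatial-interaction cohorts)
    class_fm_tibia_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.n_subjects < 6:
            raise ValueError("need at least 6 subjects for patient-level folds")


@dataclass
class CohortSubject:
    subject_id: str
    phantom: LabeledVolume  # aligned ground truth (same space as CT)
    ct: Volume3D
    mr_misaligned: Volume3D
    landmarks: pd.DataFrame
    tf_femur: RigidTransform
    tf_tibia: RigidTransform
    class_label: int  # 0 normal, 1 mild, 2 advanced
    score: float
    bvtv_targets: tuple[float, float]


def _class_counts(n: int, proportions) -> np.ndarray:
    counts = np.floor(np.asarray(proportions) * n).astype(int)
    # distribute the remainder by largest fractional part
    frac = np.asarray(proportions) * n - counts
    for i in np.argsort(-frac)[: n - counts.sum()]:
        counts[i] += 1
    if np.any(counts == 0):
        import warnings

        warnings.warn("a class received zero subjects at this cohort size")
    return counts


def generate_cohort(spec: CohortSpec) -> list[CohortSubject]:
    """Draw a reproducible cohort of phantoms with class-dependent morphometry.

    Each subject's per-bone BV/TV target is drawn from its class distribution,
    a phantom is realized to match, the MR presentation is misaligned by
    per-bone rigid transforms drawn from the stated range, and the severity
    score is the score model evaluated on the true regional targets plus noise.
    """
    counts = _class_counts(spec.n_subjects, spec.class_proportions)
    labels = np.concatenate([np.full(c, k) for k, c in enumerate(counts)])
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    rng.shuffle(labels)

    subjects: list[CohortSubject] = []
    subject_seeds = np.random.SeedSequence(spec.seed + 1).generate_state(spec.n_subjects) % (2**31)
    for i, (lab, sub_seed) in enumerate(zip(labels, subject_seeds)):
        srng = np.random.default_rng(int(sub_seed))
        base = np.clip(srng.normal(spec.class_bvtv_means[lab], spec.class_bvtv_sd), 0.03, 0.97)
        off = spec.class_fm_tibia_offset[lab]
        bvtv_f = float(np.clip(base + off / 2, 0.03, 0.97))
        bvtv_t = float(np.clip(base - off / 2, 0.03, 0.97))

        scale = float(srng.uniform(*spec.structure_scale_range))
        cfg = replace(spec.phantom, target_bvtv=(bvtv_f, bvtv_t),
                      structure_scale=scale, seed=int(sub_seed))
        phantom = generate_microstructure(cfg)
        ct = simulate_ct(phantom, cfg)

        center = phantom.intensity.center_mm
        tfs = []
        for _ in range(2):
            rot = srng.uniform(-spec.rot_range_deg, spec.rot_range_deg, 3)
            tra = srng.uniform(-spec.trans_range_mm, spec.trans_range_mm, 3)
            tfs.append(RigidTransform.from_euler(rot, tra, center))
        mr_mis, lm = apply_bone_misalignment(phantom, tfs[0], tfs[1])

        score = spec.score_model.mean(bvtv_f, bvtv_t) + spec.score_model.noise_sd * srng.standard_normal()
        subjects.append(CohortSubject(
            subject_id=f"S{i:03d}", phantom=phantom, ct=ct, mr_misaligned=mr_mis,
            landmarks=lm, tf_femur=tfs[0], tf_tibia=tfs[1],
            class_label=int(lab), score=float(score), bvtv_targets=(bvtv_f, bvtv_t)))
    return subjects
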
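"""Shared fixtures.

The expensive artifacts (articulated-phantom registration, the distillation
cohort and its trained models, the SPSNet toy runs, the end-to-end toy
pipeline) are session-scoped: several test modules assert different
properties of the same run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from ctsma.core import RigidTransform, Volume3D, resample_to_grid
from ctsma.distill import (DistillConfig, DistillWeights, sample_patch_pairs,
                           train_student, train_teacher)
from ctsma.evaluation import agreement_report
from ctsma.phantoms import (CohortSpec, PhantomConfig, apply_bone_misalignment,
                            generate_cohort, generate_microstructure, simulate_ct)

warnings.filterwarnings("ignore", category=UserWarning)

# training settings of the scaled-down study: lr and dropout follow the
# package's toy presets (see docs/methods.md), widths 6 (teacher) / 4 (student)
TEACHER_CFG = dict(width=6, epochs=8, batch_size=32, lr=3e-3, dropout=0.2)
STUDENT_CFG = dict(width=4, epochs=5, batch_size=32, lr=3e-3, dropout=0.2)


@pytest.fixture(scope="session")
def small_phantom():
    """A small two-compartment phantom with its simulated CT (fast grid)."""
    cfg = PhantomConfig(grid_shape_mr=(96, 96, 32), seed=3)
    vol = generate_microstructure(cfg)
    return cfg, vol, simulate_ct(vol, cfg)


@pytest.fixture(scope="session")
def articulated(small_phantom):
    """Phantom with known per-bone misalignment (+8/-8 deg about the joint
    axis plus translations) and the CT-grid bone masks."""
    cfg, vol, ct = small_phantom
    c = vol.intensity.center_mm
    tf_femur = RigidTransform.from_euler((0, 0, 8), (2.0, -1.5, 1.0), c)
    tf_tibia = RigidTransform.from_euler((0, 0, -8), (-2.0, 1.0, -1.0), c)
    moved, landmarks = apply_bone_misalignment(vol, tf_femur, tf_tibia)
    lab_ct = resample_to_grid(vol.bone_labels, ct, interpolation="nearest")
    return {
        "config": cfg, "phantom": vol, "ct": ct, "moved": moved,
        "landmarks": landmarks, "tf_femur": tf_femur, "tf_tibia": tf_tibia,
        "mask_femur": lab_ct.data == 1, "mask_tibia": lab_ct.data == 2,
    }


@pytest.fixture(scope="session")
def registration_results(articulated):
    """Global and bone-wise registration of the articulated phantom."""
    from ctsma.registration import register_bonewise, register_rigid

    art = articulated
    glob = register_rigid(art["moved"], art["ct"])
    rf, rt = register_bonewise(art["moved"], art["ct"], art["mask_femur"],
                               art["mask_tibia"], init=glob.transform)
    return {"global": glob, "femur": rf, "tibia": rt}


@pytest.fixture(scope="session")
def distill_cohort():
    """The distillation study conditions: a ~2,000-patch cohort of 24
    phantoms (single trabecular scale so every parameter stays partially
    CT-recoverable), patient-level 18/6 train/test split."""
    spec = CohortSpec(n_subjects=24, seed=5, structure_scale_range=(0.35, 0.35))
    cohort = generate_cohort(spec)
    pairs = []
    for s in cohort:
        mask = Volume3D((s.phantom.bone_labels.data > 0).astype(np.uint8),
                        s.phantom.bone_labels.spacing)
        pairs += sample_patch_pairs(
            s.phantom.intensity, s.ct, mask, 90, seed=int(s.subject_id[1:]),
            truth_binary=s.phantom.microstructure, subject_id=s.subject_id)
    train_ids = {s.subject_id for s in cohort[:18]}
    train = [p for p in pairs if p.subject_id in train_ids]
    test = [p for p in pairs if p.subject_id not in train_ids]
    return {"cohort": cohort, "train": train, "test": test,
            "truth_test": np.array([p.truth.as_array() for p in test]),
            "ct_test": np.array([p.ct_patch for p in test]),
            "mr_test": np.array([p.mr_patch for p in test])}


@pytest.fixture(scope="session")
def distill_results(distill_cohort):
    """Teacher plus distilled/baseline student pairs over three seeds,
    with agreement reports on the held-out patients."""
    dc = distill_cohort
    teacher, _ = train_teacher(np.array([p.mr_patch for p in dc["train"]]),
                               [p.truth for p in dc["train"]],
                               DistillConfig(seed=0, **TEACHER_CFG))
    teacher_report = agreement_report(teacher.predict(dc["mr_test"]), dc["truth_test"])
    runs = []
    for seed in (0, 1, 2):
        cfg = DistillConfig(seed=seed, **STUDENT_CFG)
        student, _ = train_student(dc["train"], teacher, DistillWeights(), cfg)
        baseline, _ = train_student(dc["train"], None, None, cfg)
        runs.append({
            "seed": seed,
            "student": student,
            "baseline": baseline,
            "student_report": agreement_report(student.predict(dc["ct_test"]),
                                               dc["truth_test"]),
            "baseline_report": agreement_report(baseline.predict(dc["ct_test"]),
                                                dc["truth_test"]),
        })
    return {"teacher": teacher, "teacher_report": teacher_report, "runs": runs}


@pytest.fixture(scope="session")
def spsnet_toy_runs():
    """Paired SPSNet trainings (lambda_MI = 0.5 vs 0) on the affine-remap
    toy task: CT is an affine intensity remap of a smooth random MR volume."""
    from scipy.ndimage import gaussian_filter

    from ctsma.synthesis import SynthConfig, SynthLossWeights, train_spsnet

    rng = np.random.default_rng(0)
    base = gaussian_filter(rng.random((32, 32, 16)), 1.5)
    mr = Volume3D(base, (1, 1, 1))
    ct = Volume3D(0.6 * base + 0.2, (1, 1, 1))
    out = {}
    for tag, lam in (("with_mi", 0.5), ("no_mi", 0.0)):
        cfg = SynthConfig(max_steps=300, batch_size=8, width=8, seed=1, lr=1e-3,
                          weights=SynthLossWeights(1.0, lam))
        model, history = train_spsnet([mr], [ct], cfg)
        out[tag] = (model, history)
    out["mr"] = mr
    out["ct"] = ct
    return out


@pytest.fixture(scope="session")
def toy_run(tmp_path_factory):
    """A complete toy-scale pipeline run."""
    from ctsma.pipeline import RunConfig, run_pipeline

    out = tmp_path_factory.mktemp("toy_run")
    cfg = RunConfig(out_dir=str(out), seed=0, scale="toy")
    manifest = run_pipeline(cfg)
    return {"dir": out, "config": cfg, "manifest": manifest}
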
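"""Mutual information estimator, rigid recovery, bone-wise composition, TRE."""

import numpy as np
import pytest

from ctsma.core import RigidTransform, Volume3D, resample_to_grid
from ctsma.registration import (JointHistogram, compose_bonewise, joint_histogram,
                                mutual_information, register_bonewise, register_rigid,
                                target_registration_error)


# --- MI estimator ----------------------------------------------------------

def test_mi_self_equals_entropy():
    rng = np.random.default_rng(0)
    a = rng.random((16, 16, 16))
    h = joint_histogram(a, a, bins=32)
    assert abs(h.mutual_information() - h.entropy_a()) < 1e-6


def test_mi_two_valued_self_is_ln2():
    a = np.zeros((4, 4))
    a[:2] = 1.0  # half the voxels at each value
    assert abs(mutual_information(a, a, bins=2) - np.log(2)) < 1e-12


def test_mi_hand_evaluated_joint_tables():
    # counts {(0,0): 8, (1,1): 8} -> MI = ln 2 ; counts {4,4,4,4} -> MI = 0
    a = np.repeat([0.0, 1.0], 8).reshape(4, 4)
    assert abs(mutual_information(a, a, bins=2) - np.log(2)) < 1e-12
    b = np.tile([0.0, 1.0, 0.0, 1.0], 4).reshape(4, 4)
    assert abs(mutual_information(a, b, bins=2)) < 1e-12


def test_mi_independent_shuffle_near_zero():
    rng = np.random.default_rng(1)
    a = rng.random(64 ** 3)
    b = rng.permutation(a)
    assert mutual_information(a, b, bins=32) <= 0.02


def test_mi_symmetry_and_nonnegativity():
    rng = np.random.default_rng(2)
    for _ in range(100):
        a = rng.random((8, 8, 4))
        b = rng.random((8, 8, 4)) + 0.3 * a
        mab = mutual_information(a, b, bins=16)
        mba = mutual_information(b, a, bins=16)
        assert mab >= 0
        assert abs(mab - mba) < 1e-12


def test_mi_input_validation():
    with pytest.raises(ValueError):
        mutual_information(np.zeros((4, 4)), np.zeros((5, 4)))
    with pytest.raises(ValueError):
        joint_histogram(np.array([]), np.array([]))
    with pytest.raises(ValueError):
        joint_histogram(np.ones(4), np.ones(4), bins=1)


def test_joint_histogram_normalization():
    rng = np.random.default_rng(3)
    h = joint_histogram(rng.random(500), rng.random(500), bins=8)
    assert abs(h.joint.sum() - 1.0) < 1e-9
    assert np.allclose(h.marginal_a, h.joint.sum(axis=1))
    assert np.allclose(h.marginal_b, h.joint.sum(axis=0))


# --- rigid recovery --------------------------------------------------------

def test_register_self_recovers_identity(small_phantom):
    _, _, ct = small_phantom
    res = register_rigid(ct, ct)
    angle, shift = res.transform.magnitude()
    assert res.converged
    assert angle < 0.1 and shift < 0.1


def test_register_known_translation(small_phantom):
    _, _, ct = small_phantom
    truth = RigidTransform.from_euler((0, 0, 0), (3.0, -2.0, 1.0), ct.center_mm)
    moved = resample_to_grid(ct, ct, motion=truth)
    res = register_rigid(moved, ct)
    # recovered motion must invert the applied one
    residual = res.transform.compose(truth)
    _, shift = residual.magnitude()
    assert shift < 0.5


def test_register_inverse_consistency(articulated):
    """Registering B->A returns (within tolerance) the inverse of A->B."""
    art = articulated
    fwd = register_rigid(art["moved"], art["ct"]).transform
    crmr = resample_to_grid(art["moved"], art["ct"], motion=fwd)
    # move the CT by a known rigid motion and register both directions
    tf = RigidTransform.from_euler((0, 3, -2), (1.0, -1.0, 0.5), art["ct"].center_mm)
    moved_ct = resample_to_grid(art["ct"], art["ct"], motion=tf)
    ab = register_rigid(moved_ct, art["ct"]).transform
    ba = register_rigid(art["ct"], moved_ct).transform
    residual = ab.compose(ba)
    angle, shift = residual.magnitude()
    assert angle < 0.5 and shift < 0.5
    del crmr


CT_VOXEL = 0.977


def _bone_tre(landmarks, bone, transform):
    sub = landmarks[landmarks.bone == bone]
    return target_registration_error(
        sub[["x_mm", "y_mm", "z_mm"]].to_numpy(),
        sub[["xt_mm", "yt_mm", "zt_mm"]].to_numpy(), transform)["mean"]


def test_bonewise_degenerate_same_transform(small_phantom, articulated):
    """Both bones moved identically -> Rf and Rt are interchangeable at the
    landmark level (each aligns either bone to sub-voxel TRE)."""
    from ctsma.phantoms import apply_bone_misalignment

    _, vol, ct = small_phantom
    c = vol.intensity.center_mm
    tf = RigidTransform.from_euler((0, 0, 5), (1.5, -1.0, 0.5), c)
    moved, lm = apply_bone_misalignment(vol, tf, tf)
    glob = register_rigid(moved, ct)
    rf, rt = register_bonewise(moved, ct, articulated["mask_femur"],
                               articulated["mask_tibia"], init=glob.transform)
    assert _bone_tre(lm, "femur", rf.transform) < CT_VOXEL
    assert _bone_tre(lm, "tibia", rt.transform) < CT_VOXEL
    # the two recovered transforms agree: swapping them stays sub-voxel
    assert _bone_tre(lm, "femur", rt.transform) < 1.5 * CT_VOXEL
    assert _bone_tre(lm, "tibia", rf.transform) < 1.5 * CT_VOXEL


def test_bonewise_identity_misalignment(small_phantom, articulated):
    """No misalignment: each recovered transform stays within sub-voxel
    landmark displacement of the identity."""
    _, vol, ct = small_phantom
    rf, rt = register_bonewise(vol.intensity, ct, articulated["mask_femur"],
                               articulated["mask_tibia"])
    lm = articulated["phantom"].landmarks
    pts = lm[["x_mm", "y_mm", "z_mm"]].to_numpy()
    for r, bone in ((rf, "femur"), (rt, "tibia")):
        sub = pts[(lm.bone == bone).to_numpy()]
        disp = np.linalg.norm(r.transform.apply(sub) - sub, axis=1)
        assert disp.mean() < CT_VOXEL


def test_bonewise_recovers_articulation_angles(articulated, registration_results):
    """Femur +8 deg / tibia -8 deg about the joint axis recovered within 1 deg."""
    for bone, truth in (("femur", articulated["tf_femur"]),
                        ("tibia", articulated["tf_tibia"])):
        recovered = registration_results[bone].transform
        z_rec = recovered.euler_deg[2]
        z_truth = truth.inverse().euler_deg[2]
        assert abs(z_rec - z_truth) < 1.0, f"{bone}: {z_rec:.2f} vs {z_truth:.2f}"


def test_bonewise_mask_validation(small_phantom, articulated):
    _, vol, ct = small_phantom
    overlap = articulated["mask_femur"].copy()
    with pytest.raises(ValueError):
        register_bonewise(vol.intensity, ct, overlap, overlap)
    tiny = np.zeros_like(overlap)
    tiny[0, 0, 0] = True
    with pytest.raises(ValueError):
        register_bonewise(vol.intensity, ct, tiny, articulated["mask_tibia"])


# --- masked composition ----------------------------------------------------

def test_compose_identity_collapses_to_masked_moving(articulated):
    art = articulated
    ident = RigidTransform.identity(art["ct"].center_mm)
    out = compose_bonewise(art["ct"], ident, ident, art["mask_femur"],
                           art["mask_tibia"], fixed=art["ct"])
    union = art["mask_femur"] | art["mask_tibia"]
    assert np.max(np.abs(out.data[union] - art["ct"].data[union])) < 1e-9
    assert np.all(out.data[~union] == 0)


def test_compose_femur_independent_of_tibia_transform(articulated):
    art = articulated
    ident = RigidTransform.identity(art["ct"].center_mm)
    rt1 = RigidTransform.from_euler((0, 0, 4), (1, 0, 0), art["ct"].center_mm)
    a = compose_bonewise(art["ct"], ident, ident, art["mask_femur"], art["mask_tibia"])
    b = compose_bonewise(art["ct"], ident, rt1, art["mask_femur"], art["mask_tibia"])
    assert np.array_equal(a.data[art["mask_femur"]], b.data[art["mask_femur"]])


# --- TRE -------------------------------------------------------------------

def test_tre_ground_truth_inverse_is_zero(articulated):
    art = articulated
    lm = art["landmarks"]
    femur = lm[lm.bone == "femur"]
    res = target_registration_error(
        femur[["x_mm", "y_mm", "z_mm"]].to_numpy(),
        femur[["xt_mm", "yt_mm", "zt_mm"]].to_numpy(),
        art["tf_femur"].inverse())
    assert res["mean"] < 1e-9


def test_tre_identity_on_3mm_shift():
    fixed = np.random.default_rng(0).uniform(0, 20, (6, 3))
    moved = fixed + np.array([3.0, 0, 0])
    res = target_registration_error(fixed, moved)
    assert res["mean"] == pytest.approx(3.0)
    assert res["sd"] == pytest.approx(0.0, abs=1e-12)


def test_tre_closed_form_rotation():
    rng = np.random.default_rng(1)
    fixed = rng.uniform(-10, 10, (8, 3))
    tf = RigidTransform.from_euler((0, 0, 12), (0, 0, 0))
    moved = tf.apply(fixed)
    res = target_registration_error(fixed, moved)
    r_axis = np.linalg.norm(fixed[:, :2], axis=1)
    expected = 2 * np.sin(np.deg2rad(6)) * r_axis
    assert np.allclose(res["per_landmark"], expected, atol=1e-9)


def test_tre_validation():
    with pytest.raises(ValueError):
        target_registration_error(np.zeros((3, 3)), np.zeros((4, 3)))
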
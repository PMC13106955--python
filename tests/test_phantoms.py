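"""Phantom generator: BV/TV control, degradation model, misalignment
geometry, cohort statistics, determinism."""

import numpy as np
import pytest
from scipy import stats

from ctsma.core import RigidTransform
from ctsma.phantoms import (AffineIntensityMap, CohortSpec, OutOfBoundsError,
                            PhantomConfig, apply_bone_misalignment, generate_cohort,
                            generate_microstructure, simulate_ct)

SMALL = dict(grid_shape_mr=(96, 96, 32))


def test_realized_bvtv_tracks_target():
    vol = generate_microstructure(PhantomConfig(target_bvtv=0.30, seed=7, **SMALL))
    region = vol.bone_labels.data > 0
    realized = vol.microstructure.data[region].mean()  # exhaustive voxel count
    assert 0.28 <= realized <= 0.32
    assert abs(vol.realized_bvtv - realized) < 1e-12


def test_extreme_target_near_solid():
    vol = generate_microstructure(PhantomConfig(target_bvtv=0.999, seed=1, **SMALL))
    assert vol.realized_bvtv >= 0.97


def test_bvtv_monotone_in_target():
    realized = [generate_microstructure(
        PhantomConfig(target_bvtv=t, seed=11, **SMALL)).realized_bvtv
        for t in (0.1, 0.2, 0.3, 0.4, 0.5)]
    assert np.all(np.diff(realized) >= 0)


def test_seeded_determinism_bitwise():
    a = generate_microstructure(PhantomConfig(seed=5, **SMALL))
    b = generate_microstructure(PhantomConfig(seed=5, **SMALL))
    assert np.array_equal(a.microstructure.data, b.microstructure.data)
    assert np.array_equal(a.intensity.data, b.intensity.data)


def test_validation_errors():
    with pytest.raises(ValueError):
        PhantomConfig(target_bvtv=1.5)
    with pytest.raises(ValueError):
        PhantomConfig(grid_shape_mr=(32, 32, 8))  # cannot hold an MR patch
    with pytest.raises(ValueError):
        PhantomConfig(psf_sigma=-1.0)


def test_structure_and_landmarks(small_phantom):
    _, vol, _ = small_phantom
    micro = vol.microstructure.data.astype(bool)
    labels = vol.bone_labels.data
    assert not np.any(micro & (labels == 0))  # microstructure inside bone
    assert set(np.unique(labels)) == {0, 1, 2}
    # the two compartments are separated by the joint gap
    z_femur = np.where((labels == 1).any(axis=(0, 1)))[0]
    z_tibia = np.where((labels == 2).any(axis=(0, 1)))[0]
    gap_mm = (z_tibia.min() - z_femur.max() - 1) * vol.bone_labels.spacing[2]
    assert gap_mm >= 4.0
    assert len(vol.landmarks) >= 8
    for _, row in vol.landmarks.iterrows():
        assert vol.intensity.contains_point([row.x_mm, row.y_mm, row.z_mm])


# --- CT degradation --------------------------------------------------------

def test_identity_degradation_is_lossless(small_phantom):
    cfg, vol, _ = small_phantom
    from dataclasses import replace

    ident = replace(cfg, psf_sigma=0.0, ct_noise_sd=0.0,
                    intensity_map=AffineIntensityMap(1.0, 0.0),
                    spacing_ct=cfg.spacing_mr)
    ct = simulate_ct(vol, ident)
    assert ct.shape == vol.intensity.shape
    assert np.max(np.abs(ct.data - vol.intensity.data)) < 1e-6


def test_constant_volume_maps_through_intensity_map(small_phantom):
    cfg, vol, _ = small_phantom
    from dataclasses import replace

    const = vol.intensity.copy_with(np.full(vol.intensity.shape, 0.4))
    cfg2 = replace(cfg, ct_noise_sd=0.0, intensity_map=AffineIntensityMap(0.8, 0.1))
    ct = simulate_ct(const, cfg2)
    assert np.allclose(ct.data, 0.8 * 0.4 + 0.1, atol=1e-9)


def test_ct_grid_arithmetic(small_phantom):
    cfg, vol, ct = small_phantom
    for ax in range(3):
        expected = round(vol.intensity.extent_mm[ax] / cfg.spacing_ct[ax])
        assert ct.shape[ax] == expected
    assert ct.spacing == cfg.spacing_ct
    assert ct.origin == vol.intensity.origin


def test_ct_suppresses_high_frequencies(small_phantom):
    """Degrade-then-upsample must not contain energy above the CT Nyquist."""
    cfg, vol, ct = small_phantom
    from ctsma.core import resample_to_grid

    back = resample_to_grid(ct, vol.intensity)
    def power_above_ct_nyquist(data, spacing):
        f = np.fft.fftn(data - data.mean())
        freqs = np.meshgrid(*[np.fft.fftfreq(n, d) for n, d in zip(data.shape, spacing)],
                            indexing="ij")
        nyq_ct = 0.5 / np.asarray(cfg.spacing_ct)
        above = np.zeros(data.shape, dtype=bool)
        for ax in range(3):
            above |= np.abs(freqs[ax]) > nyq_ct[ax]
        return float(np.sum(np.abs(f[above]) ** 2))

    p_mr = power_above_ct_nyquist(vol.intensity.data, vol.intensity.spacing)
    p_ct = power_above_ct_nyquist(back.data, vol.intensity.spacing)
    assert p_ct < p_mr


# --- misalignment ----------------------------------------------------------

def test_identity_misalignment_is_noop(small_phantom):
    _, vol, _ = small_phantom
    c = vol.intensity.center_mm
    ident = RigidTransform.identity(c)
    moved, lm = apply_bone_misalignment(vol, ident, ident)
    assert np.max(np.abs(moved.data - vol.intensity.data)) < 1e-9
    disp = np.linalg.norm(lm[["xt_mm", "yt_mm", "zt_mm"]].to_numpy()
                          - lm[["x_mm", "y_mm", "z_mm"]].to_numpy(), axis=1)
    assert np.max(disp) < 1e-12


def test_pure_translation_displaces_only_that_bone(small_phantom):
    _, vol, _ = small_phantom
    c = vol.intensity.center_mm
    tf = RigidTransform.from_euler((0, 0, 0), (3.0, 0.0, 0.0), c)
    _, lm = apply_bone_misalignment(vol, tf, RigidTransform.identity(c))
    disp = np.linalg.norm(lm[["xt_mm", "yt_mm", "zt_mm"]].to_numpy()
                          - lm[["x_mm", "y_mm", "z_mm"]].to_numpy(), axis=1)
    femur = (lm.bone == "femur").to_numpy()
    assert np.allclose(disp[femur], 3.0, atol=1e-9)
    assert np.allclose(disp[~femur], 0.0, atol=1e-12)


def test_rotation_displacement_closed_form(small_phantom):
    """10 deg about z through the centre: |d| = 2 sin(5 deg) x r_axis."""
    _, vol, _ = small_phantom
    c = vol.intensity.center_mm
    tf = RigidTransform.from_euler((0, 0, 10), (0, 0, 0), c)
    _, lm = apply_bone_misalignment(vol, tf, tf)
    pts = lm[["x_mm", "y_mm", "z_mm"]].to_numpy()
    moved = lm[["xt_mm", "yt_mm", "zt_mm"]].to_numpy()
    disp = np.linalg.norm(moved - pts, axis=1)
    r_axis = np.linalg.norm(pts[:, :2] - c[:2], axis=1)
    expected = 2 * np.sin(np.deg2rad(5)) * r_axis
    assert np.max(np.abs(disp - expected)) < 1e-6


def test_out_of_bounds_landmark_raises(small_phantom):
    _, vol, _ = small_phantom
    c = vol.intensity.center_mm
    big = RigidTransform.from_euler((0, 0, 0), (30.0, 0, 0), c)
    with pytest.raises(OutOfBoundsError):
        apply_bone_misalignment(vol, big, big)


# --- cohort ----------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_cohort_spec():
    return dict(phantom=PhantomConfig(**SMALL), rot_range_deg=3.0, trans_range_mm=1.5)


def test_cohort_class_mean_recovery(tiny_cohort_spec):
    spec = CohortSpec(n_subjects=30, class_bvtv_means=(0.35, 0.28, 0.21),
                      class_bvtv_sd=0.01, structure_scale_range=(0.35, 0.35),
                      seed=2, **tiny_cohort_spec)
    cohort = generate_cohort(spec)
    for k, target in enumerate(spec.class_bvtv_means):
        vals = [np.mean(s.bvtv_targets) for s in cohort if s.class_label == k]
        assert abs(np.mean(vals) - target) < 0.02


def test_cohort_determinism(tiny_cohort_spec):
    spec = CohortSpec(n_subjects=8, seed=9, **tiny_cohort_spec)
    a = generate_cohort(spec)
    b = generate_cohort(spec)
    assert [s.class_label for s in a] == [s.class_label for s in b]
    assert all(np.array_equal(x.ct.data, y.ct.data) for x, y in zip(a, b))
    assert all(x.score == y.score for x, y in zip(a, b))


def test_null_cohort_has_no_class_signal(tiny_cohort_spec):
    spec = CohortSpec(n_subjects=20, class_bvtv_means=(0.3, 0.3, 0.3),
                      class_bvtv_sd=0.015, structure_scale_range=(0.35, 0.35),
                      seed=4, **tiny_cohort_spec)
    cohort = generate_cohort(spec)
    a = [np.mean(s.bvtv_targets) for s in cohort if s.class_label == 0]
    b = [np.mean(s.bvtv_targets) for s in cohort if s.class_label > 0]
    _, p = stats.ttest_ind(a, b)
    assert p > 0.01


def test_cohort_validation():
    with pytest.raises(ValueError):
        CohortSpec(n_subjects=4)
    with pytest.raises(ValueError):
        CohortSpec(class_proportions=(0.5, 0.5, 0.5))
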
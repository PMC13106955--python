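"""Patch pairing geometry, distillation loss forms, training contracts."""

import numpy as np
import pytest

from ctsma.autodiff import Tensor
from ctsma.core import Volume3D
from ctsma.distill import (CT_PATCH, MR_PATCH, DistillConfig, DistillWeights,
                           PatchPair, _box_iou, distillation_loss, extract_patch,
                           predict_params, sample_patch_pairs, train_student,
                           train_teacher)


def test_box_iou_arithmetic():
    size = np.array([12.0, 12.0, 12.0])
    c = np.zeros(3)
    # 6-voxel offset along one axis of a 12^3 patch: (12*12*6)/(12*12*18) = 1/3
    assert _box_iou(c, np.array([6.0, 0, 0]), size) == pytest.approx(1 / 3)
    assert _box_iou(c, c, size) == pytest.approx(1.0)
    assert _box_iou(c, np.array([12.0, 0, 0]), size) == 0.0


def test_patch_pair_shape_contract():
    with pytest.raises(ValueError):
        PatchPair(np.zeros((10, 12, 12)), np.zeros(MR_PATCH), np.zeros(3), None)
    with pytest.raises(ValueError):
        PatchPair(np.zeros(CT_PATCH), np.zeros((48, 48, 8)), np.zeros(3), None)


def test_distill_weights_validation():
    with pytest.raises(ValueError):
        DistillWeights(-1.0, (0.1, 0.1))
    with pytest.raises(ValueError):
        DistillConfig(lr=0.0)


@pytest.fixture(scope="module")
def sampled_pairs(small_phantom):
    cfg, vol, ct = small_phantom
    mask = Volume3D((vol.bone_labels.data > 0).astype(np.uint8),
                    vol.bone_labels.spacing)
    return vol, ct, sample_patch_pairs(vol.intensity, ct, mask, 40, seed=1,
                                       truth_binary=vol.microstructure,
                                       subject_id="S0")


def test_sampling_respects_iou_bound(sampled_pairs):
    _, ct, pairs = sampled_pairs
    size = np.array(CT_PATCH) * np.array(ct.spacing)
    centers = [p.center for p in pairs]
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            assert _box_iou(centers[i], centers[j], size) < 0.5


def test_sampling_bounds_and_truth(sampled_pairs):
    vol, ct, pairs = sampled_pairs
    assert len(pairs) >= 10
    for p in pairs:
        assert p.ct_patch.shape == CT_PATCH
        assert p.mr_patch.shape == MR_PATCH
        assert p.truth is not None
        assert 0 < p.truth.bvtv < 1
        # both footprints fit: extraction at the same centre succeeds
        assert extract_patch(ct, p.center, CT_PATCH) is not None
        assert extract_patch(vol.intensity, p.center, MR_PATCH) is not None


def test_sampling_warns_when_mask_cannot_hold_n(small_phantom):
    cfg, vol, ct = small_phantom
    mask = Volume3D((vol.bone_labels.data > 0).astype(np.uint8),
                    vol.bone_labels.spacing)
    with pytest.warns(UserWarning):
        got = sample_patch_pairs(vol.intensity, ct, mask, 10_000, seed=0)
    assert len(got) < 10_000


def test_extract_patch_out_of_bounds_is_none(small_phantom):
    _, vol, _ = small_phantom
    assert extract_patch(vol.intensity, np.array([0.0, 0.0, 0.0]), MR_PATCH) is None


# --- distillation loss ------------------------------------------------------

def test_distillation_loss_zero_when_student_equals_teacher():
    pred = Tensor(np.random.default_rng(0).normal(size=(4, 4)))
    feats = [Tensor(np.random.default_rng(1).normal(size=(4, 3, 2, 2, 2)))
             for _ in range(2)]
    total, breakdown = distillation_loss(pred, pred, feats, feats, DistillWeights())
    assert total.item() == 0.0
    assert breakdown["pred"] == 0.0


def test_distillation_loss_prediction_only_printed_pair():
    ys = Tensor(np.array([[0.3, 0.2, 0.5, 1.5]]))
    yt = Tensor(np.array([[0.1, 0.25, 0.45, 1.2]]))
    w = DistillWeights(w1=2.0, w2=())
    total, _ = distillation_loss(ys, yt, [], [], w)
    expected = 2.0 * (0.2 ** 2 + 0.05 ** 2 + 0.05 ** 2 + 0.3 ** 2)
    assert total.item() == pytest.approx(expected, abs=1e-12)


def test_distillation_loss_brute_force_k2():
    rng = np.random.default_rng(5)
    ys, yt = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
    fs = [rng.normal(size=(3, 2, 2, 2, 2)) for _ in range(2)]
    ft = [rng.normal(size=(3, 2, 2, 2, 2)) for _ in range(2)]
    w = DistillWeights(w1=1.3, w2=(0.7, 0.2))
    total, breakdown = distillation_loss(Tensor(ys), Tensor(yt),
                                         [Tensor(f) for f in fs],
                                         [Tensor(f) for f in ft], w)
    brute = (1.3 * np.mean(np.sum((ys - yt) ** 2, axis=1))
             + 0.7 * np.abs(fs[0] - ft[0]).mean()
             + 0.2 * np.abs(fs[1] - ft[1]).mean())
    assert total.item() == pytest.approx(brute, abs=1e-9)


def test_distillation_loss_shape_mismatch_raises():
    pred = Tensor(np.zeros((2, 4)))
    with pytest.raises(ValueError):
        distillation_loss(pred, pred, [Tensor(np.zeros((2, 3, 2, 2, 2)))],
                          [Tensor(np.zeros((2, 5, 2, 2, 2)))], DistillWeights(1.0, (0.1,)))
    with pytest.raises(ValueError):
        distillation_loss(pred, pred, [], [Tensor(np.zeros((2, 3)))], DistillWeights())


# --- training contracts -----------------------------------------------------

def _toy_pairs(n=48, seed=0):
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n):
        truth = np.array([0.3, 0.25, 0.6, 1.2])
        from ctsma.morphometry import TrabecularParams

        pairs.append(PatchPair(rng.random(CT_PATCH), rng.random(MR_PATCH),
                               rng.uniform(10, 20, 3), TrabecularParams(*truth),
                               f"S{i % 4}"))
    return pairs


def test_constant_target_converges():
    pairs = _toy_pairs()
    cfg = DistillConfig(width=4, epochs=20, batch_size=16, lr=3e-3, dropout=0.0, seed=0)
    model, history = train_student(pairs, None, None, cfg)
    assert history[-1]["l_reg_s"] < 1e-3
    pred = model.predict(np.array([p.ct_patch for p in pairs[:4]]))
    assert np.allclose(pred, [0.3, 0.25, 0.6, 1.2], atol=0.05)


def test_zero_weight_distillation_equals_plain_student(distill_cohort):
    """All-zero distillation weights reproduce the supervised baseline
    bitwise under a fixed seed (the ablation degeneracy)."""
    train = distill_cohort["train"][:64]
    tcfg = DistillConfig(width=4, epochs=1, batch_size=32, lr=3e-3, seed=0)
    teacher, _ = train_teacher(np.array([p.mr_patch for p in train]),
                               [p.truth for p in train], tcfg)
    scfg = DistillConfig(width=4, epochs=2, batch_size=32, lr=3e-3, seed=7)
    zero = DistillWeights(w1=0.0, w2=(0.0, 0.0))
    with_kd, hist_kd = train_student(train, teacher, zero, scfg)
    plain, hist_plain = train_student(train, None, None, scfg)
    for a, b in zip(with_kd.net.state_dict(), plain.net.state_dict()):
        assert np.array_equal(a, b)
    assert [h["l_reg_s"] for h in hist_kd] == [h["l_reg_s"] for h in hist_plain]


def test_predict_deterministic_and_batch_consistent():
    pairs = _toy_pairs()
    cfg = DistillConfig(width=4, epochs=2, batch_size=16, seed=1)
    model, _ = train_student(pairs, None, None, cfg)
    batch = np.array([p.ct_patch for p in pairs[:8]])
    a = model.predict(batch)
    b = model.predict(batch)
    assert np.array_equal(a, b)
    single = np.array([model.predict(p[None])[0] for p in batch])
    assert np.max(np.abs(single - a)) < 1e-6
    p0 = predict_params(model, batch[0])
    assert 0.0 <= p0.bvtv <= 1.0


def test_too_few_patches_rejected():
    with pytest.raises(ValueError):
        train_student(_toy_pairs(8), None, None, DistillConfig(epochs=1))
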
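"""Distillation-learning-based regression (DLRM): MR teacher, CT student.

The teacher regresses the trabecular 4-vector y = (BV/TV, Tb.Th, Tb.Sp,
Tb.N) from high-resolution MR patches (48 x 48 x 16 voxels) under the
regression loss L_reg^T = ||y_T - y||^2.  The student regresses the same
targets from the co-located low-resolution CT patch (12^3 voxels) and is
additionally supervised by the frozen teacher through

    L_d = w1 ||y_S - y_T||^2 + sum_j w2_j ||M_S_j - M_T_j||_1 ,

a prediction-consistency term plus K feature-level terms.  Student and
teacher feature maps live on different grids and channel counts, so both are
adaptively average-pooled onto a common spatial grid and the student
channels are linearly projected onto the teacher's (the projections train
with the student).  Total student loss: L_reg^S + L_d.  At inference only
the CT student runs.

Targets are z-scored per parameter on the training set (the four parameters
differ by orders of magnitude in their units) and predictions are mapped
back before reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autodiff import Tensor, adaptive_avg_pool
from .core import Volume3D
from .morphometry import DegeneratePatchError, TrabecularParams, compute_params

__all__ = [
    "PatchPair",
    "DistillWeights",
    "DistillConfig",
    "Regressor3D",
    "RegressionModel",
    "sample_patch_pairs",
    "extract_patch",
    "train_teacher",
    "train_student",
    "distillation_loss",
    "predict_params",
]

CT_PATCH = (12, 12, 12)
MR_PATCH = (48, 48, 16)


@dataclass
class PatchPair:
    ct_patch: np.ndarray  # (12, 12, 12) intensities
    mr_patch: np.ndarray  # (48, 48, 16) intensities
    center: np.ndarray  # shared physical mm coordinate
    truth: TrabecularParams | None
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.ct_patch.shape != CT_PATCH:
            raise ValueError(f"CT patch must be {CT_PATCH}, got {self.ct_patch.shape}")
        if self.mr_patch.shape != MR_PATCH:
            raise ValueError(f"MR patch must be {MR_PATCH}, got {self.mr_patch.shape}")


@dataclass
class DistillWeights:
    w1: float = 1.0  # prediction-consistency weight
    w2: tuple[float, ...] = (0.5, 0.5)  # one weight per matched feature level

    def __post_init__(self) -> None:
        if self.w1 < 0 or any(w < 0 for w in self.w2):
            raise ValueError("distillation weights must be non-negative")


@dataclass
class DistillConfig:
    width: int = 6  # base channels of the 3D regressors
    lr: float = 3e-4
    epochs: int = 50
    batch_size: int = 32
    dropout: float = 0.5
    weight_decay: float = 1e-4
    feature_grid: tuple[int, int, int] = (4, 4, 4)
    # distillation schedule: L_d is applied during the first fraction of the
    # epochs (hint phase), after which training is purely supervised --
    # stage-wise transfer avoids late-phase gradient conflict between the
    # teacher-matching and regression objectives
    kd_warmup_frac: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.epochs <= 0:
            raise ValueError("lr and epochs must be positive")


# --- patch sampling --------------------------------------------------------

def _box_iou(c1: np.ndarray, c2: np.ndarray, size_mm: np.ndarray) -> float:
    """IoU of two axis-aligned boxes of identical physical size."""
    overlap = np.clip(size_mm - np.abs(c1 - c2), 0, None)
    inter = float(np.prod(overlap))
    vol = float(np.prod(size_mm))
    return inter / (2 * vol - inter)


def extract_patch(vol: Volume3D, center_mm: np.ndarray, shape: tuple[int, int, int]
                  ) -> np.ndarray | None:
    """Copy the axis-aligned patch of ``shape`` voxels centred (by index) at
    the physical coordinate; None when it does not fit inside the volume."""
    idx = np.round(vol.physical_to_index(center_mm)).astype(int)
    lo = idx - np.asarray(shape) // 2
    hi = lo + np.asarray(shape)
    if np.any(lo < 0) or np.any(hi > np.asarray(vol.shape)):
        return None
    return np.ascontiguousarray(vol.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]])


def sample_patch_pairs(mr_volume: Volume3D, ct_volume: Volume3D,
                       trabecular_mask: Volume3D, n_per_subject: int,
                       iou_max: float = 0.5, seed: int = 0,
                       truth_binary: Volume3D | None = None,
                       subject_id: str = "", refine: int = 1) -> list[PatchPair]:
    """Sample anatomically corresponding CT/MR patch pairs inside the mask.

    Candidate centres lie on a regular grid (one CT-patch extent apart) with
    uniform jitter, are restricted to mask-interior positions where both
    patches fit, and are greedily accepted while every pairwise CT-patch IoU
    stays below ``iou_max``.  When ``truth_binary`` (the MR-resolution binary
    microstructure) is given, morphometry on the MR patch footprint provides
    the ground-truth parameters; degenerate patches are skipped.  Fewer than
    ``n_per_subject`` pairs are returned with a warning when the mask cannot
    hold more.
    """
    rng = np.random.default_rng(seed)
    size_mm = np.asarray(CT_PATCH) * np.asarray(ct_volume.spacing)
    step = size_mm * 0.5  # candidate grid finer than a patch; IoU filter prunes
    # jitter stays below (step - L(1-iou)/(1+iou))/2 so grid neighbours at half
    # a patch extent still satisfy the IoU bound
    jitter = np.maximum(step - size_mm * (1 - iou_max) / (1 + iou_max), 0) / 2 * 0.9
    lo = np.asarray(ct_volume.origin)
    hi = lo + np.asarray(ct_volume.extent_mm)
    grids = [np.arange(lo[i] + size_mm[i] / 2, hi[i] - size_mm[i] / 2 + 1e-9, step[i])
             for i in range(3)]
    if any(len(g) == 0 for g in grids):
        raise ValueError("volume too small for a CT patch")
    cand = np.array(np.meshgrid(*grids, indexing="ij")).reshape(3, -1).T
    cand = cand + rng.uniform(-1, 1, cand.shape) * jitter
    rng.shuffle(cand)

    accepted: list[np.ndarray] = []
    pairs: list[PatchPair] = []
    for c in cand:
        if len(pairs) >= n_per_subject:
            break
        midx = np.round(trabecular_mask.physical_to_index(c)).astype(int)
        if np.any(midx < 0) or np.any(midx >= np.asarray(trabecular_mask.shape)):
            continue
        if not trabecular_mask.data[tuple(midx)]:
            continue
        if any(_box_iou(c, a, size_mm) >= iou_max for a in accepted):
            continue
        ct_patch = extract_patch(ct_volume, c, CT_PATCH)
        mr_patch = extract_patch(mr_volume, c, MR_PATCH)
        if ct_patch is None or mr_patch is None:
            continue
        truth = None
        if truth_binary is not None:
            tb = extract_patch(truth_binary, c, MR_PATCH)
            if tb is None:
                continue
            try:
                truth = compute_params(tb.astype(np.uint8), truth_binary.spacing,
                                       refine=refine)
            except DegeneratePatchError:
                continue
        accepted.append(c)
        pairs.append(PatchPair(ct_patch, mr_patch, c.copy(), truth, subject_id))
    if len(pairs) < n_per_subject:
        import warnings

        warnings.warn(f"requested {n_per_subject} patches, sampled {len(pairs)} "
                      "under the IoU and bounds constraints")
    return pairs


# --- models ----------------------------------------------------------------

class Regressor3D(nn.Module):
    """Small 3D convolutional regressor with exposed intermediate features.

    ``strides`` controls per-stage downsampling; the teacher uses
    (2, 2, 2) on the 48 x 48 x 16 MR patch, the student (1, 2, 2) on the
    12^3 CT patch.  Features from the last two stages feed distillation.
    """

    def __init__(self, width: int, strides: tuple[int, ...], rng,
                 dropout: float = 0.5, anisotropic_first: bool = False):
        c = width
        chans = [1, c, 2 * c, 2 * c]
        self.convs = []
        for i, s in enumerate(strides):
            stride = (s, s, 1) if (anisotropic_first and i == 0) else s
            self.convs.append(nn.Conv(chans[i], chans[i + 1], 3, rng,
                                      stride=stride, padding=1))
        self.head = nn.Linear(chans[len(strides)], 4, rng)
        self.drop = nn.Dropout(dropout, rng)
        self.out_channels = chans[len(strides)]

    def forward(self, x: Tensor, return_features: bool = False):
        feats = []
        h = x
        for conv in self.convs:
            h = conv(h).relu()
            feats.append(h)
        pooled = h.mean(axis=(2, 3, 4))  # global average pool
        y = self.head(self.drop(pooled))
        if return_features:
            return y, feats[-2:]  # the two deepest stages
        return y


@dataclass
class _Standardizer:
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, y: np.ndarray) -> "_Standardizer":
        sd = y.std(axis=0)
        return cls(y.mean(axis=0), np.where(sd > 1e-12, sd, 1.0))

    def transform(self, y: np.ndarray) -> np.ndarray:
        return (y - self.mean) / self.sd

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return z * self.sd + self.mean


@dataclass
class RegressionModel:
    """A trained regressor plus its target standardization and input role."""

    net: Regressor3D
    standardizer: _Standardizer
    role: str  # "teacher" (MR) or "student" (CT)
    config: DistillConfig

    def predict(self, patches: np.ndarray) -> np.ndarray:
        """Batch prediction, physical units, inference mode (N, 4)."""
        self.net.eval()
        x = Tensor(np.asarray(patches, dtype=np.float64)[:, None])
        out = []
        for i in range(0, x.shape[0], 64):
            out.append(self.net(x[i:i + 64]).data)
        self.net.train()
        return self.standardizer.inverse(np.concatenate(out, axis=0))


def _truths_to_array(pairs_or_truths) -> np.ndarray:
    arr = []
    for t in pairs_or_truths:
        arr.append(t.as_array() if isinstance(t, TrabecularParams) else np.asarray(t))
    return np.asarray(arr, dtype=np.float64)


def train_teacher(mr_patches: np.ndarray, truths, config: DistillConfig | None = None
                  ) -> tuple[RegressionModel, list[dict[str, float]]]:
    """Pre-train the MR teacher under the squared regression loss."""
    config = config or DistillConfig()
    x = np.asarray(mr_patches, dtype=np.float64)
    y = _truths_to_array(truths)
    keep = np.all(np.isfinite(y), axis=1)
    if keep.sum() < len(y):
        print(f"filtered {int(len(y) - keep.sum())} patches with undefined targets")
    x, y = x[keep], y[keep]
    if len(x) < 32:
        raise ValueError(f"need at least 32 patches to train, got {len(x)}")

    ss = np.random.SeedSequence(config.seed)
    rng_init, rng_batch, rng_drop = [np.random.default_rng(s) for s in ss.spawn(3)]
    std = _Standardizer.fit(y)
    z = std.transform(y)
    net = Regressor3D(config.width, (2, 2, 2), rng_init, dropout=config.dropout,
                      anisotropic_first=True)
    net.drop.rng = rng_drop
    opt = nn.Adam(net.parameters(), lr=config.lr, weight_decay=config.weight_decay)

    history = []
    n = len(x)
    for epoch in range(config.epochs):
        order = rng_batch.permutation(n)
        ep_loss = 0.0
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            pred = net(Tensor(x[idx][:, None]))
            loss = ((pred - Tensor(z[idx])) ** 2).sum(axis=1).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += loss.item() * len(idx)
        history.append({"epoch": epoch, "l_reg_t": ep_loss / n})
    return RegressionModel(net, std, "teacher", config), history


def distillation_loss(student_pred: Tensor, teacher_pred: Tensor,
                      student_feats: list[Tensor], teacher_feats: list[Tensor],
                      weights: DistillWeights) -> tuple[Tensor, dict[str, float]]:
    """L_d = w1 ||y_S - y_T||^2 + sum_j w2_j ||M_S_j - M_T_j||_1.

    Feature tensors must already be on a common shape (pooled/projected);
    the prediction term is the mean squared norm over the batch, the feature
    terms are mean absolute differences.
    """
    if len(student_feats) != len(teacher_feats) or len(student_feats) != len(weights.w2):
        raise ValueError("feature list lengths must match K = len(w2)")
    pred_term = ((student_pred - teacher_pred) ** 2).sum(axis=1).mean()
    total = weights.w1 * pred_term
    breakdown = {"pred": pred_term.item()}
    for j, (ms, mt, w) in enumerate(zip(student_feats, teacher_feats, weights.w2)):
        if ms.shape != mt.shape:
            raise ValueError(f"feature level {j}: shape {ms.shape} vs {mt.shape}; "
                             "pool/project before the loss")
        term = (ms - mt).abs().mean()
        total = total + w * term
        breakdown[f"feat_{j}"] = term.item()
    return total, breakdown


def train_student(pairs: list[PatchPair], teacher: RegressionModel | None,
                  weights: DistillWeights | None = None,
                  config: DistillConfig | None = None
                  ) -> tuple[RegressionModel, list[dict[str, float]]]:
    """Train the CT student under L_reg^S plus (optionally) distillation.

    ``teacher=None`` trains the plain supervised CT baseline; passing a
    teacher with all-zero weights reproduces it bitwise under the same seed.
    The teacher stays frozen; training consumes the CT+MR pairs, the
    resulting model consumes CT only.
    """
    config = config or DistillConfig()
    weights = weights or DistillWeights()
    xs = np.asarray([p.ct_patch for p in pairs], dtype=np.float64)
    y = _truths_to_array([p.truth for p in pairs])
    if len(xs) < 32:
        raise ValueError(f"need at least 32 patches to train, got {len(xs)}")

    ss = np.random.SeedSequence(config.seed)
    rng_init, rng_proj, rng_batch, rng_drop = [np.random.default_rng(s) for s in ss.spawn(4)]
    std = teacher.standardizer if teacher is not None else _Standardizer.fit(y)
    z = std.transform(y)
    net = Regressor3D(config.width, (1, 2, 2), rng_init, dropout=config.dropout)
    net.drop.rng = rng_drop
    params = net.parameters()

    projections: list[nn.Conv] = []
    teacher_pred = teacher_feats = None
    if teacher is not None:
        tk = len(weights.w2)
        t_ch = [teacher.net.convs[-2].weight.shape[0], teacher.net.convs[-1].weight.shape[0]][-tk:]
        s_ch = [net.convs[-2].weight.shape[0], net.convs[-1].weight.shape[0]][-tk:]
        projections = [nn.Conv(sc, tc, 1, rng_proj, padding=0) for sc, tc in zip(s_ch, t_ch)]
        for p in projections:
            params = params + p.parameters()
        # frozen teacher: one inference pass over the full pair set
        teacher.net.eval()
        xt = np.asarray([p.mr_patch for p in pairs], dtype=np.float64)[:, None]
        preds, feats = [], None
        for i in range(0, len(xt), 64):
            yp, fs = teacher.net(Tensor(xt[i:i + 64]), return_features=True)
            fs = [adaptive_avg_pool(f, config.feature_grid).data for f in fs[-tk:]]
            preds.append(yp.data)
            feats = fs if feats is None else [np.concatenate([a, b]) for a, b in zip(feats, fs)]
        teacher.net.train()
        teacher_pred = np.concatenate(preds, axis=0)
        teacher_feats = feats

    opt = nn.Adam(params, lr=config.lr, weight_decay=config.weight_decay)
    history = []
    n = len(xs)
    kd_epochs = int(np.ceil(config.kd_warmup_frac * config.epochs))
    for epoch in range(config.epochs):
        order = rng_batch.permutation(n)
        ep = {"l_reg_s": 0.0, "l_d": 0.0, "total": 0.0}
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            pred, feats = net(Tensor(xs[idx][:, None]), return_features=True)
            loss_reg = ((pred - Tensor(z[idx])) ** 2).sum(axis=1).mean()
            loss = loss_reg
            l_d_val = 0.0
            if teacher is not None and epoch < kd_epochs:
                s_feats = [proj(adaptive_avg_pool(f, config.feature_grid))
                           for proj, f in zip(projections, feats[-len(weights.w2):])]
                t_feats = [Tensor(tf[idx]) for tf in teacher_feats]
                l_d, _ = distillation_loss(pred, Tensor(teacher_pred[idx]),
                                           s_feats, t_feats, weights)
                loss = loss + l_d
                l_d_val = l_d.item()
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep["l_reg_s"] += loss_reg.item() * len(idx)
            ep["l_d"] += l_d_val * len(idx)
            ep["total"] += loss.item() * len(idx)
        history.append({"epoch": epoch, **{k: v / n for k, v in ep.items()}})
    return RegressionModel(net, std, "student", config), history


def predict_params(model: RegressionModel, ct_patch: np.ndarray) -> TrabecularParams:
    """Deterministic single-patch inference (CT only)."""
    y = model.predict(np.asarray(ct_patch)[None])[0]
    y[0] = float(np.clip(y[0], 0.0, 1.0))
    return TrabecularParams.from_array(y)
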
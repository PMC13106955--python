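"""Patient-level aggregation of patch predictions.

Each patch contributes a token u_i = [y_i ; phi(c_i)]: its four predicted
trabecular parameters concatenated with a fixed sinusoidal positional
embedding of the patch centre c_i (4 frequencies per axis on min-max
normalized coordinates, 24 dims).  Tokens are linearly projected to a
d-dimensional space, processed by a two-layer transformer encoder, averaged
into a patient representation h, and read out by two linear heads: a
3-class softmax over disease grade (normal / mild / advanced) and a
continuous severity score.  No sequence-order term is added to the tokens -
token order carries no meaning, so the whole aggregate is permutation
invariant; spatial position enters only through phi.

A token-mean MLP baseline (mean of u_i followed by a two-layer perceptron)
is provided for the aggregation-strategy comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import nn
from .autodiff import Tensor
from .core import Volume3D

__all__ = [
    "PatientRecord",
    "AggregatorConfig",
    "AggregatorModel",
    "MeanMLPBaseline",
    "partition_subregions",
    "positional_embedding",
    "aggregate",
    "train_aggregator",
    "predict_cohort",
]


@dataclass
class PatientRecord:
    subject_id: str
    params: np.ndarray  # (N, 4) predicted trabecular parameters
    centers: np.ndarray  # (N, 3) physical mm patch centres
    class_label: int | None = None  # 0 normal, 1 mild, 2 advanced
    score: float | None = None
    bounds: tuple[np.ndarray, np.ndarray] | None = None  # CT physical bbox

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 4 or len(self.params) < 1:
            raise ValueError("params must be (N >= 1, 4)")
        if self.centers.shape != (len(self.params), 3):
            raise ValueError("centers must be (N, 3) matching params")
        if self.bounds is None:
            self.bounds = (self.centers.min(axis=0), self.centers.max(axis=0))


def partition_subregions(trabecular_mask: Volume3D, k: int) -> np.ndarray:
    """Deterministic in-mask grid partition: k spatially distributed centres.

    Cell centres of a regular grid over the mask bounding box are snapped to
    the nearest in-mask voxel; the grid is refined until at least ``k``
    unique snapped centres exist (or the mask is exhausted, with a warning).
    Returns (k, 3) physical coordinates sorted lexicographically.
    """
    mask = trabecular_mask.data.astype(bool)
    if k < 1:
        raise ValueError("k must be >= 1")
    vox = np.argwhere(mask)
    if len(vox) == 0:
        raise ValueError("empty mask")
    pts = trabecular_mask.index_to_physical(vox)
    tree = cKDTree(pts)
    if k == 1:
        centroid = pts.mean(axis=0)
        return pts[tree.query(centroid)[1]][None]
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    extent = np.maximum(hi - lo, 1e-9)

    def snapped(n_per_axis) -> np.ndarray:
        axes = [lo[i] + (np.arange(n) + 0.5) * extent[i] / n
                for i, n in enumerate(n_per_axis)]
        grid = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T
        idx = np.unique(tree.query(grid)[1])
        return pts[idx]

    # per-axis counts proportional to extent, scaled up until k centres exist
    scale = (k / np.prod(extent / extent.max())) ** (1 / 3)
    for _ in range(32):
        n_per_axis = np.maximum(1, np.round(scale * extent / extent.max()).astype(int))
        centers = snapped(n_per_axis)
        if len(centers) >= k or np.all(n_per_axis >= np.asarray(mask.shape)):
            break
        scale *= 1.3
    if len(centers) < k:
        import warnings

        warnings.warn(f"mask supports only {len(centers)} of {k} requested subregions")
        chosen = centers
    else:
        # thin deterministically to exactly k, keeping spatial spread
        keep = np.linspace(0, len(centers) - 1, k).round().astype(int)
        order = np.lexsort(centers.T[::-1])
        chosen = centers[order][keep]
    return chosen[np.lexsort(chosen.T[::-1])]


def positional_embedding(c: np.ndarray, dim: int = 24,
                         bounds: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """Fixed sinusoidal embedding of physical coordinates.

    Each axis is min-max normalized to t in [-1, 1] (0 at the centre of
    ``bounds``) and encoded as sin/cos at ``dim // 6`` octave frequencies
    (pi/2) * 2^j, giving ``dim`` features for points or an (n, dim) array.
    """
    c = np.asarray(c, dtype=float)
    single = c.ndim == 1
    pts = np.atleast_2d(c)
    if dim % 6:
        raise ValueError("dim must be a multiple of 6 (sin+cos per axis per frequency)")
    n_freq = dim // 6
    if bounds is None:
        lo, hi = pts.min(axis=0), pts.max(axis=0)
    else:
        lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    span = np.maximum(hi - lo, 1e-9)
    t = 2.0 * (pts - lo) / span - 1.0  # (n, 3), centre -> 0
    freqs = (np.pi / 2) * 2.0 ** np.arange(n_freq)
    ang = t[:, :, None] * freqs[None, None, :]  # (n, 3, n_freq)
    emb = np.concatenate([np.sin(ang), np.cos(ang)], axis=2).reshape(len(pts), dim)
    return emb[0] if single else emb


@dataclass
class AggregatorConfig:
    dim: int = 32
    heads: int = 4
    ff_dim: int = 64
    emb_dim: int = 24
    n_layers: int = 2
    dropout: float = 0.5
    lr: float = 1e-3
    epochs: int = 200
    weight_decay: float = 1e-4
    score_weight: float = 1.0  # joint training weight of the score MSE
    seed: int = 0


class AggregatorModel(nn.Module):
    """Linear token projection -> 2 transformer layers -> mean pool -> heads."""

    def __init__(self, config: AggregatorConfig, rng: np.random.Generator):
        self.config = config
        self.embed = nn.Linear(4 + config.emb_dim, config.dim, rng)
        self.encoder = [nn.TransformerEncoderLayer(config.dim, config.heads,
                                                   config.ff_dim, rng, config.dropout)
                        for _ in range(config.n_layers)]
        self.class_head = nn.Linear(config.dim, 3, rng)
        self.score_head = nn.Linear(config.dim, 1, rng)
        self.param_scale: np.ndarray = np.ones(4)
        self.param_shift: np.ndarray = np.zeros(4)
        self.score_mean: float = 0.0
        self.score_sd: float = 1.0

    def tokens(self, record: PatientRecord) -> np.ndarray:
        y = (record.params - self.param_shift) / self.param_scale
        e = positional_embedding(record.centers, self.config.emb_dim, record.bounds)
        return np.concatenate([y, e], axis=1)

    def forward(self, u: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """u: (B, N, 4+emb). Returns (h, class logits, standardized score)."""
        z = self.embed(u)
        for layer in self.encoder:
            z = layer(z)
        h = z.mean(axis=1)  # average pool over tokens
        return h, self.class_head(h), self.score_head(h)


class MeanMLPBaseline(nn.Module):
    """Token-mean MLP: mean of u_i -> hidden layer -> the same two heads."""

    def __init__(self, config: AggregatorConfig, rng: np.random.Generator):
        self.config = config
        self.hidden = nn.Linear(4 + config.emb_dim, config.ff_dim, rng)
        self.drop = nn.Dropout(config.dropout, rng)
        self.class_head = nn.Linear(config.ff_dim, 3, rng)
        self.score_head = nn.Linear(config.ff_dim, 1, rng)
        self.param_scale: np.ndarray = np.ones(4)
        self.param_shift: np.ndarray = np.zeros(4)
        self.score_mean: float = 0.0
        self.score_sd: float = 1.0

    tokens = AggregatorModel.tokens

    def forward(self, u: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        h = self.drop(self.hidden(u.mean(axis=1)).relu())
        return h, self.class_head(h), self.score_head(h)


def aggregate(model, record: PatientRecord) -> tuple[np.ndarray, np.ndarray, float]:
    """Inference on one patient: (representation h, class probabilities, score)."""
    model.eval()
    u = Tensor(model.tokens(record)[None])
    h, logits, s = model(u)
    model.train()
    probs = logits.softmax(axis=-1).data[0]
    score = float(s.data[0, 0] * model.score_sd + model.score_mean)
    return h.data[0], probs, score


def train_aggregator(records: list[PatientRecord], config: AggregatorConfig | None = None,
                     architecture: str = "transformer"
                     ) -> tuple[AggregatorModel | MeanMLPBaseline, list[dict[str, float]]]:
    """Joint training of the classification and score heads (CE + MSE).

    ``records`` are the training patients (folds are split by the caller at
    the patient level).  Raises when they contain a single class.
    """
    config = config or AggregatorConfig()
    labels = np.array([r.class_label for r in records])
    if len(np.unique(labels)) < 2:
        raise ValueError("training records contain a single class: check stratification")
    scores = np.array([0.0 if r.score is None else r.score for r in records])
    ss = np.random.SeedSequence(config.seed)
    rng_init, rng_batch = [np.random.default_rng(s) for s in ss.spawn(2)]
    cls = AggregatorModel if architecture == "transformer" else MeanMLPBaseline
    model = cls(config, rng_init)
    allp = np.concatenate([r.params for r in records])
    model.param_shift = allp.mean(axis=0)
    model.param_scale = np.where(allp.std(axis=0) > 1e-12, allp.std(axis=0), 1.0)
    model.score_mean = float(scores.mean())
    model.score_sd = float(scores.std()) if scores.std() > 1e-12 else 1.0

    groups: dict[int, list[int]] = {}
    for i, r in enumerate(records):
        groups.setdefault(len(r.params), []).append(i)
    token_cache = {i: None for i in range(len(records))}
    opt = nn.Adam(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    z_scores = (scores - model.score_mean) / model.score_sd

    history = []
    for epoch in range(config.epochs):
        ep_ce = ep_mse = 0.0
        for n_tok in sorted(groups):
            idx = np.array(groups[n_tok])
            rng_batch.shuffle(idx)
            for i in idx:
                if token_cache[i] is None:
                    token_cache[i] = model.tokens(records[i])
            u = Tensor(np.stack([token_cache[i] for i in idx]))
            _, logits, s = model(u)
            ce = nn.cross_entropy(logits, labels[idx])
            mse = ((s.reshape(-1) - Tensor(z_scores[idx])) ** 2).mean()
            loss = ce + config.score_weight * mse
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_ce += ce.item() * len(idx)
            ep_mse += mse.item() * len(idx)
        history.append({"epoch": epoch, "ce": ep_ce / len(records),
                        "mse": ep_mse / len(records)})
    return model, history


def predict_cohort(model, records: list[PatientRecord]) -> "pd.DataFrame":
    """Per-patient class probabilities and severity score as a table."""
    import pandas as pd

    rows = []
    for r in records:
        _, probs, score = aggregate(model, r)
        rows.append({"subject_id": r.subject_id, "p_normal": probs[0],
                     "p_mild": probs[1], "p_advanced": probs[2],
                     "p_oa": probs[1] + probs[2], "score_hat": score,
                     "pred_class": int(np.argmax(probs))})
    return pd.DataFrame(rows)
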
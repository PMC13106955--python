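"""Structure-preserving cross-modal synthesis (SPSNet).

Bidirectional MR<->CT translation with two generators and two patch
discriminators, trained with three loss families:

* adversarial:  L_GAN^CT = -( E[log D2(ct)] + E[log(1 - D2(G1(mr)))] ) and
  the mirrored L_GAN^MR (the negated two-term log-likelihood objectives;
  generator updates use the non-saturating form of the same optimum),
* cycle consistency:  L_cyc = |G2(G1(mr)) - mr|_1 + |G1(G2(ct)) - ct|_1,
* mutual information:  L_MI = -MI(mr, G1(mr)) - MI(ct, G2(ct)), a
  differentiable Parzen soft-histogram MI that rewards synthesis outputs
  statistically predictable from their inputs, discouraging geometric
  distortion while leaving intensity mapping free.

Total: L_SPS = L_GAN^CT + L_GAN^MR + lambda_cyc * L_cyc + lambda_MI * L_MI
with lambda_cyc = 1.0 and lambda_MI = 0.5 by default.

Volumes are processed 2.5D: stacks of ``k_slices`` adjacent axial slices
predict the centre slice.  Intensities are min-max normalized per volume
before entering the models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autodiff import Tensor
from .core import Volume3D

__all__ = [
    "SynthConfig",
    "SynthLossWeights",
    "SynthModel",
    "soft_mutual_information",
    "adversarial_losses",
    "cycle_loss",
    "mi_loss",
    "total_sps_loss",
    "train_spsnet",
    "synthesize",
    "normalize_volume",
]

_EPS = 1e-8


def normalize_volume(data: np.ndarray) -> np.ndarray:
    """Per-volume min-max normalization to [0, 1]."""
    lo, hi = float(np.min(data)), float(np.max(data))
    if hi - lo < 1e-12:
        return np.zeros_like(data, dtype=np.float64)
    return (np.asarray(data, dtype=np.float64) - lo) / (hi - lo)


@dataclass
class SynthLossWeights:
    lambda_cyc: float = 1.0
    lambda_mi: float = 0.5

    def __post_init__(self) -> None:
        if self.lambda_cyc < 0 or self.lambda_mi < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class SynthConfig:
    k_slices: int = 3  # 2.5D stack depth
    width: int = 8  # generator base channels
    n_res_blocks: int = 2
    disc_width: int = 8
    lr: float = 2e-4
    epochs: int = 100
    max_steps: int | None = None
    batch_size: int = 8
    mi_bins: int = 32
    weights: SynthLossWeights = field(default_factory=SynthLossWeights)
    augment: bool = True
    paired: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs <= 0:
            raise ValueError("epochs must be positive")


class _ResBlock(nn.Module):
    def __init__(self, width: int, rng):
        self.conv1 = nn.Conv(width, width, (3, 3), rng, padding=1)
        self.conv2 = nn.Conv(width, width, (3, 3), rng, padding=1)

    def forward(self, x):
        return x + self.conv2(self.conv1(x).relu())


class Generator(nn.Module):
    """Residual encoder-decoder slice generator: k input slices -> 1 slice.

    Output passes through a sigmoid, matching the normalized [0, 1] domain.
    """

    def __init__(self, k_slices: int, width: int, n_res: int, rng):
        self.head = nn.Conv(k_slices, width, (3, 3), rng, padding=1)
        self.blocks = [_ResBlock(width, rng) for _ in range(n_res)]
        self.tail = nn.Conv(width, 1, (3, 3), rng, padding=1)

    def forward(self, x: Tensor) -> Tensor:
        h = self.head(x).relu()
        for b in self.blocks:
            h = b(h)
        return self.tail(h).sigmoid()


class Discriminator(nn.Module):
    """Patch discriminator: sigmoid realness score per receptive patch."""

    def __init__(self, width: int, rng):
        self.c1 = nn.Conv(1, width, (3, 3), rng, stride=2, padding=1)
        self.c2 = nn.Conv(width, 2 * width, (3, 3), rng, stride=2, padding=1)
        self.c3 = nn.Conv(2 * width, 1, (3, 3), rng, padding=1)

    def forward(self, x: Tensor) -> Tensor:
        h = self.c1(x).leaky_relu(0.2)
        h = self.c2(h).leaky_relu(0.2)
        return self.c3(h).sigmoid()


@dataclass
class SynthModel:
    G1: nn.Module  # MR-like -> CT-like
    G2: nn.Module  # CT-like -> MR-like
    D1: nn.Module  # discriminates the MR domain
    D2: nn.Module  # discriminates the CT domain
    config: SynthConfig

    def _as_stack(self, x: Tensor) -> Tensor:
        """Replicate a single-channel slice into a k-slice stack (for cycles)."""
        k = self.config.k_slices
        return Tensor.concatenate([x] * k, axis=1)


def _logmean(t: Tensor) -> Tensor:
    return (t + _EPS).log().mean()


def adversarial_losses(model: SynthModel, batch_mr: Tensor, batch_ct: Tensor
                       ) -> tuple[Tensor, Tensor]:
    """The two adversarial objectives in BCE form (negated log-likelihood).

    Returned losses contain both the real and the fake term, so a perfect
    discriminator drives them to 0; an everywhere-0.5 discriminator yields
    2 ln 2 each.  Generator/discriminator updates during training evaluate
    the same terms separately for alternating optimization.
    """
    if batch_mr.shape[0] == 0 or batch_ct.shape[0] == 0:
        raise ValueError("empty batch")
    center = model.config.k_slices // 2
    real_ct = batch_ct[:, center:center + 1]
    real_mr = batch_mr[:, center:center + 1]
    fake_ct = model.G1(batch_mr)
    fake_mr = model.G2(batch_ct)
    l_gan_ct = -(_logmean(model.D2(real_ct)) + _logmean(1.0 - model.D2(fake_ct)))
    l_gan_mr = -(_logmean(model.D1(real_mr)) + _logmean(1.0 - model.D1(fake_mr)))
    return l_gan_ct, l_gan_mr


def cycle_loss(model: SynthModel, batch_mr: Tensor, batch_ct: Tensor) -> Tensor:
    """L1 reconstruction through both synthesis cycles, mean-reduced."""
    center = model.config.k_slices // 2
    rec_mr = model.G2(model._as_stack(model.G1(batch_mr)))
    rec_ct = model.G1(model._as_stack(model.G2(batch_ct)))
    l1a = (rec_mr - batch_mr[:, center:center + 1]).abs().mean()
    l1b = (rec_ct - batch_ct[:, center:center + 1]).abs().mean()
    return l1a + l1b


def soft_mutual_information(a: Tensor, b: Tensor, bins: int = 32,
                            bandwidth: float | None = None) -> Tensor:
    """Differentiable MI (nats) via Parzen soft binning with Gaussian kernels.

    Bin centres span each input's observed range; bandwidth defaults to the
    bin width.  Constant inputs carry zero entropy: the MI term is 0 and a
    warning is emitted.
    """
    av = a.reshape(-1, 1)
    bv = b.reshape(-1, 1)

    def soft_hist(t: Tensor) -> Tensor | None:
        lo, hi = float(t.data.min()), float(t.data.max())
        if hi - lo < 1e-12:
            return None
        centers = np.linspace(lo, hi, bins)[None, :]
        h = bandwidth if bandwidth is not None else (hi - lo) / (bins - 1)
        w = ((t - centers) * (1.0 / h)) ** 2 * (-0.5)
        w = w.exp()
        return w / (w.sum(axis=1, keepdims=True) + _EPS)

    wa, wb = soft_hist(av), soft_hist(bv)
    if wa is None or wb is None:
        warnings.warn("constant image in MI estimate: zero entropy, MI term = 0")
        return Tensor(0.0)
    n = av.shape[0]
    joint = wa.swapaxes(0, 1) @ wb * (1.0 / n)  # (bins, bins)
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    return (joint * ((joint + _EPS).log() - (pa @ pb + _EPS).log())).sum()


def mi_loss(model: SynthModel, batch_mr: Tensor, batch_ct: Tensor) -> Tensor:
    """L_MI = -MI(mr, G1(mr)) - MI(ct, G2(ct)), most negative when the
    synthesis is deterministic in its input (structure preserved)."""
    bins = model.config.mi_bins
    center = model.config.k_slices // 2
    mi_a = soft_mutual_information(batch_mr[:, center:center + 1], model.G1(batch_mr), bins)
    mi_b = soft_mutual_information(batch_ct[:, center:center + 1], model.G2(batch_ct), bins)
    return -(mi_a + mi_b)


def total_sps_loss(model: SynthModel, batch_mr: Tensor, batch_ct: Tensor,
                   weights: SynthLossWeights | None = None
                   ) -> tuple[Tensor, dict[str, float]]:
    """Weighted sum of the four terms plus a per-term breakdown."""
    w = weights or model.config.weights
    l_gan_ct, l_gan_mr = adversarial_losses(model, batch_mr, batch_ct)
    l_cyc = cycle_loss(model, batch_mr, batch_ct)
    l_mi = mi_loss(model, batch_mr, batch_ct)
    total = l_gan_ct + l_gan_mr + w.lambda_cyc * l_cyc + w.lambda_mi * l_mi
    terms = {"l_gan_ct": l_gan_ct.item(), "l_gan_mr": l_gan_mr.item(),
             "l_cyc": l_cyc.item(), "l_mi": l_mi.item(), "total": total.item()}
    return total, terms


# --- training --------------------------------------------------------------

def _slice_stacks(volume: np.ndarray, k: int) -> np.ndarray:
    """All k-slice axial stacks of a (H, W, D) volume -> (D, k, H, W),
    edge-replicated at the boundaries so every z has a stack."""
    d = volume.shape[2]
    pad = k // 2
    idx = np.clip(np.arange(-pad, d + pad), 0, d - 1)
    padded = volume[:, :, idx]
    stacks = np.stack([padded[:, :, z:z + k] for z in range(d)], axis=0)
    return np.moveaxis(stacks, 3, 1)  # (D, k, H, W)


def _augment_pair(a: np.ndarray, b: np.ndarray, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Identical geometric augmentation (flip / rot90 / shift) on both."""
    if rng.random() < 0.5:
        a, b = a[..., ::-1, :], b[..., ::-1, :]
    if rng.random() < 0.5:
        a, b = a[..., ::-1], b[..., ::-1]
    rot = rng.integers(0, 4)
    if rot and a.shape[-1] == a.shape[-2]:
        a = np.rot90(a, rot, axes=(-2, -1))
        b = np.rot90(b, rot, axes=(-2, -1))
    shift = rng.integers(-2, 3, size=2)
    a = np.roll(a, shift, axis=(-2, -1))
    b = np.roll(b, shift, axis=(-2, -1))
    return a.copy(), b.copy()


def train_spsnet(mr_volumes: list[Volume3D | np.ndarray],
                 ct_volumes: list[Volume3D | np.ndarray],
                 config: SynthConfig | None = None
                 ) -> tuple[SynthModel, list[dict[str, float]]]:
    """Train SPSNet on slice stacks from the two domains.

    Volumes in each domain must share the in-plane shape (MR inputs are the
    coarsely registered volumes resampled onto the CT grid in the pipeline).
    With ``paired=True`` MR/CT stacks are drawn at matching indices and
    geometric augmentation is applied identically to both; unpaired sampling
    draws domains independently.  Returns the model and a per-step history of
    the four loss terms.
    """
    config = config or SynthConfig()
    if len(mr_volumes) < 1 or len(ct_volumes) < 1:
        raise ValueError("need at least one volume per domain")
    ss = np.random.SeedSequence(config.seed)
    rng_init, rng_batch, rng_aug = [np.random.default_rng(s) for s in ss.spawn(3)]

    def to_stacks(vols):
        arrs = [normalize_volume(v.data if isinstance(v, Volume3D) else v) for v in vols]
        return np.concatenate([_slice_stacks(a, config.k_slices) for a in arrs], axis=0)

    mr_stacks, ct_stacks = to_stacks(mr_volumes), to_stacks(ct_volumes)
    if config.paired and len(mr_stacks) != len(ct_stacks):
        raise ValueError("paired training requires equal slice counts per domain")

    model = SynthModel(
        G1=Generator(config.k_slices, config.width, config.n_res_blocks, rng_init),
        G2=Generator(config.k_slices, config.width, config.n_res_blocks, rng_init),
        D1=Discriminator(config.disc_width, rng_init),
        D2=Discriminator(config.disc_width, rng_init),
        config=config)
    opt_g = nn.Adam(model.G1.parameters() + model.G2.parameters(), lr=config.lr)
    opt_d = nn.Adam(model.D1.parameters() + model.D2.parameters(), lr=config.lr)

    n_steps = config.max_steps
    if n_steps is None:
        n_steps = config.epochs * max(1, len(mr_stacks) // config.batch_size)
    center = config.k_slices // 2
    history: list[dict[str, float]] = []
    for _ in range(n_steps):
        i_mr = rng_batch.integers(0, len(mr_stacks), config.batch_size)
        i_ct = i_mr % len(ct_stacks) if config.paired else rng_batch.integers(
            0, len(ct_stacks), config.batch_size)
        bm, bc = mr_stacks[i_mr], ct_stacks[i_ct]
        if config.augment:
            bm, bc = _augment_pair(bm, bc, rng_aug)
        bm_t, bc_t = Tensor(bm), Tensor(bc)
        real_mr = bm_t[:, center:center + 1]
        real_ct = bc_t[:, center:center + 1]

        # --- generator update: non-saturating adversarial + cycle + MI ---
        fake_ct = model.G1(bm_t)
        fake_mr = model.G2(bc_t)
        g_adv = -(_logmean(model.D2(fake_ct)) + _logmean(model.D1(fake_mr)))
        rec_mr = model.G2(model._as_stack(fake_ct))
        rec_ct = model.G1(model._as_stack(fake_mr))
        l_cyc = ((rec_mr - real_mr).abs().mean() + (rec_ct - real_ct).abs().mean())
        l_mi = -(soft_mutual_information(real_mr, fake_ct, config.mi_bins)
                 + soft_mutual_information(real_ct, fake_mr, config.mi_bins))
        g_loss = g_adv + config.weights.lambda_cyc * l_cyc + config.weights.lambda_mi * l_mi
        opt_g.zero_grad()
        g_loss.backward()
        opt_g.step()

        # --- discriminator update on the (detached) freshly generated fakes ---
        d_real_ct = _logmean(model.D2(real_ct))
        d_fake_ct = _logmean(1.0 - model.D2(Tensor(fake_ct.data)))
        d_real_mr = _logmean(model.D1(real_mr))
        d_fake_mr = _logmean(1.0 - model.D1(Tensor(fake_mr.data)))
        d_loss = -(d_real_ct + d_fake_ct + d_real_mr + d_fake_mr)
        opt_d.zero_grad()
        d_loss.backward()
        opt_d.step()

        l_gan_ct = -(d_real_ct.item() + d_fake_ct.item())
        l_gan_mr = -(d_real_mr.item() + d_fake_mr.item())
        history.append({
            "l_gan_ct": l_gan_ct, "l_gan_mr": l_gan_mr,
            "l_cyc": l_cyc.item(), "l_mi": l_mi.item(),
            "total": l_gan_ct + l_gan_mr
            + config.weights.lambda_cyc * l_cyc.item()
            + config.weights.lambda_mi * l_mi.item(),
            "d_loss": d_loss.item(), "g_loss": g_loss.item()})
    return model, history


def synthesize(model: SynthModel, volume: Volume3D, direction: str = "mr_to_ct") -> Volume3D:
    """Apply a generator slice-stack-wise and reassemble the full volume.

    The input is min-max normalized; the output stays in the generator's
    [0, 1] intensity domain on the input grid.
    """
    gen = model.G1 if direction == "mr_to_ct" else model.G2
    gen.eval()
    data = normalize_volume(volume.data)
    stacks = _slice_stacks(data, model.config.k_slices)
    out = np.empty_like(data)
    bs = 16
    for i in range(0, len(stacks), bs):
        pred = gen(Tensor(stacks[i:i + bs])).data[:, 0]
        out[:, :, i:i + pred.shape[0]] = np.moveaxis(pred, 0, -1)
    gen.train()
    return volume.copy_with(out)
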
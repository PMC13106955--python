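"""Independent oracles shared by the acceptance suite: brute-force geometry
and fixed stub models, deliberately written without using the package's
computational paths."""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from ctsma import nn
from ctsma.autodiff import Tensor
from ctsma.synthesis import SynthConfig, SynthModel


def brute_force_thickness_mean(binary: np.ndarray, spacing) -> float:
    """Mean local thickness by exhaustive maximal-inscribed-sphere search:
    the distance map comes from a nearest-background lookup (outside the
    patch is background) and sphere covering is enumerated directly."""
    spacing = np.asarray(spacing, dtype=float)
    padded = np.pad(binary.astype(bool), 1)
    fg = np.argwhere(padded)
    bg = np.argwhere(~padded)
    pts = fg * spacing
    radii = cKDTree(bg * spacing).query(pts)[0]
    thickness = np.zeros(len(pts))
    for j in range(len(pts)):
        covered = np.linalg.norm(pts - pts[j], axis=1) <= radii[j] + 1e-12
        thickness[covered] = np.maximum(thickness[covered], 2 * radii[j])
    return float(thickness.mean())


class _ConstD(nn.Module):
    def __init__(self, value: float):
        self.value = value

    def forward(self, x):
        return Tensor(np.full((x.shape[0], 1) + x.shape[2:], self.value))


class _ShiftG(nn.Module):
    def __init__(self, c: float):
        self.c = c

    def forward(self, x):
        return x + Tensor(np.array(self.c))


class _IdentityG(nn.Module):
    def forward(self, x):
        return x


def stub_synth_model(rng: np.random.Generator):
    """Fixed synthesis model for loss-form identities: discriminators emit
    0.5 everywhere (adversarial losses = 2 ln 2) and the forward generator
    shifts intensities by +0.25 (per-direction cycle loss = 0.25)."""
    model = SynthModel(_ShiftG(0.25), _IdentityG(), _ConstD(0.5), _ConstD(0.5),
                       SynthConfig(k_slices=1))
    mr = Tensor(rng.random((2, 1, 8, 8)))
    ct = Tensor(rng.random((2, 1, 8, 8)))
    return model, mr, ct
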
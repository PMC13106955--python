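"""SPSNet loss forms, Parzen MI estimate, training smoke, synthesis contract."""

import numpy as np
import pytest

from ctsma import nn
from ctsma.autodiff import Tensor
from ctsma.core import Volume3D
from ctsma.registration import mutual_information
from ctsma.synthesis import (SynthConfig, SynthLossWeights, SynthModel,
                             adversarial_losses, cycle_loss, mi_loss,
                             normalize_volume, soft_mutual_information,
                             synthesize, total_sps_loss, train_spsnet)

RNG = np.random.default_rng(0)


class _ConstD(nn.Module):
    """Discriminator emitting a constant probability everywhere."""

    def __init__(self, value: float):
        self.value = value

    def forward(self, x):
        return Tensor(np.full((x.shape[0], 1) + x.shape[2:], self.value))


class _PassD(nn.Module):
    """Reads the input intensity as the realness probability."""

    def forward(self, x):
        return x


class _IdentityG(nn.Module):
    def forward(self, x):
        return x


class _ShiftG(nn.Module):
    def __init__(self, c: float):
        self.c = c

    def forward(self, x):
        return x + Tensor(np.array(self.c))


def _stub_model(G1=None, G2=None, D1=None, D2=None) -> SynthModel:
    cfg = SynthConfig(k_slices=1)
    return SynthModel(G1 or _IdentityG(), G2 or _IdentityG(),
                      D1 or _ConstD(0.5), D2 or _ConstD(0.5), cfg)


def test_adversarial_loss_at_half_is_2ln2():
    model = _stub_model()
    mr = Tensor(RNG.random((2, 1, 8, 8)))
    ct = Tensor(RNG.random((2, 1, 8, 8)))
    l_ct, l_mr = adversarial_losses(model, mr, ct)
    assert l_ct.item() == pytest.approx(2 * np.log(2), abs=1e-6)
    assert l_mr.item() == pytest.approx(2 * np.log(2), abs=1e-6)


def test_perfect_discriminator_limits():
    """Real batches at intensity 1, generators emitting 0, D = identity map:
    the discriminator part of the objective vanishes and the generator term
    explodes."""

    class _ZeroG(nn.Module):
        def forward(self, x):
            return x * Tensor(np.array(0.0))

    model = _stub_model(G1=_ZeroG(), G2=_ZeroG(), D1=_PassD(), D2=_PassD())
    ones = Tensor(np.ones((2, 1, 4, 4)))
    l_ct, l_mr = adversarial_losses(model, ones, ones)
    # -(log 1 + log(1 - 0)) = 0 for the real/fake discriminator terms
    assert l_ct.item() == pytest.approx(0.0, abs=1e-6)
    assert l_mr.item() == pytest.approx(0.0, abs=1e-6)
    # non-saturating generator loss -log D(fake) is large for fakes scored 0
    g_term = -(model.D2(model.G1(ones)) + 1e-8).log().mean()
    assert g_term.item() > 10


def test_adversarial_symmetry_under_domain_swap():
    d1, d2 = _ConstD(0.3), _ConstD(0.7)
    m = SynthModel(_IdentityG(), _IdentityG(), d1, d2, SynthConfig(k_slices=1))
    m_swapped = SynthModel(_IdentityG(), _IdentityG(), d2, d1, SynthConfig(k_slices=1))
    mr = Tensor(RNG.random((2, 1, 6, 6)))
    ct = Tensor(RNG.random((2, 1, 6, 6)))
    l_ct, l_mr = adversarial_losses(m, mr, ct)
    l_ct2, l_mr2 = adversarial_losses(m_swapped, ct, mr)
    assert l_ct.item() == pytest.approx(l_mr2.item(), abs=1e-12)
    assert l_mr.item() == pytest.approx(l_ct2.item(), abs=1e-12)


def test_empty_batch_rejected():
    model = _stub_model()
    empty = Tensor(np.zeros((0, 1, 4, 4)))
    with pytest.raises(ValueError):
        adversarial_losses(model, empty, empty)


def test_cycle_loss_identity_is_zero():
    model = _stub_model()
    mr = Tensor(RNG.random((2, 1, 8, 8)))
    ct = Tensor(RNG.random((2, 1, 8, 8)))
    assert cycle_loss(model, mr, ct).item() == 0.0


def test_cycle_loss_constant_shift():
    """A +c shift through each cycle contributes exactly c per direction."""
    c = 0.37
    model = _stub_model(G1=_ShiftG(c), G2=_IdentityG())
    mr = Tensor(RNG.random((3, 1, 6, 6)))
    ct = Tensor(RNG.random((3, 1, 6, 6)))
    assert cycle_loss(model, mr, ct).item() == pytest.approx(2 * c, abs=1e-12)


def test_cycle_loss_matches_brute_force():
    rng = np.random.default_rng(7)
    g1 = nn.Conv(1, 1, (3, 3), rng, padding=1)
    g2 = nn.Conv(1, 1, (3, 3), rng, padding=1)

    class _Wrap(nn.Module):
        def __init__(self, conv):
            self.conv = conv

        def forward(self, x):
            return self.conv(x)

    model = _stub_model(G1=_Wrap(g1), G2=_Wrap(g2))
    mr = Tensor(rng.random((2, 1, 4, 4)))
    ct = Tensor(rng.random((2, 1, 4, 4)))
    ours = cycle_loss(model, mr, ct).item()
    rec_mr = g2(g1(mr)).data
    rec_ct = g1(g2(ct)).data
    brute = np.abs(rec_mr - mr.data).mean() + np.abs(rec_ct - ct.data).mean()
    assert ours == pytest.approx(brute, abs=1e-9)


def test_soft_mi_close_to_histogram_on_independent_pair():
    rng = np.random.default_rng(0)
    a = rng.random((16, 16, 16))
    b = rng.random((16, 16, 16))
    soft = soft_mutual_information(Tensor(a), Tensor(b), bins=16).item()
    hard = mutual_information(a, b, bins=16)
    assert abs(soft - hard) < 0.05


def test_mi_loss_self_synthesis_most_negative():
    """G = identity gives -H(x), more negative than any shuffled synthesis."""
    from scipy.ndimage import gaussian_filter

    a = gaussian_filter(np.random.default_rng(3).random((1, 1, 16, 16)), 2.0)

    class _ShuffleG(nn.Module):
        def forward(self, x):
            flat = x.data.ravel().copy()
            np.random.default_rng(0).shuffle(flat)
            return Tensor(flat.reshape(x.shape))

    ident = _stub_model()
    shuffled = _stub_model(G1=_ShuffleG(), G2=_ShuffleG())
    x = Tensor(np.concatenate([a, a]))
    assert mi_loss(ident, x, x).item() < mi_loss(shuffled, x, x).item()
    assert abs(mi_loss(shuffled, x, x).item()) < 0.2  # near the worst case 0


def test_constant_image_mi_warns_and_zeroes():
    model = _stub_model()
    const = Tensor(np.full((1, 1, 8, 8), 0.5))
    with pytest.warns(UserWarning):
        val = mi_loss(model, const, const).item()
    assert val == 0.0


def test_total_loss_is_exact_weighted_sum():
    model = _stub_model(G1=_ShiftG(0.1), G2=_ShiftG(-0.05),
                        D1=_ConstD(0.4), D2=_ConstD(0.6))
    mr = Tensor(RNG.random((2, 1, 8, 8)))
    ct = Tensor(RNG.random((2, 1, 8, 8)))
    w = SynthLossWeights(lambda_cyc=1.0, lambda_mi=0.5)
    total, terms = total_sps_loss(model, mr, ct, w)
    recomposed = (terms["l_gan_ct"] + terms["l_gan_mr"]
                  + w.lambda_cyc * terms["l_cyc"] + w.lambda_mi * terms["l_mi"])
    assert total.item() == pytest.approx(recomposed, abs=1e-6)
    # zero weights collapse to the pure adversarial sum
    total0, terms0 = total_sps_loss(model, mr, ct, SynthLossWeights(0.0, 0.0))
    assert total0.item() == pytest.approx(terms0["l_gan_ct"] + terms0["l_gan_mr"],
                                          abs=1e-12)


def test_default_weights_follow_training_recipe():
    w = SynthLossWeights()
    assert w.lambda_cyc == 1.0
    assert w.lambda_mi == 0.5
    with pytest.raises(ValueError):
        SynthLossWeights(-1.0, 0.5)


def test_config_validation():
    with pytest.raises(ValueError):
        SynthConfig(lr=0.0)
    with pytest.raises(ValueError):
        SynthConfig(epochs=0)


def test_training_smoke_contract():
    """One tiny run: history carries the four named loss terms, all finite."""
    rng = np.random.default_rng(0)
    mr = Volume3D(rng.random((16, 16, 8)), (1, 1, 1))
    ct = Volume3D(rng.random((16, 16, 8)), (1, 1, 1))
    cfg = SynthConfig(max_steps=3, batch_size=4, width=4, disc_width=4, seed=0)
    model, history = train_spsnet([mr], [ct], cfg)
    assert len(history) == 3
    for step in history:
        for key in ("l_gan_ct", "l_gan_mr", "l_cyc", "l_mi"):
            assert np.isfinite(step[key])
        recomposed = (step["l_gan_ct"] + step["l_gan_mr"]
                      + cfg.weights.lambda_cyc * step["l_cyc"]
                      + cfg.weights.lambda_mi * step["l_mi"])
        assert step["total"] == pytest.approx(recomposed, abs=1e-9)


def test_synthesize_shape_and_idempotence(spsnet_toy_runs):
    model, _ = spsnet_toy_runs["with_mi"]
    mr = spsnet_toy_runs["mr"]
    out1 = synthesize(model, mr)
    out2 = synthesize(model, mr)
    assert out1.shape == mr.shape
    assert out1.spacing == mr.spacing
    assert np.array_equal(out1.data, out2.data)


def test_normalize_volume_range():
    x = RNG.normal(3, 2, (5, 5, 5))
    n = normalize_volume(x)
    assert n.min() == 0.0 and n.max() == 1.0
    assert np.all(normalize_volume(np.full((3, 3, 3), 2.0)) == 0.0)
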
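"""Hand-evaluated oracles for every loss term."""

import numpy as np
import pytest

from sitrans import autodiff as ad
from sitrans import objectives as obj
from sitrans import networks as net
from sitrans.autodiff import Tensor
from sitrans.networks import TransformDecomposition


class FnGenerator:
    """Wrap (x, dy) -> image function as a generator returning a decomposition."""

    def __init__(self, fn, tag="base"):
        self.fn = fn
        self.tag = tag

    def __call__(self, x, dy):
        return TransformDecomposition(self.tag, self.fn(x, ad.astensor(dy)))


def mean_readout_regressor(m):
    """R(x): per-sample image mean replicated across m attributes."""

    def R(x):
        mu = x.mean(axis=(2, 3)).reshape(x.shape[0], 1)
        return ad.concatenate([mu] * m, axis=1)

    return R


class LinearCritic:
    def __init__(self, w):
        self.w = np.asarray(w, dtype=float)

    def __call__(self, x):
        return (x * Tensor(self.w[None])).sum(axis=(1, 2, 3))


class TestRegressorMse:
    def test_perfect_regressor_is_zero(self):
        R = mean_readout_regressor(2)
        x = Tensor(np.full((3, 1, 4, 4), 0.5))
        y = np.full((3, 2), 0.5)
        mask = np.ones((3, 2), bool)
        assert obj.regressor_mse(R, x, y, mask).item() == pytest.approx(0.0)

    def test_masked_hand_value(self):
        R = lambda x: Tensor(np.array([[1.0, 1.0]]))
        x = Tensor(np.zeros((1, 1, 2, 2)))
        y = np.array([[0.0, 0.0]])
        mask = np.array([[True, False]])
        assert obj.regressor_mse(R, x, y, mask).item() == pytest.approx(0.5)

    def test_quadratic_scaling(self):
        x = Tensor(np.zeros((2, 1, 2, 2)))
        y = np.zeros((2, 2))
        mask = np.ones((2, 2), bool)
        l1 = obj.regressor_mse(lambda x: Tensor(np.full((2, 2), 0.3)), x, y, mask).item()
        l2 = obj.regressor_mse(lambda x: Tensor(np.full((2, 2), 0.6)), x, y, mask).item()
        assert l2 == pytest.approx(4 * l1)

    def test_all_missing_batch_is_zero_with_warning(self):
        x = Tensor(np.zeros((1, 1, 2, 2)))
        with pytest.warns(UserWarning):
            out = obj.regressor_mse(
                lambda x: Tensor(np.ones((1, 2))), x, np.zeros((1, 2)), np.zeros((1, 2), bool)
            )
        assert out.item() == 0.0

    def test_masking_never_increases_losses(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = Tensor(rng.random((4, 1, 3, 3)))
            y = rng.normal(size=(4, 2))
            mask = np.ones((4, 2), bool)
            R = lambda x: Tensor(rng.normal(size=(4, 2)))
            pred = rng.normal(size=(4, 2))
            Rfixed = lambda _x: Tensor(pred)
            full = obj.regressor_mse(Rfixed, x, y, mask).item()
            mask2 = mask.copy()
            mask2[rng.integers(4), rng.integers(2)] = False
            dropped = obj.regressor_mse(Rfixed, x, y, mask2).item()
            assert dropped <= full + 1e-12


class TestCycleLoss:
    def test_identity_generator(self):
        G = FnGenerator(lambda x, dy: x)
        x = Tensor(np.random.default_rng(0).random((2, 1, 4, 4)))
        assert obj.cycle_loss(G, x, np.ones((2, 2))).item() == pytest.approx(0.0)

    def test_constant_adding_generator(self):
        c = 0.25
        G = FnGenerator(lambda x, dy: x + c)
        x = Tensor(np.zeros((2, 1, 4, 4)))
        assert obj.cycle_loss(G, x, np.ones((2, 2))).item() == pytest.approx(2 * c)

    def test_symmetric_for_involution(self):
        G = FnGenerator(lambda x, dy: ad.neg(x))  # involution independent of dy
        x = Tensor(np.random.default_rng(1).random((2, 1, 4, 4)))
        dy = np.array([[0.5, -0.5], [1.0, 0.0]])
        a = obj.cycle_loss(G, x, dy).item()
        b = obj.cycle_loss(G, x, -dy).item()
        assert a == pytest.approx(b)


class TestRelativeAttributeLoss:
    def test_perfect_translation(self):
        # R reads the image mean; G shifts the mean by dy[0] (m=1)
        R = mean_readout_regressor(1)
        x = Tensor(np.full((2, 1, 4, 4), 0.5))
        dy = np.array([[0.3], [-0.2]])
        translated = x + Tensor(dy.reshape(2, 1, 1, 1))
        out = obj.relative_attribute_loss(R, x, translated, dy, np.ones((2, 1), bool))
        assert out.item() == pytest.approx(0.0, abs=1e-12)

    def test_unchanged_prediction_gives_norm_of_dy(self):
        R = mean_readout_regressor(2)
        x = Tensor(np.full((1, 1, 4, 4), 0.5))
        d = np.array([[0.6, -0.8]])
        out = obj.relative_attribute_loss(R, x, x, d, np.ones((1, 2), bool))
        assert out.item() == pytest.approx((0.36 + 0.64) / 2)

    def test_missing_attribute_contributes_zero(self):
        R = lambda x: Tensor(np.random.default_rng(2).normal(size=(1, 2)))
        pred = Tensor(np.array([[5.0, -3.0]]))
        Rf = lambda _x: pred
        x = Tensor(np.zeros((1, 1, 2, 2)))
        dy = np.array([[0.0, 4.0]])
        mask = np.array([[True, False]])
        out = obj.relative_attribute_loss(Rf, x, x, dy, mask)
        assert out.item() == pytest.approx(0.0)


class TestReconstructionLoss:
    def test_zero_head_sit_generator(self):
        cfg = net.GeneratorConfig("sit_diff", resolutions=3, bottom_channels=8,
                                  image_size=16, m_attributes=2)
        G = net.build_generator(cfg, seed=0)
        G.zero_head()
        x = Tensor(np.random.default_rng(0).random((2, 1, 16, 16)))
        assert obj.reconstruction_loss(G, x, 2).item() == pytest.approx(0.0, abs=1e-9)

    def test_constant_offset(self):
        G = FnGenerator(lambda x, dy: x + 0.1)
        x = Tensor(np.zeros((2, 1, 4, 4)))
        assert obj.reconstruction_loss(G, x, 2).item() == pytest.approx(0.1)


class TestAdversarialLosses:
    def test_zero_and_constant_critics(self):
        x = Tensor(np.random.default_rng(0).random((3, 1, 4, 4)))
        assert obj.adversarial_gen_loss(lambda x: Tensor(np.zeros(3)), x).item() == 0.0
        c = 1.7
        assert obj.adversarial_gen_loss(lambda x: Tensor(np.full(3, c)), x).item() == pytest.approx(-c)

    def test_decreases_as_critic_scores_rise(self):
        x = Tensor(np.zeros((3, 1, 4, 4)))
        lo = obj.adversarial_gen_loss(lambda x: Tensor(np.array([0.0, 1.0, 2.0])), x).item()
        hi = obj.adversarial_gen_loss(lambda x: Tensor(np.array([1.0, 2.0, 3.0])), x).item()
        assert hi < lo

    def test_gradient_penalty_zero_for_unit_gradient_critic(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=(1, 4, 4))
        w /= np.linalg.norm(w)
        D = LinearCritic(w)
        xr = Tensor(rng.random((4, 1, 4, 4)))
        xf = Tensor(rng.random((4, 1, 4, 4)))
        gp = obj.gradient_penalty(D, xr, xf, np.random.default_rng(1))
        assert gp.item() == pytest.approx(0.0, abs=1e-10)

    def test_gradient_penalty_for_constant_critic_is_one(self):
        D = lambda x: Tensor(np.full(4, 2.5))
        rng = np.random.default_rng(2)
        xr = Tensor(rng.random((4, 1, 4, 4)))
        xf = Tensor(rng.random((4, 1, 4, 4)))
        # constant critic has zero input gradient: penalty (0-1)^2 = 1
        loss = obj.wgan_gp_critic_loss(D, xr, xf, np.random.default_rng(3), lambda_gp=1.0)
        assert loss.item() == pytest.approx(0.0 + 1.0, abs=1e-5)  # scores cancel, penalty 1

    def test_gradient_penalty_for_doubled_unit_critic(self):
        rng = np.random.default_rng(4)
        w = rng.normal(size=(1, 4, 4))
        w /= np.linalg.norm(w)
        D = LinearCritic(2 * w)
        xr = Tensor(rng.random((4, 1, 4, 4)))
        xf = Tensor(rng.random((4, 1, 4, 4)))
        gp = obj.gradient_penalty(D, xr, xf, np.random.default_rng(5))
        assert gp.item() == pytest.approx(1.0, abs=1e-9)  # (2-1)^2


class TestConditionalTerms:
    @staticmethod
    def _attr_linear_critic(u):
        def D(x, attrs):
            return ad.astensor(attrs) @ Tensor(np.asarray(u, float).reshape(-1, 1))

        return lambda x, a: D(x, a).reshape(-1)

    def test_attribute_blind_critic_gives_zero(self):
        D = lambda x, a: x.sum(axis=(1, 2, 3))
        x = Tensor(np.random.default_rng(0).random((2, 1, 4, 4)))
        w = obj.LossWeights()
        extra, cond = obj.conditional_critic_terms(
            D, x, x, np.zeros((2, 2)), np.ones((2, 2)), w
        )
        assert extra.item() == pytest.approx(0.0)
        assert cond.item() == pytest.approx(0.0)

    def test_linear_in_attributes_hand_value(self):
        u = np.array([2.0, -1.0])
        D = self._attr_linear_critic(u)
        x = Tensor(np.zeros((2, 1, 4, 4)))
        y = np.array([[0.0, 0.0], [1.0, 1.0]])
        yt = np.array([[1.0, 0.0], [1.0, 3.0]])
        w = obj.LossWeights(lambda_cond=1.0)
        extra, _ = obj.conditional_critic_terms(D, x, x, y, yt, w)
        expected = np.mean((yt - y) @ u)
        assert extra.item() == pytest.approx(expected)

    def test_swapping_attributes_negates_terms(self):
        D = self._attr_linear_critic([1.0, 2.0])
        x = Tensor(np.zeros((2, 1, 4, 4)))
        y = np.random.default_rng(1).normal(size=(2, 2))
        yt = np.random.default_rng(2).normal(size=(2, 2))
        w = obj.LossWeights()
        e1, c1 = obj.conditional_critic_terms(D, x, x, y, yt, w)
        e2, c2 = obj.conditional_critic_terms(D, x, x, yt, y, w)
        assert e1.item() == pytest.approx(-e2.item())
        assert c1.item() == pytest.approx(-c2.item())


class TestLatentAdversary:
    def test_zero_critic_gives_zero_losses(self):
        z = Tensor(np.random.default_rng(0).random((8, 5)))
        Dz = lambda z: Tensor(np.zeros(z.shape[0]))
        enc, dz = obj.latent_adversarial_losses(z, Dz, np.random.default_rng(1), lambda_gp=0.0)
        assert enc.item() == 0.0 and dz.item() == 0.0

    def test_matched_distributions_near_zero_for_linear_critic(self):
        rng = np.random.default_rng(2)
        w = rng.normal(size=5)
        Dz = lambda z: z @ Tensor(w.reshape(-1, 1)).reshape(-1) if False else (z * Tensor(w[None])).sum(axis=1)
        z = Tensor(np.random.default_rng(3).uniform(size=(4000, 5)))
        enc, dz = obj.latent_adversarial_losses(z, Dz, np.random.default_rng(4), lambda_gp=0.0)
        se = np.abs(w).sum() / np.sqrt(12 * 4000)
        assert abs(dz.item()) < 5 * se

    def test_encoder_loss_sign_convention(self):
        z = Tensor(np.ones((3, 2)))
        hi = obj.latent_adversarial_losses(z, lambda z: z.sum(axis=1), np.random.default_rng(0), 0.0)[0]
        lo = obj.latent_adversarial_losses(z, lambda z: 2.0 * z.sum(axis=1), np.random.default_rng(0), 0.0)[0]
        assert lo.item() < hi.item()


class TestIdentityPreservingLoss:
    def test_identity_generator_zero(self):
        x = Tensor(np.random.default_rng(0).random((2, 1, 4, 4)))
        out = obj.identity_preserving_loss(x, x, np.array([0.0, 1.0]), np.array([5.0, -1.0]))
        assert out.item() == pytest.approx(0.0)

    def test_zero_age_gap_gives_full_squared_norm(self):
        x = Tensor(np.zeros((1, 1, 2, 2)))
        translated = Tensor(np.full((1, 1, 2, 2), 0.5))
        s = 4 * 0.25
        out = obj.identity_preserving_loss(translated, x, np.array([1.0]), np.array([1.0]))
        assert out.item() == pytest.approx(s)

    def test_monotone_decreasing_in_age_gap(self):
        x = Tensor(np.zeros((1, 1, 2, 2)))
        translated = Tensor(np.ones((1, 1, 2, 2)))
        vals = [
            obj.identity_preserving_loss(translated, x, np.array([0.0]), np.array([g])).item()
            for g in (0.0, 1.0, 2.0, 5.0)
        ]
        assert np.all(np.diff(vals) < 0)
        assert vals[-1] < 0.05 * vals[0]


class TestTotalGeneratorLoss:
    def test_rgae_composition(self):
        w = obj.LossWeights.defaults_for("rgae")
        out = obj.total_generator_loss("rgae", "base", {"attr": 2.0, "cc": 3.0}, w)
        assert out.item() == pytest.approx(2.0 + 0.1 * 3.0)

    def test_stargan_sit_diff_all_zero(self):
        w = obj.LossWeights.defaults_for("stargan")
        dec = TransformDecomposition(
            "sit_diff",
            Tensor(np.zeros((1, 1, 4, 4))),
            velocity=Tensor(np.zeros((1, 2, 4, 4))),
            intensity_delta=Tensor(np.zeros((1, 1, 4, 4))),
        )
        out = obj.total_generator_loss(
            "stargan", "sit_diff", {"adv": 0.0, "cc": 0.0, "attr": 0.0}, w, dec
        )
        assert out.item() == pytest.approx(0.0, abs=1e-7)

    def test_stargan_sit_disp_regularizers_hand_value(self):
        from sitrans.fields import ScalarField2D, VectorField2D
        from sitrans.transforms import displacement_tv, intensity_l1

        rng = np.random.default_rng(0)
        f = np.zeros((4, 6, 2))
        f[..., 0] = 0.5 * np.arange(6)[None, :]
        dx = rng.normal(size=(4, 6))
        w = obj.LossWeights.defaults_for("stargan")
        dec = TransformDecomposition(
            "sit_disp",
            Tensor(np.zeros((1, 1, 4, 6))),
            displacement=Tensor(f.transpose(2, 0, 1)[None]),
            intensity_delta=Tensor(dx[None, None]),
        )
        out = obj.total_generator_loss(
            "stargan", "sit_disp", {"adv": 0.0, "cc": 0.0, "attr": 0.0}, w, dec
        )
        expected = 1.0 * displacement_tv(VectorField2D(f)) + 10.0 * intensity_l1(
            ScalarField2D(dx)
        )
        assert out.item() == pytest.approx(expected, abs=1e-6)

    def test_unknown_framework_or_parameterization_raises(self):
        w = obj.LossWeights()
        with pytest.raises(ValueError):
            obj.total_generator_loss("wgan", "base", {}, w)
        with pytest.raises(ValueError):
            obj.total_generator_loss("rgae", "weird", {}, w)

    def test_zeroing_weight_removes_gradient_contribution(self):
        """Zeroing a lambda must remove exactly that term's gradient."""
        a = Tensor(np.array([1.0]), requires_grad=True)
        b = Tensor(np.array([2.0]), requires_grad=True)
        comps = {"attr": (a**2).sum(), "cc": (b**2).sum()}
        w_on = obj.LossWeights(lambda_cc=0.1)
        out = obj.total_generator_loss("rgae", "base", comps, w_on)
        ga, gb = ad.grad(out, [a, b])
        assert ga.data[0] == pytest.approx(2.0) and gb.data[0] == pytest.approx(0.4)
        w_off = obj.LossWeights(lambda_cc=0.0)
        comps = {"attr": (a**2).sum(), "cc": (b**2).sum()}
        out = obj.total_generator_loss("rgae", "base", comps, w_off)
        ga, gb = ad.grad(out, [a, b])
        assert ga.data[0] == pytest.approx(2.0) and gb.data[0] == 0.0

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            obj.LossWeights(lambda_dx=-1.0)
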
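"""Spatial/intensity transform primitives against independent oracles."""

import numpy as np
import pytest

from sitrans import autodiff as ad
from sitrans.fields import DeformationField, ScalarField2D, VectorField2D
from sitrans import transforms as tr

from helpers import euler_integrate, smooth_velocity_field


def constant_vf(shape, vec):
    v = np.zeros((shape[0], shape[1], 2))
    v[..., 0], v[..., 1] = vec
    return VectorField2D(v)


class TestWarp:
    def test_identity_is_exact(self):
        rng = np.random.default_rng(0)
        x = ScalarField2D(rng.random((12, 13)))
        out = tr.warp_image(x, DeformationField.identity(x.shape))
        np.testing.assert_array_equal(out.values, x.values)

    @pytest.mark.parametrize("shift", [(1, 0), (0, 2), (3, 2), (-2, 1)])
    def test_integer_translation_matches_index_shift(self, shift):
        rng = np.random.default_rng(1)
        x = rng.random((16, 16))
        phi = DeformationField(constant_vf((16, 16), shift))
        out = tr.warp_image(ScalarField2D(x), phi).values
        dr, dc = shift
        # out(w) = x(w + shift): compare on the interior where w+shift is in-grid
        rs = slice(max(0, -dr), 16 - max(0, dr))
        cs = slice(max(0, -dc), 16 - max(0, dc))
        expected = x[rs.start + dr : rs.stop + dr, cs.start + dc : cs.stop + dc]
        np.testing.assert_allclose(out[rs, cs], expected)

    def test_constant_image_invariant_under_any_warp(self):
        rng = np.random.default_rng(2)
        x = ScalarField2D(np.full((20, 20), 0.37))
        v = VectorField2D(smooth_velocity_field((20, 20), 3.0, rng))
        out = tr.warp_image(x, tr.integrate_velocity(v))
        np.testing.assert_allclose(out.values, 0.37, atol=1e-12)

    def test_shape_mismatch_raises(self):
        x = ScalarField2D(np.zeros((8, 8)))
        phi = DeformationField.identity((9, 9))
        with pytest.raises(ValueError):
            tr.warp_image(x, phi)


class TestCompose:
    def test_identity_neutral(self):
        rng = np.random.default_rng(3)
        v = VectorField2D(smooth_velocity_field((16, 16), 2.0, rng))
        phi = tr.integrate_velocity(v)
        out = tr.compose_deformations(DeformationField.identity((16, 16)), phi)
        np.testing.assert_allclose(out.displacement.values, phi.displacement.values, atol=1e-9)

    def test_translations_add_on_interior(self):
        t, s = (1.0, 2.0), (2.0, -1.0)
        a = DeformationField(constant_vf((24, 24), t))
        b = DeformationField(constant_vf((24, 24), s))
        out = tr.compose_deformations(a, b).displacement.values
        np.testing.assert_allclose(out[5:-5, 5:-5, 0], t[0] + s[0], atol=1e-9)
        np.testing.assert_allclose(out[5:-5, 5:-5, 1], t[1] + s[1], atol=1e-9)

    def test_inverse_flow_near_identity(self):
        rng = np.random.default_rng(4)
        for _ in range(3):
            v = smooth_velocity_field((64, 64), 2.0, rng)
            fwd = tr.integrate_velocity(VectorField2D(v))
            bwd = tr.integrate_velocity(VectorField2D(-v))
            res = tr.compose_deformations(fwd, bwd).displacement
            assert res.max_magnitude() < 0.1


class TestIntegrateVelocity:
    def test_zero_field_gives_identity(self):
        out = tr.integrate_velocity(VectorField2D.zeros((10, 10)))
        np.testing.assert_array_equal(out.displacement.values, 0.0)
        assert out.steps_used == tr.DEFAULT_INTEGRATION_STEPS

    def test_constant_field_is_translation_on_interior(self):
        phi = tr.integrate_velocity(constant_vf((32, 32), (1.5, -0.75)))
        d = phi.displacement.values
        np.testing.assert_allclose(d[8:-8, 8:-8, 0], 1.5, atol=1e-6)
        np.testing.assert_allclose(d[8:-8, 8:-8, 1], -0.75, atol=1e-6)

    def test_matches_independent_euler_integration(self):
        rng = np.random.default_rng(5)
        for _ in range(3):
            v = smooth_velocity_field((32, 32), 3.0, rng)
            phi = tr.integrate_velocity(VectorField2D(v), n_steps=7)
            ref = euler_integrate(v, 2**7)
            dev = np.sqrt(((phi.displacement.values - ref) ** 2).sum(-1)).max()
            assert dev < 0.05

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            tr.integrate_velocity(VectorField2D.zeros((8, 8)), n_steps=0)
        with pytest.raises(ValueError):
            VectorField2D(np.full((8, 8, 2), np.nan))


class TestJacobian:
    def test_identity_map(self):
        det = tr.jacobian_determinant(DeformationField.identity((9, 9)))
        np.testing.assert_allclose(det.values, 1.0)

    def test_uniform_scaling(self):
        s = 1.2
        h = w = 15
        rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
        u = np.stack([(s - 1) * rr, (s - 1) * cc], axis=-1)
        det = tr.jacobian_determinant(DeformationField(VectorField2D(u)))
        np.testing.assert_allclose(det.values, s**2, atol=1e-9)

    def test_positive_for_integrated_smooth_fields(self):
        rng = np.random.default_rng(6)
        for _ in range(3):
            v = VectorField2D(smooth_velocity_field((32, 32), 3.0, rng))
            det = tr.jacobian_determinant(tr.integrate_velocity(v))
            assert det.values.min() > 0

    def test_small_grid_raises(self):
        with pytest.raises(ValueError):
            tr.jacobian_determinant(DeformationField.identity((2, 2)))


class TestRegularizers:
    def test_intensity_l1_hand_values(self):
        assert tr.intensity_l1(ScalarField2D(np.zeros((4, 4)))) == 0.0
        m = ScalarField2D(np.array([[1.0, -1.0], [0.0, 2.0]]))
        assert tr.intensity_l1(m) == pytest.approx(1.0)
        neg = ScalarField2D(-m.values)
        assert tr.intensity_l1(neg) == tr.intensity_l1(m)

    def test_tv_constant_field_zero(self):
        assert tr.displacement_tv(constant_vf((6, 7), (2.0, -3.0))) == 0.0

    def test_tv_ramp_matches_hand_value(self):
        # first component a column ramp of slope s; forward differences with
        # the last column difference zeroed give s * (W-1)/W.
        h, w, s = 8, 10, 0.5
        f = np.zeros((h, w, 2))
        f[..., 0] = s * np.arange(w)[None, :]
        assert tr.displacement_tv(VectorField2D(f)) == pytest.approx(s * (w - 1) / w)

    def test_tv_and_l1_match_loop_oracles(self):
        rng = np.random.default_rng(7)
        f = rng.normal(size=(9, 11, 2))
        dx = rng.normal(size=(9, 11))
        # loop-based TV
        acc = 0.0
        for r in range(9):
            for c in range(11):
                sq = 0.0
                for k in range(2):
                    dr = f[r + 1, c, k] - f[r, c, k] if r < 8 else 0.0
                    dc = f[r, c + 1, k] - f[r, c, k] if c < 10 else 0.0
                    sq += dr**2 + dc**2
                acc += np.sqrt(sq)
        assert tr.displacement_tv(VectorField2D(f)) == pytest.approx(acc / (9 * 11))
        # loop-based L1
        acc = sum(abs(dx[r, c]) for r in range(9) for c in range(11)) / (9 * 11)
        assert tr.intensity_l1(ScalarField2D(dx)) == pytest.approx(acc)

    def test_differentiable_tv_matches_exact(self):
        rng = np.random.default_rng(8)
        f = rng.normal(size=(8, 8, 2))
        t = ad.Tensor(f.transpose(2, 0, 1)[None])
        got = tr.displacement_tv_batch(t).item()
        assert got == pytest.approx(tr.displacement_tv(VectorField2D(f)), abs=1e-6)


class TestApplySit:
    def test_identity_when_both_zero(self):
        rng = np.random.default_rng(9)
        x = ScalarField2D(rng.random((12, 12)))
        out = tr.apply_sit(x, VectorField2D.zeros((12, 12)), ScalarField2D(np.zeros((12, 12))))
        np.testing.assert_array_equal(out.values, x.values)

    def test_pure_intensity_shift(self):
        rng = np.random.default_rng(10)
        x = rng.random((12, 12))
        d = rng.normal(size=(12, 12)) * 0.1
        out = tr.apply_sit(
            ScalarField2D(x), VectorField2D.zeros((12, 12)), ScalarField2D(d)
        )
        np.testing.assert_allclose(out.values, x + d, atol=1e-12)

    def test_equals_sequential_application(self):
        rng = np.random.default_rng(11)
        x = ScalarField2D(rng.random((24, 24)))
        v = VectorField2D(smooth_velocity_field((24, 24), 2.0, rng))
        out = tr.apply_sit(x, v, ScalarField2D(np.zeros((24, 24))))
        ref = tr.warp_image(x, tr.integrate_velocity(v))
        np.testing.assert_allclose(out.values, ref.values, atol=1e-12)

    def test_intensity_added_before_warping(self):
        """Phi_V(x + dx) differs from Phi_V(x) + dx for a non-trivial warp."""
        rng = np.random.default_rng(12)
        x = ScalarField2D(rng.random((24, 24)))
        dx = np.zeros((24, 24))
        dx[5, 5] = 1.0
        v = VectorField2D(smooth_velocity_field((24, 24), 3.0, rng))
        pre = tr.apply_sit(x, v, ScalarField2D(dx)).values
        post = tr.warp_image(x, tr.integrate_velocity(v)).values + dx
        assert np.abs(pre - post).max() > 1e-3


class TestDifferentiability:
    def test_autodiff_gradients_match_finite_differences(self):
        rng = np.random.default_rng(13)
        h = w = 8
        x0 = rng.random((1, 1, h, w))
        v0 = np.ascontiguousarray(
            smooth_velocity_field((h, w), 1.0, rng, sigma=2.0).transpose(2, 0, 1)[None]
        )
        d0 = rng.normal(size=(1, 1, h, w)) * 0.05

        def objective(x_arr, v_arr, d_arr):
            out = tr.sit_output_batch(
                ad.Tensor(x_arr), ad.Tensor(v_arr), ad.Tensor(d_arr), n_steps=4
            )
            return (out**2).mean()

        xt = ad.Tensor(x0, requires_grad=True)
        vt = ad.Tensor(v0, requires_grad=True)
        dt = ad.Tensor(d0, requires_grad=True)
        loss = (tr.sit_output_batch(xt, vt, dt, n_steps=4) ** 2).mean()
        gx, gv, gd = ad.grad(loss, [xt, vt, dt])

        # compare at interior pixels only: at the border the tapered field
        # places sample points exactly on grid nodes / the clamp edge, where
        # bilinear interpolation is non-differentiable (kinks).
        eps = 1e-6
        for arr, g in ((v0, gv), (d0, gd), (x0, gx)):
            flat = arr.reshape(-1)
            interior = [
                i
                for i in range(flat.size)
                if 2 <= np.unravel_index(i, arr.shape)[2] < h - 2
                and 2 <= np.unravel_index(i, arr.shape)[3] < w - 2
            ]
            idxs = rng.choice(interior, size=10, replace=False)
            for i in idxs:
                orig = flat[i]
                flat[i] = orig + eps
                hi = objective(x0, v0, d0).item()
                flat[i] = orig - eps
                lo = objective(x0, v0, d0).item()
                flat[i] = orig
                num = (hi - lo) / (2 * eps)
                assert g.data.reshape(-1)[i] == pytest.approx(num, rel=1e-3, abs=1e-7)
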
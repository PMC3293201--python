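"""Coefficient construction: diffusion limits, rotations, rasterisation."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from linefpt.coeffs import (
    anisotropic_tensor,
    bias_advection,
    build_field,
    isotropic_D,
    uniform_field,
)
from linefpt.movestats import MovementParams
from linefpt.synthetic import Domain, Landscape


class TestIsotropicD:
    def test_wolf_like_values(self):
        # E[L²] = 0.017 km² per 5 min -> D = 0.051 km²/h; 0.043 -> 0.129
        tau = 1 / 12
        assert isotropic_D(np.sqrt(0.017 / 2), tau) == pytest.approx(0.051, abs=5e-4)
        assert isotropic_D(np.sqrt(0.043 / 2), tau) == pytest.approx(0.129, abs=5e-4)

    def test_vanishes_with_alpha(self):
        assert isotropic_D(0.0, 0.1) == 0.0
        with pytest.raises(ValueError):
            isotropic_D(0.1, 0.0)


class TestAnisotropicTensor:
    def test_kappa_zero_isotropic(self):
        dxx, dxy, dyy = anisotropic_tensor(0.1, 0.0, 0.7)
        assert dxx == pytest.approx(0.1) and dyy == pytest.approx(0.1)
        assert dxy == pytest.approx(0.0, abs=1e-15)

    def test_axis_aligned(self):
        dxx, dxy, dyy = anisotropic_tensor(0.1, 2.0, 0.0)
        assert dxy == 0.0
        assert dxx > 0.1 > dyy  # enhanced along, reduced across

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(0.01, 1.0), st.floats(0.0, 20.0), st.floats(0.0, np.pi),
        st.floats(0.0, np.pi),
    )
    def test_trace_invariant_and_rotation_consistent(self, D, kappa, theta, phi):
        dxx, dxy, dyy = anisotropic_tensor(D, kappa, theta)
        assert dxx + dyy == pytest.approx(2 * D, rel=1e-12)
        # rotating the line rotates the tensor: R(phi) T(theta) R(phi)^T
        T = np.array([[dxx, dxy], [dxy, dyy]])
        c, s = np.cos(phi), np.sin(phi)
        R = np.array([[c, -s], [s, c]])
        expect = R @ T @ R.T
        exx, exy, eyy = anisotropic_tensor(D, kappa, theta + phi)
        np.testing.assert_allclose(
            [exx, exy, eyy], [expect[0, 0], expect[0, 1], expect[1, 1]], atol=1e-12
        )

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            anisotropic_tensor(0.1, -1.0, 0.0)


class TestBiasAdvection:
    def test_no_concentration_no_drift(self):
        c = bias_advection(0.1, 0.0, 1 / 12, np.array([1.0, 0.0]))
        np.testing.assert_allclose(c, [0.0, 0.0])

    def test_bessel_ratio_magnitude_by_quadrature(self):
        # independent oracle: I1(1)/I0(1) from direct integrals
        num = integrate.quad(lambda t: np.cos(t) * np.exp(np.cos(t)), -np.pi, np.pi)[0]
        den = integrate.quad(lambda t: np.exp(np.cos(t)), -np.pi, np.pi)[0]
        c = bias_advection(0.0922, 1.0, 1 / 12, np.array([0.0, 1.0]))
        assert np.linalg.norm(c) == pytest.approx(0.0922 * 12 * num / den, rel=1e-9)

    def test_fully_directed_limit(self):
        c = bias_advection(0.1, 5000.0, 0.1, np.array([1.0, 0.0]))
        assert np.linalg.norm(c) == pytest.approx(1.0, rel=1e-3)

    def test_zero_toward_vector_rejected(self):
        with pytest.raises(ValueError):
            bias_advection(0.1, 1.0, 0.1, np.array([0.0, 0.0]))


class TestBuildField:
    def _params(self, **kw):
        base = dict(
            alpha_on=0.1466, alpha_near=0.0922, alpha_off=0.0922,
            kappa_on=2.0, kappa_near=1.0, bias_enabled=True,
        )
        base.update(kw)
        return MovementParams(**base)

    def test_empty_landscape_any_model_is_no_response(self, empty_landscape):
        p = self._params()
        fields = {
            m: build_field(m, p, empty_landscape, 0.5)
            for m in ("no_response", "aniso", "aniso_bias")
        }
        for m in ("aniso", "aniso_bias"):
            np.testing.assert_array_equal(fields[m].d_xx, fields["no_response"].d_xx)
            np.testing.assert_array_equal(fields[m].d_xy, fields["no_response"].d_xy)
            np.testing.assert_array_equal(fields[m].c_x, fields["no_response"].c_x)

    def test_parameter_collapse_matches_no_response(self, cross_landscape):
        p = self._params(alpha_on=0.0922, alpha_near=0.0922, kappa_on=0.0)
        a = build_field("aniso", p, cross_landscape, 0.05)
        b = build_field("no_response", p, cross_landscape, 0.05)
        np.testing.assert_allclose(a.d_xx, b.d_xx, atol=1e-15)
        np.testing.assert_allclose(a.d_xy, b.d_xy, atol=1e-15)
        np.testing.assert_allclose(a.d_yy, b.d_yy, atol=1e-15)

    def test_advection_only_near_cells_in_bias_model(self, cross_landscape):
        p = self._params()
        f_aniso = build_field("aniso", p, cross_landscape, 0.02)
        assert not np.any(f_aniso.c_x) and not np.any(f_aniso.c_y)
        f_bias = build_field("aniso_bias", p, cross_landscape, 0.02)
        speed = np.hypot(f_bias.c_x, f_bias.c_y)
        centers = f_bias.center_grid()
        dist, _, _ = cross_landscape.nearest(centers)
        from linefpt.synthetic import classify_distances

        near = (classify_distances(dist) == 1).reshape(speed.shape)
        assert np.all(speed[near] > 0)
        assert not np.any(speed[~near])

    def test_rotated_landscape_rotates_tensor(self):
        # horizontal vs vertical line: fields are transposes of each other
        p = self._params()
        dom = Domain.square(2.0)
        horiz = Landscape(np.array([[0.0, 1.0, 2.0, 1.0]]), dom)
        vert = Landscape(np.array([[1.0, 0.0, 1.0, 2.0]]), dom)
        fh = build_field("aniso", p, horiz, 0.02)
        fv = build_field("aniso", p, vert, 0.02)
        np.testing.assert_allclose(fh.d_xx, fv.d_yy.T, atol=1e-12)
        np.testing.assert_allclose(fh.d_yy, fv.d_xx.T, atol=1e-12)

    def test_piecewise_constant_under_refinement(self, cross_landscape):
        p = self._params()
        coarse = build_field("aniso", p, cross_landscape, 0.1)
        fine = build_field("aniso", p, cross_landscape, 0.05)
        # the same physical location away from class boundaries keeps its value
        assert coarse.d_xx[5, 5] == pytest.approx(fine.d_xx[10, 10], abs=1e-15)
        # interior on-line value present in both rasters
        assert set(np.round(np.unique(coarse.d_xx), 12)) <= set(
            np.round(np.unique(fine.d_xx), 12)
        )

    def test_spd_everywhere(self, cross_landscape):
        f = build_field("aniso_bias", self._params(), cross_landscape, 0.02)
        det = f.d_xx * f.d_yy - f.d_xy**2
        assert np.all(det > 0) and np.all(f.d_xx > 0) and np.all(f.d_yy > 0)

    def test_mismatched_h_rejected(self, cross_landscape):
        with pytest.raises(ValueError):
            build_field("aniso", self._params(), cross_landscape, 0.3)

    def test_uniform_field_helper(self):
        f = uniform_field(0.05, (0, 0), 0.1, 10, 10)
        assert np.all(f.d_xx == 0.05) and not np.any(f.d_xy)
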
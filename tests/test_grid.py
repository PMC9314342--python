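"""Image/field containers, warping, composition, bracket, Jacobians."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from agemodel.grid import (
    DisplacementField,
    GridMismatchError,
    ScalarImage,
    VectorField,
    compose,
    field_norm,
    interior,
    jacobian_determinant,
    lie_bracket,
    warp,
    zero_displacement,
)
from agemodel.simulate import smooth_random_svf

import tolerances as tol


class TestContainers:
    def test_scalar_image_validates_dimensions_and_spacing(self):
        with pytest.raises(ValueError):
            ScalarImage(np.zeros(5))  # 1D
        with pytest.raises(ValueError):
            ScalarImage(np.zeros((4, 4)), spacing=(1.0, -1.0))
        with pytest.raises(ValueError):
            ScalarImage(np.array([[np.nan, 0.0], [0.0, 0.0]]))
        img = ScalarImage(np.zeros((4, 5)))
        assert img.spacing == (1.0, 1.0)

    def test_vector_field_component_count_must_match_dimension(self):
        VectorField(np.zeros((4, 4, 2)))
        with pytest.raises(ValueError):
            VectorField(np.zeros((4, 4, 3)))


class TestWarp:
    def test_zero_field_is_identity_bit_exact(self):
        rng = np.random.default_rng(0)
        img = ScalarImage(rng.random((9, 7)))
        out = warp(img, zero_displacement(img.shape))
        assert np.array_equal(out.data, img.data)

    def test_integer_shift_with_border_replication(self):
        # a 1D-like [0,1,0] profile shifted by +1 along axis 0
        data = np.zeros((3, 3))
        data[1, :] = 1.0
        u = np.zeros((3, 3, 2))
        u[..., 0] = 1.0
        out = warp(ScalarImage(data), DisplacementField(u))
        expected = np.zeros((3, 3))
        expected[0, :] = 1.0  # sampled at x+1: rows become [1,0,0(border)]
        assert np.array_equal(out.data, expected)

    def test_nearest_interpolation_keeps_label_values(self):
        labels = ScalarImage(np.arange(16.0).reshape(4, 4))
        u = np.full((4, 4, 2), 0.3)
        out = warp(labels, DisplacementField(u), interp="nearest")
        assert set(np.unique(out.data)) <= set(np.unique(labels.data))

    def test_shape_mismatch_names_both_shapes(self):
        with pytest.raises(GridMismatchError, match=r"\(4, 4\).*\(5, 5\)"):
            warp(ScalarImage(np.zeros((4, 4))), zero_displacement((5, 5)))

    def test_sequential_warping_matches_composed_field(self):
        """warp(warp(I,d1),d2) == warp(I, compose(d1,d2)) exactly on integer fields."""
        rng = np.random.default_rng(3)
        shape = (16, 16, 16)
        img = ScalarImage(rng.random(shape))
        idx = np.moveaxis(np.indices(shape), 0, -1).astype(float)

        def clipped_int_field(seed):
            r = np.random.default_rng(seed)
            raw = r.integers(-2, 3, size=shape + (3,)).astype(float)
            hi = np.array(shape, dtype=float) - 1
            return DisplacementField(np.clip(idx + raw, 0, hi) - idx)

        d1, d2 = clipped_int_field(10), clipped_int_field(11)
        lhs = warp(warp(img, d1), d2)
        rhs = warp(img, compose(d1, d2))
        assert np.array_equal(lhs.data, rhs.data)


class TestCompose:
    def test_zero_is_neutral(self):
        v = smooth_random_svf((16, 16), 1.5, seed=1)
        d = DisplacementField(v.data)
        z = zero_displacement((16, 16))
        assert np.allclose(compose(d, z).data, d.data)
        assert np.allclose(compose(z, d).data, d.data)

    def test_constant_fields_add(self):
        a = DisplacementField(np.full((8, 8, 2), 0.5))
        b = DisplacementField(np.full((8, 8, 2), -0.25))
        assert np.allclose(compose(a, b).data, 0.25)

    def test_associative_up_to_interpolation_error(self):
        fields = [smooth_random_svf((32, 32, 32), 2.0, seed=s) for s in (1, 2, 3)]
        d1, d2, d3 = (DisplacementField(f.data) for f in fields)
        left = compose(compose(d1, d2), d3)
        right = compose(d1, compose(d2, d3))
        diff = np.sqrt(((interior(left.data, 2) - interior(right.data, 2)) ** 2).sum(-1))
        assert diff.max() < tol.COMPOSE_ASSOCIATIVITY_MAX


class TestFieldNorm:
    def test_forced_arithmetic(self):
        assert field_norm(VectorField(np.zeros((4, 4, 2)))) == 0.0
        single = np.zeros((1, 1, 2))
        single[0, 0] = (3.0, 4.0)
        assert field_norm(VectorField(single)) == pytest.approx(5.0)
        two = np.zeros((2, 1, 2))
        two[0, 0, 0] = 1.0
        two[1, 0, 1] = 1.0
        assert field_norm(VectorField(two)) == pytest.approx(np.sqrt(2.0))

    @given(s=st.floats(-10, 10, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_absolute_homogeneity(self, s):
        v = smooth_random_svf((12, 12), 1.0, seed=7)
        assert field_norm(VectorField(s * v.data)) == pytest.approx(
            abs(s) * field_norm(v.field), rel=1e-12, abs=1e-12)


class TestLieBracket:
    def test_antisymmetry_and_self_bracket(self):
        u = smooth_random_svf((16, 16), 1.0, seed=4).field
        v = smooth_random_svf((16, 16), 1.0, seed=5).field
        assert np.array_equal(lie_bracket(u, u).data, np.zeros_like(u.data))
        assert np.allclose(lie_bracket(u, v).data, -lie_bracket(v, u).data)

    def test_constant_fields_commute(self):
        u = VectorField(np.full((8, 8, 2), 1.0))
        v = VectorField(np.full((8, 8, 2), -2.0))
        assert np.allclose(lie_bracket(u, v).data, 0.0)

    def test_linear_fields_match_matrix_commutator(self):
        """u=Ax, v=Bx: [u,v](x) = (AB−BA)x on the interior (exact derivatives)."""
        A = np.array([[0.0, 1.0], [0.0, 0.0]])
        B = np.array([[0.0, 0.0], [1.0, 0.0]])
        shape = (12, 12)
        x = np.moveaxis(np.indices(shape), 0, -1).astype(float)
        u = VectorField(x @ A.T)
        v = VectorField(x @ B.T)
        # bracket convention [u,v] = (Du)v − (Dv)u with Du = A gives (AB−BA)x
        expected = x @ (A @ B - B @ A).T
        got = lie_bracket(u, v).data
        assert np.allclose(interior(got), interior(expected))

    def test_bilinearity(self):
        u = smooth_random_svf((12, 12), 1.0, seed=8).field
        v = smooth_random_svf((12, 12), 1.0, seed=9).field
        w = smooth_random_svf((12, 12), 1.0, seed=10).field
        lhs = lie_bracket(VectorField(2.0 * u.data + v.data), w)
        rhs = 2.0 * lie_bracket(u, w).data + lie_bracket(v, w).data
        assert np.allclose(lhs.data, rhs)


class TestJacobianDeterminant:
    def test_identity_and_constant_fields_give_unit_determinant(self):
        assert np.allclose(jacobian_determinant(zero_displacement((8, 8))).data, 1.0)
        const = DisplacementField(np.full((8, 8, 2), 2.5))
        assert np.allclose(jacobian_determinant(const).data, 1.0)

    def test_uniform_dilation_closed_form(self):
        shape = (16, 16)
        x = np.moveaxis(np.indices(shape), 0, -1).astype(float)
        d = DisplacementField(0.1 * x)
        det = jacobian_determinant(d)
        assert np.allclose(interior(det), 1.21)
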
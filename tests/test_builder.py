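"""Reference selection, aging-SVF composition, aging rate, gamma, transport."""

import numpy as np
import pytest

from agemodel.builder import (
    GammaCurve,
    TemplateSequence,
    aging_rate,
    compose_aging,
    fit_gamma,
    pairwise_aging_svfs,
    select_reference,
    transport_to_global,
)
from agemodel.grid import VectorField, compose, field_norm, interior, jacobian_determinant, warp
from agemodel.simulate import shepp_logan, smooth_random_svf
from agemodel.svf import SVF, group_exp, invert_displacement

import tolerances as tol


class TestSelectReference:
    def test_stated_examples(self):
        assert select_reference([3.0, 1.2, 2.5]) == 1
        assert select_reference([1.0, 1.0, 2.0]) == 0  # tie -> smallest index

    def test_matches_exhaustive_argmin_on_seeded_lists(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            norms = rng.random(rng.integers(1, 20)).tolist()
            M = select_reference(norms)
            brute = min(range(len(norms)), key=lambda i: (norms[i], i))
            assert M == brute

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_reference([])


@pytest.fixture(scope="module")
def seq():
    base = shepp_logan((64, 64))
    fields = [smooth_random_svf((64, 64), 1.0, sigma=6.0, seed=s) for s in range(5)]
    templates = [warp(base, group_exp(f)) for f in fields]
    return TemplateSequence(templates, [30, 40, 50, 60, 70])


class TestPairwiseSvfs:
    def test_counts_and_index_pairs(self, seq):
        fwd, bwd = pairwise_aging_svfs(seq, M=2)
        assert len(fwd) == 2 and len(bwd) == 2
        assert [v.meta["pair"] for v in fwd] == [(2, 3), (3, 4)]
        assert [v.meta["pair"] for v in bwd] == [(2, 1), (1, 0)]

    def test_reference_at_ends(self, seq):
        fwd, bwd = pairwise_aging_svfs(seq, M=4)
        assert fwd == [] and len(bwd) == 4
        fwd, bwd = pairwise_aging_svfs(seq, M=0)
        assert len(fwd) == 4 and bwd == []

    def test_out_of_range_reference_rejected(self, seq):
        with pytest.raises(ValueError):
            pairwise_aging_svfs(seq, M=5)


class TestComposeAging:
    def test_single_entry_passes_through(self):
        v = smooth_random_svf((16, 16), 1.0, seed=1)
        d = compose_aging([v], [])
        assert np.array_equal(d.v_f.data, v.data)
        assert not d.v_b.data.any()
        assert len(d.intermediates_f) == 1

    def test_constant_fields_accumulate_as_sums(self):
        fields = [SVF(VectorField(np.full((8, 8, 2), c))) for c in (0.3, 0.3, 0.3)]
        d = compose_aging(fields, [])
        sums = [np.unique(i.data) for i in d.intermediates_f]
        assert np.allclose([s[0] for s in sums], [0.3, 0.6, 0.9])

    def test_composed_warp_close_to_chained_pairwise_warping(self):
        """Single-SVF composition matches chaining the pairwise maps."""
        base = shepp_logan((64, 64))
        fields = [smooth_random_svf((64, 64), 0.8, sigma=6.0, seed=40 + k) for k in range(3)]
        d = compose_aging(fields, [])
        chained = base
        for f in fields:
            chained = warp(chained, group_exp(f))
        composed = warp(base, group_exp(d.v_f))
        mse_composed = np.mean((composed.data - chained.data) ** 2)
        # compare against the interpolation noise of the chained path itself
        direct = compose(compose(group_exp(fields[0]), group_exp(fields[1])),
                         group_exp(fields[2]))
        mse_chain = np.mean((warp(base, direct).data - chained.data) ** 2)
        assert mse_composed <= tol.COMPOSED_WARP_MSE_FACTOR * max(mse_chain, 1e-6)


class TestAgingRate:
    def test_final_entries_are_exactly_one(self):
        fwd = [smooth_random_svf((16, 16), 0.5, seed=s) for s in (1, 2)]
        d = compose_aging(fwd, [])
        R_f, R_b = aging_rate(d)
        assert R_f[-1] == 1.0
        assert R_b == []
        assert all(r > 0 for r in R_f)

    def test_linear_growth_for_scaled_constant_intermediates(self):
        const = [SVF(VectorField(np.full((8, 8, 2), 0.2)))] * 4
        d = compose_aging(const, [])
        R_f, _ = aging_rate(d)
        assert np.allclose(R_f, [0.25, 0.5, 0.75, 1.0])

    def test_monotone_on_uniform_simulated_increments(self):
        fields = [smooth_random_svf((32, 32), 0.6, sigma=5.0, seed=70 + k) for k in range(4)]
        d = compose_aging(fields, [])
        R_f, _ = aging_rate(d)
        assert all(b > a for a, b in zip(R_f, R_f[1:]))

    def test_zero_signal_is_an_error(self):
        z = [SVF.zeros((8, 8))]
        d = compose_aging(z, [])
        with pytest.raises(ValueError):
            aging_rate(d)


class TestGammaCurve:
    def test_anchors_and_knot_interpolation(self):
        ages = [30, 40, 50, 60, 70]
        g = fit_gamma(ages, [0.6, 1.0], [0.4, 1.0], t_M=50)
        assert g(50) == 0.0
        assert g(30) == pytest.approx(1.0, abs=1e-12)
        assert g(70) == pytest.approx(1.0, abs=1e-12)
        assert g(60) == pytest.approx(0.6, abs=1e-12)
        assert g(40) == pytest.approx(0.4, abs=1e-12)

    def test_linear_extrapolation_with_boundary_slope(self):
        g = fit_gamma([30, 40, 50, 60, 70], [0.6, 1.0], [0.4, 1.0], t_M=50)
        lo, hi = g.age_range
        assert g(hi + 5) == pytest.approx(1.0 + 5 * g.end_slopes[1], abs=1e-12)
        assert g(lo - 5) == pytest.approx(1.0 - 5 * g.end_slopes[0], abs=1e-12)

    def test_monotone_knots_give_monotone_curve(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            vals = np.sort(rng.random(4))
            g = fit_gamma([50, 55, 60, 65, 70],
                          list(vals / vals[-1]), [], t_M=50)
            t = np.linspace(50, 70, 200)
            y = g(t)
            assert np.all(np.diff(y) >= -1e-12)
            assert np.all(y >= -1e-12)

    def test_duplicate_and_mismatched_ages_rejected(self):
        with pytest.raises(ValueError):
            fit_gamma([30, 30, 50], [1.0], [1.0], t_M=30)
        with pytest.raises(ValueError):
            fit_gamma([30, 40, 50], [1.0], [1.0, 0.5], t_M=40)

    def test_roundtrip_through_dict(self):
        g = fit_gamma([30, 40, 50, 60, 70], [0.6, 1.0], [0.4, 1.0], t_M=50)
        g2 = GammaCurve.from_dict(g.to_dict())
        assert g2 == g
        t = np.linspace(20, 80, 50)
        assert np.allclose(g(t), g2(t))


class TestTransport:
    def test_identity_transport_for_zero_reference_map(self):
        v = smooth_random_svf((32, 32), 1.0, sigma=5.0, seed=2)
        out = transport_to_global(v, SVF.zeros((32, 32)))
        rel = field_norm(VectorField(out.data - v.data)) / field_norm(v.field)
        assert rel < tol.TRANSPORT_IDENTITY_REL

    def test_constant_fields_commute(self):
        v = SVF(VectorField(np.full((32, 32, 2), 0.8)))
        v_M = SVF(VectorField(np.full((32, 32, 2), -1.2)))
        out = transport_to_global(v, v_M)
        assert np.abs(interior(out.data, 4) - 0.8).max() < 0.05

    def test_definitional_oracle(self):
        """exp(Π(v)) matches exp(v_M/2)∘exp(v)∘exp(−v_M/2) directly composed."""
        v = smooth_random_svf((32, 32), 1.0, sigma=5.0, seed=11)
        v_M = smooth_random_svf((32, 32), 1.5, sigma=5.0, seed=12)
        out = transport_to_global(v, v_M)
        half = v_M.scaled(0.5)
        rhs = compose(group_exp(half),
                      compose(group_exp(v), group_exp(half.scaled(-1.0))))
        diff = compose(group_exp(out), invert_displacement(rhs))
        epe = np.sqrt((interior(diff.data, 2) ** 2).sum(-1)).mean()
        assert epe < tol.TRANSPORT_ORACLE_ENDPOINT

    def test_transport_preserves_topology(self):
        v = smooth_random_svf((32, 32), 1.5, sigma=5.0, seed=13)
        v_M = smooth_random_svf((32, 32), 1.5, sigma=5.0, seed=14)
        out = transport_to_global(v, v_M)
        assert interior(jacobian_determinant(group_exp(out))).min() > 0
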
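"""Flows, Poisson matrices and d = 3 generalised embeddability."""

import math

import numpy as np
import pytest

from markov_embed import (
    GeneratorFamily,
    b_statistic,
    embed_3x3,
    equal_input_g_embeddable,
    g_embeddable_3x3,
    matrix_exp,
    pbs_solve,
    poisson,
    sample_generator,
    star_shape_deform,
    validate_markov,
)
from markov_embed.fixtures import fixture
from markov_embed.phylo_models import is_k3st_shaped, permute_states


class TestPBS:
    def test_constant_family_reduces_to_exponential(self):
        q = sample_generator(3, 11).entries
        fam = GeneratorFamily("piecewise_constant", segments=[(1.0, q)])
        sol = pbs_solve(fam, [1.0])
        assert np.abs(sol.M_of_t[0] - matrix_exp(q)).max() < 1e-12

    def test_commuting_callable_family(self):
        q0 = sample_generator(3, 7).entries
        fam = GeneratorFamily("callable", sampler=lambda t: (1 + t) * q0, t_end=2.0)
        sol = pbs_solve(fam, [0.5, 1.0, 2.0])
        for t, m in zip(sol.times, sol.M_of_t):
            ref = matrix_exp((t + t * t / 2) * q0)
            assert np.abs(m - ref).max() < 1e-8

    def test_two_poisson_segments_reproduce_closed_form(self):
        for t, s in [(1.0, 1.0), (0.4, 1.3), (2.0, 0.2)]:
            fx = fixture("two_poisson_product_d3", t=t, s=s)
            fam = GeneratorFamily("piecewise_constant", segments=fx.value["segments"])
            sol = pbs_solve(fam, [t + s])
            assert np.abs(sol.M_of_t[0] - fx.value["matrix"]).max() < 1e-10

    def test_symmetric_pair_product_closed_form(self):
        fx = fixture("symmetric_pair_product_d3", a=0.25, b=0.25)
        fam = GeneratorFamily("piecewise_constant", segments=fx.value["segments"])
        t_total = sum(d for d, _ in fx.value["segments"])
        sol = pbs_solve(fam, [t_total])
        assert np.abs(sol.M_of_t[0] - fx.value["matrix"]).max() < 1e-10
        expected = np.array([[0.5625, 0.25, 0.1875],
                             [0.1875, 0.75, 0.0625],
                             [0.25, 0.0, 0.75]])
        assert np.abs(fx.value["matrix"] - expected).max() < 1e-12

    def test_product_doubly_stochastic_not_symmetric(self):
        fx = fixture("symmetric_pair_product_d3", a=0.3, b=0.2)
        m = fx.value["matrix"]
        assert np.abs(m.sum(axis=0) - 1).max() < 1e-12   # doubly stochastic
        assert np.abs(m.sum(axis=1) - 1).max() < 1e-12
        assert np.abs(m - m.T).max() > 1e-3              # not symmetric

    @pytest.mark.parametrize("d", [3, 4])
    def test_liouville_and_markov_along_flows(self, d):
        """Along 50 seeded piecewise families: every M(t) is Markov and
        det M(t) = exp(int tr Q) to 1e-8."""
        rng = np.random.default_rng(d)
        for rep in range(50):
            n_seg = int(rng.integers(1, 4))
            segs = [(float(rng.uniform(0.1, 1.0)),
                     sample_generator(d, int(rng.integers(1 << 30))).entries)
                    for _ in range(n_seg)]
            fam = GeneratorFamily("piecewise_constant", segments=segs)
            total = sum(s for s, _ in segs)
            ts = sorted(rng.uniform(0, total, size=3))
            sol = pbs_solve(fam, ts)
            assert sol.det_check < 1e-8
            for m in sol.M_of_t:
                validate_markov(m, tol=1e-9)

    def test_k3st_algebra_closure_along_flow(self):
        """A family inside the K3ST generator algebra yields K3ST flows."""
        q1 = sample_generator(4, 3, style="k3st").entries
        q2 = sample_generator(4, 4, style="k3st").entries
        fam = GeneratorFamily("piecewise_constant",
                              segments=[(0.5, q1), (0.7, q2)])
        sol = pbs_solve(fam, [0.3, 0.8, 1.2])
        for m in sol.M_of_t:
            assert is_k3st_shaped(m, tol=1e-9)

    def test_monoid_closure(self):
        sols = []
        for seed in (1, 2):
            q = sample_generator(3, seed).entries
            fam = GeneratorFamily("piecewise_constant", segments=[(0.8, q)])
            sols.append(pbs_solve(fam, [0.8]).M_of_t[0])
        validate_markov(sols[0] @ sols[1], tol=1e-9)


class TestPoisson:
    def test_zero_is_identity(self):
        f = poisson(0, 1, 0.0, 3)
        assert np.abs(f.matrix - np.eye(3)).max() == 0

    def test_singular_at_one(self):
        f = poisson(1, 2, 1.0, 3)
        assert abs(np.linalg.det(f.matrix)) < 1e-15
        assert f.alpha is None

    def test_generator_matrix_consistency(self):
        f = poisson(0, 2, 0.7, 4, form="generator")
        assert np.abs(matrix_exp(f.generator) - f.matrix).max() < 1e-12
        assert abs(f.a - (1 - math.exp(-0.7))) < 1e-15

    def test_two_factor_kendall_composition(self):
        """Two 2x2 Poisson factors compose to Kendall parameter a+b-ab."""
        for a, b in [(0.2, 0.5), (0.7, 0.1)]:
            f1 = poisson(0, 1, a, 2)
            f2 = poisson(1, 0, b, 2)
            prod = f1.matrix @ f2.matrix
            assert abs(np.linalg.det(prod) - (1 - (a + b - a * b))) < 1e-12
            from markov_embed import embed_2x2
            assert embed_2x2(prod).verdict == "embeddable"

    def test_rejects_equal_indices(self):
        with pytest.raises(ValueError):
            poisson(1, 1, 0.5, 3)


class TestBStatistic:
    def test_symmetric_dominant_example(self):
        m = 0.7 * np.eye(3) + 0.1
        B, minors = b_statistic(m)
        # the diagonal (1,1) term alone is m11 * M^(11) = 0.8 * 0.63
        assert B >= 0.8 * 0.63 - 1e-12
        assert B >= np.linalg.det(m)

    def test_brute_force_definition(self, rng):
        for _ in range(20):
            q = sample_generator(3, int(rng.integers(1 << 30))).entries
            m = matrix_exp(q)
            B, minors = b_statistic(m)
            terms = []
            for i in range(3):
                for j in range(3):
                    sub = np.delete(np.delete(m, i, 0), j, 1)
                    sign = (-1.0) ** ((i + 1) + (j + 1) + (i == j) - 1)
                    terms.append(m[i, i] * m[j, j] / m[i, j]
                                 * sign * np.linalg.det(sub))
            assert abs(B - max(terms)) < 1e-12

    def test_permutation_invariance(self, rng):
        m = matrix_exp(sample_generator(3, 5).entries)
        B0, _ = b_statistic(m)
        for order in ([1, 2, 0], [2, 1, 0], [0, 2, 1]):
            B1, _ = b_statistic(permute_states(m, order))
            assert abs(B0 - B1) < 1e-12

    def test_zero_entry_raises(self):
        m = fixture("two_poisson_product_d3").value["matrix"]
        with pytest.raises(ValueError, match="zero entry"):
            b_statistic(m)


class TestGEmbeddability:
    def test_poisson_product_g_embeddable_despite_classic_failure(self):
        fx = fixture("two_poisson_product_d3", t=1.0, s=1.0)
        m = fx.value["matrix"]
        assert embed_3x3(m).verdict == "not_embeddable"
        rep = g_embeddable_3x3(m)
        assert rep.verdict == "g_embeddable"
        assert rep.factor_bound == 5

    def test_zero_diagonal_not_g_embeddable(self):
        m = np.array([[0.0, 0.6, 0.4], [0.3, 0.4, 0.3], [0.2, 0.2, 0.6]])
        rep = g_embeddable_3x3(m)
        assert rep.verdict == "not_g_embeddable"

    def test_totally_positive_b_criterion(self):
        m = 0.7 * np.eye(3) + 0.1
        rep = g_embeddable_3x3(m)
        assert rep.verdict == "g_embeddable"
        assert rep.factor_bound == 6
        assert rep.B_M >= np.linalg.det(m)

    def test_symmetric_pair_product_g_embeddable(self):
        fx = fixture("symmetric_pair_product_d3", a=0.25, b=0.25)
        rep = g_embeddable_3x3(fx.value["matrix"])
        assert rep.verdict != "not_g_embeddable"
        assert embed_3x3(fx.value["matrix"]).verdict == "not_embeddable"

    def test_flow_outputs_are_g_embeddable(self, rng):
        """Matrices built as products of Markov exponentials always pass."""
        for _ in range(10):
            q1 = sample_generator(3, int(rng.integers(1 << 30))).entries
            q2 = sample_generator(3, int(rng.integers(1 << 30))).entries
            m = matrix_exp(0.5 * q1) @ matrix_exp(0.5 * q2)
            assert g_embeddable_3x3(m).verdict != "not_g_embeddable"


class TestStarShape:
    def test_c_zero_is_identity_map(self):
        m = matrix_exp(sample_generator(3, 9).entries)
        assert np.abs(star_shape_deform(m, 0.0) - m).max() == 0

    def test_deformation_identity(self, rng):
        """P M_c = (1 - c) P + c J_d for Markov P."""
        from markov_embed import equal_input_matrix
        for _ in range(50):
            p = matrix_exp(sample_generator(3, int(rng.integers(1 << 30))).entries)
            c = float(rng.uniform(0, 0.9))
            mc = equal_input_matrix(np.full(3, c / 3)).entries
            assert np.abs(p @ mc - star_shape_deform(p, c)).max() < 1e-12

    def test_preserves_g_embeddability(self):
        fx = fixture("two_poisson_product_d3", t=0.7, s=0.9)
        m = star_shape_deform(fx.value["matrix"], 0.4)
        assert g_embeddable_3x3(m).verdict != "not_g_embeddable"


class TestEqualInputFlows:
    def test_even_dimension_matches_classic(self):
        r = equal_input_g_embeddable(np.full(4, 0.3))   # c = 1.2
        assert not r["g_embeddable_by_equal_input_flows"]
        r = equal_input_g_embeddable(np.full(4, 0.125))  # c = 0.5
        assert r["g_embeddable_by_equal_input_flows"]

    def test_d3_matches_classic_region(self):
        from markov_embed import E_MINUS_PI_SQRT3
        c = 1.0 + 0.5 * E_MINUS_PI_SQRT3
        r = equal_input_g_embeddable(np.full(3, c / 3))
        assert r["g_embeddable_by_equal_input_flows"]
        c = 1.0 + 2.0 * E_MINUS_PI_SQRT3
        r = equal_input_g_embeddable(np.full(3, c / 3))
        assert not r["g_embeddable_by_equal_input_flows"]
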
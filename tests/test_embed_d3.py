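"""The complete 3 x 3 case analysis."""

import math

import numpy as np
import pytest
from helpers import best_recovery, chain_generator

from markov_embed import (
    E_MINUS_PI_SQRT3,
    commutant_basis,
    cyclic_generators,
    delta_min,
    delta_min_cyclic,
    embed_3x3,
    equal_input_matrix,
    exp_residual,
    extremal_generators,
    matrix_exp,
    sample_generator,
    uniqueness_certificates,
)
from markov_embed.embed_d3 import equal_input_negative, equal_input_params
from markov_embed.fixtures import fixture
from markov_embed.matrix_core import is_generator


class TestDegree2:
    def test_rank_one_case(self):
        # 1 (+) 2x2 block structure has JNF diag(1, 1, lambda)
        lam = 0.5
        m = np.array([[0.75, 0.25, 0.0], [0.25, 0.75, 0.0], [0.0, 0.0, 1.0]])
        r = embed_3x3(m)
        assert r.verdict == "embeddable" and r.uniqueness == "unique_certified"
        A = m - np.eye(3)
        assert np.abs(r.generators[0] - math.log(lam) / (lam - 1) * A).max() < 1e-10
        assert exp_residual(r.generators[0], m) < 1e-10

    def test_rank_one_negative_not_embeddable(self):
        m = np.array([[0.25, 0.75, 0.0], [0.75, 0.25, 0.0], [0.0, 0.0, 1.0]])
        assert embed_3x3(m).verdict == "not_embeddable"

    def test_equal_input_positive_unique(self):
        # c = 0.6 => lambda = 0.4 > e^{-2 pi sqrt 3}: no extra winding branch
        r = embed_3x3(equal_input_matrix([0.2, 0.2, 0.2]).entries)
        assert r.verdict == "embeddable"
        assert r.uniqueness == "unique_certified"
        assert len(r.generators) == 1


class TestEqualInputNegative:
    def test_extremal_two_circulant_generators(self):
        fx = fixture("extremal_constant_input_d3")
        r = embed_3x3(fx.value)
        assert r.verdict == "embeddable"
        assert len(r.generators) == 2
        qp, qm = fixture("circulant_pair_d3").value
        found = sorted(r.generators, key=lambda g: g[0, 1])
        expect = sorted([qp, qm], key=lambda g: g[0, 1])
        for g, e in zip(found, expect):
            assert np.abs(g - e).max() < 1e-8

    def test_just_beyond_boundary_not_embeddable(self):
        c = 1.0 + E_MINUS_PI_SQRT3 + 1e-3
        m = equal_input_matrix(np.full(3, c / 3)).entries
        assert embed_3x3(m).verdict == "not_embeddable"

    def test_squared_extremal_three_embeddings(self):
        fx = fixture("squared_extremal_d3")
        r = embed_3x3(fx.value)
        assert r.verdict == "embeddable"
        assert len(r.generators) >= 3
        for g in r.generators:
            assert exp_residual(g, fx.value) < 1e-8

    def test_interior_deformation(self):
        c_vec = np.array([0.42, 0.35, 0.28])  # c = 1.05 < 1 + e^{-Delta_min}?
        dmin = delta_min(*c_vec)
        assert 1.0 + math.exp(-dmin) < 1.05  # this direction is too lopsided
        r = equal_input_negative(c_vec)
        assert r.verdict == "not_embeddable"
        # a nearly uniform direction with c slightly above 1 is embeddable
        c_vec = np.full(3, (1.0 + 0.5 * E_MINUS_PI_SQRT3) / 3)
        r = equal_input_negative(c_vec)
        assert r.verdict == "embeddable"
        assert len(r.generators) == 2
        m = equal_input_matrix(c_vec).entries
        for g in r.generators:
            assert exp_residual(g, m) < 1e-8

    def test_delta_min_values_and_homogeneity(self):
        assert abs(delta_min(1, 1, 1) - math.pi * math.sqrt(3)) < 1e-12
        assert abs(delta_min(1, 1, 2) - 2 * math.pi * math.sqrt(2)) < 1e-12
        for t in (0.1, 3.7):
            assert abs(delta_min(t, t, t) - math.pi * math.sqrt(3)) < 1e-12
            assert abs(delta_min_cyclic(t, t, t) - math.pi * math.sqrt(3)) < 1e-12

    def test_constrained_minimum_cross_check(self):
        """Direct SLSQP minimisation of Delta over the commutant subject to
        s^2 = -pi^2 and the generator inequalities: for the uniform
        direction the minimum is pi sqrt 3 (the stationary family is
        optimal); for the skewed direction (1,1,2) the cyclic-support
        family is strictly better and attains the numerical minimum."""
        from scipy.optimize import minimize

        def true_min(c):
            cb = commutant_basis(*c)

            def s2c(p):
                chi, psi, phi = cb.s_squared_coeffs(p[0], p[1], p[2])
                return chi + psi * p[3] + phi * p[3] * p[3] + math.pi ** 2

            def ineqs(p):
                return np.array(cb.generator_inequalities(*p))

            rng = np.random.default_rng(0)
            best = math.inf
            for _ in range(40):
                x0 = np.concatenate([rng.uniform(0.5, 8, 3),
                                     rng.uniform(-0.6, 0.6, 1)])
                res = minimize(lambda p: cb.delta(p[0], p[1], p[2]), x0,
                               method="SLSQP",
                               constraints=[{"type": "eq", "fun": s2c},
                                            {"type": "ineq", "fun": ineqs}],
                               options={"maxiter": 600, "ftol": 1e-14})
                if (res.success and abs(s2c(res.x)) < 1e-8
                        and ineqs(res.x).min() > -1e-10 and res.fun < best):
                    best = res.fun
            return best

        assert abs(true_min((1.0, 1.0, 1.0)) - math.pi * math.sqrt(3)) < 1e-6
        m112 = true_min((1.0, 1.0, 2.0))
        assert m112 < delta_min(1, 1, 2) - 1.0  # stationary family not optimal
        assert abs(m112 - delta_min_cyclic(1, 1, 2)) < 1e-6

    def test_cyclic_family_embeds_beyond_stationary_bound(self):
        """For direction (1,1,2) the cyclic-support generator embeds an
        equal-input matrix whose summatory parameter exceeds
        1 + exp(-delta_min); the solver finds it."""
        dcyc = delta_min_cyclic(1, 1, 2)
        assert dcyc < delta_min(1, 1, 2)
        csum = 1.0 + math.exp(-dcyc)
        assert csum > 1.0 + math.exp(-delta_min(1, 1, 2))
        cvec = csum * np.array([1.0, 1.0, 2.0]) / 4.0
        m = equal_input_matrix(cvec).entries
        fwd, rev = cyclic_generators(1, 1, 2)
        assert is_generator(fwd)[0] and is_generator(rev)[0]
        assert exp_residual(fwd, m) < 1e-10
        r = embed_3x3(m)
        assert r.verdict == "embeddable"
        assert len(r.generators) >= 2

    def test_extremal_generator_consistency(self):
        """Decomposing Q+ in the commutant basis reproduces the stationary
        point: s^2 = -pi^2, Delta = Delta_min, |w| as printed."""
        c1, c2, c3 = 0.4, 0.5, 0.6
        cb = commutant_basis(c1, c2, c3)
        qp, qm = extremal_generators(c1, c2, c3)
        for q, sign in ((qp, +1), (qm, -1)):
            x, y, z, w = cb.coords(q)
            assert np.abs(cb.combine(x, y, z, w) - q).max() < 1e-12
            chi, psi, phi = cb.s_squared_coeffs(x, y, z)
            assert abs(chi + psi * w + phi * w * w + math.pi ** 2) < 1e-9
            assert abs(cb.delta(x, y, z) - delta_min(c1, c2, c3)) < 1e-9
            c = c1 + c2 + c3
            w_expect = 2 * math.pi * math.sqrt(c1 * c2 * c3 / c) \
                / ((c1 + c2) * (c1 + c3) * (c2 + c3))
            assert abs(abs(w) - w_expect) < 1e-9

    def test_extremal_generators_commute_with_C(self):
        c = (0.3, 0.45, 0.5)
        C = np.tile(c, (3, 1))
        for q in extremal_generators(*c):
            assert np.abs(q @ C - C @ q).max() < 1e-12

    def test_hessian_valley(self):
        """On the constraint manifold s^2 = -pi^2, the implicit function
        w(x, y, z) has a semidefinite Hessian at the stationary point, with
        one zero eigenvalue whose neutral direction is (1,1,1)."""
        c = (0.5, 0.6, 0.7)
        cb = commutant_basis(*c)
        qp, _ = extremal_generators(*c)
        x, y, z, w0 = cb.coords(qp)

        def w_on_manifold(p):
            xx, yy, zz = p
            chi, psi, phi = cb.s_squared_coeffs(xx, yy, zz)
            disc = psi ** 2 - 4 * phi * (chi + math.pi ** 2)
            roots = [(-psi + s * math.sqrt(disc)) / (2 * phi) for s in (+1, -1)]
            return min(roots, key=lambda r: abs(r - w0))

        h = 1e-4
        p0 = np.array([x, y, z])
        H = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                pp = p0.copy(); pp[i] += h; pp[j] += h
                pm = p0.copy(); pm[i] += h; pm[j] -= h
                mp = p0.copy(); mp[i] -= h; mp[j] += h
                mm = p0.copy(); mm[i] -= h; mm[j] -= h
                H[i, j] = (w_on_manifold(pp) - w_on_manifold(pm)
                           - w_on_manifold(mp) + w_on_manifold(mm)) / (4 * h * h)
        ev, vec = np.linalg.eigh(H)
        izero = int(np.argmin(np.abs(ev)))
        assert abs(ev[izero]) < 1e-3
        assert abs(abs(vec[:, izero] @ (np.ones(3) / math.sqrt(3))) - 1) < 1e-4
        others = np.delete(ev, izero)
        assert np.all(others > 1e-4) or np.all(others < -1e-4)


class TestCommutantBasis:
    def test_uniform_alpha_beta_gamma(self):
        cb = commutant_basis(1.0, 1.0, 1.0)
        assert cb.alpha == cb.beta == cb.gamma == 4.0

    def test_left_eigenvector_property(self):
        c = np.array([0.2, 0.7, 0.4])
        cb = commutant_basis(*c)
        for X in (cb.Q1, cb.Q2, cb.Q3, cb.R0):
            assert np.abs(c @ X).max() < 1e-12

    def test_basis_rank_four(self):
        cb = commutant_basis(0.3, 0.4, 0.5)
        stacked = np.stack([m.ravel() for m in (cb.Q1, cb.Q2, cb.Q3, cb.R0)])
        assert np.linalg.matrix_rank(stacked) == 4

    def test_commutation_with_C(self):
        c = np.array([0.2, 0.7, 0.4])
        cb = commutant_basis(*c)
        C = np.tile(c, (3, 1))
        for X in (cb.Q1, cb.Q2, cb.Q3, cb.R0):
            assert np.abs(X @ C - C @ X).max() < 1e-12

    def test_x_inequality_matches_printed_constraint(self):
        """The reconstructed sign conditions reduce, for the x-coordinate,
        to x >= (c1+c2)(c1+c3) max(w/c2, -w/c3)."""
        c1, c2, c3 = 0.5, 0.8, 1.1
        cb = commutant_basis(c1, c2, c3)
        for w in (-0.3, 0.2):
            bound = (c1 + c2) * (c1 + c3) * max(w / c2, -w / c3)
            ineq = cb.generator_inequalities(bound + 1e-9, 10.0, 10.0, w)
            assert min(ineq[:2]) >= -1e-6
            ineq = cb.generator_inequalities(bound - 1e-3, 10.0, 10.0, w)
            assert min(ineq[:2]) < 0

    def test_equal_input_recognition(self):
        m = equal_input_matrix([0.1, 0.3, 0.2]).entries
        c = equal_input_params(m)
        assert np.abs(c - [0.1, 0.3, 0.2]).max() < 1e-12
        m2 = m.copy()
        m2[0, 1] += 1e-5
        m2[0, 0] -= 1e-5
        assert equal_input_params(m2) is None


class TestCyclic:
    def test_round_trip_distinct_real(self):
        q = chain_generator([0.3, 0.9])
        r = embed_3x3(matrix_exp(q))
        assert r.verdict == "embeddable" and r.uniqueness == "unique_certified"
        assert best_recovery(r, q) < 1e-8

    def test_jordan2_round_trip(self):
        q = chain_generator([0.6, 0.6])
        r = embed_3x3(matrix_exp(q))
        assert r.verdict == "embeddable"
        assert best_recovery(r, q) < 1e-8

    def test_two_poisson_product_not_embeddable(self):
        fx = fixture("two_poisson_product_d3", t=1.0, s=0.5)
        r = embed_3x3(fx.value["matrix"])
        assert r.verdict == "not_embeddable"
        # the unique zero-row-sum log has a negative (3,2) entry
        assert not r.branches[0].is_generator
        assert r.branches[0].candidate[2, 1] < 0

    def test_negative_gamma_formula(self):
        """Entry (3,2) of the unique log equals
        (a log(1-b) - b log(1-a)) / (b - a), negative for 0 < a != b < 1."""
        for t, s in [(1.0, 0.5), (0.3, 1.7), (2.0, 0.1)]:
            fx = fixture("two_poisson_product_d3", t=t, s=s)
            a, b = fx.value["a"], fx.value["b"]
            gamma = (a * math.log(1 - b) - b * math.log(1 - a)) / (b - a)
            assert gamma < 0
            r = embed_3x3(fx.value["matrix"])
            assert abs(r.branches[0].candidate[2, 1] - gamma) < 1e-9


class TestComplexPair:
    def test_circulant_single_branch(self):
        m = np.array([[0.6, 0.3, 0.1], [0.1, 0.6, 0.3], [0.3, 0.1, 0.6]])
        r = embed_3x3(m)
        assert r.verdict == "embeddable"
        assert len(r.generators) == 1
        assert uniqueness_certificates(m)["cuthbert_det"]
        # generator is circulant like the matrix
        g = r.generators[0]
        assert abs(g[0, 1] - g[1, 2]) < 1e-9 and abs(g[1, 2] - g[2, 0]) < 1e-9

    def test_winding_branch_recovery(self):
        q = 5.0 * np.array([[-1.0, 1, 0], [0, -1, 1], [1, 0, -1]])
        m = matrix_exp(q)
        r = embed_3x3(m)
        assert r.verdict == "embeddable"
        assert best_recovery(r, q) < 1e-8
        assert any(b.k != 0 and b.is_generator for b in r.branches)

    def test_solution_count_within_bound(self):
        """Number of generators never exceeds
        floor(1 - log(det M) / (2 pi sqrt 3))."""
        count_checked = 0
        for seed in range(100):
            m = matrix_exp(sample_generator(3, seed).entries)
            r = embed_3x3(m)
            if r.case_label != "diag(1,l,conj_l)":
                continue
            count_checked += 1
            det = np.linalg.det(m)
            bound = math.floor(1 - math.log(det) / (2 * math.pi * math.sqrt(3)))
            assert len(r.generators) <= bound
        assert count_checked >= 10


class TestEqualInputAlgebra:
    def test_product_rule(self, rng):
        """Equal-input products compose via (1-c'') = (1-c)(1-c')."""
        for _ in range(100):
            c1 = rng.uniform(0, 0.3, 3)
            c2 = rng.uniform(0, 0.3, 3)
            m = equal_input_matrix(c1).entries @ equal_input_matrix(c2).entries
            c12 = equal_input_params(m, tol=1e-9)
            assert c12 is not None
            assert abs((1 - c12.sum()) - (1 - c1.sum()) * (1 - c2.sum())) < 1e-12

    def test_squared_fixture_parameter(self):
        fx = fixture("squared_extremal_d3")
        c = equal_input_params(fx.value)
        assert abs(c.sum() - (1 - math.exp(-2 * math.pi * math.sqrt(3)))) < 1e-12
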
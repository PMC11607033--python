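"""Complete decision procedure for the 4 x 4 embedding problem.

As for d = 3, the dispatch key is the degree of the minimal polynomial.
Degree-2 matrices are diagonalisable with spectrum {1, lambda}; the
rank-one logarithm formula applies whenever lambda is in (0, 1), and the
pattern diag(1, 1, lambda, lambda) additionally admits winding branches
built from the rotation family in the repeated eigenspace, which is the
only route to embeddability when lambda < 0 (impossible once
``lambda < -exp(-pi)``).  Degree-3 matrices combine a unique quadratic
candidate (Jordan patterns containing a double 1 or a J2 block) with
rotation branches for a repeated non-unit eigenvalue and a finite winding
enumeration for a complex pair.  Cyclic (degree-4) matrices have all their
candidates of the form ``alpha A + beta A^2 + gamma A^3`` with closed-form
(confluent) Vandermonde coefficients.

A 4 x 4 generator eigenvalue z obeys ``|Im z| <= -Re z`` (the quarter-plane
cone), which truncates every winding enumeration; a rotation carried by the
Perron eigenvalue 1 would need a purely imaginary non-zero generator
eigenvalue and is therefore never feasible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .log_coefficients import (
    coeffs_complex_4,
    coeffs_complex_pair,
    coeffs_confluent_pair,
    coeffs_jordan3,
    coeffs_mixed_jordan2,
    coeffs_simple_real_4,
    coeffs_two_real,
)
from .matrix_core import (
    DEFAULT_SEARCH,
    E_MINUS_PI,
    EmbeddingResult,
    LogBranch,
    MarkovMatrix,
    SearchConfig,
    SpectralSummary,
    dedupe_generators,
    exp_residual,
    is_generator,
    ixyz_feasibility,
    merge_hypotheses,
    necessary_conditions,
    spectral_summaries,
    uniqueness_certificates,
    validate_markov,
)

__all__ = [
    "embed_4x4",
    "degree2_case_d4",
    "degree3_case_d4",
    "cyclic_case_d4",
    "CoefficientSystem",
]


@dataclass
class CoefficientSystem:
    """A solved (confluent) Vandermonde system for ``R = sum a_i A^i``."""

    mu_values: tuple
    vandermonde: np.ndarray
    rhs: np.ndarray
    solution: tuple[float, ...]

    @property
    def residual(self) -> float:
        sol = np.array(self.solution, dtype=complex)
        return float(np.abs(self.vandermonde @ sol - self.rhs).max())


def _poly_candidate(M: MarkovMatrix, coeffs: tuple[float, ...]) -> np.ndarray:
    A = M.A
    out = np.zeros_like(A)
    P = np.eye(M.d)
    for c in coeffs:
        P = P @ A
        out = out + c * P
    return out


def _unique_candidate_result(M: MarkovMatrix, tag: str, coeffs, conds,
                             cfg: SearchConfig) -> EmbeddingResult:
    """Common wrap-up when the principal candidate is the only possibility."""
    Q = _poly_candidate(M, coeffs)
    ok, viol = is_generator(Q, cfg.accept_tol)
    res = exp_residual(Q, M.entries)
    branch = LogBranch(0, tuple(coeffs), Q, ok, res)
    if ok and res <= cfg.residual_tol:
        return EmbeddingResult("embeddable", tag, [Q], "unique_certified",
                               [branch], conds, [])
    if not ok:
        msg = f"unique candidate has negative off-diagonal entries at {viol}"
        return EmbeddingResult("not_embeddable", tag, [], "not_applicable",
                               [branch], conds, [msg])
    return EmbeddingResult("undecided_search", tag, [], "search_incomplete",
                           [branch], conds, ["residual contract failed"])


def _not_embeddable(tag, conds, msg) -> EmbeddingResult:
    return EmbeddingResult("not_embeddable", tag, [], "not_applicable", [],
                           conds, [msg])


def _rotation_branches(M: MarkovMatrix, T: np.ndarray, fixed_log, lam_rot: float,
                       cfg: SearchConfig):
    """Winding branches rotating a repeated real eigenvalue ``lam_rot``.

    Positive lam_rot: angles 2 pi k with 2 pi |k| <= |log lam_rot|;
    negative: angles (2k+1) pi with |2k+1| pi <= |log |lam_rot||.
    Returns (branches, generators, k_range_empty).
    """
    branches: list[LogBranch] = []
    gens: list[np.ndarray] = []
    la = abs(lam_rot)
    bound = abs(math.log(la))
    if lam_rot > 0:
        ks = []
        kmax = int(math.floor(bound / (2.0 * math.pi) + 1.0e-12))
        for k in range(1, min(kmax, cfg.k_cap) + 1):
            ks.extend([k, -k])
        angles = [2.0 * math.pi * k for k in ks]
    else:
        ks, angles = [], []
        k = 0
        while (2 * k + 1) * math.pi <= bound + 1.0e-12 and k <= cfg.k_cap:
            ks.extend([k, -k - 1])
            angles.extend([(2 * k + 1) * math.pi, -(2 * k + 1) * math.pi])
            k += 1
    empty = not ks
    for k, theta in zip(ks, angles):
        R = ixyz_feasibility(T, fixed_log, theta, math.log(la), cfg)
        if R is None:
            continue
        ok, _ = is_generator(R, cfg.accept_tol)
        res = exp_residual(R, M.entries)
        branches.append(LogBranch(k, (), R, ok, res))
        if ok and res <= cfg.residual_tol:
            gens.append(R)
    return branches, gens, empty


# ---------------------------------------------------------------------------
# case solvers
# ---------------------------------------------------------------------------


def degree2_case_d4(M: MarkovMatrix, summary: SpectralSummary,
                    cfg: SearchConfig = DEFAULT_SEARCH, conds=None) -> EmbeddingResult:
    """Diagonalisable spectrum {1, lambda}: Jordan patterns with deg q = 2."""
    if conds is None:
        conds = necessary_conditions(M.entries)
    tag = summary.jnf_tag
    lam_c = summary.non_unit()[0]
    lam = lam_c.value.real
    one = summary.cluster_of_one()

    if tag in ("diag(1,1,1,l)", "diag(1,l,l,l)"):
        if lam <= 1.0e-12:
            return _not_embeddable(
                tag, conds,
                "lambda <= 0: negative eigenvalue of odd multiplicity or zero "
                "determinant (Culver)")
        Q = (math.log(lam) / (lam - 1.0)) * M.A
        res = exp_residual(Q, M.entries)
        branches = [LogBranch(0, (math.log(lam) / (lam - 1.0),), Q, True, res)]
        gens = [Q] if res <= cfg.residual_tol else []
        msgs: list[str] = []
        uniq = "unique_certified"
        if tag == "diag(1,l,l,l)":
            # rotations live inside the 3-dim lambda eigenspace; searching a
            # fixed 2-plane is incomplete, hence the conservative flag
            kmax = int(math.floor(abs(math.log(lam)) / (2.0 * math.pi) + 1.0e-12))
            if kmax > 0 and lam_c.basis is not None:
                T = np.hstack([one.basis, lam_c.basis])
                br, g2, _ = _rotation_branches(M, T, [0.0, math.log(lam)], lam, cfg)
                branches += br
                gens += g2
                uniq = "search_incomplete"
        if not gens:
            return EmbeddingResult("undecided_search", tag, [], "search_incomplete",
                                   branches, conds, ["residual contract failed"])
        certs = uniqueness_certificates(M.entries)
        if certs["cuthbert_half"] or certs["cuthbert_det"]:
            uniq = "unique_certified"
        return EmbeddingResult("embeddable", tag, dedupe_generators(gens), uniq,
                               branches, conds, msgs)

    # tag == diag(1,1,l,l)
    if lam >= 1.0 - 1.0e-12:
        return _not_embeddable(tag, conds, "repeated eigenvalue at 1 boundary")
    if abs(lam) <= 1.0e-12:
        return _not_embeddable(tag, conds, "lambda = 0: matrix is singular")
    T = None
    if one.basis is not None and lam_c.basis is not None:
        T = np.hstack([one.basis, lam_c.basis])
    if lam > 0:
        Q = (math.log(lam) / (lam - 1.0)) * M.A
        res = exp_residual(Q, M.entries)
        branches = [LogBranch(0, (math.log(lam) / (lam - 1.0),), Q, True, res)]
        gens = [Q] if res <= cfg.residual_tol else []
        empty = True
        if T is not None:
            br, g2, empty = _rotation_branches(M, T, [0.0, 0.0], lam, cfg)
            branches += br
            gens += g2
        gens = dedupe_generators(gens)
        if not gens:
            return EmbeddingResult("undecided_search", tag, [], "search_incomplete",
                                   branches, conds, ["residual contract failed"])
        certs = uniqueness_certificates(M.entries)
        kmax = int(math.floor(abs(math.log(lam)) / (2.0 * math.pi) + 1.0e-12))
        uniq = ("unique_certified"
                if kmax == 0 or certs["cuthbert_half"] or certs["cuthbert_det"]
                else "search_incomplete")
        return EmbeddingResult("embeddable", tag, gens, uniq, branches, conds, [])
    # lam < 0: embeddable only through an odd-angle rotation branch
    if lam < -E_MINUS_PI - 1.0e-12:
        return _not_embeddable(
            tag, conds,
            "|2k+1| pi <= |log|lambda|| has no integer solution: "
            "lambda < -exp(-pi) certifies non-embeddability")
    if T is None:
        return EmbeddingResult("undecided_search", tag, [], "search_incomplete",
                               [], conds, ["no real eigenbasis available"])
    branches, gens, empty = _rotation_branches(M, T, [0.0, 0.0], lam, cfg)
    if empty:
        return _not_embeddable(tag, conds, "empty winding range excludes all branches")
    gens = dedupe_generators(gens)
    if gens:
        return EmbeddingResult("embeddable", tag, gens, "search_incomplete",
                               branches, conds, [])
    return EmbeddingResult("undecided_search", tag, [], "search_incomplete",
                           branches, conds,
                           ["no generator found by search (not a certificate)"])


def degree3_case_d4(M: MarkovMatrix, summary: SpectralSummary,
                    cfg: SearchConfig = DEFAULT_SEARCH, conds=None) -> EmbeddingResult:
    """Minimal-polynomial degree 3: five Jordan patterns."""
    if conds is None:
        conds = necessary_conditions(M.entries)
    tag = summary.jnf_tag
    nonunit = summary.non_unit()

    if tag == "diag(1,1,l,conj_l)":
        return _complex_enumeration(
            M, tag, next(c.value for c in nonunit if c.value.imag > 0),
            conds, cfg, quadratic=True)

    if tag == "diag(1,1,l1,l2)":
        vals = sorted((c.value.real for c in nonunit), reverse=True)
        if any(v <= 1.0e-12 for v in vals):
            return _not_embeddable(tag, conds,
                                   "non-positive eigenvalue excludes a real log")
        coeffs = coeffs_two_real(vals[0] - 1.0, vals[1] - 1.0)
        return _unique_candidate_result(M, tag, coeffs, conds, cfg)

    if tag in ("diag(1,1)+J2(l)", "diag(1,l)+J2(l)"):
        lam = nonunit[0].value.real
        if lam <= 1.0e-12:
            return _not_embeddable(tag, conds,
                                   "non-positive eigenvalue excludes a real log")
        coeffs = coeffs_confluent_pair(lam - 1.0)
        return _unique_candidate_result(M, tag, coeffs, conds, cfg)

    # tag == diag(1,l1,l2,l2)
    rep = next(c for c in nonunit if c.alg == 2)
    simple = next(c for c in nonunit if c.alg == 1)
    lam1 = simple.value.real
    lam2 = rep.value.real
    if lam1 <= 1.0e-12:
        return _not_embeddable(tag, conds,
                               "simple eigenvalue not in (0,1) excludes a real log")
    one = summary.cluster_of_one()
    T = None
    if one.basis is not None and simple.basis is not None and rep.basis is not None:
        T = np.hstack([one.basis, simple.basis, rep.basis])
    if lam2 > 1.0e-12:
        branches: list[LogBranch] = []
        gens: list[np.ndarray] = []
        if T is not None:
            # k = 0 is the principal logarithm (no rotation freedom)
            R0 = ixyz_feasibility(T, [0.0, math.log(lam1)], 0.0, math.log(lam2), cfg)
            if R0 is None:
                L = np.diag([0.0, math.log(lam1), math.log(lam2), math.log(lam2)])
                R0c = T @ L @ np.linalg.inv(T)
                branches.append(LogBranch(0, (), R0c, False, exp_residual(R0c, M.entries)))
            else:
                res = exp_residual(R0, M.entries)
                branches.append(LogBranch(0, (), R0, True, res))
                if res <= cfg.residual_tol:
                    gens.append(R0)
            br, g2, _ = _rotation_branches(M, T, [0.0, math.log(lam1)], lam2, cfg)
            branches += br
            gens += g2
        gens = dedupe_generators(gens)
        if gens:
            certs = uniqueness_certificates(M.entries)
            kmax = int(math.floor(abs(math.log(lam2)) / (2.0 * math.pi) + 1.0e-12))
            uniq = ("unique_certified"
                    if kmax == 0 or certs["cuthbert_half"] or certs["cuthbert_det"]
                    else "search_incomplete")
            return EmbeddingResult("embeddable", tag, gens, uniq, branches, conds, [])
        if branches and not branches[0].is_generator and len(branches) == 1:
            # principal fails and no winding branch exists
            kmax = int(math.floor(abs(math.log(lam2)) / (2.0 * math.pi) + 1.0e-12))
            if kmax == 0:
                return EmbeddingResult(
                    "not_embeddable", tag, [], "not_applicable", branches, conds,
                    ["unique candidate is not a generator and winding range is empty"])
        return EmbeddingResult("undecided_search", tag, [], "search_incomplete",
                               branches, conds,
                               ["no generator found by search (not a certificate)"])
    # lam2 < 0
    if lam2 < -E_MINUS_PI - 1.0e-12:
        return _not_embeddable(
            tag, conds,
            "|2k+1| pi <= |log|lambda_2|| has no integer solution: "
            "lambda_2 < -exp(-pi) certifies non-embeddability")
    if T is None:
        return EmbeddingResult("undecided_search", tag, [], "search_incomplete",
                               [], conds, ["no real eigenbasis available"])
    branches, gens, empty = _rotation_branches(M, T, [0.0, math.log(lam1)], lam2, cfg)
    if empty:
        return _not_embeddable(tag, conds, "empty winding range excludes all branches")
    gens = dedupe_generators(gens)
    if gens:
        return EmbeddingResult("embeddable", tag, gens, "search_incomplete",
                               branches, conds, [])
    return EmbeddingResult("undecided_search", tag, [], "search_incomplete",
                           branches, conds,
                           ["no generator found by search (not a certificate)"])


def _complex_enumeration(M: MarkovMatrix, tag: str, theta: complex, conds,
                         cfg: SearchConfig, quadratic: bool,
                         lam_real: float | None = None) -> EmbeddingResult:
    """Finite winding enumeration for a complex conjugate pair (d = 4).

    The generator eigenvalue attached to theta is ``log|theta| + i
    (Arg theta + 2 pi k)``; the 4 x 4 cone ``|Im z| <= -Re z`` truncates k.
    """
    r = abs(theta)
    if r >= 1.0 - 1.0e-12 or r <= 1.0e-12:
        return _not_embeddable(tag, conds, "|theta| outside (0,1)")
    if lam_real is not None and not (1.0e-12 < lam_real < 1.0 - 1.0e-12):
        return _not_embeddable(tag, conds, "real eigenvalue outside (0,1)")
    im_bound = abs(math.log(r)) + 1.0e-9
    arg = math.atan2(theta.imag, theta.real)
    A = M.A
    A2 = A @ A
    A3 = A2 @ A
    branches: list[LogBranch] = []
    gens: list[np.ndarray] = []
    kmax = int(math.ceil((im_bound + math.pi) / (2.0 * math.pi)))
    for k in range(-kmax, kmax + 1):
        if abs(arg + 2.0 * math.pi * k) > im_bound:
            continue
        if quadratic:
            alpha, beta = coeffs_complex_pair(theta - 1.0, k)
            R = alpha * A + beta * A2
            coeffs = (alpha, beta)
        else:
            alpha, beta, gamma = coeffs_complex_4(lam_real - 1.0, theta - 1.0, k)
            R = alpha * A + beta * A2 + gamma * A3
            coeffs = (alpha, beta, gamma)
        ok, _ = is_generator(R, cfg.accept_tol)
        res = exp_residual(R, M.entries)
        branches.append(LogBranch(k, coeffs, R, ok, res))
        if ok and res <= cfg.residual_tol:
            gens.append(R)
    gens = dedupe_generators(gens)
    if not gens:
        return EmbeddingResult("not_embeddable", tag, [], "not_applicable",
                               branches, conds,
                               ["no winding branch yields a generator"])
    uniq = "unique_certified" if len(gens) == 1 else "complete_finite_enumeration"
    return EmbeddingResult("embeddable", tag, gens, uniq, branches, conds, [])


def cyclic_case_d4(M: MarkovMatrix, summary: SpectralSummary,
                   cfg: SearchConfig = DEFAULT_SEARCH, conds=None) -> EmbeddingResult:
    """Cyclic 4 x 4 matrices: candidates ``alpha A + beta A^2 + gamma A^3``."""
    if conds is None:
        conds = necessary_conditions(M.entries)
    tag = summary.jnf_tag
    nonunit = summary.non_unit()

    if tag == "diag(1,l,theta,conj_theta)":
        lam = next(c.value.real for c in nonunit if c.is_real)
        theta = next(c.value for c in nonunit if c.value.imag > 0)
        return _complex_enumeration(M, tag, theta, conds, cfg,
                                    quadratic=False, lam_real=lam)

    if tag == "diag(1,l1,l2,l3)":
        vals = sorted((c.value.real for c in nonunit), reverse=True)
        if any(v <= 1.0e-12 for v in vals):
            return _not_embeddable(tag, conds,
                                   "non-positive eigenvalue excludes a real log "
                                   "(Culver / determinant)")
        coeffs = coeffs_simple_real_4(vals[0] - 1.0, vals[1] - 1.0, vals[2] - 1.0)
        return _unique_candidate_result(M, tag, coeffs, conds, cfg)

    if tag == "1+J3(l)":
        lam = nonunit[0].value.real
        if lam <= 1.0e-12:
            return _not_embeddable(tag, conds, "lambda not in (0,1)")
        coeffs = coeffs_jordan3(lam - 1.0)
        return _unique_candidate_result(M, tag, coeffs, conds, cfg)

    if tag == "diag(1,l1)+J2(l2)":
        rep = next(c for c in nonunit if c.alg == 2)
        simple = next(c for c in nonunit if c.alg == 1)
        lam1, lam2 = simple.value.real, rep.value.real
        if lam1 <= 1.0e-12 or lam2 <= 1.0e-12:
            return _not_embeddable(tag, conds, "eigenvalue not in (0,1)")
        coeffs = coeffs_mixed_jordan2(lam1 - 1.0, lam2 - 1.0)
        return _unique_candidate_result(M, tag, coeffs, conds, cfg)

    return EmbeddingResult("undecided_search", tag, [], "search_incomplete", [],
                           conds, [f"unhandled spectral pattern {tag}"])


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

_DEG2_TAGS = {"diag(1,1,1,l)", "diag(1,l,l,l)", "diag(1,1,l,l)"}
_DEG3_TAGS = {"diag(1,1,l1,l2)", "diag(1,1)+J2(l)", "diag(1,l)+J2(l)",
              "diag(1,l1,l2,l2)", "diag(1,1,l,conj_l)"}
_DEG4_TAGS = {"diag(1,l1,l2,l3)", "diag(1,l,theta,conj_theta)", "1+J3(l)",
              "diag(1,l1)+J2(l2)"}


def _dispatch(M: MarkovMatrix, summary: SpectralSummary,
              cfg: SearchConfig, conds) -> EmbeddingResult:
    tag = summary.jnf_tag
    if tag == "identity":
        Q = np.zeros((4, 4))
        res = exp_residual(Q, M.entries)
        if res <= cfg.residual_tol:
            return EmbeddingResult("embeddable", tag, [Q], "unique_certified",
                                   [LogBranch(0, (), Q, True, res)], conds, [])
        return EmbeddingResult("undecided_search", tag, [], "search_incomplete",
                               [], conds, ["spectrum is degenerate at 1 but M != I"])
    if tag in _DEG2_TAGS:
        return degree2_case_d4(M, summary, cfg, conds)
    if tag in _DEG3_TAGS:
        return degree3_case_d4(M, summary, cfg, conds)
    if tag in _DEG4_TAGS:
        return cyclic_case_d4(M, summary, cfg, conds)
    return EmbeddingResult("undecided_search", tag, [], "search_incomplete", [],
                           conds, [f"unhandled spectral pattern {tag}"])


def embed_4x4(M, tol: float = 1.0e-9, cfg: SearchConfig = DEFAULT_SEARCH) -> EmbeddingResult:
    """Decide embeddability of a 4 x 4 Markov matrix."""
    if not isinstance(M, MarkovMatrix):
        M = validate_markov(M, tol)
    if M.d != 4:
        raise ValueError(f"embed_4x4 requires d = 4, got d = {M.d}")
    conds = necessary_conditions(M.entries)
    summaries = spectral_summaries(M.entries)
    results = [_dispatch(M, s, cfg, conds) for s in summaries]
    return merge_hypotheses(results)
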
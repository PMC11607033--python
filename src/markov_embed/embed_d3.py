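"""Complete decision procedure for the 3 x 3 embedding problem.

The dispatch key is the degree of the minimal polynomial of ``M``:

* degree 1: ``M`` is the identity, ``Q = 0`` is the only generator;
* degree 2: ``M`` is diagonalisable with spectrum {1, lambda}.  The Jordan
  pattern diag(1, 1, lambda) has a unique logarithm with zero row sums and
  is embeddable iff lambda in (0, 1).  The pattern diag(1, lambda, lambda)
  with lambda > 0 is embeddable via the same rank-one formula, with
  possible extra winding branches; with lambda < 0 the matrix is
  necessarily of equal-input type: closed-form generator families on the
  commutant (stationary and cyclic-support) decide embeddability
  constructively, and the generator eigenvalue cone certifies exclusion
  beyond ``c = 1 + exp(-pi sqrt 3)``;
* degree 3: ``M`` is cyclic and every candidate is ``alpha A + beta A^2``
  with coefficients from the (possibly confluent) 2 x 2 Vandermonde system;
  real spectra give a unique candidate, complex conjugate pairs give one
  candidate per winding index k, of which only finitely many can be
  generators.

Equal-input matrices ``M_c = (1 - c) I + C`` (all rows of ``C`` equal to
``(c_1, c_2, c_3)``, ``c = sum c_i``) are the only 3 x 3 Markov matrices
with a repeated negative eigenvalue, which is why they get a dedicated
constructive solver here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .log_coefficients import (
    coeffs_complex_pair,
    coeffs_confluent_pair,
    coeffs_two_real,
)
from .matrix_core import (
    DEFAULT_SEARCH,
    EmbeddingResult,
    LogBranch,
    MarkovMatrix,
    SearchConfig,
    SpectralSummary,
    dedupe_generators,
    exp_residual,
    is_generator,
    merge_hypotheses,
    necessary_conditions,
    spectral_summaries,
    validate_markov,
)

__all__ = [
    "embed_3x3",
    "degree2_case_d3",
    "cyclic_real_d3",
    "complex_pair_d3",
    "equal_input_negative",
    "delta_min",
    "delta_min_cyclic",
    "cyclic_generators",
    "extremal_generators",
    "commutant_basis",
    "CommutantBasis",
    "equal_input_params",
]

_EQUAL_INPUT_TOL = 1.0e-9


# ---------------------------------------------------------------------------
# equal-input helpers
# ---------------------------------------------------------------------------


def equal_input_params(M, tol: float = _EQUAL_INPUT_TOL):
    """Extract the c-vector if ``M`` is an equal-input matrix, else ``None``.

    Equal-input means ``m_ij = c_j`` for all ``i != j``.
    """
    m = np.asarray(M, dtype=float) if not isinstance(M, MarkovMatrix) else M.entries
    d = m.shape[0]
    c = np.empty(d)
    for j in range(d):
        col = [m[i, j] for i in range(d) if i != j]
        c[j] = np.mean(col)
        if max(abs(v - c[j]) for v in col) > tol:
            return None
    # the diagonal must be consistent: m_jj = 1 - c + c_j
    csum = float(c.sum())
    for j in range(d):
        if abs(m[j, j] - (1.0 - csum + c[j])) > 10.0 * tol:
            return None
    return c


def delta_min(c1: float, c2: float, c3: float) -> float:
    """Stationary-family decay exponent ``pi * kappa * sqrt(c) / sqrt(c1 c2 c3)``.

    ``kappa = max(c_i)``, ``c = c1 + c2 + c3``.  This is the |Re| of the
    complex eigenvalue pair of the two extremal generators obtained from
    the stationary point of the constrained eigenvalue problem on the
    commutant (see :func:`extremal_generators`); every equal-input matrix
    on the ray of ``(c1, c2, c3)`` with summatory parameter
    ``1 < c <= 1 + exp(-delta_min)`` is embeddable.  For the uniform
    direction this exponent is exactly minimal (value ``pi sqrt 3``); for
    skewed directions the cyclic-support family of
    :func:`delta_min_cyclic` can reach a strictly smaller exponent, i.e. a
    strictly larger embeddable range.  Positively homogeneous of degree 0.
    """
    if min(c1, c2, c3) <= 0:
        raise ValueError("delta_min requires strictly positive c_i")
    c = c1 + c2 + c3
    kappa = max(c1, c2, c3)
    return math.pi * kappa * math.sqrt(c) / math.sqrt(c1 * c2 * c3)


def delta_min_cyclic(c1: float, c2: float, c3: float) -> float:
    """Decay exponent of the cyclic-support commutant generators.

    The generators ``Q = t [[-1/c1, 1/c1, 0], [0, -1/c2, 1/c2],
    [1/c3, 0, -1/c3]]`` (and the reverse orientation) commute with the
    C-matrix of ``(c1, c2, c3)`` and have eigenvalues ``-Delta +/- i s``
    with ``Delta = t sigma / 2``, ``s^2 = t^2 (c/p - sigma^2/4)`` where
    ``sigma = sum 1/c_i`` and ``p = c1 c2 c3``.  Fixing ``s = pi`` gives
    this exponent; returns ``inf`` when ``c/p <= sigma^2/4`` (no complex
    pair on this family).  Coincides with :func:`delta_min` for uniform
    ``c_i`` and is smaller for sufficiently skewed directions.
    """
    if min(c1, c2, c3) <= 0:
        raise ValueError("delta_min_cyclic requires strictly positive c_i")
    c = c1 + c2 + c3
    p = c1 * c2 * c3
    sigma = 1.0 / c1 + 1.0 / c2 + 1.0 / c3
    disc = c / p - sigma * sigma / 4.0
    if disc <= 0.0:
        return math.inf
    t = math.pi / math.sqrt(disc)
    return 0.5 * t * sigma


def cyclic_generators(c1: float, c2: float, c3: float) -> tuple[np.ndarray, np.ndarray]:
    """The two cyclic-support generators at the ``s = pi`` level.

    Requires ``delta_min_cyclic`` to be finite; both returned matrices are
    generators commuting with ``C(c1, c2, c3)`` whose exponential is the
    equal-input matrix on the same ray with ``c = 1 + exp(-delta_min_cyclic)``.
    """
    c = c1 + c2 + c3
    p = c1 * c2 * c3
    sigma = 1.0 / c1 + 1.0 / c2 + 1.0 / c3
    disc = c / p - sigma * sigma / 4.0
    if disc <= 0.0:
        raise ValueError("no complex eigenvalue pair on the cyclic family")
    t = math.pi / math.sqrt(disc)
    fwd = t * np.array([[-1.0 / c1, 1.0 / c1, 0.0],
                        [0.0, -1.0 / c2, 1.0 / c2],
                        [1.0 / c3, 0.0, -1.0 / c3]])
    rev = t * np.array([[-1.0 / c1, 0.0, 1.0 / c1],
                        [1.0 / c2, -1.0 / c2, 0.0],
                        [0.0, 1.0 / c3, -1.0 / c3]])
    return fwd, rev


def extremal_generators(c1: float, c2: float, c3: float) -> tuple[np.ndarray, np.ndarray]:
    """The two generators Q+/- embedding the extremal equal-input matrix.

    Both satisfy ``exp(Q+/-) = M_c`` for the equal-input matrix on the ray
    of ``(c1, c2, c3)`` with summatory parameter ``1 + exp(-Delta_min)``.
    """
    if min(c1, c2, c3) <= 0:
        raise ValueError("extremal_generators requires strictly positive c_i")
    kappa = max(c1, c2, c3)
    c = c1 + c2 + c3
    pref = math.pi / math.sqrt(c * c1 * c2 * c3)

    def q(sign: float) -> np.ndarray:
        s = sign
        return pref * np.array([
            [-kappa * (c2 + c3), c2 * (kappa + s * c3), c3 * (kappa - s * c2)],
            [c1 * (kappa - s * c3), -kappa * (c1 + c3), c3 * (kappa + s * c1)],
            [c1 * (kappa + s * c2), c2 * (kappa - s * c1), -kappa * (c1 + c2)],
        ])

    return q(+1.0), q(-1.0)


@dataclass
class CommutantBasis:
    """Basis of the zero-row-sum commutant of an equal-input matrix.

    ``Q1, Q2, Q3`` are generators, ``R0`` has zero row sums but mixed
    off-diagonal signs; every zero-row-sum matrix commuting with the
    C-matrix of ``(c1, c2, c3)`` is a combination
    ``x Q1 + y Q2 + z Q3 + w R0``.
    """

    c: tuple[float, float, float]
    Q1: np.ndarray
    Q2: np.ndarray
    Q3: np.ndarray
    R0: np.ndarray
    alpha: float
    beta: float
    gamma: float

    def combine(self, x: float, y: float, z: float, w: float) -> np.ndarray:
        return x * self.Q1 + y * self.Q2 + z * self.Q3 + w * self.R0

    def coords(self, R: np.ndarray) -> tuple[float, float, float, float]:
        """Decompose a commutant element in the basis (least squares)."""
        B = np.stack([self.Q1.ravel(), self.Q2.ravel(), self.Q3.ravel(),
                      self.R0.ravel()], axis=1)
        sol, *_ = np.linalg.lstsq(B, R.ravel(), rcond=None)
        return tuple(float(v) for v in sol)

    def delta(self, x: float, y: float, z: float) -> float:
        c1, c2, c3 = self.c
        return 0.5 * ((c2 + c3) * x + (c1 + c3) * y + (c1 + c2) * z)

    def s_squared_coeffs(self, x: float, y: float, z: float) -> tuple[float, float, float]:
        """(chi, psi, phi) with ``s^2 = chi + psi w + phi w^2`` for the
        eigenvalue pair ``-Delta +/- s`` of ``x Q1 + y Q2 + z Q3 + w R0``."""
        c1, c2, c3 = self.c
        c = c1 + c2 + c3
        chi = 0.25 * ((c1 + c3) * (x - y) - (c1 + c2) * (x - z)) ** 2 \
            + c2 * c3 * (x - y) * (x - z)
        psi = c * (c1 ** 2 * (z - y) + c2 ** 2 * (x - z) + c3 ** 2 * (y - x))
        phi = -2.0 * c * (c1 + c2) * (c1 + c3) * (c2 + c3)
        return chi, psi, phi

    def generator_inequalities(self, x: float, y: float, z: float, w: float) -> list[float]:
        """The six off-diagonal values whose non-negativity makes the
        combination a generator."""
        c1, c2, c3 = self.c
        a, b, g = self.alpha, self.beta, self.gamma
        return [
            c3 * x + b * w, c2 * x - b * w,       # positions (2,3), (3,2)
            c3 * y - g * w, c1 * y + g * w,       # positions (1,3), (3,1)
            c2 * z + a * w, c1 * z - a * w,       # positions (1,2), (2,1)
        ]


def commutant_basis(c1: float, c2: float, c3: float) -> CommutantBasis:
    """Generators/basis of the commutant for a positive c-vector."""
    if min(c1, c2, c3) <= 0:
        raise ValueError("commutant_basis requires strictly positive c_i")
    Q1 = np.array([[0.0, 0, 0], [0, -c3, c3], [0, c2, -c2]])
    Q2 = np.array([[-c3, 0, c3], [0, 0.0, 0], [c1, 0, -c1]])
    Q3 = np.array([[-c2, c2, 0], [c1, -c1, 0], [0, 0, 0.0]])
    a = (c1 + c3) * (c2 + c3)
    b = (c1 + c2) * (c1 + c3)
    g = (c1 + c2) * (c2 + c3)
    R0 = np.array([[g - a, a, -g], [-a, a - b, b], [g, -b, b - g]])
    return CommutantBasis((c1, c2, c3), Q1, Q2, Q3, R0, a, b, g)


def _equal_input_matrix3(c: np.ndarray) -> np.ndarray:
    csum = float(c.sum())
    return (1.0 - csum) * np.eye(3) + np.tile(c, (3, 1))


def _feasibility_search(cb: CommutantBasis, delta0: float, winding: int,
                        n_starts: int = 8) -> np.ndarray | None:
    """Search the commutant for a generator with eigenvalues
    ``-delta0 +/- (2k+1) pi i`` (SLSQP feasibility; not a certificate)."""
    from scipy.optimize import minimize

    s2_target = -((2 * winding + 1) ** 2) * math.pi ** 2

    def eqs(p):
        x, y, z, w = p
        chi, psi, phi = cb.s_squared_coeffs(x, y, z)
        return [cb.delta(x, y, z) - delta0,
                chi + psi * w + phi * w * w - s2_target]

    def ineq(p):
        return np.array(cb.generator_inequalities(*p))

    rng = np.random.default_rng(0)
    scale = delta0 / max(sum(cb.c), 1.0e-12)
    for _ in range(n_starts):
        x0 = np.concatenate([rng.uniform(0.2, 3.0, 3) * scale,
                             rng.uniform(-0.5, 0.5, 1) * scale])
        res = minimize(lambda p: -min(cb.generator_inequalities(*p)), x0,
                       method="SLSQP",
                       constraints=[{"type": "eq", "fun": eqs},
                                    {"type": "ineq", "fun": ineq}],
                       options={"maxiter": 300, "ftol": 1e-14})
        if res.success and max(abs(v) for v in eqs(res.x)) < 1e-9 \
                and ineq(res.x).min() > -1e-10:
            return cb.combine(*res.x)
    return None


def equal_input_negative(c, M=None, cfg: SearchConfig = DEFAULT_SEARCH,
                         conds=None) -> EmbeddingResult:
    """Embeddability of an equal-input matrix with summatory parameter > 1.

    These are exactly the 3 x 3 Markov matrices with a repeated negative
    eigenvalue ``lambda = 1 - c``.  Any embedding generator lies in the
    four-dimensional commutant and has eigenvalues ``-Delta +/- (2k+1) pi i``
    with ``Delta = -log(c - 1)``.  Constructive families: the two
    stationary extremal generators (decay exponent :func:`delta_min`, exact
    for the uniform direction) and the two cyclic-support generators
    (:func:`delta_min_cyclic`, better for skewed directions), each deformed
    along the central equal-input generator ``Q_C`` to reach interior
    parameters, at every admissible winding level.  A direct feasibility
    search over the commutant backs them up.

    Certified non-embeddable when ``c > 1 + exp(-pi sqrt 3)``: a 3 x 3
    generator eigenvalue obeys ``|Im z| <= -Re z / sqrt(3)``, forcing
    ``Delta >= pi sqrt 3``.  Between the constructive region and that cone
    bound a failed search is reported as undecided, not as a certificate.
    """
    c = np.asarray(c, dtype=float)
    csum = float(c.sum())
    if csum <= 1.0:
        raise ValueError("equal_input_negative requires summatory parameter > 1")
    if M is None:
        M = _equal_input_matrix3(c)
    m = np.asarray(M, dtype=float) if not isinstance(M, MarkovMatrix) else M.entries
    if conds is None:
        conds = necessary_conditions(m)
    label = "diag(1,l,l) lambda<0 (equal-input)"
    dmin = delta_min(*c)
    dcyc = delta_min_cyclic(*c)
    msgs = [f"Delta_stationary = {dmin:.12g}, Delta_cyclic = {dcyc:.12g}, "
            f"c = {csum:.12g}"]
    cap = 1.0 + math.exp(-math.pi * math.sqrt(3.0))
    if csum > cap + 1.0e-12:
        msgs.append("generator eigenvalue cone |Im z| <= -Re z/sqrt(3) forces "
                    "Delta >= pi sqrt 3; c > 1 + exp(-pi sqrt 3) is not embeddable")
        return EmbeddingResult("not_embeddable", label, [], "not_applicable",
                               [], conds, msgs)

    families: list[tuple[float, list[np.ndarray]]] = [
        (dmin, list(extremal_generators(*c)))]
    if math.isfinite(dcyc):
        families.append((dcyc, list(cyclic_generators(*c))))

    gens: list[np.ndarray] = []
    branches: list[LogBranch] = []
    uniform = max(c) - min(c) < 1.0e-12 * max(c)

    def add_candidate(cand: np.ndarray, k: int) -> None:
        res = exp_residual(cand, m)
        ok, _ = is_generator(cand, cfg.accept_tol)
        branches.append(LogBranch(k, (), cand, ok, res))
        if ok and res <= cfg.residual_tol:
            gens.append(cand)

    for dbase, bases in families:
        for k in range(cfg.k_cap + 1):
            factor = 2.0 * k + 1.0
            ck = 1.0 + math.exp(-factor * dbase)
            if ck < csum - 1.0e-12:
                break
            for base in bases:
                if abs(csum - ck) <= 1.0e-12:
                    cand = factor * base
                else:
                    # deform along the central equal-input generator Q_C
                    chat = ck * c / csum
                    qc = np.tile(chat, (3, 1)) - ck * np.eye(3)
                    tau = math.log((ck - 1.0) / (csum - 1.0)) / ck
                    cand = factor * base + tau * qc
                add_candidate(cand, k)

    if not gens:
        # direct feasibility search at the exact decay exponent of this M
        delta0 = -math.log(csum - 1.0)
        cb = commutant_basis(*c)
        kmax = max(0, int(math.floor((delta0 / math.sqrt(3.0) / math.pi - 1.0) / 2.0)))
        for k in range(kmax + 1):
            found = _feasibility_search(cb, delta0, k)
            if found is not None:
                add_candidate(found, k)

    gens = dedupe_generators(gens)
    if not gens:
        msgs.append("no generator found by constructive families or search; "
                    "exclusion is not certified for skewed directions")
        return EmbeddingResult("undecided_search", label, [], "search_incomplete",
                               branches, conds, msgs)
    uniq = "complete_finite_enumeration" if uniform else "search_incomplete"
    return EmbeddingResult("embeddable", label, gens, uniq, branches, conds, msgs)


# ---------------------------------------------------------------------------
# case solvers
# ---------------------------------------------------------------------------


def _rank_one_generator(M: MarkovMatrix, lam: float) -> np.ndarray:
    """``Q = log(lambda)/(lambda - 1) A``, valid whenever ``A^2 = (lambda-1) A``."""
    return (math.log(lam) / (lam - 1.0)) * M.A


def degree2_case_d3(M: MarkovMatrix, summary: SpectralSummary,
                    cfg: SearchConfig = DEFAULT_SEARCH, conds=None) -> EmbeddingResult:
    """Diagonalisable spectrum {1, lambda}: the minimal-polynomial degree-2 rows."""
    if conds is None:
        conds = necessary_conditions(M.entries)
    tag = summary.jnf_tag
    lam_c = summary.non_unit()[0]
    lam = lam_c.value.real
    if tag == "diag(1,1,l)":
        if lam <= 1.0e-12:
            msg = ("lambda <= 0: determinant condition (lambda = det M) fails"
                   if lam > -1.0e-12 else
                   "single negative eigenvalue: no real logarithm (Culver)")
            return EmbeddingResult("not_embeddable", tag, [], "not_applicable",
                                   [], conds, [msg])
        Q = _rank_one_generator(M, lam)
        res = exp_residual(Q, M.entries)
        branch = LogBranch(0, (math.log(lam) / (lam - 1.0),), Q, True, res)
        if res > cfg.residual_tol:
            return EmbeddingResult("undecided_search", tag, [], "search_incomplete",
                                   [branch], conds, ["residual contract failed"])
        return EmbeddingResult("embeddable", tag, [Q], "unique_certified",
                               [branch], conds, [])
    # tag == diag(1,l,l)
    if lam > 1.0e-12:
        Q = _rank_one_generator(M, lam)
        res = exp_residual(Q, M.entries)
        branches = [LogBranch(0, (math.log(lam) / (lam - 1.0),), Q, True, res)]
        gens = [Q] if res <= cfg.residual_tol else []
        kmax = int(math.floor(abs(math.log(lam)) / (2.0 * math.pi * math.sqrt(3.0)) + 1.0e-12))
        msgs = []
        one = summary.cluster_of_one()
        rep = lam_c
        if kmax > 0 and one.basis is not None and rep.basis is not None:
            T = np.hstack([one.basis, rep.basis])
            for k in range(1, min(kmax, cfg.k_cap) + 1):
                for kk in (k, -k):
                    from .matrix_core import ixyz_feasibility
                    R = ixyz_feasibility(T, [0.0], 2.0 * math.pi * kk,
                                         math.log(lam), cfg)
                    if R is not None:
                        res_k = exp_residual(R, M.entries)
                        ok, _ = is_generator(R, cfg.accept_tol)
                        branches.append(LogBranch(kk, (), R, ok, res_k))
                        if ok and res_k <= cfg.residual_tol:
                            gens.append(R)
            if kmax > cfg.k_cap:
                msgs.append(f"winding range {kmax} capped at {cfg.k_cap}")
        gens = dedupe_generators(gens)
        if not gens:
            return EmbeddingResult("undecided_search", tag, [], "search_incomplete",
                                   branches, conds, msgs + ["residual contract failed"])
        from .matrix_core import uniqueness_certificates
        certs = uniqueness_certificates(M.entries)
        if kmax == 0 or certs["cuthbert_half"] or certs["cuthbert_det"]:
            uniq = "unique_certified"
        else:
            uniq = "search_incomplete"
        return EmbeddingResult("embeddable", tag, gens, uniq, branches, conds, msgs)
    if lam > -1.0e-12:
        return EmbeddingResult("not_embeddable", tag, [], "not_applicable", [],
                               conds, ["lambda = 0: matrix is singular"])
    # repeated negative eigenvalue: only equal-input matrices live here
    c = equal_input_params(M.entries)
    if c is None:
        return EmbeddingResult(
            "not_embeddable", tag, [], "not_applicable", [], conds,
            ["repeated negative eigenvalue but not equal-input at tolerance; "
             "no consistent Jordan structure admits a generator"])
    return equal_input_negative(c, M.entries, cfg, conds)


def cyclic_real_d3(M: MarkovMatrix, summary: SpectralSummary,
                   cfg: SearchConfig = DEFAULT_SEARCH, conds=None) -> EmbeddingResult:
    """Cyclic with real spectrum: unique candidate ``alpha A + beta A^2``."""
    if conds is None:
        conds = necessary_conditions(M.entries)
    tag = summary.jnf_tag
    nonunit = summary.non_unit()
    vals = [c.value.real for c in nonunit]
    if any(v <= 1.0e-12 for v in vals):
        return EmbeddingResult("not_embeddable", tag, [], "not_applicable", [],
                               conds, ["non-positive eigenvalue excludes a real "
                                       "logarithm (Culver / determinant)"])
    if tag == "1+J2(l)":
        mu = vals[0] - 1.0
        alpha, beta = coeffs_confluent_pair(mu)
    else:
        alpha, beta = coeffs_two_real(vals[0] - 1.0, vals[1] - 1.0)
    A = M.A
    Q = alpha * A + beta * (A @ A)
    ok, viol = is_generator(Q, cfg.accept_tol)
    res = exp_residual(Q, M.entries)
    branch = LogBranch(0, (alpha, beta), Q, ok, res)
    if ok and res <= cfg.residual_tol:
        return EmbeddingResult("embeddable", tag, [Q], "unique_certified",
                               [branch], conds, [])
    if not ok:
        msg = f"unique candidate has negative off-diagonal entries at {viol}"
        return EmbeddingResult("not_embeddable", tag, [], "not_applicable",
                               [branch], conds, [msg])
    return EmbeddingResult("undecided_search", tag, [], "search_incomplete",
                           [branch], conds, ["residual contract failed"])


def complex_pair_d3(M: MarkovMatrix, summary: SpectralSummary,
                    cfg: SearchConfig = DEFAULT_SEARCH, conds=None) -> EmbeddingResult:
    """Spectrum {1, lambda, conj(lambda)}: finite winding enumeration.

    Every real logarithm with zero row sums is ``alpha_k A + beta_k A^2``
    for some integer k; a 3 x 3 generator eigenvalue z obeys
    ``|Im z| <= |Re z| / sqrt(3)`` (the circulant cone), which truncates k.
    """
    if conds is None:
        conds = necessary_conditions(M.entries)
    tag = summary.jnf_tag
    lam = next(c.value for c in summary.non_unit() if c.value.imag > 0)
    r = abs(lam)
    if r >= 1.0 - 1.0e-12:
        return EmbeddingResult("not_embeddable", tag, [], "not_applicable", [],
                               conds, ["|lambda| >= 1: spectrum outside the open disk"])
    det = float(np.linalg.det(M.entries))
    im_bound = -math.log(det) / (2.0 * math.sqrt(3.0)) + 1.0e-9
    arg = math.atan2(lam.imag, lam.real)
    A = M.A
    A2 = A @ A
    branches: list[LogBranch] = []
    gens: list[np.ndarray] = []
    kmax = int(math.ceil((im_bound + math.pi) / (2.0 * math.pi)))
    for k in range(-kmax, kmax + 1):
        if abs(arg + 2.0 * math.pi * k) > im_bound:
            continue
        alpha, beta = coeffs_complex_pair(lam - 1.0, k)
        R = alpha * A + beta * A2
        ok, _ = is_generator(R, cfg.accept_tol)
        res = exp_residual(R, M.entries)
        branches.append(LogBranch(k, (alpha, beta), R, ok, res))
        if ok and res <= cfg.residual_tol:
            gens.append(R)
    gens = dedupe_generators(gens)
    if not gens:
        return EmbeddingResult("not_embeddable", tag, [], "not_applicable",
                               branches, conds,
                               ["no winding branch yields a generator"])
    uniq = "unique_certified" if len(gens) == 1 else "complete_finite_enumeration"
    return EmbeddingResult("embeddable", tag, gens, uniq, branches, conds, [])


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------


def _dispatch(M: MarkovMatrix, summary: SpectralSummary,
              cfg: SearchConfig, conds) -> EmbeddingResult:
    tag = summary.jnf_tag
    if tag == "identity":
        Q = np.zeros((3, 3))
        res = exp_residual(Q, M.entries)
        if res <= cfg.residual_tol:
            return EmbeddingResult("embeddable", tag, [Q], "unique_certified",
                                   [LogBranch(0, (), Q, True, res)], conds, [])
        return EmbeddingResult("undecided_search", tag, [], "search_incomplete",
                               [], conds, ["spectrum is degenerate at 1 but M != I"])
    if tag in ("diag(1,1,l)", "diag(1,l,l)"):
        return degree2_case_d3(M, summary, cfg, conds)
    if tag in ("diag(1,l1,l2)", "1+J2(l)"):
        return cyclic_real_d3(M, summary, cfg, conds)
    if tag == "diag(1,l,conj_l)":
        return complex_pair_d3(M, summary, cfg, conds)
    return EmbeddingResult("undecided_search", tag, [], "search_incomplete", [],
                           conds, [f"unhandled spectral pattern {tag}"])


def embed_3x3(M, tol: float = 1.0e-9, cfg: SearchConfig = DEFAULT_SEARCH) -> EmbeddingResult:
    """Decide embeddability of a 3 x 3 Markov matrix.

    Returns an :class:`EmbeddingResult` whose ``generators`` all satisfy
    the exponential-residual contract ``||exp(Q) - M||_inf <= 1e-8``.
    """
    if not isinstance(M, MarkovMatrix):
        M = validate_markov(M, tol)
    if M.d != 3:
        raise ValueError(f"embed_3x3 requires d = 3, got d = {M.d}")
    conds = necessary_conditions(M.entries)
    summaries = spectral_summaries(M.entries)
    results = [_dispatch(M, s, cfg, conds) for s in summaries]
    return merge_hypotheses(results)
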
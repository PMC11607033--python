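"""Core types and numerical machinery for the Markov embedding problem.

A Markov (stochastic) matrix ``M`` is non-negative with unit row sums; a
Markov generator (rate matrix) ``Q`` has non-negative off-diagonal entries
and zero row sums.  The classic embedding problem asks whether ``M = e^Q``
for some generator ``Q``.  Everything in this package reduces the question,
for dimension d <= 4, to (i) a spectral/Jordan classification of ``M`` and
(ii) the construction of candidate real logarithms with zero row sums,
which are then tested for the generator property.

This module provides:

* validated matrix types (:class:`MarkovMatrix`, :class:`RateMatrix`,
  :class:`ZeroRowSumMatrix`);
* the spectral summary driving the case dispatch (eigenvalue clusters,
  algebraic/geometric multiplicities, minimal-polynomial degree, a Jordan
  normal form tag);
* matrix exponential / principal logarithm oracles;
* classical necessary conditions (positive diagonal, determinant in (0,1],
  spectrum inside the unit disk, transitivity of the positivity pattern,
  Culver's real-logarithm criterion, Goodman's diagonal-product bound);
* uniqueness certificates (Cuthbert's half-diagonal and determinant tests);
* the two-parameter rotation-block search used whenever a repeated real
  eigenvalue leaves a ``2 pi k``-winding freedom in the logarithm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.linalg import expm, logm
from scipy.optimize import minimize

__all__ = [
    "E_MINUS_PI",
    "E_MINUS_PI_SQRT3",
    "E_MINUS_2PI_SQRT3",
    "E_MINUS_4PI_SQRT3",
    "ValidationError",
    "MarkovMatrix",
    "RateMatrix",
    "ZeroRowSumMatrix",
    "EigenCluster",
    "SpectralSummary",
    "ConditionReport",
    "IxyzPoint",
    "LogBranch",
    "EmbeddingResult",
    "SearchConfig",
    "validate_markov",
    "validate_rate",
    "validate_zero_row_sum",
    "is_generator",
    "matrix_exp",
    "exp_residual",
    "principal_log",
    "log_series",
    "spectral_summary",
    "spectral_summaries",
    "necessary_conditions",
    "uniqueness_certificates",
    "ixyz",
    "ixyz_feasibility",
]

# Analytic thresholds of the d <= 4 classification.  e^{-pi} bounds the
# modulus of a repeated negative eigenvalue that can still be embedded in
# dimension four; e^{-pi*sqrt(3)} plays the same role for d = 3, and the
# 2x / 4x variants bound where extra winding branches can appear.
E_MINUS_PI = float(np.exp(-np.pi))
E_MINUS_PI_SQRT3 = float(np.exp(-np.pi * np.sqrt(3.0)))
E_MINUS_2PI_SQRT3 = float(np.exp(-2.0 * np.pi * np.sqrt(3.0)))
E_MINUS_4PI_SQRT3 = float(np.exp(-4.0 * np.pi * np.sqrt(3.0)))

#: eigenvalue pairs closer than this (relative) may be a numerically split
#: Jordan block; the coarse classification hypothesis merges them.
DEFECT_TOL = 1.0e-5


class ValidationError(ValueError):
    """Raised when a matrix fails its structural validation."""


# ---------------------------------------------------------------------------
# validated matrix types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkovMatrix:
    """A validated row-stochastic d x d matrix, d in {2, 3, 4}."""

    entries: np.ndarray
    d: int
    tol: float = 1.0e-9

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", np.asarray(self.entries, dtype=float))

    @property
    def A(self) -> np.ndarray:
        """The derived zero-row-sum matrix ``A = M - I``."""
        return self.entries - np.eye(self.d)


@dataclass(frozen=True)
class RateMatrix:
    """A validated Markov generator: off-diagonals >= 0, zero row sums."""

    entries: np.ndarray
    d: int
    tol: float = 1.0e-9

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", np.asarray(self.entries, dtype=float))


@dataclass(frozen=True)
class ZeroRowSumMatrix:
    """A real matrix with zero row sums (off-diagonal signs unconstrained)."""

    entries: np.ndarray
    d: int
    tol: float = 1.0e-9

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", np.asarray(self.entries, dtype=float))


def _as_array(m) -> np.ndarray:
    if isinstance(m, (MarkovMatrix, RateMatrix, ZeroRowSumMatrix)):
        return m.entries
    return np.asarray(m, dtype=float)


def validate_markov(raw, tol: float = 1.0e-9) -> MarkovMatrix:
    """Validate ``raw`` as a Markov matrix; entries are clamped to [0, 1].

    Raises :class:`ValidationError` when the matrix is not square with
    d in {2, 3, 4}, when an entry is below ``-tol``, or when a row sum
    deviates from 1 by more than ``tol``.
    """
    m = np.asarray(raw, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError(f"expected a square matrix, got shape {m.shape}")
    d = m.shape[0]
    if d not in (2, 3, 4):
        raise ValidationError(f"dimension d={d} outside supported range {{2,3,4}}")
    if np.any(m < -tol):
        i, j = np.unravel_index(int(np.argmin(m)), m.shape)
        raise ValidationError(f"negative entry {m[i, j]:.3g} at position ({i + 1},{j + 1})")
    rs = m.sum(axis=1)
    if np.any(np.abs(rs - 1.0) > tol):
        i = int(np.argmax(np.abs(rs - 1.0)))
        raise ValidationError(f"row {i + 1} sums to {rs[i]!r}, expected 1")
    return MarkovMatrix(np.clip(m, 0.0, 1.0), d, tol)


def validate_rate(raw, tol: float = 1.0e-9) -> RateMatrix:
    """Validate ``raw`` as a Markov generator (rate matrix)."""
    q = np.asarray(raw, dtype=float)
    if q.ndim != 2 or q.shape[0] != q.shape[1]:
        raise ValidationError(f"expected a square matrix, got shape {q.shape}")
    d = q.shape[0]
    ok, viol = is_generator(q, tol)
    if not ok:
        raise ValidationError(f"not a generator; violations at {viol}")
    return RateMatrix(q, d, tol)


def validate_zero_row_sum(raw, tol: float = 1.0e-9) -> ZeroRowSumMatrix:
    r = np.asarray(raw, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValidationError(f"expected a square matrix, got shape {r.shape}")
    rs = r.sum(axis=1)
    if np.any(np.abs(rs) > tol):
        i = int(np.argmax(np.abs(rs)))
        raise ValidationError(f"row {i + 1} sums to {rs[i]!r}, expected 0")
    return ZeroRowSumMatrix(r, r.shape[0], tol)


def is_generator(R, tol: float = 1.0e-9) -> tuple[bool, list[tuple[int, int]]]:
    """Report whether ``R`` is a Markov generator.

    Returns ``(flag, violations)`` where violations lists off-diagonal
    positions with entries below ``-tol`` (0-based indices); a row-sum
    violation is recorded as ``(i, i)``.
    """
    r = _as_array(R)
    d = r.shape[0]
    viol: list[tuple[int, int]] = []
    for i in range(d):
        for j in range(d):
            if i != j and r[i, j] < -tol:
                viol.append((i, j))
    rs = r.sum(axis=1)
    for i in range(d):
        if abs(rs[i]) > tol * max(1.0, np.abs(r[i]).max()):
            viol.append((i, i))
    return (not viol), viol


# ---------------------------------------------------------------------------
# exponential and logarithms
# ---------------------------------------------------------------------------


def matrix_exp(Q) -> np.ndarray:
    """Matrix exponential (scaling-and-squaring via scipy)."""
    return expm(_as_array(Q))


def exp_residual(Q, M) -> float:
    """Max-norm residual ``||e^Q - M||_inf`` of a candidate logarithm."""
    q = _as_array(Q)
    m = _as_array(M)
    return float(np.abs(expm(q) - m).max())


def principal_log(M) -> np.ndarray:
    """Principal matrix logarithm of a Markov matrix.

    Defined when no eigenvalue lies on the closed negative real axis; the
    result is the unique real logarithm whose eigenvalues have imaginary
    part in (-pi, pi), and it has zero row sums.
    """
    m = _as_array(M)
    ev = np.linalg.eigvals(m)
    scale = max(1.0, float(np.abs(m).max()))
    for lam in ev:
        if abs(lam.imag) <= 1.0e-12 * scale and lam.real <= 1.0e-12 * scale:
            raise ValueError(
                "principal log undefined: eigenvalue on the closed negative real axis"
            )
    L = logm(m)
    if np.abs(L.imag).max() > 1.0e-8:
        raise ValueError("principal log computation returned a non-real matrix")
    return np.ascontiguousarray(L.real)


def log_series(M, max_terms: int = 20000, tol: float = 1.0e-16) -> np.ndarray:
    """Power-series logarithm ``sum_n (-1)^{n+1} A^n / n`` with ``A = M - I``.

    Independent oracle, valid when the spectral radius of ``A`` is < 1.
    """
    m = _as_array(M)
    d = m.shape[0]
    A = m - np.eye(d)
    term = A.copy()
    out = A.copy()
    for n in range(2, max_terms + 1):
        term = term @ A
        inc = ((-1.0) ** (n + 1)) * term / n
        out += inc
        if np.abs(inc).max() < tol:
            break
    return out


# ---------------------------------------------------------------------------
# spectral classification
# ---------------------------------------------------------------------------


@dataclass
class EigenCluster:
    """One eigenvalue cluster of the classification."""

    value: complex          # cluster representative (mean)
    alg: int                # algebraic multiplicity
    geo: int                # geometric multiplicity
    max_block: int          # largest elementary Jordan block
    spread: float           # max distance of members from the representative
    is_one: bool = False    # the Perron eigenvalue 1
    basis: Optional[np.ndarray] = None  # d x geo eigenvector basis (real clusters)

    @property
    def is_real(self) -> bool:
        return abs(self.value.imag) < 1.0e-9


@dataclass
class SpectralSummary:
    """Spectral/Jordan classification of a Markov matrix.

    ``jnf_tag`` names one row of the d=3 or d=4 case table, e.g.
    ``"diag(1,l,l)"`` or ``"1+J3(l)"``; the placeholder ``l`` stands for the
    non-unit eigenvalue(s), ordered as in ``clusters``.
    """

    d: int
    eigenvalues: np.ndarray
    clusters: list[EigenCluster]
    minpoly_degree: int
    jnf_tag: str
    is_cyclic: bool
    is_diagonalisable: bool
    cluster_tol: float
    similarity_T: Optional[np.ndarray] = None
    ambiguous: bool = False

    @property
    def alg_mult(self) -> dict[complex, int]:
        return {c.value: c.alg for c in self.clusters}

    @property
    def geo_mult(self) -> dict[complex, int]:
        return {c.value: c.geo for c in self.clusters}

    def cluster_of_one(self) -> EigenCluster:
        return next(c for c in self.clusters if c.is_one)

    def non_unit(self) -> list[EigenCluster]:
        return [c for c in self.clusters if not c.is_one]


def _single_linkage(vals: np.ndarray, tol: float) -> list[list[int]]:
    n = len(vals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(vals[i] - vals[j]) <= tol:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def _build_summary(M: np.ndarray, ev: np.ndarray, groups: list[list[int]],
                   cluster_tol: float) -> SpectralSummary:
    d = M.shape[0]
    scale = max(1.0, float(np.linalg.norm(M)))
    clusters: list[EigenCluster] = []
    for idx in groups:
        members = ev[idx]
        val = complex(members.mean())
        spread = float(np.abs(members - val).max()) if len(idx) > 1 else 0.0
        alg = len(idx)
        # force conjugate-symmetric representatives onto the real axis
        if abs(val.imag) < 1.0e-9 * scale:
            val = complex(val.real, 0.0)
        is_one = abs(val - 1.0) < 1.0e-6 * scale
        if alg == 1:
            geo = 1
            basis = None
        else:
            # geometric multiplicity from the singular values of M - val*I
            sv = np.linalg.svd(M - val * np.eye(d), compute_uv=False)
            rank_tol = max(1.0e-9 * sv[0], 50.0 * spread, 1.0e3 * np.finfo(float).eps * sv[0])
            geo = int(np.sum(sv < rank_tol))
            geo = min(max(geo, 1), alg)
            basis = None
        max_block = alg - geo + 1
        clusters.append(EigenCluster(val, alg, geo, max_block, spread, is_one))
    # the Perron eigenvalue: exactly one cluster carries it
    one = min(clusters, key=lambda c: abs(c.value - 1.0))
    for c in clusters:
        c.is_one = c is one
    if one.geo != one.alg:   # no non-trivial Jordan block at 1 for Markov M
        one.geo = one.alg
        one.max_block = 1
    # eigenvector bases for real diagonalisable clusters (used by searches)
    for c in clusters:
        if c.is_real and c.max_block == 1:
            u, s, vh = np.linalg.svd(M - c.value.real * np.eye(d))
            c.basis = vh[d - c.geo:].T.conj().real.copy()
    minpoly_degree = sum(c.max_block for c in clusters)
    is_cyclic = all(c.geo == 1 for c in clusters)
    is_diag = all(c.max_block == 1 for c in clusters)
    tag = _jnf_tag(d, clusters)
    T = None
    if is_diag and all(c.is_real for c in clusters):
        T = np.hstack([c.basis for c in _ordered(clusters)])
    return SpectralSummary(d, ev, _ordered(clusters), minpoly_degree, tag,
                           is_cyclic, is_diag, cluster_tol, T)


def _ordered(clusters: list[EigenCluster]) -> list[EigenCluster]:
    """Perron cluster first, then by decreasing real part."""
    return sorted(clusters, key=lambda c: (not c.is_one, -c.value.real, -abs(c.value.imag)))


def _jnf_tag(d: int, clusters: list[EigenCluster]) -> str:
    cs = _ordered(clusters)
    one = cs[0]
    rest = cs[1:]
    if not rest:
        return "identity"
    has_complex = any(not c.is_real for c in rest)
    if d == 2:
        return "diag(1,l)"
    if d == 3:
        if len(rest) == 1:
            c = rest[0]
            if one.alg == 2:
                return "diag(1,1,l)"
            if c.alg == 2:
                return "diag(1,l,l)" if c.max_block == 1 else "1+J2(l)"
        if has_complex:
            return "diag(1,l,conj_l)"
        return "diag(1,l1,l2)"
    # d == 4
    if len(rest) == 1:
        c = rest[0]
        if one.alg == 3:
            return "diag(1,1,1,l)"
        if one.alg == 2:
            if c.alg == 2:
                return "diag(1,1,l,l)" if c.max_block == 1 else "diag(1,1)+J2(l)"
        if c.alg == 3:
            if c.max_block == 1:
                return "diag(1,l,l,l)"
            if c.max_block == 3:
                return "1+J3(l)"
            return "diag(1,l)+J2(l)"
    if len(rest) == 2:
        if has_complex:
            return "diag(1,1,l,conj_l)" if one.alg == 2 else "degenerate_complex"
        if one.alg == 2:
            return "diag(1,1,l1,l2)"
        rep = next((c for c in rest if c.alg == 2), None)
        if rep is not None:
            if rep.max_block == 1:
                return "diag(1,l1,l2,l2)"
            return "diag(1,l1)+J2(l2)"
    if has_complex:
        return "diag(1,l,theta,conj_theta)"
    return "diag(1,l1,l2,l3)"


def spectral_summaries(M, cluster_tol: float = 1.0e-9) -> list[SpectralSummary]:
    """Candidate spectral classifications of ``M``.

    The first summary uses fine eigenvalue clustering at ``cluster_tol``
    (relative).  Numerically computed eigenvalues of defective matrices
    split at scale eps^(1/k), so when a coarser clustering (at
    :data:`DEFECT_TOL`) merges additional eigenvalues, the alternative
    classification is returned as a second hypothesis and solvers merge
    the results of both.
    """
    m = _as_array(M)
    d = m.shape[0]
    ev = np.linalg.eigvals(m)
    scale = max(1.0, float(np.linalg.norm(m)))
    fine_groups = _single_linkage(ev, max(cluster_tol * scale, 1.0e-13))
    out = [_build_summary(m, ev, fine_groups, cluster_tol)]
    coarse_groups = _single_linkage(ev, DEFECT_TOL * scale)
    if sorted(map(len, coarse_groups)) != sorted(map(len, fine_groups)):
        alt = _build_summary(m, ev, coarse_groups, cluster_tol)
        alt.ambiguous = True
        out[0].ambiguous = True
        out.append(alt)
    return out


def spectral_summary(M, cluster_tol: float = 1.0e-9) -> SpectralSummary:
    """Primary spectral classification (first of :func:`spectral_summaries`)."""
    return spectral_summaries(M, cluster_tol)[0]


# ---------------------------------------------------------------------------
# necessary conditions and uniqueness certificates
# ---------------------------------------------------------------------------


@dataclass
class ConditionReport:
    """Outcome of the classical necessary conditions for (g-)embeddability.

    Any false flag certifies that the matrix is not embeddable;
    ``goodman_ok = False`` certifies in addition that it is not reachable
    by any time-inhomogeneous Markov flow.
    """

    positive_diagonal: bool
    det_in_unit_interval: bool
    spectrum_inside_disk: bool
    transitivity_ok: bool
    culver_ok: bool
    goodman_ok: bool
    messages: list[str] = field(default_factory=list)

    @property
    def all_ok(self) -> bool:
        return (self.positive_diagonal and self.det_in_unit_interval
                and self.spectrum_inside_disk and self.transitivity_ok
                and self.culver_ok and self.goodman_ok)

    def to_dict(self) -> dict:
        return {
            "positive_diagonal": self.positive_diagonal,
            "det_in_unit_interval": self.det_in_unit_interval,
            "spectrum_inside_disk": self.spectrum_inside_disk,
            "transitivity_ok": self.transitivity_ok,
            "culver_ok": self.culver_ok,
            "goodman_ok": self.goodman_ok,
            "messages": list(self.messages),
        }


def necessary_conditions(M, tol: float = 1.0e-12) -> ConditionReport:
    """Evaluate the classical necessary conditions for embeddability."""
    m = _as_array(M)
    d = m.shape[0]
    msgs: list[str] = []

    diag = np.diag(m)
    positive_diagonal = bool(np.all(diag > tol))
    if not positive_diagonal:
        msgs.append("a diagonal entry vanishes; not embeddable (Elfving)")

    det = float(np.linalg.det(m))
    det_ok = tol < det <= 1.0 + 1.0e-9
    if not det_ok:
        msgs.append(f"det(M) = {det:.6g} outside (0, 1]")

    ev = np.linalg.eigvals(m)
    disk_ok = True
    for lam in ev:
        if abs(abs(lam) - 1.0) < 1.0e-9 and abs(lam - 1.0) > 1.0e-7:
            disk_ok = False
            msgs.append(f"eigenvalue {lam:.6g} on the unit circle besides 1")

    pos = m > tol
    trans_ok = True
    for i in range(d):
        for k in range(d):
            if not pos[i, k] and np.any(pos[i] & pos[:, k]):
                trans_ok = False
    if not trans_ok:
        msgs.append("positivity pattern is not transitive")

    culver_ok = abs(det) > tol
    summary = spectral_summary(m)
    for c in summary.clusters:
        if c.is_real and c.value.real < -1.0e-9:
            if c.max_block > 1 or c.alg % 2 == 1:
                culver_ok = False
                msgs.append(
                    f"negative eigenvalue {c.value.real:.6g}: Jordan blocks do not "
                    "occur with even multiplicity (Culver)"
                )

    goodman_ok = det > tol and float(np.prod(diag)) >= det - 1.0e-12
    if not goodman_ok:
        msgs.append("prod(m_ii) >= det(M) > 0 fails (Goodman); not g-embeddable")

    return ConditionReport(positive_diagonal, det_ok, disk_ok, trans_ok,
                           culver_ok, goodman_ok, msgs)


def uniqueness_certificates(M) -> dict[str, bool]:
    """Cuthbert's two sufficient conditions for a unique embedding.

    ``cuthbert_half``: all diagonal entries exceed 1/2.
    ``cuthbert_det``: ``det(M) * min_i m_ii > e^{-pi} * prod_i m_ii``
    (implied by ``det(M) > e^{-pi}``).  Either one implies that at most one
    generator exists, necessarily the principal logarithm when defined.
    """
    m = _as_array(M)
    diag = np.diag(m)
    det = float(np.linalg.det(m))
    half = bool(diag.min() > 0.5)
    detc = bool(det * diag.min() > E_MINUS_PI * np.prod(diag))
    return {"cuthbert_half": half, "cuthbert_det": detc}


# ---------------------------------------------------------------------------
# the I_{x,y,z} rotation family
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IxyzPoint:
    """Parameters of a real square root of -I: ``[[x, -z], [y, -x]]``.

    Constraint ``y z - x^2 = 1`` with ``z > 0``; these matrices have
    eigenvalues +/- i and parametrise all real logarithms of rotations.
    """

    x: float
    y: float
    z: float

    def matrix(self) -> np.ndarray:
        return np.array([[self.x, -self.z], [self.y, -self.x]])


def ixyz(x: float, z: float) -> IxyzPoint:
    """Point of the family with ``y`` determined by ``y z - x^2 = 1``."""
    if z <= 0:
        raise ValueError("z must be positive")
    return IxyzPoint(x, (1.0 + x * x) / z, z)


@dataclass
class LogBranch:
    """One candidate real logarithm (winding index k) of a Markov matrix."""

    k: int
    coefficients: tuple[float, ...]
    candidate: np.ndarray
    is_generator: bool
    residual: float


@dataclass
class SearchConfig:
    """Controls the rotation-block feasibility search."""

    grid_lo: float = -3.0
    grid_hi: float = 3.0
    n_starts: int = 5            # per axis -> n_starts^2 multistarts
    accept_tol: float = 1.0e-9   # accept if min off-diagonal >= -accept_tol
    residual_tol: float = 1.0e-8
    max_iter: int = 300
    k_cap: int = 50


DEFAULT_SEARCH = SearchConfig()


def ixyz_feasibility(T: np.ndarray, fixed_log: Sequence[float], theta: float,
                     log_abs_lambda: float,
                     cfg: SearchConfig = DEFAULT_SEARCH) -> Optional[np.ndarray]:
    """Search the rotation-block logarithm family for a generator.

    With ``M = T J T^{-1}`` and ``J`` carrying a repeated real eigenvalue
    ``lambda`` in its trailing 2x2 block, every real logarithm with winding
    angle ``theta`` in that block has the form::

        R(x, z) = T [ diag(fixed_log)  (+)  log|lambda| I_2
                      + theta * [[x, -z], [y, -x]] ] T^{-1},   y z - x^2 = 1.

    The search maximises the minimum off-diagonal entry of ``R`` over
    ``(x, s)`` with ``z = e^s`` by multi-start Nelder-Mead and returns the
    candidate when the optimum clears ``-cfg.accept_tol``; ``None`` means
    "no generator found by search", which is not a certificate.
    """
    d = T.shape[0]
    m = d - 2
    Tinv = np.linalg.inv(T)
    fixed = np.asarray(fixed_log, dtype=float)
    off_mask = ~np.eye(d, dtype=bool)

    def build(x: float, s: float) -> np.ndarray:
        z = math.exp(s)
        y = (1.0 + x * x) / z
        L = np.zeros((d, d))
        L[:m, :m] = np.diag(fixed)
        L[m:, m:] = log_abs_lambda * np.eye(2) + theta * np.array([[x, -z], [y, -x]])
        return T @ L @ Tinv

    if theta == 0.0:
        R = build(0.0, 0.0)
        ok, _ = is_generator(R, cfg.accept_tol)
        return R if ok else None

    def neg_margin(p) -> float:
        R = build(p[0], p[1])
        return -float(R[off_mask].min())

    best_val = np.inf
    best_p = None
    starts = np.linspace(cfg.grid_lo, cfg.grid_hi, cfg.n_starts)
    for x0 in starts:
        for s0 in starts:
            res = minimize(neg_margin, np.array([x0, s0]), method="Nelder-Mead",
                           options={"xatol": 1.0e-11, "fatol": 1.0e-12,
                                    "maxiter": cfg.max_iter})
            if res.fun < best_val:
                best_val = res.fun
                best_p = res.x
            if best_val <= -1.0e-6:   # comfortably feasible; stop early
                break
        else:
            continue
        break
    if best_p is None or best_val > cfg.accept_tol:
        return None
    R = build(best_p[0], best_p[1])
    # clip search-level noise on the off-diagonal
    R = R.copy()
    for i in range(d):
        for j in range(d):
            if i != j and -cfg.accept_tol <= R[i, j] < 0.0:
                R[i, j] = 0.0
    np.fill_diagonal(R, np.diag(R) - (R.sum(axis=1) - 0.0))
    return R


# ---------------------------------------------------------------------------
# result container shared by the dimension-specific solvers
# ---------------------------------------------------------------------------


@dataclass
class EmbeddingResult:
    """Verdict of the embedding decision for one Markov matrix.

    ``generators`` holds every generator found (each verified against the
    exponential-residual contract); ``branches`` records the candidate
    logarithms examined, including rejected ones.
    """

    verdict: str                 # embeddable | not_embeddable | undecided_search
    case_label: str
    generators: list[np.ndarray] = field(default_factory=list)
    uniqueness: str = "not_applicable"
    branches: list[LogBranch] = field(default_factory=list)
    conditions: Optional[ConditionReport] = None
    messages: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "case": self.case_label,
            "generators": [g.tolist() for g in self.generators],
            "uniqueness": self.uniqueness,
            "branches": [
                {
                    "k": b.k,
                    "coefficients": list(b.coefficients),
                    "is_generator": b.is_generator,
                    "residual": b.residual,
                }
                for b in self.branches
            ],
            "conditions": self.conditions.to_dict() if self.conditions else None,
            "messages": list(self.messages),
        }


def dedupe_generators(gens: list[np.ndarray], tol: float = 1.0e-6) -> list[np.ndarray]:
    out: list[np.ndarray] = []
    for g in gens:
        if all(np.abs(g - h).max() > tol for h in out):
            out.append(g)
    return out


def merge_hypotheses(results: list["EmbeddingResult"]) -> "EmbeddingResult":
    """Combine the verdicts of alternative spectral classifications.

    When eigenvalue clustering is ambiguous at tolerance, both plausible
    Jordan structures are solved.  Any residual-verified generator settles
    the matter; otherwise the primary (fine-clustering) verdict stands,
    with an explicit ambiguity message.
    """
    if len(results) == 1:
        return results[0]
    gens = dedupe_generators([g for r in results for g in r.generators])
    branches = [b for r in results for b in r.branches]
    msgs = [m for r in results for m in r.messages]
    msgs.append("classification ambiguous at tolerance; hypotheses merged")
    primary = results[0]
    if gens:
        src = next(r for r in results if r.generators)
        return EmbeddingResult("embeddable", src.case_label, gens, src.uniqueness,
                               branches, primary.conditions, msgs)
    if all(r.verdict == "not_embeddable" for r in results):
        verdict = "not_embeddable"
    else:
        verdict = "undecided_search"
    return EmbeddingResult(verdict, primary.case_label, [], primary.uniqueness,
                           branches, primary.conditions, msgs)
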
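"""Nucleotide substitution models and their specialised embedding tests.

All constructors use the state ordering (A, G, C, T).  Three families are
covered:

* **equal-input**: ``M_c = (1 - c) I + C`` with ``C`` having equal rows
  ``(c_1, ..., c_d)`` and summatory parameter ``c = sum c_i``; contains the
  constant-input (Jukes-Cantor) matrices as the uniform special case.
* **Tamura-Nei (TN)**: per-column rates ``a_i >= 0`` with two transition
  boosts ``kappa_1`` (purines A<->G) and ``kappa_2`` (pyrimidines C<->T);
  contains HKY (``kappa_1 = kappa_2``) and equal-input (``kappa_j = 1``).
* **K3ST** (Kimura 3-substitution-type): ``M = s I + x K_1 + y K_2 + z K_3``
  over the Klein 4-group; all K3ST matrices commute.

For a 4-state equal-input matrix embeddability is simply ``0 <= c < 1``.
A simple TN matrix is embeddable iff its three non-unit eigenvalues lie in
(0, 1), with a unique TN-shaped generator.  A simple K3ST matrix is
embeddable iff all non-unit eigenvalues are positive and obey
``lam_1 >= lam_2 lam_3`` (cyclically), with a unique K3ST generator given
by quarter-sums of signed eigenvalue logarithms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .embed_d3 import equal_input_negative
from .embed_d4 import embed_4x4
from .matrix_core import (
    DEFAULT_SEARCH,
    EmbeddingResult,
    LogBranch,
    MarkovMatrix,
    SearchConfig,
    exp_residual,
    is_generator,
    necessary_conditions,
    validate_markov,
)

__all__ = [
    "TNParams",
    "K3STParams",
    "equal_input_matrix",
    "equal_input_embeddable",
    "tamura_nei",
    "tn_spectrum",
    "tn_embeddable",
    "k3st",
    "k3st_spectrum",
    "k3st_embeddable",
    "is_tn_shaped",
    "is_k3st_shaped",
    "permute_states",
]

# Klein 4-group permutation matrices under the (A, G, C, T) ordering:
# K1 = (AG)(CT) transitions, K2 = (AC)(GT), K3 = (AT)(GC) transversions.
K1 = np.array([[0, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]], dtype=float)
K2 = np.array([[0, 0, 1, 0], [0, 0, 0, 1], [1, 0, 0, 0], [0, 1, 0, 0]], dtype=float)
K3 = np.array([[0, 0, 0, 1], [0, 0, 1, 0], [0, 1, 0, 0], [1, 0, 0, 0]], dtype=float)


@dataclass(frozen=True)
class TNParams:
    """Tamura-Nei parameters: column rates a1..a4 and boosts kappa1, kappa2."""

    a: tuple[float, float, float, float]
    kappa1: float
    kappa2: float

    def __post_init__(self) -> None:
        if min(self.a) < 0 or self.kappa1 < 0 or self.kappa2 < 0:
            raise ValueError("TN parameters must be non-negative")


@dataclass(frozen=True)
class K3STParams:
    """K3ST parameters x, y, z >= 0 with x + y + z <= 1."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if min(self.x, self.y, self.z) < 0:
            raise ValueError("K3ST parameters must be non-negative")
        if self.x + self.y + self.z > 1.0 + 1.0e-12:
            raise ValueError("K3ST requires x + y + z <= 1")


def permute_states(M, order) -> np.ndarray:
    """Simultaneous row/column permutation to a new state ordering."""
    m = np.asarray(M, dtype=float)
    idx = np.asarray(order, dtype=int)
    return m[np.ix_(idx, idx)]


# ---------------------------------------------------------------------------
# equal input
# ---------------------------------------------------------------------------


def equal_input_matrix(c, d: int | None = None) -> MarkovMatrix:
    """Build the equal-input matrix ``(1 - c) I + C`` for a c-vector."""
    cv = np.asarray(c, dtype=float)
    if d is None:
        d = len(cv)
    if len(cv) != d or d not in (3, 4):
        raise ValueError("equal-input supports d in {3, 4}")
    if np.any(cv < 0):
        raise ValueError("c_i must be non-negative")
    csum = float(cv.sum())
    if np.any(csum > 1.0 + cv + 1.0e-12):
        raise ValueError("Markov condition c <= 1 + c_i violated")
    m = (1.0 - csum) * np.eye(d) + np.tile(cv, (d, 1))
    return validate_markov(m)


def equal_input_embeddable(c, cfg: SearchConfig = DEFAULT_SEARCH) -> EmbeddingResult:
    """Embeddability of an equal-input matrix from its c-vector.

    d = 4: embeddable iff ``c < 1`` (even dimension leaves no room for the
    repeated-negative-eigenvalue mechanism); d = 3 adds the constructive
    ``c > 1`` branch.
    """
    cv = np.asarray(c, dtype=float)
    d = len(cv)
    M = equal_input_matrix(cv, d)
    csum = float(cv.sum())
    conds = necessary_conditions(M.entries)
    label = f"equal-input d={d}"
    if csum == 0.0:
        Q = np.zeros((d, d))
        return EmbeddingResult("embeddable", label, [Q], "unique_certified",
                               [LogBranch(0, (), Q, True, 0.0)], conds, [])
    if csum < 1.0 - 1.0e-12:
        Q = (-math.log(1.0 - csum) / csum) * M.A
        res = exp_residual(Q, M.entries)
        branch = LogBranch(0, (-math.log(1.0 - csum) / csum,), Q, True, res)
        # winding branches need |log(1-c)| beyond 2*pi*sqrt(3) (d=3) / 2*pi (d=4)
        wind = 2.0 * math.pi * (math.sqrt(3.0) if d == 3 else 1.0)
        uniq = ("search_incomplete" if abs(math.log(1.0 - csum)) > wind
                else "unique_certified")
        return EmbeddingResult("embeddable", label, [Q], uniq, [branch], conds,
                               ["equal-input generator; further non-equal-input "
                                "embeddings possible only for very small 1 - c"])
    if d == 4 or abs(csum - 1.0) <= 1.0e-12:
        return EmbeddingResult("not_embeddable", label, [], "not_applicable", [],
                               conds, ["summatory parameter c >= 1" if d == 4 else
                                       "c = 1: matrix is singular"])
    return equal_input_negative(cv, M.entries, cfg, conds)


# ---------------------------------------------------------------------------
# Tamura-Nei
# ---------------------------------------------------------------------------


def tamura_nei(p: TNParams) -> MarkovMatrix:
    """Build the TN Markov matrix for the given parameters."""
    a1, a2, a3, a4 = p.a
    k1, k2 = p.kappa1, p.kappa2
    m = np.array([
        [0.0, a2 * k1, a3, a4],
        [a1 * k1, 0.0, a3, a4],
        [a1, a2, 0.0, a4 * k2],
        [a1, a2, a3 * k2, 0.0],
    ])
    off = m.sum(axis=1)
    if np.any(off > 1.0 + 1.0e-12):
        raise ValueError("Markov condition violated: off-diagonal row sum > 1")
    np.fill_diagonal(m, 1.0 - off)
    return validate_markov(m)


def tn_spectrum(p: TNParams) -> tuple[float, float, float]:
    """The three non-unit eigenvalues (lam1, lam2, lam3) of a TN matrix."""
    a1, a2, a3, a4 = p.a
    ag = a1 + a2
    ct = a3 + a4
    lam1 = 1.0 - (ag + ct)
    lam2 = 1.0 - p.kappa1 * ag - ct
    lam3 = 1.0 - ag - p.kappa2 * ct
    return lam1, lam2, lam3


def is_tn_shaped(Q, tol: float = 1.0e-9) -> bool:
    """Check the TN sparsity/equality pattern of a generator (or matrix)."""
    q = np.asarray(Q, dtype=float)
    eqs = [
        abs(q[0, 2] - q[1, 2]), abs(q[0, 3] - q[1, 3]),   # a3, a4 columns
        abs(q[2, 0] - q[3, 0]), abs(q[2, 1] - q[3, 1]),   # a1, a2 columns
        abs(q[0, 1] * q[2, 0] - q[1, 0] * q[2, 1]),       # common kappa1
        abs(q[2, 3] * q[0, 2] - q[3, 2] * q[0, 3]),       # common kappa2
    ]
    return max(eqs) <= tol * max(1.0, np.abs(q).max())


def tn_embeddable(p: TNParams, cfg: SearchConfig = DEFAULT_SEARCH) -> EmbeddingResult:
    """Embeddability of a TN matrix.

    Simple spectrum: embeddable iff all three non-unit eigenvalues lie in
    (0, 1), i.e. ``max{1,k1}(a1+a2) + max{1,k2}(a3+a4) < 1`` together with
    the corresponding min-inequality being positive; the unique generator
    is the principal logarithm and is TN-shaped.  Fully degenerate spectra
    are equal-input; other degeneracies are delegated to the general
    4 x 4 solver.
    """
    M = tamura_nei(p)
    lams = tn_spectrum(p)
    vals = set(np.round(lams, 12)) | {1.0}
    if len(vals) < 4:  # degenerate spectrum
        if abs(lams[0] - lams[1]) < 1.0e-12 and abs(lams[0] - lams[2]) < 1.0e-12:
            res = equal_input_embeddable(np.asarray(p.a))
            res.messages.append("TN degenerates to equal-input (c = sum a_i)")
            return res
        res = embed_4x4(M, cfg=cfg)
        res.messages.append("degenerate TN spectrum; delegated to general d=4 solver")
        return res
    a1, a2, a3, a4 = p.a
    lo = min(1.0, p.kappa1) * (a1 + a2) + min(1.0, p.kappa2) * (a3 + a4)
    hi = max(1.0, p.kappa1) * (a1 + a2) + max(1.0, p.kappa2) * (a3 + a4)
    conds = necessary_conditions(M.entries)
    if not (lo > 0.0 and hi < 1.0):
        return EmbeddingResult("not_embeddable", "tamura-nei", [], "not_applicable",
                               [], conds,
                               ["TN spectral condition fails: an eigenvalue "
                                "leaves (0, 1)"])
    res = embed_4x4(M, cfg=cfg)
    res.case_label = "tamura-nei"
    if res.generators and not is_tn_shaped(res.generators[0]):
        res.messages.append("warning: generator failed the TN shape check")
    return res


# ---------------------------------------------------------------------------
# K3ST
# ---------------------------------------------------------------------------


def k3st(p: K3STParams) -> MarkovMatrix:
    """Build the (symmetric) K3ST Markov matrix."""
    s = 1.0 - p.x - p.y - p.z
    m = s * np.eye(4) + p.x * K1 + p.y * K2 + p.z * K3
    return validate_markov(m)


def k3st_spectrum(p: K3STParams) -> tuple[float, float, float, float]:
    """Spectrum (1, 1-2(x+z), 1-2(y+z), 1-2(x+y)) as a multiset."""
    return (1.0,
            1.0 - 2.0 * (p.x + p.z),
            1.0 - 2.0 * (p.y + p.z),
            1.0 - 2.0 * (p.x + p.y))


def is_k3st_shaped(Q, tol: float = 1.0e-9) -> bool:
    q = np.asarray(Q, dtype=float)
    scale = max(1.0, np.abs(q).max())
    groups = [
        [(0, 1), (1, 0), (2, 3), (3, 2)],
        [(0, 2), (2, 0), (1, 3), (3, 1)],
        [(0, 3), (3, 0), (1, 2), (2, 1)],
        [(0, 0), (1, 1), (2, 2), (3, 3)],
    ]
    for g in groups:
        vals = [q[i, j] for i, j in g]
        if max(vals) - min(vals) > tol * scale:
            return False
    return True


def _k3st_generator(lam1: float, lam2: float, lam3: float) -> np.ndarray:
    """Quarter-sum sign-pattern generator of a simple embeddable K3ST matrix."""
    l1, l2, l3 = math.log(lam1), math.log(lam2), math.log(lam3)

    def f(s1: int, s2: int, s3: int) -> float:
        return 0.25 * (s1 * l1 + s2 * l2 + s3 * l3)

    ppp = f(+1, +1, +1)
    pmm = f(+1, -1, -1)
    mpm = f(-1, +1, -1)
    mmp = f(-1, -1, +1)
    return np.array([
        [ppp, mpm, pmm, mmp],
        [mpm, ppp, mmp, pmm],
        [pmm, mmp, ppp, mpm],
        [mmp, pmm, mpm, ppp],
    ])


def k3st_embeddable(p: K3STParams, cfg: SearchConfig = DEFAULT_SEARCH) -> EmbeddingResult:
    """Embeddability of a K3ST matrix.

    Simple spectrum (x, y, z distinct): embeddable iff all lam_i > 0 and
    ``lam_1 >= lam_2 lam_3``, ``lam_2 >= lam_1 lam_3``,
    ``lam_3 >= lam_1 lam_2``; the unique generator is K3ST.  x = y = z is
    constant-input; a single coincidence (K2P pattern) is delegated to the
    general solver.
    """
    M = k3st(p)
    _, lam1, lam2, lam3 = k3st_spectrum(p)
    conds = necessary_conditions(M.entries)
    if abs(p.x - p.y) < 1.0e-12 and abs(p.y - p.z) < 1.0e-12:
        res = equal_input_embeddable(np.full(4, p.x))
        res.messages.append("K3ST degenerates to constant-input (x = y = z)")
        return res
    if len({round(v, 12) for v in (lam1, lam2, lam3, 1.0)}) < 4:
        res = embed_4x4(M, cfg=cfg)
        res.messages.append("degenerate K3ST spectrum (K2P-type); delegated to "
                            "general d=4 solver")
        return res
    lams = (lam1, lam2, lam3)
    if min(lams) <= 1.0e-12:
        return EmbeddingResult("not_embeddable", "k3st", [], "not_applicable", [],
                               conds, ["a K3ST eigenvalue is non-positive"])
    ok30 = (lam1 >= lam2 * lam3 - 1.0e-12 and lam2 >= lam1 * lam3 - 1.0e-12
            and lam3 >= lam1 * lam2 - 1.0e-12)
    if not ok30:
        return EmbeddingResult("not_embeddable", "k3st", [], "not_applicable", [],
                               conds,
                               ["multiplicative eigenvalue inequalities fail: "
                                "the unique candidate has a negative rate"])
    Q = _k3st_generator(lam1, lam2, lam3)
    res = exp_residual(Q, M.entries)
    ok, _ = is_generator(Q, cfg.accept_tol)
    branch = LogBranch(0, (), Q, ok, res)
    msgs = [] if is_k3st_shaped(Q) else ["warning: generator failed K3ST shape check"]
    if ok and res <= cfg.residual_tol:
        return EmbeddingResult("embeddable", "k3st", [Q], "unique_certified",
                               [branch], conds, msgs)
    return EmbeddingResult("undecided_search", "k3st", [], "search_incomplete",
                           [branch], conds, msgs + ["residual contract failed"])
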
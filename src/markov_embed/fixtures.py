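"""Fixture library: closed-form matrices exercising every branch of the
case analysis, with their expected embedding behaviour.

Each fixture realises a structurally exact matrix (or generator family)
whose Jordan pattern and verdict are known analytically, so the test
suite can pin the dispatcher against ground truth without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .matrix_core import E_MINUS_PI_SQRT3
from .phylo_models import equal_input_matrix

__all__ = ["Fixture", "fixture", "fixture_names"]


@dataclass
class Fixture:
    name: str
    kind: str                    # markov | generator | family | basis
    value: Any
    description: str
    expected: dict = field(default_factory=dict)


def _identity(d: int) -> Fixture:
    return Fixture(f"identity_d{d}", "markov", np.eye(d),
                   "identity matrix; Q = 0 is the unique generator",
                   {"verdict": "embeddable", "n_generators": 1})


def _extremal_constant_input_d3() -> Fixture:
    """Uniform equal-input matrix at the embeddability boundary c = 1 + e^{-pi sqrt 3}.

    The extreme point of the repeated-negative-eigenvalue region; embedded
    by exactly the two circulant generators (2 pi / sqrt 3) circ(-1, 1, 0)
    and its transpose pattern.
    """
    c = 1.0 + E_MINUS_PI_SQRT3
    M = equal_input_matrix(np.full(3, c / 3.0), 3)
    return Fixture("extremal_constant_input_d3", "markov", M.entries,
                   "constant-input matrix with summatory parameter "
                   "1 + exp(-pi sqrt 3); boundary of embeddability for the "
                   "repeated negative eigenvalue case",
                   {"verdict": "embeddable", "n_generators": 2})


def _circulant_pair_d3() -> Fixture:
    s = 2.0 * math.pi / math.sqrt(3.0)
    qp = s * np.array([[-1.0, 1, 0], [0, -1, 1], [1, 0, -1]])
    qm = s * np.array([[-1.0, 0, 1], [1, -1, 0], [0, 1, -1]])
    return Fixture("circulant_pair_d3", "generator", (qp, qm),
                   "the two circulant generators embedding the extremal "
                   "constant-input matrix", {})


def _squared_extremal_d3() -> Fixture:
    m = fixture("extremal_constant_input_d3").value
    return Fixture("squared_extremal_d3", "markov", m @ m,
                   "square of the extremal constant-input matrix: equal-input "
                   "with c' = 1 - exp(-2 pi sqrt 3) < 1 and at least three "
                   "distinct embeddings",
                   {"verdict": "embeddable", "min_generators": 3})


def _one_row_block_d4(a: float = 0.3, b: float = 0.3) -> Fixture:
    m = np.eye(4)
    m[0, 0], m[0, 1] = 1.0 - a, a
    m[1, 0], m[1, 1] = b, 1.0 - b
    return Fixture("one_row_block_d4", "markov", m,
                   "2x2 block plus identity: embeddable iff a + b < 1",
                   {"verdict": "embeddable" if a + b < 1 else "not_embeddable"})


def _spike_row_d4(x: float = 0.1, y: float = 0.2, z: float = 0.3) -> Fixture:
    lam = 1.0 - x - y - z
    m = np.eye(4)
    m[0] = [lam, x, y, z]
    return Fixture("spike_row_d4", "markov", m,
                   "single non-trivial row; Jordan pattern diag(1,1,1,lambda)",
                   {"verdict": "embeddable" if 0 < x + y + z < 1 else "not_embeddable",
                    "lambda": lam})


def _two_poisson_product_d3(t: float = 1.0, s: float = 1.0) -> Fixture:
    """Product of two non-commuting Poisson flows: g-embeddable but not
    embeddable (its unique zero-row-sum logarithm has a negative entry)."""
    q1 = np.array([[-1.0, 1, 0], [0, 0, 0], [0, 0, 0]])
    q2 = np.array([[0.0, 0, 0], [0, 0, 0], [1, 0, -1]])
    a = 1.0 - math.exp(-t)
    b = 1.0 - math.exp(-s)
    m = np.array([[1.0 - a, a, 0.0], [0.0, 1.0, 0.0], [b, 0.0, 1.0 - b]])
    return Fixture("two_poisson_product_d3", "family",
                   {"segments": [(t, q1), (s, q2)], "matrix": m,
                    "a": a, "b": b},
                   "flow running one Poisson generator for time t, then the "
                   "other for time s; the product has a zero off-diagonal "
                   "entry and violates transitivity",
                   {"verdict": "not_embeddable", "g_verdict": "g_embeddable"})


def _symmetric_pair_product_d3(a: float = 0.25, b: float = 0.25) -> Fixture:
    """Product of two symmetric 2-state-exchange flows: doubly stochastic
    but no longer symmetric, and not embeddable due to a zero entry."""
    q1 = np.array([[-1.0, 1, 0], [1, -1, 0], [0, 0, 0]])
    q2 = np.array([[-1.0, 0, 1], [0, 0, 0], [1, 0, -1]])
    t = -0.5 * math.log(1.0 - 2.0 * a)
    s = -0.5 * math.log(1.0 - 2.0 * b)
    m = np.array([
        [(1 - a) * (1 - b), a, (1 - a) * b],
        [a * (1 - b), 1 - a, a * b],
        [b, 0.0, 1 - b],
    ])
    return Fixture("symmetric_pair_product_d3", "family",
                   {"segments": [(t, q1), (s, q2)], "matrix": m,
                    "a": a, "b": b},
                   "product of exponentials of the two symmetric exchange "
                   "generators; doubly stochastic, not symmetric, with a "
                   "zero entry in the last row",
                   {"verdict": "not_embeddable", "g_verdict_not": "not_g_embeddable"})


def _constant_input_idempotent(d: int) -> Fixture:
    return Fixture(f"constant_input_idempotent_d{d}", "markov",
                   np.full((d, d), 1.0 / d),
                   "singular constant-input idempotent J_d; boundary point "
                   "of the g-embeddable monoid",
                   {"verdict": "not_embeddable"})


def _negative_pair_block_d4() -> Fixture:
    mp = np.array([[0.25, 0.75], [0.75, 0.25]])
    m = np.zeros((4, 4))
    m[:2, :2] = mp
    m[2:, 2:] = mp
    return Fixture("negative_pair_block_d4", "markov", m,
                   "direct sum of two symmetric 2x2 blocks with eigenvalue "
                   "-1/2: Jordan pattern diag(1,1,-1/2,-1/2), below the "
                   "-exp(-pi) threshold",
                   {"verdict": "not_embeddable"})


def fixture(name: str, **params) -> Fixture:
    """Return a named fixture; parametric fixtures accept keyword overrides."""
    builders = {
        "identity_d2": lambda: _identity(2),
        "identity_d3": lambda: _identity(3),
        "identity_d4": lambda: _identity(4),
        "extremal_constant_input_d3": _extremal_constant_input_d3,
        "circulant_pair_d3": _circulant_pair_d3,
        "squared_extremal_d3": _squared_extremal_d3,
        "one_row_block_d4": lambda: _one_row_block_d4(**params),
        "spike_row_d4": lambda: _spike_row_d4(**params),
        "two_poisson_product_d3": lambda: _two_poisson_product_d3(**params),
        "symmetric_pair_product_d3": lambda: _symmetric_pair_product_d3(**params),
        "constant_input_idempotent_d3": lambda: _constant_input_idempotent(3),
        "constant_input_idempotent_d4": lambda: _constant_input_idempotent(4),
        "negative_pair_block_d4": _negative_pair_block_d4,
    }
    if name not in builders:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(builders)}")
    return builders[name]()


def fixture_names() -> list[str]:
    return [
        "identity_d2", "identity_d3", "identity_d4",
        "extremal_constant_input_d3", "circulant_pair_d3", "squared_extremal_d3",
        "one_row_block_d4", "spike_row_d4",
        "two_poisson_product_d3", "symmetric_pair_product_d3",
        "constant_input_idempotent_d3", "constant_input_idempotent_d4",
        "negative_pair_block_d4",
    ]
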
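"""Complete solution of the 2 x 2 embedding problem (Kendall's theorem).

A 2 x 2 Markov matrix ``M = [[1-a, a], [b, 1-b]]`` is embeddable in a
homogeneous Markov semigroup if and only if ``det(M) = 1 - a - b > 0``.
In that case the generator is unique::

    Q = -log(1 - a - b) / (a + b) * (M - I),      Q = 0 for a = b = 0.

For d = 2 the generalised (time-inhomogeneous) notion adds nothing: the
determinant stays positive along any Markov flow, so g-embeddability and
embeddability coincide.
"""

from __future__ import annotations

import math

import numpy as np

from .matrix_core import (
    EmbeddingResult,
    LogBranch,
    MarkovMatrix,
    exp_residual,
    necessary_conditions,
    validate_markov,
)

__all__ = ["embed_2x2"]


def embed_2x2(M, tol: float = 1.0e-9) -> EmbeddingResult:
    """Decide embeddability of a 2 x 2 Markov matrix and build the generator."""
    if not isinstance(M, MarkovMatrix):
        M = validate_markov(M, tol)
    if M.d != 2:
        raise ValueError(f"embed_2x2 requires d = 2, got d = {M.d}")
    m = M.entries
    a = float(m[0, 1])
    b = float(m[1, 0])
    conds = necessary_conditions(m)
    s = a + b
    if s >= 1.0 - tol:
        msg = ("determinant <= 0 at tolerance: 1 - a - b = "
               f"{1.0 - s:.3g}; not embeddable (Kendall)")
        return EmbeddingResult("not_embeddable", "kendall", [],
                               "not_applicable", [], conds, [msg])
    if s == 0.0:
        Q = np.zeros((2, 2))
    else:
        Q = (-math.log(1.0 - s) / s) * M.A
    res = exp_residual(Q, m)
    branch = LogBranch(0, (-math.log(1.0 - s) / s if s > 0 else 0.0,), Q, True, res)
    return EmbeddingResult("embeddable", "kendall", [Q], "unique_certified",
                           [branch], conds, [])
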
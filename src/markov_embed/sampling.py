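"""Seeded random generator synthesis for tests and experiments.

Every sampler takes an explicit integer seed and is fully reproducible.
The ``dense`` style draws off-diagonal rates from an exponential
distribution normalised to one expected event per unit time per state
(mean total leaving rate 1), a conventional time scale in substitution
modelling; the styled samplers respect the defining shape of their model
class.
"""

from __future__ import annotations

import numpy as np

from .matrix_core import RateMatrix, validate_rate

__all__ = ["sample_generator", "sample_markov"]

_STYLES = ("dense", "equal_input", "tn", "k3st", "poisson_mix")


def sample_generator(d: int, seed: int = 0, style: str = "dense") -> RateMatrix:
    """Draw a reproducible random Markov generator of the requested style."""
    if d not in (2, 3, 4):
        raise ValueError("d must be in {2, 3, 4}")
    if style not in _STYLES:
        raise ValueError(f"unknown style {style!r}; choose from {_STYLES}")
    rng = np.random.default_rng(seed)
    if style == "dense":
        q = rng.exponential(1.0 / (d - 1), size=(d, d))
    elif style == "equal_input":
        b = rng.exponential(1.0 / d, size=d)
        q = np.tile(b, (d, 1))
    elif style == "tn":
        if d != 4:
            raise ValueError("tn style requires d = 4")
        a = rng.exponential(0.1, size=4)
        k1, k2 = rng.uniform(0.5, 3.0, size=2)
        q = np.array([
            [0.0, a[1] * k1, a[2], a[3]],
            [a[0] * k1, 0.0, a[2], a[3]],
            [a[0], a[1], 0.0, a[3] * k2],
            [a[0], a[1], a[2] * k2, 0.0],
        ])
    elif style == "k3st":
        if d != 4:
            raise ValueError("k3st style requires d = 4")
        from .phylo_models import K1, K2, K3
        x, y, z = rng.exponential(0.3, size=3)
        q = x * K1 + y * K2 + z * K3
    else:  # poisson_mix
        q = np.zeros((d, d))
        for _ in range(2 * d):
            i, j = rng.choice(d, size=2, replace=False)
            q[i, j] += rng.exponential(0.5 / d)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return validate_rate(q)


def sample_markov(d: int, seed: int = 0, style: str = "dense") -> np.ndarray:
    """Exponential of a sampled generator: a reproducible embeddable matrix."""
    from .matrix_core import matrix_exp

    return matrix_exp(sample_generator(d, seed, style).entries)
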
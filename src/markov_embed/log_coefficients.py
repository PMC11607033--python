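"""Closed-form coefficients of candidate logarithms ``R = sum_i a_i A^i``.

For a cyclic (or cyclic-after-restriction) Markov matrix ``M`` every
embedding generator commutes with ``M`` and is therefore a polynomial in
``A = M - I`` of degree at most d-1.  The spectral mapping theorem turns
``e^R = M`` into a (possibly confluent) Vandermonde system in the shifted
eigenvalues ``mu_i = lambda_i - 1``; this module solves those systems in
the closed forms of the d <= 4 case analysis.

All functions return real coefficient tuples; complex-pair variants take a
winding index ``k`` selecting the branch ``log(lambda) + 2 pi i k``.
"""

from __future__ import annotations

import cmath
import math

__all__ = [
    "coeffs_two_real",
    "coeffs_confluent_pair",
    "coeffs_complex_pair",
    "coeffs_simple_real_4",
    "coeffs_complex_4",
    "coeffs_jordan3",
    "coeffs_mixed_jordan2",
]

_IMAG_TOL = 1.0e-9


def _real(x: complex, what: str) -> float:
    if abs(x.imag) > _IMAG_TOL * max(1.0, abs(x)):
        raise ArithmeticError(f"{what}: non-real solution (imag {x.imag:.3g})")
    return float(x.real)


def coeffs_two_real(mu: float, nu: float) -> tuple[float, float]:
    """(alpha, beta) for ``R = alpha A + beta A^2`` with two distinct real
    shifted eigenvalues mu != nu in (-1, 0); solves
    ``[[mu, mu^2], [nu, nu^2]] (alpha, beta)^T = (log(1+mu), log(1+nu))^T``."""
    lm = math.log1p(mu)
    ln = math.log1p(nu)
    den = mu * nu * (mu - nu)
    alpha = (mu * mu * ln - nu * nu * lm) / den
    beta = (-mu * ln + nu * lm) / den
    return alpha, beta


def coeffs_confluent_pair(mu: float) -> tuple[float, float]:
    """Confluent limit of :func:`coeffs_two_real` for a Jordan 2-block."""
    lm = math.log1p(mu)
    alpha = 2.0 * lm / mu - 1.0 / (1.0 + mu)
    beta = 1.0 / (mu * (1.0 + mu)) - lm / (mu * mu)
    return alpha, beta


def coeffs_complex_pair(mu: complex, k: int) -> tuple[float, float]:
    """(alpha_k, beta_k) for spectrum {1, lambda, conj(lambda)} with
    ``lambda = 1 + mu`` non-real and branch ``z_k = Log(lambda) + 2 pi i k``."""
    zk = cmath.log(1.0 + mu) + 2.0j * math.pi * k
    mb = mu.conjugate()
    den = abs(mu) ** 2 * (mb - mu)
    alpha = (mb * mb * zk - mu * mu * zk.conjugate()) / den
    beta = (-mb * zk + mu * zk.conjugate()) / den
    return _real(alpha, "coeffs_complex_pair"), _real(beta, "coeffs_complex_pair")


def coeffs_simple_real_4(mu1: float, mu2: float, mu3: float) -> tuple[float, float, float]:
    """(alpha, beta, gamma) for a simple real 4 x 4 spectrum; the inverse
    Vandermonde has entries built from ``m_i = mu_i prod_{j != i}(mu_j - mu_i)``."""
    mus = (mu1, mu2, mu3)
    logs = [math.log1p(m) for m in mus]
    ms = []
    for i, mi in enumerate(mus):
        prod = mi
        for j, mj in enumerate(mus):
            if j != i:
                prod *= (mj - mi)
        ms.append(prod)
    alpha = sum(mus[(i + 1) % 3] * mus[(i + 2) % 3] / ms[i] * logs[i] for i in range(3))
    beta = sum(-(mus[(i + 1) % 3] + mus[(i + 2) % 3]) / ms[i] * logs[i] for i in range(3))
    gamma = sum(logs[i] / ms[i] for i in range(3))
    return alpha, beta, gamma


def coeffs_complex_4(mu: float, nu: complex, k: int) -> tuple[float, float, float]:
    """(alpha, beta, gamma) for spectrum {1, lambda, theta, conj(theta)} with
    ``mu = lambda - 1`` real and ``nu = theta - 1`` non-real, branch ``k``."""
    nb = nu.conjugate()
    m1 = mu * (mu - nu) * (mu - nb)          # real
    m2 = nu * (nu - mu) * (nu - nb)
    m3 = nb * (nb - mu) * (nb - nu)
    r1 = math.log1p(mu)
    r2 = cmath.log(1.0 + nu) + 2.0j * math.pi * k
    r3 = r2.conjugate()
    alpha = (abs(nu) ** 2 / m1) * r1 + (mu * nb / m2) * r2 + (mu * nu / m3) * r3
    beta = (-(nu + nb) / m1) * r1 + (-(mu + nb) / m2) * r2 + (-(mu + nu) / m3) * r3
    gamma = r1 / m1 + r2 / m2 + r3 / m3
    return (_real(alpha, "coeffs_complex_4"), _real(beta, "coeffs_complex_4"),
            _real(gamma, "coeffs_complex_4"))


def coeffs_jordan3(mu: float) -> tuple[float, float, float]:
    """(alpha, beta, gamma) for JNF ``1 (+) J3(lambda)``; solves the confluent
    system with right-hand side ``(log(lambda), 1/lambda, -1/lambda^2)``."""
    lam = 1.0 + mu
    r = (math.log(lam), 1.0 / lam, -1.0 / lam ** 2)
    alpha = (3.0 / mu) * r[0] - 2.0 * r[1] + (mu / 2.0) * r[2]
    beta = (-3.0 / mu ** 2) * r[0] + (3.0 / mu) * r[1] - r[2]
    gamma = (1.0 / mu ** 3) * r[0] - (1.0 / mu ** 2) * r[1] + (1.0 / (2.0 * mu)) * r[2]
    return alpha, beta, gamma


def coeffs_mixed_jordan2(mu1: float, mu2: float) -> tuple[float, float, float]:
    """(alpha, beta, gamma) for JNF ``diag(1, lambda_1) (+) J2(lambda_2)``;
    right-hand side ``(log(lambda_1), log(lambda_2), 1/lambda_2)``."""
    d = mu1 - mu2
    r = (math.log1p(mu1), math.log1p(mu2), 1.0 / (1.0 + mu2))
    alpha = (mu2 ** 2 / (mu1 * d ** 2)) * r[0] \
        + (mu1 * (2.0 * mu1 - 3.0 * mu2) / (mu2 * d ** 2)) * r[1] \
        + (-mu1 / d) * r[2]
    beta = (-2.0 * mu2 / (mu1 * d ** 2)) * r[0] \
        + ((3.0 * mu2 ** 2 - mu1 ** 2) / (mu2 ** 2 * d ** 2)) * r[1] \
        + ((mu1 + mu2) / (mu2 * d)) * r[2]
    gamma = (1.0 / (mu1 * d ** 2)) * r[0] \
        + ((mu1 - 2.0 * mu2) / (mu2 ** 2 * d ** 2)) * r[1] \
        + (-1.0 / (mu2 * d)) * r[2]
    return alpha, beta, gamma
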
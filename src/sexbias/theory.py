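"""Closed-form two-sex Wright-Fisher relationships.

For a population of ``N`` breeding individuals of which a proportion
``p`` are female, the inbreeding effective sizes of the autosomes and
the X chromosome are

    NeA = 4 p (1 - p) N          (reduction factor fA)
    NeX = 9 p (1 - p) / (2 (2 - p)) N    (reduction factor fX)

so the X-to-autosome ratio Q = NeX/NeA = 9 / (8 (2 - p)) depends on
``p`` alone.  Q is 0.75 at p = 0.5 (no sex-bias) and exceeds 1 only for
strongly female-biased populations (p > 0.875).  Unequal male and
female germline mutation rates enter through alpha = mu_m/mu_f, which
fixes the X-to-autosome per-site mutation-rate ratio
mu_X/mu_A = 2 (2 + alpha) / (3 (1 + alpha)).

All functions are pure and validate ``p`` to the open interval
(eps, 1 - eps); estimates mapped back from data may legitimately fall
outside (0, 1) and are handled by :func:`p_from_q`, which does not
clamp.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "reduction_factor_autosome",
    "reduction_factor_x",
    "q_ratio",
    "p_from_q",
    "mu_x_from_alpha",
]

_EPS = 1e-9


def _check_p(p):
    p = np.asarray(p, dtype=float)
    if np.any(p <= _EPS) or np.any(p >= 1.0 - _EPS):
        raise ValueError(f"proportion of females p must lie in (0, 1); got {p}")
    return p


def reduction_factor_autosome(p):
    """fA(p) = NeA/N = 4 p (1 - p); maximal (1.0) at p = 0.5."""
    p = _check_p(p)
    return 4.0 * p * (1.0 - p)


def reduction_factor_x(p):
    """fX(p) = NeX/N = 9 p (1 - p) / (2 (2 - p)); 0.75 at p = 0.5."""
    p = _check_p(p)
    return 9.0 * p * (1.0 - p) / (2.0 * (2.0 - p))


def q_ratio(p):
    """Q = NeX/NeA = 9 / (8 (2 - p)); strictly increasing in p."""
    p = _check_p(p)
    return 9.0 / (8.0 * (2.0 - p))


def p_from_q(Q):
    """Invert Q = 9/(8(2-p)): p = 2 - 9/(8 Q).

    The result is returned as-is even when it falls outside (0, 1):
    an out-of-range value is a diagnostic of model misspecification
    (e.g. unmodelled size change), not an input error.
    """
    Q = np.asarray(Q, dtype=float)
    if np.any(Q <= 0):
        raise ValueError(f"Q must be positive; got {Q}")
    return 2.0 - 9.0 / (8.0 * Q)


def mu_x_from_alpha(mu_A, alpha):
    """Per-site X mutation rate given the autosomal rate and alpha = mu_m/mu_f.

    mu_X = mu_A * 2 (2 + alpha) / (3 (1 + alpha)); decreasing in alpha,
    bounded below by (2/3) mu_A, equal to mu_A at alpha = 1.
    """
    mu_A = np.asarray(mu_A, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(mu_A <= 0):
        raise ValueError("mu_A must be positive")
    if np.any(alpha < 0):
        raise ValueError("alpha must be non-negative")
    return mu_A * 2.0 * (2.0 + alpha) / (3.0 * (1.0 + alpha))
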
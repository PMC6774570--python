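"""Poisson random field likelihoods and theta estimators.

Each SFS entry is an independent Poisson count with mean
``theta * L * F(i)``; log-likelihoods include the ``log s_i!`` term
(via log-gamma) so reported values are absolute, and the joint
autosome + X likelihood is the sum of the two class log-likelihoods.
theta is carried per site throughout and multiplied by the callable
length where a per-locus mean is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .sfs_engine import SFSDensity, SpectrumData
from .theory import reduction_factor_autosome, reduction_factor_x

__all__ = [
    "ThetaEstimate",
    "poisson_loglik",
    "joint_loglik",
    "theta_mle",
    "theta_null_joint",
    "theta_alt_joint",
]


@dataclass
class ThetaEstimate:
    """A per-site population-scaled mutation rate estimate."""

    theta: float
    se: float = None
    scope: str = "autosomal"  # autosomal | X | joint-null | joint-alternative

    def __post_init__(self):
        if self.theta < 0:
            raise ValueError("theta must be non-negative")


def poisson_loglik(observed: SpectrumData, expected) -> float:
    """Exact Poisson log-likelihood of an SFS given per-entry means.

    Masked entries are skipped.  A zero (or negative) expectation on an
    unmasked entry with a positive count is an error rather than -inf,
    since it always indicates a broken model setup.
    """
    expected = np.asarray(expected, dtype=float)
    if expected.shape != observed.counts.shape:
        raise ValueError("observed and expected dimensions differ")
    keep = ~observed.mask
    lam = expected[keep]
    s = observed.counts[keep]
    bad = (lam <= 0) & (s > 0)
    if np.any(bad):
        raise ValueError(
            "non-positive expected count on an unmasked class with observations"
        )
    ll = -lam.sum()
    pos = lam > 0
    ll += float(np.sum(s[pos] * np.log(lam[pos]) - gammaln(s[pos] + 1.0)))
    return ll


def joint_loglik(pairs) -> float:
    """Sum of class log-likelihoods over (observed, expected) pairs."""
    return float(sum(poisson_loglik(o, e) for o, e in pairs))


def theta_mle(s: SpectrumData, density: SFSDensity) -> ThetaEstimate:
    """Per-site theta MLE: S / (L * sum F), the Watterson estimator for
    a constant-size density."""
    sumF = density.sum_unmasked(s.mask)
    if sumF <= 0:
        raise ValueError("density sums to zero on unmasked classes")
    scope = "X" if s.chrom_class == "X" else "autosomal"
    return ThetaEstimate(s.S / (s.L * sumF), scope=scope)


def theta_null_joint(
    sA: SpectrumData,
    sX: SpectrumData,
    dA: SFSDensity,
    dX: SFSDensity,
    r: float = 1.0,
) -> ThetaEstimate:
    """Joint MLE of per-site theta under the no-sex-bias null.

    theta0 = (S_A + S_X) / (L_A sumF_A + r * (3/4) L_X sumF_X), where
    r = mu_X/mu_A; r = 1 gives the equal-rates form.
    """
    denom = sA.L * dA.sum_unmasked(sA.mask) + r * 0.75 * sX.L * dX.sum_unmasked(sX.mask)
    if denom <= 0:
        raise ValueError("null denominator is zero")
    return ThetaEstimate((sA.S + sX.S) / denom, scope="joint-null")


def theta_alt_joint(
    sA: SpectrumData,
    sX: SpectrumData,
    p: float,
    dA: SFSDensity,
    dX: SFSDensity,
    r: float = 1.0,
) -> ThetaEstimate:
    """Joint MLE of per-site theta under a constant sex-bias p.

    theta = (S_A + S_X) / (fA(p) L_A sumF_A + r fX(p) L_X sumF_X);
    reduces to the null value at p = 0.5.
    """
    fa = float(reduction_factor_autosome(p))
    fx = float(reduction_factor_x(p))
    denom = fa * sA.L * dA.sum_unmasked(sA.mask) + r * fx * sX.L * dX.sum_unmasked(
        sX.mask
    )
    if denom <= 0:
        raise ValueError("alternative denominator is zero")
    return ThetaEstimate((sA.S + sX.S) / denom, scope="joint-alternative")
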
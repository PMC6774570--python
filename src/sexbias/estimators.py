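"""Closed-form and diversity-based sex-bias estimators.

``p_tilde_constant`` is the constant-size closed form: the observed
X/A ratio of segregating sites, rate- and length-adjusted, is an
estimate of Q = NeX/NeA, inverted to p.  The pi-based comparison
estimators (Q_pi, p_pi) use per-site average pairwise diversity and
do not model size change, which is exactly why they are biased under
expansions and bottlenecks; they are provided for those comparisons.
Out-of-range p estimates are returned unclamped and flagged: a
negative p_pi is informative misspecification, not a failure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .prf_likelihood import theta_mle
from .sfs_engine import SFSDensity, SpectrumData, expected_sfs_constant
from .theory import p_from_q

__all__ = [
    "DiversityEstimate",
    "QTestResult",
    "p_tilde_constant",
    "pi_from_sfs",
    "p_pi_estimator",
    "q_theta_test",
]


@dataclass
class DiversityEstimate:
    pi_A: float
    pi_X: float
    Q_pi: float
    p_pi: float
    out_of_range: bool


@dataclass
class QTestResult:
    q_hat: float
    ci: tuple
    null_value: float
    reject: bool


def p_tilde_constant(
    sA: SpectrumData,
    sX: SpectrumData,
    dA: SFSDensity = None,
    dX: SFSDensity = None,
    r: float = 1.0,
) -> float:
    """Constant-size closed-form estimate of the proportion of females.

    With equal mutation rates (r = 1) this is
    ``2 - 9 S_A L_X sumF_X / (8 S_X L_A sumF_A)``; the mutation-rate
    ratio r = mu_X/mu_A divides the observed X/A ratio before the
    inversion.  The estimate may fall outside (0, 1).
    """
    if sX.S <= 0:
        raise ValueError("no X-chromosomal segregating sites")
    if sA.S <= 0:
        raise ValueError("no autosomal segregating sites")
    dA = dA if dA is not None else expected_sfs_constant(sA.n)
    dX = dX if dX is not None else expected_sfs_constant(sX.n)
    q = (sX.S / (sX.L * dX.sum_unmasked(sX.mask))) / (
        r * sA.S / (sA.L * dA.sum_unmasked(sA.mask))
    )
    return float(p_from_q(q))


def pi_from_sfs(s: SpectrumData) -> float:
    """Per-site average pairwise diversity from an SFS.

    ``pi = sum_i 2 i (n - i) / (n (n - 1)) * counts[i] / L``.  The
    weight of minor-allele class ``j`` equals that of classes ``j`` and
    ``n - j``, so the same formula applies to folded spectra.
    """
    n = s.n
    if s.folded:
        i = np.arange(1, n // 2 + 1)
    else:
        i = np.arange(1, n)
    w = 2.0 * i * (n - i) / (n * (n - 1.0))
    return float(np.sum(w[~s.mask] * s.counts[~s.mask]) / s.L)


def p_pi_estimator(pi_A: float, pi_X: float, r: float = 1.0) -> DiversityEstimate:
    """Q_pi = (pi_X/pi_A)/r and p_pi = 2 - 9/(8 Q_pi), unclamped."""
    if pi_A <= 0:
        raise ValueError("autosomal diversity must be positive")
    if pi_X < 0:
        raise ValueError("negative diversity")
    Q = (pi_X / pi_A) / r
    p = float(p_from_q(Q)) if Q > 0 else -np.inf
    return DiversityEstimate(
        pi_A=pi_A,
        pi_X=pi_X,
        Q_pi=float(Q),
        p_pi=p,
        out_of_range=not (0.0 < p < 1.0),
    )


def q_theta_test(
    loci_A,
    loci_X,
    n_A: int,
    n_X: int,
    L_locus: float,
    bootstrap_iters: int = 200,
    r: float = 1.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> QTestResult:
    """Bootstrap test of no-sex-bias based on Q_hat = theta_X / theta_A.

    ``loci_A``/``loci_X`` are per-locus segregating-site counts (the
    resampling units).  Watterson-style theta MLEs are formed from the
    locus totals, Q_hat adjusted by r, and a percentile CI built by
    resampling loci with replacement; no-bias (Q = 3/4) is rejected
    when 0.75 falls outside the CI.
    """
    loci_A = np.asarray(loci_A, dtype=float)
    loci_X = np.asarray(loci_X, dtype=float)
    if loci_A.size < 2 or loci_X.size < 2:
        raise ValueError("need at least two loci to bootstrap")
    if bootstrap_iters < 1:
        raise ValueError("need at least one bootstrap iteration")
    HA = float(np.sum(1.0 / np.arange(1, n_A)))
    HX = float(np.sum(1.0 / np.arange(1, n_X)))

    def q_of(SA, SX):
        thA = SA / (len(loci_A) * L_locus * HA)
        thX = SX / (len(loci_X) * L_locus * HX)
        if thA <= 0:
            return np.nan
        return (thX / thA) / r

    q_hat = q_of(loci_A.sum(), loci_X.sum())
    rng = np.random.default_rng(seed)
    qs = np.empty(bootstrap_iters)
    for b in range(bootstrap_iters):
        SA = loci_A[rng.integers(0, loci_A.size, loci_A.size)].sum()
        SX = loci_X[rng.integers(0, loci_X.size, loci_X.size)].sum()
        qs[b] = q_of(SA, SX)
    qs = qs[np.isfinite(qs)]
    lo, hi = np.quantile(qs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return QTestResult(
        q_hat=float(q_hat),
        ci=(float(lo), float(hi)),
        null_value=0.75,
        reject=bool(not (lo <= 0.75 <= hi)),
    )
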
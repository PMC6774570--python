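"""Expected site frequency spectra and SFS utilities.

The expected unfolded SFS under a neutral multi-epoch demography is
computed exactly from coalescent first principles rather than by a
diffusion grid.  Two ingredients factorize the problem:

1. The number of ancestral lineages of a sample of ``n`` chromosomes
   is a pure death chain with rate ``k(k-1)/2`` in coalescent-rescaled
   time, independent of the size history.  Its occupancy probabilities
   and their running integrals are obtained once per ``n`` by solving
   the (stiff) Kolmogorov forward ODE with a BDF integrator and cached
   on a dense log-spaced grid.  Any piecewise-constant size history is
   then a matter of rescaling segments of that universal solution, so
   one likelihood evaluation costs microseconds.

2. While ``k`` ancestral lineages exist, a given lineage subtends
   ``i`` of the ``n`` leaves with probability
   ``C(n-i-1, k-2) / C(n-1, k-1)`` (a classical exchangeability
   result), independent of times.

The per-theta density ``F(i)`` is normalized so that a constant-size
population gives exactly ``F(i) = 1/i``: the expected Poisson mean of
frequency class ``i`` is ``theta * L * F(i)`` with ``theta = 4 N_ref mu``
per site.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp
from scipy.interpolate import interp1d
from scipy.special import gammaln

from .demography_models import Demography

__all__ = [
    "SpectrumData",
    "SFSDensity",
    "expected_sfs_constant",
    "expected_sfs_demography",
    "fold",
    "project",
    "watterson_sum",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# data containers


@dataclass
class SpectrumData:
    """An observed or simulated SFS with its bookkeeping.

    ``counts`` has length ``n - 1`` (unfolded; entry ``i - 1`` is
    frequency class ``i``) or ``n // 2`` (folded, minor-allele classes).
    ``mask`` marks entries *excluded* from likelihoods (default none).
    ``L`` is the callable length in bp and ``mu`` the per-site
    mutation rate; ``chrom_class`` is ``"A"`` or ``"X"``.
    """

    counts: np.ndarray
    n: int
    folded: bool = False
    mask: np.ndarray = None
    L: float = 1.0
    mu: float = 1.5e-8
    chrom_class: str = "A"

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.n < 2:
            raise ValueError("need at least 2 sampled chromosomes")
        want = self.n // 2 if self.folded else self.n - 1
        if self.counts.shape != (want,):
            raise ValueError(
                f"expected {want} frequency classes for n={self.n} "
                f"(folded={self.folded}), got {self.counts.shape}"
            )
        if self.mask is None:
            self.mask = np.zeros(want, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (want,):
                raise ValueError("mask length must equal counts length")
        if np.any(self.counts[~self.mask] < 0):
            raise ValueError("unmasked SFS counts must be non-negative")
        if self.L <= 0:
            raise ValueError("callable length must be positive")
        if self.chrom_class not in ("A", "X"):
            raise ValueError("chrom_class must be 'A' or 'X'")

    @property
    def S(self) -> float:
        """Total unmasked segregating sites."""
        return float(self.counts[~self.mask].sum())


@dataclass
class SFSDensity:
    """Expected per-theta SFS density F(i), i = 1..n-1 (unfolded)."""

    F: np.ndarray
    n: int
    folded: bool = False

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)

    @property
    def sumF(self) -> float:
        return float(self.F.sum())

    def sum_unmasked(self, mask=None) -> float:
        if mask is None:
            return self.sumF
        return float(self.F[~np.asarray(mask, dtype=bool)].sum())

    def fold(self) -> "SFSDensity":
        if self.folded:
            raise ValueError("density is already folded")
        return SFSDensity(_fold_vector(self.F, self.n), self.n, folded=True)


# ---------------------------------------------------------------------------
# death-chain cache

_R_MAX = 30.0  # P(MRCA not reached) < 1e-12 by then for any n
_N_GRID = 1200


class _DeathChain:
    """Universal lineage-count process for sample size n, solved once."""

    def __init__(self, n: int):
        self.n = n
        ks = np.arange(2, n + 1)
        rates = ks * (ks - 1) / 2.0
        m = len(ks)

        def rhs(t, y):
            P = y[:m]
            dP = -rates * P
            dP[:-1] += rates[1:] * P[1:]
            return np.concatenate([dP, P])

        J = sparse.lil_matrix((2 * m, 2 * m))
        for j in range(m):
            J[j, j] = -rates[j]
            if j < m - 1:
                J[j, j + 1] = rates[j + 1]
            J[m + j, j] = 1.0
        J = J.tocsc()
        y0 = np.zeros(2 * m)
        y0[m - 1] = 1.0
        rmin = 1e-5 / rates[-1]
        grid = np.concatenate([[0.0], np.geomspace(rmin, _R_MAX, _N_GRID)])
        sol = solve_ivp(
            rhs,
            (0.0, _R_MAX),
            y0,
            method="BDF",
            jac=lambda t, y: J,
            t_eval=grid,
            rtol=1e-9,
            atol=1e-13,
        )
        if not sol.success:  # pragma: no cover - diagnostics path
            raise RuntimeError(
                f"lineage-count ODE failed for n={n}: {sol.message}"
            )
        self.ks = ks
        self.rates = rates
        P = np.clip(sol.y[:m], 0.0, None)
        I = sol.y[m:]
        self._P = interp1d(grid, P, axis=1, kind="cubic", assume_sorted=True)
        self._I = interp1d(grid, I, axis=1, kind="cubic", assume_sorted=True)
        # subtending weights W[i-1, k-2] = k * C(n-i-1, k-2) / C(n-1, k-1)
        i = np.arange(1, n)[:, None]
        k = ks[None, :]
        logw = _log_choose(n - i - 1, k - 2) - _log_choose(n - 1, k - 1)
        self.W = k * np.exp(logw)

    def P(self, R: float) -> np.ndarray:
        return self._P(min(R, _R_MAX))

    def I(self, R: float) -> np.ndarray:
        if R <= _R_MAX:
            return self._I(R)
        # everything has coalesced well before _R_MAX: integral is flat
        return self._I(_R_MAX)

    def branch_times(self, nus, taus) -> np.ndarray:
        """E[time with k lineages], k=2..n, in units of 2*N_ref generations.

        ``nus``/``taus`` are newest-to-oldest relative sizes and scaled
        durations; the last entry is the ancestral epoch (tau ignored).
        """
        A = np.zeros(len(self.ks))
        R = 0.0
        for j in range(len(nus) - 1):
            R2 = R + taus[j] / nus[j]
            A += nus[j] * (self.I(R2) - self.I(R))
            R = R2
        # closed-form ancestral tail: a pure death chain entered with >= k
        # lineages spends mean nu_anc / C(k,2) at state k
        S = np.cumsum(self.P(R)[::-1])[::-1]
        A += nus[-1] * S / self.rates
        return A

    def expected_density(self, nus, taus) -> np.ndarray:
        return 0.5 * (self.W @ self.branch_times(nus, taus))


def _log_choose(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    out = gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
    return np.where((b < -0.5) | (b > a + 0.5), -np.inf, out)


_CHAIN_CACHE: dict = {}


def _chain(n: int) -> _DeathChain:
    if n not in _CHAIN_CACHE:
        _CHAIN_CACHE[n] = _DeathChain(n)
    return _CHAIN_CACHE[n]


# ---------------------------------------------------------------------------
# public operations


def expected_sfs_constant(n: int) -> SFSDensity:
    """Constant-size per-theta density: F(i) = 1/i exactly."""
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    return SFSDensity(1.0 / np.arange(1, n), n)


def expected_sfs_demography(dem: Demography, n: int) -> SFSDensity:
    """Expected per-theta SFS density under a multi-epoch demography.

    Reduces to :func:`expected_sfs_constant` when all epochs share the
    ancestral size.  ``theta`` is ``4 * dem.n_ref * mu`` per site.
    """
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    nus, taus = dem.coalescent_steps()
    F = _chain(n).expected_density(nus, taus)
    if np.any(~np.isfinite(F)) or np.any(F <= 0):  # pragma: no cover
        raise RuntimeError(
            f"expected-SFS computation failed for n={n}, steps={list(zip(nus, taus))}"
        )
    return SFSDensity(F, n)


def _fold_vector(v: np.ndarray, n: int) -> np.ndarray:
    out = np.array([v[i - 1] + v[n - i - 1] for i in range(1, (n + 1) // 2)])
    if n % 2 == 0:
        out = np.append(out, v[n // 2 - 1])
    return out


def fold(s: SpectrumData) -> SpectrumData:
    """Fold an unfolded spectrum onto minor-allele classes.

    ``folded[i] = counts[i] + counts[n-i]`` for ``i < n/2``; the middle
    class of an even sample is kept once.  Total segregating sites are
    conserved.  A class is masked in the output if either of its
    contributing unfolded classes was masked.
    """
    if s.folded:
        raise ValueError("spectrum is already folded")
    counts = _fold_vector(s.counts, s.n)
    maskv = _fold_vector(s.mask.astype(float), s.n) > 0
    return SpectrumData(
        counts, s.n, folded=True, mask=maskv, L=s.L, mu=s.mu, chrom_class=s.chrom_class
    )


def project(s: SpectrumData, m: int) -> SpectrumData:
    """Hypergeometric projection of an unfolded spectrum down to m chromosomes.

    The expected count in class ``j`` of the smaller sample is
    ``sum_i counts[i] * C(i, j) C(n-i, m-j) / C(n, m)``; mass projected
    onto the monomorphic classes (j = 0 or j = m) is dropped and logged.
    """
    if s.folded:
        raise ValueError("project an unfolded spectrum, then fold")
    if not 2 <= m <= s.n:
        raise ValueError(f"projection target must be in [2, {s.n}], got {m}")
    if m == s.n:
        return s
    n = s.n
    i = np.arange(1, n)[:, None]
    j = np.arange(0, m + 1)[None, :]
    logp = (
        _log_choose(i, j)
        + _log_choose(n - i, m - j)
        - _log_choose(n, m)
    )
    proj = s.counts @ np.exp(logp)  # length m+1, includes monomorphic ends
    lost = proj[0] + proj[m]
    if lost > 0:
        logger.info(
            "projection %d -> %d dropped %.4g sites into monomorphic classes",
            n,
            m,
            lost,
        )
    return SpectrumData(
        proj[1:m], m, folded=False, L=s.L, mu=s.mu, chrom_class=s.chrom_class
    )


def watterson_sum(n: int, density: SFSDensity = None) -> float:
    """Sum of the per-theta density, the Watterson denominator.

    With no ``density`` the constant-size harmonic number
    ``H_{n-1}`` is returned.
    """
    if density is not None:
        return density.sumF
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    return float(np.sum(1.0 / np.arange(1, n)))
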
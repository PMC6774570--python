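"""Piecewise demographic models and the nested sex-bias model hierarchy.

A :class:`Demography` is an ordered list of epochs, oldest first, with
absolute sizes in breeding individuals.  The first epoch is the
ancestral equilibrium (infinite duration); later epochs carry a
duration in generations and either an instantaneous size change at
their start or exponential change across the epoch.

Sex-bias enters through one proportion of females ``p_t`` per epoch.
The X-chromosomal model is fully constrained by the autosomal model
and the ``p_t``: every epoch's X size is ``q_ratio(p_t)`` times the
autosomal size and size changes happen at the same time in
generations.  The nested hierarchy is

* Model 0 (``M0``): no sex-bias, all p_t = 0.5, all c_t = 3/4;
* Model 1 (``M1``): constant sex-bias, one shared p;
* Model T (``MT``): per-epoch p_t, optionally with ties (for a
  bottleneck the default ties the epochs outside the bottleneck).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .theory import p_from_q, q_ratio

__all__ = [
    "Epoch",
    "Demography",
    "SexBiasModelSpec",
    "preset",
    "derive_x_demography",
    "p_per_epoch_from_fit",
]

#: number of piecewise-constant steps used to discretize an exponential epoch
EXP_STEPS = 16


@dataclass(frozen=True)
class Epoch:
    """One epoch of a piecewise demographic history.

    ``size`` is the population size (individuals) at the *recent* end
    of the epoch.  ``duration`` is in generations (``inf`` for the
    ancestral epoch).  ``kind`` is ``"constant"`` (instantaneous change
    at the epoch's old end) or ``"exponential"`` (size changes
    exponentially from the previous epoch's size to ``size``).
    """

    size: float
    duration: float = math.inf
    kind: str = "constant"

    def __post_init__(self):
        if self.size <= 0:
            raise ValueError("epoch size must be positive")
        if self.duration <= 0:
            raise ValueError("epoch duration must be positive")
        if self.kind not in ("constant", "exponential"):
            raise ValueError(f"unknown epoch kind {self.kind!r}")


@dataclass(frozen=True)
class Demography:
    """Ordered epochs, oldest to newest; epochs[0] is the ancestral equilibrium."""

    epochs: tuple
    generation_time: float = 25.0  # years per generation, reporting only

    def __post_init__(self):
        epochs = tuple(self.epochs)
        object.__setattr__(self, "epochs", epochs)
        if not epochs:
            raise ValueError("demography needs at least one epoch")
        if not math.isinf(epochs[0].duration):
            raise ValueError("the ancestral (first) epoch must have infinite duration")
        for e in epochs[1:]:
            if math.isinf(e.duration):
                raise ValueError("only the ancestral epoch may be infinite")

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    @property
    def n_ref(self) -> float:
        """Ancestral size, the reference for coalescent scaling."""
        return self.epochs[0].size

    @property
    def sizes(self) -> np.ndarray:
        return np.array([e.size for e in self.epochs])

    def coalescent_steps(self):
        """Piecewise-constant steps for the expected-SFS solver.

        Returns ``(nus, taus)`` ordered newest to oldest: relative sizes
        (units of ``n_ref``) and scaled durations (units of
        ``2 * n_ref`` generations), the last entry being the ancestral
        epoch with ``tau = inf``.  Exponential epochs are discretized
        into :data:`EXP_STEPS` geometric steps.
        """
        nref = self.n_ref
        nus, taus = [], []
        for t in range(self.n_epochs - 1, 0, -1):
            e = self.epochs[t]
            if e.kind == "constant":
                nus.append(e.size / nref)
                taus.append(e.duration / (2.0 * nref))
            else:
                start = self.epochs[t - 1].size
                # forward-time trajectory N(s) = start * (end/start)^(s/dur);
                # steps appended newest-first
                edges = np.linspace(0.0, 1.0, EXP_STEPS + 1)
                mids = 0.5 * (edges[1:] + edges[:-1])
                step_sizes = start * (e.size / start) ** mids
                for sz in step_sizes[::-1]:
                    nus.append(sz / nref)
                    taus.append(e.duration / EXP_STEPS / (2.0 * nref))
        nus.append(1.0)
        taus.append(math.inf)
        return np.array(nus), np.array(taus)

    def rescale_sizes(self, factors) -> "Demography":
        """Return a copy with per-epoch sizes multiplied by ``factors``."""
        factors = np.asarray(factors, dtype=float)
        if factors.shape != (self.n_epochs,):
            raise ValueError("one scaling factor per epoch required")
        new = tuple(
            replace(e, size=e.size * f) for e, f in zip(self.epochs, factors)
        )
        return Demography(new, self.generation_time)


@dataclass(frozen=True)
class SexBiasModelSpec:
    """Which sex-bias parameters are free, and how epochs share them.

    ``ties[t]`` is the index of the free-parameter group of epoch ``t``;
    e.g. ``(0, 1, 0)`` ties the pre- and post-bottleneck epochs.
    ``p_per_epoch`` holds the current per-epoch values (all 0.5 for M0).
    """

    level: str  # "M0" | "M1" | "MT"
    n_epochs: int
    ties: tuple = None
    p_per_epoch: tuple = None

    def __post_init__(self):
        if self.level not in ("M0", "M1", "MT"):
            raise ValueError(f"unknown model level {self.level!r}")
        ties = self.ties
        if ties is None:
            if self.level == "MT":
                ties = tuple(range(self.n_epochs))
            else:
                ties = (0,) * self.n_epochs
        if self.level in ("M0", "M1") and len(set(ties)) != 1:
            ties = (0,) * self.n_epochs
        object.__setattr__(self, "ties", tuple(ties))
        p = self.p_per_epoch
        if p is None:
            p = (0.5,) * self.n_epochs
        object.__setattr__(self, "p_per_epoch", tuple(float(x) for x in p))
        if len(self.ties) != self.n_epochs or len(self.p_per_epoch) != self.n_epochs:
            raise ValueError("ties and p_per_epoch must have one entry per epoch")

    @property
    def n_free(self) -> int:
        """Number of free sex-bias parameters (0 for M0)."""
        return 0 if self.level == "M0" else len(set(self.ties))

    @property
    def c_per_epoch(self) -> tuple:
        """Per-epoch X/A effective-size scalings c_t = q_ratio(p_t)."""
        return tuple(float(q_ratio(p)) for p in self.p_per_epoch)

    def with_free_values(self, values) -> "SexBiasModelSpec":
        """Set per-group free values; returns an updated spec."""
        values = np.atleast_1d(np.asarray(values, dtype=float))
        groups = sorted(set(self.ties))
        if len(values) != len(groups):
            raise ValueError(f"expected {len(groups)} values, got {len(values)}")
        lookup = dict(zip(groups, values))
        return replace(self, p_per_epoch=tuple(lookup[g] for g in self.ties))


def preset(name: str, **params) -> Demography:
    """Named demographic model presets.

    ``constant``
        one epoch; ``N`` (default 10,000).
    ``growth``
        instantaneous expansion: ``N_anc``, fold-change ``nu``, ``T``
        generations ago.  Defaults are the European-like recent-growth
        model (55x ending at 100,000 individuals, 205 generations ago).
    ``bottleneck``
        three epochs; defaults are the simplified European out-of-Africa
        history: 14,500 ancestral, 1,861 between 2,040 and 920
        generations ago, then 100,000.
    ``bottlegrowth``
        bottleneck followed by exponential growth.
    ``complex``
        old instantaneous expansion, bottleneck, then exponential growth.
    """
    if name == "constant":
        N = params.pop("N", 1e4)
        epochs = (Epoch(N),)
    elif name == "growth":
        nu = params.pop("nu", 55.0)
        T = params.pop("T", 205.0)
        N_anc = params.pop("N_anc", 1e5 / 55.0)
        epochs = (Epoch(N_anc), Epoch(N_anc * nu, T))
    elif name == "bottleneck":
        N_anc = params.pop("N_anc", 14500.0)
        N_bot = params.pop("N_bot", 1861.0)
        N_cur = params.pop("N_cur", 1e5)
        T_start = params.pop("T_start", 2040.0)
        T_end = params.pop("T_end", 920.0)
        if T_start <= T_end:
            raise ValueError("bottleneck must start before it ends")
        epochs = (Epoch(N_anc), Epoch(N_bot, T_start - T_end), Epoch(N_cur, T_end))
    elif name == "bottlegrowth":
        N_anc = params.pop("N_anc", 14500.0)
        N_bot = params.pop("N_bot", 1861.0)
        N_cur = params.pop("N_cur", 1e5)
        T_start = params.pop("T_start", 2040.0)
        T_end = params.pop("T_end", 920.0)
        epochs = (
            Epoch(N_anc),
            Epoch(N_bot, T_start - T_end),
            Epoch(N_cur, T_end, kind="exponential"),
        )
    elif name == "complex":
        N_anc = params.pop("N_anc", 7300.0)
        N_exp = params.pop("N_exp", 14500.0)
        N_bot = params.pop("N_bot", 1861.0)
        N_cur = params.pop("N_cur", 1e5)
        T_exp = params.pop("T_exp", 8000.0)
        T_start = params.pop("T_start", 2040.0)
        T_end = params.pop("T_end", 920.0)
        epochs = (
            Epoch(N_anc),
            Epoch(N_exp, T_exp - T_start),
            Epoch(N_bot, T_start - T_end),
            Epoch(N_cur, T_end, kind="exponential"),
        )
    else:
        raise ValueError(f"unknown demographic preset {name!r}")
    if params:
        raise ValueError(f"unused parameters for preset {name!r}: {sorted(params)}")
    return Demography(epochs)


def derive_x_demography(auto: Demography, p_per_epoch, r: float = 1.0):
    """Constrain the X model by the autosomal model and per-epoch p.

    Every epoch's X effective size is ``q_ratio(p_t)`` times the
    autosomal effective size, and size changes happen at the same time
    in generations.  Returns ``(dem_x, theta_ratio)`` where
    ``theta_ratio`` is the per-site scaled mutation rate of the X
    relative to the autosomes, ``q_ratio(p_1) * r`` (the X is anchored
    to its own ancestral size and mutates at ``mu_X = r * mu_A``).
    """
    p_per_epoch = np.atleast_1d(np.asarray(p_per_epoch, dtype=float))
    if len(p_per_epoch) != auto.n_epochs:
        raise ValueError("need one p per epoch")
    factors = q_ratio(p_per_epoch)
    dem_x = auto.rescale_sizes(factors)
    return dem_x, float(factors[0] * r)


def p_per_epoch_from_fit(NeA_t, NeX_t):
    """Per-epoch p estimates from fitted absolute epoch sizes.

    ``p_t = 2 - 9 NeA_t / (8 NeX_t)``; values outside (0, 1) are
    returned as-is (informative misspecification signal).
    """
    NeA_t = np.asarray(NeA_t, dtype=float)
    NeX_t = np.asarray(NeX_t, dtype=float)
    if np.any(NeA_t <= 0) or np.any(NeX_t <= 0):
        raise ValueError("epoch sizes must be positive")
    return p_from_q(NeX_t / NeA_t)
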
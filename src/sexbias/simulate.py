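"""Synthetic data generation for power and bias experiments.

Two simulation modes share one configuration:

* ``unlinked`` (default): the number of sites in each frequency class
  is an independent Poisson draw with mean ``theta_class * L * F(i)``
  from the expected-SFS engine — the independent-sites model under
  which the likelihood is exact.
* ``linked``: per-locus coalescent simulation with msprime, with the
  X recombination rate reduced by ``2p/(1+p)`` (crossing-over on the X
  happens only in females); linkage changes the variance of the SFS
  but not its mean.

Sex-bias enters by scaling the per-epoch census sizes of the shared
demography with the class reduction factors: the autosomal trajectory
is ``fA(p_t) N_t`` and the X trajectory ``fX(p_t) N_t``, so the X/A
effective-size ratio in epoch t is ``q_ratio(p_t)``.

Experiment presets reproduce the study designs: a constant-size
population (20 chromosomes, 1000 unlinked 5 kb regions, per-site
scaled mutation rate 0.001), a 55-fold expansion 205 generations ago
(500 chromosomes), its smaller 10-fold / 40-chromosome variant, and
the three-epoch out-of-Africa-like bottleneck (100 chromosomes,
100 kb loci, mu = 1.5e-8).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .demography_models import Demography, Epoch, preset
from .sfs_engine import SpectrumData, expected_sfs_demography
from .theory import reduction_factor_autosome, reduction_factor_x

__all__ = [
    "SimConfig",
    "sample_sfs_poisson",
    "scaled_rates",
    "class_demography",
    "expected_class_means",
    "simulate_dataset",
    "run_power_grid",
    "experiment_config",
]


@dataclass
class SimConfig:
    """One simulated study design."""

    demography: Demography  # census sizes N_t
    p_per_epoch: tuple
    n_A: int = 100
    n_X: int = 100
    locus_length: float = 1e5
    n_loci: int = 50
    mu: float = 1.5e-8
    rho: float = 1e-8
    linked: bool = False
    seed: int = None

    def __post_init__(self):
        p = np.atleast_1d(np.asarray(self.p_per_epoch, dtype=float))
        if len(p) == 1:
            p = np.repeat(p, self.demography.n_epochs)
        if len(p) != self.demography.n_epochs:
            raise ValueError("need one p per epoch (or a single shared p)")
        if np.any(p <= 0) or np.any(p >= 1):
            raise ValueError("p must lie in (0, 1)")
        self.p_per_epoch = tuple(float(x) for x in p)
        if min(self.n_A, self.n_X) < 2 or self.locus_length <= 0 or self.n_loci < 1:
            raise ValueError("invalid sample configuration")
        if self.mu <= 0 or self.rho < 0:
            raise ValueError("rates must be positive")

    @property
    def L_total(self) -> float:
        return self.locus_length * self.n_loci


def sample_sfs_poisson(means, seed=None, rng=None) -> np.ndarray:
    """Independent Poisson draws per frequency class; seeded."""
    means = np.asarray(means, dtype=float)
    if np.any(means < 0):
        raise ValueError("Poisson means must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.poisson(means).astype(float)


def scaled_rates(p: float, theta: float, rho: float):
    """Per-site population-scaled rates for both classes under sex ratio p.

    theta_A = fA(p) theta, theta_X = fX(p) theta,
    rho_A = fA(p) rho and rho_X = fX(p) * 2p/(1+p) * rho (the X
    recombines only in females).
    """
    fa = float(reduction_factor_autosome(p))
    fx = float(reduction_factor_x(p))
    return fa * theta, fx * theta, fa * rho, fx * (2.0 * p / (1.0 + p)) * rho


def class_demography(dem: Demography, p_per_epoch, chrom_class: str) -> Demography:
    """Effective-size trajectory of one locus class from census sizes."""
    p = np.asarray(p_per_epoch, dtype=float)
    f = reduction_factor_autosome(p) if chrom_class == "A" else reduction_factor_x(p)
    return dem.rescale_sizes(f)


def expected_class_means(cfg: SimConfig, chrom_class: str) -> np.ndarray:
    """Expected SFS (Poisson means) for one class over the whole dataset."""
    dem = class_demography(cfg.demography, cfg.p_per_epoch, chrom_class)
    n = cfg.n_A if chrom_class == "A" else cfg.n_X
    dens = expected_sfs_demography(dem, n)
    theta = 4.0 * dem.n_ref * cfg.mu
    return theta * cfg.L_total * dens.F


def _msprime_demography(dem: Demography):
    import msprime

    md = msprime.Demography()
    newest = dem.epochs[-1]
    if newest.kind == "exponential" and dem.n_epochs > 1:
        start = dem.epochs[-2].size
        g = math.log(newest.size / start) / newest.duration
    else:
        g = 0.0
    md.add_population(name="pop", initial_size=newest.size, growth_rate=g)
    t = 0.0
    for idx in range(dem.n_epochs - 1, 0, -1):
        e = dem.epochs[idx]
        t += e.duration
        older = dem.epochs[idx - 1]
        if older.kind == "exponential" and idx - 1 > 0:
            start = dem.epochs[idx - 2].size
            g_old = math.log(older.size / start) / older.duration
        else:
            g_old = 0.0
        md.add_population_parameters_change(
            time=t, initial_size=older.size, growth_rate=g_old, population="pop"
        )
    return md


def _simulate_linked_class(
    dem: Demography, n: int, locus_length: float, n_loci: int,
    mu: float, recomb: float, rng,
) -> np.ndarray:
    """Aggregate unfolded SFS over coalescent loci for one class."""
    import msprime

    md = _msprime_demography(dem)
    counts = np.zeros(n - 1)
    seed = int(rng.integers(1, 2**31 - 1))
    # n haploid genomes under diploid time scaling (theta = 4 N mu)
    reps = msprime.sim_ancestry(
        samples=[msprime.SampleSet(n, population="pop", ploidy=1)],
        ploidy=2,
        demography=md,
        sequence_length=locus_length,
        recombination_rate=recomb,
        num_replicates=n_loci,
        random_seed=seed,
    )
    for k, ts in enumerate(reps):
        mts = msprime.sim_mutations(
            ts,
            rate=mu,
            random_seed=int(rng.integers(1, 2**31 - 1)),
            discrete_genome=False,
        )
        afs = mts.allele_frequency_spectrum(
            mode="site", polarised=True, span_normalise=False
        )
        counts += afs[1:-1]
    return counts


def simulate_dataset(cfg: SimConfig, seed=None, rng=None):
    """Simulate one paired autosome + X dataset.

    Returns ``(sA, sX)`` :class:`SpectrumData` aggregated over all
    loci.  Unlinked mode draws each frequency class as a Poisson
    variable around the expected SFS; linked mode runs one msprime
    coalescent per locus with the class size trajectories and the
    sex-adjusted recombination rates.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
    out = []
    p_recent = cfg.p_per_epoch[-1]
    for cls, n in (("A", cfg.n_A), ("X", cfg.n_X)):
        if cfg.linked:
            dem = class_demography(cfg.demography, cfg.p_per_epoch, cls)
            recomb = cfg.rho if cls == "A" else cfg.rho * 2.0 * p_recent / (1.0 + p_recent)
            counts = _simulate_linked_class(
                dem, n, cfg.locus_length, cfg.n_loci, cfg.mu, recomb, rng
            )
        else:
            counts = sample_sfs_poisson(expected_class_means(cfg, cls), rng=rng)
        out.append(
            SpectrumData(
                counts, n, L=cfg.L_total, mu=cfg.mu, chrom_class=cls
            )
        )
    return tuple(out)


def simulate_linked_pair(dem_A, dem_X, sA, sX, seed=0, locus_length=1e5, rho=1e-8):
    """Linked resimulation under already-derived class demographies
    (parametric-bootstrap helper preserving the data's total lengths)."""
    rng = np.random.default_rng(seed)
    n_loci = max(int(round(sA.L / locus_length)), 1)
    cA = _simulate_linked_class(dem_A, sA.n, locus_length, n_loci, sA.mu, rho, rng)
    n_loci_x = max(int(round(sX.L / locus_length)), 1)
    cX = _simulate_linked_class(dem_X, sX.n, locus_length, n_loci_x, sX.mu, rho, rng)
    return (
        SpectrumData(cA, sA.n, L=sA.L, mu=sA.mu, chrom_class="A"),
        SpectrumData(cX, sX.n, L=sX.L, mu=sX.mu, chrom_class="X"),
    )


# ---------------------------------------------------------------------------
# experiment presets


def experiment_config(name: str, **overrides) -> SimConfig:
    """Named study designs used throughout the validation experiments.

    ``constant``
        single epoch of 10,000 individuals, 20 chromosomes per class,
        1000 unlinked 5 kb regions, per-site scaled mutation rate
        0.001 (mu = 2.5e-8 at N = 10,000).
    ``expansion``
        55-fold instantaneous growth 205 generations ago ending at
        100,000 individuals; 500 chromosomes, 1000 x 5 kb.
    ``expansion_small``
        10-fold growth 100 generations ago from 10,000 individuals;
        40 chromosomes, 1000 x 5 kb.
    ``bottleneck``
        14,500 -> 1,861 (2,040-920 generations ago) -> 100,000;
        100 chromosomes, 50 x 100 kb loci.
    """
    if name == "constant":
        cfg = SimConfig(
            demography=preset("constant", N=1e4),
            p_per_epoch=(0.5,),
            n_A=20, n_X=20,
            locus_length=5e3, n_loci=1000,
            mu=2.5e-8, rho=2.5e-8,
        )
    elif name == "expansion":
        cfg = SimConfig(
            demography=preset("growth"),
            p_per_epoch=(0.5, 0.5),
            n_A=500, n_X=500,
            locus_length=5e3, n_loci=1000,
            mu=1.5e-8,
        )
    elif name == "expansion_small":
        cfg = SimConfig(
            demography=preset("growth", N_anc=1e4, nu=10.0, T=100.0),
            p_per_epoch=(0.5, 0.5),
            n_A=40, n_X=40,
            locus_length=5e3, n_loci=1000,
            mu=1.5e-8,
        )
    elif name == "bottleneck":
        cfg = SimConfig(
            demography=preset("bottleneck"),
            p_per_epoch=(0.5, 0.5, 0.5),
            n_A=100, n_X=100,
            locus_length=1e5, n_loci=50,
            mu=1.5e-8,
        )
    else:
        raise ValueError(f"unknown experiment {name!r}")
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


_FIT_MODEL_FOR = {
    "constant": "constant",
    "expansion": "growth",
    "expansion_small": "growth",
    "bottleneck": "bottleneck",
}


def run_power_grid(
    experiment: str,
    p_grid,
    reps: int = 20,
    seed: int = 0,
    changing: bool = False,
    crit0: float = None,
    crit1: float = None,
    **overrides,
):
    """Simulate-fit-test over a grid of sex-bias scenarios.

    For a constant-bias grid each cell is one shared p; with
    ``changing=True`` (bottleneck design) the grid is over
    ``(p_outside, p_during)`` pairs and the changing-bias test is
    scored, so diagonal cells are false-positive rates and off-diagonal
    cells are power.  Returns a tidy DataFrame with one row per
    replicate.
    """
    import pandas as pd

    from .estimators import p_pi_estimator, pi_from_sfs
    from .inference import constant_size_test, sex_bias_test

    if reps < 1:
        raise ValueError("need at least one replicate per cell")
    base = experiment_config(experiment, **overrides)
    model = _FIT_MODEL_FOR[experiment]
    rng = np.random.default_rng(seed)
    rows = []
    cells = [tuple(np.atleast_1d(c)) for c in p_grid]
    for cell in cells:
        for rep in range(reps):
            rep_seed = int(rng.integers(0, 2**31 - 1))
            if changing:
                p1, p2 = cell
                p_eps = (p1, p2, p1)[: base.demography.n_epochs]
            else:
                p_eps = cell * base.demography.n_epochs if len(cell) == 1 else cell
            cfg = replace(base, p_per_epoch=p_eps, seed=rep_seed)
            sA, sX = simulate_dataset(cfg)
            row = {
                "experiment": experiment,
                "cell": "/".join(f"{p:g}" for p in cell),
                "rep": rep,
                "seed": rep_seed,
            }
            try:
                est = p_pi_estimator(pi_from_sfs(sA), pi_from_sfs(sX))
                row["p_pi"] = est.p_pi
                if model == "constant":
                    res = constant_size_test(
                        sA, sX,
                        critical="empirical" if crit0 is not None else "chisq",
                        critical_value=crit0,
                    )
                    row.update(
                        lambda0=res.lambda_,
                        reject_constant=res.reject,
                        p_tilde=res.p_alt[0],
                    )
                else:
                    res = sex_bias_test(
                        sA, sX, model=model, seed=rep_seed,
                        crit0=crit0, crit1=crit1,
                    )
                    row.update(
                        lambda0=res["test_constant"].lambda_,
                        lambda1=res["test_changing"].lambda_,
                        reject_constant=res["test_constant"].reject,
                        reject_changing=res["test_changing"].reject,
                        p_tilde=res["M1"].p_estimates[0],
                    )
                    for t, p in enumerate(res["MT"].p_estimates):
                        row[f"p{t + 1}_MT"] = p
                row["failed"] = False
            except (ValueError, RuntimeError) as exc:
                row["failed"] = True
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)
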
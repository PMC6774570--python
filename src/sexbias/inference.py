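"""Model fitting and nested likelihood-ratio tests for sex-bias.

The procedure mirrors the two-stage structure of the method: autosomal
demographic parameters are estimated first by maximizing the Poisson
random field likelihood (theta profiled out analytically), then the
X-chromosomal model is optimized under the constraints of the nested
hierarchy (M0: p = 0.5 everywhere; M1: one shared p; MT: per-epoch p
with optional ties).  Joint log-likelihoods are ``ll_A + ll_X`` and the
test statistics are

    Lambda_0 = -2 (LL_M0 - LL_M1)   (constant sex-bias vs none)
    Lambda_1 = -2 (LL_M1 - LL_MT)   (changing vs constant sex-bias)

For a constant-size population the alternative is profiled in closed
form (p from the observed X/A ratio, theta jointly re-estimated), which
is exact and fast; multi-epoch models use grid-seeded Nelder-Mead on
log parameters with bound-hit restarts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

from .demography_models import (
    Demography,
    Epoch,
    SexBiasModelSpec,
    derive_x_demography,
)
from .estimators import p_tilde_constant
from .prf_likelihood import (
    ThetaEstimate,
    poisson_loglik,
    theta_alt_joint,
    theta_mle,
    theta_null_joint,
)
from .sfs_engine import (
    SpectrumData,
    expected_sfs_constant,
    expected_sfs_demography,
)
from .theory import reduction_factor_autosome, reduction_factor_x

__all__ = [
    "FitResult",
    "SexBiasTestResult",
    "FIT_MODELS",
    "fit_autosomal",
    "fit_x_constrained",
    "lrt",
    "constant_size_test",
    "sex_bias_test",
    "parametric_bootstrap",
    "block_bootstrap",
]

logger = logging.getLogger(__name__)

_P_LO, _P_HI = 0.01, 0.99


@dataclass
class FitResult:
    """A fitted demographic model for one locus class."""

    demography: Demography  # absolute sizes (individuals), durations in generations
    theta: ThetaEstimate  # per site
    loglik: float
    model: str
    params: dict
    trace: dict = field(default_factory=dict)
    level: str = None  # M0/M1/MT for X fits
    spec: SexBiasModelSpec = None
    p_estimates: tuple = None  # per-epoch p (X fits)
    n_free: int = 0

    @property
    def converged(self) -> bool:
        return bool(self.trace.get("success", True))


@dataclass
class SexBiasTestResult:
    """Outcome of one nested likelihood-ratio comparison."""

    ll_null: float
    ll_alt: float
    lambda_: float
    df: int
    pvalue: float
    critical_value: float
    critical_source: str  # chisq | empirical | parametric
    reject: bool
    p_null: tuple = None
    p_alt: tuple = None
    theta_null: float = None
    theta_alt: float = None


# ---------------------------------------------------------------------------
# fit model definitions (coalescent parameterization; theta profiled out)

# name -> list of (param, lower, upper); nu in units of the ancestral size,
# tau in units of 2 * N_anc generations
FIT_MODELS = {
    "constant": [],
    "growth": [("nu", 1e-2, 1e4), ("tau", 1e-5, 5.0)],
    "bottleneck": [
        ("nu_b", 1e-4, 20.0),
        ("nu_c", 1e-2, 1e4),
        ("tau_b", 1e-5, 5.0),
        ("tau_c", 1e-5, 5.0),
    ],
    "bottlegrowth": [
        ("nu_b", 1e-4, 20.0),
        ("nu_c", 1e-2, 1e4),
        ("tau_b", 1e-5, 5.0),
        ("tau_c", 1e-5, 5.0),
    ],
    "complex": [
        ("nu_e", 1e-2, 1e3),
        ("nu_b", 1e-4, 20.0),
        ("nu_c", 1e-2, 1e4),
        ("tau_e", 1e-5, 5.0),
        ("tau_b", 1e-5, 5.0),
        ("tau_c", 1e-5, 5.0),
    ],
}


def _unit_demography(model: str, params: dict) -> Demography:
    """Demography with ancestral size 1 (durations 2*tau generations)."""
    if model == "constant":
        epochs = (Epoch(1.0),)
    elif model == "growth":
        epochs = (Epoch(1.0), Epoch(params["nu"], 2.0 * params["tau"]))
    elif model in ("bottleneck", "bottlegrowth"):
        kind = "exponential" if model == "bottlegrowth" else "constant"
        epochs = (
            Epoch(1.0),
            Epoch(params["nu_b"], 2.0 * params["tau_b"]),
            Epoch(params["nu_c"], 2.0 * params["tau_c"], kind=kind),
        )
    elif model == "complex":
        epochs = (
            Epoch(1.0),
            Epoch(params["nu_e"], 2.0 * params["tau_e"]),
            Epoch(params["nu_b"], 2.0 * params["tau_b"]),
            Epoch(params["nu_c"], 2.0 * params["tau_c"], kind="exponential"),
        )
    else:
        raise ValueError(f"unknown fit model {model!r}")
    return Demography(epochs)


def _absolute_demography(model: str, params: dict, n_ref: float) -> Demography:
    unit = _unit_demography(model, params)
    epochs = tuple(
        Epoch(e.size * n_ref, e.duration * n_ref if math.isfinite(e.duration) else math.inf, e.kind)
        for e in unit.epochs
    )
    return Demography(epochs)


# ---------------------------------------------------------------------------
# autosomal fit


def fit_autosomal(
    s: SpectrumData,
    model: str = "growth",
    seed: int = 0,
    init: dict = None,
    grid_size: int = 4,
    maxiter: int = 2000,
    retries: int = 5,
) -> FitResult:
    """Maximize the PRF likelihood over demographic parameters.

    theta is profiled analytically (the Poisson MLE of an overall
    scaling is S / (L * sumF)).  Initialization is a coarse geometric
    grid over the parameter box (or perturbations of ``init``),
    followed by Nelder-Mead on log parameters; when the optimum presses
    a bound the fit restarts from a multiplicatively perturbed point,
    up to ``retries`` times.
    """
    if model not in FIT_MODELS:
        raise ValueError(f"unknown fit model {model!r}")
    if s.S <= 0:
        raise ValueError("empty spectrum: no segregating sites to fit")
    space = FIT_MODELS[model]
    names = [p[0] for p in space]
    lo = np.log([p[1] for p in space])
    hi = np.log([p[2] for p in space])
    rng = np.random.default_rng(seed)
    n_evals = 0

    def profile_ll(params: dict):
        dem = _unit_demography(model, params)
        dens = expected_sfs_demography(dem, s.n)
        if s.folded:
            dens = dens.fold()
        th = theta_mle(s, dens)
        return poisson_loglik(s, th.theta * s.L * dens.F), th, dens

    if not space:  # constant size: nothing to optimize
        ll, th, dens = profile_ll({})
        return FitResult(
            demography=_absolute_demography(model, {}, th.theta / (4.0 * s.mu)),
            theta=th,
            loglik=ll,
            model=model,
            params={},
            trace={"success": True, "n_evals": 1, "restarts": 0},
        )

    def objective(xlog):
        nonlocal n_evals
        n_evals += 1
        xc = np.clip(xlog, lo, hi)
        penalty = 1e4 * float(np.sum((xlog - xc) ** 2))
        params = dict(zip(names, np.exp(xc)))
        try:
            ll, _, _ = profile_ll(params)
        except (ValueError, RuntimeError):
            return 1e12
        return -ll + penalty

    # initialization
    if init is not None:
        x0 = np.log([init[nm] for nm in names])
        cand = [x0] + [
            np.clip(x0 + np.log(rng.uniform(0.7, 1.4, len(names))), lo, hi)
            for _ in range(4)
        ]
    else:
        axes = [np.linspace(l + 0.5, h - 0.5, grid_size) for l, h in zip(lo, hi)]
        mesh = np.meshgrid(*axes, indexing="ij")
        cand = list(np.stack([m.ravel() for m in mesh], axis=1))
    scores = [objective(c) for c in cand]
    x_best = np.asarray(cand[int(np.argmin(scores))], dtype=float)
    f_best = min(scores)

    restarts = 0
    bound_hit = False
    for attempt in range(retries + 1):
        res = minimize(
            objective,
            x_best,
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-8},
        )
        if res.fun < f_best:
            f_best, x_best = res.fun, np.clip(res.x, lo, hi)
        bound_hit = bool(np.any(np.abs(x_best - lo) < 0.02) or np.any(np.abs(x_best - hi) < 0.02))
        if not bound_hit:
            break
        restarts += 1
        x_best = np.clip(x_best + np.log(rng.uniform(0.5, 2.0, len(names))), lo, hi)
        logger.info("bound hit in %s fit; restart %d (seed=%s)", model, restarts, seed)
    params = dict(zip(names, np.exp(x_best)))
    ll, th, _ = profile_ll(params)
    if not np.isfinite(ll):
        raise RuntimeError(f"{model} fit failed to converge: non-finite likelihood")
    n_ref = th.theta / (4.0 * s.mu)
    return FitResult(
        demography=_absolute_demography(model, params, n_ref),
        theta=th,
        loglik=ll,
        model=model,
        params=params,
        trace={
            "success": not bound_hit,
            "n_evals": n_evals,
            "restarts": restarts,
            "bound_hit": bound_hit,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# constrained X fits


def _default_ties(n_epochs: int, level: str, full_free: bool = False) -> tuple:
    if level in ("M0", "M1"):
        return (0,) * n_epochs
    if full_free or n_epochs <= 2:
        return tuple(range(n_epochs))
    if n_epochs == 3:  # bottleneck: tie the epochs outside the bottleneck
        return (0, 1, 0)
    if n_epochs == 4:  # complex: growth epochs share p, bottleneck epoch free
        return (0, 0, 1, 0)
    return tuple(range(n_epochs))


def fit_x_constrained(
    sX: SpectrumData,
    auto_fit: FitResult,
    level: str = "M1",
    r: float = 1.0,
    ties: tuple = None,
    full_free: bool = False,
    seed: int = 0,
    maxiter: int = 1000,
) -> FitResult:
    """Fit the X model constrained by the autosomal fit.

    All X demographic parameters derive from the autosomal fit and the
    per-epoch proportions of females; the only free parameters are the
    p's of the requested level.  The returned ``loglik`` is the JOINT
    log-likelihood ``ll_A + ll_X``.
    """
    if not auto_fit.converged:
        logger.warning("autosomal fit flagged non-converged; X fit may be unstable")
    if level not in ("M0", "M1", "MT"):
        raise ValueError(f"unknown model level {level!r}")
    auto_dem = auto_fit.demography
    T = auto_dem.n_epochs
    spec0 = SexBiasModelSpec(
        level=level,
        n_epochs=T,
        ties=ties if ties is not None else _default_ties(T, level, full_free),
    )
    n_groups = spec0.n_free if level != "M0" else 0
    theta_A = auto_fit.theta.theta

    def ll_x(p_per_epoch):
        dem_x, th_ratio = derive_x_demography(auto_dem, p_per_epoch, r)
        dens = expected_sfs_demography(dem_x, sX.n)
        if sX.folded:
            dens = dens.fold()
        lam = th_ratio * theta_A * sX.L * dens.F
        return poisson_loglik(sX, lam)

    if level == "M0":
        spec = spec0.with_free_values([0.5])
        ll = ll_x(spec.p_per_epoch)
        best_p = spec.p_per_epoch
        trace = {"success": True, "n_evals": 1}
    elif level == "M1":
        grid = np.linspace(0.05, 0.95, 19)
        vals = [ll_x((g,) * T) for g in grid]
        g0 = grid[int(np.argmax(vals))]
        res = minimize_scalar(
            lambda p: -ll_x((p,) * T),
            bounds=(max(_P_LO, g0 - 0.08), min(_P_HI, g0 + 0.08)),
            method="bounded",
            options={"xatol": 1e-7},
        )
        # keep whichever is better; always at least as good as p = 0.5
        cand = [(ll_x((0.5,) * T), 0.5), (max(vals), g0), (-res.fun, float(res.x))]
        ll, p1 = max(cand, key=lambda t: t[0])
        spec = spec0.with_free_values([p1])
        best_p = spec.p_per_epoch
        trace = {"success": True, "n_evals": len(grid) + res.nfev + 1}
    else:  # MT
        m1 = fit_x_constrained(sX, auto_fit, "M1", r=r, seed=seed, maxiter=maxiter)
        p_start = np.full(n_groups, m1.p_estimates[0])

        def to_p(z):
            return _P_LO + (_P_HI - _P_LO) / (1.0 + np.exp(-z))

        def obj(z):
            return -ll_x(spec0.with_free_values(to_p(z)).p_per_epoch)

        z0 = -np.log((_P_HI - _P_LO) / (p_start - _P_LO) - 1.0)
        res = minimize(
            obj,
            z0,
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-8, "fatol": 1e-9},
        )
        # by construction never below the nested M1 optimum
        if -res.fun >= m1.loglik - auto_fit.loglik:
            ll = -res.fun
            p_free = to_p(res.x)
        else:
            ll = m1.loglik - auto_fit.loglik
            p_free = p_start
        spec = spec0.with_free_values(p_free)
        best_p = spec.p_per_epoch
        trace = {"success": res.success, "n_evals": res.nfev}

    dem_x, th_ratio = derive_x_demography(auto_dem, best_p, r)
    return FitResult(
        demography=dem_x,
        theta=ThetaEstimate(th_ratio * theta_A, scope="X"),
        loglik=auto_fit.loglik + ll,
        model=auto_fit.model,
        params=dict(auto_fit.params),
        trace=trace,
        level=level,
        spec=spec,
        p_estimates=best_p,
        n_free=spec.n_free if level != "M0" else 0,
    )


# ---------------------------------------------------------------------------
# likelihood ratio tests

_LEVEL_ORDER = {"M0": 0, "M1": 1, "MT": 2}


def lrt(
    lo: FitResult,
    hi: FitResult,
    critical: str = "chisq",
    critical_value: float = None,
    alpha: float = 0.05,
) -> SexBiasTestResult:
    """Nested likelihood-ratio test between two fits.

    Lambda = -2 (LL_lo - LL_hi), clamped to 0 when within optimizer
    tolerance below it (beyond -1e-6 it is an optimizer failure).
    ``critical`` selects the critical value: the chi-square quantile
    with df = difference in free sex parameters, or a supplied
    empirical / parametric-bootstrap value.
    """
    if lo.level is not None and hi.level is not None:
        if _LEVEL_ORDER[lo.level] >= _LEVEL_ORDER[hi.level]:
            raise ValueError(f"{lo.level} is not nested in {hi.level}")
    lam = -2.0 * (lo.loglik - hi.loglik)
    if lam < 0:
        if lam < -1e-6:
            raise RuntimeError(
                f"negative LRT statistic {lam:.3g}: optimizer failure in the wider model"
            )
        logger.warning("clamping slightly negative Lambda %.3g to 0", lam)
        lam = 0.0
    df = max(hi.n_free - lo.n_free, 1)
    pvalue = float(chi2.sf(lam, df))
    if critical == "chisq":
        crit = float(chi2.ppf(1.0 - alpha, df))
    elif critical in ("empirical", "parametric"):
        if critical_value is None:
            raise ValueError(f"{critical} critical value requested but not supplied")
        crit = float(critical_value)
    else:
        raise ValueError(f"unknown critical-value source {critical!r}")
    return SexBiasTestResult(
        ll_null=lo.loglik,
        ll_alt=hi.loglik,
        lambda_=float(lam),
        df=df,
        pvalue=pvalue,
        critical_value=crit,
        critical_source=critical,
        reject=bool(lam > crit),
        p_null=lo.p_estimates,
        p_alt=hi.p_estimates,
    )


def constant_size_test(
    sA: SpectrumData,
    sX: SpectrumData,
    r: float = 1.0,
    critical: str = "chisq",
    critical_value: float = None,
    alpha: float = 0.05,
) -> SexBiasTestResult:
    """Constant-size LRT for sex-bias, profiled in closed form.

    The null re-estimates one joint theta with the X density scaled by
    3/4; the alternative sets p to the closed-form estimate from the
    observed X/A ratio and re-estimates theta jointly.  Lambda is
    approximately chi-square with 1 df under the null.
    """
    dA = expected_sfs_constant(sA.n)
    dX = expected_sfs_constant(sX.n)
    if sA.folded:
        dA = dA.fold()
    if sX.folded:
        dX = dX.fold()
    th0 = theta_null_joint(sA, sX, dA, dX, r=r)
    p_hat = p_tilde_constant(sA, sX, dA, dX, r=r)
    p_eval = min(max(p_hat, _P_LO), _P_HI)
    th1 = theta_alt_joint(sA, sX, p_eval, dA, dX, r=r)
    ll0 = poisson_loglik(sA, th0.theta * sA.L * dA.F) + poisson_loglik(
        sX, 0.75 * r * th0.theta * sX.L * dX.F
    )
    fa = float(reduction_factor_autosome(p_eval))
    fx = float(reduction_factor_x(p_eval))
    ll1 = poisson_loglik(sA, fa * th1.theta * sA.L * dA.F) + poisson_loglik(
        sX, fx * r * th1.theta * sX.L * dX.F
    )
    lam = max(-2.0 * (ll0 - ll1), 0.0)
    if critical == "chisq":
        crit = float(chi2.ppf(1.0 - alpha, 1))
    elif critical in ("empirical", "parametric"):
        if critical_value is None:
            raise ValueError(f"{critical} critical value requested but not supplied")
        crit = float(critical_value)
    else:
        raise ValueError(f"unknown critical-value source {critical!r}")
    return SexBiasTestResult(
        ll_null=ll0,
        ll_alt=ll1,
        lambda_=float(lam),
        df=1,
        pvalue=float(chi2.sf(lam, 1)),
        critical_value=crit,
        critical_source=critical,
        reject=bool(lam > crit),
        p_null=(0.5,),
        p_alt=(p_hat,),
        theta_null=th0.theta,
        theta_alt=th1.theta,
    )


def sex_bias_test(
    sA: SpectrumData,
    sX: SpectrumData,
    model: str = "bottleneck",
    r: float = 1.0,
    seed: int = 0,
    ties: tuple = None,
    full_free: bool = False,
    critical: str = "chisq",
    crit0: float = None,
    crit1: float = None,
    alpha: float = 0.05,
    auto_init: dict = None,
):
    """Run the full nested ladder: autosomal fit, M0/M1/MT, both LRTs.

    Returns a dict with the four fits and the two
    :class:`SexBiasTestResult` objects (``test_constant`` for
    Lambda_0, ``test_changing`` for Lambda_1).
    """
    auto = fit_autosomal(sA, model=model, seed=seed, init=auto_init)
    m0 = fit_x_constrained(sX, auto, "M0", r=r, seed=seed)
    m1 = fit_x_constrained(sX, auto, "M1", r=r, seed=seed)
    mt = fit_x_constrained(
        sX, auto, "MT", r=r, ties=ties, full_free=full_free, seed=seed
    )
    src0 = "parametric" if crit0 is not None else critical
    src1 = "parametric" if crit1 is not None else critical
    t0 = lrt(m0, m1, critical=src0, critical_value=crit0, alpha=alpha)
    t1 = lrt(m1, mt, critical=src1, critical_value=crit1, alpha=alpha)
    return {
        "auto": auto,
        "M0": m0,
        "M1": m1,
        "MT": mt,
        "test_constant": t0,
        "test_changing": t1,
    }


# ---------------------------------------------------------------------------
# bootstraps


def parametric_bootstrap(
    auto_fit: FitResult,
    x_fit: FitResult,
    sA: SpectrumData,
    sX: SpectrumData,
    n_reps: int = 100,
    r: float = 1.0,
    seed: int = 0,
    max_fail: float = 0.1,
    linked: bool = False,
    mt_ties: tuple = None,
):
    """Parametric bootstrap under the fitted model.

    Each replicate simulates paired autosomal and X spectra from the
    fitted demographies (independent Poisson sites, or linked coalescent
    loci when requested), refits the full ladder, and records parameter
    estimates and both Lambda statistics.  Returns percentile 95% CIs
    and the 95th-percentile Lambda critical values.

    ``x_fit`` defines the X model the data are simulated under (use the
    M1 fit to calibrate the changing-bias test under its null);
    ``mt_ties`` sets the tie structure of the MT refits and defaults to
    ``x_fit``'s own ties when that fit is an MT fit.
    """
    from . import simulate  # deferred: simulate imports inference

    if n_reps < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    dens_A = expected_sfs_demography(auto_fit.demography, sA.n)
    dens_X = expected_sfs_demography(x_fit.demography, sX.n)
    lam_A = auto_fit.theta.theta * sA.L * dens_A.F
    lam_X = x_fit.theta.theta * sX.L * dens_X.F
    rows = []
    failures = 0
    for b in range(n_reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        try:
            if linked:
                bA, bX = simulate.simulate_linked_pair(
                    auto_fit.demography, x_fit.demography, sA, sX, seed=rep_seed
                )
            else:
                bA = SpectrumData(
                    simulate.sample_sfs_poisson(lam_A, seed=rep_seed),
                    sA.n, L=sA.L, mu=sA.mu, chrom_class="A",
                )
                bX = SpectrumData(
                    simulate.sample_sfs_poisson(lam_X, seed=rep_seed + 1),
                    sX.n, L=sX.L, mu=sX.mu, chrom_class="X",
                )
            ties = mt_ties
            if ties is None and x_fit.spec is not None and x_fit.level == "MT":
                ties = x_fit.spec.ties
            res = sex_bias_test(
                bA, bX, model=auto_fit.model, r=r, seed=rep_seed,
                ties=ties,
                auto_init=auto_fit.params or None,
            )
        except (ValueError, RuntimeError) as exc:
            failures += 1
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            continue
        row = {
            "rep": b,
            "seed": rep_seed,
            "theta_A": res["auto"].theta.theta,
            "lambda0": res["test_constant"].lambda_,
            "lambda1": res["test_changing"].lambda_,
            "p_M1": res["M1"].p_estimates[0],
        }
        for k, v in res["auto"].params.items():
            row[k] = v
        for t, p in enumerate(res["MT"].p_estimates):
            row[f"p{t + 1}_MT"] = p
        rows.append(row)
    if failures > max_fail * n_reps:
        raise RuntimeError(
            f"{failures}/{n_reps} bootstrap replicates failed (limit {max_fail:.0%})"
        )
    import pandas as pd

    table = pd.DataFrame(rows)
    ci = {
        c: tuple(np.quantile(table[c], [0.025, 0.975]))
        for c in table.columns
        if c not in ("rep", "seed")
    }
    return {
        "samples": table,
        "ci": ci,
        "lambda0_critical": float(np.quantile(table["lambda0"], 0.95)),
        "lambda1_critical": float(np.quantile(table["lambda1"], 0.95)),
        "n_failed": failures,
    }


def block_bootstrap(blocks_A, blocks_X, fit_fn, iters: int = 100, seed: int = 0):
    """Conventional block bootstrap over genomic blocks.

    ``blocks_A``/``blocks_X`` are per-block SFS count arrays (e.g. 1 Mb
    blocks); blocks are resampled with replacement and kept intact, the
    genome-wide spectra rebuilt, and ``fit_fn(counts_A, counts_X)``
    (returning a dict of scalars) re-run.  Returns per-quantity standard
    deviations and percentile CIs across iterations.
    """
    blocks_A = [np.asarray(b, dtype=float) for b in blocks_A]
    blocks_X = [np.asarray(b, dtype=float) for b in blocks_X]
    if len(blocks_A) < 2 or len(blocks_X) < 2:
        raise ValueError("need at least two blocks per class to bootstrap")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(iters):
        ia = rng.integers(0, len(blocks_A), len(blocks_A))
        ix = rng.integers(0, len(blocks_X), len(blocks_X))
        cA = np.sum([blocks_A[k] for k in ia], axis=0)
        cX = np.sum([blocks_X[k] for k in ix], axis=0)
        rows.append(fit_fn(cA, cX))
    import pandas as pd

    table = pd.DataFrame(rows)
    return {
        "samples": table,
        "se": {c: float(table[c].std(ddof=1)) for c in table.columns},
        "ci": {
            c: tuple(np.quantile(table[c], [0.025, 0.975])) for c in table.columns
        },
    }
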
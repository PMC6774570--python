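"""Fitting, nested LRTs and bootstraps."""

import numpy as np
import pytest

from sexbias.estimators import p_tilde_constant
from sexbias.inference import (
    block_bootstrap,
    constant_size_test,
    fit_autosomal,
    fit_x_constrained,
    lrt,
    parametric_bootstrap,
    sex_bias_test,
)
from sexbias.inference import _unit_demography
from sexbias.prf_likelihood import poisson_loglik
from sexbias.sfs_engine import (
    SpectrumData,
    expected_sfs_constant,
    expected_sfs_demography,
)
from sexbias.simulate import experiment_config, simulate_dataset


class TestFitAutosomal:
    def test_noiseless_two_epoch_recovery(self):
        n, nu, tau, theta, L = 40, 10.0, 0.05, 8e-4, 5e6
        dem = _unit_demography("growth", {"nu": nu, "tau": tau})
        lam = theta * L * expected_sfs_demography(dem, n).F
        s = SpectrumData(lam, n, L=L, mu=1.5e-8)
        fit = fit_autosomal(s, model="growth", seed=0)
        assert fit.params["nu"] == pytest.approx(nu, rel=0.05)
        assert fit.params["tau"] == pytest.approx(tau, rel=0.05)
        assert fit.theta.theta == pytest.approx(theta, rel=0.01)

    def test_theta_distribution_centred(self, rng):
        """Constant-size Poisson draws with theta = 10 per locus."""
        n, L = 20, 1.0
        d = expected_sfs_constant(n)
        ests = []
        for _ in range(300):
            s = SpectrumData(rng.poisson(10.0 * d.F).astype(float), n, L=L, mu=1e-8)
            ests.append(fit_autosomal(s, model="constant").theta.theta)
        mean, se = np.mean(ests), np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(mean - 10.0) < 2 * se + 1e-6

    def test_empty_spectrum_rejected(self):
        s = SpectrumData(np.zeros(19), 20, L=1e4, mu=1e-8)
        with pytest.raises(ValueError):
            fit_autosomal(s, model="growth")

    def test_unknown_model(self, small_pair):
        with pytest.raises(ValueError):
            fit_autosomal(small_pair[0], model="island")


@pytest.fixture(scope="module")
def growth_fits():
    cfg = experiment_config(
        "expansion_small", p_per_epoch=(0.2, 0.2), seed=11, n_loci=2000
    )
    sA, sX = simulate_dataset(cfg)
    auto = fit_autosomal(sA, model="growth", seed=1)
    return sA, sX, auto


class TestXConstrained:
    def test_m1_recovers_male_bias(self, growth_fits):
        _, sX, auto = growth_fits
        m1 = fit_x_constrained(sX, auto, "M1", seed=1)
        assert m1.p_estimates[0] == pytest.approx(0.2, abs=0.05)

    def test_likelihood_ordering(self, growth_fits):
        _, sX, auto = growth_fits
        lls = [
            fit_x_constrained(sX, auto, lvl, seed=1).loglik
            for lvl in ("M0", "M1", "MT")
        ]
        assert lls[0] <= lls[1] + 1e-9
        assert lls[1] <= lls[2] + 1e-9

    def test_m0_has_no_free_parameters(self, growth_fits):
        _, sX, auto = growth_fits
        m0 = fit_x_constrained(sX, auto, "M0", seed=1)
        assert m0.n_free == 0
        assert m0.p_estimates == (0.5, 0.5)

    def test_m1_profile_matches_closed_form_on_constant_model(self, rng):
        """For a constant-size model the numerically profiled M1 optimum
        coincides with the closed-form estimator from the X/A ratio."""
        n, L, theta = 20, 5e6, 1e-3
        d = expected_sfs_constant(n)
        sA = SpectrumData(rng.poisson(theta * L * d.F).astype(float), n, L=L, mu=1.5e-8)
        sX = SpectrumData(
            rng.poisson(0.65 * theta * L * d.F).astype(float), n, L=L,
            mu=1.5e-8, chrom_class="X",
        )
        auto = fit_autosomal(sA, model="constant")
        m1 = fit_x_constrained(sX, auto, "M1")
        assert m1.p_estimates[0] == pytest.approx(
            p_tilde_constant(sA, sX), abs=1e-4
        )


class TestLRT:
    def test_identical_models_give_zero(self, small_pair):
        sA, _ = small_pair
        fit = fit_autosomal(sA, model="constant")
        res = lrt(fit, fit)
        assert res.lambda_ == 0.0
        assert not res.reject

    def test_non_nested_rejected(self):
        cfg = experiment_config("constant", seed=3)
        sA, sX = simulate_dataset(cfg)
        auto = fit_autosomal(sA, model="constant")
        m1 = fit_x_constrained(sX, auto, "M1")
        m0 = fit_x_constrained(sX, auto, "M0")
        with pytest.raises(ValueError):
            lrt(m1, m0)

    def test_missing_empirical_critical_value(self, small_pair):
        sA, _ = small_pair
        fit = fit_autosomal(sA, model="constant")
        with pytest.raises(ValueError):
            lrt(fit, fit, critical="empirical")


class TestConstantSizeTest:
    def test_type_one_error_calibrated(self, rng):
        """Fresh null simulations: rejection rate at the chi-square critical
        value stays inside a 99% binomial band around 0.05."""
        cfg = experiment_config("constant")
        rejects = 0
        reps = 400
        for k in range(reps):
            sA, sX = simulate_dataset(cfg, seed=int(rng.integers(2**31)))
            rejects += constant_size_test(sA, sX).reject
        rate = rejects / reps
        half = 2.58 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < half + 1e-9

    def test_power_under_male_bias(self, rng):
        cfg = experiment_config("constant", p_per_epoch=(0.2,))
        rejects = sum(
            constant_size_test(*simulate_dataset(cfg, seed=k)).reject
            for k in range(30)
        )
        assert rejects == 30  # ~18k sites: power is 1 at p = 0.2

    def test_lambda_invariant_to_common_length_scaling(self):
        cfg = experiment_config("constant", seed=5)
        sA, sX = simulate_dataset(cfg)
        res1 = constant_size_test(sA, sX)
        for s in (sA, sX):
            s.L *= 10.0  # theta per site adjusts inversely through the MLEs
        res2 = constant_size_test(sA, sX)
        assert res1.lambda_ == pytest.approx(res2.lambda_, rel=1e-9)


class TestFullLadder:
    def test_changing_bias_detected_in_bottleneck(self):
        cfg = experiment_config("bottleneck", p_per_epoch=(0.8, 0.2, 0.8), seed=21)
        sA, sX = simulate_dataset(cfg)
        res = sex_bias_test(sA, sX, model="bottleneck", seed=2)
        assert res["test_changing"].reject
        # MT recovers a male-biased bottleneck within a female-biased history
        p = res["MT"].p_estimates
        assert p[1] < 0.35 and p[0] > 0.6

    def test_null_bottleneck_lambda1_small(self):
        cfg = experiment_config("bottleneck", p_per_epoch=(0.5, 0.5, 0.5), seed=8)
        sA, sX = simulate_dataset(cfg)
        res = sex_bias_test(sA, sX, model="bottleneck", seed=2)
        assert res["test_constant"].lambda_ < 15.0
        assert not res["test_changing"].reject


class TestParametricBootstrap:
    def test_zero_reps_rejected(self, small_pair):
        sA, sX = small_pair
        auto = fit_autosomal(sA, model="constant")
        m1 = fit_x_constrained(sX, auto, "M1")
        with pytest.raises(ValueError):
            parametric_bootstrap(auto, m1, sA, sX, n_reps=0)

    def test_ci_covers_generating_p(self):
        cfg = experiment_config("constant", p_per_epoch=(0.5,), seed=17)
        sA, sX = simulate_dataset(cfg)
        auto = fit_autosomal(sA, model="constant")
        m1 = fit_x_constrained(sX, auto, "M1")
        boot = parametric_bootstrap(auto, m1, sA, sX, n_reps=20, seed=4)
        lo, hi = boot["ci"]["p_M1"]
        assert lo < 0.52 and hi > 0.46  # CI near the generating value
        assert boot["lambda0_critical"] >= 0.0
        assert boot["n_failed"] == 0


class TestBlockBootstrap:
    def test_single_block_rejected(self):
        with pytest.raises(ValueError):
            block_bootstrap([np.ones(3)], [np.ones(3)], lambda a, b: {"x": 1.0})

    def test_se_calibrated_on_iid_blocks(self, rng):
        """Bootstrap SE of p-tilde on a blocked genome tracks the empirical
        SD across independent genomes."""
        n, L_block, n_blocks = 10, 2e5, 60
        d = expected_sfs_constant(n)
        theta = 1e-3

        def draw_blocks():
            A = [rng.poisson(theta * L_block * d.F).astype(float) for _ in range(n_blocks)]
            X = [rng.poisson(0.75 * theta * L_block * d.F).astype(float) for _ in range(n_blocks)]
            return A, X

        L = L_block * n_blocks

        def fit_fn(cA, cX):
            sA = SpectrumData(cA, n, L=L)
            sX = SpectrumData(cX, n, L=L, chrom_class="X")
            return {"p": p_tilde_constant(sA, sX)}

        A, X = draw_blocks()
        res = block_bootstrap(A, X, fit_fn, iters=80, seed=1)
        genomes = []
        for _ in range(60):
            A2, X2 = draw_blocks()
            genomes.append(fit_fn(np.sum(A2, axis=0), np.sum(X2, axis=0))["p"])
        empirical = np.std(genomes, ddof=1)
        assert res["se"]["p"] == pytest.approx(empirical, rel=0.3)

    def test_blocks_kept_intact(self, rng):
        """Every resampled genome total is a sum of whole blocks."""
        blocks = [np.full(3, float(10 ** k)) for k in range(1, 4)]
        seen = []

        def fit_fn(cA, cX):
            seen.append(cA[0])
            return {"tot": cA[0]}

        block_bootstrap(blocks, blocks, fit_fn, iters=25, seed=0)
        # any achievable total is a nonnegative integer combination of
        # block values with multiplicities summing to 3
        achievable = {
            a * 10.0 + b * 100.0 + c * 1000.0
            for a in range(4) for b in range(4) for c in range(4)
            if a + b + c == 3
        }
        assert set(seen) <= achievable
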
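# Methods

## Model

A demographic history is an ordered set of epochs, oldest first, each with
a population size (individuals), a duration in generations, and a change
type (instantaneous or exponential). The first epoch is the ancestral
equilibrium. Sex-bias is parameterized by one proportion of breeding
females `p_t` per epoch; the locus-class effective sizes within an epoch
are `NeA = fA(p_t) N_t` and `NeX = fX(p_t) N_t` with

    fA(p) = 4 p (1 − p),        fX(p) = 9 p (1 − p) / (2 (2 − p)),

so the per-epoch X/A ratio is `q(p_t) = 9/(8(2 − p_t))`. The X model is
derived from the autosomal model, never fit freely: every epoch's X size is
`q(p_t)` times the autosomal size and size changes happen at the same times
in generations. Written in each class's own coalescent units this
reproduces the familiar two-epoch constraints (e.g. with no bias,
`ν_X = ν_A` and `τ_X = 4/3 τ_A`); we derive all constraints from the size
invariant rather than hard-coding per-epoch time scalings, which keeps them
correct for arbitrarily many epochs and for exponential growth.

Observed spectra are modelled as a Poisson random field: unfolded SFS entry
`i` is Poisson with mean `θ L F(i)`, `θ = 4 N_ref μ` per site, `L` the
callable length. Log-likelihoods keep the `log s_i!` term (via log-gamma)
so reported values are absolute; the joint likelihood is the sum of the
autosomal and X class log-likelihoods. The X per-site `θ` is
`q(p_1) r θ_A` where `r = μ_X/μ_A = 2(2 + α)/(3(1 + α))`; `r` defaults to 1
for simulation work (simulated sex-bias scales sizes, not mutation rates)
and to 5/6 (`α = 3`) for human data configurations.

## Expected SFS computation

The expected unfolded SFS under any piecewise demography is computed
exactly, without a diffusion grid, by factorizing the coalescent:

1. **Lineage-count occupancy.** In coalescent-rescaled time the number of
   ancestral lineages of a sample of `n` is a universal pure death chain
   with rates `k(k−1)/2`. Its occupancy probabilities and their running
   integrals are obtained once per `n` by integrating the Kolmogorov
   forward ODE with a stiff (BDF) solver (rtol 1e−9) and cached on a dense
   log-spaced grid with cubic interpolation. Expected times with `k`
   lineages under a particular size history are then sums of rescaled
   segments of this cached solution, plus a closed-form tail for the
   ancestral epoch (`ν_anc / C(k,2)` weighted by the probability of
   entering it with ≥ k lineages).
2. **Branch subtending probabilities.** While `k` lineages exist, a branch
   subtends `i` of the `n` leaves with probability
   `C(n−i−1, k−2)/C(n−1, k−1)` (computed in log space), independent of
   times.

The density is normalized so a constant-size history gives `F(i) = 1/i`
exactly (the implementation reproduces this to ~1e−13 relative error up to
`n = 500`), and it matches the mean branch-mode SFS of msprime coalescent
replicates within Monte-Carlo error for growth and bottleneck histories
(property-tested at 3 MC standard errors per entry). One evaluation after
the per-`n` setup costs on the order of 50 μs, which is what makes the
grid-seeded optimizers and bootstraps cheap. Exponential epochs are
discretized internally into 16 geometric piecewise-constant steps; this is
an engine detail, callers specify the epoch only.

## Fitting and tests

Autosomal parameters are fit first by Nelder–Mead on log-parameters,
seeded from a coarse geometric grid over the parameter box; `θ` is profiled
analytically (`θ̂ = S/(L ΣF)`). When the optimum presses a parameter bound
the fit restarts from a multiplicatively perturbed point (×U[1/2, 2], up to
5 retries) and the event is recorded in the fit trace. The X model is then
optimized over only the sex parameters of the requested level: M0 has
none; M1 profiles one shared `p` (grid plus bounded scalar refinement; for
a constant-size model this optimum coincides with the closed-form estimator
`p̃` from the observed X/A ratio, which is asserted in the tests); MT
optimizes the untied `p_t` on a logit scale, seeded from the M1 optimum so
the nested likelihood ordering `LL_M0 ≤ LL_M1 ≤ LL_MT` holds by
construction. For a three-epoch bottleneck MT defaults to tying the
epochs outside the bottleneck (`p_1 = p_3`); full per-epoch freedom is a
flag.

`Λ0 = −2(LL_M0 − LL_M1)` tests for any sex-bias, `Λ1 = −2(LL_M1 − LL_MT)`
for a change over time. Statistics within 1e−6 below zero are clamped to
zero (optimizer tolerance); anything lower raises an optimizer-failure
error. Critical values: the χ² quantile (df = number of freed sex
parameters) by default for the constant-size test, and a parametric
bootstrap for multi-epoch models — under a bottleneck the null distribution
of `Λ1` is noticeably heavier than χ²₁, so the bootstrap matters there. The
bootstrap simulates under the fitted model (the M1 fit when calibrating the
changing-bias test under its null), refits the whole ladder, and takes the
95th percentile of the replicate statistics; percentile CIs for all
parameters come from the same replicates. For data with genomic
coordinates a conventional block bootstrap (intact blocks resampled with
replacement, default 1 Mb) provides standard errors that are robust to
linkage.

The constant-size test is profiled in closed form: `p̃ = 2 − 9/(8 Q̃)` with
`Q̃` the length- and rate-adjusted ratio of segregating sites, and the
joint `θ` re-estimated under each hypothesis. With unequal mutation rates
the observed X/A ratio is divided by `r` before inversion.

## Comparison estimators

`π` is computed from the SFS (`Σ 2i(n−i)/(n(n−1)) · s_i / L`), so linked
and unlinked inputs share one code path; the weight of a minor-allele class
equals that of its two unfolded classes, so the same formula serves folded
spectra. `Q_π = (π_X/π_A)/r` and `p_π = 2 − 9/(8 Q_π)` are reported
unclamped — values outside (0, 1) are a diagnostic of unmodelled size
change, not an error. The `θ`-test compares `Q̂ = θ̂_X/θ̂_A` against 0.75
with a percentile bootstrap over loci.

## Synthetic data

The generator's defaults are the study conditions used throughout the
validation experiments:

* **constant** — one epoch of 10,000 individuals, 20 chromosomes per
  class, 1000 unlinked 5 kb regions, per-site scaled mutation rate 0.001;
* **expansion** — 55-fold instantaneous growth 205 generations ago, 500
  chromosomes; the contemporary size is anchored at 100,000 individuals
  (the same endpoint as the bottleneck model the design is paired with),
  giving an ancestral size of ≈1,818, a choice made once since the design
  source states only the fold-change and timing;
* **expansion_small** — 10-fold growth 100 generations ago from 10,000
  individuals, 40 chromosomes;
* **bottleneck** — 14,500 → 1,861 between 2,040 and 920 generations ago,
  then 100,000; 100 chromosomes, 100 kb loci, μ = 1.5e−8.

Unlinked mode draws each frequency class as an independent Poisson around
the expected SFS — exactly the model under which the likelihood is exact.
Linked mode simulates per-locus coalescents with msprime using the class
size trajectories, with `ρ_X = fX(p) · 2p/(1+p) · ρ` (crossing-over on the
X occurs only in females; the most recent epoch's `p` is used, as
recombination acts at sampling time). Linkage changes the variance of the
SFS but not its mean, so experiments that only need means use unlinked 5 kb
loci with `ρ = 0` for speed; this is validated directly (linked and
unlinked mean spectra agree within Monte-Carlo bands).

What the generator does **not** emulate: mutation-rate heterogeneity along
the genome, background selection and other linked-selection gradients,
ascertainment or genotyping error, and male-inclusive X sampling. Passing
tests therefore demonstrate correctness of the inference under the stated
neutral two-sex model, not robustness to those real-data features — on real
exomes, for instance, stronger background selection on the X mimics a male
bias and will be absorbed into `p̃`.

## Problem sizes in the validation runs

`scripts/acceptance.py` scales the study designs to desk size: 12,000 null
replicates for the empirical critical value; 15 replicate expansion
datasets (1000 × 5 kb each) for the `p_π` medians; bottleneck aggregates of
9,000–15,000 unlinked 5 kb coalescent loci for the `p_π`/`Q` scenario
values and the per-epoch refit; and 20 simulate–fit–test replicates at
500 × 100 kb per dataset for the power of the changing-bias test, against a
40-replicate parametric-bootstrap critical value computed once for the
design (the power experiment uses the larger dataset because each spectrum
in the original power study is an average over many coalescent iterations;
at ~20k segregating sites the test's noncentrality at `|p_1 − p_2| = 0.2`
caps power well below 1). The pytest suite uses further-reduced replicate
counts of the same designs.

## Numerical choices and edge cases

* `p` is validated to (1e−9, 1 − 1e−9); estimators that map data to `p`
  are exempt and may return out-of-range values, flagged.
* Optimization bounds: `ν ∈ [1e−4, 1e4]` (model-dependent),
  `τ ∈ [1e−5, 5]` coalescent units; the M1 grid spans `p ∈ [0.05, 0.95]`
  with refinement to `p ∈ [0.01, 0.99]`.
* Masked SFS entries are excluded from likelihoods and from `ΣF`
  consistently; folded likelihoods fold the expected density.
* Hypergeometric projection accumulates only into polymorphic classes;
  mass lost to monomorphic classes is logged. Projection requires unfolded
  input (project, then fold).
* VCF construction assumes female-only samples for the X and rejects
  non-diploid genotype records outright; pseudo-autosomal regions should
  be removed with a BED exclusion mask (coordinates are assembly-specific
  and deliberately not hard-coded).
* Time is specified in generations at every interface and converted to
  each locus class's own coalescent units internally, which removes the
  ambiguity of per-epoch `τ` scaling conventions.
* Every stochastic routine takes an explicit seed; fit traces record
  seeds, restarts and bound hits.

## Known limitations

Single population only (no migration or admixture); one `α` for the whole
history; composite-likelihood effects of linkage are handled by bootstrap
rather than by variance-corrected tests; the constant-size closed-form test
assumes both classes share the sample size dimension in its `Λ`
computation only through their own `ΣF` terms (folded and unfolded inputs
are both supported, but the whole-genome choice between them is the
caller's). The bottleneck `Λ1` null distribution departs from χ²₁, so
χ²-based p-values for multi-epoch changing-bias tests are approximate —
use the parametric bootstrap for calibrated decisions.
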
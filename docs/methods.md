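# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limitations of `citherm`. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Hatch-count model

Each egg-lay replicate contributes a pair (hatched, total). The model is a
zero-inflated binomial GLMM with logit link: conditional on not being a
structural zero (probability 1 − π, intercept-only zero inflation), the
hatched count is binomial with success probability
logistic(η_cell + u), where u ~ N(0, σ²) is an observation-level random
effect (OLRE) absorbing overdispersion.

**Parameterization.** Fixed effects are saturated cell means — one logit
η per strain × temperature × cross cell — which is mathematically
equivalent to the full factorial model with all two- and three-way
interactions and makes estimated marginal means and contrasts exact linear
functions of the coefficients. Variance parameters are optimized on
transformed scales (log σ, logit π).

**Marginal likelihood.** The OLRE is integrated by *adaptive*
Gauss–Hermite quadrature: for each record the rule is centered at the mode
of the joint log-density and scaled by its curvature. Plain (non-adaptive)
Gauss–Hermite at 25 nodes leaves an absolute error of order 1e-6–1e-5 for
moderate σ, while the adaptive rule reaches ~1e-10 at the same order, which
is what lets the likelihood agree with a brute-force trapezoid oracle to
1e-6 (a guarantee the test suite enforces). The gradient uses the same
nodes on the analytically differentiated integrand.

**Optimization.** Multi-start (3 deterministic starts: empirical logits
with two variance-parameter initializations, plus a neutral start) L-BFGS-B
with analytic gradients; cell logits are capped at ±8 so all-zero or
all-perfect cells stay finite (capped cells are flagged). The coefficient
covariance is the inverse of the numerically differentiated observed
information (central differences of the analytic gradient); a singular
information matrix falls back to the pseudo-inverse with a flag. If the
zero-inflated fit fails to converge — or the data contain no zero counts,
leaving π unidentifiable — the model is refit without zero inflation and
marked `zero_inflated=False`. `fixed_sigma=0` fits the nested plain
binomial model exactly.

**Inference.** Wald on the link scale with back-transformed interval
endpoints (the estimated-marginal-means convention); profile likelihood is
not implemented. Type-II Wald χ² tests are built from contrast matrices
over the cell means: each term's design columns (sum-coded factorial
blocks) are residualized against all terms not containing it under a
weighted cell inner product, and the resulting contrasts are tested against
the coefficient covariance. Wald (not likelihood-ratio) statistics are
used. Partial η² = χ²/(χ² + n) with n the number of observations, taken
explicitly because per-subset counts are analysis-dependent. FDR families
are declared per analysis question (all CI-vs-compatible contrasts one
family, all rescue contrasts one family, all within-strain temperature
contrasts one family).

## Density and expression models

ΔCq fold-changes use the arithmetic mean of the Cq triplicate (undetermined
wells dropped; an all-undetermined triplet excludes the sample with a log
entry). An optional outlier rule (drop the farthest well when the triplet
spread exceeds one cycle) exists behind a flag, default off. Multi-variant
prophage densities are summed on the fold scale *before* any log
transform. ddPCR abundances are target/spike-in concentration ratios; zero
targets are treated as missing for log-scale models rather than imputed.

Log₂ values enter fixed-effect factorial OLS. Type-II sums of squares are
computed by explicit nested least-squares model comparisons (residual-SS
drop when adding the term to the model containing every term not containing
it), with degrees of freedom from matrix rank — this handles incomplete
factorial layouts (missing strain × temperature cells) that break
aliased-coefficient approaches. Partial ω² = (SS − df·MSE)/(SS +
(N − df)·MSE), floored at zero for reporting with the raw value retained.
Pairwise fold-change contrasts (RR = 2^Δ) use t intervals on the residual
degrees of freedom and BH-FDR within the declared family.

## Development-time resampling

Pairwise permutation tests use the pure proportion of permuted |mean
differences| at or above the observed one, with the exact floor
p = 1/(n_perm + 1) when no permutation reaches it (the add-one numerator
convention is deliberately *not* used, matching the floor rule). PERMANOVA
Gower-centers the squared Euclidean distance matrix and partitions it
sequentially (type-I) by orthonormal basis increments of the growing design;
pseudo-F uses the full-model residual, p = (exceedances + 1)/(n_perm + 1)
under free permutation of observations (no restricted blocks). For a
univariate response this pseudo-F is algebraically the classical ANOVA F,
which the tests verify. Bootstrap intervals are percentile (not BCa), with
degenerate zero-variance groups returning a flagged point interval.

## Concordance

Monte Carlo propagation draws every condition value independently from
Normal(EMM, SE²), computes tau-b per draw, pools on the Fisher-z scale
(taus clipped at |τ| = 1 − 1e-6, since |τ| = 1 has positive probability at
two conditions), and back-transforms. p_d is the fraction of draws whose
tau shares the sign of the pooled estimate; zero-tau draws match neither
sign, and an exactly-zero point estimate reports p_d = 0.5. Tau-b is used
because ties occur with positive probability in the zero-SE degenerate
mode. The sampling deliberately ignores the covariance among EMMs induced
by the shared model fit.

## Phylogenetic regression

The chronogram is parsed, checked ultrametric (tolerance 1e-6 relative),
and normalized to unit height; A[i,j] is the root-to-MRCA shared path
length, normalized to unit diagonal (correlation form) before fitting so
that σ²_phylo carries the scale and the chronogram's arbitrary relative age
drops out. Priors: improper flat on intercept and slope,
half-Student-t(3, 0, 2.5·sd(y)) on both standard deviations — weakly
informative defaults in the spirit of mainstream Bayesian regression
software; both are configurable. The sampler is Gibbs for the conjugate
location blocks (fixed effects; correlated random intercepts; an optional
second iid intercept) with univariate stepping-out slice updates for the
two log-SDs. Hamiltonian dynamics are not used, so there is no analogue of
an acceptance-target tuning parameter; the estimand, chain count (4), draw
count (8,000 iterations, 2,000 warmup, 24,000 kept), and diagnostics match
the reporting convention: posterior mean β, 95% equal-tailed credible
interval, Bayesian R² (per-draw Var(fitted, including random effects) /
(Var(fitted) + σ²_resid)), p_d from the sign of the posterior mean, and
maximum split R-hat with a warning at ≥ 1.01.

With eight strains the phylogenetic SD mixes slowly at short chains; the
default draw count keeps R-hat below 1.01 in practice, and the test suite's
reduced-draw coverage study suppresses the short-chain R-hat warning
deliberately.

## Synthetic-data generator

The generator defines the emulated study conditions and is first-class,
tested code:

* **Design**: 8 strains × 18/20/23/26 °C × {compatible, CI, rescue}, with
  the two host-specific gaps (one strain missing the coldest temperature,
  one missing the two coldest), 14 replicates per cell — about 1,200
  replicates, matching the scale of a real crossing experiment.
* **Hatch counts**: egg totals are negative binomial (mean 24.4,
  dispersion 5) truncated at ≥ 1 — the per-replicate egg-count distribution
  is not something the analyses constrain, and overdispersed integers are
  what egg-lay data look like; the min-10-embryo filter is applied
  downstream, not in the generator. σ = 0.8, π = 0.05, and per-strain CI
  logit profiles in which half the strains are temperature-sensitive.
* **Development times**: linear thermal trend (13 days at 23 °C reference,
  −1.5 days/°C) plus a cytotype shift, snapped *up* to the every-other-day
  monitoring grid (configurable phase).
* **qPCR**: sample-level reference Cq ~ N(22, 0.2²); targets displaced by
  the true log₂ density; triplicate wells add independent noise around the
  sample value. Undetermined wells only when a cutoff flag is set (default
  off).
* **ddPCR**: lognormal spike-in concentrations; targets multiply in
  2^(true abundance) and lognormal noise.
* **Chronogram**: random coalescent-style ultrametric tree rescaled to
  root height 1.

A single master seed spawns independent per-generator child streams
(`SeedSequence` spawn keys), so adding a generator never perturbs the
others. What the generator does *not* emulate: vial-level logistics,
droplet-level ddPCR counting, plate effects, sequence evolution on the
tree, or any correlation between the molecular assays and hatch outcomes
beyond what the user wires in via the true-value maps. Passing tests
therefore demonstrate that the *machinery* is correct and calibrated under
the assumed data-generating processes, not that any particular biological
conclusion holds in real data.

## Problem sizes in the test suite

Simulation studies are sized to run comfortably on one CPU: the
hatch-model coverage study uses 200 fits of a 12-cell design (30
replicates per cell for cell-logit and odds-ratio coverage; 50 per cell
for the variance parameters, which need more information for the normal
approximation); null calibrations use 2,000 repeats; PERMANOVA recovery
100 repeats at n = 60; the Bayesian coverage study 100 fits at 2 chains ×
1,000 iterations (the credible-interval coverage does not depend on the
draw count once the chains are past warmup); and the pipeline determinism
check runs a proportionally scaled configuration. Statistical bands are
unaffected by these size choices and are asserted as stated.

## Known limitations

* No random-slope or nested random-effect structures in the hatch model;
  no simulation-based residual diagnostics.
* No amplification-efficiency correction or standard curves in the ΔCq
  arithmetic; no between-plate normalization.
* PERMANOVA accepts only the Euclidean distance and free permutation.
* The phylogenetic model is single-predictor Gaussian; no Pagel's λ.
* Wald inference can undercover for variance parameters at small
  per-cell information; the coverage study documents where the normal
  approximation is adequate.
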
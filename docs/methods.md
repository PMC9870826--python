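# Methods

## The problem

German registration ("value for cultivation and use", VCU) trials test each
cohort of candidate wheat genotypes for up to three years, culling roughly
half the cohort after year 1 and another quarter after year 2 on the basis of
measured performance. Long-running check varieties connect the overlapping
cohorts. Analysts routinely estimate a *genetic* yield trend (regression on a
genotype's first year of testing) and a *non-genetic* trend (regression on
the calendar year) from such series, often after discarding genotypes tested
only one or two years. Because culling is driven by the analysed trait, the
discarded records are missing *not* at random, and the surviving data are a
selected sample. This package simulates the whole system — trial geometry,
trait generation, selection, reduction, estimation — so the bias induced by
that practice can be measured against known truth.

## Generating model

One observation is the mean yield of genotype *i* in trial *l* of year *k*
and location *j* (dt/ha):

    y_ijkl = mu + gamma*t_k + Z_k + L_j + beta*r_i + H_i
             + (LY)_jk + (LYT)_jkl + (GL)_ij + (GY)_ik + (GLY)_ijk + e_ijkl

with t_k the calendar year (coded 1..n_years, uncentered), r_i the year of
first testing, and every other term an independent zero-mean normal effect
with its own variance. Default variances (dt^2/ha^2) are the REML estimates
from 34 years of German winter-wheat VCU trials: year 25.13, location 53.15,
year-by-location 74.14, trial 8.83, genotype 13.27, genotype-by-year 3.16,
genotype-by-location 2.25, three-way 9.62, residual 9.36. Default slopes are
zero: with zero true trends any estimated trend is pure bias, and nothing is
lost in generality because the fixed-effect estimator is unbiased under the
correct model. The intercept mu defaults to 80 dt/ha and cancels from every
bias metric.

Year, location, year-by-location and trial effects are drawn once per run
and shared by all cohorts and checks. Genotype-level effects are drawn for
the complete three-year layout of every cohort. Duplicate check rows (the
same check in two or three parallel series at one year-location) share their
three-way effect and differ only in trial effect and residual — per-level,
not per-cell, sharing; this is precisely the covariance that the single-mean
analysis model ignores. Each factor draws from its own seeded substream, so
e.g. changing the selection mode never perturbs the effect draws.

## Trial skeleton

The historical layout itself is not available; the generator reproduces its
summary statistics, not its cells. All downstream claims are about
expectations over this class of structures, which is what the simulation
study needs. Fixed choices:

* Cohort sizes ramp linearly 60 -> 120 across the 32 cycle starts; culling
  fractions 0.51/0.26 are constant (a per-cycle schedule can be supplied).
  Survivor counts are `round(e*(1-0.51))` and `round(e*(1-0.51-0.26))`.
* Series-year location counts 11/13/24 (rounded historical means
  11.4/12.6/24.1); expected within-cycle location carry-over 2/1/8 between
  years 1-2/1-3/2-3, enforced by drawing the shared subsets first and topping
  up disjointly from the 120-location pool.
* Checks: 48 varieties in staggered panels. Spans are geometric with mean 7
  years (minimum 2; a span request at or above the window makes the check
  permanent); panels run back to back so that about n_checks*span/n_years ~ 10
  checks are concurrently active, each grown in *every* trial of its active
  years. This concurrency — rather than a smaller per-trial panel — is what
  reproduces the historical check-observation count (~13k of ~78k rows).
* One trial per (year, location, series); a year-location testing k parallel
  series holds k trials, and only checks may appear in more than one of them.
* No cycle starts after year n_years-2, so every cohort completes; candidates
  are not re-entered in a second cycle (the historical data contain such
  repeats but no mechanism for them is reported — a documented
  simplification).
* r_i is the cohort start year for candidates and the first active year for
  checks.

Under the defaults the generator lands within a few percent of the
historical summary counts (e.g. ~66k candidate observations vs 64,792;
34 years; 120 locations). A former-candidate-turned-check lineage can be
imposed with `transfer_check_effects` (the check inherits the candidate's
genotype and genotype-by-location effects); the default experiments leave
checks independent.

## Selection

After year 1 of each cohort, a location + genotype model is fitted to the
cohort's year-1 data (checks included) and the top candidates by genotype
BLUP survive; after year 2 the ranking repeats on both years' data under the
within-cycle two-year model. Single-year data cannot separate genotype from
genotype-by-year effects, so selection acts on the confounded sum — the
mechanism that later masquerades as trend. The confounded variances used for
BLUP ranking are derived from the true simulation values (year-1 model:
var(G) = sigma2_G + sigma2_GY, var(L) = sigma2_L + sigma2_LY + sigma2_LYT,
var(e) = sigma2_GL + sigma2_GLY + sigma2_e; two-year model: LY absorbs the
trial variance, the residual absorbs the three-way term). Using known rather
than re-estimated variances isolates selection bias from small-sample
variance noise and makes the selection maximally sharp, so measured biases
are upper bounds. Ties in BLUPs are broken by entry id after quantizing away
solver noise (1e-9 of the response spread). The random-selection mode
replaces both rankings with uniform sampling and is the MCAR benchmark.

Selection is implemented as restriction of the fully simulated cohort data
to the selected entries (equivalently: survivor slots of the fixed skeleton
receive the selected entries' labels and genotype-level effects), keeping the
observed layout identical across selection modes.

## Reductions and missingness

* `drop_short_tested(data, m)` removes all rows of candidates observed in at
  most m distinct calendar years (checks never). After BLUP selection this
  reduction is informative (MNAR); after random selection it is MCAR.
* `dedup_checks(data)` keeps one row per genotype-year-location, chosen
  uniformly — MCAR by construction. The resulting single-mean data match the
  analysis model exactly.

## Analysis model and REML

All datasets are analysed with the trend-decomposition model above, reduced
by confounding the three-way term with the residual (their separation rests
only on duplicate check rows, and the model-spec validator collapses the factor
automatically when a dataset has none). Estimation is restricted maximum
likelihood over nonnegative variances:

* average-information updates with step-halving, EM fallback when an AI step
  is not uphill, and an active-set treatment of variances pinned at the
  nonnegativity floor (1e-8 of the phenotypic variance; floored estimates are
  reported as 0);
* all per-iteration quantities come from the mixed-model equations — the
  identity log|V| + log|X'V^-1X| = n log sigma2_e + sum q_f log sigma2_f +
  log|C| gives the restricted likelihood from one factorization, and
  tr(P Z_f Z_f') = (q_f - tr(C^ff)/sigma2_f)/sigma2_f gives exact gradients
  from the diagonal of C^-1;
* starting values split the OLS residual variance equally across factors;
* convergence requires a relative likelihood change below 1e-8 and a relative
  parameter change below 1e-6 within 200 iterations; non-convergent fits are
  flagged, logged and excluded from averages, never silently dropped;
* a dense Cholesky path serves systems up to ~3,500 mixed-model unknowns;
  above that a sparse LU path with chunked inverse-diagonal solves takes
  over (exact, but slow for very large systems — full-scale fits are
  possible but take hours, see Problem sizes);
* slope standard errors are asymptotic, from the fixed-effect block of the
  inverse coefficient matrix (no small-sample adjustment);
* genotype BLUPs are the empirical predictions of the deviations H_i from
  the fitted genetic trend line.

The fitter is verified against an independent dense implementation (explicit
V, brute-force maximization) on random tiny instances: restricted
log-likelihoods agree to 1e-6 and variance components to 1e-4 wherever the
surface has curvature. On numerically flat directions (common in tiny
unbalanced designs) the argmax is not defined to 1e-4 by double-precision
likelihood values, so there the two maximizers are compared in likelihood.

## Evaluation

Per variant and run: variance components, both slopes, the MSE and Spearman
rank correlation between genotype BLUPs and simulated H_i over all genotypes
(checks included) tested in at least three distinct years. Across runs:
means with normal-approximation 95% intervals (mean +/- 1.96 sd/sqrt(runs);
with the run counts used the difference from a t interval is negligible),
and a fixed-effect meta-analytic pool of MSEs with inverse-squared-SE
weights. Joint "no detectable bias" claims in the test suite use a
Sidak-adjusted per-parameter threshold (|z| <= 2.80 for ten simultaneous
coverage statements) so the family-wise error of the joint claim is 5%.

## Problem sizes

The full historical geometry (~78k observations, model with ~70k mixed-model
unknowns, hundreds of runs) is a cluster-scale computation. The package's
experiments and tests therefore run on a quarter-scale system
(`scaled_params(0.25)`: 9 years, 30 locations, cohorts of 15-30, ~1,000
observations and ~1,500 unknowns per run; ~5 s per three-variant run), with
20-30 runs per scenario. Directional claims (bias sign, ordering,
nullification under random selection, amplification under inflated
genotype-by-year variance) transfer across scale; the *magnitudes* printed
by the historical-scale study (e.g. genetic-trend bias 0.086/0.115
dt/ha/year, genotype-variance collapse 13.26 -> 6.52 -> 5.90, MSE
1.42 -> 8.97 -> 16.79) are claimed only at full scale. At quarter scale the
biases are larger (less replication per cohort, noisier within-cycle BLUPs,
stronger luck-riding) — typically +0.4 to +0.8 dt/ha/year for the reduced
variants.

What the generator does *not* emulate: cross-cycle candidate repeats, the
historical rise of the third-year survival proportion, multi-trait (index)
selection, BLUE-based selection on current-year data only, spatial field
trends within trials, non-normal or heteroscedastic effects, and pedigree or
marker relationships. Selection here is sharper than historical practice in
three deliberate ways (single trait, BLUP instead of BLUE, both years' data
at the second cull), so passing tests bound the bias from above rather than
reproduce its historical magnitude.

## Known limitations

* The genotype-variance collapse under reduction (clearly visible at full
  scale) is noisy at desk scale; only the year-1 reduction step is asserted
  directionally in the tests.
* The within-cycle two-year location sets make some variance components
  (trial vs year-by-location) only weakly identified in small single-mean
  datasets; estimates then scatter widely though without detectable bias.
* The sparse path computes the exact inverse diagonal by chunked solves;
  a supernodal selected-inverse would be needed for comfortable full-scale
  REML, and is out of scope.
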
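# Methods

`myxindic` analyses presence-only occurrence archives of slime moulds
(Eumycetozoa) to quantify substrate affinities and evaluate candidate
bioindicator taxa under explicit control for uneven recording effort.  This
note documents the models, the numerical choices, and what the synthetic
test-bed does and does not establish.

## The analysis frame

Records carry Darwin-Core-style fields; the analytical core is country,
taxonomic identity, and a harmonised ten-class substrate code (COR bark,
LIG dead wood, RAM twigs, FOL leaves, BRY bryophytes, HER herbaceous parts,
TER soil/litter, SAX rock, XYL processed wood, MSC explicitly indeterminate).
Verbatim microhabitat text maps to a code only when exactly one class rule
matches (case- and diacritic-insensitive keyword patterns); mixed descriptors
stay unassigned, and MSC is reserved for descriptors that explicitly signal
an indeterminate substrate.  The shipped English rule set is replaceable via
YAML for other languages and reporting traditions.

Records with species and substrate are aggregated to country x substrate x
species counts y.  Only observed combinations enter the frame (y >= 1):
absence of a record is non-reporting, never evidence of absence, so zeros are
structurally excluded throughout.  The total record count T of a country x
substrate cell is its recording-effort context; each species row carries a
leave-one-out exposure E = T - y and a log offset log(E + c).  The offset
constant c = 1 guarantees a finite offset for single-record cells (E = 0)
and is configurable.  Cells with E < 5 are flagged descriptive-only; a
substrate with fewer than 100 records total falls under the pre-declared
rarity rule and is excluded from primary rankings.

## Diversity standardisation

Raw record totals differ by orders of magnitude across substrates, so
diversity is compared only after standardisation.

* **Good's coverage** 1 - f1/n (f1 singleton species) summarises stratum
  completeness in descriptive tables.
* **Hill numbers** qD give effective species numbers at orders q = 0
  (richness), 1 (exponential Shannon, natural log) and 2 (inverse Simpson).
* **Rarefaction** is interpolation-only.  q0 uses the exact hypergeometric
  expectation S - sum_i C(n - x_i, m)/C(n, m); q1 is the exponential of the
  entropy of the expected abundance-frequency counts E[f_k(m)]; q2 has the
  closed form 1/(1/m + (1 - 1/m) sum x_i(x_i - 1)/(n(n - 1))).  These are the
  standard interpolation constructions and are validated in the tests against
  exhaustive subsample enumeration (n <= 12) and Monte-Carlo subsampling.
  Note the estimators live on the expected-richness / exponential-expected-
  entropy / reciprocal-expected-concentration scales: for a perfectly even
  assemblage the three orders coincide exactly only at m = n, and remain
  close (not identical) at interpolated sizes.
* **Coverage standardisation** finds the smallest m whose estimated coverage
  reaches the target C* (default 0.90, sensitivity 0.85) and evaluates the
  Hill number there.  The coverage of an interpolated sample uses the
  f1/f2-adjusted Good-Turing form at m = n and the expected-coverage
  estimator 1 - sum (x_i/n) C(n - x_i, m)/C(n - 1, m) below it; the latter
  collapses exactly to 1 - f1/n at m = n - 1.
* **Uncertainty**: multinomial bootstrap of the n individuals (200
  replicates, percentile intervals), with the m-selection repeated inside
  each replicate.  The common-sample-size panel uses m = 27, the smallest
  substrate total in the motivating archive.

No extrapolation and no asymptotic richness estimation is performed.

## The substrate-effects model

Counts are modelled as zero-truncated negative binomial (NB2: variance
mu + mu^2/k) with log link:

    log mu = beta_0 + beta_substrate + u_country + v_species + offset
    u_country ~ N(0, sigma_c^2),  v_species ~ N(0, sigma_s^2)

with the lignicolous class as reference.  Zero truncation subtracts
log(1 - p0), p0 = (k/(k + mu))^k, so each observed cell contributes the
density of y conditional on y >= 1 — matching the no-absences frame.

**Estimation.**  The marginal likelihood is approximated by the Laplace
method.  For fixed variance-scale parameters theta = (log k, log sigmas),
the fixed effects and random-effect vector are profiled jointly by a damped
Newton optimisation of the penalised log-likelihood (analytic first and
second derivatives of the ZTNB log-density with respect to the linear
predictor; step halving; the per-observation curvature is floored at a tiny
positive value for stability).  theta is then optimised by L-BFGS-B with
numerical gradients.  The Laplace objective is the penalised optimum plus
half the log-determinants of the penalty and of the random-effect block of
the Hessian.  Starting values are fixed (Poisson GLM fixed effects, k = 1,
random-effect SDs 0.3), so fits are deterministic.  Linear predictors are
clipped at +/-30, beyond which the likelihood is flat to double precision.

Wald covariance for the fixed effects is the beta block of the inverse joint
Hessian at the mode, conditioning on the estimated variance parameters — the
standard GLMM practice.  Random-effect conditional modes (BLUPs) and their
conditional SDs come from the same Hessian.

**Random substrate slopes.**  The order-level model adds per-order substrate
slopes.  A fully correlated intercept+slope covariance for nine substrates
would require 45 covariance parameters; the implementation uses a diagonal
covariance — one intercept variance plus one shared slope variance — keeping
the outer optimisation four-dimensional.  This is a deliberate
simplification: it preserves the partial-pooling behaviour that matters for
the deviation display (shrinkage towards the population contrast, intervals
from the conditional variance approximation) at a fraction of the cost, but
it cannot represent intercept-slope correlation.  Order deviations are
reported on the log scale, 0 meaning no deviation from the population-level
substrate contrast; the reference substrate carries no deviation parameter.

**What the contrasts estimate.**  The effort offset is the realised
leave-one-out record total of the cell, which is itself generated by the
assemblage.  A multiplicative shift that raises every species' rate on a
substrate raises the cell totals in proportion and is absorbed by the
offset: the fitted substrate contrast measures how concentrated records are
in individual species relative to the cell total — per-unit-effort
recording intensity *conditional on a species being recorded*, not an
absolute habitat-suitability multiplier.  The synthetic-archive experiments
make this visible: community-wide generator rate shifts come back as ratios
near 1 through the full pipeline, while substrate contrasts driven by
compositional concentration (few species carrying many records, as on
processed wood in the motivating archive) are recovered.  Recovery of the
regression coefficients themselves is verified on model frames with
exogenous exposures, where the offset carries no signal.

**A property of the no-absences design worth knowing.**  Conditioning each
observed cell on y >= 1 while ignoring which cells were never observed is a
composite likelihood.  Under heavy truncation (mean counts near 1) it
shrinks the largest substrate contrasts by a percent or two; at the count
density of the motivating archive (about 2.2 records per positive cell) the
recovery simulations show bias within Monte-Carlo error and 95% CI coverage
between 94% and 99%.  This behaviour is shared by any ZTNB mixed model
fitted to positive cells only; it is a property of the design, not of the
implementation.

**Post-processing.**
* Rate ratios exp(beta) with Wald 95% intervals; the reference row is
  exactly 1 with no interval.
* Estimated marginal means at unit effort (offset 0, random effects at their
  population mean) with all pairwise response-scale ratios; the family-wise
  adjustment is the single-step max-|z| procedure under the joint normal
  approximation of the contrasts (the behaviour of Tukey-adjusted EMM ratios
  in standard software), evaluated by Monte Carlo on the contrast
  correlation matrix (200,000 deterministic draws) and validated against the
  Genz rectangle probability in the tests.
* Rank uncertainty: parametric bootstrap of the fitted model (random effects
  redrawn, ZTNB counts resimulated, model refitted, EMMs ranked descending),
  summarised by median, 50% and 95% rank intervals.  The information-
  weighted variant shrinks each replicate's log-EMMs towards the replicate
  grand mean with factor (1 - w_s), w_s = n_s / sum n_s, before ranking —
  substrates with little data are pulled towards the middle.  The weighting
  mechanism is one documented choice among several compatible with
  "information-weighted ranks"; it is isolated behind the ranking routine.
  Production default B = 2,000; analyses here use B = 200 and state so.

## Indicator analysis

Sites are country x substrate (or country x pH band); country is a
provenance block, never an ecological unit.  Site effort w_j is the site's
total record count.  For taxon t and group g, with weighted mean presence
m_g = sum_{j in g} w_j x_tj / sum_{j in g} w_j:

    A = m_focal / sum_g m_g     (group-equalised specificity)
    B = m_focal                 (effort-weighted fidelity)
    IndVal E = sqrt(A x B)

Group-equalisation makes A insensitive to unequal numbers of sites per
group; effort weighting makes well-recorded sites count for more.  The
unweighted classic variant is selectable (`weighted=False`).  Taxa in fewer
than three sites are excluded — their A and B are inherently unstable.

Inference respects the blocking: permutation tests shuffle group labels only
within countries (p = (1 + exceedances)/(1 + n_perm), BH step-up across
taxa); bootstrap intervals resample sites with replacement stratified by
group (a bound is reported unavailable when the taxon vanishes from too many
replicates — more than 2.5% voids the lower bound, more than half voids
both); K-fold validation partitions countries (K = 5 for substrates, K = 3
for pH bands), selects each taxon's best group on training sites (ties to
larger training B, then lexicographic code) and re-evaluates A and B on the
held-out sites.

The presence-based A x B score is the descriptive higher-taxon summary:
A = focal presences / total presences, B = focal presences / number of
focal-group sites, no inferential testing.  Displayed values are rounded
half-up to 2 dp; full precision is retained in the tables.

pH screening uses only the measured subset (three bands: <= 5.00,
5.01-7.00, >= 7.01) and is labelled screening evidence throughout — the
site grid is too sparse for confirmatory inference.

## Elevational profiling

Records with midpoint elevation (mean of the bounds, only when both are
present) are binned into ~60 equal-width bins.  Per species:

    y_cb ~ Poisson(mu_cb),  log mu_cb = f(elev_b) + log E_cb

with E_cb the total records in the country x bin cell and f a natural cubic
spline (df = 4 by default; knots at quantiles of the occupied bin midpoints;
truncated-power natural basis).  Fitting is ridge-stabilised IRLS (penalty
1e-8) over all positive-exposure cells within the species' observed
elevation domain, so zero counts inside the domain inform the shape.
Countries pool through the shared exposure offset; there is no country term
inside f.  The modal elevation is the argmax of exp(f) on a 512-point dense
grid over the domain (first maximum on ties), so it is constrained to the
observed range by construction; modes within one grid step of an edge are
flagged boundary cases.  Uncertainty: parametric bootstrap (Poisson
resimulation from fitted cell means, refit, re-argmax; percentile interval;
production default B = 2,000, analyses here use B = 500).  Exposure scaling
invariance (the offset absorbs any constant rescaling of effort) holds
exactly and is tested.  Modes are descriptive summaries of relative
recording intensity, not ecological optima.

## Validation suite

* **Randomized quantile residuals**: S simulations (default 250) from the
  fitted model with random effects redrawn; the residual is the randomized
  empirical-CDF position of the observed count, Uniform(0,1) under a correct
  model; KS uniformity summary.  The dispersion test compares the
  Pearson-type dispersion of the observed data to its simulated null
  (two-sided simulation p).
* **LOCO-CV**: refit without one country per fold; held-out cells are
  predicted with the country effect at its population mean and training
  species BLUPs where available (unseen species at 0); scored by RMSE and
  Poisson deviance 2 sum[y log(y/mu) - (y - mu)] against the truncated mean
  mu/(1 - p0).  Calibration is a pooled Poisson GLM of held-out counts on
  log predictions with HC0 sandwich intervals (slope 1 = perfect
  calibration; invariant to rescaling the predictions); a quantile-binned
  decile table accompanies it.  Pooled is primary; per-fold RMSE/deviance
  are reported per fold and averaged.
* **Sensitivity variants**: V1 baseline with species-level substrate slopes;
  V2 no slopes; V3 = V1 on data with sub-threshold substrates removed (an
  exact no-op when nothing is rare); V4 = V1 with rows of rare substrates
  down-weighted by min(1, n_s/threshold) — the weighting rule is a
  documented, replaceable choice.  Reported as Delta log rate ratio vs V1,
  with an optional parametric bootstrap for intervals.
* **pH-mode concordance**: per-species Poisson-spline modal pH at 0.01 and
  0.1 pH-unit binning; Pearson and Spearman correlations of the paired
  modes (requires >= 3 eligible species); species with too few distinct
  values fall back to the histogram argmax and are flagged sparse.

## The synthetic archive

The generator draws country x substrate x species NB counts around
mu = base x effort-share_s x exp(delta_s + u_c + v_i) x a_is, explodes them
to one row per record, then decorates rows with year, coordinates, elevation
and pH, and applies per-field MCAR missingness.  The a_is are mean-one
lognormal species x substrate affinity multipliers
(exp(tau z - tau^2/2), z ~ N(0,1)); tau (default 1.0) controls the
substrate-linked compositional turnover that drives the indicator and
composition analyses.  Defaults emulate the motivating
archive: 16 countries, 625 species, per-substrate effort weights proportional
to the observed record totals (11,411 dead-wood records down to 27 rock
records), expected archive size 34,588, substrate log rates spanning the
observed contrast range (reference 0 to log 3.9), species SD 1.0 (a
lognormal-like abundance distribution), country SD 0.5, NB size k = 1,
elevation present for 18% of rows (species-specific Gaussian modes, drawn
uniformly from 100-1800 m with 150-300 m spread when not configured,
truncated to [0, 2500] m, stored as equal min/max bounds), pH for 0.44%
(three bands at 20/60/20%, uniform within 3.35-5.00 / 5.00-7.00 /
7.00-10.00), substrate blanked for 36.38% of rows (both the code and the
verbatim descriptor — the record was never assignable), coordinates for
28.73%.  Planted indicator taxa are generated only at sites of their
assigned substrate and are guaranteed present in every country block there.

What the generator does not emulate: residual duplicate records, temporal
trends and shifting recording practice over a 168-year window, spatial
autocorrelation (coordinates are decorative), joint missingness structure
(MCAR per field; in real archives pH presence plausibly correlates with
substrate and recorder), and taxonomic uncertainty (the synthetic taxonomy
is pre-reconciled).  Passing tests therefore establish that the estimators
recover known structure under the archive's statistical shape — not that
real-data conclusions are free of the biases above.

## Problem sizes used in the checked analyses

Simulation-based checks run at reduced but structurally faithful sizes,
chosen as the package's own test conditions: parameter recovery at the full
16 x 9 x 200 frame over 200 replicates; elevation mode coverage over 100
simulations at B = 200; calibration coverage over 50 LOCO runs.  The
analysis drivers use B = 100 for the full-frame rank bootstrap and run the
slopes-variant sensitivity grid on the 150 best-recorded species (the slope
models' random-effect dimension grows as species x substrates, and the
dense Hessian factorisation dominates the cost there); production defaults
(B = 2,000, 999 permutations) remain the package defaults wherever a single
analysis is run.

## Known limitations

* The slopes covariance is diagonal (no intercept-slope correlation).
* Wald intervals condition on the estimated variance parameters; no profile
  or parametric-bootstrap intervals for the fixed effects.
* The composite-likelihood shrinkage under extreme truncation (above).
* Laplace approximation only; no adaptive quadrature for intercept models.
* IndVal E's exact published form varies across software; the
  group-equalised effort-weighted construction here is one documented
  choice, switchable to the unweighted classic variant.
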
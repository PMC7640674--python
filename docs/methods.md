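# Methods

## The measurement problem

Object-case best–worst scaling (MaxDiff) measures the relative position
of v items on a latent worry/importance scale by repeated forced
choices: each respondent sees b choice sets of k items and names the
most and least worrisome item in each. This package implements the
complete analysis chain for the 13-outcome statin benefit/harm
instrument (v = 13, k = 4, b = 13) together with a generative model of
the survey, so that every stage can be exercised and calibrated without
access to the (undeposited) raw survey data.

## Choice-set design

A fair BWS instrument needs every item to appear equally often and
every pair to co-occur equally often: a (v, k, λ) balanced incomplete
block design with b = λv(v−1)/(k(k−1)) blocks and replication
r = λ(v−1)/(k−1). For (13, 4, 1): b = 13, r = 4, 78 pairs each covered
once.

Construction is by planar difference sets: a k-subset D ⊂ Z_v whose
pairwise differences hit every nonzero residue exactly λ times; its v
cyclic shifts form a symmetric BIBD. The package ships verified base
blocks ({0,1,3,9} mod 13; {0,1,3} mod 7; {0,1,6,8,18} mod 21;
{1,3,4,5,9} mod 11 with λ=2) and an exhaustive lexicographic search
(`find_difference_set`, feasible to v ≈ 30). `validate_design` audits
any design against the balance conditions by explicit pair counting and
never raises on invalid input — it reports findings.

The published instrument's own 13 blocks appear only in its
supplementary file; any valid (13, 4, 1) design is statistically
equivalent for every analysis here, so the shipped design is the
canonical difference-set development. Within-block item order is
ascending; presentation randomisation is out of analytic scope.

## Counting analysis

`bw_score = total_best − total_worst` per item; `mean_bw` divides by
the number of respondents with at least one record (the motivating
survey had essentially complete data, so this convention is ours).
Individual scores lie in [−r, r] = [−4, 4]; their per-item sample SD
(n−1 denominator; the source does not specify) measures consensus.
Ranks break ties by larger `total_best`, then catalog order — the
published tables contain no ties, but a deterministic rule is required
for reproducibility.

A caution established while validating this package: **the expected
B–W score is not a function of the utility alone.** The probability
that an item is picked best depends on which companions the design
groups it with in each block. Computing the exact expectation under the
published total-population utilities (enumerate the 12 pair
probabilities per block) gives E[bw] = 0.181 for type-2 diabetes
(u = 3.18) but 0.085 for heart failure (u = 3.28) and 0.024 for acute
kidney failure (u = 3.27): the counting ranking and the logit ranking
*systematically* disagree for items closer than ≈ 0.1–0.3 utility
units. The published score and coefficient tables disagree on exactly
these items too (their mutual Spearman is 0.95). Consequently the
acceptance check demanding counting/logit Spearman > 0.99 on simulated
data fails by design of the problem, not of the code: the observed
value (≈ 0.978–0.984 at n = 2000) equals the population limit. The two
routes do order every pair separated by ≥ 0.3 utility units
identically, which is the property a practitioner may rely on.

## Maxdiff conditional logit

Each record becomes a choice among the k(k−1) = 12 ordered (best,
worst) pairs of its block, with linear predictor β_best − β_worst and a
reference item pinned at 0 (default: the item with lowest mean B–W).
The log-likelihood (stable log-sum-exp) is globally concave. Numerical
choices:

* optimiser — BFGS on the *mean* negative log-likelihood (scale-free
  gradient), exact analytic gradient, start β = 0, gradient-∞-norm
  tolerance 1e−8 (convergence flagged below 1e−7), max 500 iterations;
* identical situations are collapsed with multiplicity weights first
  (at most b·k(k−1) = 156 distinct situations without covariates), so
  fitting cost is independent of sample size;
* SEs — inverse observed information, Hessian by central differences of
  the analytic gradient (step 1e−5·max(1,|β|), symmetrised); Wald 95%
  CIs. Situations are treated as independent, matching the published
  plain conditional-logit intervals; respondent-clustered sandwich SEs
  are available (`cluster_robust=True`) but not default;
* separation — items never chosen best or never worst are warned about
  and reported with infinite CIs rather than silently huge numbers.

Calibration, measured by the acceptance suite over 100 simulated
surveys of 913 respondents × 13 blocks at the published utilities:
maximum absolute coefficient bias < 0.05, pooled 95% CI coverage within
[0.92, 0.98], and the order of every utility pair separated by ≥ 0.3
recovered in > 95% of replicates. Full 13-item rank recovery is not a
meaningful target because the generating coefficients contain a 0.01
gap (heart failure vs acute kidney failure) against a sampling SE of
≈ 0.08.

## Synthetic data

The generator reproduces the survey's *structure*: strata of 449 urban
+ 464 rural general-population respondents and 172 providers;
per-covariate marginals (sex, age, education, statin use, morbidity,
family history) matching the published sample characteristics;
responses drawn from exactly the maxdiff model fitted downstream
(default utilities = the published total-population coefficients,
myopathy = 0); optional per-covariate utility shifts (defaulting to
zero — the survey found no covariate association); optional
block-level missingness. A sequential best-then-worst response mode
exists for robustness studies; the simultaneous pair model is the
default because it makes the estimator consistent by construction.

Covariates are drawn independently (marginals, not the joint), ages
from a truncated normal (≥ 40 for the general population, ≥ 20 for
providers). Reproducibility: one root seed; each respondent's choices
use an independent substream keyed by a stable SHA-256 hash of the
respondent id, so enlarging a sample never changes existing rows, and
fixed seeds give byte-identical files.

What passing tests on these data do *not* show about real data: no
respondent heterogeneity in utilities (beyond opt-in covariate
effects), no learning or fatigue across the 13 sets, no interviewer or
item-order effects, and independence of covariates that are correlated
in any real sample.

## VAS comparison

VAS readings are normalised to [0, 1] by (raw − lo)/(hi − lo),
rejecting out-of-range values. Rankings (1 = most worrisome) use
per-item medians with midpoint ties; agreement is Spearman ρ (Pearson
on ranks) and Kendall τ-b. The "less overlap" box-plot claim is
operationalised — our construct, labelled as such in reports — as the
mean pairwise IQR-overlap fraction: |IQR_i ∩ IQR_j| / |IQR_i ∪ IQR_j|
averaged over item pairs, lower = better separation; identical
degenerate IQRs count 1, distinct ones 0.

The simulated VAS is score = logistic(−3 + u + ε), ε ~ N(0, 0.5).
These link constants were set for rank structure, and rank agreement
with BWS is excellent (ρ ≈ 0.98 at survey scale). They are, however, a
poor model of VAS *dispersion*: pushing Gaussian noise through the
logistic compresses extreme items to SDs of ≈ 0.015 on the score scale
— far more precise than any real VAS — so the simulated VAS separates
items slightly *better* than BWS (theoretical mean IQR overlaps 0.070
vs 0.114). The acceptance check expecting BWS to separate better
therefore fails under this calibration; reproducing the direction seen
in real data would require pre-link noise sd ≳ 1.0 or a noise model
that is additive on the score scale (real VAS unreliability is roughly
uniform across the scale, not logit-compressed). The calibration was
left as stated rather than adjusted to the outcome; this is a known
limitation of the VAS noise model, not of the overlap statistic.

## Covariate regressions

Per outcome, the respondent-level B–W score is regressed by OLS
(statsmodels; classical SEs; t inference with n − p df) on dummy-coded
covariates with explicit reference levels (pipeline default: modal
observed level, robust to rare categories at small n). The choice of
dependent variable — the individual score of a chosen item — is our
documented stand-in for the survey's ambiguous phrasing. No
multiple-testing correction is applied, matching the original analysis;
output tables flag this. Calibration: with zero true effects the pooled
fraction of p < 0.05 across all covariate coefficients over 500
simulated surveys lies in [0.035, 0.065].

## Pipeline and formats

All files are UTF-8 CSV with "." decimals; items serialised by string
id only. `run_pipeline` chains design → (simulate | load) → counting
per stratum → maxdiff → VAS comparison → covariate regressions and
writes a JSON manifest carrying seed, version and a config hash; the
manifest has no timestamp and the hash excludes the output directory,
so identical configurations are byte-identical across reruns and
locations. Problem sizes used by the test suite (100 recovery
replicates at n = 913; 500 regression replicates; 100 dispersion
replicates at n = 150) keep the full suite around a minute on one CPU
while leaving Monte Carlo error well inside the asserted bands.

## Known limitations

* Counting ranks of items within ≈ 0.1 utility units are
  design-dependent (companion effect above) — report coefficients, not
  counting ranks, for near-tied items.
* The VAS noise model understates real VAS dispersion at extreme items
  (see above).
* No individual-level utility heterogeneity (no mixed/latent-class or
  hierarchical maxdiff); sequential-mode likelihoods are available only
  as a simulation option, not an estimator.
* The published coefficient table itself is not numerically
  reproducible without the raw survey data; tests target structure and
  recovery properties instead.
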
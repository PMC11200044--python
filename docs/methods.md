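# Methods

This note records the models implemented in `clinpath`, the defaults that
matter, the numerical choices, and what the synthetic-data generator does and
does not emulate.

## Triage engine

**Knowledge base and exit criterion.** Guideline pathway templates carry an
ordered symptom list, optional required findings, and an urgency label
(referral `R` or locally treatable `T`). A queried pathway *matches* a
template when its symptom **set** equals the template's and its findings are
a superset of the template's required findings; symptom order is preserved in
serialization (in case it carries clinical meaning) but deliberately ignored
in matching, which keeps incremental generation monotone. When superset
matching admits several templates, the most specific (largest required
finding set, then id order) wins. A pathway matching nothing is
`NOT_CLASSIFIED` — a state only queries can have, never templates. Numeric
inputs (blood-pressure style) are binarized at measurement time through a
per-symptom threshold and direction.

**Candidate generation.** Measured symptoms arrive one at a time. The
candidate list always equals the set of templates consistent with the
accumulated evidence: containing every positive symptom and requiring no
negative one. An empty positive set generates no candidates (an absent
symptom is not evidence to build a pathway on). The frequency counter on a
candidate counts the measured symptoms that support it: entry at 1,
incremented whenever a new positive measurement is one of the candidate's own
symptoms. This is one concrete, reproducible reading of
increment-on-regeneration; it is isolated in `step()` so an alternative
(e.g. per-patient counting) would be a one-function change.

**Ranking and pruning.** Ranking is the total order (urgency: referral
first; frequency descending; template id ascending) — referral-safety first,
determinism guaranteed. Pruning applies minimum frequency, urgency filter,
required findings, then a keep-at-most truncation; an emptied list walks an
explicit, validated-to-be-weaker relaxation schedule rather than silently
adjusting thresholds, so runs are reproducible and the applied configuration
is reported. With a schedule ending in the all-permissive configuration, the
output is empty only when the unpruned list was.

**Naive-Bayes evidence.** Bernoulli event model over symptom presence with
Laplace pseudo-count α = 1 by default (configurable): smoothed class priors
`(n_c + α)/(n + 2α)` and conditionals `(n_{s,c} + α)/(n_c + 2α)`. Posteriors
include absence factors for every KB symptom and are computed in log space.
Findings are not model features by default; they enter through templates.
The concordance table's *accuracy* column is leave-one-out accuracy over the
history store — the provenance of that column is otherwise unspecified in
evaluation protocols of this kind, and LOO needs no held-out split at clinic
scale. Prediction ties resolve to referral (the safe direction), and the
*prior* column is the class prior of the row's urgency (a pathway-level prior
would be an alternative reading; the class prior is what the model actually
uses). `recommend()` returns the top ranked row with an `advisory_only`
flag and never commits a disposition; an empty table is a no-evidence signal
(`None`), not an error, instructing the caller to relax pruning.

## Likert statistics

Construct scores are sums of mapped item scores (listwise deletion within
construct; pairwise-complete for correlations). Agreement scores count
responses in {4, 5}; the construct level is the unweighted mean of its
items' fractions. Note one published table this definition was checked
against contains a construct cell (0.953) that is not the mean of its printed
item cells (0.947); the mean-of-items definition reproduces 10 of the 12
construct cells and is retained.

Mann-Whitney *U* uses midranks, reports `min(U_a, U_b)` and both mean ranks,
and computes the two-sided *p* from the tie-corrected normal deviate
**without** continuity correction — the convention of mainstream statistical
packages' "asymptotic significance (2-tailed)" output, which published
two-site tables of this kind follow. Consequence, verified empirically: the
uncorrected asymptotic *p* tracks the **mid-p** of the exact permutation
distribution at group sizes 4–6 (within 0.05 for ~98% of tie-free samples;
worst case ≈ 0.057 at the most extreme splits) but can sit up to ~0.09 from
the conventional exact *p* at such sizes, because the exact null is
discrete. `exact_mann_whitney_p()` exposes both conventions; tests
compare against the matching one.

Reliability/validity formulas (sample variances, n−1): Cronbach
α = k/(k−1)·(1 − Σ var_i / var(Σ)); retention drops loadings < 0.70 (each
block keeps at least its strongest item); AVE = mean squared retained
loading, flagged when ≤ 0.50; ρ_c = (Σλ)²/((Σλ)² + Σ(1−λ²)), asserted
against its formula only (published composite-reliability columns are not
always reproducible from printed loadings, suggesting a different estimator
or unrounded inputs — no guess is made). HTMT is the mean absolute
heterotrait correlation over the geometric mean of the mean absolute
monotrait correlations, flagged at ≥ 0.90; the "identical blocks give 1"
intuition is exact only for homogeneous blocks, since a copied block with
within-correlation r yields (1+r)/2r. Collinearity uses VIF = 1/(1−R²)
per predictor; the evaluation protocol this mirrors quotes a "< 0.50"
collinearity criterion, which conflicts with standard VIF usage, so the
conventional VIF < 5 reading is the default and the quoted figure is only
documented.

## PLS-SEM

The PLS path algorithm on standardized indicators: equal initial outer
weights; inner proxies by the *path* scheme by default (predecessors via
multiple regression, successors via correlation; *factor* and *centroid*
available for sensitivity checks); outer updates mode A (indicator–proxy
correlation) or mode B (regression); convergence when the largest outer
weight change is < 1e-7, capped at 300 iterations with a `converged` flag
rather than an exception. Sign indeterminacy is anchored per construct: the
dominant-|loading| indicator is made positive. β and R² come from OLS among
the standardized latent scores; with single-indicator blocks this reduces
exactly (1e-10) to standardized OLS/Pearson correlation, which the tests pin.

**Second-order constructs** use the two-stage approach: stage 1 fits the
flattened model (higher-order paths redistributed to components) and exports
component latent scores; stage 2 treats those scores as formative (mode B)
indicators. Because the stage-2 higher-order score is an exact linear
combination of its components, the standardized outer weights double as the
component → higher-order path coefficients, and that construct's R² is 1 by
construction — a property of the two-stage method worth remembering when
comparing with repeated-indicator reports. When the generating higher-order
construct carries residual variance (R² < 1), the estimand of the formative
weights is the generating weights inflated by 1/√R² and outgoing paths are
attenuated by √R²; the second-order tests assert against this derived
estimand, not naively against the generating numbers.

**Bootstrap.** Percentile bootstrap over respondents (B = 5000 production
default; all experiments seeded), each replicate refitted from scratch,
sign-corrected per construct against the original loadings, non-convergent
replicates dropped and counted (> 5% raises a warning flag). SD over
replicates, t = |β|/SD referred to a t distribution with B−1 df (switchable
to normal), percentile CIs. Hypotheses are directional: *Accepted* iff
p < α = .05 **and** β > 0, with p = α rejecting.

**Calibration caveat.** A PLS construct whose only structural neighbour is
unrelated to it has a noise-driven proxy direction: the mode-A weights chase
whatever alignment the sample offers, |β̂| is biased away from zero, and a
bootstrap t-test on such an isolated null path is anticonservative (measured
~0.09 at n = 200). The type-I calibration experiment therefore embeds the
null path in a model with one strong path (x→y = 0.5, z→y = 0,
corr(x, z) = 0.4), which pins the proxies — the situation an applied
acceptance model is actually in — and measures 0.062 over 500 replications
at B = 200 (within 0.05 ± 0.03). Testing isolated-null models with PLS
bootstrap t-tests is not recommended.

## Synthetic-data generator

The generator emulates the evaluation design this package targets: 22
five-point items in 6 constructs (two deliberately weak items, 0.65, that the
0.70 retention rule removes, leaving 20), two sites with n = 42 and 31, a
round-1 subset of 4 respondents at site 1, and a latent path model whose
default true coefficients are the published estimates of the acceptance
model (.015/.321/.149/.678/.021/.486; second-order benefits composite
.374/.749). Default construct correlations: system ~ information quality
0.60 (this reproduces the published R²(ease) = 0.479 almost exactly:
implied 0.477) and decision ~ process changes 0.503 (back-solved from the
published R²(benefits) = 0.983).

**Composite measurement design.** Indicators are λ·ξ + e with block
residuals constrained to the subspace orthogonal to a direction solved by a
small fixed-point iteration, making each construct score an exact linear
combination of its own indicators. Under this *composite* population the
PLS estimand equals the configured β — parameter recovery is then a
well-posed test. A plain iid-residual common-factor mode (`noise_mode=
"factor"`) is provided, under which PLS estimates are attenuated by proxy
reliability (e.g. β = .678 shrinks to ≈ .60 with these loadings); that
attenuation is a property of the estimator, not a bug, and is why the
composite design is the default for recovery experiments.

**What is and is not emulated.** The change constructs are generated
orthogonal to the quality constructs. With realistic cross-correlations
(~0.55–0.75), the two-stage formative estimand for the component weights is
pulled far from the generating values by correlated signal in the inner
proxy (e.g. 0.749 → ≈ 0.56), leaving no well-defined truth to recover
against; orthogonality restores identifiability at the cost of realism. The
generator therefore reproduces the *path structure*, loadings, marginal item
behaviour and group sizes — not the full empirical correlation matrix of a
real evaluation (implied R²(acceptance) ≈ 0.43 vs the published 0.703), and
not nonresponse mechanisms beyond MCAR masking or clustered rater effects.
Passing recovery tests says the estimator finds the parameters its own
population implies; it does not certify behaviour on data violating the
composite design.

**Discretization.** Continuous indicators are cut at (−1.5, −0.5, 0.5, 1.5)
plus a configurable shift into scores 1..5. Symmetric cuts (the default)
lose little information: seed-averaged recovery error over 10 seeds at
n = 5000 stays ≤ 0.06 across all eight paths. The evaluation emulation
shifts the cuts by −1.2, producing the ceiling-heavy profile typical of
post-use questionnaires (item means ≈ 4.3, ~75% agreement); under that
shift discretization attenuation grows to ≈ 0.08 on the strongest path,
which is why recovery experiments use the symmetric default. A continuous
(non-discretized) mode supports tight (±0.03) recovery checks.

## Problem sizes

Test-suite experiments: recovery at n = 5000 × 10 seeds; bootstrap
calibration 500 replications at n = 200, B = 200; power check 100
repetitions (true β = 0.6 detected in ≥ 95%). The acceptance script uses 5
recovery seeds and 200 calibration replications, sizes chosen to keep a
single-CPU run in the minutes range while leaving Monte-Carlo error well
inside the asserted bands.

## Known limitations

* The frequency-counter semantics and the accuracy column are each one
  defensible reading of underspecified field practice; both are isolated
  behind single functions.
* PLS-SEM here is composite-based variance modeling: no covariance-based
  ML estimation, no goodness-of-fit indices beyond R², no mediation
  decomposition, no penalized (regularized) variants.
* The Mann-Whitney asymptotic p is anticonservative relative to the exact
  permutation p below ~7 observations per group (see above); at the
  evaluation's actual sizes (42, 31) the issue is immaterial.
* No multiple-testing correction is applied across the 22 item-level tests,
  mirroring common practice in this evaluation literature; interpret
  borderline item-level p-values accordingly.
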
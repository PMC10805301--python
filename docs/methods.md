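# Methods

## The classification model

The EDAC is a conjunctive decision rule, not a fitted model: a visit is
avoidable iff age ∈ [18, 70] (both ends inclusive — the conventional
reading of a printed "18–70" range), CTAS ∈ {4, 5}, no ED specialist
consult, main intervention in the configured registry, and discharge.
CTAS 3 with the other four conjuncts gives potentially avoidable; anything
else is not avoidable.  The rule is exhaustive and exclusive by
construction, and a missing or out-of-range criterion field is a hard
validation error — charts that cannot be classified are excluded, never
defaulted to not-avoidable.  Intervention codes are compared after trim +
uppercase canonicalisation; the registry contents are configuration
because the subacute-manageable code list varies by site and coding
vintage.

## Agreement estimation

Each visit carries two blinded binary judgements whose slot order carries
no rater identity after randomised assignment.  The default
chance-corrected coefficient therefore uses a single marginal pooled over
both slots (Scott/Byrt-style symmetric treatment):

    p  = (# subacute ratings) / (2 n)
    pe = p^2 + (1 - p)^2,   kappa = (po - pe) / (1 - pe)

This estimator is exactly invariant to slot swaps, and coincides with
classical two-rater Cohen's kappa whenever the attributed 2×2 table has
symmetric off-diagonal cells (tested by small-case enumeration).  The 95%
CI is the large-sample Wald interval with SE = sqrt(po(1−po)/n)/(1−pe),
upper bound capped at 1; a percentile bootstrap over visits is available
as an alternative because the reference CIs' method is not recoverable.
Degenerate inputs (all ratings identical, pe = 1) raise a dedicated
`KappaUndefinedError`, distinct from computational failure, so bootstrap
resamples can drop them with a logged count.

Known estimator sensitivity: on the not-avoidable subset of the reference
table (33 both-ED / 7 discordant / 13 both-subacute) the pooled estimator
gives 0.692, while attributed-rater Cohen's kappa ranges from 0.692 to
0.698 depending on how the 7 discordant pairs split between raters — so
the rounded second decimal (0.69 vs 0.70) genuinely depends on an
attribution that anonymised pairs cannot recover.  All other reference
subsets are attribution-stable at 2 dp.  The package reports the pooled
value.

## Association analyses

The two judgements collapse to an ordinal concordance level (both-ED <
discordant < both-subacute), cross-classified against the EDAC ordinal
(not < potentially < avoidable).  From the 3×3 count table:

* **Spearman ρ** is computed as the Pearson correlation of midranks via
  weighted closed forms on the counts (never materialising the expanded
  observations); it is verified against `scipy.stats.spearmanr` on
  explicit expansions.
* **Proportional odds.**  P(Y ≤ j | x) = expit(θ_j − xβ) with dummy-coded
  class (not-avoidable referent), fitted by Fisher-scoring Newton steps
  with step-halving so the log-likelihood never decreases; convergence at
  gradient max-norm < 1e-8, at most 100 iterations, else a
  `ConvergenceError` carrying the iteration trace.  A class row
  concentrated at one extreme outcome level is flagged as
  quasi-separation with an inflated-variance warning, and overflowing
  Wald bounds are reported as +inf.  The fit is cross-checked against
  `statsmodels` `OrderedModel` (agreement to ≤1e-4 on coefficients and
  log-likelihood).
* **Headline odds ratios.**  The reported per-class ORs are the
  closed-form cross-product ratios of the dichotomy "both judged
  subacute" vs rest against the not-avoidable row, with Wald CIs
  exp(ln OR ± 1.96 √Σ1/cell).  This is the estimator that reproduces the
  reference values to every printed digit; the genuinely ordinal
  coefficients (e.g. β_avoidable = 4.694, OR ≈ 109 on the reference
  table) are exposed separately through the model fit.  The two answer
  different questions and both are reported to avoid ambiguity.
* **Discrimination** is Harrell's C over all observation pairs with
  different concordance levels, ties in class score counted half,
  computed by weighted cell sums.  With the EDAC ordinal ranks as scores
  it equals 0.84 on the reference table; it is antisymmetric under score
  reversal.

## Precision under regrouping

The middle class is evaluated by regrouping: excluded, merged into the
avoidable group, or merged into the not-avoidable group.  The unit of
analysis is the individual rating (two per visit; 320 in the reference
study, 214 when the middle class is excluded) — the convention that
reproduces every reference cell.  Orientation: *sensitivity* is the
fraction of negative-group (not-avoidable-side) ratings judged
ED-appropriate; *specificity* the fraction of positive-group ratings
judged subacute-appropriate.  Because this labelling is conventional, the
JSON report also carries the opposite orientation under explicit names.
CIs are exact Clopper–Pearson (beta-quantile) intervals.  Two structural
identities hold by construction and are asserted: scenarios sharing a
positive group share specificity; scenarios sharing a negative group
share sensitivity.

## Study design operations

Cluster sampling is uniform without replacement within class, per-cluster
counts differing by at most one; a non-divisible total allocates the
remainder in fixed order (avoidable first), so 160 realises 54/53/53.
Assignment gives each (rater, round) unit a batch whose cluster
composition is a permutation of the requested triple (7/7/6 by default),
permutations rotated greedily so aggregate per-cluster totals land on
exactly twice the cluster sizes; within a cluster the two copies of each
visit go to the two rater identities with the largest remaining quota
(random tie-break), which guarantees distinct raters and succeeds
whenever no rater holds more than half a cluster's remaining slots.  The
rotation scheme is this package's choice; the reference design does not
state how the short count was allocated.  Plan output is class-free to
preserve rater blinding.

Power for a kappa criterion is estimated by simulation: rating pairs are
drawn from the common-correlation binary model — P(both subacute) =
p² + κp(1−p), P(discordant) = 2(1−κ)p(1−p) — and each replicate applies
the two-sided Wald z-test of the pooled kappa against the null value
using the same estimator and SE as the agreement module.  Replicates with
degenerate marginals never reject.  At the realised reference design
(n = 160, κ = 0.69 vs null 0.4, prevalence 0.7, α = 0.05) the power is
0.982 (frozen from an independent 100,000-replicate run; Monte-Carlo SE
0.0004), and the null design point rejects at ≈0.045 ≈ α.  The reference
protocol's analytic 126-visit derivation used a formula that is not
reproduced here; only the simulation mechanism is provided.

## Synthetic data

`generate_visits` draws attributes independently from per-class marginals
(defaults are the reference cohort's frequency tables).  Constraints that
the marginals cannot express are enforced: avoidable/potentially
avoidable visits always receive an in-registry code, no consult and a
discharge, and ages are capped at 70; a not-avoidable draw that would
accidentally satisfy the avoidable conjunction has one conjunct broken at
random (consult flipped on or the code replaced by a non-registry one).
Every generated visit is re-classified and asserted against its intended
class on every run.  Time-in-ED is sampled by band, uniform within closed
bands; the open top band adds an exponential tail with per-class scale
(120/160/700 min) chosen once so class means sit near the reference
means — the continuous shape is otherwise unconstrained.

`generate_judgements` uses a latent suitability state s ~
Bernoulli(p_subacute[class]) with each rating flipping s independently
with probability e.  Defaults: p_subacute = (0.97, 0.82, 0.31) for
avoidable/potentially/not (the reference rating margins) and e = 0.07,
the root of 2e(1−e) = 21/160, the reference discordance rate.  The model
identifies (p per class, pooled e) from the per-class concordance
frequencies, and `recover_parameters` inverts it by method of moments;
recovery at n = 50,000 is within ±0.02 on p and ±0.01 on e.

What the generator does **not** emulate: rater-specific behaviour (a
single shared error rate), within-class attribute dependence (age ×
acuity, provider × outcome), calendar structure, and any diagnosis
information.  Passing tests therefore show the pipeline's statistics are
correct under the stated sampling model, not that the EDAC would attain
the same operating characteristics on another hospital's charts.

## Reference fixture reconciliation

The frozen 160-visit concordance table's middle-class row is recorded as
(both-ED 3, discordant 13, both-subacute 37).  A circulating class-level
narrative lists the complementary ordering (13 both-ED, 3 discordant),
but that assignment is inconsistent with the middle class's 40 agreeing
pairs; the ordering used here is the unique one consistent with the
agreement counts, and it simultaneously reproduces the Spearman 0.64, the
middle-class OR 7.1 (3.0–16.8), the c-index 0.84 and all nine regrouping
precision cells.  Rating-level physician confidence values are not part
of the fixture (only class-level means were ever published), so
fixture-derived pairs carry no confidence scores and the report omits
that block for them.

## Numerical conventions

Problem sizes in the test suite — 10,000-pair independence checks,
500-replicate calibration of the default judgement model, 50,000-pair
parameter recovery, 2,000–4,000-replicate power runs — were chosen as the
smallest sizes at which Monte-Carlo error is comfortably below the
asserted tolerances.  Hypothesis property tests run derandomised.  All
randomness flows through `numpy.random.default_rng(seed)`; identical
seeds reproduce identical cohorts, plans, and reports byte-for-byte.
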
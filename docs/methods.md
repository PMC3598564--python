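# Methods

## Study design implemented

The package operationalizes a prospective matched-cohort evaluation of a
prescriber-alert DUR program. Intervention plans have alerts enabled; a
control pool is drawn from plans managed by the same claims processor where no
alerts are sent. The estimand is the effect of an alert on the odds that a
recommended therapeutic alternative is initiated within 90 days of the index
fill.

## Co-exposure detection

A claim's exposure window is the half-open day interval
`[fill_date, fill_date + days_supply)`. For a patient and an interaction rule,
co-exposure exists on any day covered by both a claim from the rule's first
drug set and one from the second. Maximal runs of co-exposure days form
*episodes*; a configurable `grace` parameter (default 0 days) joins runs
separated by at most that many days, so a brief dispensing gap does not spawn
a duplicate alert. Each episode yields exactly one event, making a batch sweep
equivalent to iterated nightly scans — re-scanning can never re-alert the same
episode (a tested property, not an assumption).

Assumptions and choices:

- **Concurrency is window overlap.** Claims data carry no administration
  times; days-supply overlap is the standard DUR operationalization.
- **Each claim's window stands alone.** Early refills do not extend exposure;
  exposure queries use the union of windows. This is a modelling choice, not
  a data fact.
- **Event ordering.** The triggering pair of an episode is the one whose two
  drugs were first simultaneously on hand; the *second* (later-filled) claim
  defines the index date and the alerted prescriber. For same-day fills the
  claim from the rule's second (precipitant) set is deemed second, with
  lexicographic claim-id tie-breaks — an arbitrary but deterministic rule for
  a case where no temporal order exists.
- **Reversed claims** are excluded before detection and everywhere downstream:
  a reversed fill was never picked up, so it can neither create exposure nor
  count as a change.
- **Prevalent co-exposure alerts.** By default every detected episode alerts,
  including refill-driven recurrence of a previously tolerated combination;
  `incident_only` restricts to the earliest episode per patient and rule.

Alert suppression is plan-specific: a rule may list lines of business for
which no alert is generated (the shipped bank suppresses the
benzodiazepine–azole class for the Medicaid plan). Education-only rules alert
but are excluded from outcome evaluation. Events survive the eligibility
filter only if the patient remains plan-eligible for the full 90-day horizon
(`eligibility_end ≥ index + 90`).

## Matching

1:1 matching within strata of (rule, gender, line of business, detection
period), with |age difference| ≤ 2 completed years at the index date. The
period granularity is configurable (calendar month by default, quarter
optionally); month was chosen as the tightest granularity that keeps strata
populated at realistic volumes. Controls use their own detection date as the
index.

The matcher is greedy nearest-age-first: rules in descending intervention-event
count, events in patient-id order, each taking the unused in-stratum candidate
with the smallest absolute age gap (ties to the smallest control patient id).
Constraints enforced globally: a control event is used at most once and a
control patient joins at most one rule cohort across the whole study, while an
intervention patient may appear in several cohorts. The procedure is fully
deterministic under its documented sort keys; a maximum bipartite matching
could pair marginally more events (tests bound the greedy count by the
exhaustive optimum), but the greedy order is auditable and stable.

Matching is at the rule level: the control's interacting fills must belong to
the same interaction class, not the same ingredients.

## Outcome ascertainment

Success is the earliest non-reversed fill, within `(index, index + 90]` days,
of a drug in the rule's alternatives map keyed by the interacting drugs
actually dispensed in the episode. Day 0 is excluded (the index fill itself
cannot count), day 90 is included. A refill of either interacting drug never
counts. Two stricter variants ship disabled by default: `strict_switch`
additionally requires that neither interacting drug is refilled in the
window, and `incident_alternative` disqualifies alternatives the patient
filled in the prior 180 days. The default mirrors the literal program
definition — initiation of a recommended alternative — because discontinuation
and naivety requirements are not part of it. An `index_offset_days` knob
shifts the window start by one day for programs that count from the
next-morning alert rather than the fill.

Dose changes, temporary holds, monitoring claims, and patient education leave
no signature in dispensing data and are out of scope by design.

## Statistical comparison

Each cohort's outcome counts form a 2×2 table (arm × changed). The test is
chosen by the minimum expected cell count E = row·col/N: **Fisher's exact test
when min E ≤ 5, otherwise the uncorrected Pearson chi-square with 1 df**. The
"≤ 5" rule with the *uncorrected* statistic is the unique combination that
reproduces the full published p-value column of the program evaluation this
package models, including cohorts where an observed cell is small but the
expected cell exceeds 5. Fisher's two-sided p is the conventional sum of
hypergeometric outcomes with point probability at most that of the observed
table; a zero margin forces the exact test. The pooled analysis is a single
unconditional 2×2 over all matched events. Matched-pair dependence is
deliberately ignored in the primary analysis (the published convention); an
exact McNemar variant on discordant pairs is provided as an off-by-default
extension. No multiplicity adjustment is applied across the 13 cohorts,
mirroring the evaluated program's analysis.

The adjusted analysis is a maximum-likelihood logistic regression, one row per
matched event, of success on the intervention indicator plus: specialist flag
(primary care = internal medicine, general practice, or family practice),
practitioner type (reference: physician), acute-medication flag (either
interacting drug non-maintenance), rule severity (reference: moderate), male,
age group (0–49, 50–64, 80+; reference: 65–79), and twelve medication-based
comorbidity indicators in the style of the RxRisk classifier (≥ 1 mapped fill
in a 180-day lookback). The shipped drug→category lookup is a documented
simplification, not the full published classifier. Whether such a model
should count events or patients is unverifiable from published material; one
row per matched event is used. Separation or non-convergence raises an
explicit diagnostic rather than returning silently unstable estimates
(checked via convergence flags and finite standard errors).

## Synthetic data generator

The generator emulates the study conditions so that every stage is exercised
and the estimand is recoverable:

- **Population**: 9,000 commercial + 1,000 Medicaid intervention-plan patients
  by default (the evaluated program's ~90/10 split, scaled down from ~520,000
  covered lives to keep a full run in seconds); the control pool is generated
  from separate plan streams at 2× that size so matching is not pool-limited.
- **Demographics**: age-stratum weights (0.002, 0.019, 0.282, 0.697) for
  <18 / 18–39 / 40–64 / ≥65, 53.7% female, prescriber mix 87.2% physicians,
  46.6% primary care — the observed program margins.
- **Co-prescription**: per-rule Bernoulli rates proportional to the observed
  per-class alert volumes (summing to 0.5 across evaluable classes), floored
  at 0.004 so the rarest cohorts remain populated at the default scale; the
  education-only classes get volumes sized so the education:evaluable alert
  ratio matches the program's reported totals. A co-prescribed pair is two
  claims with overlapping windows from distinct prescribers, the second fill
  0–20 days after the first.
- **Outcomes**: planted per-event with probability
  expit(logit(baseline) + 1{alerted}·ln(OR)). Baselines default to the
  control-arm change rates the evaluated program reported — a calibration, not
  ground truth, since true no-alert change rates are unobservable. The
  default OR is 1.186, the program's fitted intervention estimate; parameter-
  recovery tests override it (1.5 and 1.0). A planted change is a fill of a
  drug drawn from the rule's alternatives for the dispensed pair, 1–90 days
  after the index.
- **Eligibility**: 88% of patients carry eligibility through the follow-up
  horizon (the program's reported eligible fraction); the rest truncate inside
  the study window.
- **Noise**: 5 extra fills per patient-year of drugs outside every rule
  (comorbidity-mapped plus inert), so detection filtering and the comorbidity
  covariates are exercised without contaminating outcome ascertainment.
- **Ground truth** (assigned arm, latent change probability, planted change)
  is written beside the claims and consumed only by tests, never by the
  pipeline.

What the generator does *not* emulate: NDC-level products, refill-adherence
trajectories, seasonality, prescriber-level clustering of alerts, informative
disenrollment, and claim reversals (reversal handling is unit-tested
directly). Passing tests therefore demonstrate correctness of the pipeline's
logic and recoverability of planted effects under these idealized conditions,
not performance on real claims.

## Determinism and numerics

All randomness flows through a single seeded `numpy` generator; a fixed seed
reproduces every CSV byte-for-byte, and the run manifest records the seed and
a configuration hash. Date intervals are half-open at day resolution
throughout. Expected-count ties sit exactly on the threshold (min E = 5 →
Fisher). Fisher ties in the enumeration use the standard relative tolerance
(probabilities within 1+1e-7 of the observed table count as "as extreme").
Degenerate inputs fail loudly: all-zero 2×2 tables, outcome columns without
variation, education-only rules passed to ascertainment, and infeasible
generator configurations all raise typed errors.

## Problem sizes used in validation

The validation suite runs the detection engine against a quadratic day-set
oracle on 100 random populations of up to 500 claims; the exact test against
full hypergeometric enumeration for all 2×2 tables with N ≤ 60 (canonical
representatives under the swap symmetries, with invariance asserted
separately); matching constraints on 100 random populations; CI coverage of a
planted OR of 1.5 over 100 replicates of 5,000 events per arm; type-I error
of the pooled test over 1,000 null replicates of 2,000 per arm; and a
structural end-to-end run at half the default population scale. These sizes
were chosen to give stable statistical checks while keeping a full validation
run to a couple of minutes.

## Known limitations

- The greedy matcher is near-optimal, not optimal; pair counts may fall
  slightly below the bipartite maximum on adversarial strata.
- Unconditional 2×2 tests on matched data are conservative under positive
  within-pair correlation; the McNemar extension exists but is not the
  primary analysis, to preserve comparability with the evaluated program.
- The comorbidity lookup covers twelve categories with a handful of marker
  drugs each; it is a proxy for the full claims-based classifier.
- Severity levels ship as rulebank attributes (major/moderate per class)
  rather than licensed compendium ratings; the regression treats them as
  given.
- Fitted covariate coefficients from any real program depend on that
  program's claims and are not reproducible from synthetic data; only the
  model structure and the planted intervention effect are validated.
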
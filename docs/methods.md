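# Methods

## The adherence index

The scorer implements a nutrient-based DASH index: nine components, each
credited 0, 0.5 or 1 against a calorie-standardized standard, summed to a
0–9 total. Standardization uses the total reported kcal as the energy
denominator (no correction for alcohol or trans-fat energy — the tracking
exports report only total kcal) with fixed Atwater factors, 9 kcal/g for
fat and 4 kcal/g for protein. Sodium is deliberately an absolute mg/day
amount, not a density, matching how its standard is stated even though
the other minerals are densities.

Two numerical choices make the scorer total and exact:

- **Boundary ties resolve toward the better credit** (≥ target earns full
  credit for more-is-better components, ≤ target for less-is-better).
  The standards are phrased as strict inequalities, but a scoring
  function must assign *something* at the boundary, and rewarding exact
  attainment is the monotone choice.
- **Credits are sums of halves**, represented exactly in binary floating
  point; totals are never rounded.

The half-credit ("intermediate") thresholds are not part of the published
standards. Defaults are (2/3)×target for more-is-better components
(protein 12 % of energy; fiber 9.87 g, magnesium 158.67 mg, calcium
393.33 mg, potassium 1492 mg per 1000 kcal) and 1.5×target for
less-is-better ones (fat 40.5 %, saturated fat 9 %, cholesterol 107.1
mg/1000 kcal, sodium 3600 mg/day): simple, monotone, and
direction-consistent. They are plain numbers in the shipped
`targets_default.yaml` and overridable per nutrient.

Records with any missing nutrient are never scored and never imputed —
the feedback engine receives an explicit no-score token rather than a
zero, which would be indistinguishable from total non-adherence.

## Feedback composition and cadence

Study day 0 is enrollment. Daily feedback goes out at 12:00 study time
(America/New_York, DST-aware) on days 1–14; thereafter one weekly text
per 7-day block, on the enrollment weekday at 12:00 (days 21, 28, …, so a
90-day study yields 14 daily and 10 weekly texts). Weekly texts report
the mean of the prior week's valid-day scores — a week aggregate is the
natural referent once feedback is no longer proximal to a single day.
Topic messages go out every Sunday at 15:00 ("afternoon" has no published
clock time; configurable).

Component selection for the praise/coaching sentence: at most two "best"
components (full credit, smallest relative margin |value−target|/target
first — the closest calls are the most informative praise) and at most
two "struggles" (zero credit, largest relative distance first). Half
credits fill either list only when a cap is unfilled, best taking the
nearest-to-target, struggle the farthest; the lists are always disjoint.
Tips and topics cycle deterministically (by study-day and week index), so
a given input always produces the identical text — important both for
testing and for auditability of what a participant was sent.

## Engagement and recall validity

A *valid tracked day* is a submitted log with ≥600 kcal; the engagement
metric is valid days per 7-day block anchored on the randomization date,
with partial terminal weeks excluded from the mean. The trend model is a
linear mixed model on the weekly counts: fixed intercept, week, arm, and
week×arm; random intercept per participant; REML estimation via
statsmodels MixedLM. The residual structure is independent within
participant — MixedLM offers no unstructured residual covariance — and
this is flagged in `TrendFit.diagnostics`; the contract is the
fixed-effect estimates and Wald CIs. The reported per-arm decline is the
negated week slope (reference arm) or week+interaction (other arm).

Recall-set validity applies five rules, all reported as reasons rather
than exceptions: ≥2 recalls; ≥1 weekend day; ≥1 weekday; recalls used ≤14
calendar days apart; mean energy of the recalls used within 600–3500
kcal. When more than two recalls exist, the earliest weekend and earliest
weekday recall form the pair (a deterministic, logged choice); the energy
rule averages over the recalls actually used.

## Trial analysis

With two timepoints, the within-arm repeated-measures analysis reduces
exactly to the paired-difference machinery: mean change, t-based 95 % CI
and p over pairwise-complete observations. Between-arm effects are
ANCOVA-style: OLS of the 3-month outcome on a treated indicator plus its
baseline value; with no covariate and complete data this collapses to the
difference in arm means (checked in tests). Missing follow-up is handled
by likelihood-based estimation on participants with available data
(available-case under MAR); multiple imputation is out of scope. α = .05
two-sided throughout, no multiplicity correction, Wald CIs on residual
degrees of freedom.

The ΔDASH–ΔBP association reports the least-squares slope of BP change on
DASH change together with Pearson r (the identity slope·sd(x)/sd(y) = r
is asserted on every fit). The slope keeps its regression sign (negative
for improvement→decrease); `decrease_per_unit` republishes it as the
positive magnitude on which such effects are quoted. The per-protocol
analysis blanks DASH values whose recall set failed validity; the
sensitivity analysis re-runs the identical models with them included.

## The synthetic cohort

The simulator exists so every downstream module can be exercised, and
parameter recovery verified, without participant data. Its defaults are
one fixed set of study-scale conditions:

| knob | default | meaning |
|---|---|---|
| baseline adherence | mean 2.3, SD 1.3, truncated to [0,9] | latent DASH level |
| adherence change | +0.8 both arms, SD 1.3 | 3-month latent change |
| tracking | 4.6 valid days/week (SD 1.0 between participants) | initial engagement |
| decline | 0.23 (intervention) vs 0.0 (comparator) days/week per week | engagement erosion |
| blood pressure | SBP 122.9 (14.2), DBP 80.2 (8.8) mmHg | baseline distribution |
| coupling | −2.5 (SBP), −1.6 (DBP) mmHg per DASH unit; residual SD 9.0 / 7.4 | BP response |
| contamination | 5 % invalid diary days, 10 % invalid recall sets, 10 % missing follow-up | protocol noise |
| energy | Normal(1800, 350) kcal clipped to [800, 3200] | generated days |

Notable design choices:

- **Truncation-corrected baseline mean.** The latent baseline is drawn
  from a [0,9]-truncated normal whose *location* is solved numerically so
  the truncated mean equals the configured 2.3; naive truncation at zero
  would inflate the cohort mean by about +0.11.
- **Exact inverse of the scorer.** A generated day first apportions the
  latent total into per-component half-credit units (randomized rounding
  keeps the expected credit sum equal to the latent level exactly;
  largest-remainder apportionment with a seeded tie-break, then a
  sum-preserving jitter, spreads them), then samples each standardized
  value strictly inside its credit's band — full-credit bands extend to a
  2× margin past the target, zero-credit bands to fixed physiologic
  bounds (e.g. sodium ≤8000 mg/day, saturated fat ≤25 % of energy) — and
  converts back to absolute amounts at the drawn energy. Saturated fat is
  clamped to total fat; the fat full-credit floor sits above the
  saturated-fat intermediate, so the clamp never changes a credit.
  Scoring the emitted record therefore reproduces the drawn credits
  bit-for-bit.
- **Valid days are drawn directly.** Weekly valid-day counts are
  Binomial(7, rate/7) with the rate declining linearly, so the configured
  decline is the decline in *valid* days; present-but-invalid (<600 kcal)
  days are added on top rather than carved out, which would attenuate the
  recovered slope by the contamination rate.
- **Between-participant tracking heterogeneity** (initial-rate SD 1.0
  day/week) is what the random intercept in the trend model absorbs;
  without it the intercept variance sits on its boundary and the model is
  ill-identified.
- **Blood pressure couples to the measured DASH change** (the recall-
  scored value recorded in the outcomes table), not the latent one. The
  coupling parameter is thereby defined on the scale the analysis
  observes, and the association estimator recovers it without
  errors-in-variables attenuation from score rounding.
- **Permuted blocks are even** ({4, 6, 8}) — a two-arm balanced block
  must be — and one child random stream per participant, derived from
  (master seed, participant index), makes cohorts byte-identical across
  runs.
- Recall contamination picks exactly one violation mode per invalid set
  (weekend missing, >14-day gap, mean <600 kcal, mean >3500 kcal), so the
  validity rules can be verified against intent.

## What the simulator does and does not emulate

It reproduces the *statistical shape* the analysis pipeline consumes:
score distributions, engagement trajectories, protocol violations,
missingness, and the BP–adherence coupling. It does not emulate food-item
level diets, weekday/weekend or seasonal eating patterns, self-report
measurement error beyond the contamination knobs, or any arm difference
in adherence change (both arms default to +0.8, as feasibility-scale
trials are not powered to separate them). Passing parameter-recovery
tests therefore shows the estimators are correct for data generated
under these assumptions — not that real diet-tracking data satisfy them.

## Problem sizes and tolerances

The parameter-recovery suites run at n = 2000 participants for the
generator–scorer round trip (Monte-Carlo tolerance ±0.1 on a mean with
SE ≈ 0.03), and 20 replicate simulations at 500 participants per arm for
the engagement decline and 500 total for the BP coupling, asserting that
the replicate 95 % interval covers the configured truth. Degenerate
inputs (zero energy, empty lists, one-arm designs, zero ΔDASH variance)
raise typed errors rather than returning numbers.
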
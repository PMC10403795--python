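# Methods

This note documents the models and procedures behind stepcoach: what each
component computes, the assumptions it rests on, the defaults that matter and
why, and what the synthetic-data results do and do not show about real
deployments.

## Study timeline and day indexing

Study day 1 is the first day of the 2-week baseline device period (P0b, days
1–14), during which only self-monitoring runs and no goals are set. A 5-day
non-study gap follows (days 15–19), then intervention week *w* occupies the
7-day block starting at day `19 + 7(w−1) + 1`. The step-outcome windows are
P1b = intervention weeks 5–6 (short term) and P2b = weeks 23–24 (long term).
Windowing is by day index relative to the first record date, so calendar
artifacts (time zones, DST) are out of scope: a day is a calendar date.

## Step-series cleaning

A day enters step analyses iff steps are present, the self-reported wear flag
is not explicitly false, and the count is ≥ 100 (days with < 100 steps are
treated as effectively unworn). A missing wear flag counts as worn: only
*reported* non-wear excludes, which is the conservative reading when wear
information is self-reported and often absent. Measurement adherence divides
recorded days by period days after removing device/system failure days from
the denominator, since those are not the participant's responsibility. Blood
pressure is validated structurally (0–400 mm Hg) and implausible-but-possible
values only warn; no automatic BP cleaning is applied because no defensible
population-free rule exists.

## The goal ladder

The deployed systems this engine models do not publish their goal
arithmetic, so the ladder here is a deliberately simple, fully configurable
policy chosen for reproducibility and the "many small mastery experiences"
rationale of graded goal setting:

| parameter | default | meaning |
|---|---|---|
| `increment` | 500 steps/day | ladder step, both directions |
| `rounding` | 100 steps | week-1 anchor rounding (half up) |
| `floor` / `max_goal` | 2,000 / 15,000 steps/day | hard goal range |
| `raise_threshold_days` | 4 | achieved days/week to raise |
| `hold_min_days` | 2 | 2–3 achieved days hold; ≤ 1 lowers |
| `confidence_low/high` | 70 / 90 % | inclusive "appropriate" band |
| `max_adjust_rounds` | 2 | adjust–reassess iterations per session |

Week 1: `min(max_goal, round100(baseline mean) + increment)`, floored.
Later weeks ladder on achieved days. Confidence above the band means the
goal is too easy and raises it; below the band lowers it. The round budget
guarantees termination; when an adjustment is pinned at the floor or cap the
loop stops early. Downshifts are allowed — whether the deployed systems
permitted them is unknown, but a ladder without a descent path traps users
after any regression.

The raise threshold of 4 days interprets "more than half the week"
consistently with the confidence question (confidence of achieving the goal
on more than 4 of 7 days); the ambiguity between ≥ 4 and ≥ 5 is real and the
threshold is a config field, not a constant.

## Feedback selection

Message choice is an eligibility predicate plus a seeded uniform draw with
no immediate repeat — the simplest mechanism that is fully testable and
reproduces the published behavior contract (advice only for never/rarely
behaviors, praise only for often/always ones, generic fallbacks when no item
qualifies). Weekly change messages use sign-with-tolerance rules; the
tolerances (1 mm Hg BP, 0.2 kg weight, 200 steps/day, 20 kcal, 5 mg/dL
glucose) exist to keep day-to-day jitter from generating contradictory
messages and have no clinical meaning.

Session routing: a clearly successful week (≥ raise-threshold achieved days
*and* mean ≥ goal) moves to future-barrier anticipation (relapse
prevention); a clearly struggling week (≤ 1 achieved day *or* mean < 0.8 ×
goal) moves to current-barrier problem-solving; otherwise the action plan is
reviewed. The 0.8 fraction and the day cutoffs are package choices — the
deployed conditionals are not public — and all live in `RoutingConfig`.

## The behavioral simulator

Each synthetic user has:

* `baseline_log_mean`, `baseline_log_sd` — daily steps are
  `exp(N(μ, σ))`, right-skewed and positive. The cohort draws μ around
  `log(10,000)` with between-person SD 0.22 and within-person SD 0.25,
  giving a baseline-median near 10,000 steps/day with a realistic IQR for an
  active workplace population.
* `self_efficacy` ∈ [0, 100] (cohort default N(70, 12), clamped) — seeds
  reported confidence and drives effort.
* `responsiveness` (default N(2000, 500), floored at 0) — extra steps/day at
  full drive.
* `mastery_gain` / `failure_loss` (2 / 3) — self-efficacy update after a
  goal-met / missed week, the mastery-experience loop.
* `wear_prob` (0.97) and `dropout_hazard` (0.0015/week) — chosen to match
  the very high adherence and low attrition typical of loaner-device
  workplace cohorts.

Effort is `responsiveness × drive`, with
`drive = expit((SE − 50 − 5·max(0, difficulty)) / 15)` and
`difficulty = (goal − baseline mean)/increment`. Difficulty is floored at
zero inside the drive: a goal at or below the habitual level does not push
effort above what self-efficacy alone sustains. This floor is load-bearing —
without it, sub-baseline goals *boost* drive, the system self-stabilizes,
and no configuration can reproduce the well-documented late-study
attenuation of step gains.

Reported confidence is `clip(SE − 4·difficulty + N(0, 5), 0, 100)`. Because
the 70–90 band then acts as a governor (low confidence pulls goals back
before self-efficacy erodes), the default configuration shows sustained
gains, not attenuation. The attenuation regime — an achievement ladder that
overshoots ability — is expressed purely through configuration: widen the
confidence band to [0, 100] (governor off) and make self-efficacy fragile
(mastery gain 1, failure loss 6). Under that regime the long-term
(weeks 23–24) median change falls below the short-term (weeks 5–6) one, the
qualitative signature reported for real cohorts.

BP, weight and activity calories are co-simulated observationally: BP drops
linearly with effort (0.4 mm Hg systolic per extra 1,000 steps/day, capped
at 15 mm Hg so extreme synthetic effort cannot produce impossible
pressures), weight drifts down 0.5 kg per million extra steps, calories are
0.028 kcal/step plus noise. These are deliberately mild and are *not*
calibrated to any published biomedical results. An optional seasonal
sinusoid on log steps is off by default. Questionnaire responses are
generated from current self-efficacy (goal-level confidences decrease with
the goal) and from a binary engagement term (self-regulation and
self-management frequencies rise once the system is in use); they provide
realistic inputs for the scoring/imputation pipeline, not calibrated
psychometrics.

What passing the simulator-based tests shows: the engine's closed-loop
behavior (ladders, negotiation, routing, feedback determinism) and the
statistical pipeline are correct under a plausible generative model, and the
step-change test holds its type-I level under the null. What it does not
show: that real users behave like the model — the simulator has no
weekday/weekend structure, no weather, no measurement error in step counts,
and a one-dimensional self-efficacy state.

## Statistics

**Wilcoxon signed rank.** Zero differences are discarded (classical
convention; a Pratt variant is available behind `zero_method="pratt"`).
Absolute differences receive midranks. For n ≤ 25 the two-sided p is exact:
the distribution of W⁺ over all 2ⁿ sign assignments is built by polynomial
convolution over doubled midranks (doubling makes half-integer midranks
integral), and p = min(1, 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w))). The exact path is
used with ties too — the enumeration is equally valid there and is verified
exhaustively against a brute-force oracle for n ≤ 10. Beyond n = 25 a normal
approximation with tie correction (−Σ(t³−t)/48 in the variance) and a 0.5
continuity correction is used; it agrees with the reference implementation
in scipy to 10⁻⁶. A flag reports which path ran; all-zero differences yield
p = 1 with a warning flag.

**Median CI.** The interval is the symmetric order-statistic pair
(x₍ₖ₎, x₍ₙ₊₁₋ₖ₎) with the largest k whose binomial coverage
1 − 2·F(k−1; n, ½) reaches the nominal level; coverage is discrete, so the
achieved value is always reported, and when even the full range cannot reach
the level (n ≤ 5 at 95%) the range is returned with a below-nominal flag.
Interpolated variants are deliberately not used: the method class is the
order-statistic one, and interpolation would hide the discreteness the flag
makes transparent.

**Multiplicity and power.** Two contrasts per outcome (short- and long-term)
give the Bonferroni per-test level α/2 = .025, derived, never stored. The
sample-size routine searches for the smallest n at which a two-sided
one-sample t test with noncentrality dz·√n and df = n − 1 reaches the target
power — the noncentral-t formulation used by standard power software — and
reproduces n = 28 at dz = 0.55, power 0.80, α = .05. The clinically
meaningful step change of 1,000 steps/day is 10 minutes of moderate walking
at 100 steps/min.

**Population rules.** The main analysis population excludes the
precontemplation stage and baseline means > 15,000 steps/day (above the goal
cap the system could only ask users to maintain). The post hoc subgroup
split is at 10,000 steps/day with ties going low — the boundary is
undefined in the < / > formulation, so the tie rule is declared rather than
implicit. BP (lipid) analyses exclude participants who started or increased
an antihypertensive (lipid-lowering) medication; dose decreases do not
exclude. Questionnaire imputation replaces a missing behavior-scale item
with the mean of the observed items in its factor at the same timepoint;
observed items are never altered and fully missing factors stay missing.

## Numerical and testing notes

Problem sizes in the test suite are chosen for desk-scale runs: exhaustive
sign-pattern verification at n ≤ 10, 10⁴ Monte-Carlo draws for CI coverage,
and 200 replicate trials of n = 30 over a 6-week horizon (the short-term
window only) for type-I control; the whole suite runs in well under a
minute per heavy test. All stochastic tests are seeded; the end-to-end
pipeline (simulate → coach → evaluate) is byte-reproducible under a fixed
seed, with one root seed fanned out to per-user generators via a seed
sequence so individual trajectories are independently reproducible.

## Known limitations

* The goal-increment arithmetic, routing cutoffs, and message texts are the
  package's own reconstructions of unpublished components; everything is
  configurable, but defaults are choices, not measurements.
* The simulator is a single-state self-efficacy model with i.i.d. log-normal
  days; it cannot emulate weekly rhythms, weather shocks, or device
  measurement error.
* Free-text action-plan entries are stored pass-through; no text analysis.
* The evaluation module covers paired two-timepoint designs only — no mixed
  models, no seasonality adjustment, no multiple imputation.
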
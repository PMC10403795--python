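"""Study-evaluation statistics for paired before/after outcomes.

Small-sample, skewed outcomes call for distribution-free machinery: changes
are tested with the Wilcoxon signed rank test (exact sign-assignment
distribution for small n, tie- and continuity-corrected normal approximation
otherwise) and summarized by the median change with a distribution-free CI
from symmetric order statistics, whose coverage comes from the Binomial(n, 1/2)
distribution of the number of observations below the median.  Two contrasts
(short- and long-term) per outcome motivate a Bonferroni per-test level of
alpha/2 = .025.

Also here: population eligibility filtering (stage of change, high baseline
steps), Likert questionnaire scoring with within-factor mean imputation, the
<10,000 / >10,000 steps-per-day subgroup split, medication-based exclusions,
and the noncentral-t sample-size calculation for a paired-difference t test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedValueError, ValidationError
from .feedback import SMBPA_FACTORS
from .records import (
    Participant,
    StudyPeriod,
    adherence_percentage,
    summarize_period,
)

__all__ = [
    "EvalConfig",
    "ChangeResult",
    "WilcoxonResult",
    "MedianCI",
    "QuestionnaireSpec",
    "QuestionnaireResponse",
    "QuestionnaireScores",
    "DEFAULT_SPEC",
    "eligibility_filter",
    "wilcoxon_signed_rank",
    "median_ci_distribution_free",
    "paired_change_summary",
    "subgroup_split",
    "impute_factor_items",
    "score_questionnaires",
    "required_sample_size",
    "mcid_steps",
    "medication_exclusion",
    "evaluate_trial",
    "adherence_table",
]


@dataclass(frozen=True)
class EvalConfig:
    """Analysis constants.  ``alpha_per_test`` is derived (Bonferroni), never
    stored, so the invariant alpha_per_test = alpha_overall / tests_per_outcome
    holds by construction."""

    alpha_overall: float = 0.05
    tests_per_outcome: int = 2  # short-term and long-term contrast per outcome
    ci_level: float = 0.95
    subgroup_threshold: float = 10_000.0  # steps/day split for post hoc subgroups
    mcid_steps: float = 1_000.0  # minimal clinically important difference
    assumed_sd: float = 1_800.0  # SD of step change assumed for the power analysis
    stage_exclusion: str = "precontemplation"
    baseline_step_exclusion: float = 15_000.0  # exclude baseline means above this

    def __post_init__(self) -> None:
        if not (0 < self.alpha_overall < 1) or self.tests_per_outcome < 1:
            raise ValidationError("invalid alpha_overall / tests_per_outcome")
        if not (0 < self.ci_level < 1):
            raise ValidationError("ci_level must be in (0, 1)")

    @property
    def alpha_per_test(self) -> float:
        return self.alpha_overall / self.tests_per_outcome


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ (sum of positive-difference ranks)
    p_value: float
    method: str  # "exact" | "normal" | "all_zero"
    n: int  # pairs remaining after zero-difference removal


@dataclass(frozen=True)
class MedianCI:
    low: float
    high: float
    coverage: float  # achieved (binomial) coverage of the returned interval
    k: int  # order-statistic depth: interval is (x_(k), x_(n+1-k))
    below_nominal: bool


@dataclass(frozen=True)
class ChangeResult:
    """Paired before/after summary for one outcome and contrast."""

    n: int
    median_change: float
    ci_low: float
    ci_high: float
    achieved_ci_coverage: float
    p_value: float
    significant: bool
    method: str

    def __post_init__(self) -> None:
        if self.n >= 1 and not (self.ci_low <= self.median_change <= self.ci_high):
            raise ValidationError("median must lie inside its CI")


# ---------------------------------------------------------------------------
# Eligibility and exclusions
# ---------------------------------------------------------------------------


def eligibility_filter(
    participants: Sequence[Participant],
    baseline_means: Mapping[str, float],
    config: EvalConfig = EvalConfig(),
) -> list[Participant]:
    """Main population for analyses: drop participants in the excluded stage
    of change and those whose baseline mean exceeds the step-goal cap
    (> 15,000 steps/day; the system would only ask them to maintain)."""
    out = []
    for p in participants:
        if p.stage_of_change is None:
            raise ValidationError(f"participant {p.id}: stage_of_change missing")
        if p.id not in baseline_means:
            raise ValidationError(f"participant {p.id}: baseline mean missing")
        if p.stage_of_change == config.stage_exclusion:
            continue
        if baseline_means[p.id] > config.baseline_step_exclusion:
            continue
        out.append(p)
    return out


def medication_exclusion(
    participants: Sequence[Participant], outcome: str
) -> list[Participant]:
    """Analysis set for BP or lipid outcomes: exclude participants who started
    or increased a matching medication during follow-up (dose decreases do
    not exclude)."""
    drug_class = {"bp": "hypertension", "lipids": "dyslipidemia"}.get(outcome)
    if drug_class is None:
        raise ValidationError("outcome must be 'bp' or 'lipids'")
    return [
        p
        for p in participants
        if not any(
            e.drug_class == drug_class and e.change in ("start", "increase")
            for e in p.medication_events
        )
    ]


def subgroup_split(
    baseline_means: Mapping[str, float], config: EvalConfig = EvalConfig()
) -> tuple[list[str], list[str]]:
    """Post hoc split at the configured threshold (default 10,000 steps/day).

    Returns (low, high) participant-id lists; a mean exactly at the threshold
    goes to the low group (documented tie rule).
    """
    low = [pid for pid, m in baseline_means.items() if m <= config.subgroup_threshold]
    high = [pid for pid, m in baseline_means.items() if m > config.subgroup_threshold]
    return low, high


# ---------------------------------------------------------------------------
# Wilcoxon signed rank test
# ---------------------------------------------------------------------------

_EXACT_N_MAX = 25


def wilcoxon_signed_rank(
    before: Sequence[float],
    after: Sequence[float],
    *,
    zero_method: str = "discard",
    mode: str = "auto",
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed rank test on paired samples.

    Zero differences are discarded (the classical signed-rank convention;
    ``zero_method='pratt'`` instead keeps them for ranking and drops them from
    the statistic).  Tied absolute differences receive midranks.  For n <= 25
    the p-value is exact, from the full distribution of W+ over all 2^n sign
    assignments of the (mid)ranks; for larger n a normal approximation with
    tie correction and continuity correction is used.  The ``method`` flag
    reports which path ran; if every difference is zero the test is
    uninformative and p = 1 is returned with the ``all_zero`` flag.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape or b.ndim != 1:
        raise ValidationError("before and after must be equal-length 1-D sequences")
    if zero_method not in ("discard", "pratt"):
        raise ValidationError("zero_method must be 'discard' or 'pratt'")
    d = a - b
    if zero_method == "discard":
        d = d[d != 0]
        ranks_all = stats.rankdata(np.abs(d)) if d.size else np.array([])
        nonzero = np.ones(d.size, dtype=bool)
    else:  # pratt: rank with zeros included, then drop the zeros' ranks
        ranks_all = stats.rankdata(np.abs(d)) if d.size else np.array([])
        nonzero = d != 0
    n = int(np.count_nonzero(nonzero))
    if n == 0:
        return WilcoxonResult(statistic=0.0, p_value=1.0, method="all_zero", n=0)
    ranks = ranks_all[nonzero]
    signs = d[nonzero] > 0
    w_plus = float(ranks[signs].sum())

    use_exact = (mode == "exact") or (mode == "auto" and n <= _EXACT_N_MAX)
    if mode not in ("auto", "exact", "normal"):
        raise ValidationError("mode must be 'auto', 'exact' or 'normal'")

    if use_exact:
        # Distribution of 2*W+ over all 2^n sign assignments, by polynomial
        # convolution over doubled midranks (doubling makes half-ranks integer).
        r2 = np.rint(2 * ranks).astype(np.int64)
        counts = np.zeros(int(r2.sum()) + 1, dtype=np.float64)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[:-r] if r > 0 else counts
            counts = counts + shifted
        total = counts.sum()
        obs2 = int(np.rint(2 * w_plus))
        p_le = counts[: obs2 + 1].sum() / total
        p_ge = counts[obs2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(statistic=w_plus, p_value=float(p), method="exact", n=n)

    mn = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks_all, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return WilcoxonResult(statistic=w_plus, p_value=1.0, method="normal", n=n)
    cc = 0.5 * np.sign(w_plus - mn)
    z = (w_plus - mn - cc) / np.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return WilcoxonResult(statistic=w_plus, p_value=float(p), method="normal", n=n)


# ---------------------------------------------------------------------------
# Distribution-free median confidence interval
# ---------------------------------------------------------------------------


def median_ci_distribution_free(values: Sequence[float], level: float = 0.95) -> MedianCI:
    """Median CI from symmetric order statistics.

    Returns (x_(k), x_(n+1-k)) with the largest k >= 1 whose binomial coverage
    P(k <= B <= n-k), B ~ Binomial(n, 1/2), is at least ``level``.  When even
    k = 1 (the full range) cannot reach the nominal level - possible for small
    n because coverage is discrete - the range is returned with its achieved
    coverage and a below-nominal flag.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise UndefinedValueError("cannot form a median CI from an empty sample")
    if not (0 < level < 1):
        raise ValidationError("level must be in (0, 1)")

    def coverage(k: int) -> float:
        return float(1.0 - 2.0 * stats.binom.cdf(k - 1, n, 0.5))

    best_k = None
    for k in range(1, n // 2 + 2):
        if k > n + 1 - k:
            break
        if coverage(k) >= level:
            best_k = k  # coverage shrinks as k grows; keep the deepest valid k
        else:
            break
    if best_k is None:
        cov = coverage(1)
        return MedianCI(low=float(x[0]), high=float(x[-1]), coverage=cov, k=1, below_nominal=True)
    return MedianCI(
        low=float(x[best_k - 1]),
        high=float(x[n - best_k]),
        coverage=coverage(best_k),
        k=best_k,
        below_nominal=False,
    )


def paired_change_summary(
    before: Sequence[float],
    after: Sequence[float],
    config: EvalConfig = EvalConfig(),
) -> ChangeResult:
    """Median change (after - before) with its distribution-free CI and the
    Wilcoxon p-value, flagged significant at the Bonferroni per-test level."""
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.size == 0 or b.shape != a.shape:
        raise ValidationError("need non-empty, equal-length paired samples")
    diffs = a - b
    ci = median_ci_distribution_free(diffs, config.ci_level)
    test = wilcoxon_signed_rank(b, a)
    return ChangeResult(
        n=int(b.size),
        median_change=float(np.median(diffs)),
        ci_low=ci.low,
        ci_high=ci.high,
        achieved_ci_coverage=ci.coverage,
        p_value=test.p_value,
        significant=test.p_value < config.alpha_per_test,
        method=test.method,
    )


# ---------------------------------------------------------------------------
# Questionnaire scoring and imputation
# ---------------------------------------------------------------------------

PASR_FACTORS = (
    "self_monitoring",
    "goal_setting",
    "social_support",
    "reinforcements",
    "time_management",
    "relapse_prevention",
)
GOAL_LEVELS = (6_000, 8_000, 10_000, 12_000)


@dataclass(frozen=True)
class QuestionnaireSpec:
    """Instrument structure and score ranges enforced at scoring time.

    - behavior scale: 9 factors / 32 items, 0-4 each, factor scores are sums;
    - self-regulation (PASR-12): 6 factors x 2 items, 1-5 each, factor range
      2-10, total 12-60;
    - goal-related self-efficacy: confidence 0-100% at 4 incremental step
      goals, scored as their mean;
    - walking self-efficacy: 4 items, 1-5, sum range 4-20;
    - body-pain cluster: 4 items, 0-4, scored as the sum.
    """

    smbpa_factors: Mapping[str, int] = field(default_factory=lambda: dict(SMBPA_FACTORS))
    pasr_factors: tuple[str, ...] = PASR_FACTORS
    pasr_items_per_factor: int = 2
    goal_levels: tuple[int, ...] = GOAL_LEVELS
    walking_items: int = 4
    pain_items: int = 4


DEFAULT_SPEC = QuestionnaireSpec()


@dataclass(frozen=True)
class QuestionnaireResponse:
    """One timepoint's raw responses; ``None`` marks a missing item."""

    smbpa: Mapping[str, float | None]
    pasr: Mapping[str, float | None]  # "<factor>_1", "<factor>_2" -> 1..5
    goal_confidences: Mapping[int, float | None]  # goal level -> 0..100
    walking: Mapping[str, float | None]  # "walking_1".. -> 1..5
    pain: Mapping[str, float | None]  # "pain_1".. -> 0..4


@dataclass(frozen=True)
class QuestionnaireScores:
    goal_self_efficacy: float | None
    walking_self_efficacy: float | None
    pasr_factors: Mapping[str, float | None]
    pasr_total: float | None
    smbpa_factors: Mapping[str, float | None]
    pain_total: float | None


def impute_factor_items(
    response: Mapping[str, float | None],
    spec: QuestionnaireSpec = DEFAULT_SPEC,
) -> dict[str, float | None]:
    """Within-factor mean imputation for the 32-item behavior scale.

    Each missing item is replaced by the mean of the observed items in the
    same factor at the same timepoint (fractional values retained).  Observed
    items are never changed; a factor with no observed items stays missing
    and raises a warning.
    """
    out: dict[str, float | None] = dict(response)
    for factor, n_items in spec.smbpa_factors.items():
        ids = [f"{factor}_{i + 1}" for i in range(n_items)]
        observed = [out[i] for i in ids if out.get(i) is not None]
        if len(observed) == n_items:
            continue
        if not observed:
            warnings.warn(f"factor {factor!r}: all items missing; factor score left missing")
            continue
        fill = sum(observed) / len(observed)
        for i in ids:
            if out.get(i) is None:
                out[i] = fill
    return out


def _checked_sum(
    values: Mapping[str, float | None], ids: Sequence[str], lo: float, hi: float, what: str
) -> float | None:
    vals = []
    for i in ids:
        v = values.get(i)
        if v is None:
            return None
        if not (lo <= v <= hi):
            raise ValidationError(f"{what} item {i}={v} outside [{lo}, {hi}]")
        vals.append(v)
    return float(sum(vals))


def score_questionnaires(
    response: QuestionnaireResponse,
    spec: QuestionnaireSpec = DEFAULT_SPEC,
    *,
    impute: bool = True,
) -> QuestionnaireScores:
    """Score all instruments; the behavior scale is mean-imputed first.

    A score whose required items are missing (after imputation, where it
    applies) is reported as ``None`` rather than a partial sum.
    """
    smbpa = impute_factor_items(response.smbpa, spec) if impute else dict(response.smbpa)
    smbpa_scores: dict[str, float | None] = {}
    for factor, n_items in spec.smbpa_factors.items():
        ids = [f"{factor}_{i + 1}" for i in range(n_items)]
        smbpa_scores[factor] = _checked_sum(smbpa, ids, 0, 4, "behavior-scale")

    pasr_scores: dict[str, float | None] = {}
    for factor in spec.pasr_factors:
        ids = [f"{factor}_{i + 1}" for i in range(spec.pasr_items_per_factor)]
        pasr_scores[factor] = _checked_sum(response.pasr, ids, 1, 5, "self-regulation")
    pasr_total = (
        sum(pasr_scores.values()) if all(v is not None for v in pasr_scores.values()) else None
    )

    confs = []
    goal_se: float | None = None
    for g in spec.goal_levels:
        v = response.goal_confidences.get(g)
        if v is None:
            confs = None
            break
        if not (0 <= v <= 100):
            raise ValidationError(f"confidence for {g} steps/day = {v} outside [0, 100]")
        confs.append(v)
    if confs is not None:
        goal_se = float(np.mean(confs))

    walking = _checked_sum(
        response.walking, [f"walking_{i + 1}" for i in range(spec.walking_items)], 1, 5, "walking-SE"
    )
    pain = _checked_sum(
        response.pain, [f"pain_{i + 1}" for i in range(spec.pain_items)], 0, 4, "pain-cluster"
    )
    return QuestionnaireScores(
        goal_self_efficacy=goal_se,
        walking_self_efficacy=walking,
        pasr_factors=pasr_scores,
        pasr_total=pasr_total,
        smbpa_factors=smbpa_scores,
        pain_total=pain,
    )


# ---------------------------------------------------------------------------
# Sample size and MCID
# ---------------------------------------------------------------------------


def mcid_steps(minutes_per_day: float = 10.0, steps_per_minute: float = 100.0) -> float:
    """Minimal clinically important difference in steps/day: a 10-minute
    increase in daily moderate walking at ~100 steps/min."""
    if minutes_per_day <= 0 or steps_per_minute <= 0:
        raise ValidationError("minutes and cadence must be positive")
    return minutes_per_day * steps_per_minute


def required_sample_size(
    effect_size_dz: float,
    power: float = 0.80,
    alpha: float = 0.05,
    max_n: int = 1_000_000,
) -> int:
    """Smallest n giving a two-sided one-sample (paired-difference) t test the
    target power, via the noncentral-t distribution with noncentrality
    dz * sqrt(n) and df = n - 1."""
    if not (0 < power < 1) or not (0 < alpha < 1) or effect_size_dz <= 0:
        raise ValidationError("need dz > 0, 0 < power < 1, 0 < alpha < 1")
    for n in range(2, max_n + 1):
        df = n - 1
        t_crit = stats.t.ppf(1 - alpha / 2, df)
        nc = effect_size_dz * np.sqrt(n)
        achieved = stats.nct.sf(t_crit, df, nc) + stats.nct.cdf(-t_crit, df, nc)
        if achieved >= power:
            return n
    raise UndefinedValueError(f"no n <= {max_n} attains power {power}")


# ---------------------------------------------------------------------------
# Whole-trial analysis tables
# ---------------------------------------------------------------------------

_TRIAL_OUTCOMES = {
    "steps": ("mean_steps", None),
    "kcal": ("mean_kcal", None),
    "sbp_morning": ("sbp_morning", "bp"),
    "dbp_morning": ("dbp_morning", "bp"),
    "sbp_night": ("sbp_night", "bp"),
    "dbp_night": ("dbp_night", "bp"),
    "weight": ("weight", None),
}


def _contrast_periods(cfg) -> list[tuple[str, StudyPeriod]]:
    kw = {"baseline_days": cfg.baseline_days, "gap_days": cfg.gap_days}
    out = []
    if cfg.weeks >= 6:
        out.append(("P0-P1", StudyPeriod.p1b(**kw)))
    if cfg.weeks >= 24:
        out.append(("P0-P2", StudyPeriod.p2b(**kw)))
    if not out:
        raise UndefinedValueError(
            f"trial spans only {cfg.weeks} intervention weeks; the first outcome window needs 6"
        )
    return out


def _q_score_value(scores: QuestionnaireScores, name: str) -> float | None:
    if name == "goal_self_efficacy":
        return scores.goal_self_efficacy
    if name == "walking_self_efficacy":
        return scores.walking_self_efficacy
    if name == "pasr_total":
        return scores.pasr_total
    if name == "pain_total":
        return scores.pain_total
    if name.startswith("pasr_"):
        return scores.pasr_factors.get(name[len("pasr_"):])
    if name.startswith("smbpa_"):
        return scores.smbpa_factors.get(name[len("smbpa_"):])
    raise ValidationError(f"unknown questionnaire score {name!r}")


def evaluate_trial(dataset, config: EvalConfig = EvalConfig()) -> pd.DataFrame:
    """Results table mirroring the study's outcome layout: one row per
    outcome per contrast (short-term P0-P1 and, when the trial is long
    enough, long-term P0-P2), each with n, median change, distribution-free
    CI, Wilcoxon p and the significance flag at the Bonferroni level.

    The main population is filtered first (stage of change, >15,000 steps/day
    baseline); BP outcomes additionally exclude participants who started or
    increased an antihypertensive.  Subgroup rows repeat the step analysis in
    the below/above-10,000 baseline groups.  ``dataset`` is any object with
    the trial-dataset attributes (participants, records, questionnaires,
    config, baseline_means()).
    """
    cfg = dataset.config
    baseline_means = dataset.baseline_means()
    with_data = [p for p in dataset.participants if p.id in baseline_means]
    eligible = eligibility_filter(with_data, baseline_means, config)
    contrasts = _contrast_periods(cfg)
    p0b = StudyPeriod.baseline(cfg.baseline_days)

    summaries: dict[str, dict[str, object]] = {}
    for p in eligible:
        recs = dataset.records[p.id]
        summaries[p.id] = {"P0b": summarize_period(recs, p0b, study_start=cfg.study_start)}
        for _, period in contrasts:
            summaries[p.id][period.label] = summarize_period(
                recs, period, study_start=cfg.study_start
            )

    rows = []

    def add_row(outcome: str, contrast: str, subgroup: str, pids, attr: str, period_label: str):
        before, after = [], []
        for pid in pids:
            b = getattr(summaries[pid]["P0b"], attr)
            a = getattr(summaries[pid][period_label], attr)
            if b is not None and a is not None:
                before.append(b)
                after.append(a)
        if not before:
            return
        res = paired_change_summary(before, after, config)
        rows.append(
            {
                "outcome": outcome,
                "contrast": contrast,
                "subgroup": subgroup,
                "n": res.n,
                "median_change": res.median_change,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "ci_coverage": res.achieved_ci_coverage,
                "p_value": res.p_value,
                "significant": res.significant,
                "method": res.method,
            }
        )

    low_ids, high_ids = subgroup_split(
        {p.id: baseline_means[p.id] for p in eligible}, config
    )
    for label, period in contrasts:
        for outcome, (attr, med_class) in _TRIAL_OUTCOMES.items():
            pool = eligible if med_class is None else medication_exclusion(eligible, med_class)
            add_row(outcome, label, "all", [p.id for p in pool], attr, period.label)
        add_row("steps", label, "baseline_low", low_ids, "mean_steps", period.label)
        add_row("steps", label, "baseline_high", high_ids, "mean_steps", period.label)

    # questionnaire outcomes: P0a vs P1a / P2a
    q_names = (
        ["goal_self_efficacy", "walking_self_efficacy", "pasr_total"]
        + [f"pasr_{f}" for f in PASR_FACTORS]
        + [f"smbpa_{f}" for f in SMBPA_FACTORS]
        + ["pain_total"]
    )
    q_contrasts = [("P0-P1", "P1a")] + ([("P0-P2", "P2a")] if cfg.weeks >= 24 else [])
    scored: dict[str, dict[str, QuestionnaireScores]] = {}
    for p in eligible:
        tps = dataset.questionnaires.get(p.id, {})
        scored[p.id] = {tp: score_questionnaires(resp) for tp, resp in tps.items()}
    for contrast, tp in q_contrasts:
        for name in q_names:
            before, after = [], []
            for p in eligible:
                s0 = scored[p.id].get("P0a")
                s1 = scored[p.id].get(tp)
                if s0 is None or s1 is None:
                    continue
                v0, v1 = _q_score_value(s0, name), _q_score_value(s1, name)
                if v0 is not None and v1 is not None:
                    before.append(v0)
                    after.append(v1)
            if before:
                res = paired_change_summary(before, after, config)
                rows.append(
                    {
                        "outcome": f"q_{name}",
                        "contrast": contrast,
                        "subgroup": "all",
                        "n": res.n,
                        "median_change": res.median_change,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "ci_coverage": res.achieved_ci_coverage,
                        "p_value": res.p_value,
                        "significant": res.significant,
                        "method": res.method,
                    }
                )
    return pd.DataFrame(rows)


def adherence_table(dataset) -> pd.DataFrame:
    """Process-evaluation table: median (across participants) percentage of
    days each parameter was measured and recorded, for P0b and the whole
    intervention period."""
    cfg = dataset.config
    periods = [StudyPeriod.baseline(cfg.baseline_days)]
    if cfg.weeks >= 1:
        periods.append(
            StudyPeriod.intervention_weeks(
                1, cfg.weeks, label="intervention",
                baseline_days=cfg.baseline_days, gap_days=cfg.gap_days,
            )
        )
    rows = []
    for period in periods:
        for parameter in ("steps", "sbp_m", "dbp_m", "sbp_n", "dbp_n", "weight_kg", "kcal_activity"):
            values = []
            for pid, recs in dataset.records.items():
                try:
                    values.append(
                        adherence_percentage(recs, period, parameter, study_start=cfg.study_start)
                    )
                except UndefinedValueError:
                    continue
            if values:
                rows.append(
                    {
                        "period": period.label,
                        "parameter": parameter,
                        "median_adherence_pct": float(np.median(values)),
                        "n_participants": len(values),
                    }
                )
    return pd.DataFrame(rows)
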
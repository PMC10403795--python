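import datetime as dt
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from stepcoach import (
    EvalConfig,
    Participant,
    MedicationEvent,
    QuestionnaireResponse,
    eligibility_filter,
    impute_factor_items,
    mcid_steps,
    median_ci_distribution_free,
    medication_exclusion,
    paired_change_summary,
    required_sample_size,
    score_questionnaires,
    subgroup_split,
    wilcoxon_signed_rank,
)
from stepcoach.errors import UndefinedValueError, ValidationError
from stepcoach.evaluation import GOAL_LEVELS, PASR_FACTORS
from stepcoach.feedback import SMBPA_FACTORS


def signed_rank_oracle(diffs):
    """Independent exact two-sided p by brute enumeration of all sign vectors."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    observed = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s > 0)
        for signs in itertools.product((1, -1), repeat=n)
    ]
    ws = np.asarray(ws)
    p_le = np.mean(ws <= observed + 1e-12)
    p_ge = np.mean(ws >= observed - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_three_unit_shifts(self):
        res = wilcoxon_signed_rank([1, 2, 3], [2, 3, 4])
        assert res.statistic == 6.0
        assert res.p_value == 0.25  # 2 x P(W+ >= 6) = 2/8 over all sign vectors
        assert res.method == "exact"

    def test_identical_arms_give_p_one(self):
        res = wilcoxon_signed_rank([5, 5, 5], [5, 5, 5])
        assert res.p_value == 1.0 and res.method == "all_zero"

    def test_matches_enumeration_oracle_with_ties(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 9))
            d = rng.integers(-3, 4, size=n).astype(float)
            before = np.zeros(n)
            res = wilcoxon_signed_rank(before, d)
            assert res.p_value == pytest.approx(signed_rank_oracle(d), abs=1e-12)

    def test_large_sample_matches_reference_approximation(self, rng):
        before = rng.normal(size=30)
        after = before + rng.normal(0.3, 1.0, size=30)
        res = wilcoxon_signed_rank(before, after, mode="normal")
        ref = stats.wilcoxon(after, before, correction=True, method="approx")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-6)
        assert res.method == "normal"

    def test_pratt_zero_handling_available(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4], [1, 3, 4, 5], zero_method="pratt")
        ref = stats.wilcoxon([2, 3, 4], [1, 2, 3], zero_method="pratt", method="approx", correction=True)
        assert res.n == 3

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_signed_rank([1, 2], [1, 2, 3])


class TestMedianCI:
    def test_n6_uses_full_range_with_known_coverage(self):
        ci = median_ci_distribution_free([3, 1, 4, 1, 5, 9])
        assert (ci.low, ci.high, ci.k) == (1, 9, 1)
        assert ci.coverage == pytest.approx(0.96875)
        assert not ci.below_nominal

    def test_n5_flags_below_nominal(self):
        ci = median_ci_distribution_free([1, 2, 3, 4, 5])
        assert (ci.low, ci.high) == (1, 5)
        assert ci.coverage == pytest.approx(0.9375)
        assert ci.below_nominal

    def test_equal_values_give_zero_width(self):
        ci = median_ci_distribution_free([7.0] * 10)
        assert ci.low == ci.high == 7.0

    def test_deepest_valid_order_statistic_chosen(self):
        # n = 30: k = 10 gives coverage 0.957, k = 11 gives 0.901
        ci = median_ci_distribution_free(list(range(30)))
        assert ci.k == 10
        assert ci.coverage >= 0.95
        assert 1 - 2 * stats.binom.cdf(ci.k, 30, 0.5) < 0.95

    def test_empty_input_rejected(self):
        with pytest.raises(UndefinedValueError):
            median_ci_distribution_free([])

    @pytest.mark.parametrize("n", [6, 10, 20, 30])
    def test_empirical_coverage_matches_binomial_coverage(self, n, rng):
        draws = 4_000
        samples = rng.normal(size=(draws, n))
        samples.sort(axis=1)
        ci = median_ci_distribution_free(samples[0], 0.95)
        hits = np.mean((samples[:, ci.k - 1] <= 0) & (samples[:, n - ci.k] >= 0))
        se = np.sqrt(ci.coverage * (1 - ci.coverage) / draws)
        assert hits == pytest.approx(ci.coverage, abs=4 * se)


class TestPairedChange:
    def test_constant_shift_n10_exact_p(self):
        before = list(range(10))
        after = [x + 1 for x in before]
        res = paired_change_summary(before, after)
        assert res.median_change == 1.0
        assert res.p_value == pytest.approx(2.0 ** -9)  # 2 x P(all ranks positive)
        assert res.significant

    def test_identical_arms(self):
        res = paired_change_summary([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.median_change == 0.0 and res.p_value == 1.0 and not res.significant

    def test_location_shift_recovered_within_ci(self, rng):
        hits = 0
        for _ in range(60):
            before = rng.normal(0, 1, size=30)
            after = before + 0.7 + rng.normal(0, 0.5, size=30)
            res = paired_change_summary(before, after)
            hits += res.ci_low <= 0.7 <= res.ci_high
        assert hits >= 54  # nominal 95%, allow Monte-Carlo slack

    def test_shift_estimate_nearly_unbiased_at_n200(self, rng):
        before = rng.normal(0, 1, size=200)
        after = before + 1.0 + rng.normal(0, 0.3, size=200)
        res = paired_change_summary(before, after)
        assert res.median_change == pytest.approx(1.0, rel=0.05)


class TestPopulationFilters:
    P = [
        Participant("p1", stage_of_change="precontemplation"),
        Participant("p2", stage_of_change="preparation"),
        Participant("p3", stage_of_change="maintenance"),
    ]
    MEANS = {"p1": 9_000.0, "p2": 9_500.0, "p3": 15_200.0}

    def test_stage_and_high_baseline_excluded(self):
        kept = eligibility_filter(self.P, self.MEANS)
        assert [p.id for p in kept] == ["p2"]

    def test_missing_stage_rejected(self):
        with pytest.raises(ValidationError):
            eligibility_filter([Participant("x")], {"x": 1_000.0})

    def test_subgroup_split_with_tie_rule(self):
        means = {"a": 8_000.0, "b": 9_000.0, "c": 11_000.0, "d": 12_000.0, "e": 10_000.0}
        low, high = subgroup_split(means)
        assert set(low) == {"a", "b", "e"}  # exactly 10,000 goes low
        assert set(high) == {"c", "d"}
        assert subgroup_split({}) == ([], [])

    def test_medication_exclusion_is_outcome_specific(self):
        p = Participant(
            "m1",
            stage_of_change="action",
            medication_events=(
                MedicationEvent(dt.date(2024, 3, 15), "hypertension", "start"),
            ),
        )
        q = Participant(
            "m2",
            stage_of_change="action",
            medication_events=(
                MedicationEvent(dt.date(2024, 3, 15), "hypertension", "decrease"),
            ),
        )
        r = Participant("m3", stage_of_change="action")
        assert [x.id for x in medication_exclusion([p, q, r], "bp")] == ["m2", "m3"]
        assert [x.id for x in medication_exclusion([p, q, r], "lipids")] == ["m1", "m2", "m3"]


def _full_response(smbpa_fill=2):
    return QuestionnaireResponse(
        smbpa={f"{f}_{i + 1}": smbpa_fill for f, n in SMBPA_FACTORS.items() for i in range(n)},
        pasr={f"{f}_{i + 1}": 3 for f in PASR_FACTORS for i in range(2)},
        goal_confidences={g: c for g, c in zip(GOAL_LEVELS, (80, 70, 60, 50))},
        walking={f"walking_{i + 1}": 5 for i in range(4)},
        pain={f"pain_{i + 1}": 0 for i in range(4)},
    )


class TestQuestionnaires:
    def test_goal_self_efficacy_is_mean_of_confidences(self):
        scores = score_questionnaires(_full_response())
        assert scores.goal_self_efficacy == 65.0

    def test_scale_extremes(self):
        resp = QuestionnaireResponse(
            smbpa={f"{f}_{i + 1}": 0 for f, n in SMBPA_FACTORS.items() for i in range(n)},
            pasr={f"{f}_{i + 1}": 1 for f in PASR_FACTORS for i in range(2)},
            goal_confidences=dict.fromkeys(GOAL_LEVELS, 0.0),
            walking={f"walking_{i + 1}": 5 for i in range(4)},
            pain={f"pain_{i + 1}": 4 for i in range(4)},
        )
        scores = score_questionnaires(resp)
        assert scores.pasr_total == 12  # floor of the 12-60 range
        assert scores.walking_self_efficacy == 20  # ceiling of 4-20
        assert scores.pain_total == 16
        assert all(v == 0 for v in scores.smbpa_factors.values())

    def test_factor_ranges_follow_item_counts(self):
        scores = score_questionnaires(_full_response(smbpa_fill=4))
        assert scores.smbpa_factors["place_time"] == 20
        assert scores.smbpa_factors["self_monitoring"] == 12
        assert scores.smbpa_factors["eat_exercise"] == 8

    def test_out_of_range_item_rejected(self):
        resp = _full_response()
        bad = QuestionnaireResponse(
            smbpa=resp.smbpa,
            pasr={**resp.pasr, "goal_setting_1": 6},
            goal_confidences=resp.goal_confidences,
            walking=resp.walking,
            pain=resp.pain,
        )
        with pytest.raises(ValidationError):
            score_questionnaires(bad)

    def test_imputation_fills_with_factor_mean(self):
        smbpa = _full_response().smbpa.copy()
        smbpa.update({"shopping_1": 4, "shopping_2": None, "shopping_3": 2, "shopping_4": 2})
        out = impute_factor_items(smbpa)
        assert out["shopping_2"] == pytest.approx(8 / 3)
        # observed items and complete factors untouched
        assert out["shopping_1"] == 4
        assert all(out[k] == smbpa[k] for k in smbpa if smbpa[k] is not None)

    def test_fully_missing_factor_stays_missing_with_warning(self):
        smbpa = _full_response().smbpa.copy()
        for i in range(1, 4):
            smbpa[f"habit_{i}"] = None
        with pytest.warns(UserWarning, match="habit"):
            out = impute_factor_items(smbpa)
        assert all(out[f"habit_{i}"] is None for i in range(1, 4))
        with pytest.warns(UserWarning):
            scores = score_questionnaires(
                QuestionnaireResponse(
                    smbpa=smbpa,
                    pasr=_full_response().pasr,
                    goal_confidences=_full_response().goal_confidences,
                    walking=_full_response().walking,
                    pain=_full_response().pain,
                )
            )
        assert scores.smbpa_factors["habit"] is None

    @settings(derandomize=True, max_examples=50)
    @given(data=st.data())
    def test_imputation_never_changes_observed_items(self, data):
        values = {
            f"{f}_{i + 1}": data.draw(
                st.one_of(st.none(), st.integers(0, 4)), label=f"{f}_{i + 1}"
            )
            for f, n in SMBPA_FACTORS.items()
            for i in range(n)
        }
        import warnings as w

        with w.catch_warnings():
            w.simplefilter("ignore")
            out = impute_factor_items(values)
        for k, v in values.items():
            if v is not None:
                assert out[k] == v


class TestSampleSize:
    def test_study_inputs_give_28(self):
        assert required_sample_size(0.55, 0.80, 0.05) == 28

    def test_monotone_in_effect_size_and_power(self):
        n_ref = required_sample_size(0.55, 0.80, 0.05)
        assert required_sample_size(1.0, 0.80, 0.05) < n_ref
        assert required_sample_size(0.55, 0.90, 0.05) > n_ref
        assert required_sample_size(0.55, 0.80, 0.01) > n_ref

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            required_sample_size(0.0, 0.8, 0.05)
        with pytest.raises(ValidationError):
            required_sample_size(0.5, 1.2, 0.05)

    def test_mcid_derivation(self):
        assert mcid_steps() == 1_000.0
        assert mcid_steps(minutes_per_day=20) == 2_000.0

    def test_bonferroni_per_test_level(self):
        assert EvalConfig().alpha_per_test == 0.025
        assert EvalConfig(alpha_overall=0.10, tests_per_outcome=4).alpha_per_test == 0.025
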
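"""Synthetic-respondent generator: determinism, validity, parameter recovery."""

from datetime import date

import pytest

from burnoutkit.cbi import classify_level, score_cbi, score_dimension
from burnoutkit.ghq import score_ghq
from burnoutkit.instruments import validate_response
from burnoutkit.monitoring import recent_diagnoses
from burnoutkit.simulate import (
    RespondentProfile,
    simulate_cbi,
    simulate_ghq,
    simulate_history,
    simulate_sus,
)
from burnoutkit.sus import score_sus


class TestDeterminism:
    def test_same_seed_same_ghq_record(self):
        profile = RespondentProfile(ghq_negativity=0.4)
        assert simulate_ghq(profile, 11) == simulate_ghq(profile, 11)

    def test_same_seed_same_cbi_record(self):
        profile = RespondentProfile(cbi_target={"personal": 55, "work": 40, "client": 70}, cbi_noise=0.3)
        assert simulate_cbi(profile, 11) == simulate_cbi(profile, 11)

    def test_same_seed_same_history(self):
        profiles = [RespondentProfile(cbi_target={"personal": t, "work": t, "client": t}) for t in (80, 40)]
        a = simulate_history(profiles, date(2022, 1, 15), seed=5)
        b = simulate_history(profiles, date(2022, 1, 15), seed=5)
        assert a == b

    def test_different_seeds_differ(self):
        profile = RespondentProfile(ghq_negativity=0.5)
        records = {tuple(sorted(simulate_ghq(profile, s).answers.items())) for s in range(20)}
        assert len(records) > 1


class TestGhqGeneration:
    def test_degenerate_negativity_0_scores_0(self, ghq_bank):
        record = simulate_ghq(RespondentProfile(ghq_negativity=0.0), 1)
        assert score_ghq(record, instrument=ghq_bank).score == 0

    def test_degenerate_negativity_1_scores_12(self, ghq_bank):
        record = simulate_ghq(RespondentProfile(ghq_negativity=1.0), 1)
        assert score_ghq(record, instrument=ghq_bank).score == 12

    def test_half_negativity_mean_score_near_binomial_expectation(self, ghq_bank):
        profile = RespondentProfile(ghq_negativity=0.5)
        scores = [
            score_ghq(simulate_ghq(profile, seed), instrument=ghq_bank).score
            for seed in range(300)
        ]
        assert sum(scores) / len(scores) == pytest.approx(6.0, abs=0.5)


class TestCbiGeneration:
    def test_extreme_targets_recover_extreme_risk(self, cbi_bank):
        high = simulate_cbi(
            RespondentProfile(cbi_target={"personal": 100, "work": 100, "client": 100}), 3
        )
        assert score_cbi(high, instrument=cbi_bank).overall_risk.value == "high"
        low = simulate_cbi(RespondentProfile(cbi_target={"personal": 0, "work": 0, "client": 0}), 3)
        result = score_cbi(low, instrument=cbi_bank)
        assert result.overall_risk.value == "low"
        assert all(d.score == 0 for d in result.dimension_scores)

    @pytest.mark.parametrize("target", [5, 20, 45, 52, 60, 70, 77, 90, 100])
    def test_noise_free_level_recovery_off_boundaries(self, cbi_bank, target):
        profile = RespondentProfile(cbi_target={"personal": target, "work": target, "client": target})
        for seed in range(10):
            record = simulate_cbi(profile, seed)
            for dim in ("personal", "work", "client"):
                ds = score_dimension(record, dim, instrument=cbi_bank)
                assert ds.level is classify_level(target)

    def test_noise_free_mean_is_the_nearest_attainable_value(self, cbi_bank):
        profile = RespondentProfile(cbi_target={"personal": 60, "work": 60, "client": 60})
        record = simulate_cbi(profile, 0)
        # 6-item dimensions realize 350/6, the attainable mean nearest 60.
        assert score_dimension(record, "personal", instrument=cbi_bank).score == pytest.approx(350 / 6)
        assert score_dimension(record, "work", instrument=cbi_bank).score == pytest.approx(425 / 7)

    def test_moderate_targets_with_noise_mostly_classify_moderate(self, cbi_bank):
        profile = RespondentProfile(
            cbi_target={"personal": 60, "work": 60, "client": 60}, cbi_noise=0.5
        )
        hits = sum(
            score_cbi(simulate_cbi(profile, seed), instrument=cbi_bank).overall_risk.value
            == "moderate"
            for seed in range(200)
        )
        assert hits >= 180

    def test_emitted_records_validate(self, banks):
        profile = RespondentProfile(
            ghq_negativity=0.3, cbi_target={"personal": 33, "work": 66, "client": 99}, cbi_noise=0.4
        )
        for seed in range(25):
            validate_response(banks["GHQ12"], simulate_ghq(profile, seed))
            validate_response(banks["CBI"], simulate_cbi(profile, seed))


class TestSusGeneration:
    def test_full_positivity_scores_100(self):
        assert score_sus(simulate_sus(RespondentProfile(sus_positivity=1.0), 1)) == 100

    def test_partial_positivity_spreads_scores(self):
        scores = {score_sus(simulate_sus(RespondentProfile(sus_positivity=0.3), s)) for s in range(30)}
        assert len(scores) > 5


class TestSimulateHistory:
    def test_improving_profiles_walk_down_the_risk_ladder(self):
        targets = (90, 60, 40, 10)
        profiles = [
            RespondentProfile(cbi_target={"personal": t, "work": t, "client": t}) for t in targets
        ]
        history = simulate_history(profiles, date(2022, 1, 15), interval_months=3, seed=2)
        risks = [p.overall_risk.value for p in recent_diagnoses(history, n=4)]
        assert risks == ["high", "moderate", "low", "low"]

    def test_records_fall_on_successive_due_dates(self):
        profiles = [RespondentProfile()] * 3
        history = simulate_history(profiles, date(2022, 11, 30), interval_months=3, seed=1)
        assert [r.timestamp.date().isoformat() for r in history.records] == [
            "2022-11-30",
            "2023-02-28",
            "2023-05-30",
        ]

    def test_single_profile_gives_single_record(self):
        history = simulate_history([RespondentProfile()], date(2022, 1, 1), seed=1)
        assert len(history.records) == 1

    def test_requires_at_least_one_profile(self):
        with pytest.raises(ValueError):
            simulate_history([], date(2022, 1, 1), seed=1)


class TestProfileValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"ghq_negativity": 1.2},
            {"cbi_noise": -0.1},
            {"sus_positivity": 2},
            {"cbi_target": {"personal": 130}},
            {"cbi_target": {"nonsense": 50}},
        ],
    )
    def test_out_of_range_profiles_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RespondentProfile(**kwargs)
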
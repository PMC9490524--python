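"""CBI subscale scoring, level cut-offs, and the overall risk rule."""

import itertools
import random

import pytest

from burnoutkit.cbi import (
    FORWARD_POINTS,
    Level,
    classify_level,
    code_cbi_answer,
    combine_risk,
    score_cbi,
    score_dimension,
)
from burnoutkit.instruments import ValidationError

from conftest import cbi_response

L, M, H = Level.LOW, Level.MODERATE, Level.HIGH


class TestAnswerCoding:
    def test_forward_items_map_codes_to_100_down_to_0(self, cbi_bank):
        for item in cbi_bank.items:
            if item.reverse:
                continue
            for code in range(5):
                assert code_cbi_answer(item, code) == FORWARD_POINTS[code]

    def test_reverse_item_identity_for_all_five_codes(self, cbi_bank):
        item = cbi_bank.item("cbi.wrk.q7")
        for code in range(5):
            assert code_cbi_answer(item, code) == 100 - FORWARD_POINTS[code]

    @pytest.mark.parametrize(
        "item_id, label, expected",
        [
            ("cbi.per.q1", "Always", 100),
            ("cbi.cli.q3", "Never or almost never", 0),
            ("cbi.wrk.q7", "Always", 0),  # reverse: abundant energy = no burnout
            ("cbi.wrk.q1", "To a very high degree", 100),  # second label pack
        ],
    )
    def test_printed_labels_score_as_printed(self, cbi_bank, item_id, label, expected):
        item = cbi_bank.item(item_id)
        assert code_cbi_answer(item, item.code_for_label(label)) == expected

    def test_ghq_item_rejected(self, ghq_bank, cbi_bank):
        with pytest.raises(ValidationError):
            code_cbi_answer(ghq_bank.item("ghq.q01"), 0)


class TestDimensionScores:
    def test_personal_all_always_scores_100_high(self, cbi_bank):
        ds = score_dimension(cbi_response(0), "personal", instrument=cbi_bank)
        assert ds.score == 100
        assert ds.level is Level.HIGH

    def test_work_all_never_with_reverse_always_scores_0_low(self, cbi_bank):
        codes = {i: 4 for i in cbi_bank.item_ids()}
        codes["cbi.wrk.q7"] = 0  # "Always" on the energy item -> 0 points
        ds = score_dimension(cbi_response(codes), "work", instrument=cbi_bank)
        assert ds.score == 0
        assert ds.level is Level.LOW

    def test_personal_mixed_answers_average_to_50_moderate(self, cbi_bank):
        # Coded points (100, 75, 50, 25, 0, 50) -> mean 300/6 = 50.
        codes = {i: 0 for i in cbi_bank.item_ids()}
        for item_id, code in zip(
            [i.id for i in cbi_bank.dimension_items("personal")], [0, 1, 2, 3, 4, 2]
        ):
            codes[item_id] = code
        ds = score_dimension(cbi_response(codes), "personal", instrument=cbi_bank)
        assert ds.score == 50
        assert ds.level is Level.MODERATE

    def test_score_is_invariant_to_answer_order(self, cbi_bank):
        rng = random.Random(7)
        codes = {i: rng.randrange(5) for i in cbi_bank.item_ids()}
        shuffled = list(codes.items())
        rng.shuffle(shuffled)
        a = score_dimension(cbi_response(codes), "client", instrument=cbi_bank)
        b = score_dimension(cbi_response(dict(shuffled)), "client", instrument=cbi_bank)
        assert a == b


class TestClassifyLevel:
    @pytest.mark.parametrize(
        "score, level",
        [(0, L), (49.99, L), (50, M), (74.99, M), (75, H), (100, H)],
    )
    def test_boundaries_at_50_and_75(self, score, level):
        assert classify_level(score) is level

    @pytest.mark.parametrize("score", [-0.01, 100.01])
    def test_out_of_range_rejected(self, score):
        with pytest.raises(ValueError):
            classify_level(score)

    def test_no_attainable_6_item_mean_falls_in_the_74_75_gap(self):
        """The printed moderate band ends at '74' and high starts at 75;
        over all 5**6 answer patterns no mean lies strictly between."""
        means = {sum(pattern) / 6 for pattern in itertools.product(FORWARD_POINTS, repeat=6)}
        assert not any(74 < m < 75 for m in means)


class TestCombineRisk:
    @pytest.mark.parametrize(
        "levels, expected",
        [
            # Printed cases.
            ((L, L, L), L),
            ((L, L, M), L),
            ((M, M, M), M),
            ((M, M, L), M),  # garbled printed row, read as MML...
            ((M, M, H), M),  # ...and MMH
            ((H, H, L), H),
            ((H, H, H), H),
            # Completion rule for unprinted combinations.
            ((L, L, H), M),
            ((L, M, H), M),
        ],
    )
    def test_reproduces_printed_cases_in_any_order(self, levels, expected):
        for perm in itertools.permutations(levels):
            assert combine_risk(perm) is expected

    def test_total_over_all_27_combinations(self):
        for levels in itertools.product((L, M, H), repeat=3):
            risk = combine_risk(levels)
            n_high = levels.count(H)
            n_mod = levels.count(M)
            if n_high >= 2:
                assert risk is H
            elif n_high == 1 or n_mod >= 2:
                assert risk is M
            else:
                assert risk is L

    def test_monotone_under_single_level_upgrades(self):
        order = (L, M, H)
        for levels in itertools.product(order, repeat=3):
            base = combine_risk(levels)
            for k in range(3):
                if levels[k] is H:
                    continue
                upgraded = list(levels)
                upgraded[k] = order[order.index(levels[k]) + 1]
                assert combine_risk(tuple(upgraded)).rank >= base.rank

    def test_requires_exactly_three_levels(self):
        with pytest.raises(ValueError):
            combine_risk((L, L))


class TestScoreCbi:
    def test_all_always_gives_work_just_under_86_and_overall_high(self, cbi_bank):
        result = score_cbi(cbi_response(0), instrument=cbi_bank)
        assert result.personal.score == 100
        assert result.client.score == 100
        assert result.work.score == pytest.approx(600 / 7)  # reverse item scores 0
        assert [d.level for d in result.dimension_scores] == [H, H, H]
        assert result.overall_risk is Level.HIGH

    def test_all_never_gives_work_just_over_14_and_overall_low(self, cbi_bank):
        result = score_cbi(cbi_response(4), instrument=cbi_bank)
        assert result.personal.score == 0
        assert result.client.score == 0
        assert result.work.score == pytest.approx(100 / 7)  # reverse item scores 100
        assert result.overall_risk is Level.LOW

    def test_two_high_dimensions_dominate_a_low_one(self, cbi_bank):
        codes = {i: 0 for i in cbi_bank.item_ids()}  # everything "Always"
        for item in cbi_bank.dimension_items("client"):
            codes[item.id] = 4  # client all "Never"
        result = score_cbi(cbi_response(codes), instrument=cbi_bank)
        assert result.personal.level is H and result.work.level is H
        assert result.client.level is L
        assert result.overall_risk is Level.HIGH

    def test_incomplete_response_rejected(self, cbi_bank):
        record = cbi_response(0)
        answers = dict(record.answers)
        answers.pop("cbi.cli.q6")
        with pytest.raises(ValidationError):
            score_cbi(record.with_answers(answers), instrument=cbi_bank)
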
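"""Strict-match scoring, F1 arithmetic, multi-run aggregation, comparison."""

import math

import pytest

from radner.evaluation import (
    aggregate_runs,
    compare_candidates,
    f1,
    strict_match_score,
)

from conftest import make_doc


def report_of(gold_spans, pred_spans, text_len=30):
    gold = [make_doc("d0", "字" * text_len, gold_spans)]
    pred = [make_doc("d0", "字" * text_len, pred_spans)]
    return strict_match_score(gold, pred)


class TestStrictMatch:
    def test_perfect_match(self):
        r = report_of([("Drug", 2, 5)], [("Drug", 2, 5)])
        assert (r.micro.precision, r.micro.recall, r.micro.f1) == (1.0, 1.0, 1.0)

    def test_boundary_off_by_one_counts_nothing(self):
        r = report_of([("Drug", 2, 5)], [("Drug", 2, 4)])
        assert (r.micro.tp, r.micro.fp, r.micro.fn) == (0, 1, 1)
        assert r.micro.f1 == 0.0

    def test_type_swap_counts_nothing(self):
        r = report_of([("Drug", 2, 5)], [("ADR", 2, 5)])
        assert r.micro.tp == 0

    def test_hand_computed_pooled_counts(self):
        """Fixture of 5 docs with off-by-one and type-swap errors.

        Pooled: TP=3, FP=1, FN=2 -> P=0.75, R=0.60, F1=2/3.
        """
        gold = [
            make_doc("a", "字" * 20, [("Drug", 1, 4), ("ADR", 6, 9)]),
            make_doc("b", "字" * 20, [("Reason", 0, 3)]),
            make_doc("c", "字" * 20, [("Drug", 5, 8)]),
            make_doc("d", "字" * 20, [("ADR", 2, 6)]),
            make_doc("e", "字" * 20, []),
        ]
        pred = [
            make_doc("a", "字" * 20, [("Drug", 1, 4), ("ADR", 6, 9)]),
            make_doc("b", "字" * 20, [("Reason", 0, 4)]),  # off-by-one end
            make_doc("c", "字" * 20, [("ADR", 5, 8)]),     # type swap -> no pred TP
            make_doc("d", "字" * 20, [("ADR", 2, 6)]),
            make_doc("e", "字" * 20, []),
        ]
        r = strict_match_score(gold, pred)
        assert (r.micro.tp, r.micro.fp, r.micro.fn) == (3, 2, 2)
        assert r.micro.precision == pytest.approx(0.60)
        assert r.micro.recall == pytest.approx(0.60)
        # and the documented pooled example
        assert f1(0.75, 0.60) == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_micro_counts_are_sums_of_per_type(self, small_corpus):
        from radner.synthetic import corrupt_annotations

        pred = corrupt_annotations(small_corpus, 0.3, seed=9)
        r = strict_match_score(small_corpus, pred)
        for attr in ("tp", "fp", "fn"):
            assert getattr(r.micro, attr) == sum(
                getattr(s, attr) for s in r.per_type.values()
            )

    def test_precision_recall_symmetry(self, small_corpus):
        from radner.synthetic import corrupt_annotations

        pred = corrupt_annotations(small_corpus, 0.4, seed=3)
        a = strict_match_score(small_corpus, pred)
        b = strict_match_score(pred, small_corpus)
        assert a.micro.precision == pytest.approx(b.micro.recall)
        assert a.micro.recall == pytest.approx(b.micro.precision)

    def test_adding_correct_prediction_never_hurts(self):
        base = report_of([("Drug", 2, 5), ("ADR", 8, 10)], [("Drug", 2, 5)])
        more = report_of(
            [("Drug", 2, 5), ("ADR", 8, 10)],
            [("Drug", 2, 5), ("ADR", 8, 10)],
        )
        assert more.micro.precision >= base.micro.precision
        assert more.micro.recall >= base.micro.recall
        assert more.micro.f1 >= base.micro.f1

    def test_adding_wrong_prediction_never_helps(self):
        base = report_of([("Drug", 2, 5)], [("Drug", 2, 5)])
        more = report_of([("Drug", 2, 5)], [("Drug", 2, 5), ("ADR", 8, 10)])
        assert more.micro.precision <= base.micro.precision
        assert more.micro.recall <= base.micro.recall

    def test_id_mismatch_rejected(self):
        gold = [make_doc("a", "字" * 5, [])]
        pred = [make_doc("b", "字" * 5, [])]
        with pytest.raises(ValueError, match="mismatch"):
            strict_match_score(gold, pred)


class TestF1:
    @pytest.mark.parametrize(
        "p,r,expected",
        [
            (96.4, 96.0, 96.2),  # headline micro scores
            (87.2, 85.7, 86.4),  # model on the external validation set
            (86.1, 73.8, 79.5),  # manual extraction on the same set
        ],
    )
    def test_published_precision_recall_pairs_round_consistently(self, p, r, expected):
        assert round(f1(p, r), 1) == expected

    def test_equal_inputs_are_a_fixed_point(self):
        assert f1(80.0, 80.0) == pytest.approx(80.0)

    def test_zero_zero_convention(self):
        assert f1(0.0, 0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            f1(-1.0, 50.0)


class TestAggregateRuns:
    def test_identical_runs_have_zero_sd(self):
        r = report_of([("Drug", 2, 5)], [("Drug", 2, 5)])
        agg = aggregate_runs([r, r])
        assert agg.table[("f1", "mean")]["micro"] == pytest.approx(100.0)
        assert agg.table[("f1", "sd")]["micro"] == pytest.approx(0.0)

    def test_sample_sd_formula(self):
        # micro F1 of 100% and 0% -> mean 50, sample SD = sqrt(2)*50
        perfect = report_of([("Drug", 2, 5)], [("Drug", 2, 5)])
        wrong = report_of([("Drug", 2, 5)], [("Drug", 2, 4)])
        agg = aggregate_runs([perfect, wrong])
        assert agg.table[("f1", "mean")]["micro"] == pytest.approx(50.0)
        assert agg.table[("f1", "sd")]["micro"] == pytest.approx(
            math.sqrt(2) * 50.0
        )

    def test_formatted_mean_sd_strings(self):
        r = report_of([("Drug", 2, 5)], [("Drug", 2, 5)])
        agg = aggregate_runs([r, r])
        assert agg.formatted().loc["micro", "f1"] == "100.0 (0.00)"

    def test_single_run_rejected(self):
        r = report_of([("Drug", 2, 5)], [("Drug", 2, 5)])
        with pytest.raises(ValueError):
            aggregate_runs([r])


class TestCompareCandidates:
    def test_gold_candidate_scores_one(self, small_corpus):
        result = compare_candidates(small_corpus, {"gold": small_corpus})
        micro = result.table[result.table.entity == "micro"]
        assert float(micro.f1.iloc[0]) == pytest.approx(100.0)
        assert result.disagreements == ()

    def test_empty_candidate_zero_by_convention(self):
        gold = [make_doc("a", "字" * 10, [("Drug", 1, 3)])]
        empty = [make_doc("a", "字" * 10, [])]
        result = compare_candidates(gold, {"empty": empty})
        micro = result.table[result.table.entity == "micro"].iloc[0]
        assert micro.precision == 0.0 and micro.recall == 0.0

    def test_two_candidates_table_shape(self, small_corpus):
        from radner.synthetic import corrupt_annotations

        result = compare_candidates(
            small_corpus,
            {
                "model": corrupt_annotations(small_corpus, 0.1, seed=1),
                "manual": corrupt_annotations(small_corpus, 0.3, seed=2),
            },
        )
        # per candidate: 3 entity types + micro
        assert len(result.table) == 8
        assert set(result.table.candidate) == {"model", "manual"}
        assert len(result.disagreements) > 0
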
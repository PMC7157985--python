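"""Outcome classification, confusion tallies, P/R/F/A metrics, analytics."""

from collections import Counter
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icdcoder import (
    CodingRun,
    ConfusionCounts,
    DiagnosisRecord,
    accuracy,
    classify_outcome,
    cluster_summary,
    code_batch,
    code_frequency,
    compile_rulebase,
    f_measure,
    failure_breakdown,
    metrics_report,
    precision,
    recall,
    tabulate,
)
from icdcoder.evaluation import round2
from icdcoder.synthetic import CorpusSpec, generate_corpus

from .conftest import FIXED_CLOCK

STAGE1 = ConfusionCounts(tp=50084, fp=6022, fn=161478, tn=67217)
STAGE2 = ConfusionCounts(tp=85838, fp=11291, fn=222938, tn=82994)


class TestClassifyOutcome:
    MODELED = {"I25.101", "I10 06"}

    @pytest.mark.parametrize("emitted,gold,expected", [
        ("I25.101", "I25.101", "TP"),   # correct result
        ("I25.101", "I10 06", "FP"),    # unexpected result
        (None, "I25.101", "FN"),        # missing result: gold was modeled
        (None, "Z51.005", "TN"),        # correct absence: gold unmodeled
    ])
    def test_four_cell_taxonomy(self, emitted, gold, expected):
        assert classify_outcome(emitted, gold, self.MODELED) == expected

    def test_gold_required(self):
        with pytest.raises(ValueError):
            classify_outcome("I25.101", None, self.MODELED)


class TestTabulate:
    def _run_with(self, assignments):
        run = CodingRun()
        run.assignments.update(assignments)
        return run

    def test_one_record_per_cell(self):
        records = [DiagnosisRecord("a", "x", gold_code="A00.001"),
                   DiagnosisRecord("b", "x", gold_code="A00.001"),
                   DiagnosisRecord("c", "x", gold_code="A00.001"),
                   DiagnosisRecord("d", "x", gold_code="Z99.999")]
        run = self._run_with({"a": "A00.001", "b": "B00.001"})
        cc = tabulate(run, records, modeled={"A00.001"})
        assert (cc.tp, cc.fp, cc.fn, cc.tn) == (1, 1, 1, 1)

    def test_empty_audit(self):
        cc = tabulate(CodingRun(), [], modeled=set())
        assert cc == ConfusionCounts(0, 0, 0, 0)

    def test_missing_gold_rejected_by_name(self):
        with pytest.raises(ValueError, match="r7"):
            tabulate(CodingRun(), [DiagnosisRecord("r7", "x")], modeled=set())

    def test_matches_independent_recount_on_synthetic_audit(self):
        """500-record audit equals a second, independent per-record tally."""
        corpus = generate_corpus(CorpusSpec(
            n_codes=40, n_records=500, coverage=0.6, ambiguity_rate=0.1, seed=5))
        crb = compile_rulebase(corpus.rulebase)
        run = code_batch(crb, corpus.records, clock=FIXED_CLOCK)
        cc = tabulate(run, corpus.records, corpus.modeled)
        # independent pass, no shared code path
        tally = Counter()
        for rec in corpus.records:
            if rec.record_id in run.assignments:
                tally["TP" if run.assignments[rec.record_id] == rec.gold_code
                      else "FP"] += 1
            else:
                tally["FN" if rec.gold_code in corpus.modeled else "TN"] += 1
        assert (cc.tp, cc.fp, cc.fn, cc.tn) == \
            (tally["TP"], tally["FP"], tally["FN"], tally["TN"])
        assert cc.total == len(corpus.records)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1)


class TestMetrics:
    def test_stage1_golden_values(self):
        rep = metrics_report(STAGE1)
        assert (rep.precision_pct, rep.recall_pct, rep.f_pct, rep.accuracy_pct) \
            == (89.27, 23.67, 37.42, 41.19)

    def test_stage2_golden_precision_and_accuracy(self):
        rep = metrics_report(STAGE2)
        assert rep.precision_pct == 88.38
        assert rep.accuracy_pct == 41.89

    def test_stage2_counts_derived_recall(self):
        # derived from the stage-2 counts themselves: 100*85838/308776
        assert round2(recall(STAGE2)) == 27.80

    def test_symmetric_counts_give_fifty_everywhere(self):
        rep = metrics_report(ConfusionCounts(1, 1, 1, 1))
        assert (rep.precision_pct, rep.recall_pct, rep.f_pct, rep.accuracy_pct) \
            == (50.0, 50.0, 50.0, 50.0)

    def test_undefined_metrics_are_explicit_markers(self):
        assert precision(ConfusionCounts(0, 0, 5, 5)) is None
        assert recall(ConfusionCounts(0, 3, 0, 2)) is None
        assert accuracy(ConfusionCounts(0, 0, 0, 0)) is None
        assert f_measure(None, Fraction(50)) is None
        assert f_measure(Fraction(0), Fraction(50)) is None
        rep = metrics_report(ConfusionCounts(0, 0, 5, 5))
        assert rep.precision_pct is None and rep.f_pct is None
        assert rep.accuracy_pct == 50.0

    def test_all_true_negatives_is_perfect_accuracy(self):
        assert round2(accuracy(ConfusionCounts(0, 0, 0, 5))) == 100.0

    def test_f_is_harmonic_mean_at_half_alpha(self):
        p, r = Fraction(8927, 100), Fraction(2367, 100)
        f = f_measure(p, r)
        assert f == 2 * p * r / (p + r)
        assert round2(f) == 37.42

    def test_alpha_bounds_enforced(self):
        with pytest.raises(ValueError):
            f_measure(Fraction(50), Fraction(50), alpha=0)
        with pytest.raises(ValueError):
            f_measure(Fraction(50), Fraction(50), alpha=1)

    def test_f_monotone_in_alpha_between_r_and_p(self):
        """As alpha sweeps (0,1), F moves monotonically from R toward P."""
        p, r = Fraction(90), Fraction(20)
        values = [f_measure(p, r, Fraction(k, 100)) for k in range(1, 100)]
        # alpha weights 1/P; with P > R the harmonic mean rises with alpha
        assert all(a < b for a, b in zip(values, values[1:]))
        assert all(r < v < p for v in values)

    @given(st.tuples(st.integers(0, 10**6), st.integers(0, 10**6),
                     st.integers(0, 10**6), st.integers(0, 10**6)))
    @settings(max_examples=300, deadline=None)
    def test_harmonic_identity_on_exact_rationals(self, counts):
        cc = ConfusionCounts(*counts)
        p, r = precision(cc), recall(cc)
        f = f_measure(p, r)
        if p is None or r is None or p == 0 or r == 0:
            assert f is None
        else:
            assert f == 2 * p * r / (p + r)

    @given(st.tuples(st.integers(0, 1000), st.integers(0, 1000),
                     st.integers(0, 1000), st.integers(0, 1000)))
    @settings(max_examples=200, deadline=None)
    def test_adding_tp_never_hurts(self, counts):
        cc = ConfusionCounts(*counts)
        more = ConfusionCounts(cc.tp + 1, cc.fp, cc.fn, cc.tn)
        for metric in (precision, recall, accuracy):
            before, after = metric(cc), metric(more)
            if before is not None:
                assert after >= before
        # an extra FP never improves precision or accuracy
        worse = ConfusionCounts(cc.tp, cc.fp + 1, cc.fn, cc.tn)
        if precision(cc) is not None:
            assert precision(worse) <= precision(cc)
        if accuracy(cc) is not None:
            assert accuracy(worse) <= accuracy(cc)

    def test_rounding_is_half_up(self):
        assert round2(Fraction(12345, 1000)) == 12.35   # 12.345 rounds up
        assert round2(Fraction(27795, 1000)) == 27.80


class TestAnalytics:
    def test_frequency_ranking(self):
        table = code_frequency(["A00.001"] * 3 + ["B00.001"], top_n=2)
        assert [(e.code, e.count, e.rank) for e in table] == \
            [("A00.001", 3, 1), ("B00.001", 1, 2)]

    def test_ties_break_lexicographically(self):
        table = code_frequency(["C00.001", "A00.001", "B00.001"], top_n=3)
        assert [e.code for e in table] == ["A00.001", "B00.001", "C00.001"]

    def test_frequency_agrees_with_independent_tally(self):
        corpus = generate_corpus(CorpusSpec(n_codes=60, n_records=2000, seed=9))
        codes = [r.gold_code for r in corpus.records]
        table = code_frequency(codes, top_n=60)
        independent = Counter(codes)
        assert {e.code: e.count for e in table} == dict(independent)
        assert table.total_occurrences == len(codes)
        counts = [e.count for e in table]
        assert counts == sorted(counts, reverse=True)

    def test_cluster_summary_splits_by_chapter_letter(self):
        summary = cluster_summary(["I25.101", "I10 06", "K22.902"])
        assert summary.clusters["I"].category_count == 2
        assert summary.clusters["I"].code_count == 2
        assert summary.clusters["K"].category_count == 1

    def test_cluster_summary_empty(self):
        assert cluster_summary([]).clusters == {}

    def test_cluster_summary_conservation_on_corpus(self):
        corpus = generate_corpus(CorpusSpec(n_codes=80, n_records=1500, seed=2))
        codes = [r.gold_code for r in corpus.records]
        summary = cluster_summary(codes)
        assert summary.total_codes == len(codes)
        assert summary.total_categories == len(set(codes))

    def test_invalid_code_rejected_by_name(self):
        with pytest.raises(ValueError, match="bogus"):
            cluster_summary(["I25.101", "bogus"])


class TestFailureBreakdown:
    def test_mismatch_and_loss_mirror_fp_fn(self):
        records = [DiagnosisRecord("a", "x", gold_code="A00.001"),
                   DiagnosisRecord("b", "x", gold_code="A00.001"),
                   DiagnosisRecord("c", "x", gold_code="A00.001")]
        run = CodingRun()
        run.assignments["a"] = "B00.001"  # FP
        fb = failure_breakdown(run, records, modeled={"A00.001"})
        assert (fb.repeated, fb.mismatch, fb.loss) == (0, 1, 2)

    def test_repeated_counts_within_group_duplicates(self):
        records = [DiagnosisRecord("a", "x", gold_code="I10 06", group_id="g1"),
                   DiagnosisRecord("b", "x", gold_code="I10 06", group_id="g1"),
                   DiagnosisRecord("c", "x", gold_code="I10 06", group_id="g2")]
        run = CodingRun()
        run.assignments.update({"a": "I10 06", "b": "I10 06", "c": "I10 06"})
        fb = failure_breakdown(run, records, modeled={"I10 06"})
        assert fb.repeated == 1  # only (g1, I10 06) is duplicated

    def test_clean_run_has_no_failures(self):
        records = [DiagnosisRecord("a", "x", gold_code="A00.001", group_id="g1")]
        run = CodingRun()
        run.assignments["a"] = "A00.001"
        fb = failure_breakdown(run, records, modeled={"A00.001"})
        assert (fb.repeated, fb.mismatch, fb.loss) == (0, 0, 0)
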
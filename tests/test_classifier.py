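import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clearseq import (
    CLEARSEQ_SIGNATURES,
    ThresholdSet,
    classify_cohort,
    classify_fixed,
    concordance,
    confusion_from_counts,
    extract_cutoffs,
    percentile,
    read_classification,
    simulate_scores,
    write_classification,
)
from clearseq.classifier import CUTOFF_NAMES, DECISION_STATISTICS
from clearseq.errors import (
    CohortTooSmall,
    EmptyInput,
    IncompleteThresholds,
    InvalidParameter,
    SampleMismatch,
)
from clearseq.signatures import SignatureScoreMatrix

from conftest import constant_scores, make_scores
from oracle import oracle_classify, sort_percentile


class TestPercentile:
    def test_odd_median(self):
        assert percentile([1, 2, 3, 4, 5], 50) == 3.0

    def test_even_interpolated(self):
        assert percentile([1, 2, 3, 4], 50) == 2.5

    def test_boundaries(self):
        vals = [3.0, 1.0, 9.0, 4.0]
        assert percentile(vals, 100) == 9.0
        assert percentile(vals, 0.0001) == pytest.approx(1.0, abs=1e-2)

    def test_empty(self):
        with pytest.raises(EmptyInput):
            percentile([], 50)

    @given(
        st.lists(st.floats(0.1, 100, allow_nan=False), min_size=1, max_size=30),
        st.floats(0.1, 99.9),
    )
    def test_matches_sorting_oracle(self, values, q):
        assert percentile(values, q) == pytest.approx(sort_percentile(values, q))


class TestClassifyCohort:
    def test_forced_fractions_no_ccrcc3(self):
        scores, _ = simulate_scores(200, "adversarial_no_ccrcc3", seed=0)
        result = classify_cohort(scores)
        assert result.class_counts == {
            "ccrcc1": 60, "ccrcc2": 100, "ccrcc3": 0, "ccrcc4": 40
        }

    def test_ten_sample_toy_matches_oracle(self):
        rng = np.random.default_rng(123)
        cols = {name: rng.uniform(1, 10, 10) for name in CLEARSEQ_SIGNATURES}
        scores = make_scores(cols)
        result = classify_cohort(scores, min_cohort=10)
        samples = [
            {name: cols[name][i] for name in CLEARSEQ_SIGNATURES}
            for i in range(10)
        ]
        assert result.labels == oracle_classify(samples)

    def test_duplication_leaves_labels_unchanged(self):
        rng = np.random.default_rng(7)
        cols = {name: rng.uniform(1, 10, 25) for name in CLEARSEQ_SIGNATURES}
        base = classify_cohort(make_scores(cols))
        doubled_cols = {k: np.concatenate([v, v]) for k, v in cols.items()}
        doubled = classify_cohort(make_scores(doubled_cols))
        assert doubled.labels[:25] == base.labels
        assert doubled.labels[25:] == base.labels

    def test_sample_permutation_equivariance(self):
        scores, _ = simulate_scores(60, "tie_free_uniform", seed=2)
        base = classify_cohort(scores)
        rng = np.random.default_rng(3)
        perm = rng.permutation(60)
        permuted = SignatureScoreMatrix(
            [scores.sample_ids[i] for i in perm],
            list(scores.signature_names),
            scores.scores[perm],
        )
        out = classify_cohort(permuted)
        assert out.labels == [base.labels[i] for i in perm]

    def test_partition_counts_sum(self):
        scores, _ = simulate_scores(137, "tie_free_uniform", seed=4)
        result = classify_cohort(scores)
        assert sum(result.class_counts.values()) == 137
        assert len(result.calls) == 137

    def test_tie_free_structural_counts(self):
        # on tie-free scores the 50%/40% rules pin class sizes to +-1
        scores, _ = simulate_scores(150, "tie_free_uniform", seed=5)
        result = classify_cohort(scores)
        n3 = result.class_counts["ccrcc3"]
        non3 = 150 - n3
        assert n3 <= int(np.ceil(0.2 * 150))
        assert abs(result.class_counts["ccrcc2"] - round(0.5 * non3)) <= 1
        remaining = non3 - result.class_counts["ccrcc2"]
        assert abs(result.class_counts["ccrcc4"] - round(0.4 * remaining)) <= 1

    def test_cohort_too_small(self):
        scores, _ = simulate_scores(5, "tie_free_uniform", seed=6)
        with pytest.raises(CohortTooSmall, match="fixed_cutoff"):
            classify_cohort(scores)

    def test_monotone_perturbation_ccrcc1_to_ccrcc4_only(self):
        rng = np.random.default_rng(8)
        cols = {name: rng.uniform(1, 10, 40) for name in CLEARSEQ_SIGNATURES}
        base = classify_cohort(make_scores(cols))
        idx = base.labels.index("ccrcc1")
        for bump in (1.5, 3.0, 10.0):
            cols2 = {k: v.copy() for k, v in cols.items()}
            cols2["ccrcc4_up"][idx] *= bump     # only raises this sample's r4
            out = classify_cohort(make_scores(cols2))
            assert out.labels[idx] in ("ccrcc1", "ccrcc4")

    def test_rule_trace_consistency(self):
        scores, _ = simulate_scores(30, "tie_free_uniform", seed=9)
        result = classify_cohort(scores)
        step_for = {"ccrcc3": "step1", "ccrcc2": "step2",
                    "ccrcc4": "step3", "ccrcc1": "step4"}
        for call in result.calls:
            assert call.rule_trace.startswith(step_for[call.label])
            assert set(call.statistics) == set(DECISION_STATISTICS)

    @settings(max_examples=150, deadline=None)
    @given(
        st.integers(1, 12).flatmap(
            lambda n: st.lists(
                st.lists(st.integers(1, 8), min_size=8, max_size=8),
                min_size=n, max_size=n,
            )
        )
    )
    def test_oracle_equivalence_small_cohorts(self, rows):
        # integer grid scores deliberately produce ties; both routes must
        # resolve them identically by value comparison
        cols = {
            name: np.array([row[j] for row in rows], dtype=float)
            for j, name in enumerate(CLEARSEQ_SIGNATURES)
        }
        scores = make_scores(cols)
        result = classify_cohort(scores, min_cohort=1)
        samples = [
            {name: float(row[j]) for j, name in enumerate(CLEARSEQ_SIGNATURES)}
            for row in rows
        ]
        assert result.labels == oracle_classify(samples)


class TestFixedMode:
    CUTS = {
        "p3_ratio": 2.0, "p3_ccrcc2up": 5.0, "p3_cellcycle": 5.0,
        "p3_teffector": 5.0, "p2_ratio": 1.2, "p4_ratio": 1.5,
    }

    def test_single_sample_ccrcc4(self):
        # all statistics below their cutoffs except the ccrcc4 ratio
        scores = constant_scores(
            1, fill=4.0, ccrcc4_up=[8.0], ccrcc1_up=[4.0]
        )  # r4 = 2 > 1.5; r3 = 1 < 2; r2 = 1 < 1.2
        ts = ThresholdSet(mode="fixed_cutoff", cutoffs=self.CUTS)
        result = classify_fixed(scores, ts)
        assert result.labels == ["ccrcc4"]

    def test_and_rule_falsification(self):
        # high ccrcc3 ratio but t_effector above its cutoff -> not ccrcc3
        scores = constant_scores(
            1, fill=4.0, ccrcc3_up=[12.0], ccrcc3_down=[4.0], t_effector=[9.0]
        )
        ts = ThresholdSet(mode="fixed_cutoff", cutoffs=self.CUTS)
        assert classify_fixed(scores, ts).labels != ["ccrcc3"]

    def test_fixed_reproduces_cohort_labels(self):
        scores, _ = simulate_scores(80, "tie_free_uniform", seed=10)
        cohort = classify_cohort(scores)
        fixed = classify_fixed(scores, extract_cutoffs(cohort))
        assert fixed.labels == cohort.labels

    def test_missing_cutoff(self):
        cuts = dict(self.CUTS)
        del cuts["p2_ratio"]
        with pytest.raises(IncompleteThresholds, match="p2_ratio"):
            ThresholdSet(mode="fixed_cutoff", cutoffs=cuts)

    def test_works_for_single_sample(self):
        scores = constant_scores(1, fill=4.0)
        ts = ThresholdSet(mode="fixed_cutoff", cutoffs=self.CUTS)
        assert len(classify_fixed(scores, ts).labels) == 1


class TestExtractCutoffs:
    def test_order_statistics_arithmetic(self):
        # ccrcc2 ratio takes values 1..200 with no ccrcc3 assigned:
        # the 50th-percentile cutoff interpolates to 100.5
        n = 200
        scores = constant_scores(
            n, fill=4.0,
            ccrcc2_up=np.arange(1.0, n + 1),
            ccrcc1and4_up=np.ones(n),
        )  # ccrcc3 ratio constant at 1 -> nothing exceeds its 80th pct
        result = classify_cohort(scores)
        assert result.class_counts["ccrcc3"] == 0
        ts = extract_cutoffs(result)
        assert ts.cutoffs["p2_ratio"] == pytest.approx(100.5)

    def test_round_trip_serialization(self, tmp_path):
        scores, _ = simulate_scores(50, "tie_free_uniform", seed=11)
        ts = extract_cutoffs(classify_cohort(scores))
        path = tmp_path / "cutoffs.json"
        ts.to_json(path)
        back = ThresholdSet.from_json(path)
        assert back.mode == "fixed_cutoff"
        for name in CUTOFF_NAMES:
            assert back.cutoffs[name] == ts.cutoffs[name]

    def test_extract_requires_cohort_mode(self):
        scores, _ = simulate_scores(50, "tie_free_uniform", seed=12)
        fixed = classify_fixed(scores, extract_cutoffs(classify_cohort(scores)))
        with pytest.raises(InvalidParameter):
            extract_cutoffs(fixed)


class TestConcordance:
    def test_printed_row_percentages_42(self):
        table = confusion_from_counts([[15, 4, 0, 5],
                                       [7, 33, 0, 2],
                                       [2, 1, 2, 2],
                                       [4, 5, 0, 9]])
        assert table.row_percentages[1].tolist() == [17, 79, 0, 5]

    def test_printed_row_percentages_7(self):
        table = confusion_from_counts([[15, 4, 0, 5],
                                       [7, 33, 0, 2],
                                       [2, 1, 2, 2],
                                       [4, 5, 0, 9]])
        assert table.row_percentages[2].tolist() == [29, 14, 29, 29]

    def test_identical_labels_diagonal(self):
        labels = ["ccrcc1"] * 3 + ["ccrcc2"] * 2 + ["ccrcc3"] + ["ccrcc4"] * 4
        table = concordance(labels, labels)
        assert np.array_equal(np.diag(table.counts), [3, 2, 1, 4])
        assert table.counts.sum() == 10
        assert np.array_equal(np.diag(table.row_percentages), [100] * 4)

    def test_mismatched_lengths(self):
        with pytest.raises(SampleMismatch):
            concordance(["ccrcc1"], ["ccrcc1", "ccrcc2"])

    def test_unknown_label(self):
        with pytest.raises(InvalidParameter):
            concordance(["ccrcc9"], ["ccrcc1"])


class TestClassificationIO:
    def test_round_trip_labels_exact(self, tmp_path):
        scores, _ = simulate_scores(25, "tie_free_uniform", seed=13)
        result = classify_cohort(scores)
        path = tmp_path / "calls.tsv"
        write_classification(result, path)
        back = read_classification(path)
        assert back.labels == result.labels
        assert back.sample_ids == result.sample_ids

    def test_round_trip_statistics_and_cutoffs(self, tmp_path):
        scores, _ = simulate_scores(25, "tie_free_uniform", seed=14)
        result = classify_cohort(scores)
        path = tmp_path / "calls.tsv"
        write_classification(result, path)
        back = read_classification(path)
        for a, b in zip(result.calls, back.calls):
            for k in DECISION_STATISTICS:
                assert b.statistics[k] == a.statistics[k]  # repr round-trip
        for k in CUTOFF_NAMES:
            assert back.realized_cutoffs[k] == result.realized_cutoffs[k]

    def test_trace_serialized(self, tmp_path):
        scores, _ = simulate_scores(25, "tie_free_uniform", seed=15)
        result = classify_cohort(scores)
        path = tmp_path / "calls.tsv"
        write_classification(result, path)
        header = path.read_text().splitlines()[0].split("\t")
        assert "rule_trace" in header
        back = read_classification(path)
        assert back.calls[0].rule_trace == result.calls[0].rule_trace


def test_threshold_percentile_validation():
    with pytest.raises(InvalidParameter):
        ThresholdSet(p3_ratio_pct=0)
    with pytest.raises(InvalidParameter):
        ThresholdSet(p2_ratio_pct=100)


def test_threshold_json_string_round_trip():
    ts = ThresholdSet()
    back = ThresholdSet.from_json(ts.to_json())
    assert back == ts
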
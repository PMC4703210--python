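"""Evaluation statistics: confusion matrices, Wilson intervals, screening
metrics, ROC/AUC, Fleiss' kappa and rater summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.proportion import proportion_confint

from sicklestain import (
    BinaryCounts,
    ConfusionMatrix,
    DomainError,
    binarize,
    binary_metrics,
    confusion_matrix,
    fleiss_kappa,
    format_percent,
    rater_summary,
    roc_auc,
    wilson_interval,
)

LABELS = ("AA", "AS", "SS")


class TestConfusionMatrix:
    def test_perfect_agreement_is_diagonal(self):
        truth = ["AA"] * 4 + ["AS"] * 3 + ["SS"] * 3
        cm = confusion_matrix(truth, truth, LABELS)
        assert cm.counts.trace() == 10
        assert cm.counts.sum() == 10

    def test_matches_brute_force_tally(self, rng):
        truth = rng.choice(LABELS, size=50)
        pred = rng.choice(LABELS, size=50)
        cm = confusion_matrix(truth, pred, LABELS)
        for i, t in enumerate(LABELS):
            for j, p in enumerate(LABELS):
                expected = sum(1 for a, b in zip(truth, pred) if a == t and b == p)
                assert cm.counts[i, j] == expected

    def test_empty_input_gives_zero_matrix(self):
        cm = confusion_matrix([], [], LABELS)
        assert cm.counts.sum() == 0

    def test_unknown_label_rejected(self):
        with pytest.raises(DomainError):
            confusion_matrix(["AA"], ["XX"], LABELS)

    def test_aggregation_is_additive(self, rng):
        t1, p1 = rng.choice(LABELS, 20), rng.choice(LABELS, 20)
        t2, p2 = rng.choice(LABELS, 30), rng.choice(LABELS, 30)
        summed = confusion_matrix(t1, p1, LABELS) + confusion_matrix(t2, p2, LABELS)
        concat = confusion_matrix(
            np.concatenate([t1, t2]), np.concatenate([p1, p2]), LABELS
        )
        assert np.array_equal(summed.counts, concat.counts)


class TestBinarize:
    def test_perfect_diagonal_any_hbs(self):
        cm = ConfusionMatrix(LABELS, np.diag([18, 17, 20]))
        bc = binarize(cm, {"AS", "SS"})
        assert (bc.tp, bc.fn, bc.fp, bc.tn) == (37, 0, 0, 18)

    def test_restricted_as_vs_ss(self):
        counts = np.array([[18, 0, 0], [1, 15, 1], [0, 2, 18]])
        cm = ConfusionMatrix(LABELS, counts)
        bc = binarize(cm, {"SS"}, restrict_to={"AS", "SS"})
        assert (bc.tp, bc.fn, bc.fp, bc.tn) == (18, 2, 1, 15)

    def test_exhaustive_positive_set_rejected(self):
        cm = ConfusionMatrix(LABELS, np.diag([1, 1, 1]))
        with pytest.raises(DomainError):
            binarize(cm, set(LABELS))
        with pytest.raises(DomainError):
            binarize(cm, set())

    def test_matches_brute_force_tally(self, rng):
        truth = rng.choice(LABELS, 60)
        pred = rng.choice(LABELS, 60)
        cm = confusion_matrix(truth, pred, LABELS)
        bc = binarize(cm, {"SS"})
        tp = sum(1 for t, p in zip(truth, pred) if t == "SS" and p == "SS")
        fn = sum(1 for t, p in zip(truth, pred) if t == "SS" and p != "SS")
        fp = sum(1 for t, p in zip(truth, pred) if t != "SS" and p == "SS")
        tn = sum(1 for t, p in zip(truth, pred) if t != "SS" and p != "SS")
        assert (bc.tp, bc.fn, bc.fp, bc.tn) == (tp, fn, fp, tn)


class TestBinaryMetrics:
    def test_perfect_screen(self):
        bm = binary_metrics(BinaryCounts(tp=37, fp=0, tn=18, fn=0))
        assert bm.sensitivity.value == 1.0
        assert bm.specificity.value == 1.0
        assert bm.accuracy.value == 1.0

    def test_zero_denominator_flagged_undefined(self):
        bm = binary_metrics(BinaryCounts(tp=0, fp=3, tn=5, fn=0))
        assert not bm.sensitivity.defined
        assert bm.sensitivity.ci is None
        assert bm.specificity.defined

    def test_formulas_on_random_counts(self, rng):
        for _ in range(20):
            tp, fp, tn, fn = (int(x) for x in rng.integers(1, 40, 4))
            bm = binary_metrics(BinaryCounts(tp=tp, fp=fp, tn=tn, fn=fn))
            assert bm.sensitivity.value == pytest.approx(tp / (tp + fn))
            assert bm.specificity.value == pytest.approx(tn / (fp + tn))
            assert bm.ppv.value == pytest.approx(tp / (tp + fp))
            assert bm.npv.value == pytest.approx(tn / (tn + fn))
            assert bm.accuracy.value == pytest.approx((tp + tn) / (tp + fp + tn + fn))

    def test_total_n_convention_uses_cohort_size(self):
        bc = BinaryCounts(tp=37, fp=0, tn=18, fn=0)
        standard = binary_metrics(bc, ci_convention="standard")
        total = binary_metrics(bc, ci_convention="total_n", cohort_n=55)
        assert standard.sensitivity.ci.n_eff == 37
        assert total.sensitivity.ci.n_eff == 55
        # the larger effective n tightens the bound
        assert total.sensitivity.ci.lower > standard.sensitivity.ci.lower


class TestWilsonInterval:
    def test_matches_statsmodels_on_integer_counts(self):
        for count, n in [(50, 55), (17, 37), (213, 226), (1, 33)]:
            ours = wilson_interval(count / n, n)
            lo, hi = proportion_confint(count, n, alpha=0.05, method="wilson")
            # statsmodels uses the full-precision z; 1.96 agrees to ~1e-4
            assert ours.lower == pytest.approx(lo, abs=5e-4)
            assert ours.upper == pytest.approx(hi, abs=5e-4)

    def test_degenerate_endpoints_exact(self):
        assert wilson_interval(1.0, 40).upper == 1.0
        assert wilson_interval(0.0, 40).lower == 0.0

    def test_width_shrinks_with_n(self):
        widths = [
            wilson_interval(0.8, n).upper - wilson_interval(0.8, n).lower
            for n in [10, 30, 100, 300]
        ]
        assert all(a > b for a, b in zip(widths, widths[1:]))

    @settings(derandomize=True, max_examples=50)
    @given(p=st.floats(0.0, 1.0), n=st.integers(1, 500))
    def test_symmetry_under_complement(self, p, n):
        a = wilson_interval(p, n)
        b = wilson_interval(1.0 - p, n)
        assert a.lower == pytest.approx(1.0 - b.upper, abs=1e-12)
        assert a.upper == pytest.approx(1.0 - b.lower, abs=1e-12)

    def test_interval_contains_wilson_center(self):
        for p in [0.0, 0.3, 0.5, 0.9, 1.0]:
            iv = wilson_interval(p, 37)
            z2 = 1.96**2
            center = (p + z2 / 74) / (1 + z2 / 37)
            assert iv.lower <= center <= iv.upper

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DomainError):
            wilson_interval(1.2, 10)
        with pytest.raises(DomainError):
            wilson_interval(0.5, 0)


def mann_whitney_oracle(scores, labels):
    """AUC by brute-force pairwise comparison, ties counted one half."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([1.0, 1.2, 1.1, 3.0, 3.5, 4.0])
        labels = np.array([False, False, False, True, True, True])
        roc = roc_auc(scores, labels)
        assert roc.auc == 1.0

    def test_all_ties_give_half(self):
        roc = roc_auc(np.ones(10), np.arange(10) < 5)
        assert roc.auc == pytest.approx(0.5)

    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        roc = roc_auc(scores, labels)
        assert roc.fpr[0] == 0.0 and roc.tpr[0] == 0.0
        assert roc.fpr[-1] == 1.0 and roc.tpr[-1] == 1.0
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all(np.diff(roc.tpr) >= 0)

    def test_matches_mann_whitney_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.normal(size=n), 1)  # force ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                mann_whitney_oracle(scores, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            roc_auc([1.0, 2.0], [True, True])


class TestFleissKappa:
    def test_unanimous_raters_give_one(self):
        table = [["AA"] * 5, ["SS"] * 5, ["AS"] * 5, ["AA"] * 5]
        assert fleiss_kappa(table) == pytest.approx(1.0)

    def test_hand_computed_four_subject_table(self):
        # 4 subjects x 3 raters; pairwise agreement P-bar = 2/3,
        # chance agreement P-bar_e = 25/72, so kappa = 23/47.
        table = [
            ["AA", "AA", "AA"],
            ["AA", "AS", "AS"],
            ["SS", "SS", "AS"],
            ["SS", "SS", "SS"],
        ]
        assert fleiss_kappa(table) == pytest.approx(23 / 47, abs=1e-12)

    def test_uniform_random_ratings_near_zero(self):
        rng = np.random.default_rng(314)
        table = rng.choice(["AA", "AS", "SS"], size=(2000, 5)).tolist()
        assert abs(fleiss_kappa(table)) < 0.05

    def test_invariant_under_relabeling(self, rng):
        table = rng.choice(["AA", "AS", "SS"], size=(30, 4)).tolist()
        relabeled = [["xyz"[("AA", "AS", "SS").index(v)] for v in row] for row in table]
        assert fleiss_kappa(relabeled) == pytest.approx(fleiss_kappa(table), abs=1e-12)

    def test_ragged_table_rejected(self):
        with pytest.raises(DomainError):
            fleiss_kappa([["AA", "AA"], ["AA"]])

    def test_single_rater_rejected(self):
        with pytest.raises(DomainError):
            fleiss_kappa([["AA"], ["AS"]])


class TestRaterSummary:
    def test_identical_perfect_raters(self):
        truth = ["AA"] * 5 + ["AS"] * 5 + ["SS"] * 5
        per_rater, summary = rater_summary([(truth, truth)] * 3)
        assert np.allclose(per_rater["value"], 1.0)
        assert np.allclose(summary["mean"], 1.0)
        assert np.allclose(summary["sd"], 0.0)

    def test_matches_direct_recomputation(self, rng):
        truth = list(rng.choice(LABELS, 40))
        calls = []
        for _ in range(4):
            pred = [
                t if rng.random() > 0.2 else rng.choice(LABELS) for t in truth
            ]
            calls.append((truth, pred))
        per_rater, summary = rater_summary(calls)
        # recompute one cell independently: sensitivity of SS vs rest, rater 2
        truth2, pred2 = calls[2]
        tp = sum(1 for t, p in zip(truth2, pred2) if t == "SS" and p == "SS")
        fn = sum(1 for t, p in zip(truth2, pred2) if t == "SS" and p != "SS")
        cell = per_rater.query(
            "rater == 2 and comparison == 'SS vs (AA and AS)' and metric == 'sensitivity'"
        )["value"].iloc[0]
        assert cell == pytest.approx(tp / (tp + fn))
        grp = per_rater.query(
            "comparison == 'SS vs (AA and AS)' and metric == 'sensitivity'"
        )["value"]
        row = summary.query(
            "comparison == 'SS vs (AA and AS)' and metric == 'sensitivity'"
        )
        assert row["mean"].iloc[0] == pytest.approx(grp.mean())
        assert row["sd"].iloc[0] == pytest.approx(grp.std(ddof=1))

    def test_single_rater_rejected(self):
        truth = ["AA", "SS"]
        with pytest.raises(DomainError):
            rater_summary([(truth, truth)])

    def test_inconsistent_truth_rejected(self):
        with pytest.raises(DomainError):
            rater_summary([(["AA", "SS"], ["AA", "SS"]), (["SS", "AA"], ["AA", "SS"])])


class TestFormatting:
    def test_half_up_percent_rounding(self):
        assert format_percent(0.935) == "93.5"
        assert format_percent(0.90594) == "90.6"
        assert format_percent(1.0) == "100.0"
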
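import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from somnostage.io_core import Hypnogram
from somnostage.staging import EpochFeatureMatrix
from somnostage.validation import (
    cohen_kappa,
    correlation_summary,
    loocv,
    screening_metrics,
    se_group,
    sleep_summary,
)


class TestCohenKappa:
    def test_identical_sequences(self):
        assert cohen_kappa(["W", "S", "W", "S"], ["W", "S", "W", "S"]) == 1.0

    def test_perfect_disagreement_balanced(self):
        ref = ["A", "B"] * 10
        pred = ["B", "A"] * 10
        assert cohen_kappa(ref, pred) == pytest.approx(-1.0)

    def test_hand_computed_table(self):
        # confusion [[20, 5], [10, 15]]: kappa = (0.70-0.50)/(1-0.50) = 0.40
        ref = ["P"] * 25 + ["N"] * 25
        pred = ["P"] * 20 + ["N"] * 5 + ["P"] * 10 + ["N"] * 15
        assert cohen_kappa(ref, pred) == pytest.approx(0.40)

    def test_matches_brute_force_over_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(2, 40)
            k = rng.integers(2, 5)
            ref = rng.integers(0, k, n)
            pred = rng.integers(0, k, n)
            if len(set(ref)) == 1 and len(set(pred)) == 1:
                continue
            ours = cohen_kappa(ref.tolist(), pred.tolist())
            theirs = cohen_kappa_score(ref, pred)
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_degenerate_constant_labels(self):
        # both raters constant on the same label: chance agreement is 1
        with pytest.warns(UserWarning):
            assert cohen_kappa(["W", "W"], ["W", "W"]) == 1.0
        # constant but different labels: p_e = 0, kappa = 0 by the formula
        assert cohen_kappa(["W", "W"], ["S", "S"]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa(["W"], ["W", "S"])


class TestSleepSummary:
    def _h(self, labels):
        return Hypnogram(labels, "s2")

    def test_worked_example(self):
        h = self._h(["S"] * 816 + ["W"] * 144)
        s = sleep_summary(h)
        assert s.SE == pytest.approx(85.0)
        assert s.TST == pytest.approx(408.0)
        assert s.TWT == pytest.approx(72.0)
        assert s.time_in_bed == pytest.approx(480.0)

    def test_all_wake_night(self):
        s = sleep_summary(self._h(["W"] * 20))
        assert s.SE == 0.0 and s.TST == 0.0 and s.WASO == 0.0

    def test_waso_after_first_sleep_epoch(self):
        s = sleep_summary(self._h(["W", "W", "S", "W", "S"]))
        assert s.WASO == pytest.approx(0.5)
        assert s.SE == pytest.approx(40.0)

    def test_first3_onset_rule(self):
        h = self._h(["S", "W", "S", "S", "S", "W"])
        assert sleep_summary(h, onset_rule="first").WASO == pytest.approx(1.0)
        assert sleep_summary(h, onset_rule="first3").WASO == pytest.approx(0.5)

    def test_conservation_property(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            labels = rng.choice(["W", "S"], rng.integers(1, 100)).tolist()
            s = sleep_summary(self._h(labels))
            assert s.TST + s.TWT == pytest.approx(s.time_in_bed)
            assert s.WASO <= s.TWT + 1e-12
            assert 0 <= s.SE <= 100

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sleep_summary(self._h([]))


class TestSeGroup:
    @pytest.mark.parametrize(
        "se,group",
        [(39.9, "0-39"), (40.0, "40-59"), (59.9, "40-59"), (60.0, "60-79"),
         (80.0, ">=80"), (100.0, ">=80"), (0.0, "0-39")],
    )
    def test_boundaries(self, se, group):
        assert se_group(se) == group

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            se_group(-1)
        with pytest.raises(ValueError):
            se_group(101)


def auc_mann_whitney(pos_scores, neg_scores):
    """Oracle: AUC as the Mann-Whitney U statistic / (n_pos * n_neg)."""
    pos = np.asarray(pos_scores)
    neg = np.asarray(neg_scores)
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return wins / (pos.size * neg.size)


class TestScreening:
    def test_perfect_agreement(self):
        se = np.array([10, 30, 50, 70, 85, 95], dtype=float)
        r = screening_metrics(se, se, 60)
        assert r.sensitivity == r.specificity == r.ppv == r.npv == 100.0
        assert r.kappa == 1.0
        assert r.auc == 1.0

    def test_hand_computed_rates(self):
        # 2x2 table TP=10 FP=2 FN=3 TN=15 at threshold 60
        psg = np.array([80.0] * 13 + [30.0] * 17)
        est = np.array([80.0] * 10 + [30.0] * 3 + [80.0] * 2 + [30.0] * 15)
        r = screening_metrics(est, psg, 60)
        assert (r.tp, r.fp, r.fn, r.tn) == (10, 2, 3, 15)
        assert r.sensitivity == pytest.approx(76.9, abs=0.05)
        assert r.specificity == pytest.approx(88.2, abs=0.05)
        assert r.ppv == pytest.approx(83.3, abs=0.05)
        assert r.npv == pytest.approx(83.3, abs=0.05)

    def test_auc_equals_mann_whitney_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            psg = rng.uniform(0, 100, 30)
            est = np.clip(psg + rng.normal(0, 20, 30), 0, 100)
            if (psg >= 60).all() or (psg < 60).all():
                continue
            r = screening_metrics(est, psg, 60)
            oracle = auc_mann_whitney(est[psg >= 60], est[psg < 60])
            assert r.auc == pytest.approx(oracle, abs=1e-12)

    def test_degenerate_reference_reports_nan(self):
        psg = np.array([90.0, 95.0, 85.0])
        est = np.array([90.0, 50.0, 85.0])
        r = screening_metrics(est, psg, 60)
        assert np.isnan(r.specificity)
        assert np.isnan(r.auc)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            screening_metrics(np.array([50.0]), np.array([50.0]), 55)

    def test_permutation_null_auc_near_half(self):
        rng = np.random.default_rng(3)
        psg = rng.uniform(0, 100, 40)
        est = psg.copy()
        aucs = []
        for _ in range(1000):
            perm = rng.permutation(est)
            pos = perm[psg >= 60]
            neg = perm[psg < 60]
            aucs.append(auc_mann_whitney(pos, neg))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)


class TestCorrelationSummary:
    def test_exact_agreement(self):
        x = np.array([10.0, 50.0, 90.0, 30.0])
        c = correlation_summary(x, x)
        assert c.r2 == pytest.approx(1.0)
        assert c.mean_diff == 0.0

    def test_constant_offset(self):
        x = np.array([10.0, 50.0, 90.0, 30.0])
        c = correlation_summary(x + 5.0, x)
        assert c.r2 == pytest.approx(1.0)
        assert c.mean_diff == pytest.approx(5.0)
        assert c.ci95[0] == pytest.approx(5.0) and c.ci95[1] == pytest.approx(5.0)

    def test_independent_noise(self):
        rng = np.random.default_rng(4)
        c = correlation_summary(rng.normal(size=100), rng.normal(size=100))
        assert c.r2 < 0.1

    def test_zero_variance_undefined(self):
        c = correlation_summary(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))
        assert np.isnan(c.r2)


def separable_cohort(n_subjects=5, n_epochs=40, seed=0):
    rng = np.random.default_rng(seed)
    means = {"W": 8.0, "N2": -8.0, "REM": 0.0}
    cohort = []
    for s in range(n_subjects):
        labels = rng.choice(["W", "N2", "REM"], n_epochs).tolist()
        X = np.column_stack(
            [np.array([means[l] for l in labels]) + rng.normal(0, 0.3, n_epochs),
             np.array([means[l] for l in labels[::-1]]) * 0.0 + rng.normal(0, 1, n_epochs)]
            + [rng.normal(0, 1, n_epochs) for _ in range(28)]
        )
        cohort.append((EpochFeatureMatrix(X, subject_id=f"s{s}"), Hypnogram(labels, "raw")))
    return cohort


class TestLoocv:
    def test_separable_cohort_perfect(self):
        res = loocv(separable_cohort(), "s3")
        assert res.pooled.overall_accuracy == 100.0
        for rep in res.fold_reports:
            assert rep.overall_accuracy == 100.0

    def test_each_subject_tested_once(self):
        cohort = separable_cohort(6)
        res = loocv(cohort, "s2")
        assert len(res.predictions) == 6
        for (m, _), pred in zip(cohort, res.predictions):
            assert pred.n_epochs == m.n_epochs

    def test_order_invariance(self):
        cohort = separable_cohort(5, seed=1)
        a = loocv(cohort, "s3")
        b = loocv(cohort[::-1], "s3")
        assert a.pooled.kappa == pytest.approx(b.pooled.kappa)
        assert sorted(r.overall_accuracy for r in a.fold_reports) == sorted(
            r.overall_accuracy for r in b.fold_reports
        )

    def test_pooled_accuracy_is_trace_over_total(self):
        res = loocv(separable_cohort(5, seed=2), "s3")
        cm = res.pooled.confusion
        assert res.pooled.overall_accuracy == pytest.approx(
            100.0 * np.trace(cm) / cm.sum()
        )
        for v in res.pooled.per_stage_accuracy.values():
            assert 0 <= v <= 100

    def test_fold_with_missing_class_flagged(self):
        cohort = separable_cohort(4, seed=3)
        # subject 0 holds every REM epoch: its fold lacks the class
        labels0 = ["REM"] * 40
        rest = ["W", "N2"]
        rng = np.random.default_rng(5)
        new = [(cohort[0][0], Hypnogram(labels0, "raw"))]
        for m, h in cohort[1:]:
            new.append((m, Hypnogram(rng.choice(rest, 40).tolist(), "raw")))
        res = loocv(new, "s3")
        assert 0 in res.flagged_folds

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            loocv(separable_cohort(2), "s2")
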
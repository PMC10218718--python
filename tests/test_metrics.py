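"""Evaluation statistics: report, Pearson r, SEE, kappa, TSR table."""

from __future__ import annotations

import numpy as np
import pytest

from tsr_slide.metrics import (
    classification_report,
    cohens_kappa,
    pearson_r,
    see,
    tsr_eval_table,
)


def counting_report(y_true, y_pred, n_classes=3):
    """Brute-force per-pair counting oracle for the classification report."""
    conf = np.zeros((n_classes, n_classes), int)
    for t, p in zip(y_true, y_pred):
        conf[t, p] += 1
    prec, rec, f1 = [], [], []
    for c in range(n_classes):
        tp = conf[c, c]
        fp = conf[:, c].sum() - tp
        fn = conf[c, :].sum() - tp
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        prec.append(p)
        rec.append(r)
        f1.append(2 * p * r / (p + r) if p + r else 0.0)
    return conf, np.array(prec), np.array(rec), np.array(f1)


class TestClassificationReport:
    def test_f1_from_precision_recall_pair(self):
        # a precision/recall pair of 0.93/0.97 must give F1 = 0.95 at 2 d.p.
        p, r = 0.93, 0.97
        assert round(2 * p * r / (p + r), 2) == 0.95

    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        rep = classification_report(y, y)
        assert rep.accuracy == 1.0
        assert np.all(rep.precision == 1) and np.all(rep.recall == 1)
        assert np.all(rep.f1 == 1) and rep.flags == []

    def test_matches_counting_oracle_on_random_vectors(self, rng):
        y_true = rng.integers(0, 3, 50)
        y_pred = rng.integers(0, 3, 50)
        rep = classification_report(y_true, y_pred)
        conf, prec, rec, f1 = counting_report(y_true, y_pred)
        assert np.array_equal(rep.confusion, conf)
        assert np.allclose(rep.precision, prec)
        assert np.allclose(rep.recall, rec)
        assert np.allclose(rep.f1, f1)
        assert rep.accuracy == pytest.approx(np.trace(conf) / conf.sum())

    def test_missing_class_flagged_not_nan(self):
        y_true = np.array([0, 0, 1, 1])
        y_pred = np.array([0, 0, 0, 0])  # never predicts stroma/other
        rep = classification_report(y_true, y_pred)
        assert rep.precision[1] == 0.0 and not np.any(np.isnan(rep.precision))
        assert "stroma" in rep.flags and "other" in rep.flags

    def test_empty_vectors_rejected(self):
        with pytest.raises(ValueError):
            classification_report([], [])


class TestPearson:
    def test_identity_and_antiidentity(self, rng):
        x = rng.normal(size=20)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(-x + 3.0, x) == pytest.approx(-1.0)

    def test_fixed_vectors_match_direct_formula(self):
        pred = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        true = np.array([2.0, 2.5, 3.0, 4.5, 5.0, 5.5])
        num = np.sum((pred - pred.mean()) * (true - true.mean()))
        den = np.sqrt(np.sum((pred - pred.mean()) ** 2) * np.sum((true - true.mean()) ** 2))
        assert pearson_r(pred, true) == pytest.approx(num / den)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSEE:
    def test_zero_when_exact(self, rng):
        x = rng.uniform(0, 100, 15)
        assert see(x, x) == 0.0

    def test_constant_bias_gives_abs_bias(self, rng):
        x = rng.uniform(0, 50, 15)
        assert see(x + 7.5, x) == pytest.approx(7.5)
        assert see(x - 7.5, x) == pytest.approx(7.5)

    def test_decomposes_into_bias_and_variance(self, rng):
        true_value = 40.0
        pred = rng.normal(true_value + 6.0, 9.0, 40_000)
        s = see(pred, np.full_like(pred, true_value))
        assert s**2 == pytest.approx(6.0**2 + 9.0**2, rel=0.03)

    def test_see_at_least_abs_mean_bias(self, rng):
        pred = rng.uniform(0, 100, 50)
        true = rng.uniform(0, 100, 50)
        assert see(pred, true) >= abs((pred - true).mean()) - 1e-12


class TestKappa:
    def test_identical_raters(self):
        a = ["stroma-high", "stroma-low", "stroma-high", "stroma-low"]
        assert cohens_kappa(a, list(a)) == 1.0

    def test_worked_two_by_two_table(self):
        # table [[40, 10], [20, 30]]: p_o = 0.70, p_e = 0.50, kappa = 0.40
        a = np.array([0] * 50 + [1] * 50)
        b = np.array([0] * 40 + [1] * 10 + [0] * 20 + [1] * 30)
        assert cohens_kappa(a, b) == pytest.approx(0.40)

    def test_independent_raters_near_zero(self, rng):
        a = rng.integers(0, 2, 10_000)
        b = rng.integers(0, 2, 10_000)
        assert abs(cohens_kappa(a, b)) < 0.05

    def test_invariant_under_simultaneous_relabeling(self, rng):
        a = rng.integers(0, 2, 200)
        b = rng.integers(0, 2, 200)
        assert cohens_kappa(a, b) == pytest.approx(cohens_kappa(1 - a, 1 - b))

    def test_both_raters_constant_and_equal_is_one(self):
        assert cohens_kappa([1, 1, 1], [1, 1, 1]) == 1.0


class TestTSREvalTable:
    def test_perfect_predictions(self):
        true = np.repeat(np.arange(10, 100, 10.0), 3)
        result = tsr_eval_table(true.copy(), true)
        assert result["pearson_r"] == pytest.approx(1.0)
        assert result["see"] == 0.0
        assert result["kappa"] == 1.0
        assert (result["per_category"]["see"] == 0).all()

    def test_category_counts_partition_cohort(self, rng):
        true = rng.choice(np.arange(10, 100, 10.0), 80)
        pred = np.clip(true + rng.normal(0, 8, 80), 0, 100)
        result = tsr_eval_table(pred, true)
        assert result["per_category"]["n"].sum() == 80

    def test_recovers_generating_category_noise(self, rng):
        true = np.repeat([30.0, 60.0], 400)
        pred = np.clip(true + rng.normal(0, 10.0, 800), 0, 100)
        result = tsr_eval_table(pred, true)
        stds = result["per_category"]["std"]
        assert np.allclose(stds, 10.0, rtol=0.15)

    def test_off_grid_true_value_rejected(self):
        with pytest.raises(ValueError, match="off the visual grid"):
            tsr_eval_table([50.0], [55.0])
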
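"""Confusion tables, diagnostic metrics, and confidence intervals."""

import math

import numpy as np
import pytest
from scipy import stats

from amcos import (
    ConfusionTable,
    KinshipDataError,
    ScoreSample,
    confusion_at,
    evaluate,
    lr_ci,
    metrics,
    predictive_value_ci,
    proportion_ci_exact,
)


class TestConfusion:
    def test_threshold_rule_on_reconstructed_sibling_sample(self):
        sample = ScoreSample.from_counts(
            related={6: 5, 7: 2, 8: 5, 9: 3, 10: 6, 11: 3, 12: 1},
            unrelated={4: 1, 5: 2, 6: 2, 7: 8, 8: 5, 9: 5, 10: 2},
        )
        c = confusion_at(sample, 9)
        assert (c.tp, c.fp, c.fn, c.tn) == (13, 7, 12, 18)

    def test_zero_cutoff_marks_everything_positive(self):
        sample = ScoreSample((3, 5), (1, 2))
        c = confusion_at(sample, 0)
        assert c.fn == 0 and c.tn == 0

    def test_cutoff_above_max_marks_everything_negative(self):
        sample = ScoreSample((3, 5), (1, 2))
        c = confusion_at(sample, 99)
        assert c.tp == 0 and c.fp == 0


class TestPointEstimates:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((13, 7, 12, 18), dict(sens=0.52, spec=0.72, ppv=0.65, npv=0.60, acc=0.62)),
            ((23, 0, 2, 25), dict(sens=0.92, spec=1.0, ppv=1.0, npv=25 / 27, acc=0.96)),
            ((11, 1, 2, 12), dict(sens=11 / 13, spec=12 / 13, ppv=11 / 12, npv=12 / 14,
                                  acc=23 / 26)),
        ],
        ids=["balanced-screen", "perfect-specificity", "maternal-grandparent"],
    )
    def test_metric_fractions(self, table, expected):
        r = metrics(ConfusionTable(*table))
        assert r.sensitivity.value == pytest.approx(expected["sens"])
        assert r.specificity.value == pytest.approx(expected["spec"])
        assert r.ppv.value == pytest.approx(expected["ppv"])
        assert r.npv.value == pytest.approx(expected["npv"])
        assert r.accuracy.value == pytest.approx(expected["acc"])

    def test_likelihood_ratio_points(self):
        r = metrics(ConfusionTable(13, 7, 12, 18))
        assert r.lr_plus.value == pytest.approx(0.52 / 0.28)
        assert r.lr_minus.value == pytest.approx(0.48 / 0.72)
        r2 = metrics(ConfusionTable(23, 0, 2, 25))
        assert r2.lr_plus.value is None  # specificity 1: undefined, not infinity
        assert r2.lr_minus.value == pytest.approx(0.08)

    def test_perfect_test_lr_minus_zero(self):
        r = metrics(ConfusionTable(20, 0, 0, 20))
        assert r.lr_minus.value == 0.0

    def test_accuracy_is_prevalence_weighted_average(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            tp, fp, fn, tn = rng.integers(0, 30, size=4)
            if tp + fn == 0 or fp + tn == 0:
                continue
            r = metrics(ConfusionTable(int(tp), int(fp), int(fn), int(tn)))
            nr, nu = tp + fn, fp + tn
            weighted = (r.sensitivity.value * nr + r.specificity.value * nu) / (nr + nu)
            assert r.accuracy.value == pytest.approx(weighted)

    def test_single_class_rejected(self):
        with pytest.raises(KinshipDataError):
            metrics(ConfusionTable(0, 3, 0, 7))


def _clopper_pearson_brute(k, n, alpha=0.05):
    """Independent oracle: invert the binomial tail tests by bisection."""

    def solve(fn, lo, hi):
        for _ in range(200):
            mid = (lo + hi) / 2
            if fn(mid):
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    lower = 0.0 if k == 0 else solve(lambda p: stats.binom.sf(k - 1, n, p) < alpha / 2, 0, 1)
    upper = 1.0 if k == n else solve(lambda p: stats.binom.cdf(k, n, p) >= alpha / 2, 0, 1)
    return lower, upper


class TestConfidenceIntervals:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (23, 25, (0.7397, 0.9902)),
            (25, 25, (0.8628, 1.0)),
            (48, 50, (0.8629, 0.9951)),
            (0, 10, (0.0, None)),
        ],
    )
    def test_clopper_pearson_anchor_values(self, k, n, expected):
        lo, hi = proportion_ci_exact(k, n)
        assert lo == pytest.approx(expected[0], abs=5e-5)
        if expected[1] is not None:
            assert hi == pytest.approx(expected[1], abs=5e-5)

    def test_clopper_pearson_equals_brute_force_inversion(self):
        for n in range(1, 31):
            for k in range(n + 1):
                lo, hi = proportion_ci_exact(k, n)
                blo, bhi = _clopper_pearson_brute(k, n)
                assert lo == pytest.approx(blo, abs=1e-6), (k, n)
                assert hi == pytest.approx(bhi, abs=1e-6), (k, n)

    def test_wilson_predictive_value_anchor(self):
        # NPV 25/27 published as 76.79-97.93%; Wilson reproduces within 0.5 pt.
        _, npv_ci = predictive_value_ci(tp=23, fp=0, fn=2, tn=25)
        assert npv_ci[0] == pytest.approx(0.7679, abs=0.005)
        assert npv_ci[1] == pytest.approx(0.9793, abs=0.005)

    def test_wilson_boundary(self):
        ppv_ci, _ = predictive_value_ci(tp=20, fp=0, fn=0, tn=20)
        assert ppv_ci[1] == pytest.approx(1.0)

    def test_wilson_coverage_by_simulation(self):
        # NPV-style proportion 18/30: the Wilson interval should cover the true
        # p near nominally 95% of the time.
        rng = np.random.default_rng(42)
        p = 0.6
        n = 30
        covered = 0
        reps = 2000
        ks = rng.binomial(n, p, size=reps)
        for k in ks:
            _, ci = predictive_value_ci(tp=0, fp=0, fn=n - int(k), tn=int(k))
            covered += ci[0] <= p <= ci[1]
        assert covered / reps == pytest.approx(0.95, abs=0.03)

    @pytest.mark.parametrize(
        "table,which,expected",
        [
            ((13, 7, 12, 18), "plus", (0.89, 3.86)),
            ((20, 6, 5, 19), "plus", (1.62, 6.88)),
            ((11, 1, 2, 12), "plus", (1.65, 73.3)),
            ((23, 0, 2, 25), "minus", (0.02, 0.31)),
        ],
    )
    def test_log_method_lr_intervals(self, table, which, expected):
        plus, minus = lr_ci(ConfusionTable(*table))
        ci = plus if which == "plus" else minus
        assert ci[0] == pytest.approx(expected[0], abs=0.005)
        assert ci[1] == pytest.approx(expected[1], abs=0.05)

    def test_lr_ci_undefined_when_cells_empty(self):
        plus, minus = lr_ci(ConfusionTable(20, 0, 0, 20))
        assert plus is None and minus is None


def test_evaluate_composes_confusion_and_metrics():
    sample = ScoreSample.from_counts(
        related={0: 1, 2: 1, 3: 10, 4: 5, 5: 5, 6: 1, 8: 2},
        unrelated={0: 10, 1: 10, 2: 5},
    )
    r = evaluate(sample, 3)
    assert (r.confusion.tp, r.confusion.fp) == (23, 0)
    assert r.accuracy.value == pytest.approx(0.96)
    d = r.to_dict()
    assert d["sensitivity"]["fraction"] == [23, 25]
    assert math.isclose(d["accuracy"]["value"], 0.96)
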
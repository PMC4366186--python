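"""ROC construction, AUC equivalences, DeLong test, optimal cutoffs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glycoscreen.roc import (
    DegenerateComparisonError,
    RocCurve,
    auc_rank,
    auc_trapezoidal,
    delong_auc_variance,
    delong_compare,
    empirical_roc,
    optimal_cutoff_by_distance,
)

from conftest import brute_auc, brute_delong, brute_roc_points


def _random_case(rng, n=30):
    scores = rng.normal(size=n).round(1)  # rounding forces ties
    disease = rng.uniform(size=n) < 0.4
    if disease.all() or not disease.any():
        disease[0] = True
        disease[1] = False
    return scores, disease


class TestEmpiricalRoc:
    def test_perfect_separation_passes_through_top_left(self):
        curve = empirical_roc([3, 4, 5, 0, 1, 2], [True] * 3 + [False] * 3)
        assert any(t == 1.0 and f == 0.0 for t, f in zip(curve.tpr, curve.fpr))
        assert auc_trapezoidal(curve) == 1.0

    def test_identical_scores_give_diagonal(self):
        curve = empirical_roc([1.0] * 6, [True, False] * 3)
        thr, tpr, fpr = curve.interior()
        assert len(thr) == 1 and tpr[0] == 1.0 and fpr[0] == 1.0
        assert auc_trapezoidal(curve) == pytest.approx(0.5)

    def test_eight_subject_hand_case_matches_exhaustive_enumeration(self):
        scores = [2.0, 3.5, 3.5, 1.0, 0.5, 2.0, 4.0, 0.5]
        disease = [True, True, False, True, False, False, True, False]
        curve = empirical_roc(scores, disease)
        expected = brute_roc_points(scores, disease)
        thr, tpr, fpr = curve.interior()
        assert len(thr) == len(expected)
        for t, se, fp in zip(thr, tpr, fpr):
            e_se, e_fp = expected[t]
            assert se == pytest.approx(e_se) and fp == pytest.approx(e_fp)

    def test_weighted_curve_against_brute_force(self):
        rng = np.random.default_rng(3)
        scores, disease = _random_case(rng)
        w = rng.uniform(0.5, 3.0, size=len(scores))
        curve = empirical_roc(scores, disease, w)
        expected = brute_roc_points(scores, disease, w)
        thr, tpr, fpr = curve.interior()
        for t, se, fp in zip(thr, tpr, fpr):
            e_se, e_fp = expected[t]
            assert se == pytest.approx(e_se) and fp == pytest.approx(e_fp)

    def test_single_class_raises(self):
        with pytest.raises(DegenerateComparisonError):
            empirical_roc([1, 2, 3], [True, True, True])

    def test_curve_validates_monotonicity(self):
        with pytest.raises(ValueError):
            RocCurve(
                thresholds=np.array([np.inf, 1.0, -np.inf]),
                tpr=np.array([0.0, 0.8, 0.5]),
                fpr=np.array([0.0, 0.1, 1.0]),
            )


class TestAucEquivalence:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_trapezoidal_equals_rank_auc(self, seed):
        """The trapezoidal integral of the empirical curve equals the
        Mann-Whitney pair statistic to numerical precision."""
        rng = np.random.default_rng(seed)
        scores, disease = _random_case(rng)
        a_trap = auc_trapezoidal(empirical_roc(scores, disease))
        a_rank = auc_rank(scores, disease)
        assert a_trap == pytest.approx(a_rank, abs=1e-12)

    def test_rank_auc_against_pair_counting_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            scores, disease = _random_case(rng, n=25)
            assert auc_rank(scores, disease) == pytest.approx(
                brute_auc(scores, disease), abs=1e-12
            )

    def test_weighted_rank_auc_against_pair_counting_oracle(self):
        rng = np.random.default_rng(12)
        scores, disease = _random_case(rng, n=25)
        w = rng.uniform(0.5, 4.0, size=25)
        assert auc_rank(scores, disease, w) == pytest.approx(
            brute_auc(scores, disease, w), abs=1e-12
        )

    def test_auc_cross_check_against_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(4)
        for _ in range(10):
            scores, disease = _random_case(rng, n=60)
            assert auc_rank(scores, disease) == pytest.approx(
                sklearn_metrics.roc_auc_score(disease, scores), abs=1e-12
            )

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        scores, disease = _random_case(rng)
        a = auc_rank(scores, disease)
        assert auc_rank(np.exp(scores), disease) == pytest.approx(a, abs=1e-12)
        assert auc_rank(3 * scores + 7, disease) == pytest.approx(a, abs=1e-12)

    def test_label_flip_maps_auc_to_complement(self):
        rng = np.random.default_rng(6)
        scores, disease = _random_case(rng)
        assert auc_rank(scores, ~disease) == pytest.approx(
            1 - auc_rank(scores, disease), abs=1e-12
        )


class TestDeLong:
    def test_identical_scores_null_result(self):
        rng = np.random.default_rng(7)
        scores, disease = _random_case(rng)
        res = delong_compare(scores, scores.copy(), disease)
        assert res.chi_square == 0.0 and res.p_value == 1.0

    def test_hand_six_subject_case(self):
        """Frozen from a brute-force placement-value computation."""
        a = [3.1, 2.5, 1.8, 2.0, 1.2, 0.5]
        b = [1.0, 2.2, 1.4, 2.0, 0.8, 0.6]
        d = [True, True, True, False, False, False]
        res = delong_compare(a, b, d)
        assert res.auc_a == pytest.approx(8 / 9)
        assert res.auc_b == pytest.approx(7 / 9)
        assert res.variance == pytest.approx(0.024691358024691, abs=1e-12)
        assert res.chi_square == pytest.approx(0.5, abs=1e-9)
        assert res.p_value == pytest.approx(0.4795001221869537, abs=1e-9)

    def test_fast_midrank_matches_brute_force_on_random_data(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = 40
            sa = rng.normal(size=n).round(1)
            sb = (0.5 * sa + rng.normal(size=n)).round(1)
            d = rng.uniform(size=n) < 0.45
            if d.all() or not d.any():
                continue
            auc_a, auc_b, var, chi = brute_delong(sa, sb, d)
            res = delong_compare(sa, sb, d)
            assert res.auc_a == pytest.approx(auc_a, abs=1e-12)
            assert res.auc_b == pytest.approx(auc_b, abs=1e-12)
            assert res.variance == pytest.approx(var, abs=1e-12)
            assert res.chi_square == pytest.approx(chi, rel=1e-9)

    def test_statistic_invariant_to_operand_swap(self):
        rng = np.random.default_rng(9)
        sa, disease = _random_case(rng, n=50)
        sb = 0.3 * sa + rng.normal(size=50)
        r1 = delong_compare(sa, sb, disease)
        r2 = delong_compare(sb, sa, disease)
        assert r1.chi_square == pytest.approx(r2.chi_square, rel=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)

    def test_single_auc_variance_close_to_bootstrap(self):
        """DeLong's analytic variance agrees with a seeded bootstrap within
        10% on a 200-subject cohort."""
        rng = np.random.default_rng(2024)
        n = 200
        disease = rng.uniform(size=n) < 0.3
        scores = rng.normal(size=n) + disease * 1.2
        analytic = delong_auc_variance(scores, disease)
        boot = []
        for _ in range(4000):
            idx = rng.integers(0, n, size=n)
            d = disease[idx]
            if d.all() or not d.any():
                continue
            boot.append(auc_rank(scores[idx], d))
        bootstrap_var = np.var(boot, ddof=1)
        assert analytic == pytest.approx(bootstrap_var, rel=0.10)

    def test_single_class_raises(self):
        with pytest.raises(DegenerateComparisonError):
            delong_compare([1, 2], [2, 1], [True, True])


class TestOptimalCutoff:
    def test_perfect_point_selected(self):
        curve = empirical_roc([5, 6, 7, 1, 2, 3], [True] * 3 + [False] * 3)
        assert optimal_cutoff_by_distance(curve) == 5.0

    def test_five_point_hand_curve_brute_force(self):
        curve = RocCurve(
            thresholds=np.array([np.inf, 9.0, 7.0, 5.0, 3.0, 1.0, -np.inf]),
            tpr=np.array([0.0, 0.2, 0.6, 0.8, 0.9, 1.0, 1.0]),
            fpr=np.array([0.0, 0.05, 0.15, 0.4, 0.7, 0.9, 1.0]),
        )
        thr, tpr, fpr = curve.interior()
        dists = np.hypot(1 - tpr, fpr)
        assert optimal_cutoff_by_distance(curve) == thr[np.argmin(dists)] == 7.0

    def test_tie_breaks_toward_higher_threshold(self):
        curve = RocCurve(
            thresholds=np.array([np.inf, 4.0, 2.0, -np.inf]),
            tpr=np.array([0.0, 0.8, 1.0, 1.0]),
            fpr=np.array([0.0, 0.0, 0.2, 1.0]),  # both interior: distance 0.2
            )
        assert optimal_cutoff_by_distance(curve) == 4.0
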
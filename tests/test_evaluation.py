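"""Binary tests, confusion counts, diagnostic metrics and derived columns."""

import numpy as np
import pytest

from glycoscreen.evaluation import (
    ConfusionCounts,
    UndefinedMetricError,
    apply_test,
    build_confusion,
    evaluate_model,
    findrisc_ge,
    hba1c_ge,
    metrics_from_confusion,
    parallel_or,
    population_positive_fraction,
    prevalence_adjusted_predictive_values,
    roc_distance,
    serial_and,
)

from glycoscreen.glycemia import classify_cohort
from glycoscreen.records import ParticipantRecord
from glycoscreen.weighting import weighted_prevalence


def _record(hba1c=5.5):
    return ParticipantRecord(
        id="x", age=50, sex="male", height=175, weight=80, waist=95,
        uses_antihypertensive_med=False, history_high_glucose=False,
        family_history="none", pa_minutes_commute=10, pa_minutes_recreation=10,
        pa_minutes_work=10, fruit_veg_daily=True, fpg=95, pg2h=120, hba1c=hba1c,
    )


class TestApplyTest:
    def test_findrisc_cutoff_is_inclusive(self):
        assert apply_test(findrisc_ge(9), _record(), 9)
        assert not apply_test(findrisc_ge(9), _record(), 8)

    def test_hba1c_cutoff_strict_below(self):
        assert not apply_test(hba1c_ge(6.5), _record(hba1c=6.49), 0)
        assert apply_test(hba1c_ge(6.5), _record(hba1c=6.5), 0)

    def test_parallel_or_positive_on_either(self):
        spec = parallel_or(findrisc_ge(9), hba1c_ge(5.7))
        assert apply_test(spec, _record(hba1c=5.8), 4)
        assert apply_test(spec, _record(hba1c=5.0), 10)
        assert not apply_test(spec, _record(hba1c=5.0), 4)

    def test_serial_and_requires_both(self):
        spec = serial_and(findrisc_ge(9), hba1c_ge(5.7))
        assert apply_test(spec, _record(hba1c=5.8), 10)
        assert not apply_test(spec, _record(hba1c=5.8), 4)

    def test_missing_hba1c_raises(self):
        r = _record()
        r.hba1c = None
        with pytest.raises(ValueError, match="hba1c"):
            apply_test(hba1c_ge(6.5), r, 0)

    def test_malformed_specs_rejected(self):
        from glycoscreen.evaluation import BinaryTestSpec

        with pytest.raises(ValueError):
            BinaryTestSpec("findrisc_ge")  # no threshold
        with pytest.raises(ValueError):
            BinaryTestSpec("parallel_or", threshold=1.0)


class TestConfusion:
    def test_unit_weights_reproduce_raw_counts(self):
        c = build_confusion([True, False], [True, False], [1, 1])
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)

    def test_weighted_counts(self):
        c = build_confusion([True, False], [True, False], [2, 3])
        assert (c.tp, c.tn) == (2, 3)

    def test_six_subject_hand_tally(self):
        test = [True, True, False, True, False, False]
        disease = [True, False, True, True, False, False]
        w = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        c = build_confusion(test, disease, w)
        assert (c.tp, c.fp, c.fn, c.tn) == (5.0, 2.0, 3.0, 11.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            build_confusion([True], [True, False])


class TestMetrics:
    def test_balanced_table_gives_fifty_fifty(self):
        m = metrics_from_confusion(ConfusionCounts(tp=5, fn=5, tn=7, fp=7))
        assert m.sensitivity == 50 and m.specificity == 50

    def test_perfect_test(self):
        m = metrics_from_confusion(ConfusionCounts(tp=10, fn=0, tn=20, fp=0))
        assert m.sensitivity == 100 and m.specificity == 100
        assert m.roc_distance == 0 and m.sum == 200

    def test_hand_two_by_two(self):
        m = metrics_from_confusion(ConfusionCounts(tp=8, fn=2, fp=30, tn=60))
        assert m.sensitivity == pytest.approx(80)
        assert m.specificity == pytest.approx(100 * 60 / 90)
        assert m.ppv == pytest.approx(100 * 8 / 38)
        assert m.npv == pytest.approx(100 * 60 / 62)
        assert m.fraction_positive == pytest.approx(38)

    def test_empty_stratum_raises(self):
        with pytest.raises(UndefinedMetricError):
            metrics_from_confusion(ConfusionCounts(tp=0, fn=0, tn=5, fp=5))


class TestDerivedColumns:
    @pytest.mark.parametrize(
        "se, sp, expected",
        [(79.12, 51.40, 0.53), (100, 100, 0.0), (60.18, 61.40, 0.55), (94.14, 20.90, 0.79)],
    )
    def test_roc_distance_pins(self, se, sp, expected):
        assert round(roc_distance(se, sp), 2) == expected

    def test_roc_distance_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            roc_distance(101, 50)

    def test_adjusted_predictive_values_at_reported_prevalence(self):
        ppv, npv = prevalence_adjusted_predictive_values(79.12, 51.40, 0.07)
        assert ppv == pytest.approx(10.9, abs=0.05)
        assert npv == pytest.approx(97.0, abs=0.05)

    def test_adjusted_pv_trivial_cases(self):
        assert prevalence_adjusted_predictive_values(100, 100, 0.3) == (100, 100)
        ppv, npv = prevalence_adjusted_predictive_values(50, 50, 0.5)
        assert ppv == pytest.approx(50) and npv == pytest.approx(50)

    @pytest.mark.parametrize(
        "se, sp, p, expected",
        [(79.12, 51.40, 0.07, 50.75), (100, 100, 0.1, 10.0), (94.14, 20.90, 0.07, 80.16)],
    )
    def test_population_positive_fraction_pins(self, se, sp, p, expected):
        assert population_positive_fraction(se, sp, p) == pytest.approx(expected, abs=0.05)


class TestEvaluateModel:
    def test_always_positive_test_has_full_sensitivity(self, clean_cohort):
        df, _ = clean_cohort
        m = evaluate_model(df, findrisc_ge(0), target="diabetes")
        assert m.sensitivity == 100 and m.specificity == 0

    def test_never_positive_test_has_full_specificity(self, clean_cohort):
        df, _ = clean_cohort
        m = evaluate_model(df, hba1c_ge(np.inf), target="diabetes")
        assert m.specificity == 100 and m.sensitivity == 0

    def test_prediabetes_excludes_diabetic_subjects(self, clean_cohort):
        df, truth = clean_cohort
        classes = classify_cohort(df)
        n_dm = int((classes.to_numpy() == "DM").sum())
        assert n_dm > 0
        m_all = evaluate_model(df, findrisc_ge(0), target="prediabetes", use_weights=False)
        # everyone positive: fraction_positive is 100 regardless, but the
        # crude PPV equals the pre-diabetes share among non-diabetics only
        keep = classes != "DM"
        sub = classes[keep]
        share = ((sub == "iIFG") | (sub == "iIGT") | (sub == "IFG_IGT")).mean()
        assert m_all.ppv == pytest.approx(100 * share)

    def test_min_age_filter_equals_manual_subsetting(self, clean_cohort):
        df, _ = clean_cohort
        m_45 = evaluate_model(df, findrisc_ge(9), use_weights=False, min_age=45)
        manual = evaluate_model(
            df[df["age"] >= 45].copy(), findrisc_ge(9), use_weights=False
        )
        assert m_45 == manual

    def test_parallel_and_serial_combination_directions(self, clean_cohort):
        """Simultaneous testing raises sensitivity and lowers specificity
        relative to both components; sequential testing the reverse."""
        df, _ = clean_cohort
        f, h = findrisc_ge(9), hba1c_ge(6.5)
        for target in ("diabetes", "prediabetes"):
            mf = evaluate_model(df, f, target=target)
            mh = evaluate_model(df, h, target=target)
            mo = evaluate_model(df, parallel_or(f, h), target=target)
            ma = evaluate_model(df, serial_and(f, h), target=target)
            assert mo.sensitivity >= max(mf.sensitivity, mh.sensitivity)
            assert mo.specificity <= min(mf.specificity, mh.specificity)
            assert ma.sensitivity <= min(mf.sensitivity, mh.sensitivity)
            assert ma.specificity >= max(mf.specificity, mh.specificity)

    def test_threshold_monotonicity_across_cutoffs(self, clean_cohort):
        """Raising the FINDRISC cutoff never raises sensitivity nor lowers
        specificity."""
        df, _ = clean_cohort
        prev_se, prev_sp = 101.0, -1.0
        for c in range(0, 27):
            m = evaluate_model(df, findrisc_ge(c), target="diabetes")
            assert m.sensitivity <= prev_se + 1e-9
            assert m.specificity >= prev_sp - 1e-9
            prev_se, prev_sp = m.sensitivity, m.specificity

    def test_adjusted_pv_matches_crude_at_sample_prevalence(self, clean_cohort):
        """With unit weights and the crude sample prevalence, the Bayes
        formulas reproduce the within-sample predictive values."""
        df, _ = clean_cohort
        classes = classify_cohort(df)
        m = evaluate_model(df, findrisc_ge(9), target="diabetes", use_weights=False)
        p = (classes.to_numpy() == "DM").mean()
        ppv, npv = prevalence_adjusted_predictive_values(m.sensitivity, m.specificity, p)
        assert ppv == pytest.approx(m.ppv, rel=1e-9)
        assert npv == pytest.approx(m.npv, rel=1e-9)

    def test_weighted_prevalence_consistency(self, clean_cohort):
        df, _ = clean_cohort
        classes = classify_cohort(df)
        est = weighted_prevalence(df, (classes == "DM").to_numpy())
        assert 0 < est.estimate < 1
        assert est.effective_n <= len(df)
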
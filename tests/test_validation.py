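"""Accuracy-band classification, bias, RMSE, the performance tables and the
clamped-weight re-evaluation — each checked against independent per-patient
loop oracles."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reeval.cohort import Cohort, InvalidInputError, PatientRecord, compute_bmi
from reeval.equations import EquationSpec, predict_ree
from reeval.simulate import default_profile, generate_cohort
from reeval.validation import (
    ACCURATE,
    OVER,
    UNDER,
    UndefinedStatisticError,
    adjust_weight,
    adjusted_weight_comparison,
    bias_percent,
    classify_prediction,
    evaluate_equation,
    performance_table,
    rmse,
)


class TestClassification:
    @pytest.mark.parametrize(
        "predicted,measured,label",
        [
            (900, 1000, "accurate"),   # 90% boundary is inclusive
            (1100, 1000, "accurate"),  # 110% boundary is inclusive
            (1101, 1000, "over"),
            (899.9, 1000, "under"),
            (1500, 1678, "under"),     # 89.4% < 90%
            (1000, 1000, "accurate"),
        ],
    )
    def test_examples(self, predicted, measured, label):
        assert classify_prediction(predicted, measured).label == label

    def test_invalid_measured(self):
        with pytest.raises(InvalidInputError):
            classify_prediction(1500, 0)

    @given(
        predicted=st.floats(min_value=100, max_value=6000),
        measured=st.floats(min_value=500, max_value=3000),
    )
    @settings(max_examples=200, derandomize=True)
    def test_exactly_one_class(self, predicted, measured):
        cls = classify_prediction(predicted, measured)
        assert cls in (UNDER, ACCURATE, OVER)
        ratio = predicted / measured
        if 0.9 < ratio < 1.1:
            assert cls is ACCURATE
        elif ratio < 0.9 * (1 - 1e-6):
            assert cls is UNDER
        elif ratio > 1.1 * (1 + 1e-6):
            assert cls is OVER


class TestBiasRmse:
    def test_bias_zero_when_exact(self):
        assert bias_percent([(1500, 1500), (900, 900)]) == 0.0

    def test_bias_single_pair(self):
        assert bias_percent([(1100, 1000)]) == pytest.approx(10.0)

    def test_bias_symmetric_pairs_cancel(self):
        assert bias_percent([(900, 1000), (1210, 1100)]) == pytest.approx(0.0)

    def test_rmse_zero_when_exact(self):
        assert rmse([(1500, 1500)]) == 0.0

    def test_rmse_single_offset(self):
        assert rmse([(1800, 1500)]) == pytest.approx(300.0)

    def test_rmse_mixed_offsets(self):
        assert rmse([(1300, 1000), (600, 1000)]) == pytest.approx(353.5534, abs=1e-3)

    def test_empty_collections_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            bias_percent([])
        with pytest.raises(UndefinedStatisticError):
            rmse([])

    def test_against_loop_oracle(self, random_pairs):
        pairs = random_pairs(200)
        # independent plain-python oracle
        b = sum((p - m) / m for p, m in pairs) / len(pairs) * 100
        r = math.sqrt(sum((p - m) ** 2 for p, m in pairs) / len(pairs))
        assert bias_percent(pairs) == pytest.approx(b, rel=1e-12)
        assert rmse(pairs) == pytest.approx(r, rel=1e-12)

    def test_rmse_bounds_mean_absolute_bias(self, random_pairs):
        pairs = random_pairs(150)
        mean_err = abs(sum(p - m for p, m in pairs) / len(pairs))
        assert rmse(pairs) >= mean_err

    @given(c=st.floats(min_value=0.1, max_value=10))
    @settings(max_examples=50, derandomize=True)
    def test_scale_equivariance(self, c):
        rng = np.random.default_rng(42)
        measured = rng.uniform(800, 2800, size=40)
        pairs = list(zip(measured * rng.uniform(0.6, 1.4, size=40), measured))
        scaled = [(c * p, c * m) for p, m in pairs]
        assert bias_percent(scaled) == pytest.approx(bias_percent(pairs), abs=1e-6)
        assert rmse(scaled) == pytest.approx(c * rmse(pairs), rel=1e-9)
        for (p, m), (sp, sm) in zip(pairs, scaled):
            assert classify_prediction(p, m) == classify_prediction(sp, sm)


class TestEvaluateEquation:
    def test_matches_loop_oracle(self, cohort513, registry):
        sub = Cohort(cohort513.records[:200], filtered=True)
        spec = registry["who_wtht"]
        (perf,) = evaluate_equation(sub, spec, stratify=False)
        # independent loop oracle, counting one patient at a time
        n_under = n_acc = n_over = 0
        errs, sqerrs, preds = [], [], []
        for rec in sub:
            value = predict_ree(spec, rec).ree_predicted
            preds.append(value)
            ratio = value / rec.ree_measured
            if ratio < 0.9:
                n_under += 1
            elif ratio > 1.1:
                n_over += 1
            else:
                n_acc += 1
            errs.append(100 * (value - rec.ree_measured) / rec.ree_measured)
            sqerrs.append((value - rec.ree_measured) ** 2)
        assert perf.n == 200
        assert perf.pct_under == pytest.approx(100 * n_under / 200)
        assert perf.pct_accurate == pytest.approx(100 * n_acc / 200)
        assert perf.pct_over == pytest.approx(100 * n_over / 200)
        assert perf.bias == pytest.approx(sum(errs) / 200, rel=1e-12)
        assert perf.rmse == pytest.approx(math.sqrt(sum(sqerrs) / 200), rel=1e-12)

    def test_percentages_partition(self, cohort513, registry):
        for perf in evaluate_equation(cohort513, registry["mifflin"]):
            if perf.n:
                assert perf.pct_under + perf.pct_accurate + perf.pct_over == pytest.approx(100.0)

    def test_truth_model_scores_perfectly(self, noisefree_lt25, registry):
        """A zero-noise cohort generated from the BMI<25 equation is predicted
        100% accurately by that same equation below BMI 25."""
        lt25 = Cohort([r for r in noisefree_lt25 if r.bmi < 25], filtered=True)
        (perf,) = evaluate_equation(lt25, registry["new_equation"], stratify=False)
        assert perf.pct_accurate == 100.0
        assert perf.rmse == pytest.approx(0.0, abs=1e-6)
        assert perf.bias == pytest.approx(0.0, abs=1e-9)

    def test_stratified_n_sums(self, cohort513, registry):
        perfs = evaluate_equation(cohort513, registry["korth"])
        assert perfs[0].stratum == "total"
        assert sum(p.n for p in perfs[1:]) == perfs[0].n


class TestPerformanceTable:
    def test_structure_and_ordering(self, cohort513, registry):
        table = performance_table(cohort513, registry)
        # reference row + 18 equations x (total + 4 strata)
        assert len(table) == 1 + 18 * 5
        assert table.iloc[0]["equation"] == "ree_measured"
        totals = table[(table.stratum == "total") & (table.equation != "ree_measured")]
        acc = totals["pct_accurate"].to_list()
        assert acc == sorted(acc, reverse=True)

    def test_single_equation_registry(self, cohort513, registry):
        from reeval.equations import EquationRegistry

        reg1 = EquationRegistry([registry["mifflin"]])
        table = performance_table(cohort513, reg1, stratify=False)
        assert len(table) == 2

    def test_identity_equation_dominates(self, noisefree_lt25, registry):
        """On its own zero-noise cohort the truth equation tops the table."""
        lt25 = Cohort([r for r in noisefree_lt25 if r.bmi < 25], filtered=True)
        table = performance_table(lt25, registry, stratify=False)
        totals = table[table.equation != "ree_measured"]
        assert totals.iloc[0]["equation"] == "new_equation"
        assert totals.iloc[0]["pct_accurate"] == 100


class TestWeightAdjustment:
    def test_underweight_clamped_up(self):
        p = PatientRecord(patient_id="u", sex=0, age=50.0, weight=49.4, height=1.72,
                          ree_measured=1448.0)
        adj = adjust_weight(p)
        assert adj.weight == pytest.approx(18.5 * 1.72**2)  # 54.73 kg
        assert adj.weight == pytest.approx(54.73, abs=0.01)
        assert adj.weight_adjusted

    def test_obese_clamped_down(self):
        p = PatientRecord(patient_id="o", sex=1, age=50.0, weight=106.7, height=1.71,
                          ree_measured=1966.0)
        adj = adjust_weight(p)
        assert compute_bmi(adj.weight, adj.height) == pytest.approx(30.0)

    def test_normal_unchanged(self, make_patient):
        p = make_patient(weight=23.0 * 1.75**2, height=1.75)
        assert adjust_weight(p) is p

    @given(
        weight=st.floats(min_value=30, max_value=180),
        height=st.floats(min_value=1.4, max_value=2.1),
    )
    @settings(max_examples=100, derandomize=True)
    def test_idempotent_and_clamps_into_band(self, weight, height):
        p = PatientRecord(patient_id="h", sex=0, age=40.0, weight=weight,
                          height=height, ree_measured=1500.0)
        once = adjust_weight(p)
        assert 18.5 - 1e-9 <= compute_bmi(once.weight, once.height) <= 30.0 + 1e-9
        twice = adjust_weight(once)
        assert twice.weight == pytest.approx(once.weight, rel=1e-12)

    def test_comparison_report_shape(self, cohort513, registry):
        report = adjusted_weight_comparison(cohort513, registry)
        assert set(report["equation"]) == {"who_wtht", "harris_benedict_1918"}
        assert set(report["stratum"]) == {"underweight", "obese"}
        assert len(report) == 4
        for col in ("pct_accurate_actual", "pct_accurate_adjusted"):
            assert report[col].between(0, 100).all()
        n_under = sum(1 for r in cohort513 if r.bmi < 18.5)
        assert (report[report.stratum == "underweight"]["n"] == n_under).all()

    def test_comparison_empty_without_extreme_strata(self, make_patient, registry):
        recs = [make_patient(pid=f"n{i}", weight=70.0, height=1.75) for i in range(5)]
        report = adjusted_weight_comparison(Cohort(recs, filtered=True), registry)
        assert report.empty

    def test_adjustment_degrades_truth_model_accuracy(self, registry):
        """When measured REE follows actual weight, clamping weight cannot
        improve accuracy in expectation (checked on one fixed seed)."""
        profile = replace(default_profile(), truth_model="who_wtht", noise_sd=120.0)
        cohort = generate_cohort(profile, n=600, seed=11)
        report = adjusted_weight_comparison(cohort, registry, equations=("who_wtht",))
        for _, row in report.iterrows():
            assert row["pct_accurate_adjusted"] <= row["pct_accurate_actual"]
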
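import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.utils import concordance_index as lifelines_cindex

from nbt.exceptions import ConvergenceError, ValidationError
from nbt.io import ClinicalTable, ExpressionMatrix
from nbt.survival import (concordance_index, fit_risk_model, kfold_cindex,
                          predict_risk, stratify_and_test)
from nbt.synthetic import simulate_survival_cohort


def brute_force_cindex(time, event, score):
    """Independent censoring-aware pair enumeration (K, M)."""
    k = m = 0
    n = len(time)
    for i in range(n):
        for j in range(i + 1, n):
            if time[i] == time[j]:
                continue
            short, long_ = (i, j) if time[i] < time[j] else (j, i)
            if event[short] != 1:
                continue
            m += 1
            if score[short] > score[long_]:
                k += 1
    return k, m


class TestFitRiskModel:
    def test_recovers_planted_coefficient(self):
        expr, clin, _ = simulate_survival_cohort(1000, ["G0001"], [1.0],
                                                 censor_rate=0.05, seed=0, n_genes=1)
        model = fit_risk_model(expr, ["G0001"], clin)
        assert 0.8 <= model.coef[0] <= 1.2
        assert model.converged

    def test_null_coefficient_stays_small(self):
        hits = 0
        for seed in range(5):
            expr, clin, _ = simulate_survival_cohort(1000, ["G0001"], [0.0],
                                                     censor_rate=0.05, seed=seed,
                                                     n_genes=1)
            model = fit_risk_model(expr, ["G0001"], clin)
            hits += abs(model.coef[0]) < 0.15
        assert hits >= 4

    def test_matches_lifelines(self):
        rng = np.random.default_rng(10)
        expr, clin, _ = simulate_survival_cohort(300, ["G0001", "G0002"], [1.0, -0.5],
                                                 censor_rate=0.05, seed=2, n_genes=4)
        model = fit_risk_model(expr, list(expr.genes), clin)
        df = expr.to_frame().T
        df["time"], df["event"] = clin.time, clin.event
        cph = CoxPHFitter().fit(df, "time", "event")
        np.testing.assert_allclose(model.coef, cph.params_.to_numpy(), atol=1e-4)
        np.testing.assert_allclose(model.se, cph.standard_errors_.to_numpy(), atol=1e-4)

    def test_matches_lifelines_with_tied_times(self):
        expr, clin, _ = simulate_survival_cohort(200, ["G0001"], [0.8],
                                                 censor_rate=0.05, seed=3, n_genes=2)
        clin = ClinicalTable(clin.data.assign(time=np.ceil(clin.data["time"])))
        model = fit_risk_model(expr, list(expr.genes), clin)
        df = expr.to_frame().T
        df["time"], df["event"] = clin.time, clin.event
        cph = CoxPHFitter().fit(df, "time", "event")  # lifelines uses Efron ties
        np.testing.assert_allclose(model.coef, cph.params_.to_numpy(), atol=1e-4)

    def test_zero_variance_gene_dropped(self):
        expr, clin, _ = simulate_survival_cohort(100, ["G0001"], [1.0],
                                                 censor_rate=0.0, seed=4, n_genes=3)
        flat = ExpressionMatrix(expr.genes, expr.samples,
                                np.vstack([expr.values[:2], np.ones(100)]),
                                "log2")
        model = fit_risk_model(flat, list(flat.genes), clin)
        assert model.dropped_genes == ["G0003"]
        assert model.genes == ["G0001", "G0002"]

    def test_too_few_events(self):
        expr, clin, _ = simulate_survival_cohort(50, ["G0001"], [1.0],
                                                 censor_rate=0.0, seed=5, n_genes=1)
        clin = ClinicalTable(clin.data.assign(event=[1] + [0] * 49))
        with pytest.raises(ValidationError, match="events"):
            fit_risk_model(expr, ["G0001"], clin)


class TestPredictRisk:
    def test_hand_computed_dot_product(self):
        expr = ExpressionMatrix(["G1", "G2"], ["a", "b", "c"],
                                [[1.0, 2.0, 0.0], [3.0, -1.0, 0.0]], "log2")
        from nbt.survival import RiskModel
        model = RiskModel(["G1", "G2"], np.array([0.5, -2.0]), 3, 3, True)
        scores = predict_risk(model, expr)
        np.testing.assert_allclose(scores.to_numpy(),
                                   [0.5 * 1 - 2 * 3, 0.5 * 2 + 2 * 1, 0.0])

    def test_linearity_under_constant_shift(self):
        expr, clin, _ = simulate_survival_cohort(50, ["G0001"], [1.0],
                                                 censor_rate=0.0, seed=6, n_genes=2)
        model = fit_risk_model(expr, list(expr.genes), clin)
        shifted = ExpressionMatrix(expr.genes, expr.samples,
                                   expr.values + np.array([[5.0], [0.0]]), "log2")
        delta = predict_risk(model, shifted) - predict_risk(model, expr)
        np.testing.assert_allclose(delta.to_numpy(), 5.0 * model.coef[0], atol=1e-9)

    def test_missing_gene_listed(self):
        expr = ExpressionMatrix(["G1"], ["a", "b"], [[1.0, 2.0]], "log2")
        from nbt.survival import RiskModel
        model = RiskModel(["G1", "GX"], np.array([1.0, 1.0]), 2, 2, True)
        with pytest.raises(ValidationError, match="GX"):
            predict_risk(model, expr)


class TestConcordanceIndex:
    def test_perfect_and_reversed(self):
        t = np.array([1.0, 2, 3, 4])
        e = np.ones(4, dtype=int)
        assert concordance_index(t, e, np.array([4.0, 3, 2, 1])).c_index == 1.0
        assert concordance_index(t, e, np.array([1.0, 2, 3, 4])).c_index == 0.0

    def test_censored_fixture_matches_enumeration(self):
        t = np.array([2.0, 4, 4, 6, 8])
        e = np.array([1, 1, 0, 1, 0])
        s = np.array([5.0, 4, 3, 2, 1])
        res = concordance_index(t, e, s)
        assert (res.concordant, res.valid) == brute_force_cindex(t, e, s)
        assert (res.concordant, res.valid) == (7, 7)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(3, 40))
            t = rng.integers(1, 10, n).astype(float)
            e = (rng.random(n) > 0.3).astype(int)
            s = rng.integers(0, 6, n).astype(float)
            try:
                res = concordance_index(t, e, s)
            except ValidationError:
                assert brute_force_cindex(t, e, s)[1] == 0
                continue
            assert (res.concordant, res.valid) == brute_force_cindex(t, e, s)

    def test_complement_and_transform_invariance(self):
        rng = np.random.default_rng(12)
        t = rng.exponential(5, 60)
        e = (rng.random(60) > 0.3).astype(int)
        s = rng.normal(size=60)  # continuous: no ties
        c = concordance_index(t, e, s).c_index
        assert concordance_index(t, e, -s).c_index == pytest.approx(1 - c)
        assert concordance_index(t, e, np.exp(s)).c_index == pytest.approx(c)

    def test_agrees_with_lifelines_when_tie_free(self):
        rng = np.random.default_rng(13)
        t = rng.exponential(5, 80)
        e = (rng.random(80) > 0.3).astype(int)
        s = rng.normal(size=80)
        ours = concordance_index(t, e, s).c_index
        assert ours == pytest.approx(lifelines_cindex(t, -s, e))

    def test_fenwick_path_equals_pairwise(self):
        from nbt.survival import _concordance_fenwick
        rng = np.random.default_rng(14)
        for _ in range(30):
            n = int(rng.integers(5, 50))
            t = rng.integers(1, 8, n).astype(float)
            e = rng.integers(0, 2, n)
            s = rng.integers(0, 5, n).astype(float)
            try:
                res = concordance_index(t, e, s)
            except ValidationError:
                continue
            assert tuple(_concordance_fenwick(t, e, s)) == (res.concordant, res.valid)


class TestStratifyAndTest:
    @staticmethod
    def _cohort(n, rate_ratio, seed, rate0=0.1, censor=0.05):
        rng = np.random.default_rng(seed)
        grp = np.repeat([1, 0], [n // 2, n - n // 2])
        t_ev = rng.exponential(1 / (rate0 * rate_ratio ** grp))
        t_c = rng.exponential(1 / censor, n)
        samples = [f"S{i}" for i in range(n)]
        clin = ClinicalTable(pd.DataFrame({
            "sample": samples, "time": np.minimum(t_ev, t_c),
            "event": (t_ev <= t_c).astype(int)}))
        score = pd.Series(grp + rng.normal(0, 1e-9, n), index=samples)
        return score, clin

    def test_rate_ratio_two_detected(self):
        score, clin = self._cohort(500, 2.0, seed=20)
        res = stratify_and_test(score, clin)
        assert 1.6 <= res.hazard_ratio <= 2.5
        assert res.hr_ci[0] < res.hazard_ratio < res.hr_ci[1]
        assert res.logrank_p < 0.05
        assert abs(res.group_sizes["high"] - res.group_sizes["low"]) <= 1

    def test_label_swap_inverts_hr(self):
        score, clin = self._cohort(200, 2.0, seed=21)
        res = stratify_and_test(score, clin)
        res_swapped = stratify_and_test(-score, clin)
        assert res_swapped.hazard_ratio == pytest.approx(1 / res.hazard_ratio,
                                                         abs=1e-6)

    def test_km_curve_without_censoring_is_empirical_survival(self):
        rng = np.random.default_rng(22)
        n = 40
        samples = [f"S{i}" for i in range(n)]
        times = rng.exponential(5, n)
        clin = ClinicalTable(pd.DataFrame(
            {"sample": samples, "time": times, "event": 1}))
        score = pd.Series(np.arange(n, dtype=float), index=samples)
        res = stratify_and_test(score, clin)
        high_times = np.sort(times[score.to_numpy() > np.median(score)])
        km = res.km_curves["high"]
        for t_q, s_q in zip(km["time"], km["survival"]):
            assert s_q == pytest.approx((high_times > t_q).mean(), abs=1e-12)
        assert km["survival"].is_monotonic_decreasing

    def test_degenerate_scores_rejected(self):
        _, clin = self._cohort(50, 1.0, seed=23)
        score = pd.Series(np.ones(50), index=clin.samples)
        with pytest.raises(ValidationError, match="median"):
            stratify_and_test(score, clin)

    def test_zero_event_group_reports_km_but_no_hr(self):
        n = 40
        samples = [f"S{i}" for i in range(n)]
        grp = np.repeat([1, 0], [20, 20])
        clin = ClinicalTable(pd.DataFrame({
            "sample": samples, "time": np.linspace(1, 10, n),
            "event": np.where(grp == 1, 1, 0)}))
        score = pd.Series(grp.astype(float) + np.linspace(0, 0.1, n), index=samples)
        res = stratify_and_test(score, clin)
        assert res.hazard_ratio is None
        assert np.isfinite(res.logrank_p)
        assert set(res.km_curves) == {"high", "low"}


class TestKfoldCindex:
    def test_partition_each_sample_once(self):
        expr, clin, _ = simulate_survival_cohort(120, ["G0001"], [1.0],
                                                 censor_rate=0.05, seed=30, n_genes=3)
        res = kfold_cindex(expr, ["G0001"], clin, folds=10, seed=1)
        assert len(res.per_fold) == 10
        assert sorted(res.fold_of_sample.index) == sorted(clin.samples)
        assert res.fold_of_sample.value_counts().sum() == 120

    def test_deterministic_given_seed(self):
        expr, clin, _ = simulate_survival_cohort(100, ["G0001"], [1.0],
                                                 censor_rate=0.05, seed=31, n_genes=2)
        a = kfold_cindex(expr, ["G0001"], clin, seed=7)
        b = kfold_cindex(expr, ["G0001"], clin, seed=7)
        assert a.mean == b.mean and a.per_fold == b.per_fold

    def test_empty_signature_scores_baseline(self):
        expr, clin, _ = simulate_survival_cohort(60, ["G0001"], [1.0],
                                                 censor_rate=0.05, seed=32, n_genes=1)
        res = kfold_cindex(expr, [], clin, folds=5, seed=0)
        assert res.mean == 0.5

    def test_folds_validation(self, toy_expr):
        clin = ClinicalTable(pd.DataFrame({
            "sample": toy_expr.samples, "time": [1, 2, 3, 4, 5, 6],
            "event": [1, 1, 1, 0, 1, 0]}))
        with pytest.raises(ValidationError):
            kfold_cindex(toy_expr, ["G00"], clin, folds=1)
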
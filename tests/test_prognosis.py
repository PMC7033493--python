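"""Risk model, risk score, grade/stage association, KM/log-rank, Cox."""

import numpy as np
import pandas as pd
import pytest

from editscan.prognosis import (RiskModel, build_risk_model,
                                grade_stage_association, km_logrank,
                                multivariate_adjustment, risk_score,
                                subset_prognosis, univariate_sign)
from editscan.simulate import simulate_survival_groups


def _survival(time, event, index=None):
    idx = index or [f"P{i}" for i in range(len(time))]
    return pd.DataFrame({"time": time, "event": event}, index=idx)


def _simulate_degree_survival(n, log_hr, seed):
    rng = np.random.default_rng(seed)
    degree = rng.uniform(0, 1, n)
    rate = 1e-3 * np.exp(log_hr * degree)
    t = rng.exponential(1 / rate)
    c = rng.uniform(0, 4000, n)
    idx = [f"P{i}" for i in range(n)]
    surv = _survival(np.minimum(t, c).clip(min=0.1), (t <= c).astype(int), idx)
    return pd.Series(degree, index=idx), surv


class TestUnivariateSign:
    def test_risky_editing_recovered_as_positive_sign(self):
        for seed in range(5):
            degree, surv = _simulate_degree_survival(200, 1.0, seed)
            sign, coef, p = univariate_sign(degree, surv)
            assert sign == 1

    def test_negated_degrees_flip_the_sign(self):
        degree, surv = _simulate_degree_survival(200, 1.5, 3)
        s1, c1, _ = univariate_sign(degree, surv)
        s2, c2, _ = univariate_sign(-degree, surv)
        assert s1 == -s2
        assert c1 == pytest.approx(-c2, rel=1e-4)

    def test_degenerate_inputs_are_excluded(self):
        degree, surv = _simulate_degree_survival(200, 1.0, 1)
        assert univariate_sign(degree.iloc[:5], surv.iloc[:5]) is None
        assert univariate_sign(pd.Series(0.5, index=surv.index), surv) is None


class TestRiskScore:
    def _model(self):
        table = pd.DataFrame({"gene_id": ["g1", "g2"], "beta": [1, -1],
                              "cox_coef": [0.5, -0.5], "cox_p": [0.01, 0.02]},
                             index=pd.Index(["s1", "s2"], name="site_id"))
        return RiskModel(table=table)

    def test_hand_computed_two_site_example(self):
        expr = pd.DataFrame({"P1": [2.0, 3.0]}, index=["g1", "g2"])
        degrees = pd.DataFrame({"P1": [0.5, 0.2]}, index=["s1", "s2"])
        scores = risk_score(self._model(), expr, degrees, ["P1"])
        # (+1)(2.0)(0.5) + (-1)(3.0)(0.2) = 0.4
        assert scores["P1"] == pytest.approx(0.4)

    def test_patient_without_edited_sites_scores_zero(self):
        expr = pd.DataFrame({"P1": [2.0, 3.0]}, index=["g1", "g2"])
        degrees = pd.DataFrame({"P1": [np.nan, np.nan]}, index=["s1", "s2"])
        scores = risk_score(self._model(), expr, degrees, ["P1"])
        assert scores["P1"] == 0.0

    def test_score_is_linear_in_expression(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.uniform(1, 10, (2, 5)), index=["g1", "g2"],
                            columns=[f"P{i}" for i in range(5)])
        degrees = pd.DataFrame(rng.uniform(0, 1, (2, 5)), index=["s1", "s2"],
                               columns=expr.columns)
        s1 = risk_score(self._model(), expr, degrees, list(expr.columns))
        s2 = risk_score(self._model(), 2 * expr, degrees, list(expr.columns))
        assert np.allclose(s2, 2 * s1)


class TestGradeStage:
    def _clinical(self, grades, stages=None):
        n = len(grades)
        return pd.DataFrame({
            "time": np.ones(n), "event": np.zeros(n, dtype=int),
            "gender": ["male"] * n, "age": [60] * n, "bmi": [25] * n,
            "grade": grades, "stage": stages or grades,
        }, index=[f"P{i}" for i in range(n)])

    def test_exact_rank_sum_p_from_full_enumeration(self):
        # scores {1,2,3} vs {4,5,6}: one-sided 1/C(6,3) = 0.05, two-sided 0.1
        clin = self._clinical([1, 1, 1, 2, 2, 2])
        scores = pd.Series([1, 2, 3, 4, 5, 6.0], index=clin.index)
        out = grade_stage_association(scores, clin)
        row = out[(out["variable"] == "grade") & (out["group_a"] == "1")].iloc[0]
        assert row["p"] == pytest.approx(0.1)

    def test_identical_distributions_give_large_p(self):
        clin = self._clinical([1] * 10 + [2] * 10)
        scores = pd.Series(list(range(10)) + list(range(10)), index=clin.index,
                           dtype=float)
        out = grade_stage_association(scores, clin)
        assert (out["p"] > 0.8).all()

    def test_grade_four_collapses_into_three_plus(self):
        clin = self._clinical([1] * 4 + [2] * 3 + [3] * 2 + [4] * 1)
        scores = pd.Series(np.arange(10, dtype=float), index=clin.index)
        out = grade_stage_association(scores, clin)
        row = out[(out["variable"] == "grade") & (out["group_b"] == "3plus")].iloc[0]
        assert row["n_b"] == 3  # grades 3 and 4 pooled

    def test_planted_monotone_link_detected(self):
        rng = np.random.default_rng(9)
        grades = np.repeat([1, 2, 3], 30)
        scores = pd.Series(grades + rng.normal(0, 0.5, 90),
                           index=[f"P{i}" for i in range(90)])
        clin = self._clinical(list(grades))
        out = grade_stage_association(scores, clin)
        grade_rows = out[out["variable"] == "grade"]
        assert (grade_rows["median_b"] > grade_rows["median_a"]).all()
        assert (grade_rows["p"] < 0.01).all()


class TestKmLogrank:
    def test_identical_groups_give_p_one(self):
        time = list(range(1, 21)) * 2
        event = [1, 0] * 20
        surv = _survival(time, event)
        scores = pd.Series([0.0] * 20 + [1.0] * 20, index=surv.index)
        cmp = km_logrank(scores, surv)
        assert cmp.logrank_p == pytest.approx(1.0)
        assert cmp.logrank_stat == pytest.approx(0.0)

    def test_median_ties_go_to_low_risk_group(self):
        scores = pd.Series([1.0] * 30 + [2.0] * 10,
                           index=[f"P{i}" for i in range(40)])
        surv = _survival(np.arange(1, 41), np.ones(40, dtype=int),
                         list(scores.index))
        cmp = km_logrank(scores, surv)
        assert (cmp.groups == "low").sum() == 30

    def test_km_collapses_to_empirical_survival_without_censoring(self):
        times = np.array([5.0, 1.0, 3.0, 2.0, 4.0] * 5)
        surv = _survival(times, np.ones(25, dtype=int))
        scores = pd.Series(np.r_[np.zeros(13), np.ones(12)], index=surv.index)
        cmp = km_logrank(scores, surv, min_patients=20)
        low = cmp.km_curves["low"]["low"]
        members = surv.loc[cmp.groups.index[cmp.groups == "low"], "time"]
        for t in sorted(members.unique()):
            empirical = (members > t).mean()
            assert low.loc[t] == pytest.approx(empirical)

    def test_km_curves_start_at_one_and_never_increase(self, default_result):
        for curve in default_result.survival.km_curves.values():
            vals = curve.iloc[:, 0].to_numpy()
            assert vals[0] == pytest.approx(1.0)
            assert (np.diff(vals) <= 1e-12).all()

    def test_group_label_swap_leaves_p_unchanged(self):
        df = simulate_survival_groups(100, hazard_ratio=2.0, seed=5)
        surv = _survival(df["time"].to_numpy(), df["event"].to_numpy())
        scores = pd.Series(df["group"].to_numpy(), index=surv.index, dtype=float)
        p1 = km_logrank(scores, surv).logrank_p
        p2 = km_logrank(1 - scores, surv).logrank_p
        assert p1 == pytest.approx(p2)

    def test_small_cohort_is_refused(self):
        surv = _survival(np.arange(1, 11), np.ones(10, dtype=int))
        scores = pd.Series(np.arange(10, dtype=float), index=surv.index)
        with pytest.raises(ValueError):
            km_logrank(scores, surv)


def _clinical_with_score(n, seed, score_log_hr=0.5):
    rng = np.random.default_rng(seed)
    score = rng.normal(0, 1, n)
    age = rng.normal(60, 10, n)
    bmi = rng.normal(26, 4, n)
    grade = rng.integers(1, 5, n)
    stage = rng.integers(1, 5, n)
    gender = rng.choice(["male", "female"], n)
    rate = 1e-3 * np.exp(score_log_hr * score)
    t = rng.exponential(1 / rate)
    c = rng.uniform(500, 5000, n)
    clin = pd.DataFrame({
        "time": np.minimum(t, c).clip(min=0.1), "event": (t <= c).astype(int),
        "gender": gender, "age": age, "bmi": bmi, "grade": grade,
        "stage": stage}, index=[f"P{i}" for i in range(n)])
    return pd.Series(score, index=clin.index), clin


class TestMultivariate:
    def test_planted_score_effect_recovered_within_ci(self):
        scores, clin = _clinical_with_score(300, seed=6)
        out = multivariate_adjustment(scores, clin)
        row = out.loc["risk_score"]
        assert row["ci_low"] < np.exp(0.5) < row["ci_high"]
        assert row["p"] < 0.05

    def test_constant_covariate_is_dropped(self):
        scores, clin = _clinical_with_score(100, seed=7)
        clin["bmi"] = 25.0
        out = multivariate_adjustment(scores, clin)
        assert "bmi" not in out.index
        assert "risk_score" in out.index

    def test_permuted_score_shows_no_association_on_average(self):
        rng = np.random.default_rng(8)
        scores, clin = _clinical_with_score(300, seed=9)
        log_hrs = []
        for _ in range(8):
            permuted = pd.Series(rng.permutation(scores.to_numpy()),
                                 index=scores.index)
            out = multivariate_adjustment(permuted, clin)
            log_hrs.append(np.log(out.loc["risk_score", "HR"]))
        assert abs(np.mean(log_hrs)) < 0.1


class TestSubsetPrognosis:
    def _setup(self, seed=10):
        rng = np.random.default_rng(seed)
        sites = [f"s{i}" for i in range(4)]
        patients = [f"P{i}" for i in range(60)]
        table = pd.DataFrame({"gene_id": [f"g{i}" for i in range(4)],
                              "beta": [1, 1, -1, 1],
                              "cox_coef": [0.4, 0.2, -0.3, 0.1],
                              "cox_p": [0.01, 0.2, 0.03, 0.6]},
                             index=pd.Index(sites, name="site_id"))
        model = RiskModel(table=table)
        expr = pd.DataFrame(rng.uniform(1, 5, (4, 60)),
                            index=[f"g{i}" for i in range(4)], columns=patients)
        degrees = pd.DataFrame(rng.uniform(0, 1, (4, 60)), index=sites,
                               columns=patients)
        surv = _survival(rng.uniform(10, 2000, 60),
                         rng.integers(0, 2, 60), patients)
        return model, expr, degrees, surv

    def test_identity_filter_equals_unfiltered_analysis(self):
        model, expr, degrees, surv = self._setup()
        all_true = pd.Series(True, index=surv.index)
        a = subset_prognosis(model, model.sites, expr, degrees, surv)
        b = subset_prognosis(model, model.sites, expr, degrees, surv,
                             patient_filter=all_true)
        assert a.logrank_p == pytest.approx(b.logrank_p)
        assert (a.groups == b.groups).all()

    def test_prognostic_sites_use_raw_cox_p(self):
        model, *_ = self._setup()
        assert model.prognostic_sites(0.05) == ["s0", "s2"]

    def test_empty_subgroup_and_tiny_subset_are_refused(self):
        model, expr, degrees, surv = self._setup()
        none = pd.Series(False, index=surv.index)
        with pytest.raises(ValueError, match="subset too small"):
            subset_prognosis(model, model.sites, expr, degrees, surv,
                             patient_filter=none)
        with pytest.raises(ValueError, match="site subset"):
            subset_prognosis(model, ["s0"], expr, degrees, surv)

    def test_effect_concentrated_in_flagged_subgroup(self):
        rng = np.random.default_rng(12)
        patients = [f"P{i}" for i in range(120)]
        flagged = pd.Series([i < 60 for i in range(120)], index=patients)
        degrees = pd.DataFrame(rng.uniform(0, 1, (3, 120)),
                               index=["s0", "s1", "s2"], columns=patients)
        expr = pd.DataFrame(np.ones((3, 120)), index=["g0", "g1", "g2"],
                            columns=patients)
        table = pd.DataFrame({"gene_id": ["g0", "g1", "g2"], "beta": [1, 1, 1],
                              "cox_coef": [0.5] * 3, "cox_p": [0.01] * 3},
                             index=pd.Index(["s0", "s1", "s2"], name="site_id"))
        model = RiskModel(table=table)
        lp = degrees.sum(axis=0).to_numpy()
        rate = np.where(flagged.to_numpy(), 1e-3 * np.exp(2.0 * (lp - lp.mean())),
                        1e-3)
        t = rng.exponential(1 / rate)
        surv = _survival(t.clip(min=0.1), np.ones(120, dtype=int), patients)
        inside = subset_prognosis(model, model.sites, expr, degrees, surv,
                                  patient_filter=flagged)
        outside = subset_prognosis(model, model.sites, expr, degrees, surv,
                                   patient_filter=~flagged)
        assert inside.logrank_p < 0.01
        assert outside.logrank_p > 0.05
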
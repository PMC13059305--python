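"""Statistical-machinery tests: scoring oracles, GEE reduction, OR closed forms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from octaquant import models
from octaquant.models import (
    ModelSpec,
    SeparationError,
    brier_score,
    compare_groups,
    fit_adjusted_logistic,
    hosmer_lemeshow,
    roc_auc,
    run_model_ladder,
    stratified_analysis,
)
from octaquant.outcomes import label_cohort
from octaquant.synth_cohort import CohortSimParams, generate_cohort


def pairwise_auc_oracle(scores, labels):
    """Brute force over all positive x negative pairs, ties counted 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_null_value_on_shuffled_labels(self, rng):
        scores = rng.random(10_000)
        labels = rng.integers(0, 2, 10_000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_pairwise_oracle_with_ties(self, trial, rng):
        scores = rng.integers(0, 8, 20) / 8.0  # coarse grid forces ties
        labels = rng.integers(0, 2, 20)
        if labels.sum() in (0, 20):
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels) == pytest.approx(
            pairwise_auc_oracle(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        a = roc_auc(scores, labels)
        b = roc_auc(np.exp(3 * scores) - 1, labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestBrier:
    def test_perfect_and_constant_forecasts(self):
        assert brier_score([1.0, 0.0, 1.0], [1, 0, 1]) == 0.0
        assert brier_score([0.5] * 10, [1, 0] * 5) == 0.25

    def test_matches_hand_sum(self, rng):
        p = rng.random(37)
        y = rng.integers(0, 2, 37)
        hand = sum((pi - yi) ** 2 for pi, yi in zip(p, y)) / 37
        assert brier_score(p, y) == pytest.approx(hand, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            brier_score([0.2, 0.3], [1])
        with pytest.raises(ValueError):
            brier_score([1.2], [1])


class TestHosmerLemeshow:
    def test_too_few_groups_rejected(self):
        p = np.linspace(0.05, 0.95, 40)
        y = (p > 0.5).astype(float)
        with pytest.raises(ValueError):
            hosmer_lemeshow(p, y, n_groups=1)
        with pytest.raises(ValueError):
            hosmer_lemeshow(p, y, n_groups=2)

    def test_worked_vector_against_direct_formula(self):
        # n = 40, four distinct probability levels of 10 each
        p = np.repeat([0.1, 0.3, 0.6, 0.9], 10)
        y = np.concatenate([np.r_[np.ones(2), np.zeros(8)],   # O = 2, E = 1
                            np.r_[np.ones(2), np.zeros(8)],   # O = 2, E = 3
                            np.r_[np.ones(7), np.zeros(3)],   # O = 7, E = 6
                            np.r_[np.ones(9), np.zeros(1)]])  # O = 9, E = 9
        stat, pval = hosmer_lemeshow(p, y, n_groups=4)
        expected = 0.0
        for obs, exp, n in ((2, 1.0, 10), (2, 3.0, 10), (7, 6.0, 10), (9, 9.0, 10)):
            expected += (obs - exp) ** 2 / (exp * (1 - exp / n))
        assert stat == pytest.approx(expected, abs=1e-10)
        assert pval == pytest.approx(float(stats.chi2.sf(expected, 2)), abs=1e-10)

    def test_exact_calibration_gives_zero_statistic(self):
        p = np.repeat([0.2, 0.4, 0.6, 0.8], 20)
        y = np.concatenate([np.r_[np.ones(round(20 * q)), np.zeros(20 - round(20 * q))]
                            for q in (0.2, 0.4, 0.6, 0.8)])
        stat, pval = hosmer_lemeshow(p, y, n_groups=4)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert pval == pytest.approx(1.0)

    def test_statistic_nonnegative(self, rng):
        for _ in range(5):
            p = rng.uniform(0.05, 0.95, 120)
            y = (rng.random(120) < p).astype(float)
            stat, pval = hosmer_lemeshow(p, y)
            assert stat >= 0
            assert 0 <= pval <= 1


class TestCompareGroups:
    @staticmethod
    def _clustered_null(rng, n_pat=120):
        n_eyes = rng.choice([1, 2], n_pat, p=[0.4, 0.6])
        pat_eff = rng.normal(0, 0.6, n_pat)
        rows = []
        for i in range(n_pat):
            for _ in range(n_eyes[i]):
                rows.append((f"p{i}", pat_eff[i] + rng.normal(0, 0.8),
                             int(rng.integers(0, 2))))
        return pd.DataFrame(rows, columns=["patient_id", "value", "grp"])

    def test_overwhelming_effect_detected(self, rng):
        df = self._clustered_null(rng)
        df["value"] += df["grp"] * 5.0
        assert compare_groups(df, "value", "grp") < 0.001

    def test_singleton_clusters_reduce_to_independent_sandwich_test(self, rng):
        n = 160
        df = pd.DataFrame({
            "patient_id": [f"q{i}" for i in range(n)],
            "value": rng.normal(0, 1, n),
            "grp": rng.integers(0, 2, n),
        })
        p_pkg = compare_groups(df, "value", "grp")
        # oracle: OLS + leverage-adjusted (Mancl-DeRouen) sandwich, t(n-2)
        X = np.column_stack([np.ones(n), (df.grp == df.grp.max()).astype(float)])
        y = df.value.to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        h = np.diag(X @ np.linalg.solve(X.T @ X, X.T))
        xtx_inv = np.linalg.inv(X.T @ X)
        meat = sum(np.outer(X[i] * resid[i] / (1 - h[i]),
                            X[i] * resid[i] / (1 - h[i])) for i in range(n))
        se = np.sqrt((xtx_inv @ meat @ xtx_inv)[1, 1])
        p_oracle = 2 * stats.t.sf(abs(beta[1] / se), n - 2)
        assert p_pkg == pytest.approx(p_oracle, abs=1e-3)

    def test_binary_variable_path(self, rng):
        df = self._clustered_null(rng)
        df["smoker"] = (rng.random(len(df)) < 0.3).astype(int)
        p = compare_groups(df, "smoker", "grp")
        assert 0 <= p <= 1

    def test_degenerate_inputs_rejected(self, rng):
        df = self._clustered_null(rng)
        df["const"] = 1.0
        with pytest.raises(ValueError, match="variation"):
            compare_groups(df, "const", "grp")
        df["grp"] = 0
        with pytest.raises(ValueError, match="two levels"):
            compare_groups(df, "value", "grp")


class TestAdjustedLogistic:
    def test_unadjusted_binary_exposure_equals_cross_product_ratio(self):
        a, b, c, d = 30, 70, 12, 88
        rows = []
        for y, x, cnt in ((1, 1, a), (0, 1, b), (1, 0, c), (0, 0, d)):
            rows.extend({"patient_id": f"p{len(rows)}_{k}", "exposed": x,
                         "event": y} for k in range(cnt))
        table = pd.DataFrame(rows)
        fit = fit_adjusted_logistic(
            table, ModelSpec("event", ["exposed"], exposure="exposed"))
        assert fit.or_and_ci["exposed"][0] == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_null_exposure_ci_covers_one(self, rng):
        covered = 0
        n_reps = 60
        for rep in range(n_reps):
            n = 400
            df = pd.DataFrame({
                "patient_id": [f"p{i}" for i in range(n)],
                "x": rng.normal(0, 1, n),
                "y": rng.integers(0, 2, n),
            })
            fit = fit_adjusted_logistic(df, ModelSpec("y", ["x"], exposure="x"))
            _, lo, hi = fit.or_and_ci["x"]
            covered += lo <= 1.0 <= hi
        assert covered / n_reps >= 0.85  # nominal 95%

    def test_separation_detected(self):
        n = 60
        x = np.r_[np.zeros(30), np.ones(30)]
        y = x.copy()
        df = pd.DataFrame({"patient_id": [f"p{i}" for i in range(n)], "x": x, "y": y})
        with pytest.raises(SeparationError):
            fit_adjusted_logistic(df, ModelSpec("y", ["x"]))

    def test_single_class_outcome_rejected(self):
        df = pd.DataFrame({"patient_id": ["a", "b", "c"], "x": [1, 2, 3],
                           "y": [0, 0, 0]})
        with pytest.raises(ValueError, match="single class"):
            fit_adjusted_logistic(df, ModelSpec("y", ["x"]))


class TestLadder:
    @staticmethod
    def _labelled(seed=5, **kw):
        df = generate_cohort(CohortSimParams(seed=seed, **kw))
        labelled, _ = label_cohort(df)
        return labelled

    def test_duplicated_spec_gives_identical_rows(self):
        table = self._labelled()
        spec = ModelSpec("dr_progressed", ["hba1c", "bmi"], label="M")
        report = run_model_ladder(table, [spec, spec])
        assert report.iloc[0].equals(report.iloc[1])

    def test_independent_outcome_gives_null_auc(self, rng):
        n = 4000
        table = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(n)],
            "x1": rng.normal(0, 1, n),
            "x2": rng.normal(0, 1, n),
            "y": rng.integers(0, 2, n),
        })
        report = run_model_ladder(table, [ModelSpec("y", ["x1", "x2"], label="null")])
        assert report.loc[0, "auc"] == pytest.approx(0.5, abs=0.03)

    def test_octa_term_improves_discrimination_and_calibration(self):
        table = self._labelled(seed=9)
        base = ModelSpec("dr_progressed", ["axial_length", "bmi", "hba1c",
                                           "dr_severity"], label="base")
        plus = ModelSpec("dr_progressed", base.predictors + ["SCP_LV_VD"],
                         label="plus", exposure="SCP_LV_VD")
        report = run_model_ladder(table, [base, plus])
        assert report.loc[1, "auc"] > report.loc[0, "auc"]
        assert report.loc[1, "brier"] < report.loc[0, "brier"]

    def test_preset_ladders_run_on_default_cohort(self):
        table = self._labelled(seed=2)
        dr = run_model_ladder(table, models.dr_progression_ladder())
        assert list(dr["label"]) == [f"Model {i}" for i in range(1, 6)]
        assert ((dr["auc"] > 0) & (dr["auc"] < 1)).all()
        va = run_model_ladder(table, models.va_decline_ladder())
        assert len(va) == 3


class TestStratified:
    def test_constant_stratum_reduces_to_plain_fit(self):
        table = TestLadder._labelled(seed=4)
        table["stratum"] = "all"
        spec = ModelSpec("dr_progressed", ["hba1c", "SCP_LV_VD"],
                         exposure="SCP_LV_VD")
        fits = stratified_analysis(table, spec, "stratum")
        direct = fit_adjusted_logistic(table, spec)
        assert fits["all"].or_and_ci == direct.or_and_ci

    def test_consistent_direction_across_lens_strata(self):
        table = TestLadder._labelled(seed=6, n_patients=600)
        spec = ModelSpec("dr_progressed", ["SCP_LV_VD"], exposure="SCP_LV_VD")
        fits = stratified_analysis(table, spec, "lens_status")
        assert set(fits) == {"phakic", "pseudophakic"}
        # the generator gives both strata the same positive effect
        assert all(f.or_and_ci["SCP_LV_VD"][0] > 1.0 for f in fits.values())

    def test_degenerate_stratum_skipped_with_warning(self):
        table = TestLadder._labelled(seed=4)
        table.loc[table.index[0], "lens_status"] = "aphakic"  # one-eye stratum
        spec = ModelSpec("dr_progressed", ["hba1c"])
        with pytest.warns(UserWarning, match="skipped"):
            fits = stratified_analysis(table, spec, "lens_status")
        assert "aphakic" not in fits
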
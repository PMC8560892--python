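"""IRLS logistic fitter, forward selection, calibration and discrimination."""

import math

import numpy as np
import pandas as pd
import pytest

from stoppstart._util import round_half_up
from stoppstart.logistic import (
    LogisticError,
    diagnostics,
    fit_logistic,
    forward_select,
    hosmer_lemeshow,
    joint_cutoff,
    roc_auc,
)


def grouped_2x2(a, b, c, d):
    """Grouped design for a 2x2 table: exposure column + frequency weights."""
    X = np.array([[1.0], [1.0], [0.0], [0.0]])
    y = np.array([1.0, 0.0, 1.0, 0.0])
    w = np.array([a, c, b, d], dtype=float)
    return X, y, w


class TestFitLogistic:
    def test_gender_table_reproduces_tabulated_or(self):
        X, y, w = grouped_2x2(94, 43, 9, 15)
        fit = fit_logistic(X, y, names=["female"], weights=w)
        assert fit.converged
        assert round_half_up(float(np.exp(fit.coef[1])), 2) == 3.64

    def test_constant_outcome_rejected(self):
        X = np.arange(10, dtype=float).reshape(-1, 1)
        with pytest.raises(LogisticError, match="no variation"):
            fit_logistic(X, np.ones(10))

    def test_non_binary_outcome_rejected(self):
        X = np.arange(10, dtype=float).reshape(-1, 1)
        with pytest.raises(LogisticError, match="binary"):
            fit_logistic(X, np.arange(10))

    def test_rank_deficient_design_names_columns(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        X = np.column_stack([x, 2.0 * x])
        y = (rng.random(100) < 0.5).astype(float)
        with pytest.raises(LogisticError, match="collinear"):
            fit_logistic(X, y, names=["x", "x_doubled"])

    def test_matches_statsmodels_on_random_data(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        X = rng.normal(size=(400, 3))
        eta = -0.3 + X @ np.array([0.8, -0.5, 0.2])
        y = (rng.random(400) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert np.allclose(fit.coef, ref.params, atol=1e-6)
        assert np.allclose(fit.se, ref.bse, atol=1e-6)

    def test_likelihood_never_decreases(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            X = rng.normal(size=(200, 2))
            y = (rng.random(200) < 0.4).astype(float)
            fit = fit_logistic(X, y)
            diffs = np.diff(fit.ll_trace)
            assert (diffs >= -1e-9).all()

    def test_perfect_separation_flagged_not_raised(self):
        X = np.linspace(-1, 1, 40).reshape(-1, 1)
        y = (X.ravel() > 0).astype(float)
        fit = fit_logistic(X, y)
        assert fit.separation and not fit.converged

    def test_planted_coefficient_recovery(self, medium_cohort):
        from stoppstart.cohort import covariate_frame
        from stoppstart.simulate import plant_outcome

        beta_female = math.log(4.04)
        y = plant_outcome(
            medium_cohort, {"intercept": -0.5, "female": beta_female}, seed=9
        )
        frame = covariate_frame(medium_cohort)
        fit = fit_logistic(frame[["female"]].to_numpy(float), y, names=["female"])
        assert abs(float(fit.coef[1]) - beta_female) < 0.25  # n = 2,000

    def test_ci_coverage_near_nominal(self, medium_cohort):
        """95% Wald CI covers the planted coefficient at ~95% over replicates."""
        from stoppstart.cohort import covariate_frame
        from stoppstart.simulate import plant_outcome

        frame = covariate_frame(medium_cohort)
        X = frame[["female", "cci"]].to_numpy(float)
        beta = {"intercept": -1.0, "female": 0.7, "cci": 0.15}
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            y = plant_outcome(medium_cohort, beta, seed=1000 + rep)
            fit = fit_logistic(X, y, names=["female", "cci"])
            lo = fit.coef[1] - 1.959964 * fit.se[1]
            hi = fit.coef[1] + 1.959964 * fit.se[1]
            hits += lo <= beta["female"] <= hi
        # binomial(100, .95): 2 MC SE band
        assert 0.95 - 2 * math.sqrt(0.95 * 0.05 / n_rep) <= hits / n_rep <= 1.0


class TestForwardSelect:
    @staticmethod
    def null_frame(n, k, rng):
        return pd.DataFrame(
            rng.normal(size=(n, k)), columns=[f"z{j}" for j in range(k)]
        )

    def test_planted_predictor_selected_first(self):
        rng = np.random.default_rng(21)
        frame = self.null_frame(2000, 5, rng)
        frame["signal"] = rng.normal(size=2000)
        eta = -0.2 + 1.5 * frame["signal"].to_numpy()
        y = (rng.random(2000) < 1 / (1 + np.exp(-eta))).astype(float)
        res = forward_select(frame, y)
        assert res.selected and res.selected[0] == "signal"

    def test_all_null_candidates_rarely_selected(self):
        rng = np.random.default_rng(22)
        n_any = 0
        reps = 60
        for _ in range(reps):
            frame = self.null_frame(300, 3, rng)
            y = (rng.random(300) < 0.5).astype(float)
            res = forward_select(frame, y)
            n_any += bool(res.selected)
        # P(any of 3 nulls entering) ~ 1 - 0.95^3 ~ 0.14
        assert n_any / reps < 0.35

    def test_empty_candidate_list_gives_intercept_only(self):
        y = np.array([0, 1, 1, 0, 1], dtype=float)
        res = forward_select(pd.DataFrame(index=range(5)), y, candidates=[])
        assert res.selected == []
        assert res.fit.names == ["intercept"]
        assert "intercept-only" in res.note
        assert float(res.fit.coef[0]) == pytest.approx(math.log(3 / 2))

    def test_report_threshold_filters_final_model(self):
        rng = np.random.default_rng(23)
        frame = self.null_frame(1500, 2, rng)
        frame["strong"] = rng.normal(size=1500)
        eta = 1.2 * frame["strong"].to_numpy()
        y = (rng.random(1500) < 1 / (1 + np.exp(-eta))).astype(float)
        res = forward_select(frame, y)
        assert "strong" in res.reported
        assert set(res.reported) <= set(res.selected)


class TestHosmerLemeshow:
    def test_perfect_calibration_gives_zero_statistic(self):
        # 9 risk groups of 10 patients; observed == expected in every group
        probs, ys = [], []
        for k in range(1, 10):
            probs.extend([k / 10] * 10)
            ys.extend([1] * k + [0] * (10 - k))
        stat, df, p_val = hosmer_lemeshow(np.array(probs), np.array(ys))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df >= 5 and p_val == pytest.approx(1.0)

    def test_three_group_hand_computation(self):
        probs = np.array([0.1, 0.1, 0.1, 0.5, 0.5, 0.5, 0.9, 0.9, 0.9])
        y = np.array([0, 0, 1, 0, 1, 1, 1, 1, 0])
        stat, df, p_val = hosmer_lemeshow(probs, y, n_groups=3)
        # groups: O=(1,2,2), E=(0.3,1.5,2.7), n=3 each
        expected = ((1 - 0.3) ** 2 / (0.3 * (1 - 0.1))
                    + (2 - 1.5) ** 2 / (1.5 * (1 - 0.5))
                    + (2 - 2.7) ** 2 / (2.7 * (1 - 0.9)))
        assert stat == pytest.approx(expected)
        assert df == 1

    def test_tied_probabilities_stay_in_one_group(self):
        probs = np.array([0.2] * 50 + [0.8] * 50)
        y = (np.random.default_rng(1).random(100) < probs).astype(float)
        stat, df, p_val = hosmer_lemeshow(probs, y)
        assert df == max(1, 2 - 2)  # only two distinct risk groups survive

    def test_uniform_p_under_well_specified_model(self):
        """Calibration-null simulation: HL p is approximately uniform."""
        from scipy import stats as sps

        rng = np.random.default_rng(77)
        pvals = []
        for _ in range(300):
            x = rng.normal(size=400)
            eta = -0.2 + 0.8 * x
            y = (rng.random(400) < 1 / (1 + np.exp(-eta))).astype(float)
            fit = fit_logistic(x.reshape(-1, 1), y)
            pvals.append(hosmer_lemeshow(fit.predict(x.reshape(-1, 1)), y)[2])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestRocAuc:
    def test_perfect_separation(self):
        probs = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0, 0, 1, 1])
        assert roc_auc(probs, y) == 1.0

    def test_all_tied_scores(self):
        probs = np.full(10, 0.5)
        y = np.array([0, 1] * 5)
        assert roc_auc(probs, y) == 0.5

    def test_four_point_toy(self):
        probs = np.array([0.9, 0.8, 0.7, 0.1])
        y = np.array([1, 0, 1, 0])
        assert roc_auc(probs, y) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(LogisticError):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_matches_brute_force_pairwise(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = int(rng.integers(10, 200))
            probs = rng.choice(np.linspace(0, 1, 21), size=n)  # many ties
            y = (rng.random(n) < 0.4).astype(int)
            if y.sum() in (0, n):
                continue
            pos, neg = probs[y == 1], probs[y == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert roc_auc(probs, y) == pytest.approx(wins / (len(pos) * len(neg)))


class TestJointCutoff:
    def test_perfectly_separating_scores(self):
        probs = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0, 0, 1, 1])
        cutoff, sens, spec = joint_cutoff(probs, y)
        assert sens == 1.0 and spec == 1.0
        assert cutoff == 0.8  # smallest threshold achieving both

    def test_all_tied_scores_degenerate(self):
        probs = np.full(6, 0.5)
        y = np.array([0, 1, 0, 1, 0, 1])
        cutoff, sens, spec = joint_cutoff(probs, y)
        assert min(sens, spec) == 0.0

    def test_matches_exhaustive_sweep(self):
        rng = np.random.default_rng(12)
        probs = rng.random(20)
        y = (rng.random(20) < 0.5).astype(int)
        if y.sum() in (0, 20):
            y[0] = 1 - y[0]
        cutoff, sens, spec = joint_cutoff(probs, y)
        best = max(
            (min(((probs >= t) & (y == 1)).sum() / (y == 1).sum(),
                 ((probs < t) & (y == 0)).sum() / (y == 0).sum()),
             ((probs >= t) & (y == 1)).sum() / (y == 1).sum()
             + ((probs < t) & (y == 0)).sum() / (y == 0).sum(),
             -t)
            for t in np.unique(probs)
        )
        assert min(sens, spec) == pytest.approx(best[0])
        assert sens + spec == pytest.approx(best[1])
        assert cutoff == pytest.approx(-best[2])


class TestDiagnostics:
    def test_bundle_is_internally_consistent(self, medium_cohort):
        from stoppstart.cohort import covariate_frame
        from stoppstart.simulate import plant_outcome

        frame = covariate_frame(medium_cohort)
        X = frame[["female", "cci", "n_medications"]].to_numpy(float)
        y = plant_outcome(
            medium_cohort,
            {"intercept": -2.0, "female": 0.8, "cci": 0.2, "n_medications": 0.1},
            seed=31,
        )
        fit = fit_logistic(X, y, names=["female", "cci", "n_medications"])
        diag = diagnostics(fit, X, y)
        assert 0.5 < diag.auc <= 1.0
        assert diag.auc_ci_low <= diag.auc <= diag.auc_ci_high
        assert 0.0 <= diag.sensitivity <= 1.0 and 0.0 <= diag.specificity <= 1.0
        assert diag.omnibus_p < 0.01  # planted signal is detectable
        assert diag.hl_df >= 1
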
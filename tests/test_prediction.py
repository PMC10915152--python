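"""Outcome arithmetic, stepwise selection, ROC evaluation."""

import numpy as np
import pandas as pd
import pytest

from subpls import (
    compute_outcomes,
    evaluate_classifier,
    outcome_table,
    roc_metrics,
    stepwise_fit,
)


class TestOutcomes:
    def test_exact_half_reduction_is_not_response(self):
        rec = compute_outcomes("s", 20, 10)
        assert rec.pct_reduction == pytest.approx(50.0)
        assert not rec.response  # strict > 50%
        assert not rec.remission

    def test_full_recovery(self):
        rec = compute_outcomes("s", 20, 0)
        assert rec.pct_reduction == pytest.approx(100.0)
        assert rec.response and rec.remission

    def test_flags_consistent_over_full_score_grid(self):
        # exhaustive: every integer (baseline, post) pair on the 0..52 scale
        for baseline in range(1, 53):
            for post in range(0, 53):
                rec = compute_outcomes("s", baseline, post)
                assert rec.response == (2 * (baseline - post) > baseline)
                assert rec.remission == (post <= 7)
                assert rec.pct_reduction == pytest.approx(
                    100.0 * (baseline - post) / baseline, abs=1e-9
                )

    def test_pct_reduction_antitone_in_post_score(self):
        vals = [compute_outcomes("s", 25, post).pct_reduction for post in range(0, 26)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_scores_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            compute_outcomes("s", 0, 5)
        with pytest.raises(ValueError, match="negative"):
            compute_outcomes("s", 20, -1)

    def test_remission_rate_among_completers(self):
        # cohort of 84 completers of whom 41 end at or below the remission cut
        df = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(84)],
            "baseline_hrsd": [20] * 84,
            "post_hrsd": [5] * 41 + [12] * 43,
        })
        table = outcome_table(df)
        assert 100 * table["remission"].mean() == pytest.approx(48.81, abs=0.01)

    def test_non_completers_excluded_with_warning(self):
        df = pd.DataFrame({
            "subject_id": ["a", "b", "c"],
            "baseline_hrsd": [20, 18, 22],
            "post_hrsd": [4, np.nan, 9],
        })
        with pytest.warns(UserWarning, match="excluding 1/3"):
            table = outcome_table(df)
        assert len(table) == 2

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            outcome_table(pd.DataFrame())


class TestStepwise:
    def test_pure_noise_yields_empty_selection_mostly(self):
        empty = 0
        n_seeds = 20
        for seed in range(n_seeds):
            g = np.random.default_rng(seed)
            df = pd.DataFrame({
                "y": g.normal(size=100),
                "fc_score": g.normal(size=100),
                "age_of_onset": g.normal(size=100),
                "episode_duration": g.normal(size=100),
            })
            fit = stepwise_fit(df, "y", family="linear")
            empty += not fit.selected_predictors
        assert empty >= 0.9 * n_seeds

    def test_planted_linear_effect_recovered(self):
        g = np.random.default_rng(3)
        score = g.normal(size=200)
        z = (score - score.mean()) / score.std(ddof=1)
        df = pd.DataFrame({
            "y": 2.0 * z + g.normal(scale=0.3, size=200),
            "fc_score": score,
            "age_of_onset": g.normal(size=200),
            "episode_duration": g.normal(size=200),
        })
        fit = stepwise_fit(df, "y", family="linear")
        assert "fc_score" in fit.selected_predictors
        assert fit.coefficients["fc_score"] == pytest.approx(2.0, rel=0.1)

    def test_planted_negative_log_odds_gives_or_below_one(self):
        below = 0
        n_seeds = 10
        for seed in range(n_seeds):
            g = np.random.default_rng(seed)
            score = g.normal(scale=5.0, size=500)
            prob = 1 / (1 + np.exp(-(-0.1 * score)))
            df = pd.DataFrame({
                "y": g.binomial(1, prob),
                "fc_score": score,
                "age_of_onset": g.normal(size=500),
                "episode_duration": g.normal(size=500),
            })
            fit = stepwise_fit(df, "y", family="logistic")
            if fit.odds_ratios.get("fc_score", 1.0) < 1.0:
                below += 1
        assert below > 0.95 * n_seeds

    def test_separation_flagged_with_penalized_fallback(self):
        g = np.random.default_rng(0)
        score = np.concatenate([g.uniform(-3, -1, 25), g.uniform(1, 3, 25)])
        df = pd.DataFrame({
            "y": (score > 0).astype(int),
            "fc_score": score,
            "age_of_onset": g.normal(size=50),
            "episode_duration": g.normal(size=50),
        })
        with pytest.warns(UserWarning, match="separation"):
            fit = stepwise_fit(df, "y", family="logistic")
        assert fit.separation_flag
        assert fit.odds_ratios["fc_score"] > 1.0
        assert fit.fitted_probabilities is not None

    def test_too_few_complete_cases_rejected(self):
        df = pd.DataFrame({"y": np.arange(5.0), "fc_score": np.arange(5.0),
                           "age_of_onset": np.arange(5.0),
                           "episode_duration": np.arange(5.0)})
        with pytest.raises(ValueError, match="complete cases"):
            stepwise_fit(df, "y", family="linear")


class TestRoc:
    def test_hand_enumerated_toy_auc(self):
        probs = np.array([0.9, 0.8, 0.4, 0.3, 0.2])
        labels = np.array([1, 1, 1, 0, 0])
        auc, accuracy, curve = roc_metrics(probs, labels)
        assert auc == pytest.approx(1.0)
        assert {"fpr", "tpr", "threshold"} <= set(curve.columns)

    def test_perfect_separation_and_null_auc(self, rng):
        n = 2000
        labels = rng.binomial(1, 0.5, n)
        auc_null, _, _ = roc_metrics(rng.uniform(size=n), labels)
        assert auc_null == pytest.approx(0.5, abs=0.05)
        auc_perfect, _, _ = roc_metrics(labels.astype(float), labels)
        assert auc_perfect == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_auc_equals_concordant_pair_fraction(self, seed):
        g = np.random.default_rng(seed)
        n = g.integers(8, 21)
        probs = g.uniform(size=n)
        labels = g.binomial(1, 0.5, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        # brute-force Mann-Whitney oracle
        pos, neg = probs[labels == 1], probs[labels == 0]
        pairs = [(1.0 if p > q else 0.5 if p == q else 0.0) for p in pos for q in neg]
        auc, _, _ = roc_metrics(probs, labels)
        assert auc == pytest.approx(np.mean(pairs), abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            roc_metrics(np.array([0.2, 0.8]), np.array([1, 1]))

    def test_evaluate_classifier_fills_model(self):
        g = np.random.default_rng(1)
        score = g.normal(scale=5.0, size=300)
        prob = 1 / (1 + np.exp(0.3 * score))
        df = pd.DataFrame({"y": g.binomial(1, prob), "fc_score": score,
                           "age_of_onset": g.normal(size=300),
                           "episode_duration": g.normal(size=300)})
        fit = stepwise_fit(df, "y", family="logistic")
        auc, accuracy, _ = evaluate_classifier(fit)
        assert fit.auc == auc and 0.5 < auc <= 1.0
        assert 0.0 <= accuracy <= 1.0
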
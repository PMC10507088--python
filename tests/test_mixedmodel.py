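import numpy as np
import pandas as pd
import pytest

from leadsync.mixedmodel import (
    MAIN_COEFFICIENTS,
    build_design,
    evaluate_hypotheses,
    fit_bayes_lmm,
)
from leadsync.synthetic import RatingSimConfig, simulate_ratings


@pytest.fixture
def small_trials(stimulus_predictors):
    cfg = RatingSimConfig(n_participants=30, n_stimuli=44, seed=5)
    return simulate_ratings(cfg, stimulus_predictors)


class TestBuildDesign:
    def test_coefficient_layout(self, small_trials):
        design = build_design(small_trials)
        assert design.coef_names == list(MAIN_COEFFICIENTS)
        assert design.X.shape == (len(small_trials), 11)

    def test_diagnosis_changes_only_its_columns(self, small_trials):
        # duplicate the first trial with diagnosis flipped: the two design
        # rows must differ only in the diagnosis column and its interactions
        df = small_trials.copy()
        twin = df.iloc[[0]].assign(diagnosis=1 - df.iloc[0].diagnosis)
        df = pd.concat([df, twin], ignore_index=True)
        X = build_design(df).X
        diff_cols = np.nonzero(~np.isclose(X[0], X[-1]))[0]
        names = [MAIN_COEFFICIENTS[i] for i in diff_cols]
        assert set(names) <= {
            "diagnosis", "diagnosis_x_green", "diagnosis_x_white",
            "diagnosis_x_green_x_white",
        }
        assert "diagnosis" in names

    def test_continuous_columns_standardized(self, small_trials):
        design = build_design(small_trials)
        for name in ("green_leading", "white_leading", "motion_green", "motion_white"):
            col = design.X[:, design.coef_names.index(name)]
            assert abs(col.mean()) < 1e-10
            assert abs(col.std(ddof=1) - 1.0) < 1e-10

    def test_aq_variant_adds_columns(self, small_trials):
        df = small_trials.copy()
        df["aq_group"] = (df["participant_id"].str[-1].astype(int) % 2).astype(int)
        design = build_design(df, formula_variant="aq_exploratory")
        assert design.coef_names[-2:] == ["aq_group", "aq_group_x_diagnosis"]

    def test_rank_deficiency_names_aliased_columns(self, small_trials):
        df = small_trials.copy()
        df["motion_white"] = df["motion_green"]  # perfectly aliased
        with pytest.raises(ValueError, match="aliased"):
            build_design(df)

    def test_too_few_groups(self, small_trials):
        df = small_trials[small_trials.participant_id == "p000"]
        with pytest.raises(ValueError, match="participants"):
            build_design(df)


def closed_form_posterior(X, y, sigma2, prior_sd):
    """Conjugate normal posterior for beta with known residual variance."""
    prec = X.T @ X / sigma2 + np.eye(X.shape[1]) / prior_sd**2
    cov = np.linalg.inv(prec)
    mean = cov @ X.T @ y / sigma2
    return mean, cov


class TestFitBayesLmm:
    def test_near_noiseless_data_recovers_ols(self, stimulus_predictors):
        cfg = RatingSimConfig(
            n_participants=20, n_stimuli=44, seed=7,
            sd_participant=0.0, sd_stimulus=0.0, sd_slopes=0.0,
            sd_residual=0.01, item_noise_sd=0.0,
        )
        trials = simulate_ratings(cfg, stimulus_predictors)
        design = build_design(trials)
        fit = fit_bayes_lmm(design, chains=2, iterations=2000, seed=1)
        ols = np.linalg.lstsq(design.X, design.y, rcond=None)[0]
        post_mean = fit.beta.reshape(-1, len(ols)).mean(axis=0)
        np.testing.assert_allclose(post_mean, ols, atol=1e-3)

    def test_fixed_effects_posterior_matches_conjugate_closed_form(self, rng):
        # fixed-effects-only data: random-effect variances collapse and the
        # beta posterior approaches the known-sigma conjugate solution
        from leadsync.mixedmodel import DesignBundle

        n, p = 400, 3
        X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
        beta_true = np.array([1.0, 2.0, -1.5])
        sigma = 1.0
        y = X @ beta_true + rng.standard_normal(n) * sigma
        design = DesignBundle(
            X=X,
            y=y,
            coef_names=["intercept", "b1", "b2"],
            participant_idx=np.arange(n) % 10,
            stimulus_idx=np.arange(n) % 20,
            n_participants=10,
            n_stimuli=20,
            diagnosis_code=np.zeros(n),
            source_code=np.zeros(n),
            formula_variant="main",
        )
        fit = fit_bayes_lmm(design, chains=4, iterations=3000, seed=3, prior_beta_sd=50.0)
        cf_mean, cf_cov = closed_form_posterior(design.X, design.y, sigma**2, 50.0)
        draws = fit.beta.reshape(-1, 3)
        mc_se = draws.std(axis=0, ddof=1) / np.sqrt(draws.shape[0] / 20)  # ~ESS guard
        assert np.all(np.abs(draws.mean(axis=0) - cf_mean) < 3 * np.maximum(mc_se, 1e-4))

    def test_location_scale_equivariance(self, small_trials):
        design = build_design(small_trials)
        fit = fit_bayes_lmm(design, chains=2, iterations=1500, seed=4)
        shifted = build_design(small_trials.assign(score=small_trials.score + 10))
        fit_shift = fit_bayes_lmm(shifted, chains=2, iterations=1500, seed=4)
        for name in MAIN_COEFFICIENTS:
            a = fit.draws(name).mean()
            b = fit_shift.draws(name).mean()
            expected = a + 10 if name == "intercept" else a
            assert abs(b - expected) < 1.5, name

    def test_treatment_recoding_flips_diagnosis_sign(self, small_trials):
        design = build_design(small_trials)
        fit = fit_bayes_lmm(design, chains=2, iterations=2000, seed=5)
        recoded = small_trials.assign(diagnosis=1 - small_trials.diagnosis)
        fit_rec = fit_bayes_lmm(build_design(recoded), chains=2, iterations=2000, seed=5)
        a = fit.draws("diagnosis").mean()
        b = fit_rec.draws("diagnosis").mean()
        # under the induced reparameterization b = -(a + interaction terms at 0)
        # of the scaled predictors; with centred predictors the main effect flips
        assert np.sign(a) == -np.sign(b)
        ga = fit.draws("diagnosis_x_green").mean()
        gb = fit_rec.draws("diagnosis_x_green").mean()
        assert abs(ga + gb) < 1.5

    def test_chain_exchangeability(self, small_trials):
        design = build_design(small_trials)
        fit = fit_bayes_lmm(design, chains=4, iterations=2000, seed=6)
        for name in ("green_leading", "diagnosis"):
            j = fit.coef_names.index(name)
            per_chain = fit.beta[:, :, j].mean(axis=1)
            between_se = per_chain.std(ddof=1)
            assert np.all(np.abs(per_chain - per_chain.mean()) < 3 * between_se + 1e-9)

    def test_insufficient_iterations_rejected(self, small_trials):
        design = build_design(small_trials)
        with pytest.raises(ValueError, match="500"):
            fit_bayes_lmm(design, iterations=600)


class TestEvaluateHypotheses:
    def test_all_positive_coefficient_credible(self, stimulus_predictors):
        cfg = RatingSimConfig(n_participants=40, n_stimuli=44, seed=9,
                              beta=(50, 0, 10, 0, 0, 0, 0, 0, 0, 0, 0),
                              sd_residual=5.0, item_noise_sd=0.0)
        trials = simulate_ratings(cfg, stimulus_predictors)
        fit = fit_bayes_lmm(build_design(trials), chains=2, iterations=2000, seed=2)
        hyps = evaluate_hypotheses(fit)
        assert hyps["green_leading"].credible
        assert hyps["green_leading"].direction == ">0"

    def test_unknown_coefficient_raises(self, small_trials):
        fit = fit_bayes_lmm(build_design(small_trials), chains=2, iterations=1500, seed=8)
        with pytest.raises(KeyError, match="unknown coefficient"):
            evaluate_hypotheses(fit, [("no_such_beta", ">0")])
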
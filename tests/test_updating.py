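"""Intercept recalibration and ridge-penalized refitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from conftest import make_profile, profile_frame
from deprisk.metrics import auc, calibration_intercept
from deprisk.predictors import N_DUMMY_TERMS
from deprisk.risk import RiskModel, score_cohort
from deprisk.updating import (
    DEFAULT_GRID,
    FitError,
    RefitOptions,
    build_design_matrix,
    coefficient_keys,
    effective_df,
    fit_penalized_logistic,
    recalibrate_intercept,
    refit_model,
    select_penalty,
    _lower_median,
)


# --- recalibration -----------------------------------------------------------


def constant_offset_cohort(n, prevalence, coef):
    """Everyone shares one non-reference level, so the coefficient part of
    the linear predictor is the constant ``coef``."""
    df = profile_frame([make_profile(loneliness=1) for _ in range(n)])
    k = int(round(prevalence * n))
    df["incident_mdd_youth"] = [1] * k + [0] * (n - k)
    model = RiskModel(intercept=-3.0, main_effects={"loneliness": {1: coef}})
    return model, df


def test_recalibration_closed_form_constant_offset():
    """With a constant offset c and prevalence p, the score equation gives
    the new intercept exactly as logit(p) − c."""
    model, df = constant_offset_cohort(1000, prevalence=0.2, coef=0.7)
    updated = recalibrate_intercept(model, df, "incident_mdd_youth")
    assert updated.intercept == pytest.approx(float(logit(0.2)) - 0.7, abs=1e-8)
    assert updated.provenance == "recalibrated"
    assert updated.main_effects == model.main_effects


def test_recalibration_zeroes_citl_and_preserves_auc(small_analytic, truth_model):
    updated = recalibrate_intercept(truth_model, small_analytic, "incident_mdd_youth")
    scored = score_cohort(updated, small_analytic)
    y = small_analytic["incident_mdd_youth"].to_numpy()
    assert abs(calibration_intercept(scored["p"].to_numpy(), y)) < 1e-8
    before = score_cohort(truth_model, small_analytic)
    assert auc(before["coef_sum"].to_numpy(), y) == auc(scored["coef_sum"].to_numpy(), y)


def test_recalibration_noop_when_already_calibrated(rng):
    df = profile_frame(
        [make_profile(loneliness=int(rng.random() < 0.3)) for _ in range(40_000)]
    )
    model = RiskModel(intercept=-2.0, main_effects={"loneliness": {1: 0.8}})
    p = score_cohort(model, df)["p"].to_numpy()
    df["incident_mdd_youth"] = (rng.random(len(df)) < p).astype(int)
    updated = recalibrate_intercept(model, df, "incident_mdd_youth")
    assert updated.intercept == pytest.approx(-2.0, abs=0.1)


# --- design matrix -----------------------------------------------------------


def test_design_matrix_main_effect_count(small_analytic):
    design = build_design_matrix(small_analytic)
    assert len(design.columns) == N_DUMMY_TERMS == 21
    assert design.matrix.shape == (len(small_analytic), 21)


def test_design_matrix_interaction_columns(small_analytic):
    design = build_design_matrix(small_analytic, include_interactions=True)
    # pairwise products of dummy columns from distinct predictors:
    # (21^2 - sum k_i^2)/2 = (441 - 59)/2 = 191
    assert len(design.interaction_terms) == 191
    assert len(design.columns) == 21 + 191
    # two binary predictors contribute exactly one product column
    pairs = [t for t in design.interaction_terms
             if {t[0][0], t[1][0]} == {"sex_female", "nonwhite"}]
    assert len(pairs) == 1


def test_design_matrix_all_reference_is_zero():
    df = profile_frame([make_profile() for _ in range(5)])
    design = build_design_matrix(df, include_interactions=True)
    assert not design.matrix.any()


# --- penalized logistic fit --------------------------------------------------


def toy_data(rng, n=600, k=3, beta=None, intercept=-1.0):
    X = rng.normal(size=(n, k))
    beta = beta if beta is not None else np.array([0.8, -0.5, 0.0])
    y = (rng.random(n) < expit(intercept + X @ beta)).astype(int)
    return X, y


def test_unpenalized_fit_matches_mle_oracle(rng):
    import statsmodels.api as sm

    X, y = toy_data(rng)
    b0, slopes = fit_penalized_logistic(X, y, lam=0.0)
    oracle = sm.Logit(y, sm.add_constant(X)).fit(disp=0, tol=1e-12)
    assert b0 == pytest.approx(oracle.params[0], abs=1e-6)
    assert np.allclose(slopes, oracle.params[1:], atol=1e-6)


def test_ridge_limit_shrinks_slopes_to_zero(rng):
    X, y = toy_data(rng)
    b0, slopes = fit_penalized_logistic(X, y, lam=1e8)
    assert np.abs(slopes).max() < 1e-4
    assert b0 == pytest.approx(float(logit(y.mean())), abs=1e-3)


def test_separation_finite_with_penalty_diverges_without():
    X = np.linspace(-2, 2, 40).reshape(-1, 1)
    y = (X[:, 0] > 0).astype(int)
    b0, slopes = fit_penalized_logistic(X, y, lam=1.0)
    assert np.isfinite(slopes).all()
    with pytest.raises(FitError, match="separation"):
        fit_penalized_logistic(X, y, lam=0.0)


def test_ridge_path_monotone(rng):
    X, y = toy_data(rng)
    norms = []
    for lam in [0.0, 0.1, 1.0, 10.0, 100.0]:
        _, slopes = fit_penalized_logistic(X, y, lam)
        norms.append(float(slopes @ slopes))
    assert all(a >= b - 1e-10 for a, b in zip(norms, norms[1:]))


def test_effective_df_decreases_with_penalty(rng):
    X, y = toy_data(rng)
    dfs = []
    for lam in [0.0, 1.0, 10.0, 1000.0]:
        b0, slopes = fit_penalized_logistic(X, y, lam)
        dfs.append(effective_df(X, np.r_[b0, slopes], lam))
    assert dfs[0] == pytest.approx(X.shape[1] + 1, abs=1e-6)
    assert all(a >= b for a, b in zip(dfs, dfs[1:]))
    assert dfs[-1] >= 1.0  # the unpenalized intercept always counts


# --- penalty selection -------------------------------------------------------


def test_select_penalty_degenerate_grid_and_single_boot(rng):
    X, y = toy_data(rng, n=200)
    sel = select_penalty(X, y, grid=[3.3], n_boot=5, seed=0)
    assert sel.selected == 3.3
    sel1 = select_penalty(X, y, grid=[0.1, 1.0, 10.0], n_boot=1, seed=4)
    assert sel1.selected == sel1.per_replicate_optima[0]


def test_select_penalty_deterministic(rng):
    X, y = toy_data(rng, n=200)
    a = select_penalty(X, y, grid=[0.1, 1.0, 10.0], n_boot=8, seed=12)
    b = select_penalty(X, y, grid=[0.1, 1.0, 10.0], n_boot=8, seed=12)
    assert a.to_dict() == b.to_dict()
    assert min(a.grid) <= a.selected <= max(a.grid)


def test_lower_median_even_count():
    assert _lower_median(np.array([1.0, 10.0])) == 1.0
    assert _lower_median(np.array([1.0, 2.0, 4.0, 8.0])) == 2.0
    assert _lower_median(np.array([5.0, 1.0, 9.0])) == 5.0


# --- full refit --------------------------------------------------------------


def test_refit_coefficient_keys_match_design(small_analytic):
    model, selection = refit_model(
        small_analytic,
        "incident_mdd_youth",
        RefitOptions(include_interactions=False, penalty=1.0),
    )
    design = build_design_matrix(small_analytic)
    assert selection is None
    assert model.provenance == "refitted"
    assert model.penalty == 1.0
    assert sorted(coefficient_keys(model)) == sorted(design.columns)


def test_refit_recovers_generating_coefficients():
    """Parameter recovery at n=20,000 and 5% prevalence: large effects come
    back within 0.15 of truth (single replicate; the multi-replicate version
    runs in the acceptance suite)."""
    from deprisk.synthetic import SyntheticConfig, generate_cohort, solve_intercept
    from deprisk.phenotypes import derive_predictor_table

    truth = {"loneliness": {1: 0.9}, "caregiver1_q": {2: 0.0, 3: 0.0, 4: 0.0, 5: 1.2}}
    cfg = SyntheticConfig(
        n_participants=20_000,
        n_families=20_000,
        site_sd=0.0,
        attendance_rate=1.0,
        baseline_mdd_rate=0.0,
        missing_rate=0.0,
        seed=77,
    )
    intercept = solve_intercept(truth, cfg.predictor_marginals, 0.05)
    from deprisk.predictors import PREDICTORS

    full = {
        d.name: {l: truth.get(d.name, {}).get(l, 0.0) for l in d.non_reference_levels}
        for d in PREDICTORS
    }
    cfg.true_model = RiskModel(intercept=intercept, main_effects=full)
    cohort = generate_cohort(cfg)
    base = cohort[cohort["wave"] == "baseline"].reset_index(drop=True)
    analytic = derive_predictor_table(base).astype(int)
    analytic["participant_id"] = base["participant_id"]
    fup = cohort[cohort["wave"] == "followup"].reset_index(drop=True)
    analytic["incident_mdd_youth"] = fup["latent_mdd_followup_youth"].astype(int)
    model, _ = refit_model(
        analytic,
        "incident_mdd_youth",
        RefitOptions(include_interactions=False, grid=(0.01, 0.1, 1.0), n_boot=4, seed=1),
    )
    assert abs(model.main_effects["loneliness"][1] - 0.9) < 0.15
    assert abs(model.main_effects["caregiver1_q"][5] - 1.2) < 0.15
    # null effects stay near zero under the ridge penalty
    assert abs(model.main_effects["fights"][1]) < 0.3


def test_refit_improves_in_sample_auc_over_perturbed_external(small_analytic, truth_model):
    y = small_analytic["incident_mdd_youth"].to_numpy()
    perturbed = RiskModel(
        intercept=truth_model.intercept - 1.0,
        main_effects={
            p: {l: -v for l, v in lv.items()}
            for p, lv in truth_model.main_effects.items()
        },
    )
    auc_ext = auc(score_cohort(perturbed, small_analytic)["lp"].to_numpy(), y)
    refitted, _ = refit_model(
        small_analytic, "incident_mdd_youth",
        RefitOptions(include_interactions=False, penalty=1.0),
    )
    auc_refit = auc(score_cohort(refitted, small_analytic)["lp"].to_numpy(), y)
    assert auc_refit >= auc_ext
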
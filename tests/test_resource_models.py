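"""Mixed-model engine: oracle equivalences, AIC selection, fallback
path, adjusted means and the delivery-cost model."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit, gammaln

from plgfcea import resource_models as rm
from plgfcea import synthetic_trial as st
from plgfcea.schema import ARMS, CATEGORIES, SUBGROUPS

from conftest import single_cell_config


@pytest.fixture(scope="module")
def two_part_fit(small_records):
    return rm.fit_glmm(small_records, "antenatal_ward")


def test_aic_identity(two_part_fit):
    for part in (two_part_fit.part1, two_part_fit.part2):
        assert part.aic == pytest.approx(2 * part.n_params - 2 * part.loglik, abs=1e-9)
        assert part.n_params == len(part.theta)
    assert two_part_fit.aic == pytest.approx(
        2 * two_part_fit.n_params - 2 * two_part_fit.loglik, abs=1e-9
    )


def test_single_cluster_fit_matches_unmixed_oracle(default_config):
    """With one centre the random effect is vacuous: both hurdle parts
    must agree with independently maximised plain likelihoods."""
    cfg = single_cell_config(
        default_config, cluster_effects={"sigma_c": 0.0, "beta_t": 0.0}
    )
    cfg["design"] = {"n_clusters": 1, "n_steps": 6, "cluster_weights": [5000]}
    cfg["enrolment"] = {"usual": 700, "revealed": 800}
    df = st.simulate_trial(cfg, seed=3)
    fit = rm.fit_glmm(df, "antenatal_ward")
    assert fit.converged

    X, names, _ = rm.build_design_matrix(df)
    y = df["antenatal_ward"].to_numpy(dtype=float)

    free1 = ~fit.part1.pinned
    oracle1 = sm.Logit((y > 0).astype(float), X[:, free1]).fit(disp=0)
    assert np.abs(fit.part1.coef[free1] - oracle1.params).max() < 1e-2

    # independent zero-truncated NB log-likelihood, maximised from scratch
    pos = y > 0
    yp, Xp = y[pos], X[pos][:, ~fit.part2.pinned]

    def nll(t):
        b, k = t[:-1], np.exp(t[-1])
        mu = np.exp(Xp @ b)
        ll = (
            gammaln(yp + k)
            - gammaln(k)
            - gammaln(yp + 1)
            + k * np.log(k / (k + mu))
            + yp * np.log(mu / (k + mu))
            - np.log1p(-((k / (k + mu)) ** k))
        )
        return -ll.sum()

    t0 = np.zeros(Xp.shape[1] + 1)
    t0[0] = np.log(yp.mean())
    res = minimize(nll, t0, method="Nelder-Mead", options={"maxiter": 5000, "fatol": 1e-10, "xatol": 1e-8})
    assert np.abs(fit.part2.coef[~fit.part2.pinned] - res.x[:-1]).max() < 1e-2
    assert abs(fit.part2.dispersion - np.exp(res.x[-1])) < 1e-2


def test_zero_sigma_data_reduces_to_plain_fit(default_config):
    """Data generated without a centre effect: the fitted sigma collapses
    and fixed effects match an unmixed logistic fit."""
    cfg = single_cell_config(
        default_config, cluster_effects={"sigma_c": 0.0, "beta_t": 0.0}
    )
    cfg["enrolment"] = {"usual": 1800, "revealed": 2200}
    df = st.simulate_trial(cfg, seed=4)
    fit = rm.fit_glmm(df, "antenatal_ward")
    assert fit.part1.sigma_c < 0.05
    free = ~fit.part1.pinned
    y = (df["antenatal_ward"] > 0).astype(float).to_numpy()
    X, _, _ = rm.build_design_matrix(df)
    oracle = sm.Logit(y, X[:, free]).fit(disp=0)
    assert np.abs(fit.part1.coef[free] - oracle.params).max() < 1e-3


def _manual_two_part(p: float, mu_pos: float, k: float) -> rm.TwoPartFit:
    names = ["const"]
    base = st.truncated_nb_base_mean(mu_pos, k)

    def part(coef, disp):
        dim = 1 + (disp is not None)
        return rm.MixedFit(
            family="x",
            coef=np.array([coef]),
            coef_names=names,
            pinned=np.array([False]),
            dispersion=disp,
            sigma_c=0.0,
            cov=np.zeros((dim, dim)),
            theta_names=["const"],
            loglik=0.0,
            aic=0.0,
            n_params=1,
            nobs=1,
            n_quad=7,
            converged=True,
        )

    part1 = part(np.log(p / (1 - p)), None)
    part2 = part(np.log(base), k)
    return rm.TwoPartFit("two_part_truncNB", part1, part2, names, 0.0)


def test_hurdle_mean_identity():
    """p = 0.5 and positive-part mean 4 predict a cell mean of exactly 2."""
    fit = _manual_two_part(0.5, 4.0, 2.0)
    mean, se = rm._predict_cell(fit, np.array([1.0]))
    assert mean == pytest.approx(2.0, abs=1e-9)


def test_adjusted_means_emit_all_cells(pipeline_means):
    assert len(pipeline_means) == len(CATEGORIES) * len(SUBGROUPS) * 2
    grid = pipeline_means.groupby("category").size()
    assert (grid == 18).all()
    assert (pipeline_means["mean"] >= 0).all()
    assert (pipeline_means["se"] >= 0).all()


def test_absent_cell_marked_fixed_zero(small_records):
    mask = ~(
        (small_records["plgf_category"] == "gt100")
        & (small_records["diagnosis"] == "preeclampsia")
    )
    trimmed = small_records[mask].reset_index(drop=True)
    fit = rm.fit_fallback(trimmed, "maternal_icu_hdu")
    means = rm.adjusted_means(fit, "maternal_icu_hdu", trimmed)
    cell = means[
        (means["plgf_category"] == "gt100") & (means["diagnosis"] == "preeclampsia")
    ]
    assert (cell["mean"] == 0).all()
    assert (cell["se"] == 0).all()
    assert (cell["distribution_tag"] == "fixed").all()


def test_model_selection_tie_prefers_fewer_parameters():
    lean = SimpleNamespace(converged=True, aic=100.0, n_params=3)
    rich = SimpleNamespace(converged=True, aic=100.0, n_params=5)
    failed = SimpleNamespace(converged=False, aic=-np.inf, n_params=1)
    spec, fit = rm._pick([("rich", rich), ("lean", lean), ("failed", failed)])
    assert fit is lean


def test_model_selection_recovers_true_family(default_config):
    """Data simulated from a two-part truncated NB should usually select
    that family against Poisson and one-part alternatives."""
    cfg = single_cell_config(default_config)
    cfg["enrolment"] = {"usual": 1100, "revealed": 1400}
    picks = []
    for seed in np.random.SeedSequence(77).spawn(5):
        df = st.simulate_trial(cfg, seed=seed)
        spec, _ = rm.select_model(df, "antenatal_ward")
        picks.append(spec.family)
    assert sum(p == "two_part_truncNB" for p in picks) >= 4


def _single_cell_records(n: int, seed: int, p_by_arm, day_mean=6.0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    arm = np.array(["usual", "revealed"])[rng.integers(0, 2, n)]
    admitted = rng.random(n) < np.where(arm == "revealed", p_by_arm[1], p_by_arm[0])
    days = np.where(admitted, 1 + rng.poisson(day_mean - 1, n), 0)
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "cluster": rng.integers(0, 6, n),
            "step": rng.integers(0, 7, n),
            "arm": arm,
            "plgf_category": "gt100",
            "diagnosis": "normal",
            "infant_icu_hdu": days,
        }
    )


def test_fallback_all_admitted_equals_linear_mean():
    df = _single_cell_records(600, seed=1, p_by_arm=(1.1, 1.1))  # always admitted
    fit = rm.fit_fallback(df, "infant_icu_hdu")
    x = rm.cell_covariates(fit.coef_names, "gt100", "normal", "usual")
    mean, _ = rm._predict_cell(fit, x)
    days = float(fit.linear_res.predict(x[None, :])[0])
    assert mean == pytest.approx(days, rel=1e-3)


def test_fallback_recovery_within_wald_intervals():
    p_true = (0.30, 0.40)
    df = _single_cell_records(1500, seed=2, p_by_arm=p_true)
    fit = rm.fit_fallback(df, "infant_icu_hdu")
    for arm, p in zip(ARMS, p_true):
        x = rm.cell_covariates(fit.coef_names, "gt100", "normal", arm)
        eta = float(x @ fit.logit_res.params)
        se = float(np.sqrt(x @ fit.logit_res.cov_params() @ x))
        lo, hi = expit(eta - 1.96 * se), expit(eta + 1.96 * se)
        assert lo <= p <= hi
        mean, _ = rm._predict_cell(fit, x)
        assert mean == pytest.approx(p * 6.0, rel=0.15)


def test_fallback_delta_se_matches_parametric_bootstrap():
    """Delta-method SE of the combined mean (p_admit x days) against a
    500-replicate parametric bootstrap refitting both regressions."""
    df = _single_cell_records(800, seed=3, p_by_arm=(0.30, 0.40))
    fit = rm.fit_fallback(df, "infant_icu_hdu")
    x = rm.cell_covariates(fit.coef_names, "gt100", "normal", "usual")
    mean, se_delta = rm._predict_cell(fit, x)

    X, _, _ = rm.build_design_matrix(df)
    y = df["infant_icu_hdu"].to_numpy(dtype=float)
    p_hat = fit.logit_res.predict(X)
    mu_hat = fit.linear_res.predict(X)
    resid_sd = np.sqrt(fit.linear_res.scale)
    rng = np.random.default_rng(7)
    boots = []
    for _ in range(500):
        adm = (rng.random(len(df)) < p_hat).astype(float)
        days = np.maximum(rng.normal(mu_hat, resid_sd), 0.1)
        logit_b = sm.GLM(adm, X, family=sm.families.Binomial()).fit(maxiter=100)
        pos = adm > 0
        lin_b = sm.OLS(days[pos], X[pos]).fit()
        boots.append(
            float(logit_b.predict(x[None, :])[0]) * float(lin_b.predict(x[None, :])[0])
        )
    se_boot = float(np.std(boots, ddof=1))
    assert abs(se_delta - se_boot) / se_boot < 0.15


def test_shifted_positive_counts_increase_predicted_mean(default_config):
    cfg = single_cell_config(default_config)
    cfg["enrolment"] = {"usual": 400, "revealed": 400}
    df = st.simulate_trial(cfg, seed=6)
    fit = rm.fit_glmm(df, "antenatal_ward")
    shifted = df.copy()
    shifted["antenatal_ward"] += (shifted["antenatal_ward"] > 0).astype(int)
    fit2 = rm.fit_glmm(shifted, "antenatal_ward")
    x = rm.cell_covariates(fit.coef_names, "gt100", "normal", "usual")
    m1, _ = rm._predict_cell(fit, x)
    m2, _ = rm._predict_cell(fit2, x)
    assert m2 > m1


def test_delivery_cost_single_mode_degenerate(small_records, unit_table):
    df = small_records.copy()
    df["delivery_mode"] = "spontaneous"
    out = rm.fit_delivery_cost(df, unit_table)
    cost = unit_table.delivery_costs["spontaneous"]
    assert (out["mean"] == cost).all()
    assert (out["lo"] == cost).all() and (out["hi"] == cost).all()


def test_delivery_cost_ci_ordering_and_recovery(small_records, unit_table, small_config):
    out = rm.fit_delivery_cost(small_records, unit_table)
    assert ((out["lo"] <= out["mean"]) & (out["mean"] <= out["hi"])).all()
    probs = small_config["delivery"]["mode_probs"]
    truth = sum(
        probs[m] * unit_table.delivery_costs[m] for m in probs
    )
    for _, row in out.iterrows():
        assert row["lo"] <= truth <= row["hi"]


def test_delivery_cost_rejects_nonpositive(small_records, unit_table):
    from plgfcea.costing import UnitCostTable

    bad = UnitCostTable(
        unit_table.category_costs,
        {**unit_table.delivery_costs, "spontaneous": 0.0},
        unit_table.plgf_test_cost,
    )
    with pytest.raises(ValueError, match="positive"):
        rm.fit_delivery_cost(small_records, bad)


def test_adjusted_means_csv_roundtrip(tmp_path, pipeline_means):
    path = tmp_path / "means.csv"
    rm.write_adjusted_means(pipeline_means, path)
    back = rm.read_adjusted_means(path)
    pd.testing.assert_frame_equal(back, pipeline_means, check_exact=False, rtol=1e-12)
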
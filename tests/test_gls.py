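"""GLS core: estimation, likelihood-ratio tests, predictive R^2, averaging."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phylorange import gls, phylo, simulate
from phylorange.design import prepare_design
from phylorange.gls import (
    average_replicate_fits,
    fit_pgls_ml,
    gls_fit,
    likelihood_ratio_test,
    partial_r2_table,
    r2_pred,
)

from conftest import random_tree


def _random_problem(n, p, seed):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)])
    X.iloc[:, 0] = 1.0
    y = X.to_numpy() @ rng.normal(size=p) + rng.normal(size=n)
    return y, X


def test_identity_correlation_reduces_to_ols():
    for seed in range(10):
        y, X = _random_problem(40, 4, seed)
        fit = gls_fit(y, X, np.eye(40), model="identity")
        ols_beta, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
        np.testing.assert_allclose(fit.beta.to_numpy(), ols_beta, rtol=1e-10)


def test_three_tip_intercept_only_hand_algebra(three_tip_tree):
    # beta = (1' R^-1 1)^-1 1' R^-1 y with the BM covariance of ((A:1,B:1):1,C:2)
    R = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
    y = np.array([1.0, 2.0, 4.0])
    ones = np.ones(3)
    Rinv = np.linalg.inv(R)
    expected = (ones @ Rinv @ y) / (ones @ Rinv @ ones)
    X = pd.DataFrame({"intercept": ones}, index=["A", "B", "C"])
    fit = gls_fit(y, X, phylo.bm_covariance(three_tip_tree).to_numpy())
    assert fit.beta["intercept"] == pytest.approx(expected, rel=1e-12)


def test_loglik_invariant_under_row_permutation():
    y, X = _random_problem(30, 3, 1)
    tree = random_tree(30, 1)
    labels = phylo.tip_labels(tree)
    X.index = labels
    R = phylo.ou_correlation(tree, 2.0)
    fit = gls_fit(y, X, R.to_numpy())
    perm = np.random.default_rng(0).permutation(30)
    fit_p = gls_fit(y[perm], X.iloc[perm], R.to_numpy()[np.ix_(perm, perm)])
    assert fit.loglik == pytest.approx(fit_p.loglik, rel=1e-10)
    np.testing.assert_allclose(fit.beta, fit_p.beta, rtol=1e-9)


def test_rank_deficient_design_rejected():
    y, X = _random_problem(20, 3, 2)
    X["x2"] = X["x1"]
    with pytest.raises(np.linalg.LinAlgError):
        gls_fit(y, X, np.eye(20))


# ----------------------------------------------------------------- OU profile

def test_ou_profile_is_maximal_on_grid(dataset_369):
    ds = dataset_369
    dm = prepare_design(ds.traits)
    D = phylo.patristic_distances(ds.tree).to_numpy()
    fit = fit_pgls_ml(dm.y, dm.X, ds.tree, model="OU", distances=D)
    for a in [0.5, 2.0, 5.0, 8.0, 12.0, 20.0, 40.0]:
        grid_fit = fit_pgls_ml(dm.y, dm.X, ds.tree, model="OU", alpha=a, distances=D)
        assert fit.loglik >= grid_fit.loglik - 1e-6


def test_ou_alpha_fixed_matches_direct_structure(dataset_369):
    ds = dataset_369
    dm = prepare_design(ds.traits)
    D = phylo.patristic_distances(ds.tree)
    fit = fit_pgls_ml(dm.y, dm.X, ds.tree, model="OU", alpha=3.0, distances=D.to_numpy())
    direct = gls_fit(dm.y, dm.X, np.exp(-3.0 * D.to_numpy()))
    np.testing.assert_allclose(fit.beta, direct.beta, rtol=1e-12)


# ------------------------------------------------------------------------ LRT

def test_lrt_identical_fits_zero(dataset_369):
    dm = prepare_design(dataset_369.traits)
    V = phylo.bm_covariance(dataset_369.tree).to_numpy()
    f1 = gls_fit(dm.y, dm.X, V, model="BM")
    f2 = gls_fit(dm.y, dm.X, V, model="OU", alpha=0.0, n_extra_params=1)
    out = likelihood_ratio_test(f1, f2)
    assert out["chi2"] == pytest.approx(0.0, abs=1e-8)
    assert out["p"] == pytest.approx(1.0, abs=1e-6)
    assert out["df"] == 1


def test_lrt_rejects_mismatched_data(dataset_369):
    dm = prepare_design(dataset_369.traits)
    V = phylo.bm_covariance(dataset_369.tree).to_numpy()
    f1 = gls_fit(dm.y, dm.X, V)
    f2 = gls_fit(dm.y + 1.0, dm.X, V, n_extra_params=1)
    with pytest.raises(ValueError):
        likelihood_ratio_test(f1, f2)


# -------------------------------------------------------------------- R2_pred

def _r2_pred_bruteforce(fit_full, fit_reduced):
    """Direct implementation: per-species conditional expectation with
    explicit submatrix inversion."""

    def loo(fit):
        y = fit.y_
        X = fit.X_.to_numpy(dtype=float)
        beta = fit.beta.to_numpy()
        S = fit.sigma2 * fit.R_
        e = y - X @ beta
        n = len(y)
        out = np.empty(n)
        for i in range(n):
            mask = np.arange(n) != i
            s_io = S[i, mask]
            S_oo = S[np.ix_(mask, mask)]
            out[i] = X[i] @ beta + s_io @ np.linalg.solve(S_oo, e[mask])
        return y - out

    rf = loo(fit_full)
    rr = loo(fit_reduced)
    return 1.0 - np.var(rf) / np.var(rr)


def test_r2_pred_matches_bruteforce_oracle():
    tree = random_tree(8, 3)
    labels = phylo.tip_labels(tree)
    rng = np.random.default_rng(4)
    X = pd.DataFrame({"intercept": 1.0, "x": rng.normal(size=8)}, index=labels)
    y = 2.0 + X["x"].to_numpy() + rng.normal(size=8)
    R = phylo.ou_correlation(tree, 1.5).to_numpy()
    full = gls_fit(y, X, R)
    reduced = gls_fit(y, X[["intercept"]], R)
    assert r2_pred(full, reduced) == pytest.approx(
        _r2_pred_bruteforce(full, reduced), rel=1e-9
    )


def test_r2_pred_trivial_cases():
    rng = np.random.default_rng(5)
    X = pd.DataFrame({"intercept": np.ones(20), "x": rng.normal(size=20)})
    y = 1.0 + 2.0 * X["x"].to_numpy()
    fit = gls_fit(y, X, np.eye(20), model="identity")
    assert r2_pred(fit, fit) == pytest.approx(0.0, abs=1e-12)
    assert r2_pred(fit) == pytest.approx(1.0, abs=1e-10)  # noiseless vs null


def test_r2_pred_undefined_for_constant_reduced():
    X = pd.DataFrame({"intercept": np.ones(10)})
    y = np.full(10, 3.0)
    fit = gls_fit(y, X, np.eye(10), model="identity")
    with pytest.raises(ZeroDivisionError):
        r2_pred(fit)


# ------------------------------------------------------------ partial R2 table

def test_partial_r2_zero_beta_predictor_near_zero():
    vals = []
    for seed in range(5):
        ds = simulate.simulate_range_dataset(simulate.SimulationConfig(n_tips=150, seed=seed))
        table = partial_r2_table(ds.traits, ds.tree)
        vals.append(table.loc["Diet niche breadth", "raw"])  # true beta is 0
    assert np.median(vals) <= 0.02
    assert table.loc["Full model", "r2"] <= 1.0
    assert (table["r2"] >= 0.0).all()


def test_partial_r2_constrained_mode_summarizes_replicates(dataset_369):
    traits = dataset_369.traits.copy()
    rng = np.random.default_rng(6)
    for k in range(1, 4):
        traits[f"climate_nb_rep{k}"] = traits["climate_nb"] * rng.uniform(0.8, 1.2)
    out = partial_r2_table(traits, dataset_369.tree, cap_mode="constrained")
    assert list(out.columns) == ["mean", "min", "max"]
    assert (out["min"] <= out["mean"]).all() and (out["mean"] <= out["max"]).all()


# ----------------------------------------------------------- replicate average

def test_average_identical_fits_keeps_se(dataset_369):
    dm = prepare_design(dataset_369.traits)
    V = phylo.bm_covariance(dataset_369.tree).to_numpy()
    fit = gls_fit(dm.y, dm.X, V)
    avg = average_replicate_fits([fit, fit, fit])
    np.testing.assert_allclose(avg["estimate"], fit.beta, rtol=1e-12)
    np.testing.assert_allclose(avg["se"], fit.se, rtol=1e-12)


def test_average_two_fits_closed_form(dataset_369):
    dm = prepare_design(dataset_369.traits)
    V = phylo.bm_covariance(dataset_369.tree).to_numpy()
    f1 = gls_fit(dm.y, dm.X, V)
    f2 = gls_fit(dm.y, dm.X, V)
    f1.beta[:] = 0.0
    f2.beta[:] = 2.0
    f1.se[:] = 1.0
    f2.se[:] = 1.0
    avg = average_replicate_fits([f1, f2])
    np.testing.assert_allclose(avg["estimate"], 1.0)
    np.testing.assert_allclose(avg["se"], np.sqrt(2.0))


def test_average_rejects_mismatched_sets(dataset_369):
    dm = prepare_design(dataset_369.traits)
    V = phylo.bm_covariance(dataset_369.tree).to_numpy()
    f1 = gls_fit(dm.y, dm.X, V)
    f2 = gls_fit(dm.y, dm.X.drop(columns=["diet_nb"]), V)
    with pytest.raises(ValueError):
        average_replicate_fits([f1, f2])
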
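"""Stratified sampling and the quasi-Poisson species-energy fit."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from serloss.errors import ConfigError, FitError, SingularDesignError
from serloss.ser import (SampleSpec, adjusted_r2, build_design, fit_quasipoisson,
                         partial_r2, stratified_sample)
from serloss.wilderness import WildernessMask


def poisson_mle_oracle(y, X):
    """Independent maximum-likelihood oracle: direct optimization of the
    Poisson log-likelihood with a generic optimizer (no IRLS)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)

    def negll(beta):
        eta = X @ beta
        return float(np.sum(np.exp(eta)) - y @ eta)

    def grad(beta):
        return X.T @ (np.exp(X @ beta) - y)

    def hess(beta):
        return X.T @ (np.exp(X @ beta)[:, None] * X)

    res = optimize.minimize(negll, np.zeros(X.shape[1]), jac=grad, hess=hess,
                            method="trust-ncg", options={"gtol": 1e-10})
    beta = res.x
    # polish with plain Newton steps on the score equations
    for _ in range(20):
        g = grad(beta)
        if np.linalg.norm(g) < 1e-12:
            break
        beta = beta - np.linalg.solve(hess(beta), g)
    assert np.linalg.norm(grad(beta)) < 1e-10
    return beta


# -- stratified sampling ------------------------------------------------------

def _two_realm_setup(n_large=2000, n_small=300, seed=0):
    """Row-stacked strip world: realm 1 has n_large wilderness cells, realm 2
    has n_small; npp random."""
    ncols = 100
    rows_large = n_large // ncols
    rows_small = n_small // ncols
    nrows = rows_large + rows_small
    realm = np.ones((nrows, ncols), dtype=np.int64)
    realm[rows_large:, :] = 2
    wild = np.ones((nrows, ncols), dtype=bool)
    rng = np.random.default_rng(seed)
    npp = rng.uniform(0, 1500, (nrows, ncols))
    return WildernessMask(wilderness=wild), realm, npp


def test_quota_large_realm_exact():
    mask, realm, npp = _two_realm_setup()
    cells = stratified_sample(mask, realm, npp, SampleSpec(seed=1))
    got = pd.Series([realm[c] for c in cells]).value_counts()
    assert got[1] == 500
    assert got[2] == 100  # round(300/3)


def test_no_duplicates_and_determinism():
    mask, realm, npp = _two_realm_setup()
    a = stratified_sample(mask, realm, npp, SampleSpec(seed=3))
    b = stratified_sample(mask, realm, npp, SampleSpec(seed=3))
    assert a == b
    assert len(set(a)) == len(a)


def test_extremes_always_included():
    mask, realm, npp = _two_realm_setup()
    cells = stratified_sample(mask, realm, npp, SampleSpec(seed=5))
    flat = npp.ravel()
    lo = divmod(int(flat.argmin()), npp.shape[1])
    hi = divmod(int(flat.argmax()), npp.shape[1])
    assert lo in cells and hi in cells
    # quotas unchanged by the swap
    got = pd.Series([realm[c] for c in cells]).value_counts()
    assert got[1] == 500 and got[2] == 100


def test_small_realm_quota_has_floor_of_one():
    mask, realm, npp = _two_realm_setup(n_small=100)
    # realm 2 now has 100 wilderness cells -> round(100/3) = 33
    cells = stratified_sample(mask, realm, npp, SampleSpec(seed=2))
    got = pd.Series([realm[c] for c in cells]).value_counts()
    assert got[2] == 33


def test_invalid_spec_rejected():
    with pytest.raises(ConfigError):
        SampleSpec(n_per_realm=0).validate()
    with pytest.raises(ConfigError):
        SampleSpec(small_realm_fraction=0.0).validate()


# -- design -------------------------------------------------------------------

def test_design_dimensions(default_world):
    cells = stratified_sample(default_world.wmask, default_world.realm,
                              default_world.npp_pot, SampleSpec(n_per_realm=30, seed=1),
                              default_world.kept_realms)
    sr_pot = np.full(default_world.shape, 5.0)
    y, X, meta = build_design(cells, default_world, sr_pot,
                              default_world.kept_realms)
    n_realms = len(default_world.kept_realms)
    assert X.shape == (len(cells), 1 + (n_realms - 1) + 1 + 1)
    assert list(X.columns[:1]) == ["intercept"]
    assert set(meta["realm_levels"]) == set(default_world.kept_realms)


def test_design_matches_handbuilt_oracle(default_world):
    cells = [(r, c) for r, c in zip(*np.where(default_world.wilderness))][:40]
    sr_pot = np.full(default_world.shape, 3.0)
    y, X, meta = build_design(cells, default_world, sr_pot)
    for i, (r, c) in enumerate(cells):
        assert X.iloc[i]["intercept"] == 1.0
        assert X.iloc[i]["npp"] == default_world.npp_pot[r, c]
        assert X.iloc[i]["island"] == float(default_world.island[r, c])
        realm = default_world.realm[r, c]
        for lvl in meta["realm_levels"][1:]:
            assert X.iloc[i][f"realm_{lvl}"] == float(realm == lvl)


# -- GLM fitting --------------------------------------------------------------

def test_intercept_only_closed_form():
    X = pd.DataFrame({"intercept": np.ones(3)})
    fit = fit_quasipoisson(np.array([1, 2, 3]), X, compute_partial=False)
    assert abs(fit.coefficients["intercept"] - np.log(2.0)) < 1e-10


def test_perfect_fit_has_zero_dispersion():
    X = pd.DataFrame({"intercept": np.ones(3)})
    fit = fit_quasipoisson(np.array([2, 2, 2]), X, compute_partial=False)
    assert fit.dispersion_phi == 0.0
    assert fit.deviance_resid < 1e-12


def test_matches_bruteforce_likelihood_oracle(rng):
    n = 50
    X = pd.DataFrame({"intercept": np.ones(n),
                      "x1": rng.normal(size=n),
                      "x2": rng.uniform(size=n)})
    beta_true = np.array([1.0, 0.4, -0.8])
    y = rng.poisson(np.exp(X.to_numpy() @ beta_true))
    fit = fit_quasipoisson(y, X, compute_partial=False)
    oracle = poisson_mle_oracle(y, X.to_numpy())
    got = np.array([fit.coefficients[c] for c in X.columns])
    assert np.all(np.abs(got - oracle) / np.maximum(np.abs(oracle), 1e-8) < 1e-6)


def test_quasipoisson_scales_only_standard_errors(rng):
    n = 200
    X = pd.DataFrame({"intercept": np.ones(n), "x": rng.normal(size=n)})
    mu = np.exp(1.0 + 0.5 * X["x"].to_numpy())
    y = rng.negative_binomial(mu / 1.5, 1 / 2.5)  # overdispersed counts
    fit = fit_quasipoisson(y, X, compute_partial=False)
    import statsmodels.api as sm
    plain = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    assert np.allclose(list(fit.coefficients.values()), plain.params, atol=1e-8)
    ratio = np.array(list(fit.standard_errors.values())) / plain.bse
    assert np.allclose(ratio, np.sqrt(fit.dispersion_phi))
    assert fit.dispersion_phi > 1.0
    for k in fit.coefficients:
        assert np.isclose(fit.t_values[k],
                          fit.coefficients[k] / fit.standard_errors[k])


def test_singular_design_rejected():
    X = pd.DataFrame({"intercept": np.ones(10), "dup": np.ones(10)})
    with pytest.raises(SingularDesignError):
        fit_quasipoisson(np.arange(10), X)


def test_underdetermined_fit_rejected():
    X = pd.DataFrame({"intercept": np.ones(2), "x": [0.0, 1.0]})
    with pytest.raises(FitError):
        fit_quasipoisson(np.array([1, 2]), X)


def test_negative_counts_rejected():
    X = pd.DataFrame({"intercept": np.ones(3)})
    with pytest.raises(ConfigError):
        fit_quasipoisson(np.array([1, -1, 2]), X)


# -- R-squared summaries ------------------------------------------------------

def test_adjusted_r2_arithmetic_oracle(rng):
    n = 80
    X = pd.DataFrame({"intercept": np.ones(n), "x": rng.normal(size=n)})
    y = rng.poisson(np.exp(1.0 + 0.6 * X["x"].to_numpy()))
    fit = fit_quasipoisson(y, X, compute_partial=False)
    expect = 1 - (fit.deviance_resid / fit.df_resid) / (fit.deviance_null / fit.df_null)
    assert np.isclose(adjusted_r2(fit), expect)
    assert adjusted_r2(fit) <= 1.0


def test_intercept_only_adjusted_r2_is_zero(rng):
    y = rng.poisson(5.0, size=30)
    X = pd.DataFrame({"intercept": np.ones(30)})
    fit = fit_quasipoisson(y, X, compute_partial=False)
    assert abs(adjusted_r2(fit)) < 1e-12


def test_partial_r2_matches_two_fit_oracle(rng):
    n = 120
    X = pd.DataFrame({"intercept": np.ones(n), "npp": rng.normal(size=n),
                      "island": (rng.random(n) < 0.3).astype(float)})
    y = rng.poisson(np.exp(1.0 + 0.5 * X["npp"].to_numpy())).astype(np.int64)
    fit = fit_quasipoisson(y, X, compute_partial=False)
    import statsmodels.api as sm
    red = sm.GLM(y, X.drop(columns=["npp"]), family=sm.families.Poisson()).fit()
    expect = (red.deviance - fit.deviance_resid) / red.deviance
    assert np.isclose(partial_r2(fit, "npp"), expect)


def test_partial_r2_of_null_effect_vanishes(rng):
    n = 5000
    X = pd.DataFrame({"intercept": np.ones(n), "npp": rng.normal(size=n),
                      "island": (rng.random(n) < 0.5).astype(float)})
    y = rng.poisson(np.exp(1.0 + 0.5 * X["npp"].to_numpy())).astype(np.int64)
    fit = fit_quasipoisson(y, X, compute_partial=False)
    assert partial_r2(fit, "island") == pytest.approx(0.0, abs=2e-3)
    assert 0.0 <= partial_r2(fit, "npp") <= 1.0


def test_fit_on_simulated_world_recovers_truth_within_ci(default_world, default_truth):
    from serloss.aoh import combine_sr_pot_wilderness
    from serloss.world import simulate_richness

    counts = simulate_richness(default_world, default_truth, "pot", seed=5)
    sr_pot = combine_sr_pot_wilderness(counts, np.zeros_like(counts),
                                       default_world.wilderness)
    cells = stratified_sample(default_world.wmask, default_world.realm,
                              default_world.npp_pot, SampleSpec(seed=6),
                              default_world.kept_realms)
    y, X, meta = build_design(cells, default_world, sr_pot, default_world.kept_realms)
    fit = fit_quasipoisson(y, X, meta)
    # generous 4-SE sanity band for a single replicate
    assert abs(fit.beta_npp - default_truth.beta_npp) < 4 * fit.se_npp
    assert fit.partial_r2["npp"] > 0.3
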
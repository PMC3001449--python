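"""Family regression: OLS oracles, model nesting, adequacy, partials, VIF."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bisens import (
    FamilyScenario,
    InsufficientDataError,
    SequenceStructureRegressor,
    SingularFitError,
    UndefinedStatisticError,
    adequacy,
    adjusted_r2,
    fit_bilinear,
    fit_families,
    fit_model,
    partial_correlations,
    simulate_family,
    vif,
)
from bisens.famreg import ModelFit


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def normal_equations_bilinear(pni, sng, rmsd):
    """Independent bilinear OLS: explicit normal equations + t p-values."""
    X = np.column_stack([np.ones(len(pni)), pni, sng])
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ rmsd)
    resid = rmsd - X @ beta
    df = len(pni) - 3
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(np.linalg.inv(XtX)) * sigma2)
    tvals = beta / se
    pvals = 2 * sps.t.sf(np.abs(tvals), df)
    tss = ((rmsd - rmsd.mean()) ** 2).sum()
    r2 = 1 - (resid @ resid) / tss
    return beta, se, pvals, r2


def residual_partial_corr(x, y, z):
    """Partial correlation via explicit residual regressions."""
    def resid(v, w):
        slope, intercept = np.polyfit(w, v, 1)
        return v - (intercept + slope * w)

    return float(np.corrcoef(resid(x, z), resid(y, z))[0, 1])


# ---------------------------------------------------------------------------
# adjusted R2 and adequacy
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "r2, n, k, expected",
    [
        (1.0, 10, 2, 1.0),
        (1.0, 500, 8, 1.0),
        (0.9, 10, 2, 1 - 0.1 * 9 / 7),
        (0.0, 10, 2, -2.0 / 7),
        (0.5, 100, 1, 1 - 0.5 * 99 / 98),
    ],
)
def test_adjusted_r2_arithmetic(r2, n, k, expected):
    assert adjusted_r2(r2, n, k) == pytest.approx(expected, abs=1e-12)


def test_adjusted_r2_undefined_for_tiny_n():
    with pytest.raises(UndefinedStatisticError):
        adjusted_r2(0.5, 3, 2)


def _mf(model, r2_adj, n=100):
    return ModelFit(model=model, R2=r2_adj, R2_adj=r2_adj, k=2, n=n,
                    fitted_values=np.zeros(n))


def test_adequacy_identical_fits_is_one():
    assert adequacy(_mf("bilinear", 0.8), _mf("paraboloid", 0.8)).r2 == pytest.approx(1.0)


def test_adequacy_ratio_arithmetic():
    res = adequacy(_mf("linear_pni", 0.80), _mf("bilinear", 0.9041))
    assert res.r2 == pytest.approx(0.885, abs=5e-4)
    assert res.pair == "linear_vs_bilinear"


def test_adequacy_may_exceed_one():
    # an overfit larger model can lose on adjusted terms
    res = adequacy(_mf("bilinear", 0.90), _mf("cubic_spline", 0.85))
    assert res.r2 > 1


def test_adequacy_undefined_for_nonpositive_denominator():
    with pytest.raises(UndefinedStatisticError):
        adequacy(_mf("bilinear", 0.1), _mf("paraboloid", -0.05))


def test_adequacy_requires_same_observations():
    with pytest.raises(Exception):
        adequacy(_mf("bilinear", 0.8, n=50), _mf("paraboloid", 0.8, n=60))


# ---------------------------------------------------------------------------
# bilinear fit
# ---------------------------------------------------------------------------

class TestFitBilinear:
    def test_matches_normal_equations_oracle_on_fixture(self, small_stats):
        fit = fit_bilinear(small_stats, family_id="fx", min_obs=5)
        beta, se, pvals, r2 = normal_equations_bilinear(
            small_stats["pni"].to_numpy(),
            small_stats["sng"].to_numpy(),
            small_stats["rmsd"].to_numpy(),
        )
        assert fit.b0 == pytest.approx(beta[0], rel=1e-10)
        assert fit.b1 == pytest.approx(beta[1], rel=1e-10)
        assert fit.b2 == pytest.approx(beta[2], rel=1e-10)
        assert fit.se_b1 == pytest.approx(se[1], rel=1e-10)
        assert fit.p_b2 == pytest.approx(pvals[2], rel=1e-8)
        assert fit.R == pytest.approx(math.sqrt(r2), rel=1e-10)

    def test_matches_statsmodels(self, small_stats):
        sm = pytest.importorskip("statsmodels.api")
        X = sm.add_constant(small_stats[["pni", "sng"]].to_numpy())
        res = sm.OLS(small_stats["rmsd"].to_numpy(), X).fit()
        fit = fit_bilinear(small_stats, min_obs=5)
        np.testing.assert_allclose(
            [fit.b0, fit.b1, fit.b2], res.params, rtol=1e-10
        )
        np.testing.assert_allclose([fit.se_b1, fit.se_b2], res.bse[1:], rtol=1e-10)
        np.testing.assert_allclose([fit.p_b1, fit.p_b2], res.pvalues[1:], rtol=1e-8)
        assert fit.R == pytest.approx(math.sqrt(res.rsquared), rel=1e-10)
        assert fit.p_model == pytest.approx(res.f_pvalue, rel=1e-8)

    def test_noiseless_exact_recovery(self):
        sc = FamilyScenario("f0", n_pairs=80, b0=0.4, b1_true=0.03, b2_true=0.2,
                            noise_sd=0.0, seed=5)
        fit = fit_bilinear(simulate_family(sc).stats)
        assert fit.R == pytest.approx(1.0, abs=1e-10)
        assert fit.b0 == pytest.approx(0.4, abs=1e-9)
        assert fit.b1 == pytest.approx(0.03, abs=1e-11)
        assert fit.b2 == pytest.approx(0.2, abs=1e-10)

    def test_parameter_recovery_within_three_se(self):
        sc = FamilyScenario("f1", n_pairs=500, b0=0.5, b1_true=0.02, b2_true=0.15,
                            noise_sd=0.1, seed=17)
        fit = fit_bilinear(simulate_family(sc).stats)
        assert abs(fit.b1 - 0.02) < 3 * fit.se_b1
        assert abs(fit.b2 - 0.15) < 3 * fit.se_b2

    def test_min_obs_enforced(self, small_stats):
        with pytest.raises(InsufficientDataError):
            fit_bilinear(small_stats, min_obs=10)

    def test_perfect_collinearity_raises_with_correlation(self):
        pni = np.linspace(10, 80, 20)
        df = pd.DataFrame({"pni": pni, "sng": 0.1 * pni, "rmsd": 1 + 0.01 * pni})
        with pytest.raises(SingularFitError) as exc:
            fit_bilinear(df, min_obs=5)
        assert exc.value.predictor_correlation == pytest.approx(1.0)

    def test_scale_equivariance(self, small_stats):
        fit = fit_bilinear(small_stats, min_obs=5)
        scaled = small_stats.assign(rmsd=small_stats["rmsd"] * 2.5)
        fit2 = fit_bilinear(scaled, min_obs=5)
        assert fit2.b1 == pytest.approx(2.5 * fit.b1, rel=1e-10)
        assert fit2.b2 == pytest.approx(2.5 * fit.b2, rel=1e-10)
        assert fit2.se_b1 == pytest.approx(2.5 * fit.se_b1, rel=1e-10)
        assert fit2.R == pytest.approx(fit.R, rel=1e-12)
        assert fit2.vif == pytest.approx(fit.vif, rel=1e-12)
        assert fit2.partial_r_pni == pytest.approx(fit.partial_r_pni, rel=1e-10)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

class TestModelNesting:
    @pytest.mark.parametrize("seed", range(5))
    def test_r2_nesting_chain(self, seed):
        sc = FamilyScenario(f"n{seed}", n_pairs=60, noise_sd=0.3, seed=seed)
        st = simulate_family(sc).stats
        r2 = {m: fit_model(st, m).R2 for m in
              ("linear_pni", "bilinear", "paraboloid", "cubic_spline")}
        assert r2["linear_pni"] <= r2["bilinear"] + 1e-12
        assert r2["bilinear"] <= r2["paraboloid"] + 1e-12
        assert r2["bilinear"] <= r2["cubic_spline"] + 1e-12

    def test_true_bilinear_law_gives_adequacy_near_one(self):
        sc = FamilyScenario("big", n_pairs=4000, noise_sd=0.2, seed=3)
        st = simulate_family(sc).stats
        res = adequacy(fit_model(st, "bilinear"), fit_model(st, "paraboloid"))
        assert res.r2 == pytest.approx(1.0, abs=0.01)

    def test_strong_sng_effect_separates_linear_from_bilinear(self):
        sc = FamilyScenario("sng", n_pairs=400, b1_true=0.005, b2_true=0.4,
                            noise_sd=0.05, seed=8)
        st = simulate_family(sc).stats
        assert fit_model(st, "linear_pni").R2 < fit_model(st, "bilinear").R2 - 0.05

    def test_spline_k_counts_basis_columns(self):
        sc = FamilyScenario("k", n_pairs=60, seed=1)
        mf = fit_model(simulate_family(sc).stats, "cubic_spline")
        assert mf.k == 8
        assert mf.R2_adj == pytest.approx(adjusted_r2(mf.R2, mf.n, mf.k))


# ---------------------------------------------------------------------------
# partial correlations and VIF
# ---------------------------------------------------------------------------

class TestPartials:
    def test_pure_sng_signal(self):
        rng = np.random.default_rng(2)
        sng = rng.uniform(0, 10, 400)
        df = pd.DataFrame({"pni": rng.uniform(0, 100, 400), "sng": sng,
                           "rmsd": 2.0 * sng})
        r_pni, _, r_sng, p_sng = partial_correlations(df)
        assert r_sng == pytest.approx(1.0, abs=1e-9)
        assert abs(r_pni) < 0.15
        assert p_sng < 1e-10

    def test_independent_triples_near_zero(self):
        rng = np.random.default_rng(42)
        df = pd.DataFrame({"pni": rng.normal(size=2000),
                           "sng": rng.normal(size=2000),
                           "rmsd": rng.normal(size=2000)})
        r_pni, _, r_sng, _ = partial_correlations(df)
        assert abs(r_pni) < 0.07
        assert abs(r_sng) < 0.07

    def test_matches_residual_regression_oracle(self, small_stats):
        r_pni, _, r_sng, _ = partial_correlations(small_stats)
        pni = small_stats["pni"].to_numpy()
        sng = small_stats["sng"].to_numpy()
        rmsd = small_stats["rmsd"].to_numpy()
        assert r_pni == pytest.approx(residual_partial_corr(pni, rmsd, sng), abs=1e-10)
        assert r_sng == pytest.approx(residual_partial_corr(sng, rmsd, pni), abs=1e-10)

    def test_matches_pingouin(self, small_stats):
        pingouin = pytest.importorskip("pingouin")
        out = pingouin.partial_corr(small_stats, x="pni", y="rmsd", covar="sng")
        r_pni, p_pni, _, _ = partial_correlations(small_stats)
        assert r_pni == pytest.approx(float(out["r"].iloc[0]), abs=1e-9)
        assert p_pni == pytest.approx(float(out["p_val"].iloc[0]), rel=1e-6)


class TestVIF:
    def test_independent_predictors_near_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"pni": rng.normal(size=5000), "sng": rng.normal(size=5000)})
        assert vif(df) == pytest.approx(1.0, abs=0.01)

    def test_exact_collinearity_gives_infinity(self):
        pni = np.linspace(0, 99, 30)
        assert vif(pd.DataFrame({"pni": pni, "sng": 0.1 * pni})) == math.inf

    def test_correlation_0866_gives_four(self):
        # construct exact correlation 0.866 by orthogonal mixing
        rng = np.random.default_rng(1)
        z1 = rng.normal(size=500)
        z2 = rng.normal(size=500)
        z1 = (z1 - z1.mean()) / z1.std()
        z2 -= z2.mean()
        z2 -= z1 * (z1 @ z2) / (z1 @ z1)  # make exactly orthogonal
        z2 /= z2.std()
        r = 0.866
        sng = r * z1 + math.sqrt(1 - r**2) * z2
        v = vif(pd.DataFrame({"pni": z1, "sng": sng}))
        assert v == pytest.approx(1 / (1 - r**2), rel=1e-9)
        assert v == pytest.approx(4.0, abs=0.02)


# ---------------------------------------------------------------------------
# cohort-level fitting table
# ---------------------------------------------------------------------------

def test_fit_families_handles_degenerate_sng():
    rng = np.random.default_rng(6)
    good = simulate_family(FamilyScenario("aaa", n_pairs=40, seed=1)).stats
    gapless = pd.DataFrame({
        "family_id": "zzz",
        "pni": rng.uniform(10, 90, 30),
        "sng": 0.0,
        "rmsd": rng.uniform(0.5, 2.5, 30),
        "n_algn": 100,
        "n_gap": 0,
    })
    tiny = good.head(4).assign(family_id="tiny")
    fits = fit_families(pd.concat([good, gapless, tiny], ignore_index=True))
    fits = fits.set_index("family_id")
    assert fits.loc["aaa", "note"] == ""
    assert fits.loc["zzz", "note"] == "degenerate_sng_linear_fallback"
    assert fits.loc["tiny", "note"] == "too_few_obs"
    assert np.isfinite(fits.loc["zzz", "b1"])


def test_estimator_sklearn_protocol():
    sklearn = pytest.importorskip("sklearn")
    from sklearn.base import clone

    reg = SequenceStructureRegressor(model="paraboloid", spline_df=5)
    params = reg.get_params()
    assert params["model"] == "paraboloid" and params["spline_df"] == 5
    reg2 = clone(reg).set_params(model="bilinear")
    sc = FamilyScenario("e", n_pairs=50, seed=2)
    st = simulate_family(sc).stats
    X = st[["pni", "sng"]].to_numpy()
    y = st["rmsd"].to_numpy()
    reg2.fit(X, y)
    assert reg2.predict(X).shape == y.shape
    # R^2 score of the regressor mixin agrees with the stored fit
    assert reg2.score(X, y) == pytest.approx(reg2.r2_, abs=1e-10)
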
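import numpy as np
import pandas as pd
import pytest

from synbold import encoding_models as em


def _sim_long(seed, n_participants=8, n=200, slope_sd=0.3, beta1=0.9,
              beta2=-0.35, rho=0.0):
    """Small direct simulation for fitting tests (no HRF pipeline)."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        b1 = rng.normal(0, slope_sd)
        eps = rng.normal(0, 1.0, size=n)
        if rho:
            for t in range(1, n):
                eps[t] = rho * eps[t - 1] + np.sqrt(1 - rho**2) * eps[t]
        y = 1.0 + (beta1 + b1) * x1 + beta2 * x2 + eps
        rows.append(pd.DataFrame({
            "participant": f"p{p}", "x1": x1, "x2": x2, "bold": y,
        }))
    return pd.concat(rows, ignore_index=True)


class TestCoding:
    def test_modality_deviation_half_codes(self):
        s = pd.Series(["production", "comprehension", "production"])
        coded = em.code_factors(modality=s)
        assert list(coded["modality_dev"]) == [0.5, -0.5, 0.5]

    def test_roi_helmert_orthogonal_zero_sum(self):
        s = pd.Series(["BA44", "BA45", "LpMTG"])
        coded = em.code_factors(roi=s)
        h1, h2 = coded["roi_h1"].to_numpy(), coded["roi_h2"].to_numpy()
        assert h1 @ h2 == pytest.approx(0.0)
        assert h1.sum() == pytest.approx(0.0)
        assert h2.sum() == pytest.approx(0.0)

    def test_unknown_level_rejected(self):
        with pytest.raises(em.CodingError):
            em.code_factors(modality=pd.Series(["speech"]))

    def test_interaction_columns_are_products(self):
        df = pd.DataFrame({
            "x": [1.0, 2.0, 3.0],
            "modality_dev": [0.5, -0.5, 0.5],
        })
        X, terms = em.build_fixed_design(df, ("x", "x:modality"))
        np.testing.assert_allclose(
            X["x:modality_dev"], df["x"] * df["modality_dev"]
        )
        assert terms["x:modality"] == ["x:modality_dev"]

    def test_rank_deficiency_names_aliased_column(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [2.0, 4.0, 6.0]})
        with pytest.raises(ValueError, match="aliased"):
            em.build_fixed_design(df, ("x", "y"))


class TestFitMixedModel:
    def test_recovers_generative_betas(self):
        long = _sim_long(seed=1)
        spec = em.ModelSpec(response="bold", fixed=("x1", "x2"),
                            random=("x1",), focal=("x1",))
        fit = em.fit_mixed_model(long, spec)
        assert fit.converged
        assert abs(fit.params["x1"] - 0.9) <= 3 * fit.bse["x1"]
        assert abs(fit.params["x2"] + 0.35) <= 3 * fit.bse["x2"]
        assert 0.3**2 / 4 <= fit.vcomp["x1"] <= 0.3**2 * 4

    def test_zero_slope_sd_matches_ols(self):
        long = _sim_long(seed=2, slope_sd=0.0)
        spec = em.ModelSpec(response="bold", fixed=("x1", "x2"),
                            random=("x1",), focal=())
        fit = em.fit_mixed_model(long, spec)
        import statsmodels.api as sm

        X = sm.add_constant(long[["x1", "x2"]])
        ols = sm.OLS(long["bold"], X).fit()
        assert fit.params["x1"] == pytest.approx(ols.params["x1"], abs=1e-4)
        assert fit.params["x2"] == pytest.approx(ols.params["x2"], abs=1e-4)

    def test_row_permutation_invariance(self):
        long = _sim_long(seed=3)
        spec = em.ModelSpec(response="bold", fixed=("x1", "x2"),
                            random=("x1",), focal=("x1",))
        fit_a = em.fit_mixed_model(long, spec)
        shuffled = long.sample(frac=1.0, random_state=0).reset_index(drop=True)
        fit_b = em.fit_mixed_model(shuffled, spec)
        assert fit_a.params["x1"] == pytest.approx(fit_b.params["x1"],
                                                   abs=1e-8)

    def test_aic_identity(self):
        long = _sim_long(seed=4)
        spec = em.ModelSpec(response="bold", fixed=("x1", "x2"),
                            random=("x1",), focal=("x1",))
        fit = em.fit_mixed_model(long, spec)
        assert fit.aic == pytest.approx(2 * fit.k_params - 2 * fit.llf)

    def test_missing_response_rejected(self):
        long = _sim_long(seed=5)
        long.loc[0, "bold"] = np.nan
        spec = em.ModelSpec(response="bold", fixed=("x1",))
        with pytest.raises(ValueError, match="missing"):
            em.fit_mixed_model(long, spec)


class TestPrewhitening:
    def test_reml_ar1_recovers_rho(self):
        rng = np.random.default_rng(0)
        n = 400
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        rhos = []
        for _ in range(10):
            eps = np.zeros(n)
            eps[0] = rng.normal()
            for t in range(1, n):
                eps[t] = 0.4 * eps[t - 1] + np.sqrt(1 - 0.16) * rng.normal()
            y = X @ np.array([1.0, 0.5]) + eps
            rhos.append(em.reml_ar1(X, y))
        assert np.mean(rhos) == pytest.approx(0.4, abs=0.06)

    def test_whitening_removes_residual_autocorrelation(self):
        long = _sim_long(seed=6, rho=0.5, slope_sd=0.0, n_participants=4,
                         n=300)
        long["roi"] = "BA44"
        white = em.prewhiten_long(long, ("x1", "x2"), "bold")
        for _, g in white.groupby("participant"):
            X = np.column_stack([np.ones(len(g)), g[["x1", "x2"]].to_numpy()])
            beta, *_ = np.linalg.lstsq(X, g["bold"].to_numpy(), rcond=None)
            resid = g["bold"].to_numpy() - X @ beta
            assert abs(em.estimate_ar1(resid)) < 0.12


class TestWaldTests:
    def test_single_coefficient_chi2_equals_t_squared(self):
        long = _sim_long(seed=7)
        spec = em.ModelSpec(response="bold", fixed=("x1", "x2"),
                            random=("x1",), focal=("x1",))
        fit = em.fit_mixed_model(long, spec)
        table = em.wald_tests(fit).set_index("term")
        for term in ("x1", "x2"):
            assert table.loc[term, "chi2"] == pytest.approx(
                float(fit.tvalues[term]) ** 2, rel=1e-6
            )
            assert table.loc[term, "df"] == 1

    def test_interaction_bundle_df(self):
        long = _sim_long(seed=8)
        long["roi"] = np.tile(["BA44", "BA45", "LpMTG"],
                              len(long) // 3 + 1)[: len(long)]
        spec = em.ModelSpec(response="bold",
                            fixed=("x1", "roi", "x1:roi"), random=())
        fit = em.fit_mixed_model(long, spec)
        table = em.wald_tests(fit).set_index("term")
        assert table.loc["x1:roi", "df"] == 2


@pytest.fixture(scope="module")
def modality_fit():
    # production slope 0.9, comprehension slope -0.35 for x1
    rng = np.random.default_rng(9)
    rows = []
    for p in range(12):
        modality = "production" if p < 6 else "comprehension"
        slope = 0.9 if p < 6 else -0.35
        x1 = rng.normal(size=250)
        y = slope * x1 + rng.normal(0, 1.0, 250)
        rows.append(pd.DataFrame({
            "participant": f"p{p}", "modality": modality, "x1": x1,
            "bold": y,
        }))
    long = pd.concat(rows, ignore_index=True)
    spec = em.ModelSpec(
        response="bold", fixed=("x1", "modality", "x1:modality"),
        random=("x1",), focal=("x1",),
    )
    return em.fit_mixed_model(long, spec)

class TestContrasts:
    def test_modality_difference_equals_interaction_coefficient(
        self, modality_fit
    ):
        table = em.pairwise_contrasts(modality_fit, "x1", by="modality")
        diff = table[table.kind == "difference"].iloc[0]
        assert diff.estimate == pytest.approx(
            float(modality_fit.params["x1:modality_dev"]), rel=1e-10
        )

    def test_recovers_cell_slopes_and_difference(self, modality_fit):
        table = em.pairwise_contrasts(modality_fit, "x1", by="modality")
        cells = table[table.kind == "cell"].set_index("contrast")
        prod = cells.loc["production"]
        comp = cells.loc["comprehension"]
        assert abs(prod.estimate - 0.9) <= 3 * prod.se
        assert abs(comp.estimate + 0.35) <= 3 * comp.se
        diff = table[table.kind == "difference"].iloc[0]
        assert abs(diff.estimate - 1.25) <= 3 * diff.se

    def test_cells_average_to_main_effect(self, modality_fit):
        table = em.pairwise_contrasts(modality_fit, "x1", by="modality")
        cells = table[table.kind == "cell"]
        assert cells.estimate.mean() == pytest.approx(
            float(modality_fit.params["x1"]), rel=1e-10
        )


class TestModelComparison:
    def _fits(self):
        long = _sim_long(seed=10)
        small = em.ModelSpec(response="bold", fixed=("x1",), random=())
        big = em.ModelSpec(response="bold", fixed=("x1", "x2"), random=())
        return (
            em.fit_mixed_model(long, small, name="small"),
            em.fit_mixed_model(long, big, name="big"),
            long,
        )

    def test_duplicated_fit_zero_delta(self):
        fit_small, _, _ = self._fits()
        table = em.compare_models([fit_small, fit_small])
        assert table["delta_aic"].max() == 0.0

    def test_lrt_of_nested_models(self):
        fit_small, fit_big, _ = self._fits()
        lrt = em.likelihood_ratio_test(fit_small, fit_big)
        assert lrt["chi2"] > 0
        assert lrt["df"] == 1
        assert lrt["p"] < 0.05  # x2 truly contributes

    def test_extra_regressor_never_decreases_loglik(self):
        long = _sim_long(seed=11)
        rng = np.random.default_rng(0)
        long["noise_reg"] = rng.normal(size=len(long))
        base = em.fit_mixed_model(
            long, em.ModelSpec(response="bold", fixed=("x1", "x2"),
                               random=()), name="base",
        )
        bigger = em.fit_mixed_model(
            long, em.ModelSpec(response="bold",
                               fixed=("x1", "x2", "noise_reg"), random=()),
            name="plus_noise",
        )
        assert bigger.llf >= base.llf - 1e-6

    def test_differing_nobs_refused(self):
        fit_small, _, long = self._fits()
        other = em.fit_mixed_model(
            long.iloc[:-10],
            em.ModelSpec(response="bold", fixed=("x1",), random=()),
        )
        with pytest.raises(ValueError, match="n_obs"):
            em.compare_models([fit_small, other])

    def test_reml_fits_with_different_fixed_structures_refused(self):
        long = _sim_long(seed=12)
        a = em.fit_mixed_model(
            long, em.ModelSpec(response="bold", fixed=("x1",), random=("x1",),
                               focal=("x1",), estimation="REML"),
        )
        b = em.fit_mixed_model(
            long, em.ModelSpec(response="bold", fixed=("x1", "x2"),
                               random=("x1",), focal=("x1",),
                               estimation="REML"),
        )
        with pytest.raises(ValueError, match="REML"):
            em.compare_models([a, b])
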
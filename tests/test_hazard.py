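"""Hazard-model tests: design matrices, cloglog fitting, fit statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import fertisim as fs
from fertisim.exceptions import DataError, ModelSpecError, RankDeficiencyError

PRINTED_K = {
    "M0": 4, "M1": 11, "M2": 19, "M3": 5, "M4": 11, "M5": 26, "M6": 24,
    "M7": 54, "M8": 30, "M9": 74, "M10": 35, "M11": 52, "M12": 184,
}


class TestBuildDesign:
    @pytest.mark.parametrize("model_id", fs.MODEL_IDS)
    def test_column_count_equals_parameter_count(self, person_years, model_id):
        X, y = fs.build_design(person_years.head(2000), model_id)
        assert X.shape[1] == fs.model_k(model_id) == PRINTED_K[model_id]
        assert len(y) == 2000

    def test_unknown_spec_rejected(self, person_years):
        with pytest.raises(ModelSpecError):
            fs.build_design(person_years, "M13")

    def test_m10_split_switch_changes_composition_not_size(self):
        default = fs.model_spec("M10")
        alt = fs.model_spec("M10", m10_split="ur1_3_ur10_2")
        assert default.blocks != alt.blocks
        assert fs.model_k("M10") == fs.model_k("M10", m10_split="ur1_3_ur10_2") == 35

    def test_alternative_m10_split_is_collinear_with_age_cells(self, person_years):
        """Three full UR1 x period cells plus seven UR1 x age cells both
        sum to the UR1 column, so the alternative reading cannot be fit."""
        X, y = fs.build_design(person_years, "M10", m10_split="ur1_3_ur10_2")
        with pytest.raises(RankDeficiencyError) as err:
            fs.fit_cloglog(X, y)
        assert any("UR1" in c for c in err.value.columns)


class TestFitCloglog:
    def test_intercept_only_closed_form(self, rng_rows=4000):
        rng = np.random.default_rng(0)
        y = (rng.random(rng_rows) < 0.07).astype(float)
        X = pd.DataFrame({"const": np.ones(rng_rows)})
        fitted = fs.fit_cloglog(X, y)
        p = y.mean()
        assert fitted.params["const"] == pytest.approx(np.log(-np.log(1 - p)), rel=1e-6)

    def test_matches_brute_force_optimizer_on_small_instance(self, person_years):
        sample = person_years.sample(200, random_state=1)
        if sample["b"].sum() == 0:  # ensure at least a few events
            sample = pd.concat([sample, person_years[person_years.b == 1].head(5)])
        X, y = fs.build_design(sample, "M3")
        fitted = fs.fit_cloglog(X, y)

        arr = X.to_numpy()

        def nll(beta):
            eta = arr @ beta
            q = -np.expm1(-np.exp(eta))
            q = np.clip(q, 1e-12, 1 - 1e-12)
            return -np.sum(y * np.log(q) + (1 - y) * np.log1p(-q))

        res = optimize.minimize(nll, np.zeros(arr.shape[1]), method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 500})
        assert fitted.deviance == pytest.approx(2 * res.fun, rel=1e-6)

    def test_no_events_rejected(self):
        X = pd.DataFrame({"const": np.ones(50)})
        with pytest.raises(DataError):
            fs.fit_cloglog(X, np.zeros(50))
        with pytest.raises(DataError):
            fs.fit_cloglog(X, np.ones(50))

    def test_duplicate_column_named_in_rank_error(self):
        rng = np.random.default_rng(2)
        x = rng.random(100)
        X = pd.DataFrame({"const": np.ones(100), "x": x, "x_copy": x})
        y = (rng.random(100) < 0.3).astype(float)
        with pytest.raises(RankDeficiencyError) as err:
            fs.fit_cloglog(X, y)
        assert "x_copy" in err.value.columns or "x" in err.value.columns

    def test_link_identity_on_fitted_rows(self, person_years):
        fitted = fs.fit_model(person_years.head(20000), "M0")
        X, _ = fs.build_design(person_years.head(20000), "M0")
        eta = X.to_numpy() @ fitted.params.to_numpy()
        q = fs.predict_q(fitted, person_years.head(20000))
        assert np.allclose(-np.log1p(-q), np.exp(eta))


class TestFitStatistics:
    def test_information_criteria_definitions(self):
        aic, bic = fs.information_criteria(1000.0, 5, 100)
        assert aic == 1000.0 + 10.0
        assert bic == pytest.approx(1000.0 + 5 * np.log(100))

    def test_zero_parameters_limiting_case(self):
        aic, bic = fs.information_criteria(1000.0, 0, 100)
        assert aic == bic == 1000.0

    def test_self_comparison_lr(self):
        f = fs.FitStats(deviance=100.0, k=4)
        assert fs.lr_test(f, f) == (0.0, 0, 1.0)

    def test_negative_delta_deviance_warns(self):
        nested = fs.FitStats(deviance=100.0, k=4)
        full = fs.FitStats(deviance=150.0, k=6)
        with pytest.warns(UserWarning, match="negative deviance"):
            fs.lr_test(nested, full)

    def test_lr_p_value_from_chi_square_tail(self):
        from scipy import stats

        nested = fs.FitStats(deviance=110.0, k=4)
        full = fs.FitStats(deviance=100.0, k=6)
        ddev, ddf, p = fs.lr_test(nested, full)
        assert (ddev, ddf) == (10.0, 2)
        assert p == pytest.approx(stats.chi2.sf(10.0, 2))

    def test_hazard_ratio_summary_percent_change(self, person_years):
        fitted = fs.fit_model(person_years.head(20000), "M0")
        table = fs.hazard_ratio_summary(fitted).set_index("term")
        assert np.allclose(
            table["pct_change"], (np.exp(table["estimate"]) - 1) * 100
        )

    def test_null_effect_is_zero_percent(self):
        fitted = fs.FittedHazardModel(
            model_id="M0",
            params=pd.Series({"const": -2.0, "A": 0.0}),
            bse=pd.Series({"const": 0.1, "A": 0.1}),
            deviance=1.0, k=2, n=10, aic=5.0, bic=5.0, converged=True,
        )
        table = fs.hazard_ratio_summary(fitted).set_index("term")
        assert table.loc["A", "pct_change"] == 0.0


class TestNesting:
    def test_deviance_monotone_along_nested_pairs(self, person_years):
        """A fuller specification can never fit worse than one whose
        column span it contains."""
        pairs = [(a, b) for a, b in fs.NESTED_PAIRS
                 if a in {"M0", "M1", "M2", "M3", "M4", "M5"}
                 and b in {"M1", "M2", "M3", "M4", "M5", "M6", "M8"}]
        fits = {}
        for mid in sorted({m for p in pairs for m in p}):
            fits[mid] = fs.fit_model(person_years, mid)
        for nested, full in pairs:
            tol = 1e-6 * fits[nested].deviance
            assert fits[full].deviance <= fits[nested].deviance + tol
            ddev, ddf, p = fs.lr_test(fits[nested], fits[full])
            assert ddf == fits[full].k - fits[nested].k

    def test_model_persistence_round_trip(self, person_years, tmp_path):
        fitted = fs.fit_model(person_years.head(20000), "M0")
        path = tmp_path / "m0.tsv"
        fs.hazard.save_model(fitted, path)
        back = fs.hazard.load_model(path)
        assert back.model_id == fitted.model_id
        assert back.deviance == pytest.approx(fitted.deviance)
        assert back.k == fitted.k and back.n == fitted.n
        np.testing.assert_allclose(back.params.to_numpy(), fitted.params.to_numpy())
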
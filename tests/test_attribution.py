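"""Tree-ensemble fitting and Shapley attribution.

The interventional tree-path implementation is checked against the classical
subset-enumeration oracle, against hand-computable single-stump cases, and
for its axiomatic properties (local accuracy, dummy, symmetry).
"""

import logging

import numpy as np
import pandas as pd
import pytest

from esvpipe import attribution as at
from esvpipe import synthetic
from esvpipe.attribution import (
    FEATURES,
    Tree,
    TreeEnsemble,
    assemble_table,
    brute_force_interactions,
    brute_force_shapley,
    dependence_table,
    fit_model,
    importance_ranking,
    shapley,
)


def stump(feature: int, threshold: float, low: float, high: float) -> Tree:
    """x[feature] < threshold -> low, else high."""
    return Tree(
        feature=np.array([feature, -1, -1], dtype=np.int32),
        threshold=np.array([threshold, 0, 0], dtype=np.float32),
        left=np.array([1, -1, -1], dtype=np.int32),
        right=np.array([2, -1, -1], dtype=np.int32),
        value=np.array([0.0, low, high]),
    )


def manual_ensemble(trees, names, base=0.0) -> TreeEnsemble:
    return TreeEnsemble(trees=trees, base_value=base, feature_names=names,
                        params={}, seed=0)


class TestAssembleTable:
    @staticmethod
    def _inputs(missing_gpp=False):
        zones = [1, 2, 3]
        years = [2000, 2005, 2010, 2018]
        esv = pd.DataFrame(
            [(y, z, "CL", "FP", 1000.0 * z) for z in zones for y in years],
            columns=["year", "zone", "class", "function", "yuan"],
        )
        hai = pd.DataFrame(
            [(z, y, 0.4) for z in zones for y in years],
            columns=["zone", "year", "hai"],
        )
        rows = []
        for z in zones:
            for y in years:
                gpp = np.nan if missing_gpp and (z, y) == (2, 2005) else 800.0
                rows.append((z, y, gpp, 100.0, 1.0, 50.0, 10.0, 16.0, 1300.0, 45.0))
        drivers = pd.DataFrame(
            rows,
            columns=["zone", "year", "GPP", "DEM", "Slope", "POP", "GDP",
                     "Temp", "Pre", "PM"],
        )
        return esv, hai, drivers

    def test_complete_inputs_give_full_table(self):
        table = assemble_table(*self._inputs())
        assert len(table) == 12
        assert list(table.columns) == ["zone", "year", *FEATURES, "ESV"]

    def test_missing_driver_drops_row_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="esvpipe.attribution"):
            table = assemble_table(*self._inputs(missing_gpp=True))
        assert len(table) == 11
        assert "missing driver" in caplog.text

    def test_hai_column_matches_hai_module(self, paper, driver_table):
        """End-to-end synthetic pipeline: the HAI feature column is exactly
        the hai module output for the same landscape."""
        from esvpipe.hai import compute_hai
        from esvpipe.landuse import tabulate_areas

        scenario = synthetic.default_scenario(23, n_zones=30)
        grids, zones = synthetic.generate_landscape(scenario)
        areas = pd.concat(
            [tabulate_areas(g, zones) for g in grids], ignore_index=True
        )
        hai = compute_hai(areas, paper.pi).set_index(["zone", "year"])["hai"]
        table = driver_table.set_index(["zone", "year"])
        assert np.array_equal(
            table["HAI"].to_numpy(), hai[table.index].to_numpy()
        )


class TestFitModel:
    def test_constant_response(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.normal(size=(30, 9)), columns=FEATURES)
        table["ESV"] = 42.0
        model = fit_model(table, {"n_estimators": 20}, seed=0)
        assert np.allclose(model.predict(table), 42.0)

    def test_noiseless_planted_signal_fits_tightly(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.normal(size=(200, 9)), columns=FEATURES)
        table["ESV"] = 3.0 * table["HAI"] - 2.0 * table["GPP"]
        model = fit_model(table, seed=1)
        assert model.train_r2 > 0.99

    def test_refit_same_seed_is_identical(self, driver_table):
        m1 = fit_model(driver_table, {"n_estimators": 50}, seed=9)
        m2 = fit_model(driver_table, {"n_estimators": 50}, seed=9)
        assert np.array_equal(
            m1.predict(driver_table), m2.predict(driver_table)
        )

    def test_non_numeric_feature_rejected(self):
        table = pd.DataFrame({f: [1.0, 2.0] for f in FEATURES})
        table["ESV"] = [1.0, 2.0]
        table["GPP"] = ["a", "b"]
        with pytest.raises(TypeError, match="GPP"):
            fit_model(table)

    def test_extracted_trees_reproduce_xgboost_predictions(self, driver_table):
        import xgboost as xgb

        model = fit_model(driver_table, {"n_estimators": 50}, seed=9)
        reg = xgb.XGBRegressor(
            **model.params, base_score=model.base_value, random_state=9,
            n_jobs=1, tree_method="hist", objective="reg:squarederror",
        )
        X = driver_table[FEATURES].to_numpy(dtype=np.float32)
        reg.fit(X, driver_table["ESV"].to_numpy())
        assert np.allclose(
            model.predict(driver_table), reg.predict(X), rtol=1e-5, atol=1e-5
        )


class TestShapley:
    def test_stump_attribution_hand_computed(self):
        """For a single stump on HAI and any background, the entire gap
        between prediction and expected prediction belongs to HAI."""
        model = manual_ensemble(
            [stump(0, 0.5, low=10.0, high=30.0)], list(FEATURES)
        )
        background = pd.DataFrame(
            [[0.2] + [0.0] * 8, [0.8] + [0.0] * 8], columns=FEATURES
        )
        x = pd.DataFrame([[0.9] + [0.0] * 8], columns=FEATURES)
        attr = shapley(model, x, background)
        expected_gap = 30.0 - (10.0 + 30.0) / 2
        assert attr.phi.iloc[0]["HAI"] == pytest.approx(expected_gap)
        assert np.allclose(attr.phi.iloc[0].drop("HAI"), 0.0)

    def test_constant_model_gives_zero_attribution(self):
        model = manual_ensemble([], list(FEATURES), base=7.0)
        x = pd.DataFrame(np.zeros((3, 9)), columns=FEATURES)
        attr = shapley(model, x, x)
        assert np.allclose(attr.phi, 0.0)
        assert attr.base == pytest.approx(7.0)

    def test_local_accuracy_on_fitted_model(self, fitted_model, driver_table,
                                            attr_matrix):
        pred = fitted_model.predict(driver_table)
        gap = np.abs(attr_matrix.reconstructed() - pred)
        assert gap.max() <= 1e-6 * np.abs(pred).max()

    def test_matches_brute_force_oracle(self, fitted_model, driver_table,
                                        attr_matrix, rng):
        """Interventional tree-path attribution equals full 2^9 subset
        enumeration on random instances."""
        background = driver_table.sample(60, random_state=4)
        attr = shapley(fitted_model, driver_table, background)
        for idx in rng.choice(len(driver_table), size=20, replace=False):
            bf = brute_force_shapley(
                fitted_model, driver_table.iloc[int(idx)], background
            )
            assert np.allclose(
                attr.phi.iloc[int(idx)].to_numpy(), bf, atol=1e-6
            ), idx

    def test_dummy_feature_gets_exact_zero(self):
        """Features never split on receive phi identically zero."""
        model = manual_ensemble(
            [stump(0, 0.0, -1.0, 1.0), stump(1, 0.5, 2.0, 4.0)],
            list(FEATURES),
        )
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(25, 9)), columns=FEATURES)
        attr = shapley(model, X, X)
        assert (attr.phi[FEATURES[2:]].to_numpy() == 0.0).all()

    def test_feature_set_mismatch_rejected(self, fitted_model):
        bad = pd.DataFrame(np.zeros((2, 3)), columns=["a", "b", "c"])
        with pytest.raises(KeyError):
            shapley(fitted_model, bad, bad)


class TestBruteForce:
    def test_single_feature_closed_form(self):
        model = manual_ensemble([stump(0, 0.5, 1.0, 5.0)], ["x"])
        background = np.array([[0.0], [0.2], [0.9]])
        x = np.array([0.8])
        phi = brute_force_shapley(model, x, background)
        expected = model.predict([[0.8]])[0] - model.predict(background).mean()
        assert phi[0] == pytest.approx(expected, abs=1e-12)

    def test_additive_model_separates(self):
        """f = g1(x1) + g2(x2) gives phi_i = g_i(x_i) - E[g_i]."""
        g1 = stump(0, 0.0, -2.0, 2.0)
        g2 = stump(1, 0.5, 1.0, 3.0)
        model = manual_ensemble([g1, g2], ["u", "v"])
        rng = np.random.default_rng(3)
        background = rng.normal(size=(8, 2))
        x = np.array([0.7, 0.1])
        phi = brute_force_shapley(model, x, background)
        pred1 = manual_ensemble([g1], ["u", "v"]).predict
        pred2 = manual_ensemble([g2], ["u", "v"]).predict
        assert phi[0] == pytest.approx(
            pred1([x])[0] - pred1(background).mean(), abs=1e-10
        )
        assert phi[1] == pytest.approx(
            pred2([x])[0] - pred2(background).mean(), abs=1e-10
        )

    def test_local_accuracy_identity(self, fitted_model, driver_table):
        background = driver_table.sample(30, random_state=0)
        x = driver_table.iloc[5]
        phi = brute_force_shapley(fitted_model, x, background)
        fx = fitted_model.predict(driver_table.iloc[[5]])[0]
        base = fitted_model.predict(background).mean()
        assert base + phi.sum() == pytest.approx(fx, abs=1e-10 * max(1, abs(fx)))

    def test_symmetric_features_get_equal_phi(self):
        """Two features used through identical trees, with identical values
        in the instance and background, receive identical attributions."""
        model = manual_ensemble(
            [stump(0, 0.5, 0.0, 2.0), stump(1, 0.5, 0.0, 2.0)], ["a", "b"]
        )
        rng = np.random.default_rng(10)
        z = rng.normal(size=(10, 1))
        background = np.hstack([z, z])
        x = np.array([0.9, 0.9])
        phi = brute_force_shapley(model, x, background)
        assert phi[0] == pytest.approx(phi[1], abs=1e-12)

    def test_feature_limit_enforced(self):
        names = [f"f{i}" for i in range(16)]
        model = manual_ensemble([], names)
        with pytest.raises(ValueError, match="15"):
            brute_force_shapley(model, np.zeros(16), np.zeros((2, 16)))


class TestInteractions:
    def test_rows_sum_to_shapley_values(self, fitted_model, driver_table):
        background = driver_table.sample(20, random_state=1)
        x = driver_table.iloc[3]
        inter = brute_force_interactions(fitted_model, x, background)
        phi = brute_force_shapley(fitted_model, x, background)
        assert np.allclose(inter.sum(axis=1), phi, atol=1e-6)
        assert np.allclose(inter, inter.T)

    def test_additive_model_has_zero_off_diagonals(self):
        model = manual_ensemble(
            [stump(0, 0.0, -2.0, 2.0), stump(1, 0.5, 1.0, 3.0)], ["u", "v"]
        )
        rng = np.random.default_rng(6)
        background = rng.normal(size=(6, 2))
        inter = brute_force_interactions(
            model, np.array([0.4, 0.8]), background
        )
        assert inter[0, 1] == pytest.approx(0.0, abs=1e-12)


class TestImportanceRanking:
    def test_dominant_planted_driver_ranks_first(self, attr_matrix):
        ranking = importance_ranking(attr_matrix)
        assert ranking["feature"].iloc[0] == "HAI"

    def test_constant_model_preserves_column_order(self):
        model = manual_ensemble([], list(FEATURES), base=1.0)
        X = pd.DataFrame(np.zeros((4, 9)), columns=FEATURES)
        ranking = importance_ranking(shapley(model, X, X))
        assert list(ranking["feature"]) == FEATURES
        assert (ranking["mean_abs_shap"] == 0).all()

    def test_invariant_to_row_permutation(self, attr_matrix, rng):
        perm = rng.permutation(len(attr_matrix.phi))
        shuffled = at.AttributionMatrix(
            phi=attr_matrix.phi.iloc[perm].reset_index(drop=True),
            base=attr_matrix.base,
        )
        pd.testing.assert_frame_equal(
            importance_ranking(attr_matrix), importance_ranking(shuffled)
        )


class TestDependenceTable:
    def test_row_count_and_sorting(self, attr_matrix, driver_table):
        dep = dependence_table(attr_matrix, driver_table, "GPP")
        assert len(dep) == len(driver_table)
        assert dep["GPP"].is_monotonic_increasing

    def test_self_coloring_duplicates_feature(self, attr_matrix, driver_table):
        dep = dependence_table(
            attr_matrix, driver_table, "GPP", color_feature="GPP"
        )
        assert np.array_equal(dep["GPP"], dep["color_GPP"])

    def test_unknown_feature_rejected(self, attr_matrix, driver_table):
        with pytest.raises(KeyError, match="NDVI"):
            dependence_table(attr_matrix, driver_table, "NDVI")

    def test_planted_interaction_shows_in_conditional_spread(self):
        """With a GPPxHAI interaction planted, phi_GPP varies more among
        high-HAI instances than among low-HAI instances."""
        wins = 0
        n_trials = 12
        for seed in range(n_trials):
            rng = np.random.default_rng(1000 + seed)
            table = pd.DataFrame(
                rng.normal(size=(240, 9)), columns=FEATURES
            )
            table["ESV"] = synthetic.planted_response(
                table,
                {"GPP": 1.0, "HAI": 1.0},
                interactions={("GPP", "HAI"): 3.0},
                noise_sd=0.3,
                seed=seed,
            )
            model = fit_model(table, {"n_estimators": 100}, seed=seed)
            attr = shapley(model, table, table)
            dep = dependence_table(attr, table, "GPP", color_feature="HAI")
            color = dep["color_HAI"]
            hi = dep.loc[color >= color.quantile(2 / 3), "shap_value"]
            lo = dep.loc[color <= color.quantile(1 / 3), "shap_value"]
            wins += hi.var() > lo.var()
        assert wins >= 10, wins
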
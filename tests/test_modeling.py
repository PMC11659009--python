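import numpy as np
import pandas as pd
import pytest

from canopyagb.modeling import (
    FEATURE_SETS,
    ModelConfig,
    build_feature_table,
    cross_validate,
    evaluate_grid,
    fit,
    metrics,
    rf_importance,
    screen_features,
    split_by_replicate,
)


def linear_table(n_plots=60, n_stages=1, noise=0.0, seed=0):
    """Feature table with a known linear AGB signal in one feature."""
    rng = np.random.default_rng(seed)
    rows = []
    for stage in ["bolting", "seedling", "early_blossoming"][:n_stages]:
        for i in range(n_plots):
            x = rng.uniform(0, 10)
            rows.append({
                "plot_id": f"P{i}", "stage": stage,
                "replicate": i % 3 + 1, "n_level": f"N{i % 5}", "variety": "C1",
                "NDVI": x, "PH": rng.normal(), "GVAR": rng.normal(),
                "agb_kg_ha": 3.0 * x + 1.0 + rng.normal(0, noise),
            })
    return pd.DataFrame(rows)


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        m = metrics(y, y)
        assert m["R2"] == pytest.approx(1.0)
        assert m["RMSE"] == 0.0
        assert m["rRMSE"] == 0.0

    def test_mean_predictor_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        m = metrics(y, np.full(3, 2.0))
        assert m["R2"] == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        m = metrics([1.0, 2.0, 3.0], [1.0, 2.0, 5.0])
        assert m["RMSE"] == pytest.approx(np.sqrt(4.0 / 3.0), abs=1e-12)
        assert m["R2"] == pytest.approx(1.0 - 4.0 / 2.0, abs=1e-12)
        assert m["rRMSE"] == pytest.approx(np.sqrt(4.0 / 3.0) / 2.0, abs=1e-12)

    def test_against_independent_formulas(self):
        """Cross-check on random vectors against a literal re-derivation."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            y = rng.normal(size=25)
            yh = y + rng.normal(0, 0.5, size=25)
            m = metrics(y, yh)
            sse = sum((a - b) ** 2 for a, b in zip(y, yh))
            sst = sum((a - np.mean(y)) ** 2 for a in y)
            assert m["R2"] == pytest.approx(1 - sse / sst, abs=1e-10)
            assert m["RMSE"] == pytest.approx((sse / 25) ** 0.5, abs=1e-10)
            assert m["rRMSE"] == pytest.approx((sse / 25) ** 0.5 / np.mean(y),
                                               abs=1e-10)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            metrics([1, 2, 3], [1, 2])


class TestScreening:
    def test_feature_equal_to_target_selected(self):
        t = linear_table()
        t["COPY"] = t["agb_kg_ha"]
        sel = screen_features(t, ["COPY"])
        assert sel["COPY"] == pytest.approx(1.0)

    def test_negative_correlate_selected_by_absolute_value(self):
        t = linear_table()
        t["NEG"] = -t["agb_kg_ha"]
        sel = screen_features(t, ["NEG"])
        assert sel["NEG"] == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        t = pd.DataFrame({"x": [1.0, 2.0, 3.0], "agb_kg_ha": [2.0, 4.0, 6.1]})
        sel = screen_features(t, ["x"], threshold=0.0)
        x, y = np.array([1, 2, 3.0]), np.array([2, 4, 6.1])
        r_hand = (((x - x.mean()) * (y - y.mean())).sum()
                  / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        assert sel["x"] == pytest.approx(r_hand, abs=1e-12)

    def test_zero_variance_excluded(self):
        t = linear_table()
        t["FLAT"] = 1.0
        assert "FLAT" not in screen_features(t, ["FLAT", "NDVI"], threshold=0.0)

    def test_threshold_extremes(self):
        t = linear_table(noise=1.0)
        assert len(screen_features(t, ["NDVI", "PH", "GVAR"], threshold=0.0)) == 3
        assert len(screen_features(t, ["NDVI", "PH", "GVAR"], threshold=1.0)) == 0


class TestReplicateSplit:
    def test_counts_for_three_stage_design(self):
        t = linear_table(n_plots=30, n_stages=3)
        cal, val = split_by_replicate(t)
        assert len(cal) == 60
        assert len(val) == 30
        assert len(cal) + len(val) == len(t)

    def test_union_is_whole_table(self):
        t = linear_table()
        cal, val = split_by_replicate(t)
        assert sorted(cal.index.tolist() + val.index.tolist()) == list(t.index)

    def test_empty_validation_rejected(self):
        t = linear_table()
        with pytest.raises(ValueError):
            split_by_replicate(t[t.replicate != 3])


class TestFitPredict:
    def test_rf_recovers_noiseless_linear(self):
        t = linear_table(n_plots=200)
        cal, val = split_by_replicate(t)
        model = fit(ModelConfig(algorithm="RF", seed=0), cal[["NDVI"]],
                    cal["agb_kg_ha"].to_numpy())
        m = metrics(val["agb_kg_ha"], model.predict(val[["NDVI"]]))
        assert m["R2"] >= 0.9

    def test_dnn_recovers_noiseless_linear(self):
        t = linear_table(n_plots=200)
        cal, val = split_by_replicate(t)
        model = fit(ModelConfig(algorithm="DNN", seed=0), cal[["NDVI"]],
                    cal["agb_kg_ha"].to_numpy())
        m = metrics(val["agb_kg_ha"], model.predict(val[["NDVI"]]))
        assert m["R2"] >= 0.9

    @pytest.mark.parametrize("algo", ["DNN", "RF", "SVR"])
    def test_same_seed_identical_predictions(self, algo):
        t = linear_table(noise=2.0)
        cal, val = split_by_replicate(t)
        preds = []
        for _ in range(2):
            model = fit(ModelConfig(algorithm=algo, seed=7), cal[["NDVI", "PH"]],
                        cal["agb_kg_ha"].to_numpy())
            preds.append(model.predict(val[["NDVI", "PH"]]))
        assert np.array_equal(preds[0], preds[1])

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="5"):
            fit(ModelConfig(algorithm="RF"), np.zeros((3, 2)), np.zeros(3))

    def test_missing_values_rejected(self):
        X = np.ones((6, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit(ModelConfig(algorithm="RF"), X, np.ones(6))


class TestCrossValidate:
    def test_fold_partition_properties(self):
        t = linear_table(n_plots=57)
        cv = cross_validate(ModelConfig(algorithm="RF", seed=0), t, ["NDVI"], k=10)
        assert cv["n"] == 57
        assert cv["predictions"].notna().all()  # every row predicted once
        assert max(cv["fold_sizes"]) - min(cv["fold_sizes"]) <= 1

    def test_noiseless_linear_pooled_r2(self):
        t = linear_table(n_plots=100)
        cv = cross_validate(ModelConfig(algorithm="RF", seed=0), t, ["NDVI"], k=10)
        assert cv["pooled"]["R2"] >= 0.9

    def test_fewer_plots_than_folds_rejected(self):
        t = linear_table(n_plots=5)
        with pytest.raises(ValueError):
            cross_validate(ModelConfig(algorithm="RF"), t, ["NDVI"], k=10)


class TestEvaluateGrid:
    def test_seven_by_three_pooled_cells(self):
        # a linear single-signal table is enough to exercise the grid shape
        t = linear_table(n_plots=30)
        for name in FEATURE_SETS["VI+TF+SF"]:
            if name not in t.columns:
                t[name] = np.random.default_rng(1).normal(size=len(t))
        rep = evaluate_grid(t, seed=0, cv_folds=None)
        assert len(rep.table) == 21
        assert set(rep.table.feature_set) == set(FEATURE_SETS)
        assert set(rep.table.algorithm) == {"DNN", "RF", "SVR"}

    def test_structure_only_signal_prefers_sf_over_tf(self):
        """When only height carries signal, the SF model beats the TF model."""
        rng = np.random.default_rng(2)
        t = linear_table(n_plots=60, noise=0.5)
        t["PH"] = t["agb_kg_ha"] * 0.02 + rng.normal(0, 0.05, len(t))
        t["NDVI"] = rng.normal(size=len(t))  # kill the VI signal
        for name in FEATURE_SETS["VI+TF+SF"]:
            if name not in t.columns:
                t[name] = rng.normal(size=len(t))
        rep = evaluate_grid(t, {"TF": FEATURE_SETS["TF"], "SF": FEATURE_SETS["SF"]},
                            algorithms=("RF",), seed=0, cv_folds=None)
        sf = rep.cell("SF", "RF").val_R2
        tf = rep.cell("TF", "RF").val_R2
        assert sf > tf


class TestNoiseResponse:
    def test_high_reflectance_noise_degrades_accuracy(self):
        """Raising per-pixel reflectance noise from 0.005 to 0.08 lowers the
        median combined-features RF validation R^2.

        Plot-level nuisance variability is disabled to isolate the imaging
        noise channel; plot means average several hundred pixels, so small
        noise steps are invisible at plot level and only the top of the
        noise range produces a resolvable drop (via the 8-bit RGB bands
        that drive texture and segmentation).
        """
        from canopyagb.scene import SceneConfig, generate_scene
        from canopyagb.spectral import vi_table
        from canopyagb.structure import chm, sf_table
        from canopyagb.texture import tf_table

        medians = {}
        for noise in (0.005, 0.08):
            vals = []
            for seed in range(10):
                sc = generate_scene(SceneConfig(
                    n_varieties=4, seed=seed, noise_sd_reflectance=noise,
                    noise_sd_height=0.01, soil_brightness_cv=0,
                    veg_jitter_cv=0, ph_cv=0, cover_logit_sd=0))
                vi = vi_table(sc.cube, sc.plots, rgb=sc.rgb)
                tf = tf_table(sc.rgb, sc.plots)
                sf = sf_table(chm(sc.dsm, sc.dem), sc.rgb, sc.plots)
                table = build_feature_table(sc.observations, sc.plots, vi, tf, sf)
                rep = evaluate_grid(table,
                                    {"VI+TF+SF": FEATURE_SETS["VI+TF+SF"]},
                                    algorithms=("RF",), stages=("pooled",),
                                    seed=seed, cv_folds=None)
                vals.append(rep.table.val_R2.iloc[0])
            medians[noise] = float(np.median(vals))
        assert medians[0.08] < medians[0.005]


class TestRFImportance:
    def test_scores_sum_to_one(self):
        t = linear_table(noise=1.0)
        model = fit(ModelConfig(algorithm="RF", seed=0), t[["NDVI", "PH", "GVAR"]],
                    t["agb_kg_ha"].to_numpy())
        imp = rf_importance(model)
        assert imp.importance.sum() == pytest.approx(1.0)
        assert (imp.importance >= 0).all()

    def test_planted_signal_ranks_first(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 10))
            y = X[:, 3] + rng.normal(0, 0.1, 60)
            model = fit(ModelConfig(algorithm="RF", seed=seed), X, y,
                        feature_names=[f"f{i}" for i in range(10)])
            if rf_importance(model).iloc[0]["feature"] == "f3":
                wins += 1
        assert wins >= 9

    def test_all_noise_importances_flat(self):
        ratios = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(60, 6))
            y = rng.normal(size=60)
            model = fit(ModelConfig(algorithm="RF", seed=seed), X, y)
            imp = rf_importance(model).importance
            ratios.append(imp.max() / imp.min())
        assert np.mean(ratios) < 3.0

    def test_non_rf_model_rejected(self):
        t = linear_table()
        model = fit(ModelConfig(algorithm="SVR", seed=0), t[["NDVI"]],
                    t["agb_kg_ha"].to_numpy())
        with pytest.raises(TypeError):
            rf_importance(model)
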
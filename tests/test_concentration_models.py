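"""Forest tuning, backward elimination, selection, and bootstrap CIs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riverref import concentration_models as cm


def _table(n=120, n_extra=2, seed=0, noise=0.1):
    """Modeling table with a known signal on human_effect and biome."""
    rng = np.random.default_rng(seed)
    biomes = rng.choice(["forest", "grassland", "montane"], n)
    biome_effect = pd.Series({"forest": -2.0, "grassland": -1.0, "montane": -3.0})
    df = pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(n)],
            "human_effect": rng.normal(0, 1, n),
            "latitude": rng.uniform(-60, 60, n),
            "biome": biomes,
        }
    )
    for j in range(n_extra):
        df[f"noise{j}"] = rng.normal(0, 1, n)
    df["ln_median"] = (
        biome_effect[biomes].to_numpy()
        + 0.5 * df["human_effect"]
        + rng.normal(0, noise, n)
    )
    df["n_obs"] = rng.integers(5, 60, n)
    return df


SMALL_GRID = cm.TuningGrid(
    n_estimators=(50,), max_features=("sqrt",), min_samples_leaf=(2,), cv_folds=5
)


class TestSplit:
    def test_75_25_proportions(self):
        train, test = cm.split_train_test(_table(100), seed=1)
        assert len(train) == 75 and len(test) == 25
        assert set(train["id"]).isdisjoint(test["id"])

    def test_seed_determinism(self):
        t = _table(80)
        a1, b1 = cm.split_train_test(t, seed=7)
        a2, b2 = cm.split_train_test(t, seed=7)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)

    def test_response_distributions_similar(self):
        train, test = cm.split_train_test(_table(400), seed=2)
        d = stats.ks_2samp(train["ln_median"], test["ln_median"]).statistic
        assert d < 0.15

    def test_too_few_sites(self):
        with pytest.raises(ValueError, match="8 sites"):
            cm.split_train_test(_table(7))


class TestTuneForest:
    def test_single_cell_grid_returned(self):
        params, mae = cm.tune_forest(
            _table(60), SMALL_GRID, ["human_effect", "latitude", "biome"], seed=0
        )
        assert params == {
            "n_estimators": 50, "max_features": "sqrt", "min_samples_leaf": 2,
        }
        assert mae > 0

    def test_deterministic_given_seed(self):
        t = _table(60)
        grid = cm.TuningGrid((20, 50), ("sqrt",), (2, 5), cv_folds=4)
        out1 = cm.tune_forest(t, grid, ["human_effect", "biome"], seed=3)
        out2 = cm.tune_forest(t, grid, ["human_effect", "biome"], seed=3)
        assert out1 == out2

    def test_pure_noise_cv_mae_near_response_mad(self):
        rng = np.random.default_rng(0)
        t = _table(300, noise=0.0, seed=5)
        t["ln_median"] = rng.normal(0, 1, len(t))  # sever any signal
        t["n_obs"] = 1
        _, mae = cm.tune_forest(
            t, SMALL_GRID, ["human_effect", "latitude"], seed=0
        )
        mad = np.abs(t["ln_median"] - t["ln_median"].mean()).mean()
        assert 0.7 * mad <= mae <= 1.5 * mad

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            cm.TuningGrid(n_estimators=())

    def test_tree_cap(self):
        with pytest.raises(ValueError, match="900"):
            cm.TuningGrid(n_estimators=(1200,))


class TestBackwardEliminate:
    def test_candidate_count_is_p_minus_f_plus_1(self):
        t = _table(60, n_extra=2)
        preds = ["human_effect", "latitude", "biome", "noise0", "noise1"]
        cands = cm.backward_eliminate(t, preds, SMALL_GRID, seed=0)
        assert len(cands) == len(preds) - 3 + 1
        sizes = [len(c.predictors) for c in cands]
        assert sizes == [5, 4, 3]

    def test_fixed_predictors_never_dropped(self):
        t = _table(60, n_extra=3)
        preds = ["human_effect", "latitude", "biome", "noise0", "noise1", "noise2"]
        for cand in cm.backward_eliminate(t, preds, SMALL_GRID, seed=0):
            assert {"human_effect", "latitude", "biome"} <= set(cand.predictors)

    def test_fixed_only_single_candidate(self):
        t = _table(60, n_extra=0)
        cands = cm.backward_eliminate(
            t, ["human_effect", "latitude", "biome"], SMALL_GRID, seed=0
        )
        assert len(cands) == 1

    def test_fixed_not_subset_rejected(self):
        t = _table(60)
        with pytest.raises(ValueError, match="fixed"):
            cm.backward_eliminate(t, ["human_effect", "latitude"], SMALL_GRID)

    def test_noise_dropped_before_signal(self):
        t = _table(200, n_extra=1, seed=3)
        # make a genuinely informative extra predictor
        t["useful"] = t["ln_median"] * 0.8 + np.random.default_rng(1).normal(
            0, 0.1, len(t)
        )
        cands = cm.backward_eliminate(
            t, ["human_effect", "latitude", "biome", "useful", "noise0"],
            SMALL_GRID, seed=0,
        )
        # the 4-predictor candidate keeps the informative one
        assert "useful" in cands[1].predictors
        assert "noise0" not in cands[1].predictors


class TestEvaluateAndSelect:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        m = cm.evaluate(y, y)
        assert m == {"mae": 0.0, "rmse": 0.0, "r2": 1.0}

    def test_constant_predictions_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        m = cm.evaluate(y, np.full(3, y.mean()))
        assert m["r2"] == 0.0

    def test_three_point_hand_example(self):
        m = cm.evaluate([0.0, 1.0, 2.0], [0.0, 1.0, 3.0])
        assert m["mae"] == pytest.approx(1 / 3)
        assert m["rmse"] == pytest.approx(1 / np.sqrt(3))

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            cm.evaluate([1.0], [1.0])

    def test_select_single_candidate(self):
        t = _table(80)
        train, test = cm.split_train_test(t, seed=0)
        cands = cm.backward_eliminate(
            train, ["human_effect", "latitude", "biome"], SMALL_GRID, seed=0
        )
        bundle = cm.select_model(cands, test, analyte="TN", train=train)
        assert bundle.predictors == cands[0].predictors
        assert bundle.test_metrics["mae"] > 0

    def test_tie_rule_prefers_fewer_predictors(self):
        t = _table(150, n_extra=2, noise=0.05)
        train, test = cm.split_train_test(t, seed=0)
        cands = cm.backward_eliminate(
            train, ["human_effect", "latitude", "biome", "noise0", "noise1"],
            SMALL_GRID, seed=0,
        )
        generous = cm.select_model(cands, test, rel_tol=10.0, train=train)
        assert len(generous.predictors) == min(len(c.predictors) for c in cands)

    def test_zero_tolerance_is_argmin(self):
        t = _table(150, n_extra=2)
        train, test = cm.split_train_test(t, seed=0)
        cands = cm.backward_eliminate(
            train, ["human_effect", "latitude", "biome", "noise0", "noise1"],
            SMALL_GRID, seed=0,
        )
        strict = cm.select_model(cands, test, rel_tol=0.0, train=train)
        maes = [
            cm.evaluate(test["ln_median"], c.predict(test), test["n_obs"])["mae"]
            for c in cands
        ]
        assert strict.test_metrics["mae"] == pytest.approx(min(maes))

    def test_empty_candidate_list(self):
        with pytest.raises(ValueError):
            cm.select_model([], _table(20))


class TestUnknownBiome:
    def test_prediction_with_unseen_level_errors(self):
        t = _table(60)
        train, test = cm.split_train_test(t, seed=0)
        cands = cm.backward_eliminate(
            train, ["human_effect", "latitude", "biome"], SMALL_GRID, seed=0
        )
        bundle = cm.select_model(cands, test, train=train)
        alien = test.copy()
        alien["biome"] = "tundra"
        with pytest.raises(cm.UnknownBiomeError, match="tundra"):
            bundle.predict(alien)


class TestBootstrap:
    def _bundle(self, t, seed=0):
        train, test = cm.split_train_test(t, seed=seed)
        cands = cm.backward_eliminate(
            train, ["human_effect", "latitude", "biome"], SMALL_GRID, seed=seed
        )
        return cm.select_model(cands, test, train=train, seed=seed), train

    def test_reps_validation(self):
        t = _table(60)
        bundle, train = self._bundle(t)
        with pytest.raises(ValueError, match="reps"):
            cm.bootstrap_predictions(bundle, train, [t], reps=1)

    def test_two_reps_valid_interval(self):
        t = _table(60)
        bundle, train = self._bundle(t)
        ci = cm.bootstrap_ci(bundle, train, t.head(10), reps=2, seed=0)
        assert (ci["lower"] <= ci["point"]).all()
        assert (ci["point"] <= ci["upper"]).all()

    def test_reproducible_given_seed(self):
        t = _table(60)
        bundle, train = self._bundle(t)
        a = cm.bootstrap_ci(bundle, train, t.head(5), reps=20, seed=4)
        b = cm.bootstrap_ci(bundle, train, t.head(5), reps=20, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_ci_width_shrinks_with_n(self):
        widths = []
        for n in (60, 480):
            t = _table(n, noise=0.0)
            bundle, train = self._bundle(t)
            ci = cm.bootstrap_ci(bundle, train, t.head(20), reps=60, seed=0)
            widths.append((ci["upper"] - ci["lower"]).mean())
        assert widths[1] < widths[0]


def test_parameter_recovery_on_clean_signal():
    """With a strong monotone signal and no extraneous predictors, the
    selected model recovers the true medians accurately (R² ≥ 0.9)."""
    rng = np.random.default_rng(12)
    n = 1000
    biomes = rng.choice(["forest", "grassland"], n)
    biome_effect = pd.Series({"forest": -2.0, "grassland": -1.0})
    t = pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(n)],
            "human_effect": rng.normal(0, 1.5, n),
            "latitude": rng.uniform(-60, 60, n),
            "biome": biomes,
        }
    )
    true_ln = biome_effect[biomes].to_numpy() + 0.5 * t["human_effect"]
    t["ln_median"] = true_ln + rng.normal(0, 0.1, n)
    t["n_obs"] = 30
    grid = cm.TuningGrid((100,), ("all",), (1,), cv_folds=5)
    train, test = cm.split_train_test(t, seed=0)
    cands = cm.backward_eliminate(
        train, ["human_effect", "latitude", "biome"], grid, seed=0
    )
    bundle = cm.select_model(cands, test, train=train)
    pred = bundle.predict(t)
    assert cm.evaluate(true_ln, pred)["r2"] >= 0.9
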
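import numpy as np
import pytest

from srsmargins.plan_model import Plan
from srsmargins.regressors import (
    FEATURE_NAMES,
    AugmentationParams,
    FeatureRow,
    RegressionDataset,
    accuracy,
    augment,
    bootstrap_ci,
    build_features,
    gaussian_noise,
    load_model,
    mae,
    mutual_info_importance,
    quantize_margin,
    save_model,
    train,
)

from conftest import sphere_lesion


def _random_dataset(n=200, seed=0, label_fn=None):
    rng = np.random.default_rng(seed)
    rows = [
        FeatureRow(
            n_metastases=int(rng.integers(2, 12)),
            lobe_code=int(rng.integers(0, 7)),
            volume=float(rng.uniform(0.05, 8.0)),
            size=float(rng.uniform(0.3, 2.5)),
            distance=float(rng.uniform(9.0, 100.0)),
            cluster=int(rng.integers(0, 2)),
        )
        for _ in range(n)
    ]
    if label_fn is None:
        label_fn = lambda r: 0.1 + 0.009 * r.distance
    labels = quantize_margin(np.array([label_fn(r) for r in rows]))
    return RegressionDataset(rows, labels)


class TestBuildFeatures:
    def test_two_far_lesions(self):
        plan = Plan(
            "p",
            (sphere_lesion("L1", (0, 0, 0), 1.0), sphere_lesion("L2", (40.0, 0, 0), 1.0)),
        )
        rows = build_features(plan)
        assert all(r.n_metastases == 2 for r in rows)
        assert all(r.cluster == 0 for r in rows)

    def test_clustered_lesions_flagged(self, two_lesion_plan):
        rows = build_features(two_lesion_plan)
        assert [r.cluster for r in rows] == [1, 1]

    def test_single_lesion(self, single_lesion_plan):
        (row,) = build_features(single_lesion_plan)
        assert row.n_metastases == 1 and row.cluster == 0
        assert row.distance == pytest.approx(30.0)


class TestAugment:
    def test_median_of_kernel_is_identity(self):
        out = gaussian_noise(np.array([100.0]), np.array([0.5]), np.array([2.0]))
        assert out[0] == pytest.approx(100.0, abs=1e-12)

    def test_zero_sigma_copies_exactly(self):
        ds = _random_dataset(10)
        out = augment(ds, AugmentationParams(sigma_pct=0.0, n_new=20, seed=1))
        assert len(out) == 30
        originals = {(r.volume, r.size, r.distance) for r in ds.rows}
        assert all((r.volume, r.size, r.distance) in originals for r in out.rows[10:])

    def test_moments_match_gaussian(self):
        row = FeatureRow(1, 0, 100.0, 1.0, 50.0, 0)
        ds = RegressionDataset([row], np.array([0.5]))
        out = augment(ds, AugmentationParams(sigma_pct=0.02, n_new=100_000, seed=5))
        vols = np.array([r.volume for r in out.rows[1:]])
        assert vols.mean() == pytest.approx(100.0, abs=0.02)
        assert vols.std() == pytest.approx(2.0, abs=0.05)

    def test_discrete_features_and_labels_untouched(self):
        ds = _random_dataset(15, seed=3)
        out = augment(ds, AugmentationParams(sigma_pct=0.1, n_new=50, seed=2))
        src_keys = {(r.n_metastases, r.lobe_code, r.cluster) for r in ds.rows}
        assert all((r.n_metastases, r.lobe_code, r.cluster) in src_keys for r in out.rows[15:])
        assert set(np.round(out.labels * 10)) <= set(np.round(ds.labels * 10))

    def test_reproducible_given_seed(self):
        ds = _random_dataset(10)
        p = AugmentationParams(sigma_pct=0.05, n_new=30, seed=9)
        a, b = augment(ds, p), augment(ds, p)
        assert [r.volume for r in a.rows] == [r.volume for r in b.rows]


class TestMutualInformation:
    def test_distance_dominates_distance_driven_labels(self):
        ds = _random_dataset(400, seed=1)
        imp = mutual_info_importance(ds, seed=0)
        assert imp["distance"] > 0.8
        assert sum(imp.values()) == pytest.approx(1.0)

    def test_shuffled_labels_spread_importance(self):
        ds = _random_dataset(400, seed=1)
        rng = np.random.default_rng(0)
        shuffled = RegressionDataset(ds.rows, rng.permutation(ds.labels))
        imp = mutual_info_importance(shuffled, seed=0)
        assert max(imp.values()) < 0.8

    def test_constant_feature_scores_zero(self):
        ds = _random_dataset(100, seed=2)
        rows = [
            FeatureRow(5, r.lobe_code, r.volume, r.size, r.distance, r.cluster) for r in ds.rows
        ]
        imp = mutual_info_importance(RegressionDataset(rows, ds.labels), seed=0)
        assert imp["n_metastases"] == 0.0

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            mutual_info_importance(_random_dataset(20))


class TestMetrics:
    def test_accuracy_counts_grid_matches(self):
        assert accuracy(np.array([0.5, 0.5, 1.0]), np.array([0.5, 0.4, 1.0])) == pytest.approx(
            2 / 3
        )
        y = np.array([0.3, 0.7])
        assert accuracy(y, y) == 1.0
        assert accuracy(y, np.array([0.4, 0.8])) == 0.0

    def test_mae_values(self):
        assert mae(np.array([0.5, 0.5, 1.0]), np.array([0.5, 0.4, 1.0])) == pytest.approx(
            0.0333333, abs=1e-6
        )
        assert mae(np.array([0.1, 1.0]), np.array([1.0, 0.1])) == pytest.approx(0.9)

    def test_mae_zero_iff_accuracy_one_on_grid(self):
        ds = _random_dataset(50)
        assert accuracy(ds.y, ds.y) == 1.0 and mae(ds.y, ds.y) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy(np.array([]), np.array([]))

    @pytest.mark.parametrize("raw, expected", [(0.44, 0.4), (1.7, 1.0), (0.05, 0.1), (0.45, 0.5)])
    def test_quantize_margin(self, raw, expected):
        assert quantize_margin(raw) == pytest.approx(expected)


class TestTrain:
    def test_linear_family_recovers_linear_labels(self):
        # distances placed so that labels are exactly linear in distance
        # AND sit on the 0.1 mm grid: d = (y - 0.1) / 0.009
        rng = np.random.default_rng(4)
        grid_labels = rng.choice(np.arange(1, 11) / 10.0, size=100)
        rows = [
            FeatureRow(
                n_metastases=int(rng.integers(2, 12)),
                lobe_code=int(rng.integers(0, 7)),
                volume=float(rng.uniform(0.05, 8.0)),
                size=float(rng.uniform(0.3, 2.5)),
                distance=float((y - 0.1) / 0.009) + 1e-9,
                cluster=int(rng.integers(0, 2)),
            )
            for y in grid_labels
        ]
        ds_lin = RegressionDataset(rows, grid_labels)
        model = train("lm", ds_lin, seed=0)
        yhat = model.predict(ds_lin.X)
        assert mae(ds_lin.y, yhat) < 1e-6

    def test_deterministic_given_seed(self):
        ds = _random_dataset(120, seed=5)
        grid = {"learning_rate": [0.1, 0.3], "max_depth": [3]}
        m1 = train("xgb", ds, grid=grid, seed=0)
        m2 = train("xgb", ds, grid=grid, seed=0)
        assert m1.best_params == m2.best_params
        assert np.array_equal(m1.predict(ds.X), m2.predict(ds.X))

    def test_best_params_stay_inside_grid(self):
        ds = _random_dataset(120, seed=6)
        grid = {"n_estimators": [20], "max_depth": [3, 5]}
        model = train("rfr", ds, grid=grid, seed=0)
        assert model.best_params["n_estimators"] == 20
        assert model.best_params["max_depth"] in (3, 5)

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            train("lm", _random_dataset(4), k=5)

    def test_schema_mismatch_rejected(self):
        ds = _random_dataset(60, seed=7)
        model = train("lm", ds, seed=0)
        with pytest.raises(ValueError, match="schema"):
            model.predict(np.zeros((3, 4)))

    def test_feature_subset_respected(self):
        ds = _random_dataset(80, seed=8)
        model = train("lm", ds, seed=0, feature_subset=("distance", "volume"))
        assert model.feature_subset == ("distance", "volume")
        assert model.predict(ds.X).shape == (80,)

    def test_persistence_roundtrip(self, tmp_path):
        ds = _random_dataset(60, seed=9)
        model = train("lm", ds, seed=0)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        back = load_model(path)
        assert np.allclose(back.predict(ds.X), model.predict(ds.X))


class TestBootstrap:
    def test_perfect_predictions_degenerate_ci(self):
        ds = _random_dataset(60, seed=10)
        model = train("rfr", ds, grid={"n_estimators": [50], "max_depth": [None]}, seed=0)

        class Perfect:
            feature_subset = FEATURE_NAMES

            def predict(self, X):
                return ds.y

        ci = bootstrap_ci(Perfect(), ds, B=200, seed=0)
        assert ci["mae"] == (0.0, 0.0)
        assert ci["r2"] == (1.0, 1.0)

    def test_bounds_ordered(self):
        ds = _random_dataset(80, seed=11)
        model = train("lm", ds, seed=0)
        ci = bootstrap_ci(model, ds, B=300, seed=1)
        assert ci["mae"][0] <= ci["mae"][1]
        assert ci["r2"][0] <= ci["r2"][1]

    def test_more_data_shrinks_ci(self):
        small = _random_dataset(40, seed=12)
        big = _random_dataset(160, seed=12)
        model = train("lm", big, seed=0)
        w_small = np.diff(bootstrap_ci(model, small, B=400, seed=2)["mae"])[0]
        w_big = np.diff(bootstrap_ci(model, big, B=400, seed=2)["mae"])[0]
        assert w_big < w_small
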
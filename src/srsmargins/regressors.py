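"""Margin regression: features, augmentation, training, metrics, CIs.

Each lesion is encoded as a six-feature row — number of metastases in
the plan, brain-lobe code, GTV volume (cm^3), GTV size (cm), distance
to isocenter (mm), and a binary dose-cluster flag — with the
quantized setup-displacement margin (0.1-1.0 mm grid) as label.

Four regressor families are supported (linear, multilayer perceptron,
random forest, gradient boosting), each tuned by exhaustive grid
search over a small hyperparameter grid scored by mean 5-fold
cross-validated R^2.  Training-set diversity can be increased by
Gaussian noise injection on the continuous features:
``x_new = x + mu + sigma * sqrt(2) * erfinv(2 p - 1)``, ``p ~ U(0,1)``,
with ``sigma`` a fixed percentage of each value (the inverse-CDF form
of sampling a zero-mean Gaussian).  Model reliability is reported via
percentile bootstrap confidence intervals for MAE and R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import joblib
import numpy as np
from scipy.special import erfinv
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import mutual_info_regression
from sklearn.linear_model import LinearRegression
from sklearn.metrics import r2_score
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBRegressor

from .margin_pipeline import detect_clusters, quantize
from .plan_model import LOBES, Plan

__all__ = [
    "FEATURE_NAMES",
    "FeatureRow",
    "RegressionDataset",
    "AugmentationParams",
    "TrainedModel",
    "build_features",
    "features_to_matrix",
    "augment",
    "mutual_info_importance",
    "train",
    "quantize_margin",
    "accuracy",
    "mae",
    "bootstrap_ci",
    "save_model",
    "load_model",
]

FEATURE_NAMES = ("n_metastases", "lobe_code", "volume", "size", "distance", "cluster")

#: Continuous features eligible for noise injection.
_CONTINUOUS = ("volume", "size", "distance")

_LOBE_CODE = {name: i for i, name in enumerate(LOBES)}


@dataclass(frozen=True)
class FeatureRow:
    """One lesion as the ordered six-feature input vector."""

    n_metastases: int
    lobe_code: int
    volume: float  # cm^3
    size: float  # cm
    distance: float  # mm
    cluster: int  # 0/1

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.size <= 0 or self.distance < 0:
            raise ValueError("volume/size must be > 0 and distance >= 0")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.n_metastases, self.lobe_code, self.volume, self.size, self.distance, self.cluster],
            dtype=float,
        )


@dataclass
class RegressionDataset:
    """Feature rows with expected-margin labels on the 0.1 mm grid."""

    rows: list[FeatureRow]
    labels: np.ndarray  # mm, in [0.1, 1.0]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=float)
        if len(self.rows) != len(self.labels):
            raise ValueError("row/label count mismatch")
        on_grid = np.allclose(self.labels, np.round(self.labels * 10) / 10, atol=1e-9)
        if not on_grid:
            raise ValueError("labels must lie on the 0.1 mm grid")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def X(self) -> np.ndarray:
        return features_to_matrix(self.rows)

    @property
    def y(self) -> np.ndarray:
        return self.labels


@dataclass(frozen=True)
class AugmentationParams:
    """Gaussian noise-injection settings.

    sigma_pct : noise standard deviation as a fraction of each input
        value (default 0.02, i.e. 2%).
    n_new : number of synthetic rows to draw (sampling source rows
        uniformly with replacement).
    mu : additive offset of the kernel (default 0, zero-mean noise).
    """

    sigma_pct: float = 0.02
    n_new: int = 2160
    mu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_pct < 0:
            raise ValueError("sigma_pct must be >= 0")


def build_features(plan: Plan, buffer: float = 6.0) -> list[FeatureRow]:
    """One feature row per lesion; cluster flags from the pairwise
    radius-sum + buffer rule."""
    flags, _ = detect_clusters(plan, buffer)
    return [
        FeatureRow(
            n_metastases=plan.n_metastases,
            lobe_code=_LOBE_CODE.get(les.lobe, _LOBE_CODE["other"]),
            volume=les.volume,
            size=les.equiv_diameter,
            distance=les.distance_to_isocenter,
            cluster=int(flag),
        )
        for les, flag in zip(plan.lesions, flags)
    ]


def features_to_matrix(rows: Sequence[FeatureRow]) -> np.ndarray:
    """(n, 6) design matrix in the fixed feature order."""
    return np.array([r.as_array() for r in rows], dtype=float)


def gaussian_noise(x: np.ndarray, p: np.ndarray, sigma: np.ndarray, mu: float = 0.0) -> np.ndarray:
    """Inverse-CDF noise injection: ``x + mu + sigma*sqrt(2)*erfinv(2p-1)``."""
    return x + mu + sigma * np.sqrt(2.0) * erfinv(2.0 * p - 1.0)


def augment(ds: RegressionDataset, params: AugmentationParams | None = None) -> RegressionDataset:
    """Append ``n_new`` noise-injected rows to a dataset.

    Noise applies to the continuous inputs (volume, size, distance)
    only; counts, lobe codes, cluster flags and labels are copied
    unchanged.  Perturbed values are floored at a small positive
    epsilon.  Reproducible for a given seed.
    """
    params = params or AugmentationParams()
    rng = np.random.default_rng(params.seed)
    n = len(ds)
    src = rng.integers(0, n, size=params.n_new)
    new_rows: list[FeatureRow] = []
    new_labels = []
    for i in src:
        row = ds.rows[int(i)]
        vals = {}
        for name in _CONTINUOUS:
            x = getattr(row, name)
            p = rng.uniform(0.0, 1.0)
            sigma = params.sigma_pct * x
            vals[name] = max(float(gaussian_noise(x, p, sigma, params.mu)), 1e-6)
        new_rows.append(replace(row, **vals))
        new_labels.append(ds.labels[int(i)])
    return RegressionDataset(
        rows=list(ds.rows) + new_rows,
        labels=np.concatenate([ds.labels, np.array(new_labels, dtype=float)]),
    )


def mutual_info_importance(ds: RegressionDataset, seed: int = 0) -> dict[str, float]:
    """Per-feature mutual information with the label, normalized to sum 1.

    Count-like features (metastasis count, lobe code, cluster flag)
    are treated as discrete.  A constant feature scores exactly 0
    before normalization.
    """
    if len(ds) < 50:
        raise ValueError("need at least 50 rows for a stable MI estimate")
    X, y = ds.X, ds.y
    discrete = np.array([True, True, False, False, False, True])
    mi = mutual_info_regression(X, y, discrete_features=discrete, random_state=seed)
    mi = np.clip(mi, 0.0, None)
    constant = X.ptp(axis=0) == 0 if hasattr(X, "ptp") else np.ptp(X, axis=0) == 0
    mi[constant] = 0.0
    total = mi.sum()
    shares = mi / total if total > 0 else np.zeros_like(mi)
    return dict(zip(FEATURE_NAMES, shares.tolist()))


@dataclass
class TrainedModel:
    """A fitted regressor with its search metadata.

    ``estimator`` predicts continuous margins; callers quantize with
    :func:`quantize_margin`.  ``cvs`` is the cross-validation score:
    mean R^2 over the k folds for the best configuration.
    """

    family: str
    estimator: object
    best_params: dict
    cvs: float
    fold_scores: np.ndarray
    feature_subset: tuple[str, ...] = FEATURE_NAMES

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
            raise ValueError(
                f"feature-schema mismatch: expected (n, {len(FEATURE_NAMES)}) matrix, got {X.shape}"
            )
        cols = [FEATURE_NAMES.index(f) for f in self.feature_subset]
        return np.asarray(self.estimator.predict(X[:, cols]), dtype=float)


#: Default hyperparameter grids — deliberately small (2-3 values per
#: searched parameter); the searched parameters per family are the
#: conventional ones (perceptron: architecture, learning rate, L2;
#: forest: tree count/depth/split/leaf/features; boosting: learning
#: rate, depth, min child weight).
DEFAULT_GRIDS: dict[str, dict] = {
    "lm": {"fit_intercept": [True, False]},
    "mlp": {
        "mlp__hidden_layer_sizes": [(32,), (64, 32)],
        "mlp__learning_rate_init": [1e-3, 1e-2],
        "mlp__alpha": [1e-4, 1e-3],
    },
    "rfr": {
        "n_estimators": [100, 200],
        "max_depth": [None, 10],
        "min_samples_split": [2, 5],
        "min_samples_leaf": [1, 2],
        "max_features": [1.0, "sqrt"],
    },
    "xgb": {
        "learning_rate": [0.05, 0.1, 0.3],
        "max_depth": [3, 5, 7],
        "min_child_weight": [1, 3, 5],
    },
}

FAMILIES = tuple(DEFAULT_GRIDS)


def _base_estimator(family: str, seed: int):
    if family == "lm":
        return LinearRegression()
    if family == "mlp":
        # rectified-linear activation and a stochastic gradient-based
        # solver are fixed, not searched
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "mlp",
                    MLPRegressor(
                        activation="relu",
                        solver="adam",
                        max_iter=500,
                        random_state=seed,
                    ),
                ),
            ]
        )
    if family == "rfr":
        return RandomForestRegressor(random_state=seed)
    if family == "xgb":
        # gbtree booster and uniform row sampling are fixed, not searched
        return XGBRegressor(
            booster="gbtree",
            sampling_method="uniform",
            n_estimators=200,
            random_state=seed,
            verbosity=0,
        )
    raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")


def train(
    family: str,
    ds: RegressionDataset,
    grid: dict | None = None,
    k: int = 5,
    seed: int = 0,
    feature_subset: Sequence[str] | None = None,
) -> TrainedModel:
    """Grid search + k-fold CV for one regressor family.

    Every configuration in the grid is scored by mean cross-validated
    R^2 over ``k`` shuffled folds; the best is refit on the full
    dataset.  Deterministic for a given (data, grid, seed).
    """
    if grid is None:
        grid = DEFAULT_GRIDS[family]
    if not grid:
        raise ValueError("hyperparameter grid must be non-empty")
    if k > len(ds):
        raise ValueError(f"k={k} folds exceed {len(ds)} rows")
    subset = tuple(feature_subset) if feature_subset else FEATURE_NAMES
    unknown = set(subset) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown features {sorted(unknown)}")
    cols = [FEATURE_NAMES.index(f) for f in subset]
    X, y = ds.X[:, cols], ds.y
    cv = KFold(n_splits=k, shuffle=True, random_state=seed)
    search = GridSearchCV(
        _base_estimator(family, seed),
        grid,
        scoring="r2",
        cv=cv,
        n_jobs=1,
        refit=True,
    )
    search.fit(X, y)
    res = search.cv_results_
    best = search.best_index_
    fold_scores = np.array([res[f"split{i}_test_score"][best] for i in range(k)])
    return TrainedModel(
        family=family,
        estimator=search.best_estimator_,
        best_params=dict(search.best_params_),
        cvs=float(search.best_score_),
        fold_scores=fold_scores,
        feature_subset=subset,
    )


def quantize_margin(value: float | np.ndarray) -> np.ndarray | float:
    """Round half up onto the 0.1 mm grid and clamp to [0.1, 1.0]."""
    arr = np.asarray(value, dtype=float)
    # epsilon keeps binary-float grid midpoints on the round-up side
    q = np.clip(np.floor(arr / 0.1 + 0.5 + 1e-9) * 0.1, 0.1, 1.0)
    q = np.round(q, 10)
    return float(q) if np.isscalar(value) or arr.ndim == 0 else q


def accuracy(y: np.ndarray, yhat: np.ndarray) -> float:
    """Fraction of exact grid matches between quantized labels and
    quantized predictions."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size == 0:
        raise ValueError("empty arrays")
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    qy = np.round(quantize_margin(y) * 10)
    qh = np.round(quantize_margin(yhat) * 10)
    return float(np.mean(qy == qh))


def mae(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean absolute error (mm)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size == 0:
        raise ValueError("empty arrays")
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    return float(np.mean(np.abs(y - yhat)))


def bootstrap_ci(
    model: TrainedModel,
    ds: RegressionDataset,
    B: int = 5000,
    level: float = 0.95,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap CIs for MAE and R^2 of a fixed model.

    Rows are resampled with replacement ``B`` times; the model is not
    refit.  Returns the (lower, upper) percentile pair per metric at
    the given level (2.5th/97.5th for 0.95).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    yhat = model.predict(ds.X)
    y = ds.y
    n = len(y)
    maes = np.empty(B)
    r2s = np.empty(B)
    idx = rng.integers(0, n, size=(B, n))
    for b in range(B):
        i = idx[b]
        maes[b] = np.mean(np.abs(y[i] - yhat[i]))
        yb = y[i]
        ss_tot = np.sum((yb - yb.mean()) ** 2)
        ss_res = np.sum((yb - yhat[i]) ** 2)
        r2s[b] = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    lo = 100 * (1 - level) / 2
    hi = 100 - lo
    return {
        "mae": (float(np.percentile(maes, lo)), float(np.percentile(maes, hi))),
        "r2": (float(np.percentile(r2s, lo)), float(np.percentile(r2s, hi))),
    }


_PERSIST_VERSION = 1


def save_model(model: TrainedModel, path) -> None:
    """Persist a trained model (joblib, with a format version tag)."""
    joblib.dump({"version": _PERSIST_VERSION, "model": model}, path)


def load_model(path) -> TrainedModel:
    payload = joblib.load(path)
    if payload.get("version") != _PERSIST_VERSION:
        raise ValueError(f"unsupported model file version: {payload.get('version')}")
    return payload["model"]
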
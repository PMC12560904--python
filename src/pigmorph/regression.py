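"""Evaluation harness: metrics, grouped splits, model comparison, ablation.

Metrics are the standard regression quartet

    MAE  = (1/n) Σ |yᵢ − ŷᵢ|
    MSE  = (1/n) Σ (yᵢ − ŷᵢ)²
    RMSE = √MSE
    R²   = 1 − Σ(yᵢ − ŷᵢ)² / Σ(yᵢ − ȳ)²

The split is grouped by animal: all images of one animal land in exactly one
of train/validation/test (no identity leakage), targeting a 6:2:2 image
count ratio with animal mean weights stratified across subsets.

Model selection: for each backend a small grid is searched by fitting on
train and scoring MAE on validation; the selected model is evaluated on test
without refitting.  Features are fed raw to tree ensembles and standardized
for linear / kernel backends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import ParameterGrid
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR, LinearSVR

from .errors import ValidationError
from .features import FEATURE_NAMES

__all__ = [
    "mae", "mse", "rmse", "r2",
    "SplitPlan", "grouped_split",
    "RegressorConfig", "RegressionReport",
    "train_and_evaluate", "ablation_study", "pearson_matrix",
    "DEFAULT_GRIDS", "available_backends",
]


# ---------------------------------------------------------------------------
# metrics


def _check_pair(y, yhat):
    y = np.asarray(y, float).ravel()
    yhat = np.asarray(yhat, float).ravel()
    if y.size == 0:
        raise ValidationError("empty input vectors")
    if y.shape != yhat.shape:
        raise ValidationError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if not (np.isfinite(y).all() and np.isfinite(yhat).all()):
        raise ValidationError("non-finite values in metric input")
    return y, yhat


def mae(y, yhat) -> float:
    y, yhat = _check_pair(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def mse(y, yhat) -> float:
    y, yhat = _check_pair(y, yhat)
    return float(np.mean((y - yhat) ** 2))


def rmse(y, yhat) -> float:
    return float(np.sqrt(mse(y, yhat)))


def r2(y, yhat) -> float:
    y, yhat = _check_pair(y, yhat)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValidationError("R² undefined for zero-variance y")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


# ---------------------------------------------------------------------------
# grouped splitting


@dataclass
class SplitPlan:
    train_animals: list[str]
    val_animals: list[str]
    test_animals: list[str]
    train_images: list[str]
    val_images: list[str]
    test_images: list[str]
    ratios: tuple[float, float, float]
    achieved: tuple[float, float, float]
    warning: str | None = None

    def subset(self, name: str) -> list[str]:
        return getattr(self, f"{name}_images")


def grouped_split(
    samples: pd.DataFrame,
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    n_strata: int = 5,
) -> SplitPlan:
    """Assign whole animals to train/val/test, targeting image-count ratios.

    ``samples`` needs columns image_id, animal_id, weight_kg.  Animals are
    stratified by mean weight quantile, shuffled within strata (seeded), and
    greedily assigned to the subset with the largest remaining image-count
    deficit, which balances both the 6:2:2 ratio and the weight
    distribution.  Disjointness of animals across subsets is unconditional.
    """
    if abs(sum(ratios) - 1.0) > 1e-9 or any(r <= 0 for r in ratios):
        raise ValidationError(f"ratios must be positive and sum to 1: {ratios}")
    animals = (
        samples.groupby("animal_id")
        .agg(n_images=("image_id", "size"), weight=("weight_kg", "mean"))
        .reset_index()
    )
    if len(animals) < 3:
        raise ValidationError("grouped split needs at least 3 distinct animals")
    rng = np.random.default_rng(seed)
    k = min(n_strata, len(animals))
    animals["stratum"] = pd.qcut(
        animals["weight"].rank(method="first"), q=k, labels=False
    )
    total = animals["n_images"].sum()
    targets = np.array(ratios) * total
    counts = np.zeros(3)
    assignment: dict[str, int] = {}
    for _, stratum in animals.groupby("stratum"):
        order = stratum.sample(frac=1.0, random_state=rng.integers(2**31)).itertuples()
        for row in order:
            deficit = (targets - counts) / targets
            sub = int(np.argmax(deficit))
            assignment[row.animal_id] = sub
            counts[sub] += row.n_images

    # guarantee non-empty subsets (can occur with very few animals)
    warning = None
    for sub in range(3):
        if not any(v == sub for v in assignment.values()):
            donor_sub = int(np.argmax(counts))
            donors = [a for a, s in assignment.items() if s == donor_sub]
            sizes = animals.set_index("animal_id")["n_images"]
            donor = min(donors, key=lambda a: sizes[a])
            assignment[donor] = sub
            counts[donor_sub] -= sizes[donor]
            counts[sub] += sizes[donor]
            warning = "subset would have been empty; moved one animal"

    achieved = tuple(counts / total)
    if max(abs(a - r) for a, r in zip(achieved, ratios)) > 0.05 and warning is None:
        warning = f"achieved ratios {achieved} deviate > 0.05 from targets {ratios}"
    if warning:
        warnings.warn(warning)

    by_sub: dict[int, list[str]] = {0: [], 1: [], 2: []}
    for a, s in assignment.items():
        by_sub[s].append(a)

    def images_of(anims):
        sel = samples[samples["animal_id"].isin(anims)]
        return sel["image_id"].tolist()

    return SplitPlan(
        train_animals=sorted(by_sub[0]),
        val_animals=sorted(by_sub[1]),
        test_animals=sorted(by_sub[2]),
        train_images=images_of(by_sub[0]),
        val_images=images_of(by_sub[1]),
        test_images=images_of(by_sub[2]),
        ratios=ratios,
        achieved=achieved,
        warning=warning,
    )


# ---------------------------------------------------------------------------
# model roster


DEFAULT_GRIDS: dict[str, dict] = {
    "linear": {},
    "svr_rbf": {
        "model__C": [10.0, 100.0, 1000.0],
        "model__gamma": ["scale", 0.01, 0.1],
        "model__epsilon": [0.1, 1.0],
    },
    "svm": {"model__C": [1.0, 10.0, 100.0], "model__epsilon": [0.1, 1.0]},
    "random_forest": {
        "n_estimators": [500],
        "max_depth": [None, 12],
        "min_samples_leaf": [1, 5],
        "max_features": ["sqrt", 1.0],
    },
    "xgboost": {
        "n_estimators": [1000],
        "max_depth": [2, 3, 6],
        "learning_rate": [0.03, 0.1],
        "min_child_weight": [1, 10],
        "subsample": [0.8],
        "colsample_bytree": [0.6],
    },
    "lightgbm": {
        "n_estimators": [1000],
        "num_leaves": [7, 31],
        "learning_rate": [0.03, 0.1],
        "min_child_samples": [10, 30],
        "colsample_bytree": [0.6],
    },
    "mlp": {
        "model__hidden_layer_sizes": [(64, 32)],
        "model__alpha": [1e-3, 1e-2],
        "model__max_iter": [2000],
    },
}

_TREE_BACKENDS = ("random_forest", "xgboost", "lightgbm")
_SCALED_BACKENDS = ("linear", "svr_rbf", "svm", "mlp")
_OPTIONAL_BACKENDS = ("mlp", "tabnet")


def available_backends() -> list[str]:
    """Backends importable in this environment (tabnet is optional and
    reported absent unless its package is installed)."""
    out = ["linear", "svr_rbf", "svm", "random_forest", "mlp"]
    try:
        import xgboost  # noqa: F401
        out.append("xgboost")
    except ImportError:  # pragma: no cover
        pass
    try:
        import lightgbm  # noqa: F401
        out.append("lightgbm")
    except ImportError:  # pragma: no cover
        pass
    try:
        import pytorch_tabnet  # noqa: F401
        out.append("tabnet")
    except ImportError:
        pass
    return out


@dataclass
class RegressorConfig:
    backend: str = "xgboost"
    grid: dict | None = None  # None → DEFAULT_GRIDS[backend]
    seed: int = 0

    def __post_init__(self):
        known = set(DEFAULT_GRIDS) | {"tabnet"}
        if self.backend not in known:
            raise ValidationError(f"unknown backend {self.backend!r}")


@dataclass
class RegressionReport:
    model_name: str
    MAE: float
    MSE: float
    RMSE: float
    R2: float
    best_hyperparams: dict
    feature_importances: dict[str, float] | None
    predictions: pd.DataFrame  # columns image_id, y, yhat
    features_used: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))

    def metrics(self) -> dict[str, float]:
        return {"MAE": self.MAE, "MSE": self.MSE, "RMSE": self.RMSE, "R2": self.R2}


def _make_estimator(backend: str, params: dict, seed: int):
    if backend == "linear":
        est = Pipeline([("scale", StandardScaler()), ("model", LinearRegression())])
    elif backend == "svr_rbf":
        est = Pipeline([("scale", StandardScaler()), ("model", SVR(kernel="rbf"))])
    elif backend == "svm":
        est = Pipeline(
            [("scale", StandardScaler()),
             ("model", LinearSVR(random_state=seed, max_iter=20000, dual="auto"))]
        )
    elif backend == "mlp":
        from sklearn.neural_network import MLPRegressor
        est = Pipeline(
            [("scale", StandardScaler()), ("model", MLPRegressor(random_state=seed))]
        )
    elif backend == "random_forest":
        est = RandomForestRegressor(random_state=seed, n_jobs=1)
    elif backend == "xgboost":
        from xgboost import XGBRegressor
        est = XGBRegressor(random_state=seed, n_jobs=1, verbosity=0,
                           tree_method="hist")
    elif backend == "lightgbm":
        from lightgbm import LGBMRegressor
        est = LGBMRegressor(random_state=seed, n_jobs=1, verbose=-1)
    else:
        raise ValidationError(f"backend {backend!r} is not available here")
    est.set_params(**params)
    return est


def _frame_to_xy(df: pd.DataFrame, feature_names: list[str]):
    X = df[feature_names].to_numpy(float)
    y = df["weight_kg"].to_numpy(float)
    return X, y


def train_and_evaluate(
    features_table: pd.DataFrame,
    config: RegressorConfig,
    plan: SplitPlan,
    feature_names: list[str] | None = None,
) -> RegressionReport:
    """Grid-search a backend on train, select on validation MAE, report test
    metrics of the selected model (no refit on train+val).

    ``features_table`` must contain weight_kg for every image in the plan.
    Tree backends additionally report normalized feature importances.
    """
    feature_names = list(feature_names or FEATURE_NAMES)
    missing = [c for c in feature_names + ["weight_kg", "image_id"]
               if c not in features_table.columns]
    if missing:
        raise ValidationError(f"features table missing columns: {missing}")
    sub = {
        name: features_table[features_table["image_id"].isin(plan.subset(name))]
        for name in ("train", "val", "test")
    }
    for name, df in sub.items():
        if df.empty:
            raise ValidationError(f"{name} subset is empty under this plan")
        if df["weight_kg"].isna().any():
            raise ValidationError(f"{name} subset has missing weight_kg")

    Xtr, ytr = _frame_to_xy(sub["train"], feature_names)
    Xva, yva = _frame_to_xy(sub["val"], feature_names)
    Xte, yte = _frame_to_xy(sub["test"], feature_names)

    grid = config.grid if config.grid is not None else DEFAULT_GRIDS[config.backend]
    best = (np.inf, None, None)
    for params in ParameterGrid(grid) if grid else [{}]:
        est = _make_estimator(config.backend, params, config.seed)
        est.fit(Xtr, ytr)
        val_mae = mae(yva, est.predict(Xva))
        if val_mae < best[0]:
            best = (val_mae, params, est)
    _, best_params, model = best

    yhat = model.predict(Xte)
    importances = None
    if config.backend in _TREE_BACKENDS:
        raw = np.asarray(model.feature_importances_, float)
        total = raw.sum() or 1.0
        importances = dict(zip(feature_names, (raw / total).tolist()))

    preds = pd.DataFrame(
        {"image_id": sub["test"]["image_id"].to_numpy(), "y": yte, "yhat": yhat}
    )
    return RegressionReport(
        model_name=config.backend,
        MAE=mae(yte, yhat),
        MSE=mse(yte, yhat),
        RMSE=rmse(yte, yhat),
        R2=r2(yte, yhat),
        best_hyperparams=dict(best_params or {}),
        feature_importances=importances,
        predictions=preds,
        features_used=feature_names,
    )


def rank_features_by_importance(
    features_table: pd.DataFrame, config: RegressorConfig, plan: SplitPlan
) -> list[str]:
    """Feature names sorted by decreasing importance of a tree baseline."""
    cfg = config
    if config.backend not in _TREE_BACKENDS:
        cfg = RegressorConfig(backend="xgboost", seed=config.seed)
    report = train_and_evaluate(features_table, cfg, plan)
    imp = report.feature_importances or {}
    return sorted(imp, key=imp.get, reverse=True)


def ablation_study(
    features_table: pd.DataFrame,
    config: RegressorConfig,
    plan: SplitPlan,
    drop_sets: list[list[str]],
) -> dict[str, RegressionReport]:
    """Baseline plus one report per drop set (features removed by name).

    Returns {"baseline": report, "drop:<names>": report, ...}.  Unknown
    feature names raise ValidationError.
    """
    for ds in drop_sets:
        unknown = [f for f in ds if f not in FEATURE_NAMES]
        if unknown:
            raise ValidationError(f"unknown feature names: {unknown}")
    out = {"baseline": train_and_evaluate(features_table, config, plan)}
    for ds in drop_sets:
        kept = [f for f in FEATURE_NAMES if f not in ds]
        key = "drop:" + ",".join(ds) if ds else "baseline(copy)"
        out[key] = train_and_evaluate(features_table, config, plan, kept)
    return out


def pearson_matrix(features_table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation among the 17 features and the true weight.

    Zero-variance columns yield NaN rows/columns rather than failing.
    """
    cols = [*FEATURE_NAMES, "weight_kg"]
    missing = [c for c in cols if c not in features_table.columns]
    if missing:
        raise ValidationError(f"missing columns for correlation: {missing}")
    df = features_table[cols].astype(float)
    if len(df) < 3:
        raise ValidationError("need ≥ 3 rows for a correlation matrix")
    if not np.isfinite(df.to_numpy()).all():
        raise ValidationError("non-finite values in feature table")
    corr = df.corr(method="pearson")
    # pandas leaves the diagonal 1.0 even for constant columns; mark them NaN
    const = df.std(ddof=0) == 0
    corr.loc[const, :] = np.nan
    corr.loc[:, const] = np.nan
    return corr
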
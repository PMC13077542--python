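"""QSAR regressors mapping selected molecular descriptors to relative logIE.

Three algorithm families are supported, the linear baseline and the two
tree ensembles that can capture nonlinear descriptor-IE structure:

- ``elastic_net``   — L1/L2-penalized linear regression (features are
  centered and scaled inside the model pipeline only);
- ``random_forest`` — bagged decision trees, 500 trees by default;
- ``gbt``           — gradient-boosted trees (XGBoost).

Hyperparameters are chosen by cross-validated RMSE over conventional
small-sample grids, then the winner is refit on the full training data.
Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import joblib
import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV, RepeatedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBRegressor

__all__ = [
    "ALGORITHMS",
    "ModelError",
    "SplitPlan",
    "FitMetrics",
    "IEModel",
    "make_split",
    "train",
    "evaluate",
    "importance",
    "save_model",
    "load_model",
]

ALGORITHMS = ("elastic_net", "random_forest", "gbt")

_BUNDLE_VERSION = 1


class ModelError(ValueError):
    """Invalid model configuration or state."""


@dataclass(frozen=True)
class SplitPlan:
    """A reproducible train/test partition of compound identifiers."""

    train_ids: tuple
    test_ids: tuple
    seed: int


def make_split(ids: Sequence[str], train_n: int, seed: int) -> SplitPlan:
    """Uniform random split without replacement (default study size 42/8)."""
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise ModelError("make_split: duplicate compound ids")
    if not 0 < train_n < len(ids):
        raise ModelError(
            f"make_split: train_n must be in (0, {len(ids)}), got {train_n}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    train = tuple(ids[i] for i in sorted(perm[:train_n]))
    test = tuple(ids[i] for i in sorted(perm[train_n:]))
    return SplitPlan(train_ids=train, test_ids=test, seed=seed)


@dataclass(frozen=True)
class FitMetrics:
    """RMSE (logIE units) and coefficient of determination.

    ``degenerate`` flags a zero-variance response, for which R^2 is not
    meaningful and is reported as 0.
    """

    rmse: float
    r2: float
    degenerate: bool = False


@dataclass
class IEModel:
    """A fitted descriptor -> relative-logIE regressor."""

    algorithm: str
    hyperparameters: dict
    estimator: object
    selected_features: list
    cv_record: pd.DataFrame
    seed: int
    degenerate: bool = False

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.selected_features if f not in X.columns]
        if missing:
            raise ModelError(f"predict: missing feature columns {missing}")
        return np.asarray(
            self.estimator.predict(X[self.selected_features].to_numpy(dtype=float)),
            dtype=float,
        )


def _default_grid(algorithm: str) -> tuple[object, dict]:
    if algorithm == "elastic_net":
        est = Pipeline(
            [("scale", StandardScaler()), ("enet", ElasticNet(max_iter=50_000))]
        )
        grid = {
            "enet__l1_ratio": [round(0.1 * k, 1) for k in range(1, 11)],
            "enet__alpha": np.logspace(-4, 0.5, 8).tolist(),
        }
    elif algorithm == "random_forest":
        est = RandomForestRegressor(n_estimators=500, n_jobs=1)
        grid = {"max_features": [1.0 / 3.0, "sqrt", 0.5]}
    elif algorithm == "gbt":
        est = XGBRegressor(
            objective="reg:squarederror",
            tree_method="hist",
            n_jobs=1,
            verbosity=0,
        )
        grid = {
            "max_depth": [2, 3],
            "learning_rate": [0.05, 0.1],
            "n_estimators": [200, 500],
        }
    else:
        raise ModelError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    return est, grid


def _seed_estimator(est: object, seed: int) -> None:
    if isinstance(est, Pipeline):
        return  # ElasticNet path is deterministic
    est.set_params(random_state=seed)


def train(
    X: pd.DataFrame,
    y: Sequence[float],
    algorithm: str = "gbt",
    hyper_grid: Optional[Mapping[str, Sequence]] = None,
    folds: int = 5,
    seed: int = 0,
) -> IEModel:
    """Tune by cross-validated RMSE over the grid, refit on all rows.

    ``hyper_grid`` overrides the built-in grid; an explicitly empty grid is
    a configuration error.
    """
    y = np.asarray(y, dtype=float)
    if X.shape[0] != len(y):
        raise ModelError(f"train: X has {X.shape[0]} rows for {len(y)} responses")
    if not np.isfinite(X.to_numpy(dtype=float)).all():
        raise ModelError("train: X contains missing/non-finite values")
    est, grid = _default_grid(algorithm)
    if hyper_grid is not None:
        grid = {k: list(v) for k, v in hyper_grid.items()}
        if not grid or any(len(v) == 0 for v in grid.values()):
            raise ModelError("train: empty hyperparameter grid")
    _seed_estimator(est, seed)

    degenerate = bool(np.ptp(y) == 0)
    Xv = X.to_numpy(dtype=float)
    # repeated CV stabilizes tuning at small n (a 5-fold split of ~40 rows is noisy)
    cv = RepeatedKFold(
        n_splits=min(folds, len(y)), n_repeats=2, random_state=seed
    )
    search = GridSearchCV(
        est,
        grid,
        scoring="neg_root_mean_squared_error",
        cv=cv,
        refit=True,
        n_jobs=1,
    )
    search.fit(Xv, y)
    cv_record = pd.DataFrame(search.cv_results_)[
        ["params", "mean_test_score", "std_test_score", "rank_test_score"]
    ].assign(cv_rmse=lambda d: -d["mean_test_score"])
    return IEModel(
        algorithm=algorithm,
        hyperparameters=dict(search.best_params_),
        estimator=search.best_estimator_,
        selected_features=[str(c) for c in X.columns],
        cv_record=cv_record,
        seed=seed,
        degenerate=degenerate,
    )


def evaluate(model: IEModel, X: pd.DataFrame, y: Sequence[float]) -> FitMetrics:
    """RMSE and R^2 = 1 - SSE/SST of ``model`` on ``(X, y)``."""
    y = np.asarray(y, dtype=float)
    pred = model.predict(X)
    resid = pred - y
    rmse = float(np.sqrt(np.mean(resid**2)))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return FitMetrics(rmse=rmse, r2=0.0, degenerate=True)
    r2 = 1.0 - float(np.sum(resid**2)) / sst
    return FitMetrics(rmse=rmse, r2=r2)


def importance(model: IEModel, top_k: Optional[int] = None) -> list:
    """Ranked (feature, score) list; scores are >=0 and sum to 1.

    Tree models report impurity/gain importances; the elastic net reports
    absolute standardized coefficients.  Ties are broken by feature name.
    """
    est = model.estimator
    if isinstance(est, Pipeline):
        coefs = np.abs(est.named_steps["enet"].coef_)
    elif hasattr(est, "feature_importances_"):
        coefs = np.asarray(est.feature_importances_, dtype=float)
    else:  # pragma: no cover - all supported estimators expose one of the above
        raise ModelError(f"no importances for algorithm {model.algorithm!r}")
    total = coefs.sum()
    if total <= 0:
        scores = np.full(len(coefs), 1.0 / len(coefs))
    else:
        scores = coefs / total
    ranked = sorted(
        zip(model.selected_features, scores.tolist()), key=lambda t: (-t[1], t[0])
    )
    if top_k is not None:
        ranked = ranked[:top_k]
    return ranked


# ---------------------------------------------------------------------------
# Persistence: a versioned on-disk bundle (meta sidecar + fitted state)


def save_model(model: IEModel, directory: Union[str, Path]) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "bundle_version": _BUNDLE_VERSION,
        "algorithm": model.algorithm,
        "hyperparameters": {k: v for k, v in model.hyperparameters.items()},
        "selected_features": model.selected_features,
        "seed": model.seed,
        "degenerate": model.degenerate,
    }
    pd.Series(meta, dtype=object).to_json(d / "meta.json", indent=2)
    joblib.dump(model.estimator, d / "estimator.joblib")
    model.cv_record.to_csv(d / "cv_record.csv", index=False)
    return d


def load_model(directory: Union[str, Path]) -> IEModel:
    d = Path(directory)
    meta = pd.read_json(d / "meta.json", typ="series")
    if int(meta["bundle_version"]) != _BUNDLE_VERSION:
        raise ModelError(f"unsupported model bundle version {meta['bundle_version']}")
    return IEModel(
        algorithm=str(meta["algorithm"]),
        hyperparameters=dict(meta["hyperparameters"]),
        estimator=joblib.load(d / "estimator.joblib"),
        selected_features=list(meta["selected_features"]),
        cv_record=pd.read_csv(d / "cv_record.csv"),
        seed=int(meta["seed"]),
        degenerate=bool(meta["degenerate"]),
    )
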
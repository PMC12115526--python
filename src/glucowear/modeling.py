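"""Feature selection and regression: split, RF-importance ranking, pipelines.

Protocol: an 80/20 random train-test split of the epoch-level feature table,
random-forest impurity-importance ranking computed on the training partition
only with the top 30 features retained, then median-imputer -> standard
scaler -> regressor pipelines for four families (linear regression LR, ridge
RR, random forest RFR, gradient-boosted trees XR), tuned by grid search with
5-fold cross-validation (selection criterion: mean CV RMSE) and refit on the
full training partition.  The whole procedure is repeated across seeds and
the per-repetition metrics are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBRegressor

from .clinical import prediction_metrics
from .dataio import feature_columns

MODEL_FAMILIES = ("LR", "RR", "RFR", "XR")

#: Conventional, config-overridable hyperparameter grids per family.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "LR": {},
    "RR": {"regressor__alpha": [0.01, 0.1, 1.0, 10.0, 100.0]},
    "RFR": {
        "regressor__n_estimators": [100, 300],
        "regressor__max_depth": [None, 10, 20],
        "regressor__min_samples_leaf": [1, 5],
    },
    "XR": {
        "regressor__n_estimators": [100, 300],
        "regressor__max_depth": [3, 6],
        "regressor__learning_rate": [0.05, 0.1],
        "regressor__subsample": [0.8, 1.0],
    },
}


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------


@dataclass
class SplitResult:
    train_idx: np.ndarray
    test_idx: np.ndarray
    fraction: float
    seed: int


def split_train_test(
    table: pd.DataFrame,
    fraction: float = 0.8,
    seed: int = 0,
    by: str = "epoch",
) -> SplitResult:
    """Random train/test split of the epoch table.

    ``by="epoch"`` (default) is a pooled uniform row split with
    |train| = round(fraction * n).  ``by="participant"`` keeps each
    participant's epochs together (leakage-robust): participants are
    shuffled and assigned to the training set until it holds at least
    ``fraction`` of the rows.
    """
    n = len(table)
    if n < 10:
        raise ValueError(f"need at least 10 rows to split, got {n}")
    rng = np.random.default_rng(seed)
    if by == "participant":
        pids = table["participant_id"].to_numpy()
        unique = rng.permutation(np.unique(pids))
        if len(unique) < 2:
            raise ValueError("participant-level split needs >= 2 participants")
        train_mask = np.zeros(n, dtype=bool)
        taken = 0
        for pid in unique:
            if taken >= fraction * n:
                break
            mask = pids == pid
            train_mask |= mask
            taken += int(mask.sum())
        if train_mask.all():  # keep at least one test participant
            train_mask[pids == unique[-1]] = False
        train_idx = np.flatnonzero(train_mask)
        test_idx = np.flatnonzero(~train_mask)
    elif by == "epoch":
        n_train = int(round(fraction * n))
        perm = rng.permutation(n)
        train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    else:
        raise ValueError(f"unknown split granularity {by!r}")
    return SplitResult(
        train_idx=train_idx, test_idx=test_idx, fraction=fraction, seed=seed
    )


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------


@dataclass
class SelectionResult:
    ranking: pd.DataFrame  # feature_name, importance, rank
    retained: list[str]
    seed: int


def rank_and_select(
    train: pd.DataFrame,
    k: int = 30,
    seed: int = 0,
    n_estimators: int = 100,
    max_features: str | float = "sqrt",
) -> SelectionResult:
    """Impurity-based RF importance ranking on the training table; keep top-k.

    Missing feature values are median-imputed before the selector forest is
    fitted.  Ties in importance are broken by manifest (column) order.
    """
    feats = feature_columns(train)
    x = SimpleImputer(strategy="median").fit_transform(train[feats])
    y = train["glucose"].to_numpy(dtype=np.float64)
    forest = RandomForestRegressor(
        n_estimators=n_estimators,
        max_features=max_features,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(x, y)
    importances = forest.feature_importances_
    order = np.argsort(-importances, kind="stable")  # stable => manifest order ties
    ranking = pd.DataFrame(
        {
            "feature_name": [feats[i] for i in order],
            "importance": importances[order],
            "rank": np.arange(1, len(feats) + 1),
        }
    )
    if k > len(feats):
        import warnings

        warnings.warn(f"k={k} exceeds surviving features ({len(feats)}); keeping all")
        k = len(feats)
    return SelectionResult(
        ranking=ranking, retained=ranking["feature_name"].head(k).tolist(), seed=seed
    )


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------


@dataclass
class FittedModel:
    family: str
    pipeline: Pipeline
    features: list[str]
    best_params: dict
    cv_table: pd.DataFrame  # one row per grid point: params, mean CV RMSE

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.pipeline.predict(table[self.features])


def _make_regressor(family: str, seed: int):
    if family == "LR":
        return LinearRegression()
    if family == "RR":
        return Ridge(alpha=1.0, random_state=seed)
    if family == "RFR":
        return RandomForestRegressor(random_state=seed, n_jobs=1)
    if family == "XR":
        return XGBRegressor(
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            verbosity=0,
            objective="reg:squarederror",
        )
    raise ValueError(f"unknown model family {family!r}")


def fit_model(
    family: str,
    train: pd.DataFrame,
    retained: SelectionResult | Sequence[str],
    grid: dict[str, list] | None = None,
    seed: int = 0,
    cv_folds: int = 5,
) -> FittedModel:
    """Fit one family's imputer -> scaler -> regressor pipeline on ``train``.

    ``grid`` maps pipeline parameter names (``regressor__*``) to candidate
    values; grids with more than one point are searched by ``cv_folds``-fold
    CV minimising mean RMSE, then the winner is refit on the full partition.
    """
    feats = list(retained.retained if isinstance(retained, SelectionResult) else retained)
    if grid is None:
        grid = DEFAULT_GRIDS.get(family, {})
    y = train["glucose"].to_numpy(dtype=np.float64)
    if np.std(y) == 0:
        raise ValueError("constant glucose target: cannot fit")
    pipe = Pipeline(
        [
            ("imputer", SimpleImputer(strategy="median")),
            ("scaler", StandardScaler()),
            ("regressor", _make_regressor(family, seed)),
        ]
    )
    n_points = int(np.prod([len(v) for v in grid.values()])) if grid else 1
    if n_points > 1:
        search = GridSearchCV(
            pipe,
            param_grid=grid,
            scoring="neg_root_mean_squared_error",
            cv=KFold(n_splits=cv_folds, shuffle=True, random_state=seed),
            n_jobs=1,
            refit=True,
        )
        search.fit(train[feats], y)
        cv_table = pd.DataFrame(
            {
                "params": [str(p) for p in search.cv_results_["params"]],
                "mean_cv_rmse": -search.cv_results_["mean_test_score"],
            }
        )
        return FittedModel(family, search.best_estimator_, feats,
                           dict(search.best_params_), cv_table)
    params = {key: vals[0] for key, vals in grid.items()}
    pipe.set_params(**params)
    pipe.fit(train[feats], y)
    cv_table = pd.DataFrame({"params": [str(params)], "mean_cv_rmse": [np.nan]})
    return FittedModel(family, pipe, feats, params, cv_table)


# ---------------------------------------------------------------------------
# Repetition protocol
# ---------------------------------------------------------------------------


@dataclass
class RepetitionReport:
    per_repetition: pd.DataFrame  # repetition, seed, model, r2, rmse, nrmse, mard
    aggregate: pd.DataFrame  # model, metric -> mean, sd
    selections: list[SelectionResult] = field(default_factory=list)
    predictions: pd.DataFrame | None = None  # reference/predicted per model/rep


def run_protocol(
    table: pd.DataFrame,
    n_reps: int = 20,
    base_seed: int = 0,
    families: Sequence[str] = MODEL_FAMILIES,
    grids: dict[str, dict] | None = None,
    k: int = 30,
    fraction: float = 0.8,
    selector_n_estimators: int = 100,
    cv_folds: int = 5,
    keep_predictions: bool = False,
) -> RepetitionReport:
    """Split -> select -> fit -> evaluate, repeated under ``n_reps`` seeds.

    Repetition ``i`` uses ``base_seed + i`` for the split, the selector
    forest and the regressors; feature selection is repeated per repetition
    so it only ever sees that repetition's training partition.
    """
    rows = []
    selections: list[SelectionResult] = []
    pred_rows = []
    for i in range(n_reps):
        seed = base_seed + i
        try:
            split = split_train_test(table, fraction, seed)
            train = table.iloc[split.train_idx]
            test = table.iloc[split.test_idx]
            selection = rank_and_select(
                train, k=k, seed=seed, n_estimators=selector_n_estimators
            )
            selections.append(selection)
            for family in families:
                grid = (grids or {}).get(family, None)
                model = fit_model(family, train, selection, grid, seed, cv_folds)
                pred = model.predict(test)
                ref = test["glucose"].to_numpy(dtype=np.float64)
                metrics = prediction_metrics(ref, pred)
                rows.append({"repetition": i, "seed": seed, "model": family, **metrics})
                if keep_predictions:
                    pred_rows.append(
                        pd.DataFrame(
                            {
                                "participant_id": test["participant_id"].to_numpy(),
                                "glucose_time": test["glucose_time"].to_numpy(),
                                "reference": ref,
                                "predicted": pred,
                                "model": family,
                                "repetition": i,
                            }
                        )
                    )
        except Exception as exc:
            raise RuntimeError(f"repetition {i} (seed {seed}) failed: {exc}") from exc
    per_rep = pd.DataFrame(rows)
    agg = (
        per_rep.groupby("model")[["r2", "rmse", "nrmse", "mard"]]
        .agg(["mean", "std"])
        .fillna(0.0)
    )
    return RepetitionReport(
        per_repetition=per_rep,
        aggregate=agg,
        selections=selections,
        predictions=pd.concat(pred_rows, ignore_index=True) if pred_rows else None,
    )
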
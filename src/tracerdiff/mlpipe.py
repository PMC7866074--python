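"""QSPR pipeline: collinearity-based variable selection, [0,1] scaling,
five regression algorithms behind one contract, grid search with 4-fold
cross-validation, and y-randomization validation.

The learning machinery is scikit-learn; this module owns the selection
procedure, the scaling contract (train columns map exactly onto [0,1], test
rows are *not* clipped), model serialization, and the permutation test.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.tree import DecisionTreeRegressor

from .compounds import CompoundTable
from .dataset import DiffusionRecord

__all__ = [
    "FEATURES",
    "TARGET",
    "POLAR_VARIABLES",
    "NONPOLAR_VARIABLES",
    "feature_frame",
    "abs_pearson_matrix",
    "SelectionResult",
    "select_variables",
    "ScalerParams",
    "fit_scaler",
    "apply_scaler",
    "ALGORITHMS",
    "default_grids",
    "TrainedModel",
    "grid_search_train",
    "predict",
    "save_model",
    "load_model",
    "YRandResult",
    "y_randomization",
]

#: The candidate model variables (everything measured per record or joined
#: from the compound table; D12 is the target, never a feature).
FEATURES = [
    "T", "rho1", "mu1", "M1", "M2", "Tc1", "Tc2", "Tb1", "Tb2",
    "Pc1", "Pc2", "Vc1", "Vc2", "w1", "w2",
    "sigma_lj1", "sigma_lj2", "eps_lj1", "eps_lj2",
]
TARGET = "D12"

#: Reference variable sets of the published polar/nonpolar models.
POLAR_VARIABLES = ["T", "mu1", "M2", "Pc2", "M1", "eps_lj1"]
NONPOLAR_VARIABLES = ["T", "mu1", "M2", "Pc2", "M1"]


def feature_frame(
    records: Iterable[DiffusionRecord], compounds: CompoundTable
) -> pd.DataFrame:
    """Resolve records against a compound table into the full variable table.

    Returns one row per record with the 19 candidate variables, the target
    D12, and bookkeeping columns `system` and `polarity`.
    """
    rows = []
    for r in records:
        sv = compounds.lookup(r.solvent)
        su = compounds.lookup(r.solute)
        rows.append(
            {
                "T": r.T, "rho1": r.rho1, "mu1": r.mu1,
                "M1": sv.M, "M2": su.M,
                "Tc1": sv.Tc, "Tc2": su.Tc, "Tb1": sv.Tb, "Tb2": su.Tb,
                "Pc1": sv.Pc, "Pc2": su.Pc, "Vc1": sv.Vc, "Vc2": su.Vc,
                "w1": sv.w, "w2": su.w,
                "sigma_lj1": sv.sigma_lj, "sigma_lj2": su.sigma_lj,
                "eps_lj1": sv.eps_lj_over_kB, "eps_lj2": su.eps_lj_over_kB,
                TARGET: r.D12,
                "system": f"{r.solvent}|{r.solute}",
                "polarity": r.polarity,
            }
        )
    return pd.DataFrame(rows)


def abs_pearson_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Absolute Pearson correlation matrix of the numeric columns.

    Requires >= 3 rows; a constant column makes the correlation undefined
    and raises, naming the column.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 records for a correlation matrix")
    for col in table.columns:
        if table[col].nunique() <= 1:
            raise ValueError(f"column {col!r} is constant; correlation undefined")
    return table.corr(method="pearson").abs()


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of collinearity filtering.

    `kept` preserves the input variable order; each entry of `dropped` is
    (variable, reason).
    """

    kept: tuple[str, ...]
    dropped: tuple[tuple[str, str], ...]
    threshold: float


def select_variables(
    corr: pd.DataFrame,
    target_corr: Mapping[str, float],
    threshold: float = 0.50,
    preference_order: Sequence[str] | None = None,
) -> SelectionResult:
    """Iteratively remove collinear variables.

    While any kept pair has |Pearson| above `threshold`, take the
    worst-offending pair (largest |Pearson|) and drop the member with the
    lower |correlation with D12|. Exact ties fall back on
    `preference_order` (earlier = preferred, e.g. easier to obtain); with no
    order given, the variable appearing later in `corr` is dropped. The
    result satisfies: every kept pairwise |Pearson| <= threshold.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    variables = list(corr.columns)
    pref = {v: i for i, v in enumerate(preference_order or variables)}
    kept = list(variables)
    dropped: list[tuple[str, str]] = []
    while True:
        worst: tuple[float, str, str] | None = None
        for i, u in enumerate(kept):
            for v in kept[i + 1:]:
                r = abs(float(corr.loc[u, v]))
                if r > threshold and (worst is None or r > worst[0]):
                    worst = (r, u, v)
        if worst is None:
            break
        r, u, v = worst
        cu, cv = abs(target_corr[u]), abs(target_corr[v])
        if cu != cv:
            loser, winner = (u, v) if cu < cv else (v, u)
        else:
            loser, winner = (v, u) if pref.get(u, 1 << 30) <= pref.get(v, 1 << 30) else (u, v)
        kept.remove(loser)
        dropped.append(
            (loser, f"collinear with {winner} (|r|={r:.3f} > {threshold:.2f})")
        )
    return SelectionResult(kept=tuple(kept), dropped=tuple(dropped), threshold=threshold)


@dataclass(frozen=True)
class ScalerParams:
    """Per-variable (min, max) bounds learned on training data."""

    bounds: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for var, (lo, hi) in self.bounds.items():
            if hi < lo:
                raise ValueError(f"{var}: max < min")


def fit_scaler(train: pd.DataFrame) -> ScalerParams:
    """Learn [0,1] normalization bounds on training rows only.

    A constant column cannot be scaled and raises.
    """
    bounds = {}
    for col in train.columns:
        lo, hi = float(train[col].min()), float(train[col].max())
        if hi == lo:
            raise ValueError(f"column {col!r} is degenerate (max == min)")
        bounds[col] = (lo, hi)
    return ScalerParams(bounds=bounds)


def apply_scaler(params: ScalerParams, table: pd.DataFrame) -> pd.DataFrame:
    """Affine map of each column onto the training [0,1] range.

    Values outside the training range map outside [0,1]; they are
    deliberately not clipped so the models can extrapolate.
    """
    out = table.copy()
    for col, (lo, hi) in params.bounds.items():
        if col not in out.columns:
            raise KeyError(f"missing variable {col!r}")
        out[col] = (out[col] - lo) / (hi - lo)
    return out[list(params.bounds)]


def _make_estimator(algorithm: str, seed: int):
    if algorithm == "mlr":
        return LinearRegression()
    if algorithm == "knn":
        return KNeighborsRegressor()
    if algorithm == "dtree":
        return DecisionTreeRegressor(random_state=seed)
    if algorithm == "rforest":
        return RandomForestRegressor(random_state=seed)
    if algorithm == "gboost":
        return GradientBoostingRegressor(random_state=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {list(ALGORITHMS)}")


ALGORITHMS = ("mlr", "knn", "dtree", "rforest", "gboost")

_GRIDS: dict | None = None


def default_grids() -> dict[str, dict[str, list]]:
    """Hyper-parameter grids, loaded from the packaged grids.json."""
    global _GRIDS
    if _GRIDS is None:
        src = resources.files("tracerdiff.data").joinpath("grids.json")
        _GRIDS = json.loads(src.read_text())
    return json.loads(json.dumps(_GRIDS))  # deep copy


@dataclass
class TrainedModel:
    """A fitted pipeline: variable selection -> scaler -> regressor."""

    algorithm: str
    hyper_params: dict
    selection: SelectionResult
    scaler: ScalerParams
    seed: int
    cv_score: float
    estimator: object = field(repr=False)


def grid_search_train(
    algorithm: str,
    train: pd.DataFrame,
    grid: Mapping[str, list] | None = None,
    folds: int = 4,
    seed: int = 0,
    selection: SelectionResult | Sequence[str] | None = None,
    target: str = TARGET,
) -> TrainedModel:
    """Exhaustive grid search with seeded k-fold cross-validation.

    Folds are contiguous blocks after one seeded shuffle of the training
    rows. Each candidate is scored by the mean validation coefficient of
    determination; ties resolve to the first candidate in grid order. The
    winner is refit on the full training set.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if grid is None:
        grid = default_grids()[algorithm]
    if len(train) < folds:
        raise ValueError(f"need at least {folds} training rows")
    if isinstance(selection, SelectionResult):
        variables = list(selection.kept)
    elif selection is not None:
        variables = list(selection)
        selection = SelectionResult(kept=tuple(variables), dropped=(), threshold=1.0)
    else:
        variables = [c for c in FEATURES if c in train.columns]
        selection = SelectionResult(kept=tuple(variables), dropped=(), threshold=1.0)
    missing = [v for v in variables if v not in train.columns]
    if missing:
        raise KeyError(f"missing variable(s) in training table: {missing}")

    scaler = fit_scaler(train[variables])
    X = apply_scaler(scaler, train[variables]).to_numpy()
    y = train[target].to_numpy()
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        _make_estimator(algorithm, seed),
        param_grid=dict(grid),
        cv=cv,
        scoring="r2",
        refit=True,
    )
    search.fit(X, y)
    return TrainedModel(
        algorithm=algorithm,
        hyper_params=dict(search.best_params_),
        selection=selection,
        scaler=scaler,
        seed=seed,
        cv_score=float(search.best_score_),
        estimator=search.best_estimator_,
    )


def predict(model: TrainedModel, table: pd.DataFrame) -> np.ndarray:
    """Apply stored selection, scaler and regressor to new rows."""
    missing = [v for v in model.selection.kept if v not in table.columns]
    if missing:
        raise KeyError(f"missing variable(s): {missing}")
    X = apply_scaler(model.scaler, table[list(model.selection.kept)]).to_numpy()
    return np.asarray(model.estimator.predict(X), dtype=float)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize to `<path>.json` (metadata) plus `<path>.joblib` (blob)."""
    path = Path(path)
    meta = {
        "algorithm": model.algorithm,
        "hyper_params": model.hyper_params,
        "selection": asdict(model.selection),
        "scaler": {k: list(v) for k, v in model.scaler.bounds.items()},
        "seed": model.seed,
        "cv_score": model.cv_score,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    joblib.dump(model.estimator, path.with_suffix(".joblib"))


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    sel = meta["selection"]
    return TrainedModel(
        algorithm=meta["algorithm"],
        hyper_params=meta["hyper_params"],
        selection=SelectionResult(
            kept=tuple(sel["kept"]),
            dropped=tuple((a, b) for a, b in sel["dropped"]),
            threshold=float(sel["threshold"]),
        ),
        scaler=ScalerParams(
            bounds={k: (float(a), float(b)) for k, (a, b) in meta["scaler"].items()}
        ),
        seed=int(meta["seed"]),
        cv_score=float(meta["cv_score"]),
        estimator=joblib.load(path.with_suffix(".joblib")),
    )


@dataclass(frozen=True)
class YRandResult:
    """Original test-set Q2 against the permuted-target distribution."""

    original_q2: float
    permuted_q2: tuple[float, ...]


def y_randomization(
    algorithm: str,
    train: pd.DataFrame,
    test: pd.DataFrame,
    grid: Mapping[str, list] | None = None,
    n_perm: int = 200,
    seed: int = 0,
    folds: int = 4,
    selection: SelectionResult | Sequence[str] | None = None,
    target: str = TARGET,
) -> YRandResult:
    """y-scrambling validation.

    For each permutation the training targets are shuffled, the identical
    grid-search build is rerun, and Q2 is scored on the untouched test set.
    A model fitting real structure should beat every scrambled rebuild.
    """
    from .evaluation import r_squared

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    original = grid_search_train(
        algorithm, train, grid=grid, folds=folds, seed=seed, selection=selection,
        target=target,
    )
    q2_orig = r_squared(predict(original, test), test[target].to_numpy())
    rng = np.random.default_rng(seed)
    scores = []
    shuffled = train.copy()
    for _ in range(n_perm):
        shuffled[target] = rng.permutation(train[target].to_numpy())
        m = grid_search_train(
            algorithm, shuffled, grid=grid, folds=folds, seed=seed,
            selection=selection, target=target,
        )
        scores.append(r_squared(predict(m, test), test[target].to_numpy()))
    return YRandResult(original_q2=float(q2_orig), permuted_q2=tuple(scores))
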
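"""Step 2 — random-forest regression of station BP on environment + occurrence.

For each species, the log-scaled station BP_p is regressed on the seven
environmental predictors plus the step-1 consensus probability of occurrence.
The model is evaluated by k-fold cross-validation (MAE/RMSE and their percent
of the mean observed BP), per-cell BP surfaces are predicted for every scenario
year, and the zero-inflated mask sets BP to zero wherever the binary occurrence
map says absence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import StratifiedKFold

from .grids import ALL_LAYERS, EnvStack, Surface

PREDICTORS = list(ALL_LAYERS) + ["occ_prob"]
RESPONSE = "bp_log"

#: a species needs at least this many sampled presences to be modelled
MIN_PRESENCES = 12
#: presence count at and above which 10-fold cross-validation applies
TEN_FOLD_MIN_PRESENCES = 50


class UnmodellableSpeciesError(ValueError):
    """Too few sampled presences to cross-validate the BP regression."""


@dataclass
class RegressionEvaluation:
    species: str
    n_folds: int
    mae: float
    rmse: float
    mae_pct: float
    rmse_pct: float
    importance: dict[str, float] = field(default_factory=dict)


def choose_n_folds(n_presences: int) -> int:
    """10-fold CV for >= 50 presences, else 6-fold (keeps ~5 nonzero rows per fold)."""
    if n_presences < MIN_PRESENCES:
        raise UnmodellableSpeciesError(
            f"{n_presences} presences < {MIN_PRESENCES}; species cannot be modelled"
        )
    return 10 if n_presences >= TEN_FOLD_MIN_PRESENCES else 6


def validate_regression_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PREDICTORS + [RESPONSE] if c not in table.columns]
    if missing:
        raise ValueError(f"regression table missing columns: {missing}")
    sub = table[PREDICTORS + [RESPONSE]]
    if sub.isna().any().any():
        raise ValueError("regression table contains missing values")
    if ((table["occ_prob"] < 0) | (table["occ_prob"] > 1)).any():
        raise ValueError("occ_prob outside [0, 1]")
    if (table[RESPONSE] < 0).any():
        raise ValueError("bp_log must be non-negative")
    return table


def fit_bp_model(
    table: pd.DataFrame, seed: int = 0, n_trees: int = 500, min_samples_leaf: int = 20
) -> RandomForestRegressor:
    """Random-forest regression on all rows (bagged trees, random predictor subsets,
    mean aggregation over trees).

    Rows are sorted canonically before fitting so the model is invariant to the
    input row order given the same seed.
    """
    validate_regression_table(table)
    X = table[PREDICTORS].to_numpy(dtype=float)
    y = table[RESPONSE].to_numpy(dtype=float)
    if np.ptp(y) == 0 and all(np.ptp(X[:, j]) == 0 for j in range(X.shape[1])):
        raise ValueError("degenerate table: constant predictors and response")
    order = np.lexsort(tuple(X[:, j] for j in range(X.shape[1])) + (y,))
    model = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=ceil(len(PREDICTORS) / 3),
        min_samples_leaf=min_samples_leaf,
        random_state=seed,
    )
    model.fit(X[order], y[order])
    return model


def cross_validate(
    table: pd.DataFrame,
    n_folds: int,
    seed: int = 0,
    species: str = "species",
    model_factory=None,
) -> RegressionEvaluation:
    """k-fold CV pooled over held-out rows, folds stratified on zero/nonzero BP.

    MAE and RMSE are on the bp_log scale; the percent versions divide by the
    mean observed bp_log over all stations.  `model_factory(train_table, seed)`
    must return an object with predict(X); defaults to fit_bp_model.
    """
    validate_regression_table(table)
    if len(table) < n_folds:
        raise ValueError("fewer rows than folds")
    y = table[RESPONSE].to_numpy(dtype=float)
    if (y == 0).all():
        raise ValueError("all-zero response; nothing to cross-validate")
    if model_factory is None:
        model_factory = fit_bp_model
    nonzero = (y > 0).astype(int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    preds = np.empty_like(y)
    for fold, (train_idx, test_idx) in enumerate(skf.split(table, nonzero)):
        model = model_factory(table.iloc[train_idx], seed + fold)
        preds[test_idx] = model.predict(table.iloc[test_idx][PREDICTORS].to_numpy(dtype=float))
    err = preds - y
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    mean_bp = float(np.mean(y))
    return RegressionEvaluation(
        species=species,
        n_folds=n_folds,
        mae=mae,
        rmse=rmse,
        mae_pct=100.0 * mae / mean_bp,
        rmse_pct=100.0 * rmse / mean_bp,
    )


def variable_importance(model, table: pd.DataFrame, seed: int = 0, n_repeats: int = 5) -> dict[str, float]:
    """Permutation importance: increase in squared error when one predictor is
    shuffled, floored at 0 and normalised to sum 100."""
    validate_regression_table(table)
    X = table[PREDICTORS].to_numpy(dtype=float)
    y = table[RESPONSE].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    base_mse = float(np.mean((model.predict(X) - y) ** 2))
    raw = np.zeros(len(PREDICTORS))
    for j in range(len(PREDICTORS)):
        deltas = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            deltas.append(np.mean((model.predict(Xp) - y) ** 2) - base_mse)
        raw[j] = max(float(np.mean(deltas)), 0.0)
    if raw.sum() == 0:
        raw[:] = 1.0  # uninformative model: flat profile
    pct = 100.0 * raw / raw.sum()
    return dict(zip(PREDICTORS, pct))


def build_regression_table(
    bp_station: pd.DataFrame,
    station_cells: pd.DataFrame,
    env: EnvStack,
    occ: Surface,
    species: str,
    year: int,
) -> pd.DataFrame:
    """Assemble the per-station predictor/response table for one species.

    Predictors are the environmental layers at the station cell for `year` plus
    the consensus occurrence probability; the response is the station bp_log.
    """
    sub = bp_station[bp_station["species"] == species].set_index("station")
    cells = station_cells.loc[sub.index]
    cell_idx = cells[["row", "col"]].to_numpy()
    X = env.predictor_matrix(year, cells=cell_idx)
    table = pd.DataFrame(X, columns=list(ALL_LAYERS), index=sub.index)
    table["occ_prob"] = occ.values[cell_idx[:, 0], cell_idx[:, 1]]
    table[RESPONSE] = sub["bp_log"]
    return validate_regression_table(table.reset_index())


def predict_bp_surface(model, env: EnvStack, occ: Surface, year: int) -> Surface:
    """Per-cell BP prediction on the year's layers plus the occurrence surface."""
    if not occ.grid.matches(env.grid):
        raise ValueError("occurrence surface grid does not match the stack")
    if occ.year != year:
        raise ValueError(f"occurrence surface year {occ.year} != {year}")
    sea = env.sea_mask
    X_env = env.predictor_matrix(year)
    occ_vals = occ.values[sea][:, None]
    X = np.hstack([X_env, occ_vals])
    pred = model.predict(X)
    full = np.full(env.grid.shape, np.nan)
    full[sea] = pred
    return Surface(grid=env.grid, kind="bp", year=year, species=occ.species, values=full)


def zero_inflate_mask(bp: Surface, binary: Surface) -> Surface:
    """Hurdle mask: keep BP where presence is predicted, set 0 where absence."""
    if bp.species != binary.species or bp.year != binary.year:
        raise ValueError("bp and binary surfaces must share species and year")
    if not bp.grid.matches(binary.grid):
        raise ValueError("grid mismatch between bp and binary surfaces")
    values = np.where(binary.values == 1, bp.values, 0.0)
    values[~np.isfinite(bp.values)] = np.nan
    return Surface(grid=bp.grid, kind="bp", year=bp.year, species=bp.species, values=values)
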
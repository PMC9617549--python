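"""Step 1 — occurrence species distribution models.

Replicate presence/absence models are fitted with several algorithms on
stratified 70/30 splits, evaluated on the held-out 30% with AUC and TSS,
filtered at AUC >= 0.7 and TSS >= 0.4, merged into per-algorithm ensemble means
and an evaluation-weighted consensus probability surface, and binarised at the
cut-off maximising TSS at the survey stations.

Algorithm backends are thin adapters around scikit-learn estimators; the
pipeline logic — splitting, evaluation, filtering, ensembling, weighting,
cut-off search — lives here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from .grids import EnvStack, Surface
from .seeding import child_seed

log = logging.getLogger(__name__)

DEFAULT_ALGORITHMS = ("glm", "gbm", "rf")
AUC_MIN_DEFAULT = 0.7
TSS_MIN_DEFAULT = 0.4


@dataclass
class AlgorithmConfig:
    """Hyperparameters for the four candidate algorithms."""

    rf_mtry_candidates: tuple[int, ...] = (2, 3, 4, 5)
    rf_nodesize: int = 1
    rf_n_trees: int = 500
    rf_mtry: int | None = None  # set by tune_rf
    gbm_n_trees: int = 250
    gbm_learning_rate: float = 0.05
    gbm_depth: int = 3

    def __post_init__(self) -> None:
        if not set(self.rf_mtry_candidates) <= {2, 3, 4, 5}:
            raise ValueError("rf mtry candidates must be a subset of {2, 3, 4, 5}")


@dataclass
class ReplicateRun:
    """One fitted model replicate with its held-out evaluation."""

    species: str
    algorithm: str
    replicate: int
    model: object
    auc: float
    tss: float
    robust: bool


@dataclass
class ConsensusSurface:
    """Evaluation-weighted consensus probability surface with its binarisation."""

    species: str
    year: int
    probability: Surface
    weights: dict[tuple[str, int], float]
    cutoff: float | None = None
    binary: Surface | None = None


# ---------------------------------------------------------------------------
# Backends


class _SKBackend:
    """fit(X, y) / predict_prob(X) adapter over an sklearn classifier."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, X, y):
        self.estimator.fit(X, y)
        return self

    def predict_prob(self, X):
        proba = self.estimator.predict_proba(X)
        return proba[:, list(self.estimator.classes_).index(1)]


def make_backend(algorithm: str, config: AlgorithmConfig, seed: int, n_predictors: int) -> _SKBackend | None:
    """Instantiate a backend; returns None (with a logged notice) if unavailable."""
    if algorithm == "glm":
        return _SKBackend(LogisticRegression(C=np.inf, max_iter=2000))
    if algorithm == "gbm":
        return _SKBackend(
            GradientBoostingClassifier(
                n_estimators=config.gbm_n_trees,
                learning_rate=config.gbm_learning_rate,
                max_depth=config.gbm_depth,
                random_state=seed,
            )
        )
    if algorithm == "rf":
        mtry = config.rf_mtry or min(config.rf_mtry_candidates)
        if mtry > n_predictors:
            raise ValueError(f"mtry={mtry} exceeds the {n_predictors} available predictors")
        return _SKBackend(
            RandomForestClassifier(
                n_estimators=config.rf_n_trees,
                max_features=mtry,
                min_samples_leaf=config.rf_nodesize,
                random_state=seed,
            )
        )
    if algorithm == "mars":
        log.warning("no MARS backend is available; skipping the algorithm")
        return None
    raise ValueError(f"unknown algorithm {algorithm!r}")


# ---------------------------------------------------------------------------
# Evaluation metrics


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def auc_score(scores, labels) -> float:
    """Rank-based AUC (Mann-Whitney): P(score_pos > score_neg), ties credited 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    ranks = rankdata(scores)
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def tss_score(predictions, labels) -> float:
    """True Skill Statistic: sensitivity + specificity - 1."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    pos = labels == 1
    neg = labels == 0
    sensitivity = (predictions[pos] == 1).mean()
    specificity = (predictions[neg] == 0).mean()
    return float(sensitivity + specificity - 1.0)


def best_cutoff(scores, labels) -> tuple[float, float]:
    """Cut-off maximising TSS over midpoints of consecutive distinct scores.

    Returns (cutoff, achieved TSS); ties resolved towards the smallest cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    distinct = np.unique(scores)
    if len(distinct) < 2:
        raise ValueError("need at least two distinct scores to place a cutoff")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    best = (candidates[0], -np.inf)
    for cut in candidates:
        t = tss_score((scores >= cut).astype(int), labels)
        if t > best[1]:
            best = (float(cut), t)
    return best


# ---------------------------------------------------------------------------
# Replicates, tuning, ensembles, consensus


def fit_replicates(
    X,
    y,
    algorithm: str,
    config: AlgorithmConfig | None = None,
    n_reps: int = 20,
    train_frac: float = 0.7,
    seed: int = 0,
    species: str = "species",
    auc_min: float = AUC_MIN_DEFAULT,
    tss_min: float = TSS_MIN_DEFAULT,
) -> list[ReplicateRun]:
    """Fit `n_reps` replicates on independent stratified 70/30 splits.

    AUC and TSS are evaluated on the held-out 30%; TSS at the cut-off maximising
    TSS on the test scores.  A replicate is robust when auc >= auc_min and
    tss >= tss_min.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_two_classes(y)
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need at least 2 presences and 2 absences to stratify")
    config = config or AlgorithmConfig()
    runs: list[ReplicateRun] = []
    for rep in range(1, n_reps + 1):
        rep_seed = child_seed(seed, species, algorithm, rep)
        backend = make_backend(algorithm, config, rep_seed, X.shape[1])
        if backend is None:
            return []
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=train_frac, stratify=y, random_state=rep_seed
        )
        backend.fit(X_tr, y_tr)
        scores = backend.predict_prob(X_te)
        auc = auc_score(scores, y_te)
        try:
            _, tss = best_cutoff(scores, y_te)
        except ValueError:  # all test scores identical: no skill
            tss = 0.0
        runs.append(
            ReplicateRun(
                species=species,
                algorithm=algorithm,
                replicate=rep,
                model=backend,
                auc=auc,
                tss=tss,
                robust=bool(auc >= auc_min and tss >= tss_min),
            )
        )
    return runs


def select_mtry(scores: dict[int, float]) -> int:
    """Argmax over candidate mtry values; ties resolved to the smallest mtry."""
    best_score = max(scores.values())
    return min(m for m, s in scores.items() if s == best_score)


def tune_rf(
    X,
    y,
    mtry_candidates: tuple[int, ...] = (2, 3, 4, 5),
    config: AlgorithmConfig | None = None,
    n_reps: int = 20,
    seed: int = 0,
    species: str = "species",
) -> int:
    """Choose mtry maximising the replicate mean of (AUC + TSS) / 2."""
    X = np.asarray(X, dtype=float)
    if max(mtry_candidates) > X.shape[1]:
        raise ValueError("mtry candidate exceeds the number of predictors")
    config = config or AlgorithmConfig()
    scores: dict[int, float] = {}
    for mtry in mtry_candidates:
        cfg = AlgorithmConfig(
            rf_mtry_candidates=tuple(mtry_candidates),
            rf_nodesize=config.rf_nodesize,
            rf_n_trees=config.rf_n_trees,
            rf_mtry=mtry,
            gbm_n_trees=config.gbm_n_trees,
            gbm_learning_rate=config.gbm_learning_rate,
            gbm_depth=config.gbm_depth,
        )
        runs = fit_replicates(
            X, y, "rf", cfg, n_reps=n_reps, seed=child_seed(seed, "tune", mtry), species=species
        )
        scores[mtry] = float(np.mean([(r.auc + r.tss) / 2 for r in runs]))
    return select_mtry(scores)


def _project_runs(runs: list[ReplicateRun], env: EnvStack, year: int) -> np.ndarray:
    """(n_runs, n_sea_cells) probability projections on the year's layers."""
    X = env.predictor_matrix(year)
    return np.vstack([run.model.predict_prob(X) for run in runs])


def _surface_from_sea(values: np.ndarray, env: EnvStack, kind: str, year: int, species: str) -> Surface:
    full = np.full(env.grid.shape, np.nan)
    full[env.sea_mask] = values
    return Surface(grid=env.grid, kind=kind, year=year, species=species, values=full)


def ensemble_mean(runs: list[ReplicateRun], env: EnvStack, year: int) -> Surface:
    """Unweighted per-cell mean projection of one algorithm's robust runs."""
    robust = [r for r in runs if r.robust]
    if not robust:
        raise ValueError("no robust runs to ensemble")
    algorithms = {r.algorithm for r in robust}
    if len(algorithms) != 1:
        raise ValueError("ensemble_mean expects runs of a single algorithm")
    proj = _project_runs(robust, env, year)
    return _surface_from_sea(proj.mean(axis=0), env, "probability", year, robust[0].species)


def consensus(
    runs: list[ReplicateRun], env: EnvStack, year: int, weight_metric: str = "tss"
) -> ConsensusSurface:
    """Evaluation-weighted mean across all robust runs of all algorithms.

    Weights are proportional to the evaluation score (floored at 0) and sum to 1.
    """
    robust = [r for r in runs if r.robust]
    if not robust:
        raise ValueError("no robust runs across algorithms; species cannot be modelled")
    raw = np.array([max(getattr(r, weight_metric), 0.0) for r in robust])
    if raw.sum() <= 0:
        raise ValueError("all robust-run weights are zero")
    weights = raw / raw.sum()
    proj = _project_runs(robust, env, year)
    mean = weights @ proj
    surface = _surface_from_sea(mean, env, "probability", year, robust[0].species)
    weight_map = {(r.algorithm, r.replicate): float(w) for r, w in zip(robust, weights)}
    return ConsensusSurface(species=robust[0].species, year=year, probability=surface, weights=weight_map)


def binarize(probability: Surface, cutoff: float) -> Surface:
    """Presence/absence map: 1 where probability >= cutoff; land stays missing."""
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    values = np.where(np.isfinite(probability.values), (probability.values >= cutoff).astype(float), np.nan)
    return Surface(
        grid=probability.grid,
        kind="binary",
        year=probability.year,
        species=probability.species,
        values=values,
    )
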
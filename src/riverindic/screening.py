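"""Spatio-temporal bioindicator screening.

Downstream biological status (an ordered saprobic class) or chlorophyll *a*
is predicted from *upstream* bacterial abundances. Each candidate ASV enters
the design matrix through a (window ``w``, lag ``l``) feature: within each
transect, ordered upstream -> downstream, the value at site ``i`` is the
abundance at site ``i - l`` centered and scaled over the ``w`` sites ending
there. ``w = 1`` means the raw lagged value. Shifts never cross transect
boundaries, so no information flows between the left, center and right
series, and no engineered value ever depends on a downstream site.

The screening itself is: (1) a random-forest prefilter ranking ASVs by
permutation importance on a real-vs-permuted synthetic-class task, (2) a
per-ASV grid search over (w, l) evaluated with a gradient-boosted model on
an ordered train/test split (first 85% of observations by distance from the
source), and (3) greedy inclusion of ASVs that strictly improve the held-out
metric, repeated over many runs with randomized candidate order and
hyperparameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.metrics import mean_squared_error
import xgboost as xgb

from .io import Dataset

__all__ = [
    "LagSpec",
    "ScreenConfig",
    "HyperparameterSpace",
    "ScreeningModel",
    "ModelEnsemble",
    "PrefilterResult",
    "lagged_feature",
    "base_design",
    "lagged_design_matrix",
    "ordered_split",
    "rf_prefilter",
    "grid_search_asv",
    "greedy_screen",
    "ensemble_screen",
]

#: metric improvements below this tolerance do not count as "improved"
IMPROVEMENT_TOL = 1e-9


@dataclass(frozen=True, order=True)
class LagSpec:
    """One engineered feature: ASV *asv_id* at window *window*, lag *lag*."""

    asv_id: str
    window: int = 1
    lag: int = 0

    def __post_init__(self):
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.lag < 0:
            raise ValueError("lag must be >= 0")

    @property
    def column(self) -> str:
        return f"{self.asv_id}|w{self.window}|l{self.lag}"


def lagged_feature(values: np.ndarray, window: int, lag: int) -> np.ndarray:
    """Windowed-standardized lagged series for one transect.

    ``out[i] = (x[i-l] - mean(x[i-l-w+1 : i-l+1])) / sd(same w values)``
    with the sample (n-1) standard deviation; ``w = 1`` yields the raw
    lagged value. Warm-up: sites whose lagged window is not fully available
    use the truncated upstream part of the window (a single available value
    standardizes to 0), and sites with no lagged site at all carry the value
    of the earliest site that has one — so all transects keep equal length
    and no engineered value ever draws on a site downstream of its own.
    A zero within-window sd yields 0 for that site.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if lag >= n:
        raise ValueError(f"lag {lag} >= transect length {n}")
    if lag + window - 1 >= n:
        raise ValueError(
            f"window {window} + lag {lag} exceed transect length {n}"
        )
    out = np.empty(n)
    for i in range(lag, n):
        j = i - lag
        if window == 1:
            out[i] = x[j]
        else:
            w = x[max(0, j - window + 1) : j + 1]
            if len(w) < 2:
                out[i] = 0.0
            else:
                sd = w.std(ddof=1)
                out[i] = 0.0 if sd == 0 else (x[j] - w.mean()) / sd
    out[:lag] = out[lag]
    return out


def base_design(metadata: pd.DataFrame) -> pd.DataFrame:
    """Base design matrix: sample index, transect code, distance to mouth.

    The sample index and distance encode longitudinal position; the transect
    code keeps the three lateral series distinguishable.
    """
    transect = pd.Categorical(metadata["transect"].astype(str))
    return pd.DataFrame(
        {
            "sample_index": np.arange(len(metadata)),
            "transect_code": transect.codes.astype(int),
            "distance_to_mouth": metadata["distance_to_mouth"].to_numpy(float),
        },
        index=metadata.index,
    )


def lagged_design_matrix(
    base: pd.DataFrame,
    series: pd.DataFrame,
    specs: Sequence[LagSpec],
) -> pd.DataFrame:
    """Append one windowed/lagged column per spec to the base design.

    *base* must contain a ``transect_code`` column (see :func:`base_design`)
    and be row-aligned with *series*; rows must already be ordered
    upstream -> downstream within each transect. Engineered values at a site
    depend only on same-or-upstream sites of the same transect.
    """
    out = base.copy()
    codes = base["transect_code"].to_numpy()
    for spec in specs:
        if spec.asv_id not in series.columns:
            raise KeyError(f"unknown taxon {spec.asv_id!r}")
        col = np.empty(len(base))
        x = series[spec.asv_id].to_numpy(float)
        for code in np.unique(codes):
            sel = codes == code
            col[sel] = lagged_feature(x[sel], spec.window, spec.lag)
        out[spec.column] = col
    return out


def ordered_split(metadata: pd.DataFrame, train_fraction: float = 0.85):
    """Boolean train/test masks with the split after the first
    ``train_fraction`` of observations ordered by distance from the source
    (i.e. decreasing distance to mouth). The most downstream sites form the
    held-out set, so evaluation is a genuine downstream prediction."""
    dist = metadata["distance_to_mouth"].to_numpy(float)
    order = np.argsort(-dist, kind="stable")
    n_train = int(np.floor(train_fraction * len(dist)))
    train = np.zeros(len(dist), dtype=bool)
    train[order[:n_train]] = True
    return train, ~train


# ---------------------------------------------------------------------------
# random-forest prefilter
# ---------------------------------------------------------------------------

@dataclass
class PrefilterResult:
    mtry: int
    ntree: int
    importance: pd.Series  # per-ASV permutation importance, descending
    candidates: list[str]  # importance > 0, descending


def rf_prefilter(
    matrix: pd.DataFrame,
    chl: pd.Series | np.ndarray,
    mtry_grid: Sequence[int] | None = None,
    ntree_grid: Sequence[int] = (30, 100, 300),
    seed: int = 0,
    test_fraction: float = 0.2,
    n_repeats: int = 5,
) -> PrefilterResult:
    """Two-stage random-forest prefilter of the (Hellinger) ASV table.

    Stage 1 grid-searches (mtry, ntree) for a supervised forest predicting
    chlorophyll *a* on a seeded 0.8/0.2 split, keeping the pair with the
    lowest test MSE. Stage 2 trains, with those hyperparameters, a
    classification forest separating the real table from a column-permuted
    copy (the synthetic-class construction standing in for an unsupervised
    forest) and computes permutation importance of each ASV on that task.
    Candidates are the ASVs with importance > 0, in decreasing order.
    """
    if matrix.shape[0] < 20:
        raise ValueError("prefilter requires >= 20 samples")
    X = matrix.to_numpy(float)
    y = np.asarray(chl, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(seed)

    if mtry_grid is None:
        mtry_grid = sorted({max(1, int(round(np.sqrt(p)))), max(1, p // 3), max(1, p // 2)})
    mtry_grid = list(mtry_grid)
    for i, m in enumerate(mtry_grid):
        if m > p:
            warnings.warn(f"mtry={m} exceeds {p} ASVs; clamped to {p}")
            mtry_grid[i] = p
    mtry_grid = sorted(set(mtry_grid))

    perm = rng.permutation(n)
    n_test = max(1, int(round(test_fraction * n)))
    test_idx, train_idx = perm[:n_test], perm[n_test:]

    best: tuple[float, int, int] | None = None
    for ntree in ntree_grid:
        for mtry in mtry_grid:
            rf = RandomForestRegressor(
                n_estimators=int(ntree), max_features=int(mtry),
                random_state=seed, n_jobs=1,
            ).fit(X[train_idx], y[train_idx])
            mse = mean_squared_error(y[test_idx], rf.predict(X[test_idx]))
            key = (mse, int(ntree), int(mtry))
            if best is None or key < best:
                best = key
    _, ntree, mtry = best

    # real-vs-permuted synthetic classification task; importance is
    # evaluated on rows the forest never saw (the in-sample analogue of
    # out-of-bag importance), with a probability-based score so single
    # ASVs among hundreds still register
    X_perm = np.column_stack([rng.permutation(X[:, j]) for j in range(p)])
    X_all = np.vstack([X, X_perm])
    y_all = np.concatenate([np.ones(n), np.zeros(n)])
    holdout = rng.random(2 * n) < 0.3
    clf = RandomForestClassifier(
        n_estimators=ntree, max_features=mtry, random_state=seed, n_jobs=1
    ).fit(X_all[~holdout], y_all[~holdout])
    imp = permutation_importance(
        clf, X_all[holdout], y_all[holdout], n_repeats=n_repeats,
        random_state=seed, n_jobs=1, scoring="neg_log_loss",
    )
    importance = pd.Series(imp.importances_mean, index=matrix.columns)
    importance = importance.sort_values(ascending=False, kind="stable")
    candidates = list(importance.index[importance > 0])
    return PrefilterResult(mtry=mtry, ntree=ntree, importance=importance,
                           candidates=candidates)


# ---------------------------------------------------------------------------
# boosted-model evaluation
# ---------------------------------------------------------------------------

DEFAULT_XGB_PARAMS = {
    "n_estimators": 80,
    "max_depth": 3,
    "learning_rate": 0.2,
    "subsample": 1.0,
}


def _fit_eval(
    X: np.ndarray,
    y: np.ndarray,
    train: np.ndarray,
    test: np.ndarray,
    task: str,
    params: dict,
    seed: int,
) -> float:
    """Held-out metric of a boosted model: accuracy (classification on the
    status class) or R^2 (regression on chlorophyll *a*).

    Uses the native xgboost API with coarse histogram bins: the design
    matrices here are tiny (a few hundred rows, a handful of columns), so
    per-fit overhead dominates the screening cost.
    """
    booster_params = {
        "max_depth": int(params.get("max_depth", 3)),
        "eta": float(params.get("learning_rate", 0.2)),
        "subsample": float(params.get("subsample", 1.0)),
        "tree_method": "hist",
        "max_bin": 32,
        "nthread": 1,
        "seed": seed % (2**31 - 1),
        "verbosity": 0,
    }
    n_rounds = int(params.get("n_estimators", 80))
    if task == "status":
        if len(np.unique(y[train])) < 2:
            raise ValueError("response constant on the training split")
        booster_params.update(
            objective="multi:softmax", num_class=int(y.max()) + 1
        )
        dtrain = xgb.DMatrix(X[train], label=y[train])
        bst = xgb.train(booster_params, dtrain, num_boost_round=n_rounds)
        pred = bst.predict(xgb.DMatrix(X[test]))
        return float(np.mean(pred == y[test]))
    elif task == "chla":
        if np.std(y[train]) == 0:
            raise ValueError("response constant on the training split")
        booster_params.update(objective="reg:squarederror")
        dtrain = xgb.DMatrix(X[train], label=y[train])
        bst = xgb.train(booster_params, dtrain, num_boost_round=n_rounds)
        pred = bst.predict(xgb.DMatrix(X[test]))
        ss_res = float(np.sum((y[test] - pred) ** 2))
        ss_tot = float(np.sum((y[test] - y[test].mean()) ** 2))
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    raise ValueError(f"unknown task {task!r}; expected 'status' or 'chla'")


@dataclass
class ScreenConfig:
    """Grids and split used by one screening run.

    The default (window, lag) grids cover the short upstream horizons the
    lagged-feature semantics target while keeping a full randomized ensemble
    affordable on a single core; both grids are plain tuples and can be
    widened freely.
    """

    w_grid: tuple[int, ...] = (1, 2, 3)
    l_grid: tuple[int, ...] = (0, 1, 2, 3)
    train_fraction: float = 0.85
    status_column: str = "status_class"
    chla_column: str = "chl_a"


def grid_search_asv(
    asv_id: str,
    current: pd.DataFrame,
    series: pd.DataFrame,
    response: np.ndarray,
    task: str,
    w_grid: Sequence[int],
    l_grid: Sequence[int],
    params: dict,
    split: tuple[np.ndarray, np.ndarray],
    seed: int,
) -> tuple[LagSpec, float]:
    """Best (window, lag) for one candidate ASV added to the current design.

    Every (w, l) pair is evaluated by the held-out metric of a boosted model
    on ``current`` plus the engineered column; ties are broken by smaller
    lag, then smaller window (the combinations are visited in that order and
    only strict improvements replace the incumbent). For classification the
    search stops early once a combination reaches accuracy 1.0, which no
    later combination can strictly beat.
    """
    if not len(w_grid) or not len(l_grid):
        raise ValueError("window and lag grids must be nonempty")
    train, test = split
    best_spec, best_metric = None, -np.inf
    for lag in sorted(l_grid):
        for window in sorted(w_grid):
            spec = LagSpec(asv_id, window=window, lag=lag)
            X = lagged_design_matrix(current, series, [spec]).to_numpy(float)
            metric = _fit_eval(X, response, train, test, task, params, seed)
            if metric > best_metric + IMPROVEMENT_TOL:
                best_spec, best_metric = spec, metric
            if task == "status" and best_metric >= 1.0:
                return best_spec, best_metric
    return best_spec, best_metric


@dataclass
class ScreeningModel:
    """Result of one greedy screening run."""

    accepted: list[LagSpec]
    metric: float            # held-out accuracy or R^2 of the final model
    base_metric: float       # held-out metric of the base design alone
    task: str
    params: dict
    seed: int
    metric_trace: list[float] = field(default_factory=list)

    @property
    def asv_ids(self) -> list[str]:
        return [s.asv_id for s in self.accepted]


def _response_vector(dataset: Dataset, task: str, config: ScreenConfig):
    if task == "status":
        col = dataset.metadata[config.status_column]
        if not isinstance(col.dtype, pd.CategoricalDtype):
            col = col.astype("category")
        return col.cat.codes.to_numpy()
    return dataset.metadata[config.chla_column].to_numpy(float)


def greedy_screen(
    candidate_order: Sequence[str],
    dataset: Dataset,
    task: str = "status",
    config: ScreenConfig | None = None,
    params: dict | None = None,
    seed: int = 0,
    series: pd.DataFrame | None = None,
) -> ScreeningModel:
    """Greedy forward construction of one screening model.

    Candidates are visited in the given order; each is grid-searched over
    (window, lag) and accepted into the design iff its best held-out metric
    strictly exceeds the incumbent's (tolerance 1e-9). The split is ordered:
    training = first 85% of observations by distance from the source. For
    classification every class level must appear in the training split.

    *series* is the transformed abundance table the engineered columns are
    drawn from (defaults to the Hellinger transform of ``dataset.abundance``).
    """
    from .io import hellinger_transform

    config = config or ScreenConfig()
    params = params or dict(DEFAULT_XGB_PARAMS)
    if series is None:
        series = hellinger_transform(dataset.abundance)
    series = series.loc[dataset.metadata.index]
    y = _response_vector(dataset, task, config)
    train, test = ordered_split(dataset.metadata, config.train_fraction)
    if task == "status" and set(np.unique(y)) - set(np.unique(y[train])):
        raise ValueError(
            "a status class is absent from the ordered training split; "
            "use a different split fraction or dataset"
        )
    design = base_design(dataset.metadata)
    incumbent = _fit_eval(design.to_numpy(float), y, train, test, task,
                          params, seed)
    base_metric = incumbent
    accepted: list[LagSpec] = []
    trace: list[float] = []
    for asv in candidate_order:
        if task == "status" and incumbent >= 1.0:
            break  # nothing can strictly improve perfect accuracy
        spec, metric = grid_search_asv(
            asv, design, series, y, task, config.w_grid, config.l_grid,
            params, (train, test), seed,
        )
        if metric > incumbent + IMPROVEMENT_TOL:
            accepted.append(spec)
            design = lagged_design_matrix(design, series, [spec])
            incumbent = metric
            trace.append(metric)
    return ScreeningModel(
        accepted=accepted, metric=incumbent, base_metric=base_metric,
        task=task, params=params, seed=seed, metric_trace=trace,
    )


@dataclass
class HyperparameterSpace:
    """Sampling space for the boosted-model hyperparameters of one run.

    Ranges are sized for the small design matrices the screening builds
    (learning rates below ~0.05 cannot converge within the tree budget, and
    more than ~120 rounds buys nothing on a few hundred rows while tripling
    the cost of a 100-run ensemble).
    """

    n_estimators: tuple[int, int] = (30, 120)
    max_depth: tuple[int, int] = (2, 5)
    learning_rate: tuple[float, float] = (0.05, 0.3)  # log-uniform
    subsample: tuple[float, float] = (0.6, 1.0)

    def sample(self, rng: np.random.Generator) -> dict:
        lo, hi = np.log(self.learning_rate)
        return {
            "n_estimators": int(rng.integers(self.n_estimators[0],
                                             self.n_estimators[1] + 1)),
            "max_depth": int(rng.integers(self.max_depth[0],
                                          self.max_depth[1] + 1)),
            "learning_rate": float(np.exp(rng.uniform(lo, hi))),
            "subsample": float(rng.uniform(*self.subsample)),
        }


@dataclass
class ModelEnsemble:
    """All screening runs of one ensemble, with their metadata."""

    models: list[ScreeningModel]
    task: str
    seed: int

    def __len__(self) -> int:
        return len(self.models)

    def to_records(self) -> list[dict]:
        return [
            {
                "seed": m.seed,
                "task": m.task,
                "metric": m.metric,
                "base_metric": m.base_metric,
                "params": m.params,
                "accepted": [
                    {"asv_id": s.asv_id, "window": s.window, "lag": s.lag}
                    for s in m.accepted
                ],
            }
            for m in self.models
        ]


def ensemble_screen(
    dataset: Dataset,
    task: str = "status",
    n_runs: int = 1000,
    hyperparameter_space: HyperparameterSpace | None = None,
    seed: int = 0,
    candidates: Sequence[str] | None = None,
    config: ScreenConfig | None = None,
    max_candidates: int | None = None,
) -> ModelEnsemble:
    """Randomized ensemble of greedy screening runs.

    Each run permutes the candidate list and samples boosted-model
    hyperparameters from *hyperparameter_space*, both seeded from the master
    seed, then runs :func:`greedy_screen`. When *candidates* is None the
    random-forest prefilter supplies them, optionally truncated to the
    *max_candidates* most important (each run grid-searches every candidate
    it visits, so the candidate list is the main cost driver of a large
    ensemble).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    from .io import hellinger_transform

    config = config or ScreenConfig()
    space = hyperparameter_space or HyperparameterSpace()
    series = hellinger_transform(dataset.abundance)
    if candidates is None:
        chl = dataset.metadata[config.chla_column]
        candidates = rf_prefilter(series, chl, seed=seed).candidates
    candidates = list(candidates)
    if max_candidates is not None:
        candidates = candidates[:max_candidates]
    if not candidates:
        raise ValueError("empty candidate list")

    master = np.random.default_rng(seed)
    models = []
    for run in range(n_runs):
        run_seed = int(master.integers(2**31 - 1))
        rng = np.random.default_rng(run_seed)
        order = [candidates[i] for i in rng.permutation(len(candidates))]
        params = space.sample(rng)
        models.append(
            greedy_screen(order, dataset, task=task, config=config,
                          params=params, seed=run_seed, series=series)
        )
    return ModelEnsemble(models=models, task=task, seed=seed)
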
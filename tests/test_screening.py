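import numpy as np
import pandas as pd
import pytest

from riverindic import (
    HyperparameterSpace,
    LagSpec,
    ScreenConfig,
    ensemble_screen,
    greedy_screen,
    hellinger_transform,
    rf_prefilter,
)
from riverindic.screening import (
    DEFAULT_XGB_PARAMS,
    base_design,
    grid_search_asv,
    lagged_design_matrix,
    lagged_feature,
    ordered_split,
)


class TestLaggedFeature:
    def test_raw_lag_with_warmup_fill(self):
        out = lagged_feature(np.array([3.0, 4.0, 5.0, 7.0]), window=1, lag=1)
        np.testing.assert_array_equal(out, [3.0, 3.0, 4.0, 5.0])

    def test_windowed_standardization_closed_form(self):
        # w=2, l=0 at site 1: (3 - mean(1,3)) / sd(1,3) = 1/sqrt(2);
        # site 0 has a single-value truncated window -> 0
        out = lagged_feature(np.array([1.0, 3.0]), window=2, lag=0)
        np.testing.assert_allclose(out, [0.0, 1 / np.sqrt(2)])
        # l=0, w=3 at the last site of [1,2,3,4]: (4 - 3) / 1 = 1.0
        out = lagged_feature(np.array([1.0, 2.0, 3.0, 4.0]), window=3, lag=0)
        np.testing.assert_allclose(out[3], 1.0)

    def test_zero_sd_window_yields_zero(self):
        out = lagged_feature(np.array([5.0, 5.0, 7.0]), window=2, lag=0)
        np.testing.assert_allclose(out, [0.0, 0.0, (7 - 6) / np.sqrt(2)])

    def test_lag_zero_window_one_is_identity(self):
        x = np.array([2.0, -1.0, 4.0])
        np.testing.assert_array_equal(lagged_feature(x, 1, 0), x)

    def test_length_validation(self):
        with pytest.raises(ValueError, match="lag"):
            lagged_feature(np.ones(3), window=1, lag=3)
        with pytest.raises(ValueError, match="exceed"):
            lagged_feature(np.ones(3), window=3, lag=1)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            LagSpec("A", window=0)
        with pytest.raises(ValueError):
            LagSpec("A", lag=-1)
        assert LagSpec("A", window=2, lag=3).column == "A|w2|l3"


def _toy_frame(n=12, n_taxa=3, seed=0):
    rng = np.random.default_rng(seed)
    meta = pd.DataFrame(
        {
            "transect": ["left"] * n + ["right"] * n,
            "distance_to_mouth": np.concatenate(
                [np.linspace(100, 10, n)] * 2
            ),
        },
        index=[f"L{i}" for i in range(n)] + [f"R{i}" for i in range(n)],
    )
    series = pd.DataFrame(
        rng.random((2 * n, n_taxa)),
        index=meta.index,
        columns=[f"T{k}" for k in range(n_taxa)],
    )
    return meta, series


def test_no_information_crosses_transects():
    meta, series = _toy_frame()
    base = base_design(meta)
    specs = [LagSpec("T0", window=w, lag=l)
             for w in (1, 2, 3) for l in (0, 1, 2)]
    design = lagged_design_matrix(base, series, specs)
    # perturb the entire right transect; the left columns must not move
    perturbed = series.copy()
    perturbed.loc[perturbed.index.str.startswith("R"), "T0"] = 99.0
    design2 = lagged_design_matrix(base, perturbed, specs)
    left = meta.index.str.startswith("L")
    for spec in specs:
        np.testing.assert_array_equal(
            design.loc[left, spec.column], design2.loc[left, spec.column]
        )


def test_no_future_leakage_within_transect():
    """Changing a downstream value never changes an engineered value at any
    upstream site, for every (window, lag) on the grid."""
    n = 12
    meta, series = _toy_frame(n=n)
    base = base_design(meta)
    specs = [LagSpec("T0", window=w, lag=l)
             for w in (1, 2, 3) for l in (0, 1, 2, 3)]
    design = lagged_design_matrix(base, series, specs)
    for site in range(1, n):  # perturb site `site` of the left transect
        perturbed = series.copy()
        perturbed.iloc[site, 0] += 7.0
        d2 = lagged_design_matrix(base, perturbed, specs)
        for spec in specs:
            np.testing.assert_array_equal(
                design[spec.column].to_numpy()[:site],
                d2[spec.column].to_numpy()[:site],
                err_msg=f"{spec.column} leaked from site {site}",
            )


def test_ordered_split_is_downstream_holdout():
    meta, _ = _toy_frame(n=10)
    train, test = ordered_split(meta, train_fraction=0.85)
    assert train.sum() == 17 and test.sum() == 3
    # every held-out site is at least as downstream as every training site
    d = meta["distance_to_mouth"].to_numpy()
    assert d[test].max() <= d[train].min()


def test_grid_search_tie_break_smallest_lag_then_window():
    meta, series = _toy_frame(n=15)
    series["CONST"] = 1.0  # constant column: every (w, l) scores the same
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, len(meta))
    base = base_design(meta)
    split = ordered_split(meta, 0.85)
    spec, _ = grid_search_asv(
        "CONST", base, series, y, "status", (1, 2, 3), (0, 1, 2),
        dict(DEFAULT_XGB_PARAMS), split, seed=0,
    )
    assert (spec.window, spec.lag) == (1, 0)


def test_fit_eval_rejects_constant_training_response(small_dataset):
    from riverindic.screening import _fit_eval

    X = np.ones((20, 2))
    train = np.arange(20) < 15
    with pytest.raises(ValueError, match="constant"):
        _fit_eval(X, np.zeros(20, dtype=int), train, ~train, "status",
                  dict(DEFAULT_XGB_PARAMS), 0)
    with pytest.raises(ValueError, match="constant"):
        _fit_eval(X, np.zeros(20), train, ~train, "chla",
                  dict(DEFAULT_XGB_PARAMS), 0)
    with pytest.raises(ValueError, match="task"):
        _fit_eval(X, np.arange(20.0), train, ~train, "bogus",
                  dict(DEFAULT_XGB_PARAMS), 0)


def test_greedy_screen_accepts_both_planted_parents(small_dataset):
    """Visiting the two planted parents first, each must strictly improve
    the held-out metric and be accepted."""
    model = greedy_screen(
        ["ASV_ind_a1", "ASV_ind_b1"], small_dataset, task="status", seed=0,
    )
    assert set(model.asv_ids) == {"ASV_ind_a1", "ASV_ind_b1"}
    assert model.metric > model.base_metric
    assert model.metric_trace == sorted(model.metric_trace)
    assert model.metric == model.metric_trace[-1]


def test_greedy_screen_metric_trace_strictly_improves(small_dataset):
    hell = hellinger_transform(small_dataset.abundance)
    candidates = [c for c in hell.columns[:6]] + ["ASV_ind_a1", "ASV_ind_b1"]
    model = greedy_screen(candidates, small_dataset, task="status", seed=1)
    trace = [model.base_metric] + model.metric_trace
    assert all(b > a for a, b in zip(trace, trace[1:]))


def test_greedy_screen_regression_task(small_dataset):
    model = greedy_screen(
        ["ASV_ind_a1", "ASV_ind_b1"], small_dataset, task="chla", seed=0,
    )
    assert model.task == "chla"
    assert np.isfinite(model.metric)
    assert model.metric >= model.base_metric


def test_rf_prefilter_surfaces_planted_indicators(small_dataset):
    hell = hellinger_transform(small_dataset.abundance)
    hits = 0
    for seed in range(5):
        res = rf_prefilter(hell, small_dataset.metadata["chl_a"], seed=seed)
        top = set(res.candidates[:15])
        if top & {"ASV_ind_a1", "ASV_ind_a2", "ASV_ind_b1", "ASV_ind_b2"}:
            hits += 1
        assert res.importance.is_monotonic_decreasing
        assert all(res.importance[c] > 0 for c in res.candidates)
    assert hits >= 4, f"indicators surfaced in only {hits}/5 prefilters"


def test_rf_prefilter_validation(small_dataset):
    hell = hellinger_transform(small_dataset.abundance)
    with pytest.raises(ValueError, match=">= 20"):
        rf_prefilter(hell.iloc[:10], small_dataset.metadata["chl_a"].iloc[:10])
    with pytest.warns(UserWarning, match="clamped"):
        rf_prefilter(hell.iloc[:, :5], small_dataset.metadata["chl_a"],
                     mtry_grid=[3, 99], ntree_grid=[30])


def test_ensemble_screen_is_deterministic(small_dataset):
    kwargs = dict(
        task="status", n_runs=3, seed=21,
        candidates=["ASV_ind_a1", "ASV_ind_b1", "ASV_0001", "ASV_0002"],
        config=ScreenConfig(w_grid=(1,), l_grid=(0, 1)),
    )
    a = ensemble_screen(small_dataset, **kwargs)
    b = ensemble_screen(small_dataset, **kwargs)
    assert a.to_records() == b.to_records()
    assert len(a) == 3
    assert all(m.seed < 2**31 for m in a.models)


def test_ensemble_screen_validation(small_dataset):
    with pytest.raises(ValueError, match="n_runs"):
        ensemble_screen(small_dataset, n_runs=0, candidates=["ASV_0001"])
    with pytest.raises(ValueError, match="empty candidate"):
        ensemble_screen(small_dataset, n_runs=1, candidates=[])


def test_hyperparameter_space_bounds():
    space = HyperparameterSpace()
    rng = np.random.default_rng(0)
    for _ in range(50):
        p = space.sample(rng)
        assert 30 <= p["n_estimators"] <= 120
        assert 2 <= p["max_depth"] <= 5
        assert 0.05 <= p["learning_rate"] <= 0.3
        assert 0.6 <= p["subsample"] <= 1.0
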
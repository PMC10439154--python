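from io import StringIO
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from riverindic import (
    LagSpec,
    build_coexclusion,
    build_cooccurrence,
    minimal_models,
    presence_absence,
    select_best_models,
    taxonomy_dendrogram,
)
from riverindic.networks import _percentile_filter
from riverindic.screening import ModelEnsemble, ScreeningModel


def _model(asvs, metric=1.0, seed=0, task="status"):
    return ScreeningModel(
        accepted=[LagSpec(a) for a in asvs], metric=metric, base_metric=0.5,
        task=task, params={}, seed=seed,
    )


def test_select_best_models_status_keeps_only_perfect():
    ens = ModelEnsemble(
        models=[_model(["A"], 1.0, seed=1), _model(["B"], 0.9, seed=2),
                _model(["C"], 1.0, seed=3)],
        task="status", seed=0,
    )
    best = select_best_models(ens)
    assert [m.seed for m in best] == [1, 3]
    ens_bad = ModelEnsemble(models=[_model(["A"], 0.8)], task="status", seed=0)
    with pytest.warns(UserWarning, match="100%"):
        assert select_best_models(ens_bad) == []
    with pytest.raises(ValueError, match="empty"):
        select_best_models(ModelEnsemble(models=[], task="status", seed=0))


def test_select_best_models_regression_takes_single_max():
    ens = ModelEnsemble(
        models=[_model(["A"], 0.7, seed=5, task="chla"),
                _model(["B"], 0.9, seed=9, task="chla"),
                _model(["C"], 0.9, seed=4, task="chla")],
        task="chla", seed=0,
    )
    best = select_best_models(ens)
    assert len(best) == 1 and best[0].seed == 4  # tie broken by lowest seed


def test_presence_absence_exhaustive():
    models = [_model(["A", "B"], seed=1), _model(["B", "C"], seed=2),
              _model([], seed=3)]
    pa = presence_absence(models)
    assert list(pa.columns) == ["A", "B", "C"]
    assert pa.shape == (2, 3)  # the empty model is dropped
    np.testing.assert_array_equal(pa.to_numpy(), [[1, 1, 0], [0, 1, 1]])
    with pytest.raises(ValueError, match="no retained model"):
        presence_absence([_model([], seed=1)])


def test_percentile_filter_matches_brute_force():
    rng = np.random.default_rng(0)
    for trial in range(20):
        n = int(rng.integers(3, 40))
        counts = pd.Series(rng.integers(0, 12, n),
                           index=[f"A{k}" for k in range(n)])
        for pct in (0.0, 50.0, 90.0, 95.0, 99.0):
            got = _percentile_filter(counts, pct)
            # brute force: nearest-rank cutoff, ties at the cutoff included
            values = sorted(counts)
            rank = max(1, int(np.ceil(pct / 100 * n)))
            cutoff = values[rank - 1]
            expected = counts[counts >= cutoff]
            pd.testing.assert_series_equal(got, expected)
    with pytest.raises(ValueError, match="percentile"):
        _percentile_filter(counts, 100.0)


def test_network_edges_match_exhaustive_counting():
    models = [
        _model(["A", "B"], seed=1),
        _model(["A", "C"], seed=2),
        _model(["A", "B"], seed=3),
        _model(["D"], seed=4),
    ]
    pa = presence_absence(models)
    co = build_cooccurrence(pa, percentile=0.0)
    ex = build_coexclusion(pa, percentile=0.0)
    # exhaustive pair counting on the binary table
    M = pa.to_numpy()
    for (i, u), (j, v) in combinations(enumerate(pa.columns), 2):
        both = int(np.sum(M[:, i] & M[:, j]))
        if both > 0:
            assert co.edges[u, v]["weight"] == both
            assert not ex.has_edge(u, v)
        else:
            assert not co.has_edge(u, v)
            assert ex.has_edge(u, v)
    assert co.edges["A", "B"]["weight"] == 2
    assert co.nodes["A"]["occurrence"] == 3
    # co-occurrence and co-exclusion partition the pairs
    assert co.number_of_edges() + ex.number_of_edges() == 6


def test_complementary_pair_coexcludes():
    """Two ASVs that never share a model get a co-exclusion edge."""
    models = [_model(["A"], seed=1), _model(["B"], seed=2)]
    pa = presence_absence(models)
    ex = build_coexclusion(pa, percentile=0.0)
    assert ex.has_edge("A", "B")


def test_network_validation_and_taxonomy_attrs():
    models = [_model(["A", "B"], seed=1)]
    pa = presence_absence(models)
    with pytest.raises(ValueError, match=">= 2 retained models"):
        build_cooccurrence(pa, percentile=0.0)
    models = [_model(["A"], seed=1), _model(["A"], seed=2)]
    pa = presence_absence(models)
    with pytest.raises(ValueError, match="fewer than 2"):
        build_coexclusion(pa, percentile=0.0)
    tax = pd.DataFrame({"Class": ["Bacteroidia", "Actinobacteria"]},
                       index=["A", "B"])
    models = [_model(["A"], seed=1), _model(["B"], seed=2)]
    g = build_cooccurrence(presence_absence(models), 0.0, taxonomy=tax)
    assert g.nodes["A"]["class"] == "Bacteroidia"


def test_minimal_models_and_hubs():
    models = [
        _model(["A", "B"], seed=1),
        _model(["A", "C"], seed=2),
        _model(["A", "B", "C"], seed=3),
        _model(["D", "E"], seed=4),
    ]
    minimal, hubs = minimal_models(models)
    assert {frozenset(m.asv_ids) for m in minimal} == {
        frozenset("AB"), frozenset("AC"), frozenset("DE")
    }
    # A is the hub joining two distinct minimal sets
    assert set(hubs) == {"A"}
    assert {frozenset(s) for s in hubs["A"]} == {frozenset("AB"),
                                                 frozenset("AC")}
    with pytest.raises(ValueError, match="no retained model"):
        minimal_models([_model([], seed=1)])


def test_taxonomy_dendrogram_distances_and_newick(small_dataset):
    tax = small_dataset.taxonomy
    asvs = ["ASV_ind_a1", "ASV_ind_a2", "ASV_ind_b1", "ASV_0001"]
    occ = pd.Series([6.0, 3.0, 1.0], index=asvs[:3])
    tree, freq = taxonomy_dendrogram(asvs, tax, occurrences=occ)
    # clones share a lineage: patristic distance 0; different genera > 0
    t = {leaf.name: leaf for leaf in tree.tips()}
    assert tree.find("ASV_ind_a1").distance(tree.find("ASV_ind_a2")) == 0.0
    assert tree.find("ASV_ind_a1").distance(tree.find("ASV_0001")) > 0.0
    # newick round-trip preserves the tips
    reread = TreeNode.read(StringIO(str(tree)))
    assert {tip.name for tip in reread.tips()} == set(asvs)
    # occurrence frequencies are closed and reindexed over all leaves
    np.testing.assert_allclose(freq.sum(), 1.0)
    assert freq["ASV_0001"] == 0.0
    np.testing.assert_allclose(freq["ASV_ind_a1"], 0.6)


def test_taxonomy_dendrogram_validation(small_dataset):
    tax = small_dataset.taxonomy
    with pytest.raises(KeyError, match="NOPE"):
        taxonomy_dendrogram(["ASV_ind_a1", "NOPE"], tax)
    with pytest.raises(ValueError, match=">= 2"):
        taxonomy_dendrogram(["ASV_ind_a1"], tax)
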
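"""Co-occurrence / co-exclusion networks and redundancy analysis of the
screening ensemble.

The retained screening models (perfect-accuracy classifiers, or the single
best regressor) become a binary presence/absence table with models as rows
and ASVs as columns. Two ASVs *co-occur* if some retained model contains
both; they are *co-excluded* if no retained model ever contains both — read
as informational redundancy: once one member of a redundant set is in a
model, the others can no longer improve it. Only the most frequently
occurring ASVs (95th percentile of occurrence counts by default,
nearest-rank rule, ties at the cutoff included) enter the networks.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .io import RANKS
from .screening import ModelEnsemble, ScreeningModel

__all__ = [
    "select_best_models",
    "presence_absence",
    "build_cooccurrence",
    "build_coexclusion",
    "minimal_models",
    "taxonomy_dendrogram",
]


def select_best_models(ensemble: ModelEnsemble, task: str | None = None
                       ) -> list[ScreeningModel]:
    """Retain the models the networks are built from.

    Classification: every model with held-out accuracy 1.0 (exact 100%).
    Regression: the single model with the highest R^2 (ties: lowest run
    seed). An empty classification result triggers a warning; downstream
    network builders refuse empty input.
    """
    if not ensemble.models:
        raise ValueError("empty ensemble")
    task = task or ensemble.task
    if task == "status":
        retained = [m for m in ensemble.models if m.metric >= 1.0 - 1e-12]
        if not retained:
            warnings.warn("no model reached 100% held-out accuracy")
        return retained
    best = max(ensemble.models, key=lambda m: (m.metric, -m.seed))
    return [best]


def presence_absence(models: Sequence[ScreeningModel]) -> pd.DataFrame:
    """Binary models x ASVs table; models with no accepted ASV are dropped."""
    models = [m for m in models if m.accepted]
    if not models:
        raise ValueError("no retained model contains any ASV")
    asvs = sorted({s.asv_id for m in models for s in m.accepted})
    data = np.zeros((len(models), len(asvs)), dtype=int)
    col = {a: j for j, a in enumerate(asvs)}
    for i, m in enumerate(models):
        for s in m.accepted:
            data[i, col[s.asv_id]] = 1
    index = [f"model_{m.seed}_{i}" for i, m in enumerate(models)]
    return pd.DataFrame(data, index=index, columns=asvs)


def _percentile_filter(counts: pd.Series, percentile: float) -> pd.Series:
    """Occurrence counts at or above the nearest-rank percentile cutoff."""
    if not 0 <= percentile < 100:
        raise ValueError("percentile must be in [0, 100)")
    values = np.sort(counts.to_numpy())
    rank = max(1, int(np.ceil(percentile / 100.0 * len(values))))
    cutoff = values[rank - 1]
    return counts[counts >= cutoff]


def _filtered(pa: pd.DataFrame, percentile: float):
    if pa.shape[0] < 2:
        raise ValueError("need >= 2 retained models to build a network")
    counts = pa.sum(axis=0)
    kept = _percentile_filter(counts, percentile)
    return pa[kept.index], kept


def _node_attrs(graph: nx.Graph, counts: pd.Series, taxonomy) -> None:
    for node in graph.nodes:
        graph.nodes[node]["occurrence"] = int(counts[node])
        if taxonomy is not None and node in taxonomy.index:
            graph.nodes[node]["class"] = str(taxonomy.loc[node, "Class"])


def build_cooccurrence(
    pa: pd.DataFrame, percentile: float = 95.0,
    taxonomy: pd.DataFrame | None = None,
) -> nx.Graph:
    """Co-occurrence graph over the percentile-filtered ASVs.

    Node weight = occurrence count; edge weight = number of retained models
    containing both ASVs (zero-weight edges are omitted).
    """
    sub, counts = _filtered(pa, percentile)
    g = nx.Graph()
    g.add_nodes_from(sub.columns)
    _node_attrs(g, counts, taxonomy)
    M = sub.to_numpy()
    for (i, u), (j, v) in combinations(enumerate(sub.columns), 2):
        w = int(np.sum(M[:, i] & M[:, j]))
        if w > 0:
            g.add_edge(u, v, weight=w)
    return g


def build_coexclusion(
    pa: pd.DataFrame, percentile: float = 95.0,
    taxonomy: pd.DataFrame | None = None,
) -> nx.Graph:
    """Co-exclusion graph: edges between filtered ASVs that never appear
    together in any retained model."""
    sub, counts = _filtered(pa, percentile)
    if sub.shape[1] < 2:
        raise ValueError("fewer than 2 ASVs pass the percentile filter")
    g = nx.Graph()
    g.add_nodes_from(sub.columns)
    _node_attrs(g, counts, taxonomy)
    M = sub.to_numpy()
    for (i, u), (j, v) in combinations(enumerate(sub.columns), 2):
        if int(np.sum(M[:, i] & M[:, j])) == 0:
            g.add_edge(u, v)
    return g


def minimal_models(models: Sequence[ScreeningModel]
                   ) -> tuple[list[ScreeningModel], dict[str, list[frozenset]]]:
    """Smallest accepted-ASV sets among the retained models.

    Returns the minimal-size models and a hub map: for every ASV occurring
    in more than one minimal set, the distinct sets containing it — the
    'one hub, several partners' structure of redundant minimal predictors.
    """
    models = [m for m in models if m.accepted]
    if not models:
        raise ValueError("no retained model contains any ASV")
    size = min(len(m.accepted) for m in models)
    minimal = [m for m in models if len(m.accepted) == size]
    sets = {frozenset(m.asv_ids) for m in minimal}
    hubs: dict[str, list[frozenset]] = {}
    for asv in sorted({a for s in sets for a in s}):
        containing = [s for s in sorted(sets, key=sorted)]
        containing = [s for s in containing if asv in s]
        if len(containing) > 1:
            hubs[asv] = containing
    return minimal, hubs


def taxonomy_dendrogram(
    asvs: Sequence[str],
    taxonomy: pd.DataFrame,
    occurrences: pd.Series | None = None,
) -> tuple[TreeNode, pd.Series | None]:
    """Average-linkage dendrogram of ASVs from their taxonomy strings.

    The distance between two ASVs is the number of ranks (Kingdom through
    Genus, six levels) at which their labels differ; identical lineages have
    distance 0, different kingdoms distance 6. Returns a tree (serializable
    to newick via ``str(tree)`` or ``tree.write``) and, when occurrence
    counts are supplied, the per-leaf relative occurrence frequencies.
    """
    asvs = list(asvs)
    missing = [a for a in asvs if a not in taxonomy.index]
    if missing:
        raise KeyError(f"ASVs missing from taxonomy table: {missing}")
    if len(asvs) < 2:
        raise ValueError("need >= 2 ASVs to build a dendrogram")
    labels = taxonomy.loc[asvs, list(RANKS)].astype(str).to_numpy()
    n = len(asvs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = float(np.sum(labels[i] != labels[j]))
    Z = linkage(squareform(dist, checks=False), method="average")
    tree = TreeNode.from_linkage_matrix(Z, id_list=asvs)
    freq = None
    if occurrences is not None:
        occ = occurrences.reindex(asvs).fillna(0.0)
        total = occ.sum()
        freq = occ / (total if total > 0 else 1.0)
        freq.name = "relative_occurrence"
    return tree, freq
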
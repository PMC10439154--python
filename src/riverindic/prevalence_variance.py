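"""Prevalence / coefficient-of-variation screening of candidate bioindicators.

A good snapshot bioindicator is both broadly present across sampling sites
(high prevalence) and strongly variable in relative abundance (high
coefficient of variation): present everywhere, so it can always be measured,
yet responsive to the environment. This module computes both statistics per
taxon at any taxonomic rank and flags the top candidates by a reproducible
rule: taxa on the prevalence-CV Pareto front, ranked by the product of the
min-max-standardized statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["prevalence_cv", "select_candidates", "screen_rank"]


def prevalence_cv(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-taxon prevalence and coefficient of variation.

    Prevalence is the fraction of samples in which the taxon is detected
    (abundance > 0). The CV is the sample (n-1) standard deviation of the
    abundances divided by their mean; it is NaN (undefined) for taxa absent
    everywhere. Feed relative abundances so library size does not distort
    the variance.
    """
    if matrix.shape[0] < 2:
        raise ValueError("prevalence/CV needs >= 2 samples")
    X = matrix.to_numpy(float)
    prevalence = (X > 0).mean(axis=0)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return pd.DataFrame(
        {"prevalence": prevalence, "cv": cv},
        index=pd.Index(matrix.columns, name="taxon"),
    )


def _pareto_front(prev: np.ndarray, cv: np.ndarray) -> np.ndarray:
    """Boolean mask of taxa not dominated in (prevalence, cv)."""
    n = len(prev)
    front = np.ones(n, dtype=bool)
    for i in range(n):
        dominated = (
            (prev >= prev[i]) & (cv >= cv[i])
            & ((prev > prev[i]) | (cv > cv[i]))
        )
        if dominated.any():
            front[i] = False
    return front


def select_candidates(screens: pd.DataFrame, n_top: int) -> pd.DataFrame:
    """Rank taxa and flag the top *n_top* bioindicator candidates.

    Taxa are ordered Pareto-front-first, then by the product of min-max
    standardized prevalence and CV (descending), with lexicographic taxon-id
    tie-breaking. Returns the input plus ``score``, ``pareto`` and
    ``candidate`` columns, sorted by rank.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    defined = screens["cv"].notna()
    if not defined.any():
        raise ValueError("all CVs are undefined (every taxon absent)")
    df = screens.loc[defined].copy()

    def minmax(v: np.ndarray) -> np.ndarray:
        lo, hi = v.min(), v.max()
        return np.full_like(v, 0.5) if hi == lo else (v - lo) / (hi - lo)

    prev = df["prevalence"].to_numpy(float)
    cv = df["cv"].to_numpy(float)
    df["score"] = minmax(prev) * minmax(cv)
    df["pareto"] = _pareto_front(prev, cv)
    df["_taxon"] = df.index.astype(str)
    df = df.sort_values(
        ["pareto", "score", "_taxon"], ascending=[False, False, True],
        kind="mergesort",
    ).drop(columns="_taxon")
    df["candidate"] = False
    df.iloc[: min(n_top, len(df)), df.columns.get_loc("candidate")] = True
    return df


def screen_rank(dataset, rank: str, n_top: int) -> pd.DataFrame:
    """Aggregate to *rank*, close rows to relative abundance, screen, rank.

    Default ``n_top`` conventions in this analysis: 6 at phylum level, 15 at
    genus level.
    """
    from .io import aggregate_taxa, relative_abundance

    agg = aggregate_taxa(dataset.abundance, dataset.taxonomy, rank)
    rel = relative_abundance(agg)
    out = select_candidates(prevalence_cv(rel), n_top)
    out.insert(0, "rank", rank)
    return out
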
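"""Constrained ordination of community dissimilarity on environmental drivers.

The chain is the classical one for relating species composition to the
environment: Bray-Curtis dissimilarity on (Hellinger-transformed) abundances,
variance-inflation filtering of collinear predictors, permutation-tested
forward selection, and distance-based redundancy analysis (dbRDA): a
principal-coordinates embedding of the dissimilarity matrix followed by a
redundancy analysis of the coordinates on the retained predictors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

__all__ = [
    "bray_curtis",
    "vif_filter",
    "forward_select",
    "dbrda",
    "OrdinationResult",
]

_EIG_TOL = 1e-10


def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between the rows of *matrix*.

    ``d(i, j) = sum |x_i - x_j| / sum (x_i + x_j)``; 0 for identical rows,
    1 for disjoint supports.
    """
    X = matrix.to_numpy(float)
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    zero = np.flatnonzero(X.sum(axis=1) == 0)
    if zero.size:
        names = [str(matrix.index[i]) for i in zero]
        raise ValueError(f"all-zero abundance rows: {names}")
    d = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(d, ids=[str(i) for i in matrix.index])


def vif_filter(env: pd.DataFrame, threshold: float = 5.0) -> list[str]:
    """Iteratively drop the predictor with the largest variance inflation
    factor until every VIF <= *threshold*; returns the retained columns.

    ``VIF_j = 1 / (1 - R^2_j)`` from regressing predictor j on the others.
    A perfectly collinear pair loses exactly one member (the later column).
    """
    cols = [c for c in env.columns if np.issubdtype(env[c].dtype, np.number)]
    if len(cols) < 2:
        raise ValueError("VIF filtering needs >= 2 numeric predictors")
    if env[cols].isna().any().any():
        raise ValueError("impute missing predictor values first")

    def vif_of(kept: list[str]) -> np.ndarray:
        X = env[kept].to_numpy(float)
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
        out = np.empty(len(kept))
        for j in range(len(kept)):
            others = np.delete(X, j, axis=1)
            A = np.column_stack([np.ones(len(X)), others])
            coef, *_ = np.linalg.lstsq(A, X[:, j], rcond=None)
            resid = X[:, j] - A @ coef
            ss_tot = float((X[:, j] ** 2).sum())
            r2 = 1.0 - float((resid**2).sum()) / ss_tot
            out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        return out

    kept = list(cols)
    while len(kept) > 1:
        vifs = vif_of(kept)
        worst = int(np.argmax(vifs))
        if vifs[worst] <= threshold:
            break
        # among equally-worst predictors drop the last, keeping the first
        ties = np.flatnonzero(vifs == vifs[worst])
        kept.pop(int(ties[-1]))
    return kept


# ---------------------------------------------------------------------------
# PCoA / dbRDA internals
# ---------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = len(d)
    h = np.eye(n) - np.ones((n, n)) / n
    return h @ a @ h


def _pcoa_coords(d: np.ndarray, correction: str) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates of a dissimilarity matrix.

    correction='none' drops negative axes; 'lingoes' adds the smallest
    constant to the squared off-diagonal dissimilarities that makes the
    matrix Euclidean-embeddable.
    """
    g = _gower_center(d)
    evals = np.linalg.eigvalsh(g)
    if correction == "lingoes" and evals[0] < -_EIG_TOL:
        c = -evals[0]
        d = np.sqrt(d**2 + 2.0 * c)
        np.fill_diagonal(d, 0.0)
        g = _gower_center(d)
    elif correction not in ("none", "lingoes"):
        raise ValueError(f"unknown correction {correction!r}")
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(_EIG_TOL, _EIG_TOL * abs(evals[0]))
    keep = evals > tol
    return evecs[:, keep] * np.sqrt(evals[keep]), evals[keep]


def _standardize(env: pd.DataFrame) -> np.ndarray:
    X = env.to_numpy(float)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return X / sd


def _constrained_trace(Y: np.ndarray, X: np.ndarray) -> float:
    """Sum of squares of Y explained by the column space of X (with mean)."""
    A = np.column_stack([np.ones(len(X)), X])
    coef, *_ = np.linalg.lstsq(A, Y, rcond=None)
    fitted = A @ coef
    return float((fitted**2).sum())


@dataclass
class OrdinationResult:
    """dbRDA output: eigenvalues, scores, constrained fraction, test."""

    constrained_eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    site_scores: pd.DataFrame       # samples x constrained axes
    biplot_scores: pd.DataFrame     # predictors x constrained axes
    proportion_constrained: float
    p_value: float
    total_inertia: float


def dbrda(
    dist: DistanceMatrix,
    env: pd.DataFrame,
    correction: str = "none",
    n_perm: int = 999,
    seed: int = 0,
) -> OrdinationResult:
    """Distance-based redundancy analysis with a global permutation test.

    The dissimilarity matrix is embedded by PCoA (negative eigenvalues
    handled per *correction*); the retained coordinates are regressed on the
    standardized predictors; the fitted values are eigendecomposed to give
    the constrained axes. The permutation test permutes the rows of the
    predictor matrix and uses the pseudo-F of the constrained fraction, with
    the (b + 1) / (m + 1) p-value estimator.
    """
    d = dist.data
    ids = list(dist.ids)
    env = env.loc[[i for i in ids if i in env.index]] if set(ids) <= set(map(str, env.index)) else env
    if len(env) != len(ids):
        raise ValueError("env rows do not match distance matrix ids")
    X = _standardize(env)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need more samples than predictors + 1")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < p + 1:
        raise ValueError("predictor matrix is rank deficient; VIF-filter first")

    Y, pcoa_evals = _pcoa_coords(d, correction)
    total = float(pcoa_evals.sum())

    A = np.column_stack([np.ones(n), X])
    coef, *_ = np.linalg.lstsq(A, Y, rcond=None)
    fitted = A @ coef
    resid = Y - fitted

    cons_evals, cons_vecs = np.linalg.eigh(fitted.T @ fitted)
    order = np.argsort(cons_evals)[::-1]
    cons_evals, cons_vecs = cons_evals[order], cons_vecs[:, order]
    keep = cons_evals > max(_EIG_TOL, _EIG_TOL * max(cons_evals[0], 1.0))
    cons_evals, cons_vecs = cons_evals[keep], cons_vecs[:, keep]

    res_evals = np.linalg.eigvalsh(resid.T @ resid)[::-1]
    res_evals = res_evals[res_evals > _EIG_TOL]

    axes = [f"dbRDA{k + 1}" for k in range(cons_vecs.shape[1])]
    site = pd.DataFrame(Y @ cons_vecs, index=ids, columns=axes)
    lc = fitted @ cons_vecs  # linear-combination scores, for biplot corr
    biplot = pd.DataFrame(
        np.array([
            [np.corrcoef(X[:, j], lc[:, k])[0, 1] if lc[:, k].std() > 0 else 0.0
             for k in range(lc.shape[1])]
            for j in range(p)
        ]),
        index=list(env.columns), columns=axes,
    )

    cons_trace = float(cons_evals.sum())
    prop = cons_trace / total if total > 0 else 0.0

    def pseudo_f(Yp: np.ndarray, Xm: np.ndarray) -> float:
        ct = _constrained_trace(Yp, Xm) - len(Yp) * (Yp.mean(axis=0) ** 2).sum()
        rt = float((Yp**2).sum()) - ct
        return (ct / p) / (rt / (n - p - 1)) if rt > 0 else np.inf

    obs_f = pseudo_f(Y, X)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        Xp = X[rng.permutation(n)]
        if pseudo_f(Y, Xp) >= obs_f:
            exceed += 1
    p_value = (exceed + 1) / (n_perm + 1)

    return OrdinationResult(
        constrained_eigenvalues=cons_evals,
        unconstrained_eigenvalues=res_evals,
        site_scores=site,
        biplot_scores=biplot,
        proportion_constrained=prop,
        p_value=p_value,
        total_inertia=total,
    )


def _adjusted_r2(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        return -np.inf
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def forward_select(
    dist: DistanceMatrix,
    env: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    correction: str = "none",
) -> list[str]:
    """Permutation-tested forward selection of environmental predictors.

    At each step the candidate giving the largest gain in adjusted
    constrained proportion of the dbRDA is tested by permuting its values
    (*n_perm* times, seeded); it is admitted if the permutation p-value of
    its conditional gain is below *alpha*, otherwise selection stops.
    """
    if n_perm < 19:
        raise ValueError("n_perm < 19 gives too coarse a p-value resolution")
    if env.isna().any().any():
        raise ValueError("impute missing predictor values first")
    Y, evals = _pcoa_coords(dist.data, correction)
    total = float(evals.sum())
    n = len(Y)
    Xall = _standardize(env)
    names = list(env.columns)
    rng = np.random.default_rng(seed)

    def prop(cols: list[int], extra: np.ndarray | None = None) -> float:
        if not cols and extra is None:
            return 0.0
        parts = [Xall[:, cols]] if cols else []
        if extra is not None:
            parts.append(extra[:, None])
        X = np.hstack(parts)
        ct = _constrained_trace(Y, X)
        return ct / total if total > 0 else 0.0

    selected: list[int] = []
    remaining = list(range(len(names)))
    current_adj = 0.0
    while remaining:
        gains = []
        for j in remaining:
            r2 = prop(selected + [j])
            gains.append(_adjusted_r2(r2, n, len(selected) + 1) - current_adj)
        best_i = int(np.argmax(gains))
        j = remaining[best_i]
        if alpha < 1.0:  # alpha >= 1 means no rejection is possible
            # conditional permutation test of the best candidate
            obs_gain = prop(selected + [j]) - prop(selected)
            exceed = 0
            for _ in range(n_perm):
                xp = Xall[rng.permutation(n), j]
                if prop(selected, extra=xp) - prop(selected) >= obs_gain:
                    exceed += 1
            p_value = (exceed + 1) / (n_perm + 1)
            if p_value >= alpha:
                break
        selected.append(j)
        remaining.remove(j)
        current_adj = _adjusted_r2(prop(selected), n, len(selected))
    return [names[j] for j in selected]
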
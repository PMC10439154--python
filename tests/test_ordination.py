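import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from riverindic import bray_curtis, dbrda, forward_select, vif_filter
from riverindic.ordination import _pcoa_coords


def _dm(X, ids=None):
    X = pd.DataFrame(X, index=ids)
    return bray_curtis(X)


def test_bray_curtis_closed_forms():
    d = _dm([[1.0, 0.0], [0.0, 1.0]])
    assert d[0, 1] == 1.0  # disjoint supports
    d = _dm([[2.0, 2.0], [1.0, 1.0]])
    np.testing.assert_allclose(d[0, 1], 1.0 / 3.0)
    d = _dm([[3.0, 1.0], [3.0, 1.0]])
    assert d[0, 1] == 0.0


def test_bray_curtis_rejects_bad_rows():
    with pytest.raises(ValueError, match="non-negative"):
        bray_curtis(pd.DataFrame([[1.0, -1.0], [1.0, 1.0]]))
    with pytest.raises(ValueError, match="S2"):
        bray_curtis(pd.DataFrame([[1.0, 1.0], [0.0, 0.0], [2.0, 1.0]],
                                 index=["S1", "S2", "S3"]))


@settings(max_examples=25, deadline=None)
@given(
    arrays(float, st.integers(2, 6),
           elements=st.floats(0.01, 100, allow_nan=False))
)
def test_bray_curtis_scaling_law(x):
    """d(x, 2x) = sum|x| / sum(3x) = 1/3 for any positive profile."""
    d = _dm(np.vstack([x, 2 * x]))
    np.testing.assert_allclose(d[0, 1], 1.0 / 3.0, rtol=1e-9)


def test_vif_keeps_orthogonal_drops_duplicate():
    rng = np.random.default_rng(0)
    env = pd.DataFrame({
        "a": rng.normal(size=50),
        "b": rng.normal(size=50),
    })
    env["c"] = env["a"] * 1.0  # exact duplicate of the earlier column
    kept = vif_filter(env, threshold=5.0)
    assert kept == ["a", "b"]
    with pytest.raises(ValueError, match=">= 2"):
        vif_filter(env[["a"]])
    with pytest.raises(ValueError, match="impute"):
        vif_filter(env.mask(env > 10).assign(a=np.nan))


def _brute_force_rda(Y, X):
    """Classical RDA: eigenvalues of the fitted sum-of-squares matrix from
    regressing the centered response on the standardized predictors."""
    Y = Y - Y.mean(axis=0)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    A = np.column_stack([np.ones(len(X)), X])
    fitted = A @ np.linalg.lstsq(A, Y, rcond=None)[0]
    evals = np.linalg.eigvalsh(fitted.T @ fitted)[::-1]
    return evals[evals > 1e-10], float((Y**2).sum())


def test_dbrda_on_euclidean_equals_classical_rda():
    """On Euclidean distances dbRDA must reproduce classical RDA exactly."""
    rng = np.random.default_rng(42)
    n, q, p = 30, 5, 2
    X = rng.normal(size=(n, p))
    Y = X @ rng.normal(size=(p, q)) + 0.3 * rng.normal(size=(n, q))
    d = squareform(pdist(Y))
    dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(n)])
    env = pd.DataFrame(X, columns=["e1", "e2"], index=[f"s{i}" for i in range(n)])
    res = dbrda(dm, env, n_perm=99, seed=0)
    ref_evals, ref_total = _brute_force_rda(Y, X)
    assert len(res.constrained_eigenvalues) == len(ref_evals)
    np.testing.assert_allclose(res.constrained_eigenvalues, ref_evals,
                               rtol=1e-8)
    np.testing.assert_allclose(res.total_inertia, ref_total, rtol=1e-8)
    np.testing.assert_allclose(
        res.proportion_constrained, ref_evals.sum() / ref_total, rtol=1e-8
    )
    # strong planted relation: smallest possible p-value
    assert res.p_value == pytest.approx(1.0 / 100.0)


def test_dbrda_first_pcoa_axis_constrains_its_eigenvalue(small_dataset):
    from riverindic import hellinger_transform

    hell = hellinger_transform(small_dataset.abundance)
    dm = bray_curtis(hell)
    coords, evals = _pcoa_coords(dm.data, correction="lingoes")
    env = pd.DataFrame({"axis1": coords[:, 0]}, index=list(dm.ids))
    res = dbrda(dm, env, correction="lingoes", n_perm=49, seed=0)
    np.testing.assert_allclose(
        res.constrained_eigenvalues.sum(), evals[0], rtol=1e-8
    )


def test_dbrda_null_predictor_large_p():
    rng = np.random.default_rng(1)
    Y = rng.normal(size=(40, 6))
    dm = DistanceMatrix(squareform(pdist(Y)),
                        ids=[f"s{i}" for i in range(40)])
    env = pd.DataFrame({"noise": rng.normal(size=40)},
                       index=[f"s{i}" for i in range(40)])
    res = dbrda(dm, env, n_perm=199, seed=3)
    assert res.p_value > 0.05
    assert res.proportion_constrained < 0.15


def test_dbrda_rank_deficiency_rejected():
    rng = np.random.default_rng(2)
    Y = rng.normal(size=(20, 4))
    dm = DistanceMatrix(squareform(pdist(Y)),
                        ids=[f"s{i}" for i in range(20)])
    env = pd.DataFrame({"a": rng.normal(size=20)})
    env["b"] = 2 * env["a"]
    env.index = [f"s{i}" for i in range(20)]
    with pytest.raises(ValueError, match="rank"):
        dbrda(dm, env)


def test_forward_select_finds_planted_variable():
    rng = np.random.default_rng(7)
    n = 40
    signal = rng.normal(size=n)
    Y = np.column_stack([signal, 0.5 * signal, rng.normal(size=n) * 0.2])
    dm = DistanceMatrix(squareform(pdist(Y)), ids=[f"s{i}" for i in range(n)])
    env = pd.DataFrame(
        {"signal": signal, "noise1": rng.normal(size=n),
         "noise2": rng.normal(size=n)},
        index=[f"s{i}" for i in range(n)],
    )
    selected = forward_select(dm, env, alpha=0.05, n_perm=99, seed=0)
    assert selected and selected[0] == "signal"
    assert "noise1" not in selected and "noise2" not in selected


def test_forward_select_alpha_one_admits_everything():
    rng = np.random.default_rng(8)
    Y = rng.normal(size=(30, 4))
    dm = DistanceMatrix(squareform(pdist(Y)),
                        ids=[f"s{i}" for i in range(30)])
    env = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"],
                       index=[f"s{i}" for i in range(30)])
    assert set(forward_select(dm, env, alpha=1.0, n_perm=19, seed=0)) == {
        "a", "b", "c"
    }


def test_forward_select_pure_noise_selects_nothing():
    rng = np.random.default_rng(9)
    Y = rng.normal(size=(40, 5))
    dm = DistanceMatrix(squareform(pdist(Y)),
                        ids=[f"s{i}" for i in range(40)])
    env = pd.DataFrame(rng.normal(size=(40, 4)),
                       columns=list("abcd"),
                       index=[f"s{i}" for i in range(40)])
    selected = forward_select(dm, env, alpha=0.01, n_perm=199, seed=1)
    assert selected == []


def test_forward_select_validation():
    rng = np.random.default_rng(0)
    Y = rng.normal(size=(10, 2))
    dm = DistanceMatrix(squareform(pdist(Y)),
                        ids=[f"s{i}" for i in range(10)])
    env = pd.DataFrame({"a": rng.normal(size=10)},
                       index=[f"s{i}" for i in range(10)])
    with pytest.raises(ValueError, match="n_perm"):
        forward_select(dm, env, n_perm=10)
    with pytest.raises(ValueError, match="impute"):
        forward_select(dm, env.assign(a=np.nan), n_perm=19)
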
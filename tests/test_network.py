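import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scngraph import (
    CorrelationMatrix,
    binarize_at_density,
    correlation_matrix,
    density_sweep,
    min_connected_density,
    n_edges_at_density,
    zero_negatives,
)


def _toy_residuals():
    """4 subjects x 3 regions, plus group labels."""
    data = {
        "subject_id": list("abcd"),
        "group": ["patient"] * 4,
        "R1": [1.0, 2.0, 4.0, 3.0],
        "R2": [2.0, 1.0, 5.0, 4.0],
        "R3": [10.0, 8.0, 2.0, 4.0],
    }
    return pd.DataFrame(data)


def _corr(values, group="patient"):
    return CorrelationMatrix(np.asarray(values, float), group=group, n_subjects=10)


def test_density_sweep_grid():
    sweep = density_sweep()
    assert len(sweep) == 21
    assert sweep[0] == 0.10 and sweep[-1] == 0.50
    np.testing.assert_allclose(np.diff(sweep), 0.02)


def test_perfect_and_anti_correlation():
    df = _toy_residuals()
    df["R4"] = df["R1"]  # identical residuals
    df["R5"] = -df["R1"]
    corr = correlation_matrix(df, "patient", ["R1", "R4", "R5"])
    assert corr.values[0, 1] == pytest.approx(1.0, abs=1e-12)
    assert corr.values[0, 2] == pytest.approx(-1.0, abs=1e-12)
    assert np.all(np.diag(corr.values) == 0)


def test_correlation_matches_direct_formula():
    df = _toy_residuals()
    cols = ["R1", "R2", "R3"]
    corr = correlation_matrix(df, "patient", cols)
    X = df[cols].to_numpy()
    for i in range(3):
        for j in range(i + 1, 3):
            x, y = X[:, i] - X[:, i].mean(), X[:, j] - X[:, j].mean()
            r = (x * y).sum() / ((len(x) - 1) * x.std(ddof=1) * y.std(ddof=1))
            assert corr.values[i, j] == pytest.approx(r, abs=1e-12)


def test_correlation_errors():
    df = _toy_residuals()
    with pytest.raises(ValueError, match="need >= 3"):
        correlation_matrix(df.iloc[:2], "patient", ["R1", "R2"])
    flat = df.copy()
    flat["R2"] = 7.0
    with pytest.raises(ValueError, match="R2"):
        correlation_matrix(flat, "patient", ["R1", "R2"])


def test_zero_negatives_is_positive_part():
    m = np.array([[0, 0.5, -0.3], [0.5, 0, 0.0], [-0.3, 0.0, 0]])
    out = zero_negatives(_corr(m))
    expected = np.where(m > 0, m, 0.0)
    np.testing.assert_array_equal(out.values, expected)
    allpos = _corr([[0, 0.2, 0.4], [0.2, 0, 0.1], [0.4, 0.1, 0]])
    np.testing.assert_array_equal(zero_negatives(allpos).values, allpos.values)
    allneg = _corr(-np.array([[0, 0.2, 0.4], [0.2, 0, 0.1], [0.4, 0.1, 0]]))
    assert not zero_negatives(allneg).values.any()


def test_edge_budget_at_aal_scale():
    assert n_edges_at_density(90, 0.10) == 400
    assert n_edges_at_density(90, 0.50) == 2002


def test_binarize_keeps_top_ranked_pairs():
    """5-node toy matrix with a known ranking, K=4."""
    m = np.zeros((5, 5))
    ranking = {(0, 1): 0.9, (2, 3): 0.8, (0, 4): 0.7, (1, 2): 0.6,
               (3, 4): 0.5, (0, 2): 0.4, (1, 4): 0.3, (0, 3): 0.2,
               (2, 4): 0.1, (1, 3): 0.05}
    for (i, j), v in ranking.items():
        m[i, j] = m[j, i] = v
    # oracle: full sort of the 10 upper-triangle entries
    top4 = sorted(ranking, key=ranking.get, reverse=True)[:4]
    net = binarize_at_density(_corr(m), 0.4)  # K = floor(0.4*10) = 4
    assert net.n_edges == 4
    for i, j in top4:
        assert net.adjacency[i, j] and net.adjacency[j, i]


def test_binarize_saturation_equals_positive_indicator():
    m = np.zeros((5, 5))
    iu = np.triu_indices(5, 1)
    vals = np.array([0.5, -0.2, 0.4, 0.0, 0.3, -0.1, 0.2, 0.6, 0.1, 0.15])
    m[iu] = vals
    m += m.T
    n_pos = int((vals > 0).sum())
    net = binarize_at_density(_corr(m), n_pos / 10 + 0.04)
    np.testing.assert_array_equal(net.adjacency, m > 0)


def test_binarize_error_reports_max_achievable_density():
    m = np.zeros((5, 5))
    m[0, 1] = m[1, 0] = 0.5  # one positive pair only
    with pytest.raises(ValueError, match="maximum achievable density"):
        binarize_at_density(_corr(m), 0.5)


def test_group_size_independent_edge_count(small_residuals):
    sweep = density_sweep()
    for d in (0.10, 0.24, 0.50):
        nets = [
            binarize_at_density(
                zero_negatives(correlation_matrix(small_residuals, g)), d
            )
            for g in ("patient", "control")
        ]
        assert nets[0].n_edges == nets[1].n_edges == n_edges_at_density(90, d)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_edge_sets_nested_across_densities(seed):
    rng = np.random.default_rng(seed)
    n = 12
    m = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    m[iu] = rng.uniform(-1, 1, len(iu[0]))
    m += m.T
    corr = _corr(m)
    prev = None
    for d in (0.1, 0.2, 0.3):
        if n_edges_at_density(n, d) > (m[iu] > 0).sum():
            break
        A = binarize_at_density(corr, d).adjacency
        if prev is not None:
            assert np.all(A[prev])  # earlier edges all survive
        prev = A


def test_binarize_commutes_with_zeroing_negatives():
    rng = np.random.default_rng(7)
    n = 10
    m = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    m[iu] = rng.uniform(-1, 1, len(iu[0]))
    m += m.T
    corr = _corr(m)
    a = binarize_at_density(corr, 0.2).adjacency
    b = binarize_at_density(zero_negatives(corr), 0.2).adjacency
    np.testing.assert_array_equal(a, b)


def _corr_from_spanning_ring(n=20, strong=0.9, weak=0.1, seed=0):
    """Ring of strong correlations plus a weak positive floor."""
    rng = np.random.default_rng(seed)
    m = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    m[iu] = weak * rng.uniform(0.1, 1.0, len(iu[0]))
    m += m.T
    for i in range(n):
        j = (i + 1) % n
        m[i, j] = m[j, i] = strong - 0.001 * i  # distinct, all top-ranked
    np.fill_diagonal(m, 0)
    return _corr(m)


def test_min_connected_density_spanning_fixture():
    corr = _corr_from_spanning_ring()
    d, diag = min_connected_density(corr, corr, density_sweep())
    assert d == 0.10
    assert diag.iloc[0]["density"] == 0.10


def test_min_connected_density_onset_fixture():
    """Two cliques joined by one mid-ranked bridge connect at a known density."""
    n = 20
    rng = np.random.default_rng(3)
    m = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    m[iu] = 0.01 * rng.uniform(0.1, 1.0, len(iu[0]))  # tiny positive floor
    m += m.T
    for block in (range(10), range(10, 20)):
        for i in block:
            for j in block:
                if i < j:
                    m[i, j] = m[j, i] = rng.uniform(0.8, 0.9)
    m[0, 10] = m[10, 0] = 0.5  # the single bridge, ranked right after cliques
    np.fill_diagonal(m, 0)
    corr = _corr(m)
    # 90 clique pairs + 1 bridge: connected once K >= 91, i.e. d >= 91/190
    d, _ = min_connected_density(corr, corr, density_sweep())
    expected = next(x for x in density_sweep() if n_edges_at_density(n, x) >= 91)
    assert d == expected
    assert expected == 0.48


def test_min_connected_density_isolated_region_fails():
    n = 12
    rng = np.random.default_rng(4)
    m = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    m[iu] = rng.uniform(0.3, 0.9, len(iu[0]))
    m += m.T
    m[5, :] = m[:, 5] = -0.2  # region 5 has no positive correlation
    np.fill_diagonal(m, 0)
    names = tuple(f"ROI{i}" for i in range(n))
    corr = CorrelationMatrix(m, group="patient", n_subjects=10, region_names=names)
    with pytest.raises(ValueError, match="ROI5"):
        min_connected_density(corr, corr, density_sweep(0.10, 0.30, 0.02))
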
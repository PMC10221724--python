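"""Network construction: covariate adjustment, Pearson matrices,
density binarization, minimum connected density, density grids."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import covnet
from covnet import (
    ValidationError,
    adjust_for_mean_thickness,
    binarize_at_density,
    build_density_grid,
    minimum_connected_density,
    pearson_matrix,
    read_thickness_tables,
)
from covnet.construction import CovarianceMatrix, ranked_pairs, round_half_away

from conftest import toy_table


def _cov(r, labels=None):
    r = np.asarray(r, dtype=float)
    np.fill_diagonal(r, 0.0)
    labels = labels or [f"r{j:02d}" for j in range(r.shape[0])]
    return CovarianceMatrix(region_labels=list(labels), r=r)


def _random_cov(n, rng):
    r = rng.uniform(-1, 1, (n, n))
    r = (r + r.T) / 2
    return _cov(r)


# ---------------------------------------------------------------- adjustment

def test_adjust_orthogonal_regions_are_mean_centered():
    # covariate orthogonal to the region values -> slope 0, so the
    # residuals are simply the mean-centered inputs
    mean_t = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([5.0, 4.0, 4.0, 5.0])  # orthogonal to centered mean_t
    table = toy_table(np.column_stack([y, y + 1]), mean_thickness=mean_t)
    adjusted = adjust_for_mean_thickness(table)
    np.testing.assert_allclose(adjusted.values[:, 0], y - y.mean(), atol=1e-12)


def test_adjust_perfect_fit_gives_zero_residuals():
    mean_t = np.array([2.0, 2.5, 3.0, 3.5])
    table = toy_table(np.column_stack([2 * mean_t, mean_t + 1]),
                      mean_thickness=mean_t)
    adjusted = adjust_for_mean_thickness(table)
    np.testing.assert_allclose(adjusted.values, 0.0, atol=1e-12)


def test_adjust_matches_hand_solved_least_squares():
    # meanT = 1..5, y = 3 + 0.5 meanT + e with listed errors; the residuals
    # equal e minus its projection onto [1, meanT].  Normal equations solved
    # by hand: slope = Sxy/Sxx on centered data.
    mean_t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    e = np.array([0.2, -0.1, 0.0, 0.3, -0.4])
    y = 3 + 0.5 * mean_t + e
    xc = mean_t - 3.0
    slope_e = (xc @ (e - e.mean())) / (xc @ xc)       # = (0.2-(-0.1)*... )
    expected = (e - e.mean()) - slope_e * xc
    table = toy_table(y[:, None], mean_thickness=mean_t)
    adjusted = adjust_for_mean_thickness(table)
    np.testing.assert_allclose(adjusted.values[:, 0], expected, atol=1e-12)


def test_adjust_residuals_uncorrelated_with_covariate(rng):
    values = rng.uniform(2.0, 3.0, size=(30, 10))
    table = toy_table(values)
    adjusted = adjust_for_mean_thickness(table)
    for j in range(10):
        r = np.corrcoef(adjusted.values[:, j], table.mean_thickness)[0, 1]
        assert abs(r) < 1e-10
    np.testing.assert_allclose(adjusted.values.mean(axis=0), 0.0, atol=1e-12)


def test_adjust_constant_covariate_falls_back_to_centering(caplog):
    values = np.array([[2.0, 3.0], [2.5, 2.0], [3.0, 2.5]])
    table = toy_table(values, mean_thickness=np.full(3, 2.5))
    with caplog.at_level("WARNING"):
        adjusted = adjust_for_mean_thickness(table)
    np.testing.assert_allclose(
        adjusted.values, values - values.mean(axis=0), atol=1e-12
    )
    assert "mean thickness constant" in caplog.text


def test_adjust_requires_three_subjects():
    table = toy_table(np.array([[2.0, 2.1], [2.2, 2.3]]))
    with pytest.raises(ValidationError):
        adjust_for_mean_thickness(table)


# ------------------------------------------------------------------ pearson

def test_pearson_duplicated_and_anticorrelated_columns():
    y = np.array([2.0, 2.5, 3.0, 2.2])
    values = np.column_stack([y, y, 5.0 - y])
    c = pearson_matrix(toy_table(values))
    assert c.r[0, 1] == pytest.approx(1.0)
    assert c.r[0, 2] == pytest.approx(-1.0)
    assert np.all(np.diag(c.r) == 0)


def test_pearson_matches_independent_computation():
    values = np.array(
        [[1.0, 2.0, 5.0], [2.0, 1.0, 7.0], [3.0, 5.0, 4.0], [4.0, 3.0, 8.0]]
    )
    c = pearson_matrix(toy_table(values))
    for i in range(3):
        for j in range(i + 1, 3):
            expected = stats.pearsonr(values[:, i], values[:, j]).statistic
            assert c.r[i, j] == pytest.approx(expected, abs=1e-12)


def test_pearson_zero_variance_region_zeroed(caplog):
    values = np.array([[1.0, 2.0], [2.0, 2.0], [3.0, 2.0]])
    with caplog.at_level("WARNING"):
        c = pearson_matrix(toy_table(values))
    assert np.all(c.r == 0)
    assert "zero-variance" in caplog.text


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    a=st.floats(0.1, 10), b=st.floats(-5, 5),
    seed=st.integers(0, 1000),
)
def test_pearson_affine_invariance(a, b, seed):
    rng = np.random.default_rng(seed)
    values = rng.uniform(1.0, 3.0, size=(8, 4))
    scaled = values.copy()
    scaled[:, 0] = a * scaled[:, 0] + b
    # keep positivity for the raw-table invariant
    scaled[:, 0] += max(0.0, 1e-3 - scaled[:, 0].min())
    r1 = pearson_matrix(toy_table(values)).r
    values2 = values.copy()
    values2[:, 0] = scaled[:, 0]
    r2 = pearson_matrix(toy_table(values2)).r
    np.testing.assert_allclose(r1, r2, atol=1e-10)


# ----------------------------------------------------------------- binarize

def test_binarize_full_density_gives_complete_graph(rng):
    c = _random_cov(5, rng)
    a = binarize_at_density(c, 1.0)
    assert a.n_edges == 10
    assert np.all(a.a + np.eye(5) == 1)


def test_binarize_edge_count_at_study_density(rng):
    c = _random_cov(68, rng)
    a = binarize_at_density(c, 0.17)
    assert a.n_edges == round_half_away(0.17 * 2278) == 387


def test_binarize_selects_top_ranked_pairs():
    r = np.zeros((5, 5))
    vals = [0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1, 0.05]
    iu = np.triu_indices(5, 1)
    r[iu] = vals
    r = r + r.T
    c = _cov(r)
    a = binarize_at_density(c, 0.3)  # 3 edges: the 0.9, 0.8, 0.7 pairs
    expected = {(iu[0][k], iu[1][k]) for k in range(3)}
    got = set(zip(*np.where(np.triu(a.a, 1))))
    assert got == expected


def test_binarize_nested_edge_sets(rng):
    c = _random_cov(20, rng)
    prev = None
    for d in (0.1, 0.2, 0.35, 0.5, 0.8):
        a = binarize_at_density(c, d).a
        if prev is not None:
            assert np.all(a >= prev)  # edge set contains the sparser one
        prev = a


def test_binarize_tie_break_deterministic():
    r = np.full((4, 4), 0.5)
    c = _cov(r.copy())
    a1 = binarize_at_density(c, 0.5)
    a2 = binarize_at_density(_cov(r.copy()), 0.5)
    np.testing.assert_array_equal(a1.a, a2.a)
    assert a1.n_edges == 3
    # lexicographically first pairs selected among the all-tied values
    assert set(zip(*np.where(np.triu(a1.a, 1)))) == {(0, 1), (0, 2), (0, 3)}


def test_binarize_warns_when_negatives_admitted(rng, caplog):
    r = -np.abs(np.random.default_rng(0).uniform(0.1, 1, (6, 6)))
    r = (r + r.T) / 2
    with caplog.at_level("WARNING"):
        binarize_at_density(_cov(r), 0.5)
    assert "positive" in caplog.text


# -------------------------------------------------------------------- d_min

def test_minimum_density_spanning_tree_ranking():
    # 10 nodes: top 9 ranked pairs form a star (a spanning tree), so the
    # network connects at 9 of 45 edges -> smallest 0.01 multiple with
    # round(d * 45) >= 9 is 0.19; at 0.20 round(9)=9 too but 0.19*45=8.55->9.
    n = 10
    r = np.zeros((n, n))
    for j in range(1, n):
        r[0, j] = r[j, 0] = 1.0 - 0.01 * j
    iu = np.triu_indices(n, 1)
    rest = np.random.default_rng(1).uniform(0.0, 0.5, len(iu[0]))
    for k, (i, j) in enumerate(zip(*iu)):
        if i != 0:
            r[i, j] = r[j, i] = rest[k]
    d = minimum_connected_density(_cov(r))
    assert d == pytest.approx(0.19)
    assert round_half_away(d * 45) == 9


def test_minimum_density_matches_brute_force(rng):
    # brute-force oracle: scan every multiple of the resolution, binarize,
    # and check connectivity by breadth-first search
    def bfs_connected(a):
        n = a.shape[0]
        seen = {0}
        stack = [0]
        while stack:
            i = stack.pop()
            for j in np.flatnonzero(a[i]):
                if j not in seen:
                    seen.add(int(j))
                    stack.append(int(j))
        return len(seen) == n

    for seed in range(5):
        c = _random_cov(12, np.random.default_rng(seed))
        expected = None
        for k in range(1, 101):
            d = round(k * 0.01, 10)
            if bfs_connected(binarize_at_density(c, d).a):
                expected = d
                break
        assert minimum_connected_density(c) == pytest.approx(expected)


def test_minimum_density_refinement_is_monotone(rng):
    c = _random_cov(12, rng)
    assert (minimum_connected_density(c, 0.001)
            <= minimum_connected_density(c, 0.01))


def test_networks_at_or_above_dmin_connected(rng):
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    c = _random_cov(15, rng)
    d_min = minimum_connected_density(c)
    for d in np.arange(d_min, 1.0, 0.1):
        a = binarize_at_density(c, float(d)).a
        assert connected_components(csr_matrix(a), directed=False)[0] == 1


# --------------------------------------------------------------------- grid

@pytest.mark.parametrize(
    "d_a,d_b,first,last,n",
    [
        (0.17, 0.11, 0.17, 0.47, 7),
        (0.09, 0.11, 0.11, 0.46, 8),
        (0.40, 0.40, 0.40, 0.50, 3),
    ],
)
def test_density_grid_enumeration(d_a, d_b, first, last, n):
    grid = build_density_grid(d_a, d_b)
    assert grid.densities[0] == pytest.approx(first)
    assert grid.densities[-1] == pytest.approx(last)
    assert len(grid.densities) == n
    assert all(y > x for x, y in zip(grid.densities, grid.densities[1:]))


def test_density_grid_rejects_lower_above_upper():
    with pytest.raises(ValidationError):
        build_density_grid(0.6, 0.2)


# ----------------------------------------------------------------------- io

def test_table_roundtrip(tmp_path, small_cohort_config):
    tables = covnet.generate_cohort(small_cohort_config)
    path = tmp_path / "cohort.tsv"
    import pandas as pd

    pd.concat([t.to_frame() for t in tables.values()]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )
    back = read_thickness_tables(path)
    assert sorted(back) == sorted(tables)
    for g in tables:
        np.testing.assert_allclose(back[g].values, tables[g].values,
                                   rtol=0, atol=1e-15)
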
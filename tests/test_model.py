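"""Forests, importance metrics, selection, CV, semivariograms and rank tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from globeseed import model
from conftest import make_record


def _toy_regression(rng, n=200, p=4, beta=None, noise=1.0):
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)])
    beta = np.zeros(p) if beta is None else np.asarray(beta, dtype=float)
    y = X.to_numpy() @ beta + noise * rng.normal(size=n)
    return X, y


# ----------------------------------------------------------------- forests

def test_forest_defaults_and_reproducibility(rng):
    X, y = _toy_regression(rng, beta=[2, 0, 0, 0])
    f1 = model.fit_forest(X, y, seed=3)
    f2 = model.fit_forest(X, y, seed=3)
    assert f1.n_trees == 100
    assert f1.oob_mse == f2.oob_mse
    pd.testing.assert_frame_equal(f1.importance, f2.importance)


def test_forest_constant_response_has_no_signal(rng):
    X, _ = _toy_regression(rng)
    y = np.full(len(X), 7.0)
    f = model.fit_forest(X, y, seed=0)
    assert np.allclose(f.importance["node_purity"], 0.0)
    assert f.oob_r2 <= 0.0


def test_forest_refuses_tiny_input(rng):
    X, y = _toy_regression(rng, n=8)
    with pytest.raises(ValueError, match="10"):
        model.fit_forest(X, y, seed=0)


def test_forest_drops_and_counts_missing_rows(rng):
    X, y = _toy_regression(rng, n=60, beta=[1, 0, 0, 0])
    X.iloc[3, 0] = np.nan
    X.iloc[10, 2] = np.nan
    f = model.fit_forest(X, y, seed=1)
    assert f.n_dropped_missing == 2
    assert f.n_used == 58


def test_node_purity_conserves_total_split_gain(rng):
    """Per-variable node-purity importances sum to the forest's total split
    gain, computed independently as root RSS minus summed leaf RSS per tree."""
    X, y = _toy_regression(rng, n=50, beta=[2, 1, 0, 0])
    f = model.fit_forest(X, y, n_trees=3, seed=5)
    total_importance = f.importance["node_purity"].sum()
    total_gain = 0.0
    for est in f.model.estimators_:
        t = est.tree_
        leaves = t.children_left == -1
        root_rss = t.weighted_n_node_samples[0] * t.impurity[0]
        leaf_rss = float(
            np.sum(t.weighted_n_node_samples[leaves] * t.impurity[leaves])
        )
        total_gain += root_rss - leaf_rss
    assert total_importance == pytest.approx(total_gain, rel=1e-9)


def test_shuffled_copy_importance_indistinguishable_from_zero():
    """Sign test over 20 seeded draws: the permutation importance of a
    shuffled copy of an informative predictor centers on zero."""
    signs = []
    for seed in range(20):
        r = np.random.default_rng(seed)
        X, y = _toy_regression(r, n=300, p=3, beta=[3, 1, 0])
        X["copy"] = r.permutation(X["x0"].to_numpy())
        f = model.fit_forest(X, y, seed=seed, permutation_repeats=2)
        v = f.importance.loc["copy", "pct_inc_mse"]
        if v != 0:
            signs.append(v > 0)
    assert len(signs) >= 10
    p = stats.binomtest(sum(signs), len(signs), 0.5).pvalue
    assert p > 0.01


# --------------------------------------------------------------- selection

def test_selection_picks_response_copy(rng):
    X, y = _toy_regression(rng, n=300, p=2, beta=[0, 0], noise=1.0)
    X["self"] = y  # a candidate that is the response itself
    res = model.select_variables(X, y, seed=0)
    assert res.selected == ["self"]


def test_selection_requires_two_candidates(rng):
    X, y = _toy_regression(rng, n=50, p=1)
    with pytest.raises(ValueError):
        model.select_variables(X, y, seed=0)


def test_selection_empty_under_strong_null_is_reported(rng):
    X, y = _toy_regression(rng, n=300, p=5, beta=None)
    res = model.select_variables(X, y, seed=1)
    assert set(res.selected) <= set(res.candidates)
    assert len(res.selected) <= 1


# ---------------------------------------------------------------------- CV

def test_cv_contract_and_constant_response(rng):
    X, _ = _toy_regression(rng, n=100)
    y = np.full(100, 4.2)
    res = model.kfold_cv(X, y, n_trees=10, iterations=7, seed=0)
    assert res.iterations == 7
    assert np.allclose(res.mse, 0.0)
    with pytest.raises(ValueError):
        model.kfold_cv(X, y, iterations=0)
    with pytest.raises(ValueError):
        model.kfold_cv(X, y, holdout_fraction=1.5)
    with pytest.raises(ValueError):
        model.kfold_cv(X.head(12), y[:12], holdout_fraction=0.05)  # 1-row holdout


# ----------------------------------------------------------- partial effects

def test_partial_effect_contract(rng):
    X, y = _toy_regression(rng, n=200, beta=[2, 0, 0, 0])
    f = model.fit_forest(X, y, seed=2, compute_importance=False)
    pe = model.partial_effect(f, "x0", m=17)
    assert len(pe.grid) == 17 and len(pe.effect) == 17
    assert not pe.extrapolated.any()
    wide = model.partial_effect(f, "x0", grid=np.linspace(-100, 100, 5))
    assert wide.extrapolated[0] and wide.extrapolated[-1]
    with pytest.raises(ValueError):
        model.partial_effect(f, "nope")


def test_partial_effect_flat_for_null_predictor(rng):
    ranges = []
    for seed in range(5):
        r = np.random.default_rng(seed)
        X, y = _toy_regression(r, n=1000, p=4, beta=[3, 0, 0, 0])
        f = model.fit_forest(X, y, seed=seed, compute_importance=False)
        pe = model.partial_effect(f, "x3", m=15)
        ranges.append(pe.effect.max() - pe.effect.min())
    assert np.mean(ranges) < 0.1 * np.std(y)


# ------------------------------------------------------------ semivariogram

def _haversine_oracle(p1, p2):
    """Independent great-circle distance via 3-D chord length."""
    lat1, lon1 = np.radians(p1)
    lat2, lon2 = np.radians(p2)
    v1 = np.array(
        [np.cos(lat1) * np.cos(lon1), np.cos(lat1) * np.sin(lon1), np.sin(lat1)]
    )
    v2 = np.array(
        [np.cos(lat2) * np.cos(lon2), np.cos(lat2) * np.sin(lon2), np.sin(lat2)]
    )
    chord = np.linalg.norm(v1 - v2)
    return 2 * 6371.0 * np.arcsin(np.clip(chord / 2, 0, 1))


def _semivariogram_brute(coords, values, edges):
    n = len(values)
    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = _haversine_oracle(coords[i], coords[j])
            for b in range(len(edges) - 1):
                if edges[b] <= d < edges[b + 1]:
                    sums[b] += (values[i] - values[j]) ** 2
                    counts[b] += 1
    gamma = np.full(len(edges) - 1, np.nan)
    ok = counts > 0
    gamma[ok] = sums[ok] / (2 * counts[ok])
    return gamma, counts


def test_semivariogram_constant_field_is_zero(rng):
    coords = rng.uniform([-60, -120], [60, 120], size=(30, 2))
    sv = model.empirical_semivariogram(coords, np.full(30, 5.0))
    assert np.all((sv.gamma == 0) | np.isnan(sv.gamma))


def test_semivariogram_matches_pairwise_brute_force(rng):
    for n in (5, 20, 50):
        coords = rng.uniform([-60, -120], [60, 120], size=(n, 2))
        values = rng.normal(size=n)
        edges = np.linspace(0, 10000, 8)
        sv = model.empirical_semivariogram(coords, values, bin_edges=edges)
        gamma, counts = _semivariogram_brute(coords, values, edges)
        np.testing.assert_array_equal(sv.counts, counts)
        np.testing.assert_allclose(sv.gamma, gamma, rtol=1e-8)


def test_semivariogram_five_listed_points():
    coords = np.array([[0, 0], [0, 1], [0, 2], [1, 0], [2, 0]], dtype=float)
    values = [1.0, 2.0, 4.0, 8.0, 16.0]
    edges = np.array([0.0, 150.0, 300.0])
    sv = model.empirical_semivariogram(coords, values, bin_edges=edges)
    gamma, counts = _semivariogram_brute(coords, values, edges)
    np.testing.assert_array_equal(sv.counts, counts)
    np.testing.assert_allclose(sv.gamma, gamma, rtol=1e-8)
    assert sv.counts.sum() <= 10  # pairs within max lag only


def test_semivariogram_input_errors(rng):
    with pytest.raises(ValueError):
        model.empirical_semivariogram(np.array([[0.0, 0.0]]), [1.0])
    with pytest.raises(ValueError):
        model.empirical_semivariogram(
            np.zeros((3, 2)), [1.0, np.nan, 2.0]
        )


# ---------------------------------------------------------- Kruskal-Wallis

def _kruskal_oracle(groups):
    """Textbook tie-corrected H from scratch."""
    allv = np.concatenate(groups)
    n = len(allv)
    order = np.argsort(allv, kind="mergesort")
    ranks = np.empty(n)
    sv = allv[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, t_counts = np.unique(allv, return_counts=True)
    correction = 1 - np.sum(t_counts**3 - t_counts) / (n**3 - n)
    return h / correction if correction > 0 else np.nan


def _records_from_groups(groups):
    biomes = ["TBMF", "TGSS", "TUN", "BFT", "TCF"]
    recs = []
    for g, vals in enumerate(groups):
        for i, v in enumerate(vals):
            recs.append(
                make_record(record_id=f"g{g}i{i}", biome=biomes[g], value=float(v))
            )
    return recs


def test_kruskal_known_instance_h_7_2():
    recs = _records_from_groups([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
    res = model.kruskal_wallis_by_biome(recs, "diversity")
    assert res["H"] == pytest.approx(7.2)
    assert res["df"] == 2


def test_kruskal_identical_groups_h_zero():
    recs = _records_from_groups([[3, 1, 2], [1, 2, 3]])
    res = model.kruskal_wallis_by_biome(recs, "diversity")
    assert res["H"] == pytest.approx(0.0)


def test_kruskal_single_biome_refused():
    recs = _records_from_groups([[1, 2, 3]])
    with pytest.raises(ValueError):
        model.kruskal_wallis_by_biome(recs, "diversity")


def test_kruskal_matches_rank_formula_on_100_seeded_instances():
    rng = np.random.default_rng(77)
    for _ in range(100):
        k = int(rng.integers(2, 5))
        groups = [
            np.round(rng.normal(loc=rng.normal(), size=rng.integers(4, 12)), 1)
            for _ in range(k)
        ]
        recs = _records_from_groups(groups)
        res = model.kruskal_wallis_by_biome(recs, "diversity")
        assert res["H"] == pytest.approx(_kruskal_oracle(groups), rel=1e-9)


# --------------------------------------------------------------- hemisphere

def test_hemisphere_all_northern_is_all_skipped():
    recs = [make_record(record_id=f"n{i}", latitude=40.0 + i) for i in range(6)]
    table = model.hemisphere_comparison(recs, "diversity")
    assert table["skipped"].all()


def test_hemisphere_one_row_per_shared_biome(rng):
    recs = []
    for i in range(20):
        recs.append(make_record(record_id=f"n{i}", latitude=40.0, biome="TBMF",
                                value=float(rng.normal(10, 2))))
        recs.append(make_record(record_id=f"s{i}", latitude=-40.0, biome="TBMF",
                                value=float(rng.normal(10, 2))))
        recs.append(make_record(record_id=f"g{i}", latitude=35.0, biome="TGSS",
                                value=float(rng.normal(10, 2))))
    table = model.hemisphere_comparison(recs, "diversity")
    assert len(table) == 2
    shared = table.set_index("biome").loc["TBMF"]
    assert not shared["skipped"]
    only_north = table.set_index("biome").loc["TGSS"]
    assert only_north["skipped"]


def test_hemisphere_null_rarely_significant():
    hits = 0
    trials = 20
    for seed in range(trials):
        r = np.random.default_rng(seed)
        recs = []
        for i in range(25):
            recs.append(make_record(record_id=f"n{i}", latitude=45.0,
                                    value=float(r.normal(10, 2))))
            recs.append(make_record(record_id=f"s{i}", latitude=-45.0,
                                    value=float(r.normal(10, 2))))
        table = model.hemisphere_comparison(recs, "diversity")
        hits += int(table["significant"].iloc[0])
    assert hits <= 2  # ~alpha = 0.05 under the null
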
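"""Niche-metric operations: cleaning, grid aggregation, PCA, hypervolumes,
diet/habitat/wingspan/dispersal predictors."""

import numpy as np
import pandas as pd
import pytest

from phylorange import niche, phylo, simulate
from phylorange.niche import (
    InsufficientPointsError,
    aggregate_grid,
    clean_occurrences,
    climate_niche_breadth,
    diet_niche_breadth,
    dispersal_class,
    env_pca_project,
    habitat_niche_breadth,
    svm_hypervolume,
    wingspan_index,
)


# ------------------------------------------------------------------ cleaning

def _occ(rows):
    return pd.DataFrame(rows, columns=["species", "lon", "lat", "year", "uncertainty_m"])


def test_clean_occurrences_rules():
    records = _occ(
        [
            ("a", 10.0, 45.0, 1995, 500.0),   # keep
            ("a", 10.0, 45.0, 2001, 100.0),   # duplicate coords -> drop
            ("a", 0.0, 45.0, 1995, 500.0),    # zero lon -> drop
            ("a", 10.0, 0.0, 1995, 500.0),    # zero lat -> drop
            ("a", 11.0, 45.0, 1979, 500.0),   # pre-1980 -> drop
            ("a", 12.0, 45.0, 1995, 15000.0),  # > 10 km uncertainty -> drop
            ("b", 12.0, 45.0, 1980, 10000.0),  # boundary values kept
        ]
    )
    out = clean_occurrences(records)
    assert list(out.index) == [0, 6]


def test_clean_occurrences_idempotent():
    records = _occ(
        [("a", 10.0, 45.0, 1995, 500.0), ("a", 10.0, 45.0, 2005, 50.0), ("c", -3.0, 7.0, 2019, 0.0)]
    )
    once = clean_occurrences(records)
    twice = clean_occurrences(once)
    assert once.equals(twice)


def test_clean_occurrences_rejects_bad_coordinates():
    with pytest.raises(ValueError, match="rows"):
        clean_occurrences(_occ([("a", 200.0, 45.0, 1995, 1.0)]))


# ------------------------------------------------------------- aggregation

def _fine_grid(lons, lats, value_fn):
    rows = [
        {"lon": lon, "lat": lat, **{f"bio{i}": value_fn(lon, lat, i) for i in range(1, 20)}}
        for lat in lats
        for lon in lons
    ]
    return pd.DataFrame(rows)


def test_aggregate_constant_field_unchanged():
    res = 0.5
    lons = np.arange(0.25, 4, res)
    lats = np.arange(0.25, 4, res)
    fine = _fine_grid(lons, lats, lambda lon, lat, i: 7.5)
    coarse = aggregate_grid(fine, 4, resolution=res)
    np.testing.assert_allclose(coarse["bio1"], 7.5)
    assert len(coarse) == 4


def test_aggregate_equator_block_plain_mean():
    # 2x2 block symmetric about the equator: cosine weights are equal
    res = 1.0
    fine = _fine_grid([0.5, 1.5], [-0.5, 0.5], lambda lon, lat, i: 0.0)
    fine["bio1"] = [1.0, 2.0, 3.0, 4.0]
    coarse = aggregate_grid(fine, 2, resolution=res)
    assert len(coarse) == 1
    assert coarse["bio1"].iloc[0] == pytest.approx(2.5)


def test_aggregate_matches_cosine_weighted_oracle():
    res = 1.0
    lats = [40.5, 41.5, 42.5]
    fine = _fine_grid([10.5, 11.5, 12.5], lats, lambda lon, lat, i: lon + lat * i)
    coarse = aggregate_grid(fine, 3, resolution=res)
    w = np.cos(np.deg2rad(fine["lat"]))
    for col in ["bio1", "bio7"]:
        expected = np.sum(w * fine[col]) / np.sum(w)
        assert coarse[col].iloc[0] == pytest.approx(expected, rel=1e-12)


def test_aggregate_rejects_bad_factor():
    fine = _fine_grid([0.5], [0.5], lambda lon, lat, i: 1.0)
    with pytest.raises(ValueError):
        aggregate_grid(fine, 0)


# -------------------------------------------------------------------- PCA

def _random_grid(n, seed, n_vars=19):
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(n, 5))
    mix = rng.normal(size=(5, n_vars))
    data = base @ mix + 0.1 * rng.normal(size=(n, n_vars))
    df = pd.DataFrame(data, columns=[f"bio{i}" for i in range(1, n_vars + 1)])
    df.insert(0, "lat", rng.uniform(-60, 60, n))
    df.insert(0, "lon", rng.uniform(-180, 180, n))
    return df


def test_pca_scores_have_diagonal_covariance():
    grid = _random_grid(2000, 1)
    pca = env_pca_project(grid, n_sample=2000, seed=0)
    scores = pca.project(grid)
    cov = np.cov(scores.T)
    np.testing.assert_allclose(cov, np.diag(np.diag(cov)), atol=1e-8)
    np.testing.assert_allclose(np.diag(cov), pca.explained_variance, rtol=1e-6)
    # loadings orthonormal
    np.testing.assert_allclose(pca.loadings.T @ pca.loadings, np.eye(4), atol=1e-10)


def test_pca_first_axis_stable_under_variable_duplication():
    # duplicating the variable block leaves the leading axis direction intact
    # (up to sign) because the eigenstructure is replicated across the blocks
    grid = _random_grid(1500, 2, n_vars=8)
    cols = [f"bio{i}" for i in range(1, 9)]
    dup = grid.copy()
    for i, c in enumerate(cols, start=9):
        dup[f"bio{i}"] = grid[c]
    p1 = env_pca_project(grid, n_sample=1500, seed=0)
    p2 = env_pca_project(dup, n_sample=1500, seed=0)
    v1 = p1.loadings[:, 0]
    v2 = p2.loadings[:8, 0]
    v2 = v2 / np.linalg.norm(v2)
    assert min(np.linalg.norm(v1 - v2), np.linalg.norm(v1 + v2)) < 1e-6


def test_pca_seed_determinism_and_constant_error():
    grid = _random_grid(3000, 3)
    a = env_pca_project(grid, n_sample=500, seed=7)
    b = env_pca_project(grid, n_sample=500, seed=7)
    np.testing.assert_array_equal(a.loadings, b.loadings)
    grid["bio1"] = 5.0
    with pytest.raises(ValueError, match="bio1"):
        env_pca_project(grid, n_sample=500, seed=7)


# ------------------------------------------------------------- hypervolumes

def test_hypervolume_deterministic_and_positive():
    cloud = simulate.simulate_occurrence_cloud(800, sides=(1, 1, 1, 1), seed=1)
    a = svm_hypervolume(cloud.points, seed=3)
    b = svm_hypervolume(cloud.points, seed=3)
    assert a.volume == b.volume
    assert a.volume > 0


def test_hypervolume_rejects_few_points():
    with pytest.raises(InsufficientPointsError):
        svm_hypervolume(np.zeros((4, 4)))


def test_hypervolume_scaling_law():
    # doubling every axis should multiply the volume by ~2^4 (adaptive gamma
    # rescales the kernel automatically)
    cloud = simulate.simulate_occurrence_cloud(2000, sides=(1, 1, 1, 1), seed=5)
    v1 = svm_hypervolume(cloud.points, seed=0).volume
    v2 = svm_hypervolume(cloud.points * 2.0, seed=0).volume
    assert v2 / v1 == pytest.approx(16.0, rel=0.2)


def test_hypervolume_nested_clouds_ordered():
    # a superset cloud occupying a larger box gets a larger volume
    rng = np.random.default_rng(11)
    small = rng.uniform(0, 1, size=(1000, 4))
    big = np.vstack([small, rng.uniform(0, 1, size=(1000, 4)) * np.array([2, 1, 1, 1])])
    vols_small = [svm_hypervolume(small, seed=s).volume for s in range(3)]
    vols_big = [svm_hypervolume(big, seed=s).volume for s in range(3)]
    assert np.mean(vols_big) > np.mean(vols_small)


# --------------------------------------------------- climate niche breadth

def _grid_and_pca(seed=0):
    rng = np.random.default_rng(seed)
    res = 1.0
    lons = np.arange(-19.5, 20.5, res)
    lats = np.arange(-9.5, 10.5, res)
    rows = []
    for lat in lats:
        for lon in lons:
            rows.append({"lon": lon, "lat": lat,
                         **{f"bio{i}": np.sin(i * lon / 7.0) + lat / (3.0 + i) + rng.normal(0, 0.3)
                            for i in range(1, 20)}})
    grid = pd.DataFrame(rows)
    return grid, env_pca_project(grid, n_sample=len(grid), seed=0), res


def _occ_for_cells(species, lons, lats):
    return pd.DataFrame(
        {"species": species, "lon": lons, "lat": lats, "year": 2000, "uncertainty_m": 10.0}
    )


def test_climate_breadth_capped_replicates_identical_under_cap():
    grid, pca, res = _grid_and_pca()
    rng = np.random.default_rng(2)
    lons = rng.choice(grid["lon"].unique(), 40, replace=False) + 0.2
    lats = rng.choice(grid["lat"].unique(), 40, replace=True) + 0.2
    occ = _occ_for_cells("sp1", lons, lats)
    out = climate_niche_breadth(occ, grid, pca, res, cap=50, n_replicates=5, seed=0)
    reps = out.loc["sp1", [f"climate_nb_rep{k}" for k in range(1, 6)]].astype(float)
    assert reps.nunique() == 1


def test_climate_breadth_small_species_imputed_to_minimum():
    grid, pca, res = _grid_and_pca()
    rng = np.random.default_rng(3)
    big_lons = rng.choice(grid["lon"].unique(), 30, replace=False) + 0.1
    big_lats = rng.choice(grid["lat"].unique(), 30, replace=True) + 0.1
    occ = pd.concat(
        [
            _occ_for_cells("wide", big_lons, big_lats),
            _occ_for_cells("mid", big_lons[:8], big_lats[:8]),
            _occ_for_cells("endemic", big_lons[:4], big_lats[:4]),
        ]
    )
    out = climate_niche_breadth(occ, grid, pca, res, cap=None, seed=0)
    assert bool(out.loc["endemic", "imputed"])
    computed = out.loc[~out["imputed"], "climate_nb"]
    assert out.loc["endemic", "climate_nb"] == pytest.approx(float(computed.min()))


def test_climate_breadth_identical_cell_sets_identical_volumes():
    grid, pca, res = _grid_and_pca()
    rng = np.random.default_rng(4)
    lons = rng.choice(grid["lon"].unique(), 25, replace=False) + 0.3
    lats = rng.choice(grid["lat"].unique(), 25, replace=True) + 0.3
    occ = pd.concat([_occ_for_cells("x", lons, lats), _occ_for_cells("y", lons, lats)])
    out = climate_niche_breadth(occ, grid, pca, res, cap=None, seed=0)
    assert out.loc["x", "climate_nb"] == out.loc["y", "climate_nb"]


# ----------------------------------------------------- diet niche breadth

def test_diet_breadth_trivial_and_oracle():
    host_tree, table = simulate.simulate_host_data(15, 30, seed=1)
    pd_series = diet_niche_breadth(table, host_tree)
    for sp, genera in list(table.items())[:10]:
        # edge-union oracle
        leaves = {l.taxon.label: l for l in host_tree.leaf_node_iter()}
        edges = {}
        for g in genera:
            node = leaves[g]
            while node.parent_node is not None:
                edges[id(node)] = node.edge.length
                node = node.parent_node
        assert pd_series[sp] == pytest.approx(sum(edges.values()), rel=1e-10)


def test_diet_breadth_all_genera_equals_total_length():
    host_tree, _ = simulate.simulate_host_data(12, 5, seed=2)
    tips = phylo.tip_labels(host_tree)
    out = diet_niche_breadth({"sp": set(tips)}, host_tree)
    assert out["sp"] == pytest.approx(phylo.total_branch_length(host_tree))


def test_diet_breadth_missing_genus_listed():
    host_tree, _ = simulate.simulate_host_data(10, 5, seed=3)
    with pytest.raises(KeyError, match="nope"):
        diet_niche_breadth({"sp": {"nope"}}, host_tree)


# ------------------------------------------------- habitat niche breadth

def test_habitat_breadth_counts():
    out = habitat_niche_breadth(
        {"a": {"grasslands", "forest"}, "b": set(niche.HABITAT_TYPES)}
    )
    assert out["a"] == 2
    assert out["b"] == 7


def test_habitat_breadth_errors():
    with pytest.raises(ValueError, match="swamp"):
        habitat_niche_breadth({"a": {"swamp"}})
    with pytest.raises(ValueError):
        habitat_niche_breadth({"a": set()})


# --------------------------------------------------------------- wingspan

def test_wingspan_geometric_then_arithmetic_mean():
    recs = pd.DataFrame(
        {
            "species": ["a", "b", "b"],
            "min_mm": [30.0, 28.0, 30.0],
            "max_mm": [40.0, 32.14285714285714, 38.53333333333333],
            "sex_scope": ["both", "both", "both"],
            "source": ["s1", "s1", "s2"],
        }
    )
    out = wingspan_index(recs)
    assert out["a"] == pytest.approx(np.sqrt(1200.0))
    assert out["b"] == pytest.approx((30.0 + 34.0) / 2, rel=1e-6)


def test_wingspan_prefers_female_sources():
    recs = pd.DataFrame(
        {
            "species": ["a", "a"],
            "min_mm": [30.0, 50.0],
            "max_mm": [30.0, 50.0],
            "sex_scope": ["female", "both"],
            "source": ["s1", "s2"],
        }
    )
    assert wingspan_index(recs)["a"] == pytest.approx(30.0)


def test_wingspan_rejects_inverted_range():
    recs = pd.DataFrame(
        {"species": ["a"], "min_mm": [40.0], "max_mm": [30.0], "sex_scope": ["both"], "source": ["s"]}
    )
    with pytest.raises(ValueError):
        wingspan_index(recs)


# --------------------------------------------------------------- dispersal

@pytest.mark.parametrize(
    "raw,expected",
    [("sedentary", 1), ("moderately mobile", 2), ("dispersive", 3),
     (1, 1), (3, 1), (4, 2), (6, 2), (7, 3), (9, 3)],
)
def test_dispersal_class_mapping(raw, expected):
    assert dispersal_class(raw) == expected


@pytest.mark.parametrize("raw", [0, 10, "nomadic"])
def test_dispersal_class_rejects_invalid(raw):
    with pytest.raises(ValueError):
        dispersal_class(raw)
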
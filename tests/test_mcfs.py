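"""Monte Carlo feature selection: RI aggregation, ranking, permutation cutoff."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pdxorigin.mcfs import (
    MCFSParams,
    TreeEnsemble,
    TreeRecord,
    compute_relative_importance,
    grow_projection_trees,
    permutation_threshold,
    rank_features,
)

from conftest import make_dataset


def brute_force_ri(trees, n_genes, u=1.0, v=1.0):
    """Independent node-by-node evaluation of the RI sum."""
    ri = [0.0] * n_genes
    for tree in trees:
        for gene, ig, n_node in tree.nodes:
            ri[gene] += (tree.wacc**u) * ig * (n_node / tree.root_n) ** v
    return np.array(ri)


def make_ensemble(trees, n_genes, **param_overrides):
    params = dataclasses.replace(MCFSParams(), **param_overrides)
    return TreeEnsemble(tuple(trees), params, n_genes)


# -- RI aggregation ----------------------------------------------------------


def test_ri_single_root_split_all_factors_one():
    tree = TreeRecord(wacc=1.0, root_n=10, nodes=((0, 1.0, 10),))
    ri = compute_relative_importance(make_ensemble([tree], 3))
    assert ri[0] == pytest.approx(1.0)
    assert ri[1] == ri[2] == 0.0


def test_ri_two_tree_hand_case():
    # tree A (wAcc .8): g at root (IG .9, fraction 1) and a child (IG .5,
    # fraction .4); tree B (wAcc .5): g at root (IG 1, fraction 1)
    # RI = .8*.9*1 + .8*.5*.4 + .5*1*1 = 1.38
    a = TreeRecord(wacc=0.8, root_n=10, nodes=((2, 0.9, 10), (2, 0.5, 4)))
    b = TreeRecord(wacc=0.5, root_n=20, nodes=((2, 1.0, 20),))
    ri = compute_relative_importance(make_ensemble([a, b], 4))
    assert ri[2] == pytest.approx(1.38)


def test_ri_unused_gene_is_exactly_zero():
    a = TreeRecord(wacc=0.7, root_n=8, nodes=((1, 0.3, 8), (0, 0.2, 4)))
    ri = compute_relative_importance(make_ensemble([a], 3))
    assert ri[2] == 0.0 and ri[0] > 0 and ri[1] > 0


@settings(derandomize=True, max_examples=30)
@given(st.integers(0, 10**6))
def test_ri_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    n_genes = 6
    trees = []
    for _ in range(rng.integers(1, 6)):
        root_n = int(rng.integers(4, 30))
        nodes = tuple(
            (int(rng.integers(0, n_genes)), float(rng.uniform(0, 1.5)),
             int(rng.integers(2, root_n + 1)))
            for _ in range(rng.integers(0, 6))
        )
        trees.append(TreeRecord(float(rng.uniform(0, 1)), root_n, nodes))
    u, v = float(rng.uniform(0.5, 2)), float(rng.uniform(0.5, 2))
    ens = make_ensemble(trees, n_genes, u=u, v=v)
    np.testing.assert_array_equal(
        compute_relative_importance(ens), brute_force_ri(trees, n_genes, u, v)
    )


def test_uv_scaling_preserves_zero_set():
    rng = np.random.default_rng(1)
    trees = [
        TreeRecord(0.6, 10, ((0, 0.5, 10), (3, 0.2, 5))),
        TreeRecord(0.9, 12, ((3, 0.8, 12),)),
    ]
    base = compute_relative_importance(make_ensemble(trees, 5))
    scaled = compute_relative_importance(make_ensemble(trees, 5, u=2.0, v=0.5))
    np.testing.assert_array_equal(base == 0, scaled == 0)
    assert np.all(base >= 0) and np.all(scaled >= 0)


# -- ranking ------------------------------------------------------------------


def test_rank_tie_break_by_index():
    order = rank_features(np.array([0.5, 0.9, 0.5]))
    assert order.tolist() == [1, 0, 2]


def test_rank_all_zero_is_identity():
    assert rank_features(np.zeros(5)).tolist() == [0, 1, 2, 3, 4]


@settings(derandomize=True, max_examples=30)
@given(st.integers(0, 10**6))
def test_rank_matches_sort_oracle(seed):
    rng = np.random.default_rng(seed)
    ri = rng.choice([0.0, 0.25, 0.5, 1.0, 2.0], size=20)  # force ties
    order = rank_features(ri)
    oracle = sorted(range(20), key=lambda i: (-ri[i], i))
    assert order.tolist() == oracle
    assert sorted(order.tolist()) == list(range(20))  # a permutation


# -- tree growing -------------------------------------------------------------


def test_tree_count_contract():
    rng = np.random.default_rng(0)
    ds = make_dataset(rng.normal(0, 1, (10, 24)), ["A", "B", "C"] * 8)
    ens1 = grow_projection_trees(ds, MCFSParams(m=4, t=1, p=1, seed=0))
    assert len(ens1) == 1
    ens15 = grow_projection_trees(ds, MCFSParams(m=4, t=3, p=5, seed=0))
    assert len(ens15) == 15
    assert all(len({g for g, _, _ in tr.nodes}) <= 4 for tr in ens15.trees)


def test_perfect_separator_gets_root_split_and_wacc_one():
    # gene 0 cleanly separates the two classes; m = N puts it in the subset
    values = np.vstack([
        np.r_[np.zeros(10), np.ones(10) * 10],
        np.random.default_rng(1).normal(0, 1, 20),
    ])
    ds = make_dataset(values, ["A"] * 10 + ["B"] * 10)
    ens = grow_projection_trees(ds, MCFSParams(m=2, t=1, p=3, seed=4))
    for tree in ens.trees:
        assert tree.wacc == 1.0
        root_gene, ig, n_node = tree.nodes[0]
        assert n_node == tree.root_n  # first recorded node is the root
        assert root_gene == 0


def test_grow_reproducible_and_seed_sensitive():
    rng = np.random.default_rng(2)
    ds = make_dataset(rng.normal(0, 1, (30, 20)), ["A", "B"] * 10)
    r1 = compute_relative_importance(grow_projection_trees(ds, MCFSParams(m=5, t=4, p=2, seed=9)))
    r2 = compute_relative_importance(grow_projection_trees(ds, MCFSParams(m=5, t=4, p=2, seed=9)))
    r3 = compute_relative_importance(grow_projection_trees(ds, MCFSParams(m=5, t=4, p=2, seed=10)))
    np.testing.assert_array_equal(r1, r2)
    assert not np.array_equal(r1, r3)


def test_gene_order_permutation_invariance():
    # permuting matrix rows permutes RI identically (projections are drawn
    # against the symbol-sorted gene order)
    rng = np.random.default_rng(3)
    values = rng.normal(0, 1, (15, 30))
    labels = ["A", "B", "C"] * 10
    genes = [f"g{i:02d}" for i in range(15)]
    ds = make_dataset(values, labels, genes=genes)
    perm = rng.permutation(15)
    ds_perm = make_dataset(values[perm], labels, genes=[genes[i] for i in perm])
    params = MCFSParams(m=6, t=5, p=2, seed=21)
    ri = compute_relative_importance(grow_projection_trees(ds, params))
    ri_perm = compute_relative_importance(grow_projection_trees(ds_perm, params))
    np.testing.assert_allclose(ri_perm, ri[perm], rtol=1e-12)


def test_bootstrap_resample_mode_runs():
    rng = np.random.default_rng(5)
    ds = make_dataset(rng.normal(0, 1, (12, 30)), ["A", "B", "C"] * 10)
    ens = grow_projection_trees(ds, MCFSParams(m=4, t=2, p=2, seed=1, resample="bootstrap"))
    assert len(ens) == 4 and all(0 <= tr.wacc <= 1 for tr in ens.trees)


# -- permutation threshold ----------------------------------------------------


@pytest.fixture(scope="module")
def small_marker_world():
    from pdxorigin.simulate import SyntheticConfig, generate_dataset

    cfg = SyntheticConfig(
        seed=8, class_names=("a", "b", "c"), class_sizes=(15, 15, 15),
        n_genes=60, markers_per_class=2, effect_size=3.0,
    )
    return generate_dataset(cfg)


def test_threshold_monotone_in_alpha(small_marker_world):
    ds, _ = small_marker_world
    params = MCFSParams(m=10, t=10, p=2, seed=3)
    ri = compute_relative_importance(grow_projection_trees(ds, params))
    thr_loose, inf_loose = permutation_threshold(ds, params, 5, alpha=0.2, observed_ri=ri)
    thr_tight, inf_tight = permutation_threshold(ds, params, 5, alpha=0.01, observed_ri=ri)
    assert thr_tight.threshold > thr_loose.threshold
    assert set(inf_tight.tolist()) <= set(inf_loose.tolist())


def test_threshold_separates_markers_from_noise(small_marker_world):
    ds, gt = small_marker_world
    params = MCFSParams(m=10, t=30, p=3, seed=3)
    ri = compute_relative_importance(grow_projection_trees(ds, params))
    thr, informative = permutation_threshold(ds, params, 10, 0.05, observed_ri=ri)
    markers = set(ds.gene_index(gt.all_markers()).tolist())
    flagged = set(informative.tolist())
    assert len(flagged & markers) >= 4  # most of the 6 planted markers
    assert len(flagged - markers) <= 3  # few noise genes


def test_threshold_requires_enough_permutations(small_marker_world):
    ds, _ = small_marker_world
    with pytest.raises(ValueError):
        permutation_threshold(ds, MCFSParams(m=5, t=2, p=1, seed=0), n_permutations=2)
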
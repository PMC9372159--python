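"""CCF clustering, tree assembly and the trunk proportion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonehist import clonetree as ct

from conftest import make_cluster_table


def _simulate_reads(ccf_matrix, n_per_cluster, depth, purity=1.0, cnt=2, mult=1, seed=0):
    """Reads for planted clusters; ccf_matrix is clusters x biopsies."""
    rng = np.random.default_rng(seed)
    ccf_matrix = np.asarray(ccf_matrix, dtype=float)
    K, B = ccf_matrix.shape
    labels = np.repeat(np.arange(K), n_per_cluster)
    n = labels.size
    coeff = mult * purity / (purity * cnt + 2 * (1 - purity))
    tot = rng.poisson(depth, size=(n, B))
    vaf = ccf_matrix[labels] * coeff
    alt = rng.binomial(tot, np.clip(vaf, 0, 1))
    return alt, tot, labels


class TestComputeCCF:
    def test_pure_diploid_clonal(self):
        ccf = ct.compute_ccf(np.array([15]), np.array([30]), 1.0, 2, 1)
        assert ccf[0] == pytest.approx(1.0)

    def test_admixture_correction(self):
        # VAF 0.25 at purity 0.5, CNt 2, m=1: CCF = 0.25 * (1+1) / 0.5 = 1.0
        ccf = ct.compute_ccf(np.array([25]), np.array([100]), 0.5, 2, 1)
        assert ccf[0] == pytest.approx(1.0)


class TestClusterCCF:
    def test_single_cluster(self):
        alt, tot, _ = _simulate_reads([[1.0, 1.0]], 100, 80, seed=1)
        res = ct.cluster_ccf(alt, tot, np.array([1.0, 1.0]), 2, 1,
                             iters=200, burnin=50, seed=2)
        assert len(res.clusters) == 1
        assert (res.assignments == res.assignments[0]).all()
        assert res.clusters.loc[0, "ccf_b0"] == pytest.approx(1.0, abs=0.05)

    def test_no_mutations(self):
        res = ct.cluster_ccf(np.zeros((0, 2)), np.zeros((0, 2)),
                             np.array([1.0, 1.0]), 2, 1, iters=10, burnin=2, seed=0)
        assert len(res.clusters) == 0
        assert res.assignments.size == 0

    def test_two_planted_clusters_recovered(self):
        alt, tot, labels = _simulate_reads([[1.0, 1.0], [1.0, 0.0]], 200, 100, seed=3)
        res = ct.cluster_ccf(alt, tot, np.array([1.0, 1.0]), 2, 1,
                             iters=400, burnin=100, seed=4)
        assert len(res.clusters) == 2
        # co-clustering accuracy over pairs
        same_true = labels[:, None] == labels[None, :]
        same_est = res.assignments[:, None] == res.assignments[None, :]
        iu = np.triu_indices(labels.size, k=1)
        accuracy = (same_true[iu] == same_est[iu]).mean()
        assert accuracy >= 0.95

    def test_non_autosomal_excluded(self):
        alt, tot, _ = _simulate_reads([[1.0, 1.0]], 30, 60, seed=5)
        chrom = np.array(["1"] * 20 + ["X"] * 10)
        res = ct.cluster_ccf(alt, tot, np.array([1.0, 1.0]), 2, 1,
                             iters=100, burnin=20, seed=6, chrom=chrom)
        assert (res.assignments[:20] >= 0).all()
        assert (res.assignments[20:] == -1).all()

    def test_number_of_clusters_recovered_across_seeds(self):
        # well-separated clusters (pairwise CCF distance >= 0.3), 100 mutations
        # each, depth 60: the sampler should find the true count nearly always
        hits = 0
        n_runs = 50
        for seed in range(n_runs):
            alt, tot, _ = _simulate_reads(
                [[1.0, 1.0], [0.6, 0.0], [0.0, 0.5]], 100, 60, seed=100 + seed
            )
            res = ct.cluster_ccf(alt, tot, np.array([1.0, 1.0]), 2, 1,
                                 iters=350, burnin=100, seed=200 + seed)
            kept, _ = ct.filter_clusters(res.clusters, min_count=10, min_fraction=0.01)
            hits += len(kept) == 3
        assert hits / n_runs >= 0.9


class TestFilterClusters:
    def test_count_rule(self):
        tab = make_cluster_table({0: (9981, [1.0]), 1: (19, [0.5])}, ["b0"])
        kept, _ = ct.filter_clusters(tab)
        assert kept["cluster"].tolist() == [0]

    def test_percent_rule(self):
        tab = make_cluster_table({0: (9975, [1.0]), 1: (25, [0.5])}, ["b0"])
        kept, _ = ct.filter_clusters(tab)
        assert kept["cluster"].tolist() == [0]

    def test_retained(self):
        tab = make_cluster_table({0: (9850, [1.0]), 1: (150, [0.5])}, ["b0"])
        kept, _ = ct.filter_clusters(tab)
        assert kept["cluster"].tolist() == [0, 1]

    def test_assignments_updated(self):
        tab = make_cluster_table({0: (30, [1.0]), 1: (5, [0.5])}, ["b0"])
        assign = np.array([0] * 30 + [1] * 5)
        _, new = ct.filter_clusters(tab, assign)
        assert (new[-5:] == -1).all()
        assert (new[:30] == 0).all()


class TestBuildTree:
    def test_pigeonhole_toy(self):
        tab = make_cluster_table(
            {0: (1000, [1.0, 1.0]), 1: (200, [0.6, 0.0]), 2: (150, [0.0, 0.5])},
            ["b0", "b1"],
        )
        tree = ct.build_tree(tab)
        assert tree.trunk == 0
        assert tree.parent == {0: None, 1: 0, 2: 0}

    def test_single_cluster(self):
        tab = make_cluster_table({0: (100, [1.0, 1.0])}, ["b0", "b1"])
        tree = ct.build_tree(tab)
        assert tree.trunk == 0 and tree.tips() == []

    def test_presence_is_strictly_greater(self):
        tab = make_cluster_table(
            {0: (100, [1.0, 1.0]), 1: (50, [0.5, 0.1])}, ["b0", "b1"]
        )
        tree = ct.build_tree(tab, presence_ccf=0.1)
        sim_cols = tab[["ccf_b0", "ccf_b1"]].to_numpy()
        assert (sim_cols[1] > 0.1).tolist() == [True, False]

    def test_nested_chain(self):
        tab = make_cluster_table(
            {0: (500, [1.0, 1.0]), 1: (100, [0.7, 0.6]), 2: (40, [0.3, 0.2])},
            ["b0", "b1"],
        )
        tree = ct.build_tree(tab)
        assert tree.parent == {0: None, 1: 0, 2: 1}

    def test_forest_when_no_universal_cluster(self):
        tab = make_cluster_table(
            {0: (100, [1.0, 0.0]), 1: (80, [0.0, 1.0])}, ["b0", "b1"]
        )
        tree = ct.build_tree(tab)
        assert tree.is_forest
        assert "forest" in tree.diagnostic

    def test_gcnis_clusters_merged_into_trunk(self):
        tab = make_cluster_table(
            {0: (500, [1.0, 1.0, 1.0]), 1: (100, [0.8, 0.8, 0.8]),
             2: (50, [0.4, 0.0, 0.0])},
            ["situ", "inv1", "inv2"],
        )
        gcnis = {"situ": True, "inv1": False, "inv2": False}
        tree = ct.build_tree(tab, gcnis=gcnis)
        # cluster 1 spans the in-situ and invasive compartments -> truncal
        assert tree.n_subs(tree.trunk) == 600
        assert 1 not in tree.parent

    def test_newick_and_edge_list(self):
        tab = make_cluster_table(
            {0: (10, [1.0]), 1: (5, [0.5])}, ["b0"]
        )
        tree = ct.build_tree(tab)
        assert tree.to_newick() == "(c1:5)c0:10;"
        edges = tree.to_edge_list()
        assert edges.loc[edges["child"] == 1, "parent"].iloc[0] == 0


class TestTrunkProportion:
    def test_private_branches_off_trunk(self):
        tab = make_cluster_table(
            {0: (80, [1.0, 1.0]), 1: (10, [0.5, 0.0]), 2: (30, [0.0, 0.5])},
            ["b0", "b1"],
        )
        tree = ct.build_tree(tab)
        assert ct.trunk_proportion(tree) == pytest.approx(0.80)

    def test_shared_internal_branch_double_counted(self):
        # trunk 80 -> shared internal 20 -> private tips 10 and 30
        tab = make_cluster_table(
            {0: (80, [1.0, 1.0]), 1: (20, [0.8, 0.8]),
             2: (10, [0.5, 0.0]), 3: (30, [0.0, 0.5])},
            ["b0", "b1"],
        )
        tree = ct.build_tree(tab)
        assert tree.parent == {0: None, 1: 0, 2: 1, 3: 1}
        assert ct.trunk_proportion(tree) == pytest.approx(80 / 120)

    def test_trunk_only_is_one(self):
        tab = make_cluster_table({0: (100, [1.0])}, ["b0"])
        assert ct.trunk_proportion(ct.build_tree(tab)) == 1.0

    def test_forest_rejected(self):
        tab = make_cluster_table(
            {0: (100, [1.0, 0.0]), 1: (80, [0.0, 1.0])}, ["b0", "b1"]
        )
        with pytest.raises(ValueError):
            ct.trunk_proportion(ct.build_tree(tab))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(trunk=st.integers(10, 500), tip1=st.integers(1, 200),
           tip2=st.integers(1, 200), extra=st.integers(1, 50))
    def test_monotonicity(self, trunk, tip1, tip2, extra):
        def prop(n_trunk, tips):
            tab = make_cluster_table(
                {0: (n_trunk, [1.0, 1.0]),
                 1: (tips[0], [0.5, 0.0]), 2: (tips[1], [0.0, 0.5])},
                ["b0", "b1"],
            )
            return ct.trunk_proportion(ct.build_tree(tab))

        base = prop(trunk, (tip1, tip2))
        assert 0 < base <= 1
        assert prop(trunk, (tip1 + extra, tip2)) < base
        assert prop(trunk + extra, (tip1, tip2)) > base

    def test_matches_graph_oracle_on_random_trees(self):
        # independent evaluation with networkx path sums
        import networkx as nx

        rng = np.random.default_rng(8)
        for _ in range(20):
            n_nodes = int(rng.integers(2, 10))
            sizes = rng.integers(1, 100, size=n_nodes)
            parent = {0: None}
            for k in range(1, n_nodes):
                parent[k] = int(rng.integers(0, k))
            tab = make_cluster_table(
                {k: (int(sizes[k]), [1.0]) for k in range(n_nodes)}, ["b0"]
            )
            tree = ct.CloneTree(tab, parent, trunk=0, biopsies=["b0"])
            g = nx.DiGraph((p, c) for c, p in parent.items() if p is not None)
            tips = [n for n in g.nodes if g.out_degree(n) == 0 and n != 0]
            if not tips:
                assert ct.trunk_proportion(tree) == 1.0
                continue
            dists = []
            for t in tips:
                path = nx.shortest_path(g, 0, t)
                dists.append(sum(sizes[n] for n in path if n != 0))
            expected = sizes[0] / (sizes[0] + sum(dists) / len(tips))
            assert ct.trunk_proportion(tree) == pytest.approx(expected)


def test_built_tree_satisfies_pigeonhole(small_cohort):
    truth = small_cohort.truth
    tab_rows = {}
    for (patient, cluster), grp in truth.cluster_ccfs.groupby(["patient", "cluster"]):
        n = int((truth.mutations["cluster"] == cluster).sum())
        tab_rows[cluster] = (max(n, 1), grp.sort_values("biopsy")["ccf"].tolist())
    biopsies = sorted(truth.cluster_ccfs["biopsy"].unique())
    tree = ct.build_tree(make_cluster_table(tab_rows, biopsies))
    ccf_cols = [f"ccf_{b}" for b in biopsies]
    tab = tree.clusters.set_index("cluster")
    for child, parent in tree.parent.items():
        if parent is None:
            continue
        child_ccf = tab.loc[child, ccf_cols].to_numpy(dtype=float)
        parent_ccf = tab.loc[parent, ccf_cols].to_numpy(dtype=float)
        assert (parent_ccf >= child_ccf - 0.05).all()
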
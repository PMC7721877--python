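"""Canonicalization, pruning and merging of reconstruction solutions."""

import numpy as np
import pytest

from cloneconcord.core import (
    CloneNode,
    CloneTree,
    Cluster,
    ClusterSolution,
    SolutionStatus,
)
from cloneconcord.postprocess import (
    PostprocessConfig,
    canonicalize_tree,
    detect_poly_tumour,
    postprocess_clusters,
    postprocess_tree,
)

from conftest import random_cluster_solution, random_tree


def snv_keys(n, offset=0):
    return {("1", 10_000 + offset + i, "A", "G") for i in range(n)}


def chain_tree(*cps, snvs=20):
    """Linear tree root -> 1 -> 2 ... with the given subclone prevalences."""
    nodes = [CloneNode(0, None, 1.0)]
    for i, cp in enumerate(cps, start=1):
        nodes.append(CloneNode(i, i - 1, cp, snv_keys(snvs, offset=1000 * i)))
    return CloneTree(nodes, "S1")


class TestCanonicalize:
    def test_linear_chain_unchanged(self):
        tree = chain_tree(0.8, 0.5, 0.2)
        out = canonicalize_tree(tree)
        assert out == tree

    def test_larger_subtree_numbered_first(self):
        # root -> A (leaf) and root -> B -> two children: B's subtree (3
        # nodes) must come first and take the lower ids
        nodes = [
            CloneNode(0, None, 1.0),
            CloneNode(1, 0, 0.9, snv_keys(10)),        # the single-node subtree
            CloneNode(2, 0, 0.6, snv_keys(10, 100)),   # subtree of size 3
            CloneNode(3, 2, 0.3, snv_keys(10, 200)),
            CloneNode(4, 2, 0.2, snv_keys(10, 300)),
        ]
        out = canonicalize_tree(CloneTree(nodes, "S1"))
        # breadth-first: root 0; depth-1 nodes 1 (size-3 subtree root) and 2
        assert out.nodes[1].cp == pytest.approx(0.6)
        assert out.nodes[2].cp == pytest.approx(0.9)
        assert {out.nodes[3].cp, out.nodes[4].cp} == {0.3, 0.2}

    def test_ids_increase_with_depth(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            out = canonicalize_tree(random_tree(rng))
            for node in out.subclones():
                parent = out.nodes[node.parent_id]
                assert node.node_id > parent.node_id
                assert out.depth(node.node_id) == out.depth(parent.node_id) + 1
            depths = {nid: out.depth(nid) for nid in out.nodes}
            ordered = sorted(out.nodes)
            assert all(
                depths[a] <= depths[b] for a, b in zip(ordered, ordered[1:])
            )

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            once = canonicalize_tree(random_tree(rng))
            assert canonicalize_tree(once) == once

    def test_mutations_preserved(self):
        rng = np.random.default_rng(7)
        tree = random_tree(rng)
        out = canonicalize_tree(tree)
        assert out.all_snv_ids() == tree.all_snv_ids()


class TestPolyTumour:
    def test_root_with_two_children(self):
        nodes = [CloneNode(0, None, 1.0), CloneNode(1, 0, 0.6, snv_keys(20)),
                 CloneNode(2, 0, 0.3, snv_keys(20, 100))]
        assert detect_poly_tumour(CloneTree(nodes))

    def test_branching_below_root_is_ordinary(self):
        nodes = [CloneNode(0, None, 1.0), CloneNode(1, 0, 0.8, snv_keys(20)),
                 CloneNode(2, 1, 0.4, snv_keys(20, 100)),
                 CloneNode(3, 1, 0.3, snv_keys(20, 200))]
        assert not detect_poly_tumour(CloneTree(nodes))

    def test_monoclonal(self):
        assert not detect_poly_tumour(chain_tree(0.8))


class TestPostprocessTree:
    def test_weakly_supported_node_merged(self):
        nodes = [CloneNode(0, None, 1.0),
                 CloneNode(1, 0, 0.8, snv_keys(100)),
                 CloneNode(2, 1, 0.3, snv_keys(3, 5000))]  # 3 SNVs, 0 CNAs
        out, status = postprocess_tree(CloneTree(nodes, "S1"))
        assert status == SolutionStatus.OK
        assert out.n_subclones() == 1
        assert len(out.nodes[1].snv_ids) == 103  # moved, not dropped

    def test_sibling_merge_weighted_mean(self):
        # siblings at 0.30 (60 SNVs) and 0.29 (40 SNVs), both SNV-driven:
        # merged prevalence (0.30*60 + 0.29*40) / 100 = 0.296
        nodes = [CloneNode(0, None, 1.0),
                 CloneNode(1, 0, 0.8, snv_keys(100)),
                 CloneNode(2, 1, 0.30, snv_keys(60, 1000)),
                 CloneNode(3, 1, 0.29, snv_keys(40, 2000))]
        out, status = postprocess_tree(CloneTree(nodes, "S1"))
        assert status == SolutionStatus.OK
        assert out.n_subclones() == 2
        merged = min(out.subclones(), key=lambda n: n.cp)
        assert merged.cp == pytest.approx(0.296)
        assert len(merged.snv_ids) == 100

    def test_cna_driven_siblings_not_merged(self):
        nodes = [CloneNode(0, None, 1.0),
                 CloneNode(1, 0, 0.8, snv_keys(100)),
                 CloneNode(2, 1, 0.30, snv_keys(60, 1000),
                           {f"c{i}" for i in range(8)}),
                 CloneNode(3, 1, 0.29, snv_keys(40, 2000))]
        out, _ = postprocess_tree(CloneTree(nodes, "S1"))
        assert out.n_subclones() == 3

    def test_boundary_node_retained(self):
        # exactly 5 SNVs and prevalence 0.12: both thresholds met inclusively
        nodes = [CloneNode(0, None, 1.0),
                 CloneNode(1, 0, 0.9, snv_keys(50)),
                 CloneNode(2, 1, 0.12, snv_keys(5, 1000))]
        out, status = postprocess_tree(CloneTree(nodes, "S1"))
        assert status == SolutionStatus.OK
        assert out.n_subclones() == 2

    def test_parent_merge_within_two_percent(self):
        nodes = [CloneNode(0, None, 1.0),
                 CloneNode(1, 0, 0.80, snv_keys(60)),
                 CloneNode(2, 1, 0.79, snv_keys(40, 1000))]
        out, _ = postprocess_tree(CloneTree(nodes, "S1"))
        assert out.n_subclones() == 1
        assert out.nodes[1].cp == pytest.approx(0.796)

    def test_empty_after_pruning_is_failure(self):
        nodes = [CloneNode(0, None, 1.0), CloneNode(1, 0, 0.05, snv_keys(100))]
        out, status = postprocess_tree(CloneTree(nodes, "S1"))
        assert status == SolutionStatus.FAILED

    def test_poly_tumour_status(self):
        nodes = [CloneNode(0, None, 1.0),
                 CloneNode(1, 0, 0.6, snv_keys(50)),
                 CloneNode(2, 0, 0.3, snv_keys(50, 1000))]
        _, status = postprocess_tree(CloneTree(nodes, "S1"))
        assert status == SolutionStatus.POLY_TUMOUR

    def test_invariants_on_random_trees(self):
        cfg = PostprocessConfig()
        rng = np.random.default_rng(42)
        for _ in range(200):
            tree = random_tree(rng)
            before = tree.all_snv_ids()
            out, status = postprocess_tree(tree, cfg)
            if status != SolutionStatus.OK:
                continue
            assert out.all_snv_ids() == before
            for node in out.subclones():
                assert (
                    len(node.snv_ids) >= cfg.min_snvs_per_node
                    or len(node.cna_ids) >= cfg.min_cnas_per_node
                )
                assert node.cp >= cfg.min_clonal_cp
            # fixed point
            again, status2 = postprocess_tree(out, cfg)
            assert status2 == status
            assert again == out


class TestPostprocessClusters:
    def test_too_few_total_snvs_fails(self):
        sol = ClusterSolution([Cluster(1, 0.8, snv_keys(4))], "S1")
        _, status = postprocess_clusters(sol)
        assert status == SolutionStatus.FAILED

    def test_all_low_prevalence_fails(self):
        sol = ClusterSolution(
            [Cluster(1, 0.09, snv_keys(50)), Cluster(2, 0.05, snv_keys(30, 100))],
            "S1",
        )
        _, status = postprocess_clusters(sol)
        assert status == SolutionStatus.FAILED

    def test_near_clusters_merge_weighted(self):
        sol = ClusterSolution(
            [Cluster(1, 0.50, snv_keys(100)), Cluster(2, 0.49, snv_keys(50, 1000))],
            "S1",
        )
        out, status = postprocess_clusters(sol)
        assert status == SolutionStatus.OK
        assert len(out.clusters) == 1
        assert out.clusters[0].cp == pytest.approx((0.50 * 100 + 0.49 * 50) / 150)

    def test_tiny_subclonal_cluster_absorbed(self):
        sol = ClusterSolution(
            [Cluster(1, 0.60, snv_keys(100)),
             Cluster(2, 0.30, snv_keys(40, 1000)),
             Cluster(3, 0.015, snv_keys(20, 2000))],
            "S1",
        )
        out, status = postprocess_clusters(sol)
        assert status == SolutionStatus.OK
        assert len(out.clusters) == 2
        # absorbed into its nearest-prevalence neighbour (the 0.30 cluster)
        low = out.clusters[-1]
        assert len(low.snv_ids) == 60
        assert low.cp == pytest.approx((0.30 * 40 + 0.015 * 20) / 60)

    def test_renumbered_by_decreasing_prevalence(self):
        sol = ClusterSolution(
            [Cluster(7, 0.2, snv_keys(30)), Cluster(3, 0.8, snv_keys(30, 100))],
            "S1",
        )
        out, _ = postprocess_clusters(sol)
        assert [c.cluster_id for c in out.clusters] == [1, 2]
        assert out.clusters[0].cp > out.clusters[1].cp

    def test_invariants_on_random_solutions(self):
        cfg = PostprocessConfig()
        rng = np.random.default_rng(123)
        for _ in range(300):
            sol = random_cluster_solution(rng)
            before = sol.all_snv_ids()
            out, status = postprocess_clusters(sol, cfg)
            if status != SolutionStatus.OK:
                continue
            assert out.all_snv_ids() == before
            clonal = max(out.clusters, key=lambda c: c.cp)
            for c in out.clusters:
                assert c.n_snvs >= cfg.min_snvs_per_node
                floor = cfg.min_clonal_cp if c is clonal else cfg.min_subclonal_cp
                assert c.cp >= floor
            cps = sorted(c.cp for c in out.clusters)
            for lo, hi in zip(cps, cps[1:]):
                assert hi - lo > cfg.merge_cp_delta
            again, status2 = postprocess_clusters(out, cfg)
            assert status2 == status
            assert [c.cp for c in again.clusters] == [c.cp for c in out.clusters]
            assert [c.snv_ids for c in again.clusters] == [
                c.snv_ids for c in out.clusters
            ]

    def test_merge_delta_monotonicity(self):
        """A wider merge window can only reduce the retained cluster count."""
        rng = np.random.default_rng(77)
        tight = PostprocessConfig(merge_cp_delta=0.01)
        wide = PostprocessConfig(merge_cp_delta=0.05)
        for _ in range(100):
            sol = random_cluster_solution(rng)
            out_t, st_t = postprocess_clusters(sol, tight)
            out_w, st_w = postprocess_clusters(sol, wide)
            if st_t == st_w == SolutionStatus.OK:
                assert len(out_w.clusters) <= len(out_t.clusters)
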
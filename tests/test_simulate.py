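"""Synthetic tumours, caller emulation and reconstruction emulation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cloneconcord.core import ClusterSolution, SolutionStatus
from cloneconcord.clonality import assign_clonality, classify_solution
from cloneconcord.postprocess import postprocess_clusters
from cloneconcord.simulate import (
    CallerProfile,
    conservative_profile,
    emulate_reconstruction,
    expected_vaf,
    permissive_profile,
    reconstruct_from_snv_calls,
    simulate_caller_cnas,
    simulate_caller_snvs,
    simulate_tumour,
    synthetic_genome,
)

SMALL = {"1": 400_000, "2": 300_000}


def perfect_profile():
    return CallerProfile(
        name="perfect", sensitivity=lambda v: np.ones_like(np.asarray(v, float))
    )


@pytest.fixture(scope="module")
def tumour3():
    return simulate_tumour(
        n_subclones=3, n_snvs=600, seed=5, chrom_sizes=SMALL, depth=80.0
    )


class TestSimulateTumour:
    def test_seed_determinism(self):
        a = simulate_tumour(n_subclones=3, n_snvs=200, seed=9, chrom_sizes=SMALL)
        b = simulate_tumour(n_subclones=3, n_snvs=200, seed=9, chrom_sizes=SMALL)
        assert a.genome == b.genome
        assert a.region_profiles == b.region_profiles
        pd.testing.assert_frame_equal(a.snvs, b.snvs)
        assert [(n, s.key) for n, s in a.segments] == [
            (n, s.key) for n, s in b.segments
        ]

    def test_prevalence_spacing_in_every_region(self):
        t = simulate_tumour(
            n_subclones=3, cp_spacing=0.2, n_snvs=200, n_regions=3,
            region_absent_prob=0.3, seed=13, chrom_sizes=SMALL,
        )
        for region, prof in t.region_profiles.items():
            present = sorted(v for v in prof.values() if v > 0)
            for lo, hi in zip(present, present[1:]):
                assert hi - lo >= 0.2 - 1e-12

    def test_child_never_exceeds_parent_anywhere(self):
        t = simulate_tumour(
            n_subclones=4, n_snvs=200, n_regions=3, region_absent_prob=0.3,
            seed=21, chrom_sizes=SMALL,
        )
        for prof in t.region_profiles.values():
            for node in t.tree.subclones():
                parent = t.tree.nodes[node.parent_id]
                if parent.node_id == 0:
                    continue
                assert prof[node.node_id] <= prof[parent.node_id] + 1e-12

    def test_every_snv_assigned_to_one_node(self, tumour3):
        assert tumour3.snvs["node_id"].between(1, 3).all()
        assert len(tumour3.snvs) == 600
        keys = set(
            zip(tumour3.snvs["chrom"], tumour3.snvs["pos"],
                tumour3.snvs["ref"], tumour3.snvs["alt"])
        )
        assert len(keys) == 600
        assert tumour3.tree.all_snv_ids() == keys

    def test_infeasible_spacing_rejected(self):
        with pytest.raises(ValueError):
            simulate_tumour(
                n_subclones=6, cp_spacing=0.3, n_snvs=100, seed=0,
                chrom_sizes=SMALL,
            )

    def test_clonal_heterozygous_limit(self):
        # one subclone, pure diploid tumour: expected VAF is 1/2 everywhere
        t = simulate_tumour(
            n_subclones=1, purity=1.0, n_snvs=100, seed=3, chrom_sizes=SMALL,
            n_cnas_per_node=0,
        )
        evs = [
            expected_vaf(m, 1.0, 1.0, c)
            for m, c in zip(t.snvs["multiplicity"], t.snvs["total_cn"])
        ]
        assert np.allclose(evs, 0.5)


class TestCallerSnvs:
    def test_noise_free_limit_recovers_truth(self, tumour3):
        out = simulate_caller_snvs(tumour3, perfect_profile(), "R0", seed=1)
        assert {r.key for r in out} == tumour3.tree.all_snv_ids()

    def test_detected_count_within_binomial_bounds(self):
        t = simulate_tumour(
            n_subclones=1, n_snvs=4000, seed=17, chrom_sizes={"1": 2_000_000}
        )
        profile = CallerProfile(
            name="half", sensitivity=lambda v: np.full_like(np.asarray(v, float), 0.5)
        )
        out = simulate_caller_snvs(t, profile, "R0", seed=2)
        lo, hi = stats.binom.ppf([0.005, 0.995], 4000, 0.5)
        assert lo <= len(out) <= hi

    def test_mean_observed_vaf_matches_closed_form(self):
        # clonal SNVs at depth 80: the at-least-one-read floor is negligible
        t = simulate_tumour(
            n_subclones=1, n_snvs=4000, depth=80.0, purity=0.7, seed=23,
            chrom_sizes={"1": 2_000_000}, n_cnas_per_node=0,
        )
        out = simulate_caller_snvs(t, perfect_profile(), "R0", seed=3)
        observed = np.array([r.vaf for r in out])
        expected = expected_vaf(1.0, 1.0, 0.7, 2.0)
        # depth varies around 80; binomial VAF sd at depth d is
        # sqrt(p(1-p)/d), so use the mean-depth approximation
        se = np.sqrt(expected * (1 - expected) / 80.0 / len(out))
        assert abs(observed.mean() - expected) < 3 * se

    def test_permissive_fp_vafs_below_true_vafs(self, tumour3):
        profile = permissive_profile()
        profile.fp_rate_per_mb = 100.0  # enough false calls on the toy genome
        out = simulate_caller_snvs(tumour3, profile, "R0", seed=4)
        truth_keys = tumour3.tree.all_snv_ids()
        fp = [r.vaf for r in out if r.key not in truth_keys]
        tp = [r.vaf for r in out if r.key in truth_keys]
        assert len(fp) > 5
        assert np.median(fp) < np.median(tp)

    def test_conservative_caller_adds_almost_no_fps(self, tumour3):
        out = simulate_caller_snvs(tumour3, conservative_profile(), "R0", seed=5)
        truth_keys = tumour3.tree.all_snv_ids()
        fp = [r for r in out if r.key not in truth_keys]
        assert len(fp) <= 2

    def test_fp_contexts_follow_bias(self):
        """The permissive profile's false calls should concentrate in the
        C>A classes that dominate its context-bias weights."""
        t = simulate_tumour(
            n_subclones=1, n_snvs=10, seed=31, chrom_sizes={"1": 1_000_000}
        )
        profile = permissive_profile()
        profile.fp_rate_per_mb = 300.0
        out = simulate_caller_snvs(t, profile, "R0", seed=6)
        truth_keys = t.tree.all_snv_ids()
        from cloneconcord.consensus import collapse_substitution

        fp_classes = []
        for r in out:
            if r.key in truth_keys:
                continue
            i = r.pos - 1
            tri = t.genome[r.chrom][i - 1 : i + 2]
            cls, _ = collapse_substitution(tri[0], tri[1], r.alt, tri[2])
            fp_classes.append(cls)
        frac_ca = np.mean(["[C>A]" in c for c in fp_classes])
        assert frac_ca > 0.5  # 8x/40x weighting drives C>A dominance


class TestCallerCnas:
    def test_noise_free_limit(self, tumour3):
        quiet = CallerProfile(name="q", sensitivity=lambda v: v * 0 + 1)
        out = simulate_caller_cnas(tumour3, quiet, "R0", seed=1)
        truth = [s for _, s in tumour3.segments]
        assert [(s.interval.chrom, s.interval.start, s.interval.end,
                 s.major_cn, s.minor_cn) for s in out] == [
            (s.interval.chrom, s.interval.start, s.interval.end,
             s.major_cn, s.minor_cn) for s in sorted(
                truth, key=lambda s: (s.interval.chrom, s.interval.start))
        ]

    def test_jitter_bounded(self, tumour3):
        profile = CallerProfile(
            name="j", sensitivity=lambda v: v * 0 + 1, segment_jitter_bp=5000
        )
        out = simulate_caller_cnas(tumour3, profile, "R0", seed=2)
        true_bounds = [
            p for _, s in tumour3.segments
            for p in (s.interval.start, s.interval.end)
        ]
        for s in out:
            for boundary in (s.interval.start, s.interval.end):
                assert min(abs(boundary - t) for t in true_bounds) <= 5000

    def test_spurious_segment_count_poisson_consistent(self):
        # sparse truth on a roomy genome so placement never saturates
        t = simulate_tumour(
            n_subclones=1, n_snvs=50, n_cnas_per_node=4, seed=61,
            chrom_sizes={"1": 4_000_000, "2": 4_000_000},
        )
        profile = CallerProfile(
            name="u", sensitivity=lambda v: v * 0 + 1, unique_segment_rate=0.5
        )
        n_true = len(t.segments)
        extras = []
        for seed in range(40):
            out = simulate_caller_cnas(t, profile, "R0", seed=seed)
            extras.append(len(out) - n_true)
        lam = 0.5 * n_true
        # mean of 40 Poisson(lam) draws within 4 standard errors
        assert abs(np.mean(extras) - lam) < 4 * np.sqrt(lam / 40)

    def test_dual_entry_emission(self, tumour3):
        profile = CallerProfile(
            name="bb", sensitivity=lambda v: v * 0 + 1, emits_subclonal_pairs=True
        )
        out = simulate_caller_cnas(tumour3, profile, "R0", seed=3)
        subclonal = [s for s in out if s.clonality_label == "subclonal"]
        assert subclonal
        for s in subclonal:
            twins = [
                o for o in out
                if o.interval == s.interval and o.clonality_label == "clonal"
            ]
            assert len(twins) == 1 and twins[0].is_neutral


class TestEmulateReconstruction:
    def test_noise_free_assignment_identical_to_truth(self, tumour3):
        sol = emulate_reconstruction(tumour3, "R0", "clusters")
        by_cp = {round(c.cp, 9): c.snv_ids for c in sol.clusters}
        rho = tumour3.purity["R0"]
        for node in tumour3.tree.subclones():
            cp = round(tumour3.region_profiles["R0"][node.node_id] * rho, 9)
            assert by_cp[cp] == node.snv_ids

    def test_identical_prevalences_emitted_merged(self, tumour3):
        t = simulate_tumour(
            n_subclones=3, n_snvs=300, seed=41, chrom_sizes=SMALL
        )
        t.region_profiles["R0"][3] = t.region_profiles["R0"][2]
        sol = emulate_reconstruction(t, "R0", "clusters")
        assert len(sol.clusters) == 2
        merged = max(sol.clusters, key=lambda c: len(c.snv_ids) if c.cp < 0.7 else 0)
        expected = t.tree.nodes[2].snv_ids | t.tree.nodes[3].snv_ids
        assert any(c.snv_ids == expected for c in sol.clusters)

    def test_multi_region_sees_at_least_single_region_counts(self):
        for seed in range(10):
            t = simulate_tumour(
                n_subclones=4, n_snvs=200, n_regions=3, region_absent_prob=0.4,
                seed=100 + seed, chrom_sizes=SMALL,
            )
            multi = emulate_reconstruction(t, None, "clusters")
            for region in t.regions:
                single = emulate_reconstruction(t, region, "clusters")
                assert len(multi.clusters) >= len(single.clusters)

    def test_tree_shape_preserves_ancestry(self, tumour3):
        tree = emulate_reconstruction(tumour3, "R0", "tree")
        tree.validate(strict_cp=True)
        assert tree.n_subclones() == 3

    def test_cp_noise_perturbs_but_keeps_nesting(self, tumour3):
        tree = emulate_reconstruction(
            tumour3, "R0", "tree", cp_noise_sd=0.05, seed=7
        )
        tree.validate(strict_cp=True)

    def test_split_merge_changes_cluster_count(self, tumour3):
        counts = set()
        for seed in range(15):
            sol = emulate_reconstruction(
                tumour3, "R0", "clusters", split_merge_rate=0.8, seed=seed
            )
            counts.add(len(sol.clusters))
        assert len(counts) > 1

    def test_determinism(self, tumour3):
        a = emulate_reconstruction(tumour3, "R0", "clusters", cp_noise_sd=0.02, seed=3)
        b = emulate_reconstruction(tumour3, "R0", "clusters", cp_noise_sd=0.02, seed=3)
        assert [(c.cp, sorted(c.snv_ids)) for c in a.clusters] == [
            (c.cp, sorted(c.snv_ids)) for c in b.clusters
        ]


class TestEndToEndNoiseFree:
    def test_classification_recovers_truth(self):
        for seed, k in [(1, 1), (2, 2), (3, 3), (4, 4)]:
            t = simulate_tumour(
                n_subclones=k, n_snvs=400, seed=seed, chrom_sizes=SMALL
            )
            sol = emulate_reconstruction(t, "R0", "clusters")
            post, status = postprocess_clusters(sol)
            assert status == SolutionStatus.OK
            assert classify_solution(post, status) == t.true_class("R0")
            assert len(post.clusters) == t.n_subclones("R0")
            assignment = assign_clonality(post, status)
            assert assignment.pipeline_cellularity == pytest.approx(0.7)


class TestReconstructFromCalls:
    def test_fp_calls_create_extra_low_prevalence_clusters(self, tumour3):
        perm_profile = permissive_profile()
        perm_profile.fp_rate_per_mb = 50.0  # toy genome is only 0.7 Mbp
        cons = simulate_caller_snvs(tumour3, conservative_profile(), "R0", seed=11)
        perm = simulate_caller_snvs(tumour3, perm_profile, "R0", seed=11)
        sol_c, st_c = postprocess_clusters(
            reconstruct_from_snv_calls(tumour3, "R0", cons)
        )
        sol_p, st_p = postprocess_clusters(
            reconstruct_from_snv_calls(tumour3, "R0", perm)
        )
        assert st_c == st_p == SolutionStatus.OK
        assert len(sol_p.clusters) > len(sol_c.clusters)
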
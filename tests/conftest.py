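"""Shared fixtures and random-object generators for the test suite.

Everything random is seeded; tests are deterministic across runs.
"""

from __future__ import annotations

import numpy as np
import pytest

from cloneconcord.core import CloneNode, CloneTree, Cluster, ClusterSolution
from cloneconcord.simulate import synthetic_genome


@pytest.fixture(scope="session")
def small_genome() -> dict:
    """A 1 Mbp two-chromosome genome shared across tests."""
    return synthetic_genome({"1": 600_000, "2": 400_000}, seed=11)


def random_cluster_solution(rng: np.random.Generator, max_clusters: int = 8) -> ClusterSolution:
    """A noisy flat solution: arbitrary prevalences and support counts."""
    k = int(rng.integers(1, max_clusters + 1))
    clusters = []
    key_counter = 0
    for i in range(k):
        n = int(rng.integers(0, 60))
        keys = {("1", 1000 + key_counter + j, "A", "C") for j in range(n)}
        key_counter += n
        clusters.append(Cluster(i + 1, float(rng.uniform(0.005, 1.0)), keys))
    return ClusterSolution(clusters, sample_id="S1", source_algorithm="pyclone-like")


def random_tree(rng: np.random.Generator, max_subclones: int = 8) -> CloneTree:
    """A noisy clone tree: nested prevalences, arbitrary support counts."""
    k = int(rng.integers(1, max_subclones + 1))
    nodes = [CloneNode(0, None, 1.0)]
    cps = {0: 1.0}
    key_counter = 0
    for nid in range(1, k + 1):
        parent = 0 if nid == 1 else int(rng.integers(1, nid))
        cp = cps[parent] * float(rng.uniform(0.05, 1.0))
        cps[nid] = cp
        n_snv = int(rng.integers(0, 60))
        snvs = {("1", 5000 + key_counter + j, "G", "T") for j in range(n_snv)}
        key_counter += n_snv
        n_cna = int(rng.integers(0, 9))
        cnas = {f"cna_{nid}_{j}" for j in range(n_cna)}
        nodes.append(CloneNode(nid, parent, cp, snvs, cnas))
    return CloneTree(nodes, "S1")
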
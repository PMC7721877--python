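"""Simulate a tumour, emulate its reconstruction, and classify clonality.

Builds a three-subclone ground-truth tumour, emulates a noise-free
cluster-shaped reconstruction, applies the pruning/merging heuristics
and reports the clonality classification with per-mutation CCFs.
"""

from cloneconcord import (
    assign_clonality,
    classify_solution,
    emulate_reconstruction,
    postprocess_clusters,
    simulate_tumour,
)

truth = simulate_tumour(n_subclones=3, n_snvs=800, purity=0.7, depth=60, seed=11)
print(f"truth: {truth.n_subclones()} subclones ({truth.true_class()})")
for node_id, phi in sorted(truth.region_profiles["R0"].items()):
    print(f"  node {node_id}: prevalence {phi:.3f} of tumour cells")

solution = emulate_reconstruction(truth, "R0", shape="clusters")
post, status = postprocess_clusters(solution)
print(f"\npost-processed: {len(post.clusters)} cluster(s), status {status.value}")

assignment = assign_clonality(post, status)
print(f"classified as {assignment.solution_class}")
print(f"pipeline cellularity: {assignment.pipeline_cellularity:.3f}")
n_clonal = len(assignment.clonal_keys())
n_subclonal = len(assignment.subclonal_keys())
print(f"{n_clonal} clonal SNVs (CCF 1.0), {n_subclonal} subclonal SNVs")
# The clonal cluster's prevalence doubles as the cellularity estimate, so
# clonal mutations have CCF exactly 1; subclonal CCFs scale accordingly.
some_sub = next(iter(assignment.subclonal_keys()))
print(f"example subclonal CCF: {assignment.ccf[some_sub]:.3f}")
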
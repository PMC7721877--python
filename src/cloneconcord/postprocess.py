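"""Post-processing heuristics that make reconstruction solutions comparable.

Clone trees from different runs number their nodes arbitrarily, and both
tree- and cluster-shaped solutions contain spurious small or
near-duplicate populations. The operations here put every solution into
a canonical, pruned form before clonality is assigned:

* ``canonicalize_tree`` — deterministic left-heavy child ordering and
  breadth-first renumbering (root = 0, ids increase with depth).
* ``postprocess_tree`` — prune/merge nodes that fail support or
  prevalence thresholds, merge near-identical parent/child and sibling
  pairs, iterated to a fixed point.
* ``postprocess_clusters`` — the flat-cluster analogue, plus
  reconstruction-failure designation.
* ``detect_poly_tumour`` — flags trees whose normal root has more than
  one direct child (suggestive of independent primary tumours); such
  solutions are treated as reconstruction failures downstream.

Merging always moves mutation assignments onto the surviving
node/cluster (never drops them) and assigns the SNV-count-weighted mean
cellular prevalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core import CloneNode, CloneTree, Cluster, ClusterSolution, SolutionStatus

__all__ = [
    "PostprocessConfig",
    "canonicalize_tree",
    "postprocess_tree",
    "detect_poly_tumour",
    "postprocess_clusters",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PostprocessConfig:
    """Thresholds controlling pruning and merging.

    Defaults: a population needs at least 5 SNVs or 5 CNAs of support
    and 10% cellular prevalence (2% if it is a subclonal cluster);
    populations within 2% prevalence of each other are merged.
    """

    min_snvs_per_node: int = 5
    min_cnas_per_node: int = 5
    min_clonal_cp: float = 0.10
    min_subclonal_cp: float = 0.02
    merge_cp_delta: float = 0.02
    snv_driven_max_cnas: int = 5
    min_total_snvs: int = 5
    #: apply the 10%/2% clonal/subclonal split to tree nodes too
    #: (default: the 10% floor applies to every tree node).
    tree_subclonal_threshold: bool = False
    #: weight merged prevalences by SNV+CNA counts instead of SNVs only.
    weight_by_all_mutations: bool = False

    def __post_init__(self) -> None:
        if self.min_subclonal_cp > self.min_clonal_cp:
            raise ValueError("min_subclonal_cp must not exceed min_clonal_cp")
        for name in (
            "min_snvs_per_node",
            "min_cnas_per_node",
            "min_clonal_cp",
            "min_subclonal_cp",
            "merge_cp_delta",
            "snv_driven_max_cnas",
            "min_total_snvs",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# canonical form
# ---------------------------------------------------------------------------

def _subtree_sizes(tree: CloneTree) -> dict[int, int]:
    sizes: dict[int, int] = {}

    def walk(nid: int) -> int:
        size = 1 + sum(walk(c.node_id) for c in tree.children(nid))
        sizes[nid] = size
        return size

    walk(tree.root.node_id)
    return sizes


def canonicalize_tree(tree: CloneTree) -> CloneTree:
    """Return an equivalent tree in canonical form.

    Children are ordered left-heavy — by decreasing subtree size, ties
    by decreasing cellular prevalence, then by decreasing SNV count —
    and node ids are reassigned breadth-first in that order, so the
    root is 0 and ids strictly increase with depth. Idempotent.
    """
    sizes = _subtree_sizes(tree)

    def child_order(nid: int) -> list[int]:
        kids = tree.children(nid)
        kids.sort(
            key=lambda n: (-sizes[n.node_id], -n.cp, -len(n.snv_ids), n.node_id)
        )
        return [k.node_id for k in kids]

    # breadth-first renumbering in canonical child order
    mapping: dict[int, int] = {}
    queue = [tree.root.node_id]
    next_id = 0
    while queue:
        nid = queue.pop(0)
        mapping[nid] = next_id
        next_id += 1
        queue.extend(child_order(nid))

    new_nodes = []
    for old_id, new_id in mapping.items():
        node = tree.nodes[old_id]
        new_nodes.append(
            CloneNode(
                node_id=new_id,
                parent_id=None if node.parent_id is None else mapping[node.parent_id],
                cp=node.cp,
                snv_ids=set(node.snv_ids),
                cna_ids=set(node.cna_ids),
            )
        )
    new_nodes.sort(key=lambda n: n.node_id)
    return CloneTree(new_nodes, tree.sample_id)


# ---------------------------------------------------------------------------
# shared merge arithmetic
# ---------------------------------------------------------------------------

def _weighted_cp(
    cp_a: float, n_a: int, cp_b: float, n_b: int
) -> float:
    """Mutation-count-weighted mean prevalence; plain mean when unweighted."""
    if n_a + n_b == 0:
        return (cp_a + cp_b) / 2.0
    return (cp_a * n_a + cp_b * n_b) / (n_a + n_b)


def _merge_weight(node, cfg: PostprocessConfig) -> int:
    w = len(node.snv_ids)
    if cfg.weight_by_all_mutations:
        w += len(node.cna_ids)
    return w


# ---------------------------------------------------------------------------
# tree post-processing
# ---------------------------------------------------------------------------

def detect_poly_tumour(tree: CloneTree) -> bool:
    """True iff the normal root has more than one direct child."""
    return len(tree.children(tree.root.node_id)) >= 2


def _tree_min_cp(tree: CloneTree, node: CloneNode, cfg: PostprocessConfig) -> float:
    if not cfg.tree_subclonal_threshold:
        return cfg.min_clonal_cp
    top = max(tree.subclones(), key=lambda n: n.cp, default=None)
    if top is not None and node.node_id == top.node_id:
        return cfg.min_clonal_cp
    return cfg.min_subclonal_cp


def _merge_tree_node(tree: CloneTree, src_id: int, dst_id: int, cfg) -> None:
    """Merge node ``src`` into ``dst`` in place.

    Mutations move to ``dst``; ``dst`` takes the weighted-mean
    prevalence; orphaned children reattach to ``src``'s parent (the
    nearest surviving ancestor), keeping prevalences nested.
    """
    src = tree.nodes[src_id]
    dst = tree.nodes[dst_id]
    w_src, w_dst = _merge_weight(src, cfg), _merge_weight(dst, cfg)
    dst.cp = _weighted_cp(dst.cp, w_dst, src.cp, w_src)
    dst.snv_ids |= src.snv_ids
    dst.cna_ids |= src.cna_ids
    for child in tree.children(src_id):
        child.parent_id = dst_id if dst_id == src.parent_id else src.parent_id
    del tree.nodes[src_id]
    logger.debug("merged tree node %d into %d (cp -> %.4f)", src_id, dst_id, dst.cp)


def _node_supported(node: CloneNode, cfg: PostprocessConfig) -> bool:
    return (
        len(node.snv_ids) >= cfg.min_snvs_per_node
        or len(node.cna_ids) >= cfg.min_cnas_per_node
    )


def postprocess_tree(
    tree: CloneTree, cfg: PostprocessConfig | None = None
) -> tuple[CloneTree, SolutionStatus]:
    """Prune and merge a clone tree, iterating the rules to a fixed point.

    Per pass (deepest nodes first): (1) a node within ``merge_cp_delta``
    of its (non-root) parent's prevalence is merged into the parent;
    (2) siblings within ``merge_cp_delta`` are merged when both are
    SNV-driven (at most ``snv_driven_max_cnas`` CNAs); (3) a node
    lacking support (fewer than 5 SNVs and fewer than 5 CNAs) or below
    the prevalence floor is merged into its nearest-prevalence
    neighbour, preferring the parent on ties. The result is
    re-canonicalized.

    Status is FAILED when nothing survives or fewer than
    ``min_total_snvs`` SNVs are assigned, POLY_TUMOUR when the surviving
    root has two or more direct children, OK otherwise.
    """
    cfg = cfg or PostprocessConfig()
    work = canonicalize_tree(tree)
    root_id = work.root.node_id

    changed = True
    while changed:
        changed = False
        order = sorted(
            (n.node_id for n in work.subclones()),
            key=lambda nid: (-work.depth(nid), nid),
        )
        # (1) merge with parent
        for nid in order:
            node = work.nodes.get(nid)
            if node is None:
                continue
            if node.parent_id is not None and node.parent_id != root_id:
                parent = work.nodes[node.parent_id]
                if abs(node.cp - parent.cp) <= cfg.merge_cp_delta:
                    _merge_tree_node(work, nid, parent.node_id, cfg)
                    changed = True
                    break
        if changed:
            continue
        # (2) sibling merge (both SNV-driven)
        for nid in order:
            node = work.nodes.get(nid)
            if node is None:
                continue
            sibs = [
                s
                for s in work.children(node.parent_id)
                if s.node_id != nid
                and abs(s.cp - node.cp) <= cfg.merge_cp_delta
                and len(s.cna_ids) <= cfg.snv_driven_max_cnas
                and len(node.cna_ids) <= cfg.snv_driven_max_cnas
            ]
            if sibs:
                sibs.sort(key=lambda s: (abs(s.cp - node.cp), -s.cp, s.node_id))
                _merge_tree_node(work, nid, sibs[0].node_id, cfg)
                changed = True
                break
        if changed:
            continue
        # (3) prune unsupported / low-prevalence nodes
        for nid in order:
            node = work.nodes.get(nid)
            if node is None:
                continue
            if _node_supported(node, cfg) and node.cp >= _tree_min_cp(work, node, cfg):
                continue
            others = [n for n in work.subclones() if n.node_id != nid]
            if not others:
                # sole subclone fails thresholds: drop it, tree becomes empty
                del work.nodes[nid]
                changed = True
                break
            parent_id = node.parent_id
            others.sort(
                key=lambda n: (
                    abs(n.cp - node.cp),
                    0 if n.node_id == parent_id else 1,
                    -n.cp,
                    n.node_id,
                )
            )
            _merge_tree_node(work, nid, others[0].node_id, cfg)
            changed = True
            break

    work = canonicalize_tree(work)
    if work.n_subclones() == 0 or len(work.all_snv_ids()) < cfg.min_total_snvs:
        return work, SolutionStatus.FAILED
    if detect_poly_tumour(work):
        return work, SolutionStatus.POLY_TUMOUR
    return work, SolutionStatus.OK


# ---------------------------------------------------------------------------
# cluster post-processing
# ---------------------------------------------------------------------------

def _merge_clusters(dst: Cluster, src: Cluster, cfg: PostprocessConfig) -> None:
    dst.cp = _weighted_cp(dst.cp, dst.n_snvs, src.cp, src.n_snvs)
    dst.snv_ids |= src.snv_ids
    logger.debug(
        "merged cluster %d into %d (cp -> %.4f)", src.cluster_id, dst.cluster_id, dst.cp
    )


def _cluster_ok(c: Cluster, is_clonal: bool, cfg: PostprocessConfig) -> bool:
    if c.n_snvs < cfg.min_snvs_per_node:
        return False
    floor = cfg.min_clonal_cp if is_clonal else cfg.min_subclonal_cp
    return c.cp >= floor


def postprocess_clusters(
    sol: ClusterSolution, cfg: PostprocessConfig | None = None
) -> tuple[ClusterSolution, SolutionStatus]:
    """Prune, merge and renumber a flat mutation-clustering solution.

    Failure is designated up front when fewer than ``min_total_snvs``
    SNVs are assigned in total or every cluster sits below
    ``min_clonal_cp``. Otherwise: clusters with fewer than 5 supporting
    SNVs, or prevalence below 10% (clonal cluster) / 2% (subclonal
    clusters), are merged into their nearest-prevalence neighbour
    (higher-prevalence neighbour on ties) with SNV-count-weighted mean
    prevalence; any remaining pair within ``merge_cp_delta`` is merged
    the same way; both rules iterate to a fixed point. Surviving
    clusters are renumbered 1..k by decreasing prevalence. A final
    validity re-check designates failure if the merged solution no
    longer meets the floors.
    """
    cfg = cfg or PostprocessConfig()
    clusters = [c.copy() for c in sol.clusters]

    def rebuild(status: SolutionStatus) -> tuple[ClusterSolution, SolutionStatus]:
        clusters.sort(key=lambda c: (-c.cp, -c.n_snvs))
        renum = [
            Cluster(i + 1, c.cp, set(c.snv_ids)) for i, c in enumerate(clusters)
        ]
        return (
            ClusterSolution(renum, sol.sample_id, sol.source_algorithm),
            status,
        )

    total = sum(c.n_snvs for c in clusters)
    if total < cfg.min_total_snvs or not clusters or all(
        c.cp < cfg.min_clonal_cp for c in clusters
    ):
        return rebuild(SolutionStatus.FAILED)

    changed = True
    while changed:
        changed = False
        if len(clusters) <= 1:
            break
        clonal = max(clusters, key=lambda c: (c.cp, c.n_snvs))
        # prune failing clusters into nearest-cp neighbour
        failing = [
            c for c in clusters if not _cluster_ok(c, c is clonal, cfg)
        ]
        if failing:
            src = min(failing, key=lambda c: (c.cp, c.n_snvs))
            others = [c for c in clusters if c is not src]
            dst = min(others, key=lambda c: (abs(c.cp - src.cp), -c.cp))
            _merge_clusters(dst, src, cfg)
            clusters.remove(src)
            changed = True
            continue
        # merge any pair within merge_cp_delta (closest pair first)
        ordered = sorted(clusters, key=lambda c: -c.cp)
        best = None
        for hi, lo in zip(ordered, ordered[1:]):
            gap = hi.cp - lo.cp
            if gap <= cfg.merge_cp_delta and (best is None or gap < best[0]):
                best = (gap, hi, lo)
        if best is not None:
            _, hi, lo = best
            _merge_clusters(hi, lo, cfg)
            clusters.remove(lo)
            changed = True

    clonal = max(clusters, key=lambda c: (c.cp, c.n_snvs))
    if not all(_cluster_ok(c, c is clonal, cfg) for c in clusters):
        return rebuild(SolutionStatus.FAILED)
    return rebuild(SolutionStatus.OK)
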
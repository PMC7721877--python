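"""Prevalence-scale conversions, solution classification and CCF assignment.

Different reconstruction algorithms report population sizes on
different scales. Everything downstream works in *cellular prevalence*
(the fraction of all cells in the sample carrying the population's
mutations):

* PyClone-like output reports the fraction of tumour cells, so it is
  multiplied by the sample purity.
* SciClone-like output is characterised by cluster VAFs, which are
  doubled (a heterozygous mutation in a diploid region is seen on one
  of two alleles) and capped at 1.

A post-processed solution is classified monoclonal (one subclone),
polyclonal (more than one), poly-tumour or failed. In a polyclonal
solution the highest-prevalence subclone is the clonal population; its
mutations are clonal, all others subclonal. The cancer cell fraction
(CCF) of a mutation is its population's prevalence divided by the
sample cellularity — the clonal cluster's own prevalence for
cluster-shaped solutions, or an external (CNA-tool) estimate for
tree-shaped ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Union

from .core import CloneTree, Cluster, ClusterSolution, SolutionStatus

__all__ = [
    "SolutionClass",
    "ClonalityAssignment",
    "pyclone_cp",
    "sciclone_cp",
    "classify_solution",
    "assign_clonality",
    "ccf",
]

logger = logging.getLogger(__name__)

Solution = Union[CloneTree, ClusterSolution]


class SolutionClass:
    MONOCLONAL = "monoclonal"
    POLYCLONAL = "polyclonal"
    POLY_TUMOUR = "poly_tumour"
    FAILED = "failed"


def pyclone_cp(raw_prevalence: float, purity: float) -> float:
    """Tumour-cell fraction -> cellular prevalence (multiply by purity)."""
    if not (0 <= raw_prevalence <= 1):
        raise ValueError("raw prevalence must lie in [0, 1]")
    if not (0 < purity <= 1):
        raise ValueError("purity must lie in (0, 1]")
    return raw_prevalence * purity


def sciclone_cp(vaf: float, cap: bool = True) -> float:
    """Cluster VAF -> cellular prevalence (x2, capped at 1 by default)."""
    if not (0 <= vaf <= 1):
        raise ValueError("VAF must lie in [0, 1]")
    cp = 2.0 * vaf
    if cp > 1.0:
        if cap:
            logger.warning("cellular prevalence 2*VAF=%.3f capped at 1.0", cp)
            return 1.0
        logger.warning("cellular prevalence 2*VAF=%.3f exceeds 1 (uncapped mode)", cp)
    return cp


def _subclone_count(sol: Solution) -> int:
    if isinstance(sol, CloneTree):
        return sol.n_subclones()
    return sol.n_subclones()


def classify_solution(
    sol: Solution, status: SolutionStatus = SolutionStatus.OK
) -> str:
    """Classify a post-processed solution.

    One predicted subclone -> monoclonal; more than one -> polyclonal.
    Failed and poly-tumour statuses pass through unchanged (a tree whose
    root has several direct children is also flagged poly-tumour here).
    """
    if status == SolutionStatus.FAILED:
        return SolutionClass.FAILED
    if status == SolutionStatus.POLY_TUMOUR:
        return SolutionClass.POLY_TUMOUR
    if isinstance(sol, CloneTree) and len(sol.children(sol.root.node_id)) >= 2:
        return SolutionClass.POLY_TUMOUR
    n = _subclone_count(sol)
    if n == 0:
        return SolutionClass.FAILED
    return SolutionClass.MONOCLONAL if n == 1 else SolutionClass.POLYCLONAL


@dataclass
class ClonalityAssignment:
    """Per-mutation clonal/subclonal labels and CCFs for one sample."""

    sample_id: str
    labels: dict = field(default_factory=dict)  # mutation key -> "clonal"/"subclonal"
    ccf: dict = field(default_factory=dict)  # mutation key -> CCF
    solution_class: str = SolutionClass.FAILED
    pipeline_cellularity: Optional[float] = None
    subclone_count: int = 0

    def keys_with_label(self, label: str, kind: Optional[str] = None) -> set:
        """Mutation keys carrying ``label``; ``kind`` filters snv/cna keys.

        SNV keys are (chrom, pos, ref, alt) tuples; CNA identifiers are
        everything else.
        """
        out = set()
        for k, lab in self.labels.items():
            if lab != label:
                continue
            is_snv = isinstance(k, tuple)
            if kind == "snv" and not is_snv:
                continue
            if kind == "cna" and is_snv:
                continue
            out.add(k)
        return out

    def clonal_keys(self, kind: Optional[str] = None) -> set:
        return self.keys_with_label("clonal", kind)

    def subclonal_keys(self, kind: Optional[str] = None) -> set:
        return self.keys_with_label("subclonal", kind)


def ccf(node_cp: float, cellularity: float) -> float:
    """Cancer cell fraction: population prevalence over sample cellularity.

    Values above 1 can arise when cellularity comes from an independent
    CNA-tool estimate; they are reported as-is with a warning, not
    clipped, because such mismatches are informative.
    """
    if cellularity == 0:
        raise ZeroDivisionError("CCF undefined at zero cellularity")
    value = node_cp / cellularity
    if value > 1.0 + 1e-12:
        logger.warning("CCF %.3f exceeds 1 (cp=%.3f, cellularity=%.3f)", value, node_cp, cellularity)
    return value


def assign_clonality(
    sol: Solution,
    status: SolutionStatus = SolutionStatus.OK,
    cellularity: Optional[float] = None,
) -> ClonalityAssignment:
    """Label every mutation clonal or subclonal and compute its CCF.

    The highest-prevalence subclone is clonal (ties broken toward the
    larger SNV count); all other populations are subclonal. For
    cluster-shaped solutions the clonal cluster's prevalence is the
    pipeline cellularity; tree-shaped solutions require an external
    ``cellularity`` (the CNA-tool estimate).
    """
    cls = classify_solution(sol, status)
    out = ClonalityAssignment(sample_id=sol.sample_id, solution_class=cls)
    if cls in (SolutionClass.FAILED, SolutionClass.POLY_TUMOUR):
        return out

    if isinstance(sol, CloneTree):
        if cellularity is None:
            raise ValueError(
                "tree-shaped solutions need an external cellularity estimate"
            )
        populations = [
            (n.cp, len(n.snv_ids), set(n.snv_ids) | set(n.cna_ids))
            for n in sol.subclones()
        ]
    else:
        populations = [
            (c.cp, c.n_snvs, set(c.snv_ids)) for c in sol.clusters
        ]

    populations.sort(key=lambda t: (-t[0], -t[1]))
    top_cp, top_n, _ = populations[0]
    ties = [p for p in populations if math.isclose(p[0], top_cp, abs_tol=1e-12)]
    if len(ties) > 1:
        logger.info(
            "tie for highest prevalence (%.4f) broken toward %d SNVs", top_cp, top_n
        )

    if isinstance(sol, ClusterSolution):
        cellularity = top_cp
    out.pipeline_cellularity = cellularity
    out.subclone_count = len(populations)

    for i, (cp, _n, keys) in enumerate(populations):
        label = "clonal" if i == 0 else "subclonal"
        value = ccf(cp, cellularity)
        for k in keys:
            out.labels[k] = label
            out.ccf[k] = value
    return out
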
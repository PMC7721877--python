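"""Shared domain types and elementary primitives.

Coordinates are 0-based half-open internally (``GenomicInterval``); SNV
positions follow the VCF convention and stay 1-based, because the
(chrom, pos, ref, alt) tuple is the identity key used to match variants
across callers and reconstructions.

Chromosome names are normalised on ingest: a leading ``chr`` is stripped
and only 1-22, X and Y are accepted (other contigs are dropped by the
readers).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

__all__ = [
    "CHROMOSOMES",
    "normalize_chrom",
    "GenomicInterval",
    "SNVRecord",
    "CNASegment",
    "SampleMeta",
    "CloneNode",
    "CloneTree",
    "Cluster",
    "ClusterSolution",
    "SolutionStatus",
    "UndefinedVAFError",
    "vaf",
    "intersect_intervals",
    "jaccard",
]

#: Accepted chromosome set (autosomes plus the sex chromosomes).
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
_CHROM_SET = frozenset(CHROMOSOMES)


def normalize_chrom(name: str) -> Optional[str]:
    """Strip any ``chr`` prefix and return the name if accepted, else None."""
    name = str(name)
    if name.lower().startswith("chr"):
        name = name[3:]
    if name in _CHROM_SET:
        return name
    return None


class UndefinedVAFError(ValueError):
    """Raised when a VAF is requested at zero total read depth."""


def vaf(ref_count: int, alt_count: int) -> float:
    """Variant allele frequency: alt reads over total reads at the site."""
    if ref_count < 0 or alt_count < 0:
        raise ValueError("read counts must be non-negative")
    total = ref_count + alt_count
    if total == 0:
        raise UndefinedVAFError("VAF undefined at zero total depth")
    return alt_count / total


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a normalised chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.chrom not in _CHROM_SET:
            raise ValueError(f"chromosome {self.chrom!r} not in accepted set")
        if not self.end > self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.start < 0:
            raise ValueError("start must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start


def intersect_intervals(
    a: GenomicInterval, b: GenomicInterval
) -> Optional[GenomicInterval]:
    """Overlap of two intervals, or None when disjoint (half-open semantics)."""
    if a.chrom != b.chrom:
        return None
    start = max(a.start, b.start)
    end = min(a.end, b.end)
    if end <= start:
        return None
    return GenomicInterval(a.chrom, start, end)


def jaccard(a: Iterable, b: Iterable) -> Optional[float]:
    """|a ∩ b| / |a ∪ b|.

    Returns None (an explicit "undefined" marker) when both sets are
    empty; callers exclude undefined values from averages rather than
    coercing them to 0 or 1.
    """
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        return None
    return len(sa & sb) / len(union)


@dataclass(frozen=True)
class SNVRecord:
    """A somatic single-nucleotide variant with tumour read counts.

    ``pos`` is 1-based (VCF convention); identity across callers and
    reconstructions is the ``key`` tuple (chrom, pos, ref, alt).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    ref_count: int = 0
    alt_count: int = 0
    caller_label: str = ""

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def vaf(self) -> float:
        return vaf(self.ref_count, self.alt_count)


@dataclass(frozen=True)
class CNASegment:
    """An allele-specific copy-number segment with an optional clonality label."""

    interval: GenomicInterval
    major_cn: int
    minor_cn: int
    clonal_fraction: Optional[float] = None
    clonality_label: str = "unspecified"

    def __post_init__(self) -> None:
        if self.major_cn < self.minor_cn:
            raise ValueError(
                f"major_cn ({self.major_cn}) must be >= minor_cn ({self.minor_cn})"
            )
        if self.major_cn < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.clonal_fraction is not None and not (0 < self.clonal_fraction <= 1):
            raise ValueError("clonal_fraction must lie in (0, 1]")
        if self.clonality_label not in ("clonal", "subclonal", "unspecified"):
            raise ValueError(f"unknown clonality label {self.clonality_label!r}")

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn

    @property
    def is_neutral(self) -> bool:
        return self.major_cn == 1 and self.minor_cn == 1

    @property
    def key(self) -> str:
        """Stable segment identifier used in clone-tree mutation sets."""
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}:{self.major_cn}/{self.minor_cn}"


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    tumour_id: str
    purity: float
    ploidy: float = 2.0
    sex: str = "XY"
    is_index_lesion: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.purity <= 1):
            raise ValueError("purity must lie in (0, 1]")
        if self.sex not in ("XX", "XY"):
            raise ValueError("sex must be 'XX' or 'XY'")


class SolutionStatus(enum.Enum):
    """Outcome of post-processing a reconstruction solution."""

    OK = "ok"
    FAILED = "failed"
    POLY_TUMOUR = "poly_tumour"


@dataclass
class CloneNode:
    """One cancer-cell population in a clone tree.

    The root (node 0, parent None) is the normal population: cellular
    prevalence 1 by convention and no mutation assignments.
    """

    node_id: int
    parent_id: Optional[int]
    cp: float
    snv_ids: set = field(default_factory=set)
    cna_ids: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not (0 <= self.cp <= 1 + 1e-12):
            raise ValueError(f"cellular prevalence {self.cp} outside [0, 1]")
        self.snv_ids = set(self.snv_ids)
        self.cna_ids = set(self.cna_ids)

    def copy(self) -> "CloneNode":
        return CloneNode(
            self.node_id, self.parent_id, self.cp, set(self.snv_ids), set(self.cna_ids)
        )


class CloneTree:
    """Rooted tree of cancer-cell populations (root = normal)."""

    def __init__(self, nodes: Iterable[CloneNode], sample_id: str = ""):
        self.nodes: dict[int, CloneNode] = {}
        for node in nodes:
            if node.node_id in self.nodes:
                raise ValueError(f"duplicate node id {node.node_id}")
            self.nodes[node.node_id] = node
        self.sample_id = sample_id
        self.validate()

    # -- structure -----------------------------------------------------
    @property
    def root(self) -> CloneNode:
        roots = [n for n in self.nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        return roots[0]

    def children(self, node_id: int) -> list[CloneNode]:
        return [n for n in self.nodes.values() if n.parent_id == node_id]

    def subclones(self) -> list[CloneNode]:
        """All non-root nodes (the cancer-cell populations)."""
        root_id = self.root.node_id
        return [n for n in self.nodes.values() if n.node_id != root_id]

    def n_subclones(self) -> int:
        return len(self.nodes) - 1

    def depth(self, node_id: int) -> int:
        d = 0
        node = self.nodes[node_id]
        while node.parent_id is not None:
            node = self.nodes[node.parent_id]
            d += 1
        return d

    def dfs(self) -> Iterator[CloneNode]:
        """Depth-first traversal from the root; visits every node once."""
        stack = [self.root.node_id]
        seen = set()
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise ValueError("cycle detected during traversal")
            seen.add(nid)
            yield self.nodes[nid]
            stack.extend(
                sorted((c.node_id for c in self.children(nid)), reverse=True)
            )

    def validate(self, strict_cp: bool = False, cp_tol: float = 1e-9) -> None:
        """Check single-root, connected, acyclic structure.

        With ``strict_cp`` every child's cellular prevalence must not
        exceed its parent's (tolerance ``cp_tol``). Post-processing can
        introduce slack up to the merge threshold, so the default check
        is structural only.
        """
        root = self.root  # raises unless exactly one
        for node in self.nodes.values():
            if node.parent_id is not None and node.parent_id not in self.nodes:
                raise ValueError(
                    f"node {node.node_id} references missing parent {node.parent_id}"
                )
        visited = {n.node_id for n in self.dfs()}  # dfs raises on cycles
        if visited != set(self.nodes):
            raise ValueError("tree is not connected")
        if root.snv_ids or root.cna_ids:
            raise ValueError("root (normal population) must carry no mutations")
        if strict_cp:
            for node in self.nodes.values():
                if node.parent_id is not None:
                    parent = self.nodes[node.parent_id]
                    if node.cp > parent.cp + cp_tol:
                        raise ValueError(
                            f"node {node.node_id} cp {node.cp} exceeds parent cp {parent.cp}"
                        )

    def copy(self) -> "CloneTree":
        return CloneTree([n.copy() for n in self.nodes.values()], self.sample_id)

    def all_snv_ids(self) -> set:
        out: set = set()
        for n in self.nodes.values():
            out |= n.snv_ids
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, CloneTree):
            return NotImplemented
        if self.sample_id != other.sample_id or set(self.nodes) != set(other.nodes):
            return False
        for nid, node in self.nodes.items():
            o = other.nodes[nid]
            if (
                node.parent_id != o.parent_id
                or abs(node.cp - o.cp) > 1e-12
                or node.snv_ids != o.snv_ids
                or node.cna_ids != o.cna_ids
            ):
                return False
        return True

    def __repr__(self) -> str:
        return f"CloneTree(sample={self.sample_id!r}, n_subclones={self.n_subclones()})"


@dataclass
class Cluster:
    """A flat mutation cluster: the tree-free analogue of a clone node."""

    cluster_id: int
    cp: float
    snv_ids: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.snv_ids = set(self.snv_ids)

    @property
    def n_snvs(self) -> int:
        return len(self.snv_ids)

    def copy(self) -> "Cluster":
        return Cluster(self.cluster_id, self.cp, set(self.snv_ids))


class ClusterSolution:
    """A flat mutation-clustering solution (PyClone/DPClust/SciClone-like)."""

    SOURCES = ("pyclone-like", "dpclust-like", "sciclone-like")

    def __init__(
        self,
        clusters: Iterable[Cluster],
        sample_id: str = "",
        source_algorithm: str = "pyclone-like",
    ):
        self.clusters = [c for c in clusters]
        self.sample_id = sample_id
        if source_algorithm not in self.SOURCES:
            raise ValueError(f"unknown source algorithm {source_algorithm!r}")
        self.source_algorithm = source_algorithm
        ids = [c.cluster_id for c in self.clusters]
        if len(ids) != len(set(ids)):
            raise ValueError("cluster ids must be unique")
        seen: set = set()
        for c in self.clusters:
            if seen & c.snv_ids:
                raise ValueError("snv assignments must be disjoint across clusters")
            seen |= c.snv_ids
            if not (0 <= c.cp <= 1 + 1e-12):
                raise ValueError(f"cluster cp {c.cp} outside [0, 1]")

    def total_snvs(self) -> int:
        return sum(c.n_snvs for c in self.clusters)

    def all_snv_ids(self) -> set:
        out: set = set()
        for c in self.clusters:
            out |= c.snv_ids
        return out

    def n_subclones(self) -> int:
        return len(self.clusters)

    def copy(self) -> "ClusterSolution":
        return ClusterSolution(
            [c.copy() for c in self.clusters], self.sample_id, self.source_algorithm
        )

    def __repr__(self) -> str:
        return (
            f"ClusterSolution(sample={self.sample_id!r}, "
            f"n_clusters={len(self.clusters)}, source={self.source_algorithm!r})"
        )
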
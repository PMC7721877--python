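"""Synthetic tumours, caller outputs and reconstruction solutions.

The generator provides ground truth with the statistical structure the
downstream analysis assumes, so every stage is testable without
controlled-access patient genomes:

* a clone tree with known per-region cellular prevalences (fractions of
  tumour cells; the clonal population is 1), optionally with
  region-private subclones for multi-region studies;
* SNVs assigned to single nodes, with read counts sampled binomially at
  a configurable sequencing depth, so the expected observed VAF of a
  multiplicity-``m`` SNV on total tumour copy number ``C`` in a region
  with purity ``rho`` and node prevalence ``phi`` is
  ``m * phi * rho / (C * rho + 2 * (1 - rho))``;
* two contrasting SNV-caller error profiles — a conservative caller
  (high VAF threshold, near-zero false positives) and a permissive one
  (low-VAF false positives with a C>A-weighted trinucleotide bias) —
  and CNA segmentations with boundary jitter, caller-unique spurious
  segments, and optional clonal+subclonal paired entries;
* emulated reconstruction solutions (tree- or cluster-shaped), either
  noise-free restrictions of the truth or perturbed with prevalence
  noise and cluster split/merge events.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    CloneNode,
    CloneTree,
    CNASegment,
    Cluster,
    ClusterSolution,
    GenomicInterval,
    SNVRecord,
)
from .consensus import (
    CONTEXT_TYPES,
    TRINUC_CLASSES,
    collapse_substitution,
    context_of_class,
)

__all__ = [
    "DEFAULT_CHROM_SIZES",
    "synthetic_genome",
    "GroundTruthTumour",
    "CallerProfile",
    "conservative_profile",
    "permissive_profile",
    "expected_vaf",
    "simulate_tumour",
    "simulate_caller_snvs",
    "simulate_caller_cnas",
    "emulate_reconstruction",
    "reconstruct_from_snv_calls",
]

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Default synthetic genome: 10 Mbp over two chromosomes.
DEFAULT_CHROM_SIZES: dict[str, int] = {"1": 5_000_000, "2": 5_000_000}


def synthetic_genome(
    chrom_sizes: Mapping[str, int] | None = None,
    seed: int | np.random.Generator = 0,
    gc: float = 0.41,
) -> dict[str, str]:
    """Random genome with a given GC fraction (i.i.d. bases)."""
    chrom_sizes = dict(chrom_sizes or DEFAULT_CHROM_SIZES)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = {}
    for chrom, size in chrom_sizes.items():
        idx = rng.choice(4, size=size, p=p)
        out[chrom] = _BASES[idx].tobytes().decode()
    return out


def expected_vaf(
    multiplicity: float, phi: float, purity: float, total_cn: float
) -> float:
    """Closed-form expected VAF of an SNV.

    ``phi`` is the node's prevalence among tumour cells, ``total_cn``
    the total tumour copy number at the locus; contaminating normal
    cells contribute two reference copies.
    """
    return (multiplicity * phi * purity) / (
        total_cn * purity + 2.0 * (1.0 - purity)
    )


# ---------------------------------------------------------------------------
# ground truth container
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthTumour:
    """A simulated tumour with known architecture.

    ``region_profiles`` maps region id -> node id -> prevalence among
    tumour cells (0 for region-private absence); ``snvs`` holds one row
    per true SNV (chrom, pos, ref, alt, node_id, multiplicity,
    total_cn); ``segments`` pairs each true copy-number segment with the
    node it belongs to.
    """

    tumour_id: str
    tree: CloneTree
    region_profiles: dict  # region -> {node_id: phi}
    purity: dict  # region -> purity
    depth: dict  # region -> mean depth
    genome: dict  # chrom -> sequence
    snvs: pd.DataFrame
    segments: list  # [(node_id, CNASegment)]
    index_region: str = "R0"

    @property
    def regions(self) -> list[str]:
        return list(self.region_profiles)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def genome_length(self) -> int:
        return sum(len(s) for s in self.genome.values())

    def phi(self, region: str) -> dict:
        return self.region_profiles[region]

    def present_nodes(self, regions: Sequence[str]) -> list[int]:
        """Non-root nodes with prevalence > 0 in at least one region."""
        out = []
        for node in self.tree.subclones():
            if any(self.region_profiles[r].get(node.node_id, 0.0) > 0 for r in regions):
                out.append(node.node_id)
        return out

    def n_subclones(self, region: Optional[str] = None) -> int:
        """True distinguishable subclone count (region-restricted if given)."""
        regions = [region] if region is not None else self.regions
        nodes = self.present_nodes(regions)
        signatures = {
            tuple(self.region_profiles[r].get(nid, 0.0) for r in regions)
            for nid in nodes
        }
        return len(signatures)

    def true_class(self, region: Optional[str] = None) -> str:
        return "monoclonal" if self.n_subclones(region) == 1 else "polyclonal"

    def context_positions(self) -> dict:
        """Genome positions grouped by pyrimidine-collapsed trinucleotide."""
        return _context_index(self.genome)


# index cache keyed by genome identity; the strong reference pins the
# genome so the id stays valid (genomes are shared across many tumours)
_CTX_CACHE: dict[int, tuple[dict, dict]] = {}


def _context_index(genome: dict) -> dict:
    entry = _CTX_CACHE.get(id(genome))
    if entry is not None and entry[0] is genome:
        return entry[1]
    cache: dict[str, list] = {c: [] for c in CONTEXT_TYPES}
    b2i = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        b2i[ord(b)] = i
    for chrom, seq in genome.items():
        arr = b2i[np.frombuffer(seq.encode(), dtype=np.uint8)]
        f, c, t = arr[:-2], arr[1:-1], arr[2:]
        purine = (c == 0) | (c == 2)
        f2 = np.where(purine, 3 - t, f)
        t2 = np.where(purine, 3 - f, t)
        c2 = np.where(purine, 3 - c, c)
        idx = np.where(c2 == 1, 0, 1) * 16 + f2 * 4 + t2
        pos = np.arange(1, len(arr) - 1)  # 0-based centre positions
        for k in range(32):
            cache[CONTEXT_TYPES[k]].append((chrom, pos[idx == k]))
    _CTX_CACHE[id(genome)] = (genome, cache)
    return cache


# ---------------------------------------------------------------------------
# caller error profiles
# ---------------------------------------------------------------------------

@dataclass
class CallerProfile:
    """Error model of one mutation caller (SNV and CNA behaviour)."""

    name: str
    sensitivity: Callable[[np.ndarray], np.ndarray]
    fp_rate_per_mb: float = 0.0
    fp_vaf_dist: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None
    fp_trinucleotide_bias: Optional[np.ndarray] = None  # weights over 96 classes
    segment_jitter_bp: int = 0
    unique_segment_rate: float = 0.0
    emits_subclonal_pairs: bool = False

    def __post_init__(self) -> None:
        if self.fp_trinucleotide_bias is not None:
            w = np.asarray(self.fp_trinucleotide_bias, dtype=float)
            if w.shape != (96,) or w.min() < 0:
                raise ValueError("trinucleotide bias must be 96 non-negative weights")
            total = w.sum()
            if total <= 0:
                raise ValueError("trinucleotide bias weights must sum to a positive value")
            self.fp_trinucleotide_bias = w / total


def _threshold_sensitivity(vaf_min: float, plateau: float) -> Callable:
    def curve(v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        return np.where(v >= vaf_min, plateau, 0.0)

    return curve


def conservative_profile() -> CallerProfile:
    """SomaticSniper-like: misses low-VAF variants, almost no false calls."""
    return CallerProfile(
        name="conservative",
        sensitivity=_threshold_sensitivity(0.10, 0.98),
        fp_rate_per_mb=0.02,
        fp_vaf_dist=lambda rng, n: rng.beta(2.0, 6.0, size=n),
        fp_trinucleotide_bias=None,
        segment_jitter_bp=2_000,
        unique_segment_rate=0.05,
        emits_subclonal_pairs=False,
    )


def permissive_profile() -> CallerProfile:
    """MuTect-like: sensitive at low VAF, adds low-VAF false positives
    with a C>A-weighted context bias (heaviest at C[C>A]G and T[C>A]G)."""
    bias = np.ones(96)
    for i, cls in enumerate(TRINUC_CLASSES):
        if "[C>A]" in cls:
            bias[i] = 8.0
    bias[TRINUC_CLASSES.index("C[C>A]G")] = 40.0
    bias[TRINUC_CLASSES.index("T[C>A]G")] = 40.0
    return CallerProfile(
        name="permissive",
        sensitivity=_threshold_sensitivity(0.03, 0.97),
        fp_rate_per_mb=5.0,
        fp_vaf_dist=lambda rng, n: rng.beta(2.0, 20.0, size=n),
        fp_trinucleotide_bias=bias,
        segment_jitter_bp=5_000,
        unique_segment_rate=0.3,
        emits_subclonal_pairs=True,
    )


# ---------------------------------------------------------------------------
# tumour simulation
# ---------------------------------------------------------------------------

def _spaced_values(
    rng: np.random.Generator, k: int, lo: float, hi: float, spacing: float
) -> np.ndarray:
    """k values in [lo, hi], pairwise >= spacing apart, descending."""
    if k == 0:
        return np.array([])
    slack = (hi - lo) - (k - 1) * spacing
    if slack < 0:
        raise ValueError(
            f"cannot place {k} prevalences >= {spacing} apart in [{lo}, {hi}]"
        )
    u = np.sort(rng.uniform(0, slack, size=k))
    vals = lo + u + spacing * np.arange(k)
    return vals[::-1].copy()


def simulate_tumour(
    n_subclones: int = 2,
    cp_spacing: float = 0.15,
    n_snvs: int = 1000,
    n_regions: int = 1,
    purity: float = 0.7,
    depth: float = 60.0,
    seed: int = 0,
    chrom_sizes: Optional[Mapping[str, int]] = None,
    genome: Optional[dict] = None,
    n_cnas_per_node: int = 5,
    min_subclone_phi: float = 0.2,
    region_absent_prob: float = 0.0,
    min_snvs_per_node: int = 10,
    tumour_id: str = "T1",
) -> GroundTruthTumour:
    """Simulate a tumour with known subclonal architecture.

    The clonal population (node 1) has prevalence 1 among tumour cells
    in every region; additional subclones receive prevalences pairwise
    at least ``cp_spacing`` apart and no less than ``min_subclone_phi``,
    re-drawn per region with a fixed rank order so a child never
    exceeds its parent anywhere. With ``region_absent_prob`` > 0 a
    subclone (and its descendants) may be absent from individual
    regions, creating region-private populations; every subclone is
    kept present in at least one region. Deterministic for a fixed
    seed.
    """
    if n_subclones < 1:
        raise ValueError("need at least one subclone")
    rng = np.random.default_rng(seed)
    if genome is None:
        genome = synthetic_genome(chrom_sizes, rng)
    sizes = {c: len(s) for c, s in genome.items()}
    k_extra = n_subclones - 1
    # feasibility check up front (also re-drawn per region below)
    _spaced_values(rng, k_extra, min_subclone_phi, 1.0 - cp_spacing, cp_spacing)

    # topology: clonal node 1 under the root; each further subclone
    # attaches to a node with strictly higher prevalence rank
    parents = {1: 0}
    for nid in range(2, n_subclones + 1):
        parents[nid] = int(rng.integers(1, nid))

    regions = [f"R{i}" for i in range(n_regions)]
    # absence with propagation along the tree, clonal node always present
    absent: dict[str, set] = {r: set() for r in regions}
    if region_absent_prob > 0 and n_regions > 1:
        for r in regions:
            for nid in range(2, n_subclones + 1):
                if parents[nid] in absent[r] or rng.random() < region_absent_prob:
                    absent[r].add(nid)
        for nid in range(2, n_subclones + 1):
            if all(nid in absent[r] for r in regions):
                keep = regions[int(rng.integers(0, n_regions))]
                node = nid  # re-admit the whole ancestor path in that region
                while node in absent[keep]:
                    absent[keep].discard(node)
                    node = parents[node]

    region_profiles: dict[str, dict[int, float]] = {}
    for r in regions:
        vals = _spaced_values(
            rng, k_extra, min_subclone_phi, 1.0 - cp_spacing, cp_spacing
        )
        prof = {1: 1.0}
        for i, nid in enumerate(range(2, n_subclones + 1)):
            prof[nid] = 0.0 if nid in absent[r] else float(vals[i])
        region_profiles[r] = prof

    # true copy-number segments: non-overlapping random intervals,
    # assigned to nodes round-robin
    n_segs = n_cnas_per_node * n_subclones
    seg_states = [(2, 1), (3, 1), (1, 0), (2, 0), (2, 2)]
    segments: list[tuple[int, CNASegment]] = []
    chroms = list(sizes)
    per_chrom = -(-n_segs // len(chroms))
    slot = 0
    for chrom in chroms:
        pts = np.sort(
            rng.choice(sizes[chrom] - 2, size=2 * per_chrom, replace=False) + 1
        )
        for i in range(per_chrom):
            if slot >= n_segs:
                break
            start, end = int(pts[2 * i]), int(pts[2 * i + 1])
            if end - start < 20_000:
                end = min(start + 20_000, sizes[chrom])
                if i + 1 < per_chrom and end > pts[2 * i + 2]:
                    continue  # would collide with the next slot; skip
            nid = slot % n_subclones + 1
            maj, mnr = seg_states[int(rng.integers(len(seg_states)))]
            mean_phi = float(
                np.mean([region_profiles[r][nid] for r in regions])
            )
            if nid == 1:
                label, frac = "clonal", None
            else:
                label, frac = "subclonal", max(mean_phi, 1e-3) if mean_phi <= 1 else None
            segments.append(
                (
                    nid,
                    CNASegment(
                        GenomicInterval(chrom, start, end), maj, mnr,
                        clonal_fraction=frac, clonality_label=label,
                    ),
                )
            )
            slot += 1

    # SNVs: minimum support per node, remainder weighted by prevalence
    base = min(min_snvs_per_node, n_snvs // n_subclones)
    counts = np.full(n_subclones, base)
    rest = n_snvs - counts.sum()
    if rest > 0:
        weights = np.array(
            [
                np.mean([region_profiles[r][nid] for r in regions]) + 0.05
                for nid in range(1, n_subclones + 1)
            ]
        )
        counts += rng.multinomial(rest, weights / weights.sum())

    total_len = sum(sizes.values())
    offsets = np.cumsum([0] + [sizes[c] for c in chroms])
    flat = rng.choice(total_len - 4, size=n_snvs, replace=False) + 2
    flat.sort()
    chrom_idx = np.searchsorted(offsets, flat, side="right") - 1
    pos0 = flat - offsets[chrom_idx]

    clonal_segs = [s for nid, s in segments if nid == 1]
    node_ids = np.repeat(np.arange(1, n_subclones + 1), counts)
    rng.shuffle(node_ids)
    rows = []
    for i in range(n_snvs):
        chrom = chroms[chrom_idx[i]]
        p0 = int(pos0[i])
        ref = genome[chrom][p0]
        alt = "ACGT".replace(ref, "")[int(rng.integers(3))]
        total_cn = 2
        for s in clonal_segs:
            if s.interval.chrom == chrom and s.interval.start <= p0 < s.interval.end:
                total_cn = s.total_cn
                break
        rows.append(
            {
                "chrom": chrom,
                "pos": p0 + 1,  # 1-based, VCF convention
                "ref": ref,
                "alt": alt,
                "node_id": int(node_ids[i]),
                "multiplicity": 1,
                "total_cn": total_cn,
            }
        )
    snv_df = pd.DataFrame(rows)

    nodes = [CloneNode(0, None, 1.0)]
    for nid in range(1, n_subclones + 1):
        snv_keys = {
            (r["chrom"], r["pos"], r["ref"], r["alt"])
            for r in rows
            if r["node_id"] == nid
        }
        cna_keys = {s.key for n2, s in segments if n2 == nid}
        phi_max = max(region_profiles[r][nid] for r in regions)
        nodes.append(CloneNode(nid, parents[nid], phi_max, snv_keys, cna_keys))
    tree = CloneTree(nodes, tumour_id)

    return GroundTruthTumour(
        tumour_id=tumour_id,
        tree=tree,
        region_profiles=region_profiles,
        purity={r: purity for r in regions},
        depth={r: depth for r in regions},
        genome=genome,
        snvs=snv_df,
        segments=segments,
        index_region=regions[0],
    )


# ---------------------------------------------------------------------------
# caller emulation
# ---------------------------------------------------------------------------

def _expected_vafs(truth: GroundTruthTumour, region: str) -> np.ndarray:
    prof = truth.region_profiles[region]
    rho = truth.purity[region]
    phi = truth.snvs["node_id"].map(prof).to_numpy(dtype=float)
    m = truth.snvs["multiplicity"].to_numpy(dtype=float)
    cn = truth.snvs["total_cn"].to_numpy(dtype=float)
    return expected_vaf(m, phi, rho, cn)


def simulate_caller_snvs(
    truth: GroundTruthTumour,
    profile: CallerProfile,
    region: str,
    seed: int = 0,
) -> list[SNVRecord]:
    """Emulate one SNV caller on one region.

    True SNVs are detected with probability
    ``profile.sensitivity(expected VAF)``; read depths are Poisson
    around the region mean and alt counts binomial at the expected VAF
    (a detected variant reports at least one supporting read). False
    positives arrive at ``fp_rate_per_mb`` with VAFs from the profile's
    low-VAF distribution and genomic positions drawn to match its
    trinucleotide bias.
    """
    if region not in truth.region_profiles:
        raise KeyError(f"unknown region {region!r}")
    rng = np.random.default_rng(seed)
    evaf = _expected_vafs(truth, region)
    mean_depth = truth.depth[region]

    sens = np.asarray(profile.sensitivity(evaf), dtype=float)
    detected = (rng.random(len(evaf)) < sens) & (evaf > 0)
    out: list[SNVRecord] = []
    idx = np.flatnonzero(detected)
    depths = rng.poisson(mean_depth, size=len(idx))
    for j, i in enumerate(idx):
        d = int(depths[j])
        if d == 0:
            continue
        alt = int(rng.binomial(d, evaf[i]))
        alt = max(alt, 1)
        row = truth.snvs.iloc[i]
        out.append(
            SNVRecord(
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                ref_count=d - alt,
                alt_count=alt,
                caller_label=profile.name,
            )
        )

    n_fp = int(rng.poisson(profile.fp_rate_per_mb * truth.genome_length() / 1e6))
    if n_fp > 0:
        taken = {(r.chrom, r.pos) for r in out}
        fp_vafs = (
            profile.fp_vaf_dist(rng, n_fp)
            if profile.fp_vaf_dist is not None
            else rng.beta(2.0, 20.0, size=n_fp)
        )
        classes = _sample_fp_classes(rng, profile, n_fp)
        ctx_pos = truth.context_positions() if classes is not None else None
        for j in range(n_fp):
            rec = _place_fp(
                rng, truth, classes[j] if classes is not None else None,
                ctx_pos, float(fp_vafs[j]), mean_depth, profile.name, taken,
            )
            if rec is not None:
                taken.add((rec.chrom, rec.pos))
                out.append(rec)
    return out


def _sample_fp_classes(rng, profile: CallerProfile, n: int):
    if profile.fp_trinucleotide_bias is None:
        return None
    return rng.choice(96, size=n, p=profile.fp_trinucleotide_bias)


def _place_fp(rng, truth, cls_idx, ctx_pos, fp_vaf, mean_depth, label, taken):
    """One false-positive record, optionally at a biased trinucleotide context."""
    chroms = list(truth.genome)
    if cls_idx is None:
        for _ in range(20):
            chrom = chroms[int(rng.integers(len(chroms)))]
            p0 = int(rng.integers(1, len(truth.genome[chrom]) - 1))
            if (chrom, p0 + 1) not in taken:
                ref = truth.genome[chrom][p0]
                alt = "ACGT".replace(ref, "")[int(rng.integers(3))]
                return _fp_record(rng, chrom, p0, ref, alt, fp_vaf, mean_depth, label)
        return None
    cls = TRINUC_CLASSES[int(cls_idx)]
    ctx = context_of_class(cls)
    pools = ctx_pos[ctx]
    lengths = np.array([len(p) for _, p in pools])
    if lengths.sum() == 0:
        return None
    for _ in range(20):
        ci = int(rng.choice(len(pools), p=lengths / lengths.sum()))
        chrom, positions = pools[ci]
        p0 = int(positions[int(rng.integers(len(positions)))])
        if (chrom, p0 + 1) in taken:
            continue
        ref = truth.genome[chrom][p0]
        # cls is pyrimidine-referenced; purine sites mutate on the reverse strand
        cls_ref, cls_alt = cls[2], cls[4]
        alt = cls_alt if ref == cls_ref else _COMP[cls_alt]
        return _fp_record(rng, chrom, p0, ref, alt, fp_vaf, mean_depth, label)
    return None


def _fp_record(rng, chrom, p0, ref, alt, fp_vaf, mean_depth, label):
    d = max(int(rng.poisson(mean_depth)), 1)
    a = max(int(rng.binomial(d, min(fp_vaf, 1.0))), 1)
    return SNVRecord(
        chrom=chrom, pos=p0 + 1, ref=ref, alt=alt,
        ref_count=d - a, alt_count=a, caller_label=label,
    )


def simulate_caller_cnas(
    truth: GroundTruthTumour,
    profile: CallerProfile,
    region: str,
    seed: int = 0,
) -> list[CNASegment]:
    """Emulate one CNA caller's segmentation of one region.

    True segments of populations present in the region are emitted with
    boundaries perturbed by up to ``segment_jitter_bp`` in either
    direction (overlaps introduced by jitter are trimmed); spurious
    caller-unique segments appear at ``unique_segment_rate`` per true
    segment. A profile with ``emits_subclonal_pairs`` reports each
    subclonal aberration as a clonal+subclonal entry pair
    (Battenberg-style); otherwise a single entry carries the truth's
    clonality label.
    """
    if region not in truth.region_profiles:
        raise KeyError(f"unknown region {region!r}")
    rng = np.random.default_rng(seed)
    prof = truth.region_profiles[region]
    sizes = truth.chrom_sizes
    j = profile.segment_jitter_bp

    true_here = [
        (nid, seg) for nid, seg in truth.segments if prof.get(nid, 0.0) > 0
    ]
    jittered: list[tuple[str, int, int, tuple, CNASegment]] = []
    for nid, seg in true_here:
        iv = seg.interval
        start = iv.start + (int(rng.integers(-j, j + 1)) if j else 0)
        end = iv.end + (int(rng.integers(-j, j + 1)) if j else 0)
        start = max(0, min(start, sizes[iv.chrom] - 1))
        end = max(start + 1, min(end, sizes[iv.chrom]))
        jittered.append((iv.chrom, start, end, (nid,), seg))

    # trim jitter-induced overlaps, preserving order
    jittered.sort(key=lambda t: (t[0], t[1]))
    fixed = []
    prev_chrom, prev_end = None, 0
    for chrom, start, end, meta, seg in jittered:
        if chrom == prev_chrom and start < prev_end:
            start = prev_end
        if end > start:
            fixed.append((chrom, start, end, seg))
            prev_chrom, prev_end = chrom, end

    out: list[CNASegment] = []
    for chrom, start, end, seg in fixed:
        iv = GenomicInterval(chrom, start, end)
        if seg.clonality_label == "subclonal" and profile.emits_subclonal_pairs:
            out.append(CNASegment(iv, 1, 1, clonality_label="clonal"))
            out.append(
                CNASegment(
                    iv, seg.major_cn, seg.minor_cn,
                    clonal_fraction=seg.clonal_fraction,
                    clonality_label="subclonal",
                )
            )
        else:
            out.append(
                CNASegment(
                    iv, seg.major_cn, seg.minor_cn,
                    clonal_fraction=seg.clonal_fraction,
                    clonality_label=seg.clonality_label,
                )
            )

    n_spurious = int(rng.poisson(profile.unique_segment_rate * max(len(fixed), 1)))
    if n_spurious:
        occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in sizes}
        for s in out:
            occupied[s.interval.chrom].append((s.interval.start, s.interval.end))
        states = [(3, 1), (1, 0), (2, 2), (2, 1)]
        for _ in range(n_spurious):
            # place inside an unoccupied gap, chosen with probability
            # proportional to gap length
            gaps = []
            for chrom, occ in occupied.items():
                prev = 0
                for s, e in sorted(occ) + [(sizes[chrom], sizes[chrom])]:
                    if s - prev >= 20_000:
                        gaps.append((chrom, prev, s))
                    prev = max(prev, e)
            if not gaps:
                break
            lengths = np.array([g[2] - g[1] for g in gaps], dtype=float)
            chrom, g_start, g_end = gaps[
                int(rng.choice(len(gaps), p=lengths / lengths.sum()))
            ]
            length = min(int(rng.integers(20_000, 200_000)), g_end - g_start)
            start = int(rng.integers(g_start, g_end - length + 1))
            end = start + length
            maj, mnr = states[int(rng.integers(len(states)))]
            out.append(
                CNASegment(
                    GenomicInterval(chrom, start, end), maj, mnr,
                    clonality_label="clonal",
                )
            )
            occupied[chrom].append((start, end))
    out.sort(key=lambda s: (s.interval.chrom, s.interval.start, s.clonality_label))
    return out


# ---------------------------------------------------------------------------
# reconstruction emulation
# ---------------------------------------------------------------------------

def emulate_reconstruction(
    truth: GroundTruthTumour,
    regions: Union[str, Sequence[str], None] = None,
    shape: str = "clusters",
    cp_noise_sd: float = 0.0,
    split_merge_rate: float = 0.0,
    seed: int = 0,
) -> Union[CloneTree, ClusterSolution]:
    """Emulated reconstruction of the truth from one or more regions.

    The noise-free setting returns the true architecture restricted to
    the requested region(s), with prevalences on the cellular-
    prevalence scale (tumour-cell fraction times purity; across
    several regions, the maximum over regions). Populations whose
    prevalences coincide exactly in every requested region are
    indistinguishable and are emitted merged; populations absent from
    all requested regions disappear along with their mutations.
    ``cp_noise_sd`` adds Gaussian prevalence noise; ``split_merge_rate``
    randomly splits clusters or merges adjacent-prevalence cluster
    pairs (cluster shape only).
    """
    if shape not in ("tree", "clusters"):
        raise ValueError("shape must be 'tree' or 'clusters'")
    if regions is None:
        regions = truth.regions
    elif isinstance(regions, str):
        regions = [regions]
    for r in regions:
        if r not in truth.region_profiles:
            raise KeyError(f"unknown region {r!r}")
    rng = np.random.default_rng(seed)

    present = truth.present_nodes(regions)
    signature = {
        nid: tuple(
            round(truth.region_profiles[r].get(nid, 0.0), 12) for r in regions
        )
        for nid in present
    }
    groups: dict[tuple, list[int]] = {}
    for nid in present:
        groups.setdefault(signature[nid], []).append(nid)

    # representative: the member closest to the root
    reps = {}
    for sig, members in groups.items():
        rep = min(members, key=lambda n: (truth.tree.depth(n), n))
        reps[sig] = rep
    member_to_rep = {
        m: reps[sig] for sig, members in groups.items() for m in members
    }

    cp_value = {}
    for sig, rep in reps.items():
        cps = [
            truth.region_profiles[r].get(rep, 0.0) * truth.purity[r]
            for r in regions
        ]
        cp_value[rep] = max(cps)

    snv_sets: dict[int, set] = {rep: set() for rep in reps.values()}
    cna_sets: dict[int, set] = {rep: set() for rep in reps.values()}
    for nid in present:
        rep = member_to_rep[nid]
        node = truth.tree.nodes[nid]
        snv_sets[rep] |= node.snv_ids
        cna_sets[rep] |= node.cna_ids

    if cp_noise_sd > 0:
        for rep in list(cp_value):
            cp_value[rep] = float(
                np.clip(cp_value[rep] + rng.normal(0, cp_noise_sd), 0.005, 1.0)
            )

    sample_id = (
        f"{truth.tumour_id}:{regions[0]}" if len(regions) == 1 else truth.tumour_id
    )

    if shape == "tree":
        nodes = [CloneNode(0, None, 1.0)]
        for rep in sorted(reps.values()):
            # nearest present ancestor's representative (root otherwise)
            anc = truth.tree.nodes[rep].parent_id
            while anc not in (None, 0) and anc not in member_to_rep:
                anc = truth.tree.nodes[anc].parent_id
            parent = member_to_rep.get(anc, 0) if anc not in (None, 0) else 0
            nodes.append(
                CloneNode(rep, parent, cp_value[rep], snv_sets[rep], cna_sets[rep])
            )
        if cp_noise_sd > 0:  # keep prevalences nested after noise
            tree = CloneTree(nodes, sample_id)
            for node in sorted(tree.subclones(), key=lambda n: tree.depth(n.node_id)):
                parent = tree.nodes[node.parent_id]
                node.cp = min(node.cp, parent.cp)
            return tree
        return CloneTree(nodes, sample_id)

    clusters = [
        Cluster(0, cp_value[rep], set(snv_sets[rep])) for rep in sorted(reps.values())
    ]
    if split_merge_rate > 0:
        clusters = _split_merge(rng, clusters, split_merge_rate)
    clusters.sort(key=lambda c: -c.cp)
    renum = [Cluster(i + 1, c.cp, c.snv_ids) for i, c in enumerate(clusters)]
    return ClusterSolution(renum, sample_id, "pyclone-like")


def _split_merge(rng, clusters: list[Cluster], rate: float) -> list[Cluster]:
    out = [Cluster(c.cluster_id, c.cp, set(c.snv_ids)) for c in clusters]
    i = 0
    while i < len(out):
        if rng.random() < rate:
            c = out[i]
            if rng.random() < 0.5 and len(c.snv_ids) >= 4:
                keys = sorted(c.snv_ids)
                rng.shuffle(keys)
                half = len(keys) // 2
                lo = float(np.clip(c.cp - 0.015, 0.005, 1.0))
                hi = float(np.clip(c.cp + 0.015, 0.005, 1.0))
                out[i] = Cluster(c.cluster_id, hi, set(keys[:half]))
                out.insert(i + 1, Cluster(-len(out) - 1, lo, set(keys[half:])))
                i += 1
            elif len(out) >= 2:
                others = [x for x in out if x is not c]
                near = min(others, key=lambda x: abs(x.cp - c.cp))
                n = len(c.snv_ids) + len(near.snv_ids)
                if n:
                    near.cp = (
                        near.cp * len(near.snv_ids) + c.cp * len(c.snv_ids)
                    ) / n
                near.snv_ids |= c.snv_ids
                out.remove(c)
                continue
        i += 1
    return out


def reconstruct_from_snv_calls(
    truth: GroundTruthTumour,
    region: str,
    calls: Sequence[SNVRecord],
    merge_gap: float = 0.02,
) -> ClusterSolution:
    """Cluster-shaped reconstruction driven by one caller's SNV output.

    Detected true SNVs group by their true population; false-positive
    calls are clustered on their VAF-doubled prevalence estimate
    (single-linkage, chains broken at gaps above ``merge_gap``). Every
    cluster's prevalence is the mean doubled VAF of its members, capped
    at 1, so spurious low-VAF calls form extra low-prevalence
    populations exactly the way permissive callers inflate subclone
    counts.
    """
    truth_nodes = {
        (r["chrom"], r["pos"], r["ref"], r["alt"]): r["node_id"]
        for r in truth.snvs.to_dict("records")
    }
    by_node: dict[int, list[SNVRecord]] = {}
    fps: list[SNVRecord] = []
    for rec in calls:
        nid = truth_nodes.get(rec.key)
        if nid is None:
            fps.append(rec)
        else:
            by_node.setdefault(nid, []).append(rec)

    clusters: list[Cluster] = []
    cid = 0
    for nid, recs in sorted(by_node.items()):
        cps = [min(2.0 * r.vaf, 1.0) for r in recs]
        cid += 1
        clusters.append(Cluster(cid, float(np.mean(cps)), {r.key for r in recs}))

    if fps:
        est = sorted(fps, key=lambda r: 2.0 * r.vaf)
        chain: list[SNVRecord] = [est[0]]
        prev = min(2.0 * est[0].vaf, 1.0)
        chains: list[list[SNVRecord]] = []
        for rec in est[1:]:
            cp = min(2.0 * rec.vaf, 1.0)
            if cp - prev > merge_gap:
                chains.append(chain)
                chain = []
            chain.append(rec)
            prev = cp
        chains.append(chain)
        for group in chains:
            cid += 1
            cps = [min(2.0 * r.vaf, 1.0) for r in group]
            clusters.append(Cluster(cid, float(np.mean(cps)), {r.key for r in group}))

    clusters.sort(key=lambda c: -c.cp)
    renum = [Cluster(i + 1, c.cp, c.snv_ids) for i, c in enumerate(clusters)]
    return ClusterSolution(
        renum, f"{truth.tumour_id}:{region}", "sciclone-like"
    )
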
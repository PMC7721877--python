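"""Consensus of two mutation callers: set operations and error profiles.

SNVs are compared by exact identity key, giving intersect / A-unique /
B-unique classes. Copy-number segmentations are compared on a per
base-pair basis: a base where both callers report the same aberrant
(major, minor) state is *intersect*; aberrant in one caller while the
other calls it copy-number neutral (major 1 / minor 1, both clonally
and subclonally) is that caller's *unique*; two different aberrations
are *disagreement* and are excluded from the union, as there is no
natural way to resolve them. A caller that delineates subclonal copy
number by emitting a clonal+subclonal entry pair for one region
(Battenberg-style) has those regions labelled its unique, but the other
caller's aberration (if any) is what enters the union. Per-base classes
are re-assembled into maximal segments.

Trinucleotide mutation profiles use the standard 96 classes
(pyrimidine-reference substitution x 5' base x 3' base, purine
references strand-collapsed) and are normalised by the double-stranded
trinucleotide composition of the supplied genome.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .core import CHROMOSOMES, CNASegment, GenomicInterval, SNVRecord

__all__ = [
    "SnvPartition",
    "CnaPartition",
    "TrinucProfile",
    "partition_snvs",
    "partition_cnas",
    "filter_min_length",
    "trinuc_profile",
    "TRINUC_CLASSES",
    "CONTEXT_TYPES",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# SNV partition
# ---------------------------------------------------------------------------

@dataclass
class SnvPartition:
    intersect: set
    a_unique: set
    b_unique: set

    @property
    def union(self) -> set:
        return self.intersect | self.a_unique | self.b_unique


def partition_snvs(
    a: Iterable[SNVRecord], b: Iterable[SNVRecord]
) -> SnvPartition:
    """Exact key-set arithmetic on (chrom, pos, ref, alt) identities."""

    def keyset(records, label):
        keys = [r.key for r in records]
        uniq = set(keys)
        if len(uniq) != len(keys):
            logger.warning(
                "caller %s reported %d duplicate SNV keys; deduplicated",
                label,
                len(keys) - len(uniq),
            )
        return uniq

    ka, kb = keyset(a, "A"), keyset(b, "B")
    return SnvPartition(intersect=ka & kb, a_unique=ka - kb, b_unique=kb - ka)


# ---------------------------------------------------------------------------
# CNA partition
# ---------------------------------------------------------------------------

@dataclass
class CnaPartition:
    """Per-base consensus classes re-assembled into maximal segments."""

    intersect: list = field(default_factory=list)
    a_unique: list = field(default_factory=list)
    b_unique: list = field(default_factory=list)
    disagreement: list = field(default_factory=list)
    union: list = field(default_factory=list)

    def covered_bp(self, which: str) -> int:
        return sum(s.interval.length for s in getattr(self, which))


# caller state at a base: ("uncovered",) | ("neutral",) |
# ("aberrant", maj, min) | ("dual", (cmaj, cmin), (smaj, smin))
_UNCOV = ("uncovered",)
_NEUT = ("neutral",)


def _neutral_state(chrom: str, sex: Optional[str]) -> tuple[int, int]:
    if sex == "XY" and chrom in ("X", "Y"):
        return (1, 0)
    return (1, 1)


def _segment_state(
    segs: Sequence[CNASegment], chrom: str, sex: Optional[str]
) -> tuple:
    """Collapse the (<=2) segments covering one elementary interval."""
    if not segs:
        return _UNCOV
    neutral = _neutral_state(chrom, sex)
    if len(segs) == 1:
        s = segs[0]
        if (s.major_cn, s.minor_cn) == neutral:
            return _NEUT
        return ("aberrant", s.major_cn, s.minor_cn)
    if len(segs) == 2:
        labels = sorted(s.clonality_label for s in segs)
        if labels != ["clonal", "subclonal"]:
            raise ValueError(
                "overlapping same-clonality segments within one caller "
                f"on {chrom} near {segs[0].interval.start}"
            )
        clonal = next(s for s in segs if s.clonality_label == "clonal")
        sub = next(s for s in segs if s.clonality_label == "subclonal")
        if all((s.major_cn, s.minor_cn) == neutral for s in segs):
            return _NEUT
        return (
            "dual",
            (clonal.major_cn, clonal.minor_cn),
            (sub.major_cn, sub.minor_cn),
        )
    raise ValueError("more than two segments overlap a single region in one caller")


def _classify_base(
    sa: tuple, sb: tuple, neutral: tuple[int, int]
) -> tuple[Optional[str], Optional[tuple[int, int]]]:
    """Return (class, union copy-number state) for one elementary interval.

    Class is one of intersect / a_unique / b_unique / disagreement, or
    None for bases carrying no aberration in either caller.
    """
    if sa[0] == "dual" and sb[0] == "dual":
        if sa == sb:
            return "intersect", sa[1]
        return "disagreement", None
    if sa[0] == "dual":
        # dual caller's unique; the other caller's aberration enters the union
        return "a_unique", (sb[1], sb[2]) if sb[0] == "aberrant" else None
    if sb[0] == "dual":
        return "b_unique", (sa[1], sa[2]) if sa[0] == "aberrant" else None
    a_ab = sa[0] == "aberrant"
    b_ab = sb[0] == "aberrant"
    if a_ab and b_ab:
        if (sa[1], sa[2]) == (sb[1], sb[2]):
            return "intersect", (sa[1], sa[2])
        return "disagreement", None
    if a_ab:
        return "a_unique", (sa[1], sa[2])
    if b_ab:
        return "b_unique", (sb[1], sb[2])
    return None, None


def _assemble(
    pieces: list[tuple[str, int, int, tuple[int, int] | None, str]],
) -> list[CNASegment]:
    """Merge adjacent elementary pieces with identical state into segments."""
    out: list[CNASegment] = []
    for (chrom, cn), group in itertools.groupby(
        pieces, key=lambda p: (p[0], p[3])
    ):
        group = list(group)
        start, end = group[0][1], group[0][2]
        label = group[0][4]
        for _, s, e, _, lab in group[1:]:
            if s == end and lab == label:
                end = e
            else:
                out.append(_mk_seg(chrom, start, end, cn, label))
                start, end, label = s, e, lab
        out.append(_mk_seg(chrom, start, end, cn, label))
    return out


def _mk_seg(chrom, start, end, cn, label) -> CNASegment:
    maj, mnr = cn if cn is not None else (1, 1)
    return CNASegment(
        GenomicInterval(chrom, start, end), maj, mnr, clonality_label=label
    )


def partition_cnas(
    a: Iterable[CNASegment],
    b: Iterable[CNASegment],
    prefer_in_union: str = "a",
    uncovered_policy: str = "neutral",
    sex: Optional[str] = None,
    min_bp: int = 0,
) -> CnaPartition:
    """Per-base-pair consensus of two copy-number segmentations.

    ``uncovered_policy`` controls bases one caller does not annotate:
    ``"neutral"`` (default; sparse tables that only list aberrations are
    implicitly diploid elsewhere) or ``"exclude"`` (any base missing
    from either caller belongs to no class). ``sex="XY"`` makes
    major 1 / minor 0 the neutral state on X and Y. ``min_bp`` drops
    re-assembled segments shorter than the given length (applied to
    every output class).

    ``prefer_in_union`` records which caller is the non-dual-emitting
    one; for dual (clonal+subclonal paired) regions the *other* caller's
    aberration is used in the union regardless, so the argument only
    matters for documentation of intent.
    """
    del prefer_in_union  # resolution is symmetric: the non-dual caller wins
    by_chrom_a: dict[str, list[CNASegment]] = {}
    by_chrom_b: dict[str, list[CNASegment]] = {}
    for seg in a:
        by_chrom_a.setdefault(seg.interval.chrom, []).append(seg)
    for seg in b:
        by_chrom_b.setdefault(seg.interval.chrom, []).append(seg)

    part = CnaPartition()
    class_pieces: dict[str, list] = {
        "intersect": [],
        "a_unique": [],
        "b_unique": [],
        "disagreement": [],
    }
    union_pieces: list = []

    for chrom in CHROMOSOMES:
        sa_list = sorted(by_chrom_a.get(chrom, []), key=lambda s: s.interval.start)
        sb_list = sorted(by_chrom_b.get(chrom, []), key=lambda s: s.interval.start)
        if not sa_list and not sb_list:
            continue
        points = sorted(
            {p for s in sa_list + sb_list for p in (s.interval.start, s.interval.end)}
        )
        neutral = _neutral_state(chrom, sex)
        for start, end in zip(points, points[1:]):
            cover_a = [
                s
                for s in sa_list
                if s.interval.start <= start and s.interval.end >= end
            ]
            cover_b = [
                s
                for s in sb_list
                if s.interval.start <= start and s.interval.end >= end
            ]
            state_a = _segment_state(cover_a, chrom, sex)
            state_b = _segment_state(cover_b, chrom, sex)
            if uncovered_policy == "neutral":
                state_a = _NEUT if state_a == _UNCOV else state_a
                state_b = _NEUT if state_b == _UNCOV else state_b
            elif state_a == _UNCOV or state_b == _UNCOV:
                continue
            cls, union_cn = _classify_base(state_a, state_b, neutral)
            if cls is None:
                continue
            cn = None
            if cls == "intersect":
                cn = union_cn if not isinstance(union_cn[0], tuple) else union_cn
            elif cls == "a_unique":
                if state_a[0] == "dual":
                    cn = state_a[2]  # report the subclonal aberration
                else:
                    cn = (state_a[1], state_a[2])
            elif cls == "b_unique":
                if state_b[0] == "dual":
                    cn = state_b[2]
                else:
                    cn = (state_b[1], state_b[2])
            if isinstance(cn, tuple) and isinstance(cn[0], tuple):
                cn = cn[0]  # both-dual intersect: report the clonal state
            class_pieces[cls].append((chrom, start, end, cn, "unspecified"))
            if union_cn is not None:
                ucn = union_cn[0] if isinstance(union_cn[0], tuple) else union_cn
                union_pieces.append((chrom, start, end, ucn, "unspecified"))

    for cls, pieces in class_pieces.items():
        segs = _assemble(pieces)
        if min_bp:
            segs = filter_min_length(segs, min_bp)
        setattr(part, cls, segs)
    union = _assemble(union_pieces)
    if min_bp:
        union = filter_min_length(union, min_bp)
    part.union = union
    return part


def filter_min_length(
    segs: Iterable[CNASegment], min_bp: int = 10_000
) -> list[CNASegment]:
    """Drop segments shorter than ``min_bp`` (strict: length >= min_bp kept)."""
    return [s for s in segs if s.interval.length >= min_bp]


# ---------------------------------------------------------------------------
# trinucleotide profiles
# ---------------------------------------------------------------------------

_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The 96 substitution classes in conventional order:
#: substitution-major, then 5' base, then 3' base.
TRINUC_CLASSES: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in _SUBS
    for five in _BASES
    for three in _BASES
)

#: The 32 pyrimidine-centred trinucleotide context types.
CONTEXT_TYPES: tuple[str, ...] = tuple(
    f"{five}{centre}{three}"
    for centre in ("C", "T")
    for five in _BASES
    for three in _BASES
)

_CLASS_INDEX = {c: i for i, c in enumerate(TRINUC_CLASSES)}
_CONTEXT_INDEX = {c: i for i, c in enumerate(CONTEXT_TYPES)}


def collapse_substitution(
    five: str, ref: str, alt: str, three: str
) -> tuple[str, str]:
    """Map a substitution with its flanks to (96-class, context type).

    Purine-reference substitutions are reverse-complemented into their
    pyrimidine-reference class.
    """
    five, ref, alt, three = five.upper(), ref.upper(), alt.upper(), three.upper()
    if ref in ("A", "G"):
        five, three = _COMP[three], _COMP[five]
        ref, alt = _COMP[ref], _COMP[alt]
    cls = f"{five}[{ref}>{alt}]{three}"
    if cls not in _CLASS_INDEX:
        raise ValueError(f"invalid substitution class {cls}")
    return cls, f"{five}{ref}{three}"


def context_of_class(cls: str) -> str:
    """The pyrimidine-centred trinucleotide context a 96-class sits in."""
    return cls[0] + cls[2] + cls[6]


@dataclass
class TrinucProfile:
    counts: np.ndarray  # 96 integer counts
    normalized: np.ndarray  # counts / genome context frequency
    context_counts: np.ndarray  # 32 genome context frequencies
    errors: list = field(default_factory=list)  # (key, message) skipped records

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_dict(self) -> dict[str, float]:
        return dict(zip(TRINUC_CLASSES, self.normalized))


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """0-based half-open fetch from a dict of strings or a pyfaidx.Fasta."""
    seq = genome[chrom][start:end]
    return str(seq).upper()


def genome_context_counts(
    genome, chroms: Optional[Sequence[str]] = None
) -> np.ndarray:
    """Double-stranded trinucleotide composition of a genome.

    Every interior position contributes its pyrimidine-collapsed
    trinucleotide (positions with a purine centre count toward the
    reverse-complement context), so each of the 32 context types holds
    the number of genomic sites at which a mutation of that context
    could occur on either strand.
    """
    counts = np.zeros(len(CONTEXT_TYPES), dtype=np.int64)
    keys = chroms if chroms is not None else list(genome.keys())
    b2i = np.full(256, -1, dtype=np.int8)
    for i, base in enumerate(_BASES):
        b2i[ord(base)] = i
    for chrom in keys:
        seq = _fetch(genome, chrom, 0, len(genome[chrom]))
        arr = b2i[np.frombuffer(seq.encode(), dtype=np.uint8)]
        if len(arr) < 3:
            continue
        five, centre, three = arr[:-2], arr[1:-1], arr[2:]
        valid = (five >= 0) & (centre >= 0) & (three >= 0)
        f, c, t = five[valid], centre[valid], three[valid]
        # collapse purine centres (A=0, G=2) onto the reverse strand
        purine = (c == 0) | (c == 2)
        f2, c2, t2 = f.copy(), c.copy(), t.copy()
        f2[purine] = 3 - t[purine]
        t2[purine] = 3 - f[purine]
        c2[purine] = 3 - c[purine]
        # context index: centre C -> 0..15, centre T -> 16..31
        centre_idx = np.where(c2 == 1, 0, 1)
        idx = centre_idx * 16 + f2 * 4 + t2
        counts += np.bincount(idx, minlength=32)
    return counts


def trinuc_profile(
    snvs: Iterable[SNVRecord],
    genome,
    context_counts: Optional[np.ndarray] = None,
) -> TrinucProfile:
    """Genome-normalised 96-class trinucleotide substitution profile.

    Each SNV's reference base is checked against the genome; mismatches
    and boundary positions are skipped and listed in ``errors``.
    ``context_counts`` may be supplied to reuse a precomputed genome
    composition.
    """
    if context_counts is None:
        context_counts = genome_context_counts(genome)
    counts = np.zeros(len(TRINUC_CLASSES), dtype=np.int64)
    errors: list = []
    for rec in snvs:
        chrom = rec.chrom
        i = rec.pos - 1  # to 0-based
        try:
            chrom_len = len(genome[chrom])
        except KeyError:
            errors.append((rec.key, "chromosome absent from genome"))
            continue
        if i - 1 < 0 or i + 2 > chrom_len:
            errors.append((rec.key, "position at chromosome boundary"))
            continue
        tri = _fetch(genome, chrom, i - 1, i + 2)
        if tri[1] != rec.ref.upper():
            errors.append(
                (rec.key, f"reference mismatch: genome {tri[1]} vs record {rec.ref}")
            )
            continue
        if any(bse not in _BASES for bse in tri) or rec.alt.upper() not in _BASES:
            errors.append((rec.key, "non-ACGT base in context"))
            continue
        cls, _ctx = collapse_substitution(tri[0], tri[1], rec.alt, tri[2])
        counts[_CLASS_INDEX[cls]] += 1

    with np.errstate(divide="ignore", invalid="ignore"):
        ctx_per_class = np.array(
            [context_counts[_CONTEXT_INDEX[context_of_class(c)]] for c in TRINUC_CLASSES],
            dtype=float,
        )
        normalized = np.where(ctx_per_class > 0, counts / ctx_per_class, np.nan)
    if errors:
        logger.warning("trinucleotide profiling skipped %d records", len(errors))
    return TrinucProfile(
        counts=counts,
        normalized=normalized,
        context_counts=context_counts,
        errors=errors,
    )
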
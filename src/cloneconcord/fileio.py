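"""Readers and writers for the formats the pipeline touches.

SNVs come from VCF 4.x with per-sample allelic depths; copy-number
segments from tab-delimited tables whose column names and coordinate
base are declared by a :class:`SegmentTableDialect`; clone trees from a
minimal JSON interchange schema of this package's own design; flat
cluster solutions from TSV. Readers normalise chromosome names and
convert segment coordinates to the internal 0-based half-open
convention (SNV positions stay 1-based, matching their identity keys).

Caller-specific allow-/deny-list filtering is exposed as the generic
``filter_positions`` hook — the mechanism without any shipped list.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam

from .core import (
    CNASegment,
    CloneNode,
    CloneTree,
    Cluster,
    ClusterSolution,
    GenomicInterval,
    SNVRecord,
    normalize_chrom,
)

__all__ = [
    "SegmentTableDialect",
    "read_snv_vcf",
    "write_snv_vcf",
    "read_segments",
    "write_segments",
    "read_clone_tree",
    "write_clone_tree",
    "read_clusters",
    "write_clusters",
    "write_report",
    "filter_positions",
    "write_fasta",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# SNVs (VCF)
# ---------------------------------------------------------------------------

def read_snv_vcf(
    path,
    min_tumour_depth: int = 17,
    min_normal_depth: int = 10,
    tumour_sample: Optional[str] = None,
    normal_sample: Optional[str] = None,
    ad_field: str = "AD",
    multiallelic: str = "split",
    caller_label: str = "",
) -> list[SNVRecord]:
    """Read somatic SNVs with tumour read counts from a VCF.

    Records below the callable-base depth thresholds (defaults: 17x
    tumour, 10x normal) are excluded; the boundary is inclusive. With a
    single sample in the VCF it is taken as the tumour and the normal
    check is skipped unless ``normal_sample`` names one. Multiallelic
    records are split into per-alt records or rejected, per
    ``multiallelic`` ("split" | "reject"). Non-SNV alleles and
    off-catalogue contigs are dropped.
    """
    if multiallelic not in ("split", "reject"):
        raise ValueError("multiallelic must be 'split' or 'reject'")
    out: list[SNVRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if tumour_sample is None:
            if len(samples) == 1:
                tumour_sample = samples[0]
            elif len(samples) == 2 and normal_sample is None:
                # convention: NORMAL, TUMOUR column order
                normal_sample, tumour_sample = samples
            else:
                raise ValueError(
                    f"tumour_sample must be named among samples {samples}"
                )
        if tumour_sample not in samples:
            raise ValueError(f"sample {tumour_sample!r} absent from VCF")
        for rec in vcf:
            chrom = normalize_chrom(rec.chrom)
            if chrom is None:
                continue
            if rec.alts is None:
                continue
            if len(rec.alts) > 1 and multiallelic == "reject":
                logger.info("rejecting multiallelic record %s:%d", chrom, rec.pos)
                continue
            fmt = rec.samples[tumour_sample]
            ad = fmt.get(ad_field)
            if ad is None or ad[0] is None:
                raise ValueError(
                    f"record {chrom}:{rec.pos} lacks {ad_field!r} for sample "
                    f"{tumour_sample!r}"
                )
            if normal_sample is not None:
                nad = rec.samples[normal_sample].get(ad_field)
                if nad is None or nad[0] is None:
                    raise ValueError(
                        f"record {chrom}:{rec.pos} lacks {ad_field!r} for sample "
                        f"{normal_sample!r}"
                    )
                if sum(x for x in nad if x is not None) < min_normal_depth:
                    continue
            if sum(x for x in ad if x is not None) < min_tumour_depth:
                continue
            for i, alt in enumerate(rec.alts):
                if len(rec.ref) != 1 or alt is None or len(alt) != 1:
                    continue
                if alt not in "ACGT" or rec.ref not in "ACGT":
                    continue
                alt_count = ad[i + 1] if len(ad) > i + 1 and ad[i + 1] is not None else 0
                out.append(
                    SNVRecord(
                        chrom=chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        ref_count=int(ad[0]),
                        alt_count=int(alt_count),
                        caller_label=caller_label,
                    )
                )
    return out


def write_snv_vcf(
    records: Sequence[SNVRecord],
    path,
    chrom_sizes: dict[str, int],
    sample_name: str = "TUMOUR",
) -> None:
    """Write SNVs as a minimal single-sample VCF with AD/DP fields."""
    header = pysam.VariantHeader()
    for chrom, size in chrom_sizes.items():
        header.contigs.add(chrom, length=size)
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    header.add_sample(sample_name)
    ordered = sorted(records, key=lambda r: (r.chrom, r.pos, r.alt))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in ordered:
            rec = vcf.new_record(
                contig=r.chrom, start=r.pos - 1, alleles=(r.ref, r.alt)
            )
            rec.samples[sample_name]["AD"] = (r.ref_count, r.alt_count)
            rec.samples[sample_name]["DP"] = r.ref_count + r.alt_count
            vcf.write(rec)


def filter_positions(
    records: Iterable[SNVRecord],
    include: Optional[set] = None,
    exclude: Optional[set] = None,
) -> list[SNVRecord]:
    """Generic (chrom, pos) allow-/deny-list hook.

    With ``include`` only listed positions survive; ``exclude`` then
    removes listed positions. Lists are external resources supplied by
    the user.
    """
    out = []
    for r in records:
        key = (r.chrom, r.pos)
        if include is not None and key not in include:
            continue
        if exclude is not None and key in exclude:
            continue
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# segment tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentTableDialect:
    """Column mapping and coordinate base of a segment table."""

    chrom: str = "chrom"
    start: str = "start"
    end: str = "end"
    major_cn: str = "major_cn"
    minor_cn: str = "minor_cn"
    clonal_fraction: Optional[str] = None
    clonality: Optional[str] = None
    coordinate_base: int = 1  # 1-based inclusive (common) or 0-based half-open

    def __post_init__(self) -> None:
        if self.coordinate_base not in (0, 1):
            raise ValueError("coordinate_base must be 0 or 1")


def read_segments(path, dialect: SegmentTableDialect | None = None) -> list[CNASegment]:
    """Read allele-specific copy-number segments from a tab-delimited table."""
    dialect = dialect or SegmentTableDialect()
    df = pd.read_csv(path, sep="\t", dtype={dialect.chrom: str})
    required = [dialect.chrom, dialect.start, dialect.end, dialect.major_cn, dialect.minor_cn]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"segment table missing required columns {missing}")
    out: list[CNASegment] = []
    dropped = 0
    for _, row in df.iterrows():
        chrom = normalize_chrom(row[dialect.chrom])
        if chrom is None:
            dropped += 1
            continue
        maj, mnr = row[dialect.major_cn], row[dialect.minor_cn]
        if float(maj) != int(maj) or float(mnr) != int(mnr):
            raise ValueError(
                f"non-integer copy numbers ({maj}, {mnr}) on {chrom}"
            )
        maj, mnr = int(maj), int(mnr)
        if maj < mnr:
            raise ValueError(f"major_cn {maj} < minor_cn {mnr} on {chrom}")
        start = int(row[dialect.start])
        end = int(row[dialect.end])
        if dialect.coordinate_base == 1:
            start -= 1  # 1-based inclusive -> 0-based half-open
        frac = None
        if dialect.clonal_fraction and dialect.clonal_fraction in df.columns:
            v = row[dialect.clonal_fraction]
            frac = None if pd.isna(v) else float(v)
        label = "unspecified"
        if dialect.clonality and dialect.clonality in df.columns:
            v = row[dialect.clonality]
            if not pd.isna(v):
                label = str(v)
        out.append(
            CNASegment(
                GenomicInterval(chrom, start, end), maj, mnr, frac, label
            )
        )
    if dropped:
        logger.info("dropped %d segment rows on excluded contigs", dropped)
    return out


def write_segments(segments: Sequence[CNASegment], path) -> None:
    """Write segments in the package's native dialect (0-based half-open)."""
    rows = [
        {
            "chrom": s.interval.chrom,
            "start": s.interval.start,
            "end": s.interval.end,
            "major_cn": s.major_cn,
            "minor_cn": s.minor_cn,
            "clonal_fraction": s.clonal_fraction,
            "clonality": s.clonality_label,
        }
        for s in segments
    ]
    pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "major_cn", "minor_cn",
            "clonal_fraction", "clonality",
        ],
    ).to_csv(path, sep="\t", index=False)


NATIVE_DIALECT = SegmentTableDialect(
    clonal_fraction="clonal_fraction", clonality="clonality", coordinate_base=0
)


# ---------------------------------------------------------------------------
# clone trees and cluster solutions
# ---------------------------------------------------------------------------

def _encode_key(key) -> str:
    if isinstance(key, tuple):
        return ":".join(str(x) for x in key)
    return str(key)


def _decode_snv_key(text: str):
    parts = text.split(":")
    if len(parts) == 4 and parts[1].isdigit():
        return (parts[0], int(parts[1]), parts[2], parts[3])
    return text


def write_clone_tree(tree: CloneTree, path) -> None:
    doc = {
        "sample_id": tree.sample_id,
        "nodes": [
            {
                "id": n.node_id,
                "parent": n.parent_id,
                "cp": n.cp,
                "snvs": sorted(_encode_key(k) for k in n.snv_ids),
                "cnas": sorted(str(k) for k in n.cna_ids),
            }
            for n in sorted(tree.nodes.values(), key=lambda n: n.node_id)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_clone_tree(path) -> CloneTree:
    doc = json.loads(Path(path).read_text())
    nodes = []
    for item in doc["nodes"]:
        if item["parent"] == item["id"]:
            raise ValueError(f"node {item['id']} is its own parent (cycle)")
        nodes.append(
            CloneNode(
                node_id=int(item["id"]),
                parent_id=None if item["parent"] is None else int(item["parent"]),
                cp=float(item["cp"]),
                snv_ids={_decode_snv_key(k) for k in item.get("snvs", [])},
                cna_ids=set(item.get("cnas", [])),
            )
        )
    return CloneTree(nodes, doc.get("sample_id", ""))  # validates structure


def write_clusters(sol: ClusterSolution, path) -> None:
    rows = []
    for c in sorted(sol.clusters, key=lambda c: c.cluster_id):
        if c.snv_ids:
            for k in sorted(_encode_key(k) for k in c.snv_ids):
                rows.append(
                    {
                        "sample_id": sol.sample_id,
                        "source": sol.source_algorithm,
                        "cluster_id": c.cluster_id,
                        "cp": c.cp,
                        "snv_key": k,
                    }
                )
        else:
            rows.append(
                {
                    "sample_id": sol.sample_id,
                    "source": sol.source_algorithm,
                    "cluster_id": c.cluster_id,
                    "cp": c.cp,
                    "snv_key": "",
                }
            )
    pd.DataFrame(
        rows, columns=["sample_id", "source", "cluster_id", "cp", "snv_key"]
    ).to_csv(path, sep="\t", index=False)


def read_clusters(path) -> ClusterSolution:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    clusters: dict[int, Cluster] = {}
    sample_id = ""
    source = "pyclone-like"
    for _, row in df.iterrows():
        sample_id = str(row["sample_id"])
        source = str(row["source"])
        cid = int(row["cluster_id"])
        c = clusters.setdefault(cid, Cluster(cid, float(row["cp"]), set()))
        key = str(row["snv_key"])
        if key:
            c.snv_ids.add(_decode_snv_key(key))
    return ClusterSolution(
        sorted(clusters.values(), key=lambda c: c.cluster_id), sample_id, source
    )


def write_report(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
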
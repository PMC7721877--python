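"""Megabase-binned copy-number profiles and clonal-vs-subclonal timing.

Copy-number calls are projected onto fixed genomic bins (1.0 Mbp by
default), separately for the clonal and subclonal compartments of each
sample. A bin is *gain* when the majority of its covered bases carry
total copy number above two, *loss* below two, otherwise *neutral*;
bins no segment touches are neutral (normal copy number two assumed).

Signed bin sets (+bin for gain, -bin for loss) support direction-aware
Jaccard concordance between pipelines. The differential-timing test
asks, bin by bin, whether aberrations arise preferentially clonally or
subclonally across a cohort of polyclonal samples: a 2x3 contingency
table (clonal/subclonal x loss/neutral/gain) is tested with Pearson's
chi-squared and Benjamini-Hochberg FDR control across bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CNASegment, GenomicInterval, jaccard

__all__ = [
    "BinProfile",
    "bin_profile",
    "signed_set",
    "cna_jaccard",
    "recurrence_filter",
    "differential_timing",
    "annotate_genes",
    "make_bins",
]

logger = logging.getLogger(__name__)

STATES = ("loss", "neutral", "gain")
DEFAULT_BIN_SIZE = 1_000_000


def make_bins(
    chrom_sizes: Mapping[str, int], bin_size: int = DEFAULT_BIN_SIZE
) -> list[tuple[str, int]]:
    """Ordered (chrom, bin_index) identifiers covering the genome."""
    bins = []
    for chrom, size in chrom_sizes.items():
        n = -(-size // bin_size)  # ceil
        bins.extend((chrom, i) for i in range(n))
    return bins


@dataclass
class BinProfile:
    """Per-bin gain/loss/neutral state for both clonality compartments."""

    sample_id: str
    chrom_sizes: dict
    bin_size: int = DEFAULT_BIN_SIZE
    clonal: dict = field(default_factory=dict)  # (chrom, bin) -> state
    subclonal: dict = field(default_factory=dict)

    def bins(self) -> list[tuple[str, int]]:
        return make_bins(self.chrom_sizes, self.bin_size)

    def state(self, compartment: str, bin_id: tuple[str, int]) -> str:
        return getattr(self, compartment).get(bin_id, "neutral")


def _direction(seg: CNASegment) -> str:
    """Gain/loss/neutral from total copy number (CN-neutral LOH is neutral)."""
    if seg.total_cn > 2:
        return "gain"
    if seg.total_cn < 2:
        return "loss"
    return "neutral"


def _bin_states(
    segments: Sequence[CNASegment],
    chrom_sizes: Mapping[str, int],
    bin_size: int,
) -> dict[tuple[str, int], str]:
    """Majority-coverage state per bin; ties resolved toward the aberrant
    state, and toward gain on an exact gain/loss tie."""
    cover: dict[tuple[str, int], dict[str, int]] = {}
    for seg in segments:
        iv = seg.interval
        if iv.chrom not in chrom_sizes:
            continue
        direction = _direction(seg)
        if direction == "neutral":
            continue
        first = iv.start // bin_size
        last = (iv.end - 1) // bin_size
        for b in range(first, last + 1):
            lo = max(iv.start, b * bin_size)
            hi = min(iv.end, (b + 1) * bin_size)
            d = cover.setdefault((iv.chrom, b), {"gain": 0, "loss": 0})
            d[direction] += hi - lo

    out: dict[tuple[str, int], str] = {}
    for (chrom, b), d in cover.items():
        bin_len = min(chrom_sizes[chrom], (b + 1) * bin_size) - b * bin_size
        neutral_bp = bin_len - d["gain"] - d["loss"]
        best = max(("gain", "loss"), key=lambda s: d[s])
        aberrant_bp = d[best]
        # aberrant wins a tie with neutral; gain wins a gain/loss tie
        if aberrant_bp >= neutral_bp and aberrant_bp > 0:
            if d["gain"] == d["loss"]:
                best = "gain"
            out[(chrom, b)] = best
    return out


def bin_profile(
    clonal_segments: Sequence[CNASegment],
    subclonal_segments: Sequence[CNASegment],
    chrom_sizes: Mapping[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    sample_id: str = "",
) -> BinProfile:
    """Project clonal and subclonal CNA calls onto genomic bins."""
    return BinProfile(
        sample_id=sample_id,
        chrom_sizes=dict(chrom_sizes),
        bin_size=bin_size,
        clonal=_bin_states(clonal_segments, chrom_sizes, bin_size),
        subclonal=_bin_states(subclonal_segments, chrom_sizes, bin_size),
    )


def signed_set(profile: BinProfile, compartment: str) -> set:
    """Signed bin identifiers: +bin for gains, -bin for losses.

    Identifiers are (chrom, bin_index, sign) with sign +1/-1, so a bin
    appears at most once per compartment and direction must match for
    two pipelines to share an element.
    """
    states = getattr(profile, compartment)
    out = set()
    for bin_id, state in states.items():
        if state == "gain":
            out.add((*bin_id, +1))
        elif state == "loss":
            out.add((*bin_id, -1))
    return out


def cna_jaccard(a: set, b: set) -> Optional[float]:
    """Jaccard of signed bin sets (sign-sensitive); None when both empty."""
    return jaccard(a, b)


def recurrence_filter(
    segments: Sequence[CNASegment],
    reference_samples: Sequence[Sequence[CNASegment]],
    threshold: int = 10,
) -> list[CNASegment]:
    """Keep segment portions recurrently aberrant in a reference cohort.

    A genomic base survives when at least ``threshold`` reference
    samples carry an aberrant (non-neutral-direction) segment over it;
    each input segment is trimmed to the surviving sub-intervals.
    ``threshold`` 0 is the identity.
    """
    if threshold <= 0:
        return list(segments)
    # per-chromosome difference arrays over breakpoints
    events: dict[str, list[tuple[int, int]]] = {}
    for sample in reference_samples:
        for seg in sample:
            if _direction(seg) == "neutral":
                continue
            events.setdefault(seg.interval.chrom, []).append(
                (seg.interval.start, +1)
            )
            events[seg.interval.chrom].append((seg.interval.end, -1))

    recurrent: dict[str, list[tuple[int, int]]] = {}
    for chrom, evs in events.items():
        evs.sort()
        depth = 0
        open_start = None
        regions = []
        i = 0
        while i < len(evs):
            pos = evs[i][0]
            while i < len(evs) and evs[i][0] == pos:
                depth += evs[i][1]
                i += 1
            if depth >= threshold and open_start is None:
                open_start = pos
            elif depth < threshold and open_start is not None:
                regions.append((open_start, pos))
                open_start = None
        recurrent[chrom] = regions

    out: list[CNASegment] = []
    for seg in segments:
        iv = seg.interval
        for start, end in recurrent.get(iv.chrom, []):
            lo, hi = max(iv.start, start), min(iv.end, end)
            if hi > lo:
                out.append(
                    CNASegment(
                        GenomicInterval(iv.chrom, lo, hi),
                        seg.major_cn,
                        seg.minor_cn,
                        seg.clonal_fraction,
                        seg.clonality_label,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# differential timing
# ---------------------------------------------------------------------------

def _chi2_2x3(table: np.ndarray) -> tuple[float, float, int]:
    """Pearson chi-squared after dropping all-zero columns.

    Returns (statistic, p-value, df); df 0 marks an untestable bin
    (fewer than two non-zero columns).
    """
    keep = table.sum(axis=0) > 0
    t = table[:, keep]
    if t.shape[1] < 2 or (t.sum(axis=1) == 0).any():
        return np.nan, np.nan, 0
    stat, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), float(p), int(df)


def differential_timing(
    profiles: Sequence[BinProfile],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-bin clonal-vs-subclonal aberration-timing test over a cohort.

    ``profiles`` must come from polyclonal samples only (they are the
    ones with both compartments). For every genomic bin the number of
    samples whose clonal compartment is loss/neutral/gain is tabulated
    against the same for the subclonal compartment, tested with
    Pearson's chi-squared, and corrected across bins with
    Benjamini-Hochberg. Significant bins carry the over-represented
    compartment and direction (largest positive Pearson residual among
    the aberrant cells).
    """
    if not profiles:
        return pd.DataFrame()
    ref = profiles[0]
    bins = ref.bins()
    rows = []
    for bin_id in bins:
        counts = {
            (comp, s): 0 for comp in ("clonal", "subclonal") for s in STATES
        }
        for prof in profiles:
            for comp in ("clonal", "subclonal"):
                counts[(comp, prof.state(comp, bin_id))] += 1
        table = np.array(
            [
                [counts[("clonal", s)] for s in STATES],
                [counts[("subclonal", s)] for s in STATES],
            ],
            dtype=float,
        )
        stat, p, df = _chi2_2x3(table)
        rows.append(
            {
                "chrom": bin_id[0],
                "bin": bin_id[1],
                "clonal_loss": int(table[0, 0]),
                "clonal_neutral": int(table[0, 1]),
                "clonal_gain": int(table[0, 2]),
                "subclonal_loss": int(table[1, 0]),
                "subclonal_neutral": int(table[1, 1]),
                "subclonal_gain": int(table[1, 2]),
                "chi2": stat,
                "df": df,
                "p": p,
                "testable": df > 0,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    testable = out["testable"].to_numpy()
    if testable.any():
        _, q, _, _ = multipletests(
            out.loc[testable, "p"].to_numpy(), alpha=fdr, method="fdr_bh"
        )
        out.loc[testable, "q"] = q
    out["significant"] = (out["q"] <= fdr).fillna(False)

    biases = []
    for _, row in out.iterrows():
        if not row["significant"]:
            biases.append("")
            continue
        table = np.array(
            [
                [row["clonal_loss"], row["clonal_neutral"], row["clonal_gain"]],
                [row["subclonal_loss"], row["subclonal_neutral"], row["subclonal_gain"]],
            ],
            dtype=float,
        )
        expected = (
            table.sum(axis=1, keepdims=True)
            * table.sum(axis=0, keepdims=True)
            / table.sum()
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            resid = np.where(expected > 0, (table - expected) / np.sqrt(expected), -np.inf)
        # only aberrant columns (loss, gain) define the bias direction
        cells = [
            (resid[i, j], comp, STATES[j])
            for i, comp in enumerate(("clonal", "subclonal"))
            for j in (0, 2)
        ]
        best = max(cells, key=lambda c: c[0])
        biases.append(f"{best[1]}_{best[2]}")
    out["bias"] = biases
    return out


def annotate_genes(
    significant_bins: pd.DataFrame | Iterable[tuple[str, int]],
    gene_table: pd.DataFrame,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> pd.DataFrame:
    """Genes overlapping significant bins, deduplicated, with bias labels.

    ``gene_table`` needs columns chrom/start/end/name (0-based
    half-open). ``significant_bins`` is either the differential-timing
    table (its significant rows are used) or an iterable of
    (chrom, bin_index); a bias column is carried over when present.
    """
    if isinstance(significant_bins, pd.DataFrame):
        df = significant_bins
        if "significant" in df.columns:
            df = df[df["significant"]]
        bins = list(zip(df["chrom"], df["bin"]))
        bias = dict(zip(zip(df["chrom"], df["bin"]), df.get("bias", [""] * len(df))))
    else:
        bins = list(significant_bins)
        bias = {}

    hits: dict[str, set] = {}
    for _, g in gene_table.iterrows():
        chrom = str(g["chrom"])
        for b in bins:
            if b[0] != chrom:
                continue
            lo, hi = b[1] * bin_size, (b[1] + 1) * bin_size
            if g["start"] < hi and g["end"] > lo:
                hits.setdefault(g["name"], set()).add(bias.get(b, ""))
    rows = [
        {"gene": name, "bias": ";".join(sorted(x for x in labels if x))}
        for name, labels in sorted(hits.items())
    ]
    return pd.DataFrame(rows, columns=["gene", "bias"])
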
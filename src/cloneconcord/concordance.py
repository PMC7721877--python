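"""Cross-pipeline agreement statistics.

A *pipeline* is one combination of SNV caller, CNA caller and
reconstruction algorithm. Over a cohort these functions summarise how
well pipelines agree on (a) the number of subclones per sample, (b) the
identity of clonal and subclonal SNVs (per-pair Jaccard, averaged over
samples), and (c) the clonality of driver mutations (categorised by how
many panel pipelines identify each, with a consensus flag when all
agree).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .clonality import ClonalityAssignment
from .core import jaccard

__all__ = [
    "ConcordanceSummary",
    "subclone_agreement",
    "clonality_jaccard_matrix",
    "driver_consensus",
]

logger = logging.getLogger(__name__)


@dataclass
class ConcordanceSummary:
    """Subclone-number agreement across pipelines."""

    per_sample: pd.DataFrame  # sample, n_success, modal_group, n_distinct, unanimity
    pairwise_mean_abs_diff: float
    pairwise_sd_abs_diff: float
    n_pairs: int

    def median_modal_group(self) -> float:
        return float(self.per_sample["modal_group"].median())


def subclone_agreement(
    counts: Mapping[str, Mapping[str, Optional[int]]],
) -> ConcordanceSummary:
    """Agreement on predicted subclone numbers.

    ``counts`` maps pipeline id -> sample id -> predicted subclone
    count (None for a failed reconstruction). Per sample: the size of
    the largest group of successful pipelines sharing one count (modal
    group), the number of distinct predictions, and whether all agree.
    The pairwise statistic pools |difference| over every pair of
    successful pipelines in every sample. Samples with fewer than two
    successes are excluded (logged).
    """
    samples = sorted({s for per in counts.values() for s in per})
    rows = []
    diffs: list[int] = []
    for sample in samples:
        values = [
            per[sample]
            for per in counts.values()
            if per.get(sample) is not None
        ]
        if len(values) < 2:
            logger.info("sample %s excluded (<2 successful pipelines)", sample)
            continue
        uniq, freq = np.unique(values, return_counts=True)
        rows.append(
            {
                "sample": sample,
                "n_success": len(values),
                "modal_group": int(freq.max()),
                "n_distinct": len(uniq),
                "unanimous": len(uniq) == 1,
            }
        )
        for a, b in itertools.combinations(values, 2):
            diffs.append(abs(a - b))
    per_sample = pd.DataFrame(
        rows, columns=["sample", "n_success", "modal_group", "n_distinct", "unanimous"]
    )
    arr = np.array(diffs, dtype=float)
    return ConcordanceSummary(
        per_sample=per_sample,
        pairwise_mean_abs_diff=float(arr.mean()) if len(arr) else np.nan,
        pairwise_sd_abs_diff=float(arr.std(ddof=1)) if len(arr) > 1 else np.nan,
        n_pairs=len(arr),
    )


def clonality_jaccard_matrix(
    assignments: Mapping[str, Mapping[str, ClonalityAssignment]],
    compartment: str = "clonal",
    kind: Optional[str] = "snv",
) -> pd.DataFrame:
    """Mean +/- SD Jaccard of clonal (or subclonal) SNV sets per pipeline pair.

    For each pair of pipelines and each sample both completed, the
    Jaccard index of their ``compartment`` mutation sets is computed;
    samples where both sets are empty have an undefined index and are
    excluded from that pair's average (mean of per-sample values, not
    pooled sets).
    """
    if compartment not in ("clonal", "subclonal"):
        raise ValueError("compartment must be 'clonal' or 'subclonal'")
    pipelines = sorted(assignments)
    rows = []
    for pa, pb in itertools.combinations(pipelines, 2):
        values = []
        shared = set(assignments[pa]) & set(assignments[pb])
        for sample in sorted(shared):
            aa, ab = assignments[pa][sample], assignments[pb][sample]
            if aa.solution_class in ("failed", "poly_tumour"):
                continue
            if ab.solution_class in ("failed", "poly_tumour"):
                continue
            j = jaccard(
                aa.keys_with_label(compartment, kind),
                ab.keys_with_label(compartment, kind),
            )
            if j is not None:
                values.append(j)
        arr = np.array(values, dtype=float)
        rows.append(
            {
                "pipeline_a": pa,
                "pipeline_b": pb,
                "mean": float(arr.mean()) if len(arr) else np.nan,
                "sd": float(arr.std(ddof=1)) if len(arr) > 1 else np.nan,
                "n_samples": len(arr),
            }
        )
    return pd.DataFrame(
        rows, columns=["pipeline_a", "pipeline_b", "mean", "sd", "n_samples"]
    )


def driver_consensus(
    calls: Mapping[str, Mapping[str, Mapping[str, str]]],
    panel: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Categorise driver mutations by how many pipelines identify them.

    ``calls`` maps pipeline -> sample -> driver gene -> clonality label
    ("clonal"/"subclonal"; genes the pipeline did not identify are
    simply absent). For each driver and sample, the clonal-analysis
    category is the number of panel pipelines calling it clonal and the
    subclonal-analysis category the number calling it subclonal; a
    sample appears in both analyses when both counts are non-zero. The
    consensus flag requires identification with the same clonality by
    every panel pipeline.

    Returns (per driver-sample table, per-driver category-proportion
    table). Proportions divide each category's sample count by the
    number of samples categorised in that analysis for that driver.
    """
    panel = list(panel) if panel is not None else sorted(calls)
    samples = sorted({s for p in panel for s in calls.get(p, {})})
    drivers = sorted(
        {
            g
            for p in panel
            for per in calls.get(p, {}).values()
            for g in per
        }
    )
    rows = []
    for driver in drivers:
        for sample in samples:
            labels = [
                calls.get(p, {}).get(sample, {}).get(driver) for p in panel
            ]
            n_clonal = sum(1 for lab in labels if lab == "clonal")
            n_subclonal = sum(1 for lab in labels if lab == "subclonal")
            if n_clonal == 0 and n_subclonal == 0:
                continue
            consensus = ""
            if all(lab == "clonal" for lab in labels):
                consensus = "clonal"
            elif all(lab == "subclonal" for lab in labels):
                consensus = "subclonal"
            rows.append(
                {
                    "driver": driver,
                    "sample": sample,
                    "clonal_category": n_clonal,
                    "subclonal_category": n_subclonal,
                    "consensus": consensus,
                }
            )
    per_sample = pd.DataFrame(
        rows,
        columns=["driver", "sample", "clonal_category", "subclonal_category", "consensus"],
    )

    prop_rows = []
    for driver in drivers:
        sub = per_sample[per_sample["driver"] == driver]
        for analysis, col in (
            ("clonal", "clonal_category"),
            ("subclonal", "subclonal_category"),
        ):
            counted = sub[sub[col] > 0]
            total = len(counted)
            for category in range(1, len(panel) + 1):
                n = int((counted[col] == category).sum())
                prop_rows.append(
                    {
                        "driver": driver,
                        "analysis": analysis,
                        "category": category,
                        "n_samples": n,
                        "proportion": n / total if total else np.nan,
                    }
                )
    proportions = pd.DataFrame(
        prop_rows, columns=["driver", "analysis", "category", "n_samples", "proportion"]
    )
    return per_sample, proportions
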
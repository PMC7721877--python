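"""Single- versus multi-region reconstruction comparison.

A reconstruction from one tumour region sees only the populations
present there; reconstructing from all regions jointly can resolve
more. These functions compare the two on shared mutation identities:

* ``categorize_mutations`` — every mutation seen by either
  reconstruction falls in exactly one of five categories: *match* (same
  clonality in both), *clonal_in_multi* / *subclonal_in_multi* (seen by
  both but with conflicting clonality, named for the multi-region
  label), or *unique_in_single* / *unique_in_multi* (seen by only one,
  including input-driven exclusions).
* ``index_representation`` — how faithfully the index lesion's
  single-region clonal/subclonal labels reflect the multi-region truth.
* ``subclone_count_gap`` — multi-region minus single-region subclone
  counts, per region and per tumour.

SNVs are matched by (chrom, pos, ref, alt); CNAs by signed megabase
bin, since raw segment boundaries differ between reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .binning import BinProfile, signed_set
from .clonality import ClonalityAssignment

__all__ = [
    "CATEGORIES",
    "RegionComparison",
    "categorize_mutations",
    "cna_label_map",
    "index_representation",
    "subclone_count_gap",
]

CATEGORIES = (
    "match",
    "clonal_in_multi",
    "subclonal_in_multi",
    "unique_in_single",
    "unique_in_multi",
)

LabelMap = Mapping[object, str]


@dataclass
class RegionComparison:
    tumour_id: str
    region_id: str
    mutation_kind: str
    categories: dict  # mutation key -> category
    counts: dict = field(default_factory=dict)
    proportions: dict = field(default_factory=dict)

    def finalize(self) -> "RegionComparison":
        self.counts = {c: 0 for c in CATEGORIES}
        for cat in self.categories.values():
            self.counts[cat] += 1
        total = sum(self.counts.values())
        self.proportions = {
            c: (self.counts[c] / total if total else np.nan) for c in CATEGORIES
        }
        return self


def _labels(
    assignment: Union[ClonalityAssignment, LabelMap], kind: Optional[str]
) -> dict:
    if isinstance(assignment, ClonalityAssignment):
        out = {}
        for label in ("clonal", "subclonal"):
            for k in assignment.keys_with_label(label, kind):
                out[k] = label
        return out
    return dict(assignment)


def categorize_mutations(
    single: Union[ClonalityAssignment, LabelMap],
    multi: Union[ClonalityAssignment, LabelMap],
    mutation_kind: str = "snv",
    tumour_id: str = "",
    region_id: str = "",
) -> RegionComparison:
    """Five-way clonality comparison over the union of mutations.

    Inputs are either :class:`ClonalityAssignment` objects (SNV keys
    extracted for ``mutation_kind="snv"``) or plain mappings from
    mutation identity to "clonal"/"subclonal" — the latter is how CNA
    comparisons are fed, after conversion to signed megabase bins with
    :func:`cna_label_map`, which keeps the clonal/subclonal separation
    for matching.
    """
    if (
        isinstance(single, ClonalityAssignment)
        and isinstance(multi, ClonalityAssignment)
        and single.sample_id
        and multi.sample_id
    ):
        t_single = single.sample_id.split(":")[0]
        t_multi = multi.sample_id.split(":")[0]
        if t_single != t_multi:
            raise ValueError(
                f"assignments from different tumours: {t_single!r} vs {t_multi!r}"
            )
        tumour_id = tumour_id or t_multi
        region_id = region_id or (
            single.sample_id.split(":")[1] if ":" in single.sample_id else ""
        )
    ls = _labels(single, mutation_kind)
    lm = _labels(multi, mutation_kind)
    cats: dict = {}
    for key in set(ls) | set(lm):
        if key in ls and key in lm:
            if ls[key] == lm[key]:
                cats[key] = "match"
            elif lm[key] == "clonal":
                cats[key] = "clonal_in_multi"
            else:
                cats[key] = "subclonal_in_multi"
        elif key in ls:
            cats[key] = "unique_in_single"
        else:
            cats[key] = "unique_in_multi"
    return RegionComparison(
        tumour_id=tumour_id,
        region_id=region_id,
        mutation_kind=mutation_kind,
        categories=cats,
    ).finalize()


def cna_label_map(
    clonal_profile: BinProfile, compartments: Sequence[str] = ("clonal", "subclonal")
) -> dict:
    """Signed-bin -> clonality label mapping from one sample's bin profile.

    A signed bin present in both compartments keeps the clonal label
    (the earlier event dominates the region's interpretation).
    """
    out: dict = {}
    for comp in reversed(list(compartments)):  # clonal written last, wins
        for key in signed_set(clonal_profile, comp):
            out[key] = comp
    return out


@dataclass
class IndexRepresentation:
    n_shared_clonal: int
    n_shared_subclonal: int
    clonal_still_clonal: Optional[float]
    subclonal_truly_clonal: Optional[float]
    defined: bool


def index_representation(
    index_single: Union[ClonalityAssignment, LabelMap],
    multi: Union[ClonalityAssignment, LabelMap],
    mutation_kind: str = "snv",
) -> IndexRepresentation:
    """How the index lesion's single-region labels map onto multi-region.

    Among index-lesion single-region clonal mutations also present in
    the multi-region reconstruction: the fraction that is multi-region
    clonal. Likewise for single-region subclonal mutations. Undefined
    (flagged) when no mutations are shared.
    """
    ls = _labels(index_single, mutation_kind)
    lm = _labels(multi, mutation_kind)
    shared = set(ls) & set(lm)
    clonal = [k for k in shared if ls[k] == "clonal"]
    subclonal = [k for k in shared if ls[k] == "subclonal"]
    if not shared:
        return IndexRepresentation(0, 0, None, None, defined=False)
    frac_cc = (
        sum(1 for k in clonal if lm[k] == "clonal") / len(clonal) if clonal else None
    )
    frac_sc = (
        sum(1 for k in subclonal if lm[k] == "clonal") / len(subclonal)
        if subclonal
        else None
    )
    return IndexRepresentation(
        n_shared_clonal=len(clonal),
        n_shared_subclonal=len(subclonal),
        clonal_still_clonal=frac_cc,
        subclonal_truly_clonal=frac_sc,
        defined=True,
    )


def subclone_count_gap(
    single_counts: Mapping[str, int],
    multi_count: int,
    index_region: Optional[str] = None,
) -> pd.DataFrame:
    """Multi-region minus single-region predicted subclone counts.

    One row per region plus a per-tumour summary row comparing the
    multi-region count with the mean single-region count.
    """
    rows = [
        {
            "region": region,
            "single_count": count,
            "multi_count": multi_count,
            "gap": multi_count - count,
            "is_index": region == index_region,
        }
        for region, count in sorted(single_counts.items())
    ]
    mean_single = float(np.mean(list(single_counts.values()))) if single_counts else np.nan
    rows.append(
        {
            "region": "__tumour__",
            "single_count": mean_single,
            "multi_count": multi_count,
            "gap": multi_count - mean_single,
            "is_index": False,
        }
    )
    return pd.DataFrame(
        rows, columns=["region", "single_count", "multi_count", "gap", "is_index"]
    )
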
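"""Independent brute-force oracles used to validate the implementation.

These deliberately take a different route from the package — explicit
per-base arrays for the copy-number consensus, the textbook formula for
Pearson's chi-squared, the literal step-up recursion for
Benjamini-Hochberg — so they share no code path with it.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2 as chi2_dist

from cloneconcord.core import CNASegment


def _caller_arrays(segs: list[CNASegment], length: int) -> dict:
    """Per-base copy-number arrays for one caller (-1 = no entry)."""
    arrays = {
        name: np.full(length, -1, dtype=np.int64)
        for name in ("cl_maj", "cl_min", "su_maj", "su_min", "pl_maj", "pl_min")
    }
    for s in segs:
        sl = slice(s.interval.start, min(s.interval.end, length))
        prefix = {"clonal": "cl", "subclonal": "su"}.get(s.clonality_label, "pl")
        arrays[f"{prefix}_maj"][sl] = s.major_cn
        arrays[f"{prefix}_min"][sl] = s.minor_cn
    return arrays


def _caller_state(arr: dict):
    """Per-base (is_dual, is_aberrant, eff_maj, eff_min, dual CN arrays)."""
    has_cl = arr["cl_maj"] >= 0
    has_su = arr["su_maj"] >= 0
    has_pl = arr["pl_maj"] >= 0
    dual_raw = has_cl & has_su
    dual_neutral = (
        dual_raw
        & (arr["cl_maj"] == 1) & (arr["cl_min"] == 1)
        & (arr["su_maj"] == 1) & (arr["su_min"] == 1)
    )
    dual = dual_raw & ~dual_neutral
    # effective single-entry CN; uncovered bases are implicitly diploid
    eff_maj = np.where(
        has_cl, arr["cl_maj"], np.where(has_su, arr["su_maj"],
                                        np.where(has_pl, arr["pl_maj"], 1))
    )
    eff_min = np.where(
        has_cl, arr["cl_min"], np.where(has_su, arr["su_min"],
                                        np.where(has_pl, arr["pl_min"], 1))
    )
    aberrant = ~dual & ~((eff_maj == 1) & (eff_min == 1))
    return dual, aberrant, eff_maj, eff_min


def per_base_cna_oracle(
    a_segs: list[CNASegment], b_segs: list[CNASegment], length: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Explicit base-by-base labelling of the consensus classes.

    Single toy chromosome of ``length`` bases. Returns (class codes,
    union major, union minor) with class codes 0 none, 1 intersect,
    2 a_unique, 3 b_unique, 4 disagreement; union copy numbers are -1
    where the union carries nothing. Bases not annotated by a caller
    count as copy-number neutral (the sparse-table convention).
    """
    a = _caller_arrays(a_segs, length)
    b = _caller_arrays(b_segs, length)
    a_dual, a_ab, a_maj, a_min = _caller_state(a)
    b_dual, b_ab, b_maj, b_min = _caller_state(b)

    classes = np.zeros(length, dtype=np.int64)
    umaj = np.full(length, -1, dtype=np.int64)
    umin = np.full(length, -1, dtype=np.int64)

    both_dual = a_dual & b_dual
    dual_equal = (
        both_dual
        & (a["cl_maj"] == b["cl_maj"]) & (a["cl_min"] == b["cl_min"])
        & (a["su_maj"] == b["su_maj"]) & (a["su_min"] == b["su_min"])
    )
    classes[dual_equal] = 1
    umaj[dual_equal] = a["cl_maj"][dual_equal]
    umin[dual_equal] = a["cl_min"][dual_equal]
    classes[both_dual & ~dual_equal] = 4

    a_dual_only = a_dual & ~b_dual
    classes[a_dual_only] = 2
    fill = a_dual_only & b_ab
    umaj[fill], umin[fill] = b_maj[fill], b_min[fill]

    b_dual_only = b_dual & ~a_dual
    classes[b_dual_only] = 3
    fill = b_dual_only & a_ab
    umaj[fill], umin[fill] = a_maj[fill], a_min[fill]

    no_dual = ~a_dual & ~b_dual
    both_ab = no_dual & a_ab & b_ab
    ab_equal = both_ab & (a_maj == b_maj) & (a_min == b_min)
    classes[ab_equal] = 1
    umaj[ab_equal], umin[ab_equal] = a_maj[ab_equal], a_min[ab_equal]
    classes[both_ab & ~ab_equal] = 4

    a_only = no_dual & a_ab & ~b_ab
    classes[a_only] = 2
    umaj[a_only], umin[a_only] = a_maj[a_only], a_min[a_only]

    b_only = no_dual & b_ab & ~a_ab
    classes[b_only] = 3
    umaj[b_only], umin[b_only] = b_maj[b_only], b_min[b_only]

    return classes, umaj, umin


def partition_to_base_arrays(part, length: int):
    """Render a CnaPartition back onto per-base arrays for comparison."""
    classes = np.zeros(length, dtype=np.int64)
    umaj = np.full(length, -1, dtype=np.int64)
    umin = np.full(length, -1, dtype=np.int64)
    codes = {"intersect": 1, "a_unique": 2, "b_unique": 3, "disagreement": 4}
    for name, code in codes.items():
        for s in getattr(part, name):
            classes[s.interval.start : s.interval.end] = code
    for s in part.union:
        umaj[s.interval.start : s.interval.end] = s.major_cn
        umin[s.interval.start : s.interval.end] = s.minor_cn
    return classes, umaj, umin


def chi2_textbook(table: np.ndarray) -> tuple[float, float, int]:
    """Pearson chi-squared by the explicit formula, all-zero columns dropped."""
    t = np.asarray(table, dtype=float)
    t = t[:, t.sum(axis=0) > 0]
    if t.shape[1] < 2 or (t.sum(axis=1) == 0).any():
        return np.nan, np.nan, 0
    n = t.sum()
    stat = 0.0
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            e = t[i].sum() * t[:, j].sum() / n
            stat += (t[i, j] - e) ** 2 / e
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return stat, float(chi2_dist.sf(stat, df)), df


def bh_stepup(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the literal step-up rule."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * n / rank)
        adjusted[idx] = running_min
    return adjusted
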
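"""Binned clonal-vs-subclonal copy-number timing over a cohort.

Projects each polyclonal sample's clonal and subclonal CNA calls onto
1.0 Mbp bins, then asks per bin whether aberrations arise
preferentially early (clonal) or late (subclonal) with a 2x3 Pearson
chi-squared test and Benjamini-Hochberg FDR control.
"""

import numpy as np

from cloneconcord import bin_profile, differential_timing, signed_set, cna_jaccard
from cloneconcord.simulate import simulate_tumour, synthetic_genome

rng = np.random.default_rng(5)
genome = synthetic_genome(seed=rng)
sizes = {c: len(s) for c, s in genome.items()}

profiles = []
for i in range(50):
    truth = simulate_tumour(
        n_subclones=3, n_snvs=100, seed=int(rng.integers(2**31)),
        genome=genome, tumour_id=f"T{i}",
    )
    clonal = [s for nid, s in truth.segments if nid == 1]
    subclonal = [s for nid, s in truth.segments if nid != 1]
    profiles.append(bin_profile(clonal, subclonal, sizes, sample_id=f"T{i}"))

# signed bins (+gain / -loss) make direction part of the identity; a
# pair of samples with no clonal aberrant bins has an undefined index
# and is excluded from averages rather than coerced to 0 or 1
sets = [signed_set(p, "clonal") for p in profiles]
values = [
    j
    for a, b in zip(sets, sets[1:])
    if (j := cna_jaccard(a, b)) is not None
]
print(f"defined clonal signed-bin Jaccard values between neighbouring "
      f"samples: {len(values)}/{len(sets) - 1}, mean {np.mean(values):.3f}")

table = differential_timing(profiles, fdr=0.05)
n_sig = int(table["significant"].sum())
print(f"{int(table['testable'].sum())} testable bins, {n_sig} significant at FDR<=0.05")
for _, row in table[table["significant"]].iterrows():
    print(f"  bin {row['chrom']}:{row['bin']} biased {row['bias']} "
          f"(chi2={row['chi2']:.2f}, q={row['q']:.3g})")
# with random per-sample segment placement, few bins reach significance;
# a real cohort's recurrent events concentrate signal in specific bins
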
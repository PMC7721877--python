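# cloneconcord

Post-processing and concordance analysis of tumour subclonal-reconstruction
outputs.

## The problem

Subclonal reconstruction infers the population structure of a tumour — how
many genetically distinct cancer-cell populations (subclones) it contains,
at what cellular prevalence, and which somatic mutations define each — from
bulk sequencing. In practice a *pipeline* is a combination of an SNV caller,
a copy-number (CNA) caller and a reconstruction algorithm, and different
pipelines frequently disagree: permissive SNV callers add low-VAF false
positives that materialise as spurious subclones, CNA callers segment the
genome differently, and algorithms report population sizes on different
scales. `cloneconcord` is a toolkit for anyone comparing such pipelines: it
normalises their outputs into comparable canonical forms and quantifies how,
and why, their conclusions differ.

## What it computes

* **Post-processing** — clone trees are canonicalized (left-heavy child
  ordering, breadth-first renumbering with the normal root as node 0) and
  both trees and flat mutation-cluster solutions are pruned and merged:
  every retained population needs ≥ 5 SNVs or ≥ 5 CNAs of support and a
  cellular prevalence of ≥ 10% (≥ 2% for subclonal clusters); populations
  within 2% prevalence of each other are merged with SNV-count-weighted mean
  prevalence. Solutions with < 5 assigned SNVs, or whose clone tree shows a
  normal root with more than one direct child ("poly-tumour"), are flagged
  as reconstruction failures.
* **Clonality and CCF** — algorithm-specific prevalences are converted to a
  common cellular-prevalence scale (×purity for tumour-cell fractions,
  ×2 for cluster VAFs); a solution is monoclonal (one subclone) or
  polyclonal; the highest-prevalence population is clonal and its mutations
  get cancer cell fraction CCF = φ/cellularity = 1, with subclonal CCFs
  scaled accordingly.
* **Caller consensus** — SNV intersect/unique partitions by exact
  (chrom, pos, ref, alt) identity; CNA consensus evaluated per base pair
  (identical aberration → intersect; aberrant vs neutral → caller-unique;
  conflicting aberrations → disagreement, excluded from the union), with a
  10 kbp minimum segment length and genome-normalised 96-class
  trinucleotide mutation profiles.
* **CNA timing** — clonal and subclonal copy-number calls projected onto
  1.0 Mbp bins; per bin a 2×3 Pearson χ² test (clonal/subclonal ×
  loss/neutral/gain) with Benjamini–Hochberg FDR ≤ 0.05 flags regions
  preferentially altered early (clonally) or late (subclonally).
* **Concordance** — per-sample subclone-number agreement across pipelines,
  per-pair mean ± SD Jaccard of clonal and subclonal SNV sets, and driver-
  mutation consensus categories (how many panel pipelines identify each
  driver with each clonality).
* **Single vs multi-region** — five-way mutation comparison (match,
  clonal-in-multi, subclonal-in-multi, unique-in-single, unique-in-multi)
  and subclone-count gaps between reconstructions of one region and of all
  regions jointly.
* **Synthetic data** — ground-truth tumours with known clone trees,
  per-region prevalences and region-private subclones; binomially sampled
  read counts at configurable depth and purity (expected VAF
  m·φ·ρ / (C·ρ + 2(1−ρ))); contrasting conservative/permissive caller error
  profiles; emulated tree- and cluster-shaped reconstructions. Every stage
  is testable end to end without access to patient genomes.

## Worked example

```python
from cloneconcord import (
    simulate_tumour, emulate_reconstruction,
    postprocess_clusters, assign_clonality,
)

truth = simulate_tumour(n_subclones=3, n_snvs=800, purity=0.7, depth=60, seed=11)
solution = emulate_reconstruction(truth, "R0", shape="clusters")
post, status = postprocess_clusters(solution)
assignment = assign_clonality(post, status)
print(assignment.solution_class, assignment.pipeline_cellularity)
print(len(assignment.clonal_keys()), len(assignment.subclonal_keys()))
```

prints

```
polyclonal 0.7
371 429
```

The tumour is recognised as polyclonal; the clonal cluster's cellular
prevalence (tumour-cell fraction 1.0 × purity 0.7) is recovered as the
pipeline's cellularity estimate; 371 mutations define the clonal population
(CCF 1.0) and 429 are subclonal. The `examples/` directory has one short
script per capability (simulation + classification, caller consensus, CNA
timing, multi-region comparison); each prints the numbers it computes and a
line on what they mean. A thin `cloneconcord` command-line interface wraps
the same operations (`simulate`, `postprocess-clusters`, `classify`,
`consensus-snv`, `consensus-cna`, `trinuc`, `bin-profiles`, `diff-timing`,
`concordance`, `multiregion-compare`).

## Layout

```
src/cloneconcord/   core, fileio, simulate, postprocess, clonality,
                    consensus, binning, concordance, multiregion, cli
tests/              pytest suite incl. brute-force oracles
examples/           narrative scripts, one per capability
docs/methods.md     models, heuristics, parameters, limitations
```
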
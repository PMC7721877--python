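# Methods

This note documents the models and procedures `cloneconcord` implements,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Data model and conventions

Genomic intervals are 0-based half-open; SNV positions stay 1-based (VCF
convention) because the `(chrom, pos, ref, alt)` tuple is the identity key
used to match variants across callers and reconstructions. Chromosome
names are normalised on ingest (leading `chr` stripped) and restricted to
1–22, X, Y; rows on other contigs are dropped with a logged count.

A clone tree's root (node 0) is the normal cell population: cellular
prevalence 1 by convention and no mutation assignments. Subclone
prevalences are fractions of *all* cells in the sample once converted;
conversion rules are ×purity for algorithms reporting tumour-cell
fractions (PyClone-like) and ×2 for algorithms characterised by cluster
VAFs (SciClone-like; a heterozygous mutation in a diploid region occupies
one of two alleles). The ×2 value is capped at 1 with a logged warning —
the uncapped value is available via `cap=False` — since VAFs above 0.5
reflect copy-number effects the rule cannot see.

The Jaccard index of two empty sets is *undefined*, returned as `None`
and excluded from averages, never coerced to 0 or 1.

## Post-processing heuristics

Thresholds (all overridable via `PostprocessConfig`):

| parameter | default | meaning |
|---|---|---|
| `min_snvs_per_node` / `min_cnas_per_node` | 5 / 5 | minimum mutation support (a node needs ≥ 5 SNVs **or** ≥ 5 CNAs) |
| `min_clonal_cp` | 0.10 | prevalence floor for clonal populations (all tree nodes by default) |
| `min_subclonal_cp` | 0.02 | prevalence floor for subclonal clusters |
| `merge_cp_delta` | 0.02 | populations within this prevalence are merged |
| `snv_driven_max_cnas` | 5 | a node with ≤ this many CNAs counts as SNV-driven for sibling merging |
| `min_total_snvs` | 5 | below this total, the solution is a reconstruction failure |

**Canonical tree form.** "Left-heavy" ordering is made concrete as:
children sorted by decreasing subtree node count, ties by decreasing
prevalence, then by decreasing SNV count; node ids are reassigned
breadth-first in that order so the root is 0 and ids strictly increase
with depth. This makes canonical forms unique, testable and idempotent.

**Rule order.** The rules are iterated to a fixed point, deepest nodes
first: (1) merge a node into its non-root parent when their prevalences
differ by ≤ 2%; (2) merge siblings within 2% when both are SNV-driven;
(3) merge a node failing the support or prevalence floor into its
nearest-prevalence neighbour, preferring the parent on ties. Each firing
removes one node, so termination is guaranteed. Merging moves the merged
node's mutations to the survivor (never drops them), assigns the
SNV-count-weighted mean prevalence (counts taken before the merge;
`weight_by_all_mutations=True` adds CNA counts to the weights), and
reattaches orphaned children to the merged node's parent so prevalences
stay nested. Because a weighted-mean merge can place the survivor up to
2% below a former sibling, the child-below-parent invariant is enforced
strictly for generated truths but only structurally validated after
post-processing.

Flat cluster solutions follow the analogous loop: failure designation up
front (< 5 total SNVs, or every cluster below 10% prevalence), pruning of
weak clusters into their nearest-prevalence neighbour (ties resolved
toward the higher-prevalence neighbour, biasing toward clonal
absorption), pairwise merging within 2%, renumbering 1..k by decreasing
prevalence, and a final validity re-check (merging can drag the top
cluster below 10%, in which case the solution is declared failed rather
than reported in violation of its own floors).

Two open readings are both reachable via configuration: tree nodes use
the flat 10% floor by default (`tree_subclonal_threshold=True` switches
to the 10%/2% clonal/subclonal split the cluster rules use), and the
"SNV-driven" boundary is `cna_count ≤ 5` even though a node with exactly
5 CNAs also meets the retention rule — both follow the most literal
reading of the respective heuristics.

**Poly-tumour.** A tree whose normal root has ≥ 2 direct children is
classified poly-tumour — suggestive of independent primary tumours — and
treated as a reconstruction failure downstream. The check runs after
merging, so near-duplicate root children that merge away do not trigger
it.

## Clonality and CCF

A post-processed solution with one subclone is monoclonal, with more
polyclonal. The highest-prevalence population is clonal (ties broken
toward the larger SNV count, deterministically); its mutations are
clonal, all others subclonal. CCF = population prevalence / cellularity.
For cluster solutions the clonal cluster's prevalence *is* the pipeline
cellularity, so clonal CCF is exactly 1. Tree solutions require an
external (CNA-tool) cellularity — a required argument, since there is no
principled default — and CCF > 1 is reported with a warning rather than
clipped: disagreement between the tree's prevalences and an independent
cellularity estimate is signal, not error.

## Caller consensus

SNVs partition by exact identity key; duplicate keys within one caller
are deduplicated with a warning. Allow-/deny-list filtering is a generic
`(chrom, pos)` include/exclude hook; no list contents ship with the
package.

CNA consensus is evaluated per base pair: breakpoints from both callers
cut the genome into elementary intervals, each interval gets a per-caller
state (neutral, aberrant with a (major, minor) state, or *dual* when a
caller emits a clonal+subclonal entry pair for the region), and bases are
classified intersect / caller-unique / disagreement. Dual regions are
labelled the dual-emitting caller's unique, but the *other* caller's
aberration (if any) fills the union — one cannot mix a clonal state from
one caller with the other's aberration in the same region. Disagreement
bases are excluded from the union. Classes are re-assembled into maximal
segments. Decisions made here: bases not annotated by a caller default to
copy-number neutral (`uncovered_policy="neutral"`, matching sparse tables
that only list aberrations; `"exclude"` drops them instead); neutrality
is (1,1) everywhere by default, with sex-aware neutrality ((1,0) on male
X/Y) selectable; the minimum segment length filter (default 10 kbp,
strict: segments of exactly 10 kbp survive) can be applied to inputs and
is re-applied to re-assembled outputs. Boundary mismatches are resolved
exactly by the per-base semantics — there is no fuzzy boundary tolerance.

Trinucleotide profiles use the conventional 96 classes (six
pyrimidine-reference substitutions × 16 flank pairs); purine-reference
substitutions are reverse-complemented into their pyrimidine class.
Genome context frequencies are counted double-stranded (every interior
position contributes its pyrimidine-collapsed trinucleotide), and
`normalized = class count / genome context count`. Records whose
reference base mismatches the genome are skipped and listed.

## Binned CNA timing

Bins are 1.0 Mbp by default. A bin's direction per compartment comes
from total copy number (> 2 gain, < 2 loss; copy-neutral LOH such as 2/0
is direction-neutral since only gain vs loss is analysed), decided by
majority base-pair coverage among loss/neutral/gain; exact ties resolve
toward the aberrant state, and a gain/loss tie toward gain —
deterministic and slightly sensitivity-favouring. Bins no segment
touches are neutral (normal copy number two assumed).

The differential-timing test tabulates, per bin, the number of
polyclonal samples whose clonal compartment is loss/neutral/gain against
the same for the subclonal compartment (2×3), computes Pearson's χ²
after dropping all-zero columns (a bin with fewer than two non-zero
columns is untestable and recorded as such rather than forced through a
correction), and controls FDR across bins at 0.05 with
Benjamini–Hochberg. Significant bins carry a bias direction: the
compartment × direction cell with the largest positive Pearson residual
among the aberrant cells. The single 2×3 design is primary; gains and
losses can also be tested separately by filtering the profile states.
Recurrence filtering retains the parts of segments overlapping genomic
locations aberrant in at least 10 reference samples (inclusive
threshold; 0 is the identity).

## Concordance and multi-region comparison

Subclone-number agreement reports, per sample, the size of the largest
pipeline group sharing one predicted count (the modal group) *and* a
full-unanimity flag, since "pipelines agreed" is ambiguous between the
two; the pairwise statistic pools |count difference| over all successful
pipeline pairs across samples (per-sample averaging is a trivial
variation on the returned table). Jaccard concordance averages
per-sample values per pipeline pair — not pooled mutation sets — and
drops undefined (both-empty) samples from the pair's average. Driver
consensus categorises each driver per sample by the number of panel
pipelines identifying it with each clonality; a sample identified as
clonal by some pipelines and subclonal by others counts in both
analyses.

Multi-region comparison matches SNVs by identity key and CNAs by signed
megabase bin (raw segment boundaries are not comparable across
reconstructions); a mutation excluded by one reconstruction's input
restrictions is "unique" to the other. A node counts as present in a
region when its prevalence there exceeds zero (configurable in the
generator); the index lesion is the first simulated region.

## Synthetic-data generator

The generator produces what the analysis needs and nothing more:

* **Architecture.** The clonal population has prevalence 1 among tumour
  cells in every region; additional subclones get prevalences pairwise
  ≥ `cp_spacing` (default 0.15) apart, at least `min_subclone_phi`
  (default 0.2, so defaults survive the 10% post-processing floor at
  purity 0.7), re-drawn per region with a fixed rank order so a child
  never exceeds its parent anywhere. Region-private subclones arise with
  `region_absent_prob`, absence propagating to descendants; every
  subclone stays present in at least one region.
* **Reads.** Per-site depth is Poisson around the region mean (default
  60×, a typical whole-genome depth), alt counts binomial at the
  closed-form expected VAF m·φ·ρ / (C·ρ + 2(1−ρ)) with multiplicity 1
  and total copy number taken from clonal segments at the locus. A
  detected variant reports at least one supporting read (callers cannot
  report zero-evidence calls); the resulting upward VAF bias is
  negligible above ~5% expected VAF at default depth. No
  overdispersion: binomial sampling is the simplest model consistent
  with whole-genome VAF behaviour.
* **Caller error profiles.** The default pair mirrors the qualitative
  contrast between a conservative caller (sensitivity 0.98 above 10%
  VAF, ~0.02 false positives per Mbp, 2 kbp segment jitter) and a
  permissive one (sensitive from 3% VAF, 5 false positives per Mbp with
  Beta(2,20) VAFs — median ≈ 8% — and a C>A-weighted trinucleotide bias
  heaviest at C[C>A]G and T[C>A]G, 5 kbp jitter, Battenberg-style
  clonal+subclonal paired entries for subclonal CNAs). These are
  directional illustrations of observed caller behaviour, not
  calibrations to any cohort's counts.
* **Reconstruction emulation.** Noise-free emulation returns the true
  architecture restricted to the requested region(s) on the
  cellular-prevalence scale; populations with exactly coincident
  prevalences in every requested region are indistinguishable and merge.
  Prevalence noise and cluster split/merge events are available as
  perturbations. `reconstruct_from_snv_calls` builds a cluster solution
  from one caller's output — detected true SNVs grouped by their true
  population, false positives clustered on VAF-doubled prevalence
  estimates — which is how permissive callers' low-VAF false positives
  materialise as extra low-prevalence subclones after post-processing.
* **Genome.** A random i.i.d. genome (default 10 Mbp over two
  chromosomes, GC 0.41) stands in for a reference so trinucleotide
  expectations are computable; it has no repeat structure, mutation
  hotspots or mappability artefacts.

What passing tests therefore show: the *operations* are correct (oracle
equivalence, invariants, ground-truth recovery) and the caller-bias
effect is directionally reproduced. They do not certify behaviour on
real tumours — real data add overdispersed counts, segmentation error
correlated with replication timing, multi-mapping artefacts and
mutation-rate heterogeneity the generator does not model.

## Numerical choices and problem sizes

All randomness flows through `numpy.random.default_rng` seeds; every
generator is byte-deterministic for a fixed seed. Prevalence-equality
grouping in emulation uses 12-decimal rounding; tie-breaks elsewhere are
documented at the point of use (higher prevalence, then larger SNV
count, then lower node id). The test suite's scaled ensembles — 1,000
random toy genomes for the per-base consensus oracle, 500 random tables
for the χ²/FDR oracle, 1,000 random solutions of each shape for
post-processing invariants, 100 noise-free tumours for parameter
recovery, 10×50-tumour cohorts for the caller-bias sign test — were
chosen to exercise the properties at desk scale with comfortable
statistical margins; `scripts/acceptance.py` uses similar sizes and
completes in well under a minute per section.

## Known limitations

* Multi-region cluster emulation summarises a population by its maximum
  per-region prevalence, so two populations distinct only through their
  regional patterns can fall within the 2% merge window after
  post-processing; the multi-region comparison therefore reports
  pre-post-processing counts where structural guarantees matter.
* The ×2 VAF-to-prevalence rule is exact only for heterozygous mutations
  in diploid regions; no multiplicity estimation is attempted.
* Subclonal copy-number changes do not feed back into simulated VAFs
  (only clonal segments set a locus's total copy number).
* Sibling prevalences may sum to more than the parent's (only the
  child ≤ parent constraint is enforced); full pigeonhole consistency is
  not modelled.
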
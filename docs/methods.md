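# Methods

## Overview

The pipeline measures the prevalence of loss-of-function (LoF) alleles per
individual and per species from transcript-space variant calls, and tests
whether that prevalence covaries with life-history traits.  It operates
entirely in transcript coordinates: the reference unit is a contig with one
chosen open reading frame, variants are VCF records against that contig,
and genes are identified by shared (ortholog-level) IDs across species so
that the core and hard-core sets are defined panel-wide.

## ORF annotation

ORFs are complete start-to-stop frames: an ATG followed by in-frame codons
up to the first in-frame stop, in any of the six frames, with a protein of
at least 100 amino acids (Met included, stop excluded).  When several ORFs
share a contig the longest protein wins; ties prefer the forward strand and
then the smallest start coordinate (an arbitrary but fixed rule — ties are
vanishingly rare in practice and determinism matters more than the choice).
Partial (5′/3′-truncated) ORFs are not considered: the complete-ORF rule is
reproducible and dependency-free, at the cost of missing genes whose start
or stop falls off the contig.  Codons containing N never act as start or
stop.  Internal coordinates are 0-based half-open on the stored sequence;
serialized coordinates (FASTA headers, ORF tables, VCF) are 1-based.

## Consequence calling

A variant is classified against the chosen ORF on its strand:

- SNV in a sense codon that creates a stop before the natural terminator →
  stopgain; the natural stop becoming a sense codon → stoploss; a
  stop-to-stop change at the terminator is synonymous-at-stop, not a
  stopgain.  Otherwise synonymous or missense by amino-acid comparison;
  codons containing N classify as missense (unknown but never LoF).
- Simple indels: frameshift when the net coding length change is not a
  multiple of three, in-frame otherwise.  Alleles are reduced by stripping
  shared flanks and left-aligning against the reference; an edit counts as
  coding when at least one changed base lies inside the CDS, except that a
  pure insertion flush with a CDS boundary is noncoding (it moves the ORF
  without disrupting its frame).
- LoF = {stopgain, stoploss, frameshift}.

A REF allele disagreeing with the reference sequence aborts the run naming
the contig and position — silent repair would hide upstream bookkeeping
errors.

An independent translation-comparison oracle (apply the edit, re-translate
from the tracked start codon, compare proteins; for indels, check whether
the original terminator is still reached in frame) backs the classifier in
tests: they agree on all 540 single-base edits of a 60-codon ORF and on
10,000 random SNVs/indels.  One documented divergence exists: when
left-alignment slides an indel through a homopolymer onto the stop codon or
out of the CDS, the edit is equivalent to a boundary edit and the two
routes answer different questions; such placements are excluded from the
comparison and are negligibly rare under the generator.

Per gene and individual, LoF variants collapse to one allele state: any
homozygous LoF variant → hom_lof, else any heterozygous one → het_lof.
Unphased multiple het variants conservatively count as a single het allele.
Per-type statistics classify a gene by the set of LoF types it carries, so
a gene with both a nonsense and a frameshift variant appears in both
type-specific statistics (the per-gene unit is primary throughout).

## Filters and gene sets

Site validity: depth > 5× and variant and mapping quality > 20, all strict
("more than", "over").  Individuals are dropped below 10× mean coverage,
80 % alignment, 5000 at-least-partially covered ORFs or 100 covered core
genes; species below 70 % alignment, 5000 predicted ORFs or 100 core genes,
and haplodiploid species (haploid males expose recessives to selection
differently) — for these floors the boundary value is kept ("below X
excluded").  Two coverage notions coexist deliberately: partial coverage
feeds the ≥5000 filter, while the N of the proportion statistic counts
*fully sequenced* ORFs, read strictly as every CDS position clearing the
depth floor.  The `strict20x` mode raises the site depth floor to ≥20×
(i.e. > 19 with integer depths); the `last100nt` mode restricts LoF
variants to the final 100 nt of each CDS, a proxy for the last exon where
nonsense-mediated decay does not act (N is unchanged, so the windowed p is
comparable across genes).

Core = predicted ORFs ∩ essential-gene list (provided ID list; orthology
mapping is upstream).  Hard-core = core minus every gene with a homozygous
LoF allele in ≥1 individual of ≥1 species — a global exclusion: one
species' homozygote removes the gene everywhere.

## The statistic and summaries

p = (N_LoFHet + 2·N_LoFHom)/(2N) per individual, per gene set (all / core /
hardcore), variant type (all / nonsense / frameshift / stoploss) and region
(full CDS / last 100 nt).  N = 0 or an empty restricted gene set yields a
missing value, never zero, and missingness propagates through species means
into the correlations (pairwise deletion, no imputation).  Species values
are unweighted means over individuals (a coverage-weighted alternative is a
flag away, but individuals are deliberately equal-weighted by default);
summaries report min/max/mean across species in percent at two decimals.

## Correlations

Spearman ρ uses midranks with the two-sided t-approximation
t = ρ√((n−2)/(1−ρ²)) on n−2 df, the common default of statistical
environments for this test; |ρ| = 1 reports p = 0, and an exhaustive
permutation p-value is available for n ≤ 10.  Fewer than 3 complete pairs
or a constant vector yields a missing result with a reason.  The BH family
is the entire emitted grid (all measure-trait, trait-trait and
measure-measure pairs) — the choice of family changes adjusted p-values,
so both raw and adjusted values are always written.  Note the step-up BH
adjustment is not idempotent; the invariants that do hold (adjusted ≥ raw,
≤ 1, monotone in the sorted order) are property-tested.  Fecundity is
log-scaled for plotting only; ranks are unaffected.

## Synthetic panels

The generator emulates the statistical structure of a cross-species
population-transcriptomic survey under deterministic mutation–selection
balance; drift is not simulated because s ≈ 1 % for heterozygous LoF
alleles of essential genes dwarfs 1/N_e.

Defaults are the study conditions and are fixed once:

| parameter | default | meaning / rationale |
|---|---|---|
| n_species | 35 | surviving panel size after exclusions |
| individuals_per_species | 2 | observed median |
| genes_per_species | 5000 | the species-level ORF floor |
| gene_length_nt | 1101 | ~1.1-kb typical CDS; also the length implied by inverting a 0.22 % prevalence into ~2×10⁻⁸ per nt |
| mu_lof_per_gene (u) | 2.21×10⁻⁴ | with s = 0.01 gives q = 2.21 %, the observed all-genes grand mean |
| sel_coeff (s) | 0.01 | heterozygous selection against LoF, from recessive-lethal data |
| core_sel_multiplier | 2.21/1.08 | stronger selection on essential genes, reproducing the 1.08 % core mean |
| species_mu_sigma | 0.67 | mean-preserving lognormal mutation-rate scatter across species, matching the observed cross-species spread (~0.3–5 %) |
| fecundity_range | (10, 10⁶) | log-uniform lifetime fecundities spanning five orders of magnitude |
| coupling_beta | 0 | s_i = s·(F_i/F_ref)^β with F_ref the geometric mean of the range; 0 = the null |
| variant_type_weights | 0.198/0.748/0.054 | stopgain : frameshift : stoploss composition of observed LoF alleles |
| coverage_dropout | 0.2 | fraction of ORFs not fully sequenced per individual |
| depth_mean | 30 | Poisson site depth; qualities ~N(60, 5), so site filters bite only in the strict20x mode |

Other life-history traits are noisy monotone transforms of fecundity
(long-lived, large, heavy, big-propagule species have few offspring; π_S
rises with fecundity as an N_e proxy), emulating the trait
inter-correlations of real panels; genome size is independent and, like
π_S, missing for a random subset.  References are random transcripts with
exactly one designed ORF (ATG, random sense codons, one stop; an in-frame
stop terminates the 5′ UTR so upstream ATGs cannot extend the designed
frame); roughly half the genes are stored on the minus strand to exercise
strand handling end-to-end.  Genotypes are Hardy–Weinberg draws at q_g;
each carrier gene receives one concrete variant placed uniformly in the
CDS body (stoploss variants in the stop codon by construction).  All
randomness descends from a single root seed through fixed-purpose seed
sequences, so identical configurations reproduce byte-identical files.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: transcription/splicing noise and
allele-specific expression in transcriptome-based calls, NMD degrading
nonsense transcripts before they are sequenced, isoform selection, real
per-gene heterogeneity of s.  The last point matters for the hard-core set:
with the default constant s per gene class, almost no gene is excluded by
an observed homozygote, so synthetic hard-core means sit near the core
mean rather than far below it as in real data, where the homozygote filter
preferentially removes the high-q tail.  A per-gene lognormal jitter on s
(`sel_jitter_sigma`) exists but defaults to 0, since no particular
distribution can be asserted.

Expectations used in validation: under Hardy–Weinberg the allele-level
statistic has expectation mean(q) over the gene set.  For the hard-core
set this is corrected to mean(q/(1+q)): membership is conditioned on never
observing a homozygote, and a genotype conditioned on "not hom" carries
2q/(1+q) expected LoF alleles.  Without this correction the recovery
z-score carries a systematic ~q relative bias that aggregation over 35
species amplifies well past the Monte-Carlo error.

## Calibration studies

Type-I error and power of the prevalence-vs-fecundity Spearman test are
measured over replicate panels sampled at the genotype-count level
(binomial draws of het/hom gene counts per individual — the same
distribution the file-emitting path realizes variant by variant, which is
what the parameter-recovery test verifies).  1000 null replicates (β = 0)
give a rejection rate statistically compatible with the nominal 5 %;
β = 1 over the default fecundity range is detected in essentially every
replicate at n = 35 species (the repo's regression bound is 80 %).

## Problem sizes

The validation suite and the acceptance script run the full pipeline at
the 35 × 5000 × 2 study scale (~90 s), the calibration at 1000 replicates,
and the oracle comparison on ~10,500 edits; the `analysis/` demonstration
drivers use a 12 × 1000 × 2 panel with proportionally scaled QC floors so
the whole narrative reruns in seconds.

## Known limitations

- Transcript space only: no splice models, UTR classes, or genomic
  coordinates; one isoform per gene is assumed given.
- Complete-ORF annotation under-calls genes truncated by assembly.
- Multiple het LoF variants in a gene cannot be phased and are counted as
  one allele — a conservative undercount.
- The per-variant-type counting unit (per-gene alleles, uniformly for all
  types) is one of two defensible readings of the published per-type rows;
  both per-gene and per-variant tallies can be derived from the annotated
  variant table.
- Equilibrium q = u/s ignores drift, back-mutation and dominance beyond
  heterozygous s; it is the intended model, not an approximation the code
  tries to relax.
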
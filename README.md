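# lofprev — loss-of-function allele prevalence across species

`lofprev` asks a comparative population-genetics question: is purifying
selection stronger in species that produce more offspring?  It measures the
strength of negative selection in a species by the prevalence of
loss-of-function (LoF) alleles — stopgain and stoploss substitutions and
frameshift indels — in essential genes, and relates that prevalence to
life-history traits (lifetime fecundity, longevity, adult size, body mass,
propagule size), genome size and synonymous diversity (π_S) across a
multi-species panel of population-transcriptomic samples.  It is written
for evolutionary geneticists who want a tested, reproducible version of
this analysis chain, from transcript-space variant annotation to the
trait-correlation matrix, with a synthetic data generator standing in for
the raw sequencing data.

## The statistic and the model

For one diploid individual, with N the number of ORFs fully sequenced in
that individual, N_LoFHet the number of genes carrying a heterozygous LoF
allele and N_LoFHom the number carrying a homozygous one,

    p = (N_LoFHet + 2 · N_LoFHom) / (2 · N)

is the proportion of gene copies that are LoF.  It is computed over all
predicted ORFs, over *core* genes (those present in an essential-gene
catalogue) and over *hard-core* genes (core genes with no homozygous LoF
allele in any individual of any species — if a gene tolerates homozygous
knockout anywhere, it is not treated as essential anywhere).  Species
values are unweighted means over individuals; species means are then
correlated with each life-history trait by midrank Spearman ρ with
Benjamini–Hochberg correction over the emitted grid of tests.

Because selection against heterozygous LoF carriers of essential genes is
strong (s ≈ 1 %, far above 1/N_e in natural populations), allele
frequencies sit near the deterministic mutation–selection equilibrium

    q = u / s

which is independent of drift.  The synthetic generator builds multi-species
panels on exactly this model: per-gene q = u/s_i, Hardy–Weinberg genotypes,
concrete stopgain/frameshift/stoploss variants placed in designed ORFs,
partial ORF coverage, and a trait table whose fecundities span five orders
of magnitude.  Setting the coupling exponent β in s_i = s·(F_i/F_ref)^β to
zero gives the null in which prevalence is unrelated to fecundity; β > 0
gives the alternative the correlation analysis is meant to detect.

## Worked example

The numbered drivers under `analysis/` run a reduced demonstration survey
(12 species × 1000 genes × 2 individuals; the library defaults are the full
35 × 5000 × 2 study conditions) and write their tables under `results/run/`:

```sh
python analysis/01_simulate_panel.py
python analysis/02_annotate.py
python analysis/03_qc_genesets.py
python analysis/04_lof_statistics.py
python analysis/05_trait_correlations.py
python analysis/06_null_calibration.py
python analysis/07_equilibrium_arithmetic.py
```

Actual output of a run (seed 42):

```
expected LoF allele proportion, all genes: 1.84%
12000 ORFs chosen (median protein 366 aa)
class
frameshift    622
stopgain      185
stoploss       64
genes: 1000, core: 200, hardcore: 200
Prevalence-vs-fecundity (headline scatter):
gene_set  n     rho  p_raw
     all 12 -0.4196 0.1745
hardcore 12 -0.2587 0.4168
type-I error at alpha=0.05 (beta=0, 400 replicates): 4.2%
power under beta=1 coupling (400 replicates): 100.0%
q = 0.0022, s = 0.01:  u = 2.2e-05 per gene = 2e-08 per nucleotide (CDS 1101 nt)
```

Reading this: the panel was generated with no prevalence–fecundity coupling,
and indeed the Spearman tests do not reject (p = 0.17 and 0.42) — the
expected negative result.  The calibration block confirms the test rejects a
true null at its nominal 5 % level while detecting a fecundity-coupled
selection regime essentially always.  The last line inverts an observed
hard-core prevalence of 0.22 % through q = u/s into an implied LoF mutation
rate of ~2 × 10⁻⁸ per nucleotide per generation.

The same stages are available as a CLI (`lofprev simulate|annotate|filter|
stats|correlate|run`) and as library functions (`lofprev.find_orfs`,
`lofprev.classify_snv`, `lofprev.lof_proportion`,
`lofprev.correlation_matrix`, ...).

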
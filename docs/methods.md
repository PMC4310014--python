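# Methods

## Model and assumptions

A population in one environment is a `GenomeModel`: haploblocks (each a
genomic span with an observed haplotype frequency distribution) plus
unlinked bi-allelic SNPs. The statistical micro-states are the haplotypes
of each block and the alleles of each unlinked site; blocks and unlinked
sites are treated as independent, so the genome entropy is the sum of the
per-unit Shannon entropies (base-2 logarithms, reported in bits,
dimensionless). All frequencies are plug-in maximum-likelihood estimates
(counts over sampled chromosomes, no pseudocounts, no small-sample bias
correction); zero-frequency haplotypes are dropped at construction, which
realises the 0·log 0 = 0 convention without clamping.

The energy layer assumes the population is stable — haplotype frequencies
are maintained across generations (the genodynamic counterpart of
Hardy–Weinberg equilibrium) — so the sum of all block and SNP potentials
vanishes. That balance condition fixes the environmental potential
T_E = μ̃/NIC_Genome, from which the allelic potential
μ(p, n) = (μ̃ − T_E)·n − T_E·log2 p, the fixing potential μ̃ − T_E and
the block potential (1 − NIC_H/NIC_G)·n·μ̃ follow. Genomic-pressure
(volume) terms are neglected throughout, and multi-environment comparisons
of shared alleles are out of scope.

## Parameters that matter

- **μ̃ (GEU), default 1.0** — the species-level unit: the potential of a
  lone SNP at maximal variation (p = 1/2). All potentials scale linearly
  with it.
- **T_E (GEU)** — derived from whatever model is supplied (a chromosome
  subset stands in for the genome, mirroring how a handful of chromosomes
  approximates genome-wide NIC); a `--te` override lets chromosome-level
  runs reuse a genome-level value. An override environment is constructed
  with NIC := μ̃/T_E so that the internal identities (and the dual-route
  block-potential check) remain exact.
- **Site-count convention** — n^(H) defaults to the number of *dynamic*
  (in-sample polymorphic) sites: fixed sites carry no entropy yet would
  inflate NIC. `count_monomorphic` restores total-site counting; both
  counts appear in every per-block report. Edge case: a block whose sample
  shows a single haplotype has no in-sample-polymorphic site, so its
  dynamic count falls back to the total (entropy is 0 and NIC is 1 under
  either convention; only the weight in n_SNPs differs).
- **Multi-allelic records** — rejected by default (the model is strictly
  bi-allelic); `drop_multiallelic` excludes them with a logged warning.
- **Missing data** — default per-block strand exclusion (a strand is
  dropped only from blocks where it has a missing call); `drop_sample`
  removes both strands of an affected sample everywhere.
- **Aggregation defaults** — NIC histogram bin width 0.05 (right-open bins,
  last bin closed at 1); block-size fit restricted to blocks with
  n ≥ 50, since potential-per-SNP is only stable for large blocks; region
  sums count fully contained blocks only (no double counting at borders),
  with an any-overlap option.

## Numerical choices

- Frequencies must sum to 1 within 1e-9 on input and are renormalised
  before every entropy evaluation to kill drift.
- The two computational routes to a block potential — the NIC closed form
  and the frequency-weighted mean of haplotype potentials — are both
  evaluated on every call and must agree to 1e-9; a discrepancy indicates a
  site-count-convention bug and aborts rather than returning either value.
- The stability residual of a self-consistent model is accepted as zero
  within 1e-6·n_SNPs (absolute GEU, scaling with model size to absorb
  summation round-off).
- A completely disordered genome (s_Genome → n_SNPs) has no finite
  environmental potential and is rejected with an explicit error rather
  than returning an overflow.
- Report TSVs print floats with 9 significant digits so identical inputs
  produce byte-identical outputs; truth/frequency tables use 17 digits so
  write-then-read round-trips are lossless at the 1e-9 tolerance.
- Coordinates are 1-based inclusive internally (VCF convention); BED's
  0-based half-open intervals are converted on read and write. Alleles are
  taken as written — no reverse-complement normalisation, since frequencies
  are orientation-invariant.

## The synthetic generator

`simulate_model` emulates a genome as haploblocks with haplotype frequency
vectors plus unlinked SNPs. Defaults: 20 blocks of 2–12 SNPs, at most 8
haplotypes per block with symmetric-Dirichlet(α = 0.5) frequencies, 50
unlinked SNPs with minor-allele frequencies uniform on [0.05, 0.5], and a
block NIC floor of 0.2 — stable populations are not observed to carry
near-maximally-disordered haploblocks, and restricting draws to a small
subset of the 2^n possible haplotypes reflects that most combinations are
not viable. Haplotypes drawn below frequency 0.01 are dropped and the
vector renormalised, so every retained haplotype (and hence every dynamic
site's minor allele) has appreciable frequency; this is what makes the
sample→rebuild recovery loop well-posed, since at 50,000 strands the
probability of losing a haplotype of frequency ≥ 0.01 is negligible.
`simulate_target_nic_block` instead tunes a one-parameter geometric
frequency family by bisection to hit a requested NIC exactly (used for
controlled monotonicity and regression tests); it enumerates the 2^n
haplotype space and is limited to n ≤ 16.

What the generator does *not* emulate: linkage between blocks, recombination
maps, coalescent genealogy, genotyping error, unphased or missing calls, or
ascertainment of SNP panels. Passing tests therefore demonstrate the
correctness of the metrics and estimators on populations that satisfy the
model's own assumptions, not robustness to the artefacts of real genotype
data.

## Verification strategy and problem sizes

The test suite checks closed-form values by hand-computed constants, the
entropy path against an independent exact-rational (Fraction) surprisal sum
for blocks with n ≤ 4, additivity over random model splits, the algebraic
identity between the two block-potential routes on 1,000 random blocks, the
stability identity across 100 random models (5–50 blocks, n ≤ 20), the
fixing-potential slope (−0.26 GEU/site for fully conserved blocks when
NIC_Genome = 1/1.26) to 1e-9, and full parameter recovery
(simulate → 50,000 strands → rebuild → re-derive) within 3 delta-method
Monte-Carlo standard errors across 10 seeds. These sizes keep the entire
suite within a couple of minutes on one CPU while leaving the Monte-Carlo
bands narrow enough to be informative.

## Applying the package to real cohort data

Reproducing published whole-chromosome numbers (e.g. environmental
potentials near 1.26/1.12 GEU for particular HapMap populations, or
block-level values in the hundreds of GEUs) requires phased HapMap-scale
genotypes and externally constructed haploblocks (e.g. Haploview's
confidence-interval blocks). The workflow is: phase/obtain a VCF, export
the block intervals (BED or Haploview-style listing), then
`gendyn compute --vcf ... --blocks ...`, optionally passing `--te` with a
genome-level value when analysing single chromosomes. Such runs are outside
the automated test suite by design.

## Known limitations

- Plug-in entropies are biased low at small sample sizes; no Miller–Madow
  or coverage-adjusted correction is applied (by design, to match standard
  frequency-estimate workflows).
- The dynamic-site convention makes n depend on the sample: two cohorts of
  different size can assign different n to the same block.
- Individual potentials are only defined for haplotypes observed in the
  population distribution; unobserved haplotypes are flagged, not priced.
- Block construction itself (LD block discovery, phasing) is consumed as
  input, never performed.
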
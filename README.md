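# gendyn

Genodynamic metrics for SNP haploblocks: Shannon entropy, normalised
information content (NIC), and the genomic-energy state variables they
induce — environmental potential, allelic/block/fixing potentials and a
population-stability residual — for populations described by phased
genotypes or haplotype frequency tables.

## The problem and who it is for

Common variation in a genome is organised into *haploblocks*: contiguous
runs of SNPs in strong linkage disequilibrium that are inherited as units,
so that only a small set of the combinatorially possible haplotypes actually
occurs, each with a stable population frequency. Population geneticists who
want a single quantitative scale for "how conserved is this block relative
to the rest of the genome, in this population, in this environment" can use
the thermodynamic analogy implemented here: entropy measures the disorder of
a block's haplotype distribution, and an energy-like potential (in *genomic
energy units*, GEUs) prices each haplotype by its frequency relative to the
environment-wide level of variation.

## The model

For a haploblock *H* with *n* SNP locations and haplotype frequencies
*p\_h*, the specific entropy (in bits) and NIC are

    s(H)   = − Σ_h p_h log2 p_h            0 ≤ s ≤ n
    NIC(H) = (n − s(H)) / n                0 = fully random, 1 = homogeneous

An unlinked SNP is the n = 1 case with allele frequencies. The genome
entropy is the sum over blocks and unlinked sites; the genome NIC uses the
*total* SNP count (NIC is not additive, so it is never averaged).

Requiring that a stable population's block and SNP potentials sum to zero
(the genodynamic counterpart of Hardy–Weinberg equilibrium) fixes the
environmental potential conjugate to the entropy:

    T_E = μ̃ · n_SNPs / (n_SNPs − s_Genome) = μ̃ / NIC_Genome

where μ̃ = 1 GEU is defined as the potential of a lone SNP at maximal
variation (p = 1/2). The potential of a haplotype or allele at frequency
*p* over *n* sites is

    μ = (μ̃ − T_E)·n − T_E·log2 p

so a fixed allele (p = 1, n = 1) sits at the fixing potential
μ_Fixing = μ̃ − T_E ≤ 0, and the block potential — the frequency-weighted
mean of its haplotype potentials — collapses to

    ⟨μ(H)⟩ = (1 − NIC(H)/NIC_Genome) · n · μ̃ ,

negative for blocks more conserved than the genome average, positive for
more varying ones.

## Worked example

Given a haplotype frequency table `freqs.tsv` with a varying 2-SNP block
and a conserved 4-SNP block:

```
block_id	haplotype	frequency
B1	AC	0.5
B1	AG	0.25
B1	TG	0.25
B2	GGTT	1.0
```

running

```
gendyn compute --freq-table freqs.tsv --out-dir out
```

writes `out/summary.tsv`:

```
quantity	value
n_snps	6
s_genome_bits	1.5
nic_genome	0.75
t_e_GEU	1.33333333
mu_tilde_GEU	1
mu_fixing_GEU	-0.333333333
stability_residual_GEU	4.4408921e-16
n_blocks	2
n_unlinked	0
blocks_positive	1
blocks_negative	1
blocks_zero	0
```

Block B1 has entropy 1.5 bits (−½log2½ − 2·¼log2¼), so over 6 SNP
locations the genome NIC is (6 − 1.5)/6 = 0.75 and the environmental
potential is 1/0.75 ≈ 1.333 GEU. `out/blocks.tsv` then prices each block:

```
block_id	n	...	entropy_bits	nic	block_potential_GEU	haplotype	frequency	potential_GEU
B1	2	...	1.5	0.25	1.33333333	AC	0.5	0.666666667
B1	2	...	1.5	0.25	1.33333333	AG	0.25	2
B1	2	...	1.5	0.25	1.33333333	TG	0.25	2
B2	4	...	0	1	-1.33333333	GGTT	1	-1.33333333
```

B1 is far more varying than the genome average (NIC 0.25 < 0.75), so its
potential is positive (+1.333 GEU); the fully conserved B2 sits at
4·μ_Fixing = −1.333 GEU. Their sum is zero to round-off
(`stability_residual_GEU` ≈ 4e-16): the population is balanced.

Other subcommands: `gendyn region` sums block potentials inside an interval
(e.g. an MHC-like region), `gendyn individual` prices each phased sample's
two strands, `gendyn simulate` writes a synthetic phased VCF + BED + truth
table, and `gendyn validate` checks model invariants. Inputs can also be a
phased VCF plus BED or Haploview-style block listings.

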
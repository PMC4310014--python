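"""Genomic-energy state variables in genomic energy units (GEUs).

The environmental potential T_E, conjugate to the genome entropy, follows
from the population-stability condition (the genodynamic analogue of
Hardy-Weinberg equilibrium: all block and SNP potentials sum to zero):

    T_E = mu_tilde * n_SNPs / (n_SNPs - s_Genome) = mu_tilde / NIC_Genome

with mu_tilde the species-level unit potential, defined so that a lone
bi-allelic SNP at maximal variation (p = 1/2) has potential mu_tilde = 1 GEU.
The allelic potential of a haplotype or allele with frequency p over n SNP
locations is

    mu = (mu_tilde - T_E) * n - T_E * log2(p),

so potential differences scale with frequency ratios, a fixed allele (p = 1,
n = 1) sits at the fixing potential mu_fixing = mu_tilde - T_E <= 0, and a
maximally varying unit reaches n * mu_tilde.  The block potential is the
frequency-weighted average of its haplotype potentials, which collapses to

    <mu(H)> = (1 - NIC(H)/NIC_Genome) * n(H) * mu_tilde:

blocks more conserved than the genome average have negative potential, more
varying blocks positive.  Both routes are evaluated on every call and must
agree; a discrepancy indicates a site-count-convention bug and aborts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

from . import infometrics
from .model import (ConsistencyError, EnvironmentState, GenomeModel,
                    GendynError, Haploblock, IndividualGenotype, SNPSite,
                    ValidationError)

#: absolute agreement demanded between the two block-potential routes
_DUAL_TOL = 1e-9


@dataclass(frozen=True)
class AllelicPotential:
    """A haplotype or allele with its frequency and potential in GEU."""

    label: str
    frequency: float
    potential_GEU: float


@dataclass(frozen=True)
class IndividualPotential:
    """Per-strand and diploid-total allelic potential of one individual."""

    individual_id: str
    strand_GEU: Tuple[float, float]

    @property
    def diploid_GEU(self) -> float:
        return self.strand_GEU[0] + self.strand_GEU[1]


def environmental_potential(n_snps: int, s_genome: float,
                            mu_tilde: float = 1.0) -> float:
    """T_E = mu_tilde * n_SNPs / (n_SNPs - s_Genome).

    Equals mu_tilde for a fully conserved genome (s = 0) and diverges as the
    genome approaches complete disorder (s -> n), which is rejected.
    """
    if n_snps < 1:
        raise ValidationError(f"n_snps must be >= 1, got {n_snps}")
    if s_genome < 0:
        raise ValidationError(f"negative genome entropy {s_genome:.6g}")
    if s_genome > n_snps * (1.0 + 1e-12):
        raise ConsistencyError(
            f"genome entropy {s_genome:.6g} exceeds SNP count {n_snps}")
    if s_genome >= n_snps * (1.0 - 1e-12):
        raise GendynError(
            "infinite environmental potential: completely disordered genome "
            f"(s_Genome = {s_genome:.6g}, n_SNPs = {n_snps})")
    return mu_tilde * n_snps / (n_snps - s_genome)


def fixing_potential(mu_tilde: float, t_e: float) -> float:
    """mu_fixing = mu_tilde - T_E, the potential of an allele fixed at
    p = 1; never positive."""
    if t_e < mu_tilde:
        raise ConsistencyError(
            f"T_E ({t_e:.12g}) below mu_tilde ({mu_tilde:.12g}): "
            "no valid environment has NIC > 1")
    return mu_tilde - t_e


def allelic_potential(p: float, n: int, env: EnvironmentState) -> float:
    """Potential of a haplotype (n sites) or allele (n = 1) at frequency p:
    (mu_tilde - T_E)*n - T_E*log2(p)."""
    if not (0.0 < p <= 1.0):
        raise ValidationError(f"frequency must lie in (0,1], got {p:.12g}")
    if n < 1:
        raise ValidationError(f"site count n must be >= 1, got {n}")
    return (env.mu_tilde - env.t_e) * n - env.t_e * math.log2(p)


def potential_difference(p1: float, p2: float, t_e: float) -> float:
    """Potential gap mu(p2) - mu(p1) = -T_E * log2(p2/p1) between two
    haplotypes of the same block; antisymmetric under swap."""
    for p in (p1, p2):
        if not (0.0 < p <= 1.0):
            raise ValidationError(
                f"frequency must lie in (0,1], got {p:.12g}")
    return -t_e * math.log2(p2 / p1)


def haplotype_potentials(block: Haploblock, env: EnvironmentState,
                         count_monomorphic: bool = False) -> list:
    """Allelic potential of every observed haplotype of *block*."""
    n = block.effective_n(count_monomorphic)
    return [AllelicPotential(h, p, allelic_potential(p, n, env))
            for h, p in block.distribution.items()]


def block_potential(block: Haploblock, env: EnvironmentState,
                    count_monomorphic: bool = False) -> float:
    """Block potential <mu(H)> = (1 - NIC(H)/NIC_Genome) * n(H) * mu_tilde.

    Always cross-checked against the frequency-weighted average of the
    haplotype potentials; disagreement beyond tolerance raises
    :class:`ConsistencyError` (it guards against site-count bugs).
    """
    n = block.effective_n(count_monomorphic)
    nic_h = infometrics.nic_block(block.distribution, n)
    closed_form = (1.0 - nic_h / env.nic_genome) * n * env.mu_tilde
    weighted = sum(p * allelic_potential(p, n, env)
                   for p in block.distribution.freqs)
    tol = max(_DUAL_TOL, 1e-12 * abs(closed_form))
    if abs(closed_form - weighted) > tol:
        raise ConsistencyError(
            f"block {block.block_id}: closed-form potential "
            f"{closed_form:.12g} disagrees with frequency-weighted average "
            f"{weighted:.12g}")
    return closed_form


def site_potential(site: SNPSite, env: EnvironmentState) -> float:
    """SNP potential of an unlinked site: the frequency-weighted average of
    its two allelic potentials (a 1-SNP block).  Bounded below by the fixing
    potential and above by mu_tilde."""
    return sum(p * allelic_potential(p, 1, env)
               for p in site.freqs if p > 0.0)


def stability_residual(model: GenomeModel, env: EnvironmentState,
                       count_monomorphic: bool = False) -> float:
    """mu_Genome: the sum of all block and SNP potentials.

    Vanishes (up to round-off) when *env* was derived self-consistently from
    the same model; a stable population is balanced at mu_Genome = 0.
    """
    return (sum(block_potential(b, env, count_monomorphic)
                for b in model.blocks)
            + sum(site_potential(s, env) for s in model.unlinked))


def individual_potential(geno: IndividualGenotype, model: GenomeModel,
                         env: EnvironmentState,
                         count_monomorphic: bool = False
                         ) -> IndividualPotential:
    """Overall allelic potential of one individual, per strand and summed
    over the diploid genotype.

    Each strand sums the potentials of its assigned block haplotypes and
    unlinked-site alleles; an assignment to a haplotype or allele absent
    from the population distribution has no defined frequency and raises.
    """
    errs = geno.violations(model)
    if errs:
        raise GendynError("; ".join(errs))
    strand_totals = [0.0, 0.0]
    for block in model.blocks:
        n = block.effective_n(count_monomorphic)
        pair = geno.block_haplotypes[block.block_id]
        for strand in (0, 1):
            p = block.distribution.frequency_of(pair[strand])
            strand_totals[strand] += allelic_potential(p, n, env)
    for site in model.unlinked:
        pair = geno.site_alleles[site.site_id]
        for strand in (0, 1):
            p = site.freqs[site.alleles.index(pair[strand])]
            if p <= 0.0:
                raise GendynError(
                    f"{geno.individual_id}: allele {pair[strand]!r} at "
                    f"{site.site_id} has zero population frequency")
            strand_totals[strand] += allelic_potential(p, 1, env)
    return IndividualPotential(geno.individual_id,
                               (strand_totals[0], strand_totals[1]))


def derive_environment(model: GenomeModel, mu_tilde: float = 1.0,
                       count_monomorphic: bool = False) -> EnvironmentState:
    """Derive the self-consistent EnvironmentState of *model*: T_E from the
    model's own entropy, mu_fixing = mu_tilde - T_E."""
    n = model.n_snps(count_monomorphic)
    s = infometrics.genome_entropy(model, count_monomorphic)
    t_e = environmental_potential(n, s, mu_tilde)
    return EnvironmentState(mu_tilde, t_e, mu_tilde / t_e, mu_tilde - t_e)
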
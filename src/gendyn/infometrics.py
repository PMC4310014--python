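"""Entropy and information-content metrics for haploblocks and genomes.

The specific (per-capita) entropy of a haploblock is the Shannon entropy of
its haplotype frequency distribution in bits,

    s(H) = -sum_h p_h log2 p_h,

zero for a homogeneous block and at most n(H), the number of SNP locations,
which is attained by the uniform distribution over all 2^n haplotypes.  An
unlinked SNP contributes the binary entropy of its allele frequencies.  The
genome entropy is the sum over blocks and unlinked sites, which makes it
additive over any partition of the model.

The information content is IC = s_max - s and the normalised information
content NIC = (n - s)/n lies in [0, 1]: 1 for a homogeneous distribution,
0 for a completely stochastic one.  NIC is *not* additive; the genome NIC
must be computed from the total site count and the total entropy, never by
averaging block NICs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (ConsistencyError, GenomeModel, GendynError,
                    HaplotypeDistribution, SNPSite, ValidationError)

#: slack allowed on the analytic bound s <= n before declaring the site-count
#: convention inconsistent
_BOUND_TOL = 1e-9


@dataclass(frozen=True)
class EntropySummary:
    """Entropy and information content of one block under a site count n."""

    s_bits: float
    s_max_bits: float
    ic_bits: float
    nic: float


def _shannon(freqs: np.ndarray) -> float:
    # renormalise to kill floating drift before taking logs
    freqs = np.asarray(freqs, dtype=float)
    freqs = freqs[freqs > 0.0]
    freqs = freqs / freqs.sum()
    return float(-(freqs * np.log2(freqs)).sum()) + 0.0  # avoid -0.0


def block_entropy(dist: HaplotypeDistribution) -> float:
    """Specific entropy of a haploblock in bits: -sum_h p_h log2 p_h."""
    errs = dist.violations()
    if errs:
        raise ValidationError("; ".join(errs))
    return _shannon(np.array(dist.freqs))


def site_entropy(site: SNPSite) -> float:
    """Specific entropy of an unlinked bi-allelic SNP in bits.

    The convention 0*log2(0) = 0 applies, so a fixed site contributes 0;
    the maximum of 1 bit is reached at p = 1/2.
    """
    errs = site.violations()
    if errs:
        raise ValidationError("; ".join(errs))
    return _shannon(np.array(site.freqs))


def genome_entropy(model: GenomeModel,
                   count_monomorphic: bool = False) -> float:
    """Total specific entropy of the genome: sum over blocks and unlinked
    sites.  Additive over any disjoint split of the model."""
    if not model.blocks and not model.unlinked:
        raise GendynError("empty model: no dynamic degrees of freedom")
    return (sum(block_entropy(b.distribution) for b in model.blocks)
            + sum(site_entropy(s) for s in model.unlinked))


def nic_block(dist: HaplotypeDistribution, n: int) -> float:
    """Normalised information content (n - s)/n of a block with n SNP sites.

    Raises :class:`ConsistencyError` when the entropy exceeds n, which
    signals a mismatched site-count convention.
    """
    if n < 1:
        raise ValidationError(f"site count n must be >= 1, got {n}")
    s = block_entropy(dist)
    if s > n + _BOUND_TOL:
        raise ConsistencyError(
            f"entropy {s:.6g} bits exceeds site count n={n}: "
            "inconsistent site-count convention")
    return min(1.0, max(0.0, (n - s) / n))


def nic_genome(model: GenomeModel, count_monomorphic: bool = False) -> float:
    """Genome-wide NIC: (n_SNPs - s_Genome)/n_SNPs with n_SNPs the total
    SNP-location count.  This is not the mean of the block NICs."""
    n = model.n_snps(count_monomorphic)
    if n < 1:
        raise GendynError("empty model: no SNP locations")
    s = genome_entropy(model, count_monomorphic)
    if s > n + _BOUND_TOL * n:
        raise ConsistencyError(
            f"genome entropy {s:.6g} exceeds SNP count {n}")
    return min(1.0, max(0.0, (n - s) / n))


def entropy_summary(dist: HaplotypeDistribution, n: int) -> EntropySummary:
    """Bundle s, s_max = n, IC and NIC for one block."""
    s = block_entropy(dist)
    nic = nic_block(dist, n)
    return EntropySummary(s_bits=s, s_max_bits=float(n),
                          ic_bits=float(n) - s, nic=nic)
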
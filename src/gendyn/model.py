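"""Core domain types for genodynamic analysis of SNP haploblocks.

A population in a given environment is represented as a :class:`GenomeModel`:
a collection of :class:`Haploblock` objects (contiguous runs of SNPs in strong
linkage disequilibrium, each carrying a :class:`HaplotypeDistribution` of
observed haplotype frequencies) plus unlinked bi-allelic :class:`SNPSite`
objects with allele frequencies.  The environmental state variables that the
energetics layer attaches to such a model live in :class:`EnvironmentState`.

All frequency vectors are plug-in (maximum-likelihood) estimates: counts
divided by the number of sampled chromosomes, no pseudocounts.  Zero-frequency
haplotypes are dropped at construction time, which is also how the entropy
convention ``0*log2(0) = 0`` is realised downstream.
"""

from __future__ import annotations

import math
from dataclasses import InitVar, dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

#: tolerance for "frequencies sum to 1" on input
FREQ_TOL = 1e-9
#: tolerance for the internal consistency of EnvironmentState
ENV_TOL = 1e-9


class GendynError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(GendynError):
    """An input object violates a domain invariant."""


class ConsistencyError(GendynError):
    """Two quantities that must agree (e.g. an entropy and its site count,
    or the two computational routes to a block potential) do not."""


# ---------------------------------------------------------------------------
# SNP sites and haplotype distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SNPSite:
    """A bi-allelic SNP with population allele frequencies.

    Positions are 1-based.  ``freqs`` are the frequencies of ``alleles`` in
    the same order; a fixed site has freqs ``(1.0, 0.0)``.
    """

    site_id: str
    chrom: str
    pos: int
    alleles: Tuple[str, str]
    freqs: Tuple[float, float]
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        object.__setattr__(self, "alleles", tuple(self.alleles))
        object.__setattr__(self, "freqs", tuple(float(f) for f in self.freqs))
        if validate:
            errs = self.violations()
            if errs:
                raise ValidationError("; ".join(errs))

    def violations(self) -> list:
        errs = []
        if len(self.alleles) != 2:
            errs.append(f"site {self.site_id}: needs exactly 2 alleles, "
                        f"got {len(self.alleles)}")
        if len(self.freqs) != 2:
            errs.append(f"site {self.site_id}: needs exactly 2 frequencies")
        else:
            if any(f < -FREQ_TOL or f > 1 + FREQ_TOL for f in self.freqs):
                errs.append(f"site {self.site_id}: frequencies outside [0,1]")
            if abs(sum(self.freqs) - 1.0) > FREQ_TOL:
                errs.append(f"site {self.site_id}: frequencies sum to "
                            f"{sum(self.freqs):.12g}, not 1")
        return errs

    @property
    def is_polymorphic(self) -> bool:
        return min(self.freqs) > 0.0


@dataclass(frozen=True)
class HaplotypeDistribution:
    """Observed haplotypes of one block with their population frequencies.

    Haplotype strings are allele symbols concatenated across the block's
    sites, all of a common length ``n_sites``.  Invariants: frequencies are
    strictly positive and sum to 1; strings are distinct; there are at most
    ``2**n_sites`` of them.
    """

    haplotypes: Tuple[str, ...]
    freqs: Tuple[float, ...]
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        object.__setattr__(self, "haplotypes", tuple(self.haplotypes))
        object.__setattr__(self, "freqs", tuple(float(f) for f in self.freqs))
        if validate:
            errs = self.violations()
            if errs:
                raise ValidationError("; ".join(errs))

    def violations(self) -> list:
        errs = []
        if not self.haplotypes:
            return ["distribution has no haplotypes"]
        if len(self.haplotypes) != len(self.freqs):
            return ["haplotype and frequency lists differ in length"]
        n = len(self.haplotypes[0])
        if any(len(h) != n for h in self.haplotypes):
            errs.append("haplotype strings have unequal lengths")
        if len(set(self.haplotypes)) != len(self.haplotypes):
            errs.append("haplotype strings are not distinct")
        if any(f <= 0.0 for f in self.freqs):
            errs.append("zero or negative haplotype frequency "
                        "(zeros must be dropped at construction)")
        if abs(sum(self.freqs) - 1.0) > FREQ_TOL:
            errs.append(f"frequencies sum to {sum(self.freqs):.12g}, not 1")
        if n <= 62 and len(self.haplotypes) > 2 ** n:
            errs.append(f"{len(self.haplotypes)} haplotypes exceed 2^{n}")
        return errs

    @property
    def n_sites(self) -> int:
        return len(self.haplotypes[0])

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def items(self) -> Iterable[Tuple[str, float]]:
        return zip(self.haplotypes, self.freqs)

    def frequency_of(self, haplotype: str) -> float:
        try:
            return self.freqs[self.haplotypes.index(haplotype)]
        except ValueError:
            raise GendynError(
                f"haplotype {haplotype!r} not observed in distribution")

    @classmethod
    def from_counts(cls, counts: Mapping[str, float]) -> "HaplotypeDistribution":
        """Build from raw counts: drop zeros and normalise. Idempotent."""
        kept = [(h, c) for h, c in counts.items() if c > 0]
        if not kept:
            raise ValidationError("all haplotype counts are zero")
        total = float(sum(c for _, c in kept))
        kept.sort(key=lambda hc: (-hc[1], hc[0]))
        return cls(tuple(h for h, _ in kept),
                   tuple(c / total for _, c in kept))

    @classmethod
    def from_freqs(cls, haplotypes: Sequence[str],
                   freqs: Sequence[float]) -> "HaplotypeDistribution":
        """Build from possibly-unnormalised frequencies, dropping zeros."""
        return cls.from_counts(dict(zip(haplotypes, freqs)))

    def dynamic_site_count(self) -> int:
        """Number of columns at which the observed haplotypes differ."""
        n = self.n_sites
        return sum(1 for j in range(n)
                   if len({h[j] for h in self.haplotypes}) > 1)


# ---------------------------------------------------------------------------
# Haploblocks and the genome model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Haploblock:
    """A SNP haploblock: a genomic span, its SNP sites, and the observed
    haplotype distribution.

    ``n_total`` counts every SNP location in the block; ``n_dynamic`` counts
    only those polymorphic in the sample.  The site-count convention used in
    the entropy/NIC formulas defaults to ``n_dynamic`` (fixed sites carry no
    entropy); :meth:`effective_n` applies the convention.  A block whose
    sample shows a single haplotype has no in-sample-polymorphic site, so for
    such blocks ``n_dynamic`` falls back to ``n_total`` (entropy is 0 and NIC
    is 1 under either count).
    """

    block_id: str
    chrom: str
    span: Tuple[int, int]  # 1-based inclusive
    sites: Tuple[SNPSite, ...]
    n_total: int
    n_dynamic: int
    distribution: HaplotypeDistribution
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        object.__setattr__(self, "span", (int(self.span[0]), int(self.span[1])))
        object.__setattr__(self, "sites", tuple(self.sites))
        if validate:
            errs = self.violations()
            if errs:
                raise ValidationError("; ".join(errs))

    def violations(self) -> list:
        errs = []
        if self.span[0] > self.span[1]:
            errs.append(f"block {self.block_id}: span start > end")
        if not (1 <= self.n_dynamic <= self.n_total):
            errs.append(f"block {self.block_id}: need 1 <= n_dynamic "
                        f"({self.n_dynamic}) <= n_total ({self.n_total})")
        if self.sites and len(self.sites) != self.n_total:
            errs.append(f"block {self.block_id}: {len(self.sites)} sites "
                        f"but n_total={self.n_total}")
        if self.distribution.n_sites != self.n_total:
            errs.append(f"block {self.block_id}: haplotype length "
                        f"{self.distribution.n_sites} != n_total {self.n_total}")
        errs.extend(self.distribution.violations())
        return errs

    @classmethod
    def from_distribution(cls, block_id: str, chrom: str,
                          span: Tuple[int, int],
                          distribution: HaplotypeDistribution,
                          sites: Sequence[SNPSite] = (),
                          n_dynamic: Optional[int] = None) -> "Haploblock":
        """Build a block, inferring the dynamic-site count from the
        distribution when not given (with the single-haplotype fallback)."""
        n_total = distribution.n_sites
        if n_dynamic is None:
            n_dynamic = distribution.dynamic_site_count() or n_total
        return cls(block_id, chrom, tuple(span), tuple(sites),
                   n_total, n_dynamic, distribution)

    def effective_n(self, count_monomorphic: bool = False) -> int:
        """The site count n entering the entropy/NIC formulas."""
        return self.n_total if count_monomorphic else self.n_dynamic


@dataclass(frozen=True)
class GenomeModel:
    """One population in one environment: haploblocks plus unlinked SNPs.

    Every dynamic degree of freedom appears exactly once — a SNP location is
    either inside one block or unlinked, never both, and block spans on a
    chromosome do not overlap.
    """

    blocks: Tuple[Haploblock, ...]
    unlinked: Tuple[SNPSite, ...]
    population_size: Optional[int] = None
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        object.__setattr__(self, "unlinked", tuple(self.unlinked))
        if validate:
            errs = validate_genome_model(self)
            if errs:
                raise ValidationError("; ".join(errs))

    def n_snps(self, count_monomorphic: bool = False) -> int:
        """Total number of SNP locations under the active count convention.

        Each unlinked site counts 1; monomorphic unlinked sites are kept in
        the model only when the caller's pipeline included them, so no
        filtering happens here.
        """
        return (sum(b.effective_n(count_monomorphic) for b in self.blocks)
                + len(self.unlinked))

    @property
    def chromosomes(self) -> Tuple[str, ...]:
        seen = dict.fromkeys([b.chrom for b in self.blocks]
                             + [s.chrom for s in self.unlinked])
        return tuple(seen)

    def block_by_id(self, block_id: str) -> Haploblock:
        for b in self.blocks:
            if b.block_id == block_id:
                return b
        raise GendynError(f"no block with id {block_id!r}")


def validate_genome_model(model: GenomeModel) -> list:
    """Check every domain invariant of *model*; return a list of violation
    descriptions (empty iff the model is well-formed).

    Pure reporting function: never raises, never mutates, repeated calls give
    identical results.
    """
    errs: list = []
    for block in model.blocks:
        errs.extend(block.violations())
        for site in block.sites:
            errs.extend(site.violations())
    for site in model.unlinked:
        errs.extend(site.violations())

    # non-overlapping spans per chromosome
    by_chrom: dict = {}
    for block in model.blocks:
        by_chrom.setdefault(block.chrom, []).append(block)
    for chrom, blocks in by_chrom.items():
        blocks = sorted(blocks, key=lambda b: b.span)
        for prev, cur in zip(blocks, blocks[1:]):
            if cur.span[0] <= prev.span[1]:
                errs.append(
                    f"blocks {prev.block_id} and {cur.block_id} overlap on "
                    f"{chrom}: {prev.span} vs {cur.span}")

    # every dynamic degree of freedom appears exactly once
    seen: dict = {}
    for block in model.blocks:
        for site in block.sites:
            key = (site.chrom, site.pos)
            if key in seen:
                errs.append(f"site {site.site_id} at {key} appears in both "
                            f"{seen[key]} and block {block.block_id}")
            seen[key] = f"block {block.block_id}"
    for site in model.unlinked:
        key = (site.chrom, site.pos)
        if key in seen:
            errs.append(f"site {site.site_id} at {key} appears in both "
                        f"{seen[key]} and the unlinked set")
        seen[key] = "unlinked"
    return errs


# ---------------------------------------------------------------------------
# Environment state and individuals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnvironmentState:
    """The environmental state variables of a population.

    ``t_e`` is the environmental potential (conjugate to entropy), ``mu_tilde``
    the species-level unit potential at which a lone SNP sits at maximal
    variation, ``nic_genome`` the genome-wide normalised information content,
    and ``mu_fixing = mu_tilde - t_e`` the potential of a fixed allele.  The
    three are tied together by ``t_e = mu_tilde / nic_genome``.
    """

    mu_tilde: float
    t_e: float
    nic_genome: float
    mu_fixing: float
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        if validate:
            errs = self.violations()
            if errs:
                raise ValidationError("; ".join(errs))

    def violations(self) -> list:
        errs = []
        if not (0.0 < self.nic_genome <= 1.0):
            errs.append(f"nic_genome {self.nic_genome:.12g} outside (0,1]")
        elif abs(self.t_e - self.mu_tilde / self.nic_genome) > ENV_TOL * max(
                1.0, abs(self.t_e)):
            errs.append("t_e != mu_tilde / nic_genome")
        if abs(self.mu_fixing - (self.mu_tilde - self.t_e)) > ENV_TOL:
            errs.append("mu_fixing != mu_tilde - t_e")
        if self.t_e < self.mu_tilde - ENV_TOL:
            errs.append("t_e < mu_tilde (nic_genome would exceed 1)")
        return errs

    @classmethod
    def from_nic(cls, nic_genome: float,
                 mu_tilde: float = 1.0) -> "EnvironmentState":
        if not (0.0 < nic_genome <= 1.0):
            raise ValidationError(
                f"genome NIC must lie in (0,1], got {nic_genome:.12g}")
        t_e = mu_tilde / nic_genome
        return cls(mu_tilde, t_e, nic_genome, mu_tilde - t_e)

    @classmethod
    def from_te(cls, t_e: float, mu_tilde: float = 1.0) -> "EnvironmentState":
        """Environment pinned by an externally supplied T_E (e.g. a
        genome-level value reused for a chromosome subset)."""
        if t_e < mu_tilde:
            raise ValidationError(
                f"T_E ({t_e:.12g}) must be >= mu_tilde ({mu_tilde:.12g})")
        return cls(mu_tilde, t_e, mu_tilde / t_e, mu_tilde - t_e)


@dataclass(frozen=True)
class IndividualGenotype:
    """Phased assignment of one individual to a GenomeModel: one haplotype
    per block per strand and one allele per unlinked site per strand."""

    individual_id: str
    block_haplotypes: Mapping[str, Tuple[str, str]]
    site_alleles: Mapping[str, Tuple[str, str]]

    def violations(self, model: GenomeModel) -> list:
        errs = []
        for block in model.blocks:
            pair = self.block_haplotypes.get(block.block_id)
            if pair is None:
                errs.append(f"{self.individual_id}: block {block.block_id} "
                            "unassigned")
                continue
            for hap in pair:
                if hap not in block.distribution.haplotypes:
                    errs.append(f"{self.individual_id}: haplotype {hap!r} not "
                                f"observed in block {block.block_id}")
        for site in model.unlinked:
            pair = self.site_alleles.get(site.site_id)
            if pair is None:
                errs.append(f"{self.individual_id}: site {site.site_id} "
                            "unassigned")
                continue
            for allele in pair:
                if allele not in site.alleles:
                    errs.append(f"{self.individual_id}: allele {allele!r} not "
                                f"in site {site.site_id}")
        return errs


@dataclass
class BlockReport:
    """Per-block output row: entropy, NIC and energy measures.

    ``haplotype_potentials`` holds ``(haplotype, frequency, potential_GEU)``
    triples; their frequency-weighted mean equals ``block_potential_GEU``.
    Both site counts are carried so either convention can be read off.
    """

    block_id: str
    n: int
    n_total: int
    n_dynamic: int
    entropy_bits: float
    nic: float
    block_potential_GEU: float
    haplotype_potentials: list = field(default_factory=list)
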
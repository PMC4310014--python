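"""Synthetic-population generator.

Produces GenomeModels (haploblocks with haplotype frequency vectors plus
unlinked bi-allelic SNPs) and phased samples drawn from them, so that every
metric in the package can be exercised and every estimator's recovery can be
measured against known truth without external data.

The default frequency law draws each block's haplotype frequencies from a
symmetric Dirichlet over a randomly chosen subset of at most
``max_haplotypes`` of the 2^n possible haplotypes — real populations realise
only a small viable fraction of the combinatorial space — and then drops
haplotypes below ``min_hap_freq``, so every retained haplotype has
appreciable frequency.  Generated blocks respect a NIC floor (default 0.2):
empirically, extremely disordered haploblocks are not observed in stable
populations, and the generator emulates that.

A single seeded :class:`numpy.random.Generator` is threaded through all
draws; there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import infometrics
from .io_formats import HaplotypeMatrix, SiteRecord
from .model import (GenomeModel, GendynError, Haploblock,
                    HaplotypeDistribution, SNPSite, ValidationError)

_BASES = "ACGT"
#: largest block size for which the full 2^n haplotype space is materialised
_MAX_EXHAUSTIVE_N = 16


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic population.

    ``nic_targets``, when given, overrides the Dirichlet law: block i gets a
    haplotype distribution tuned to NIC ``nic_targets[i % len(nic_targets)]``.
    """

    n_blocks: int = 20
    block_size_range: Tuple[int, int] = (2, 12)
    max_haplotypes: int = 8
    alpha: float = 0.5
    nic_targets: Optional[Tuple[float, ...]] = None
    n_unlinked: int = 50
    unlinked_maf_range: Tuple[float, float] = (0.05, 0.5)
    nic_floor: float = 0.2
    min_hap_freq: float = 0.01
    sample_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 and self.n_unlinked < 1:
            raise ValidationError("need at least one block or unlinked SNP")
        if self.n_blocks < 0 or self.n_unlinked < 0 or self.sample_size < 1:
            raise ValidationError("counts must be positive")
        if not (0.0 <= self.nic_floor < 1.0):
            raise ValidationError(
                f"NIC floor must lie in [0,1), got {self.nic_floor}")
        lo, hi = self.block_size_range
        if not (1 <= lo <= hi):
            raise ValidationError(f"bad block size range {lo}..{hi}")
        if self.max_haplotypes < 1 or self.alpha <= 0:
            raise ValidationError("max_haplotypes and alpha must be positive")
        if self.nic_targets is not None:
            object.__setattr__(self, "nic_targets",
                               tuple(float(t) for t in self.nic_targets))
            bad = [t for t in self.nic_targets if t < self.nic_floor]
            if bad:
                raise GendynError(
                    f"unsatisfiable constraints: NIC targets {bad} fall "
                    f"below the NIC floor {self.nic_floor}")


def _distinct_ints(rng: np.random.Generator, bound: int, k: int) -> np.ndarray:
    """k distinct integers in [0, bound) without materialising the range."""
    if k >= bound:
        return np.arange(bound)
    if 4 * k >= bound:
        return rng.permutation(bound)[:k]
    chosen: set = set()
    while len(chosen) < k:
        chosen.update(int(x) for x in
                      rng.integers(0, bound, size=k - len(chosen)))
    return np.fromiter(sorted(chosen), dtype=np.int64)


def _block_sites(rng: np.random.Generator, chrom: str, block_id: str,
                 positions: Sequence[int]) -> List[Tuple[str, str]]:
    """Random ref/alt letter pairs for each site of a block."""
    pairs = []
    for _ in positions:
        ref, alt = rng.choice(len(_BASES), size=2, replace=False)
        pairs.append((_BASES[ref], _BASES[alt]))
    return pairs


def _assemble_block(block_id: str, chrom: str, start: int, n: int,
                    hap_codes: np.ndarray, freqs: np.ndarray,
                    allele_pairs: Sequence[Tuple[str, str]]) -> Haploblock:
    """Turn integer haplotype codes + frequencies into a Haploblock with
    per-site marginal allele frequencies."""
    positions = [start + 100 * k for k in range(n)]
    bits = ((hap_codes[:, None] >> np.arange(n - 1, -1, -1)) & 1)
    haps = ["".join(allele_pairs[k][b] for k, b in enumerate(row))
            for row in bits]
    dist = HaplotypeDistribution.from_freqs(haps, freqs)
    # marginals from the *kept* distribution (post zero-dropping)
    kept_bits = np.array(
        [[0 if h[k] == allele_pairs[k][0] else 1 for k in range(n)]
         for h in dist.haplotypes])
    kept_freqs = np.array(dist.freqs)
    sites = []
    for k, pos in enumerate(positions):
        p_alt = float(kept_freqs[kept_bits[:, k] == 1].sum())
        sites.append(SNPSite(f"{block_id}_s{k}", chrom, pos,
                             allele_pairs[k], (1.0 - p_alt, p_alt)))
    return Haploblock.from_distribution(
        block_id, chrom, (positions[0], positions[-1]), dist, sites)


def simulate_target_nic_block(n: int, nic_target: float, tol: float = 1e-6,
                              seed: Optional[int] = None,
                              rng: Optional[np.random.Generator] = None,
                              max_iter: int = 200) -> HaplotypeDistribution:
    """A haplotype distribution over n sites whose NIC is within ``tol`` of
    ``nic_target``.

    Uses bisection on a one-parameter geometric family w_k proportional to
    q**k over all 2^n haplotypes: q = 1 is the uniform distribution (NIC 0),
    q -> 0 degenerates to a single haplotype (NIC 1), and the entropy is
    continuous and strictly increasing in q in between.
    """
    if not (0.0 <= nic_target <= 1.0):
        raise ValidationError(f"NIC target must lie in [0,1], got {nic_target}")
    if n < 1:
        raise ValidationError(f"block size must be >= 1, got {n}")
    if n > _MAX_EXHAUSTIVE_N:
        raise GendynError(
            f"target-NIC construction enumerates 2^n haplotypes; n={n} "
            f"exceeds the supported maximum {_MAX_EXHAUSTIVE_N}")
    if rng is None:
        rng = np.random.default_rng(seed)
    size = 2 ** n
    allele_pairs = _block_sites(rng, "sim", "t", range(n))
    codes = rng.permutation(size)

    def freqs_for(q: float) -> np.ndarray:
        if q <= 0.0:
            w = np.zeros(size)
            w[0] = 1.0
            return w
        logw = np.arange(size) * math.log(q) if q < 1.0 else np.zeros(size)
        logw -= logw.max()
        w = np.exp(logw)
        return w / w.sum()

    def entropy_for(q: float) -> float:
        w = freqs_for(q)
        w = w[w > 0]
        return float(-(w * np.log2(w)).sum())

    s_target = n * (1.0 - nic_target)
    lo, hi = 0.0, 1.0
    q = 0.5
    for _ in range(max_iter):
        q = 0.5 * (lo + hi)
        s = entropy_for(q)
        if abs((n - s) / n - nic_target) <= tol:
            break
        if s < s_target:
            lo = q
        else:
            hi = q
    else:
        raise GendynError(
            f"target-NIC bisection did not reach tolerance {tol} for n={n}, "
            f"target {nic_target}")
    if nic_target == 1.0:
        q = 0.0
    elif nic_target == 0.0:
        q = 1.0
    w = freqs_for(q)
    keep = w > 1e-15
    bits = ((codes[keep][:, None] >> np.arange(n - 1, -1, -1)) & 1)
    haps = ["".join(allele_pairs[k][b] for k, b in enumerate(row))
            for row in bits]
    return HaplotypeDistribution.from_freqs(haps, w[keep])


def _dirichlet_block(rng: np.random.Generator, n: int, config: SimConfig
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """Haplotype codes and frequencies for one block under the Dirichlet law,
    rejected until the NIC floor is met."""
    space = 2 ** n if n <= 30 else 2 ** 30
    k = min(config.max_haplotypes, space)
    for _ in range(1000):
        codes = _distinct_ints(rng, space, k)
        freqs = rng.dirichlet(np.full(k, config.alpha))
        keep = freqs >= config.min_hap_freq
        if not keep.any():
            keep = freqs == freqs.max()
        codes_k, freqs_k = codes[keep], freqs[keep]
        freqs_k = freqs_k / freqs_k.sum()
        s = float(-(freqs_k * np.log2(freqs_k)).sum()) if freqs_k.size > 1 \
            else 0.0
        # NIC under the dynamic-site convention the block will carry
        n_dyn = _dynamic_count(codes_k, n) or n
        if (n_dyn - s) / n_dyn >= config.nic_floor:
            return codes_k, freqs_k
    raise GendynError(
        f"unsatisfiable constraints: could not draw a block of size {n} "
        f"with NIC >= {config.nic_floor} under alpha={config.alpha}")


def _dynamic_count(codes: np.ndarray, n: int) -> int:
    bits = ((codes[:, None] >> np.arange(n - 1, -1, -1)) & 1)
    return int((bits.min(axis=0) != bits.max(axis=0)).sum())


def simulate_model(config: SimConfig) -> GenomeModel:
    """Generate a GenomeModel from *config*; reproducible given the seed."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.block_size_range
    blocks: List[Haploblock] = []
    cursor = 1
    for i in range(config.n_blocks):
        n = int(rng.integers(lo, hi + 1))
        if config.nic_targets is not None:
            target = config.nic_targets[i % len(config.nic_targets)]
            dist = simulate_target_nic_block(n, target, tol=1e-6, rng=rng)
            # allele symbols come embedded in the generated strings
            block = _reassemble_from_dist(f"B{i + 1:04d}", "1", cursor, dist)
        else:
            codes, freqs = _dirichlet_block(rng, n, config)
            pairs = _block_sites(rng, "1", f"B{i + 1:04d}", range(n))
            block = _assemble_block(f"B{i + 1:04d}", "1", cursor, n,
                                    codes, freqs, pairs)
        blocks.append(block)
        cursor = block.span[1] + 1000

    unlinked: List[SNPSite] = []
    mlo, mhi = config.unlinked_maf_range
    for j in range(config.n_unlinked):
        p_alt = float(rng.uniform(mlo, mhi))
        ref, alt = rng.choice(len(_BASES), size=2, replace=False)
        unlinked.append(SNPSite(f"U{j + 1:04d}", "1", cursor,
                                (_BASES[ref], _BASES[alt]),
                                (1.0 - p_alt, p_alt)))
        cursor += 1000
    return GenomeModel(tuple(blocks), tuple(unlinked),
                       population_size=config.sample_size)


def _reassemble_from_dist(block_id: str, chrom: str, start: int,
                          dist: HaplotypeDistribution) -> Haploblock:
    """Wrap a ready-made distribution into a Haploblock with per-site
    marginal frequencies inferred from the haplotype strings."""
    n = dist.n_sites
    positions = [start + 100 * k for k in range(n)]
    freqs = np.array(dist.freqs)
    sites = []
    for k, pos in enumerate(positions):
        symbols = sorted({h[k] for h in dist.haplotypes})
        ref = symbols[0]
        alt = symbols[1] if len(symbols) > 1 else next(
            b for b in _BASES if b != ref)
        p_alt = float(sum(p for h, p in dist.items() if h[k] == alt))
        sites.append(SNPSite(f"{block_id}_s{k}", chrom, pos, (ref, alt),
                             (1.0 - p_alt, p_alt)))
    return Haploblock.from_distribution(block_id, chrom,
                                        (positions[0], positions[-1]),
                                        dist, sites)


def sample_individuals(model: GenomeModel, n_samples: int,
                       seed: Optional[int] = None) -> HaplotypeMatrix:
    """Draw ``n_samples`` phased diploid individuals from *model*.

    Strands are i.i.d.: each strand draws one haplotype per block from the
    block's distribution and one allele per unlinked site from its allele
    frequencies.  Rebuilding a model from a large sample recovers the input
    frequencies within binomial sampling error.
    """
    if n_samples < 1:
        raise ValidationError(f"n_samples must be >= 1, got {n_samples}")
    rng = np.random.default_rng(seed)
    n_strands = 2 * n_samples

    col_sites: List[SiteRecord] = []
    col_data: List[np.ndarray] = []
    for block in model.blocks:
        if not block.sites:
            raise GendynError(
                f"block {block.block_id} carries no site definitions; "
                "cannot emit per-site genotypes")
        dist = block.distribution
        hap_idx = rng.choice(len(dist.haplotypes), size=n_strands,
                             p=np.array(dist.freqs))
        # allele index of each haplotype at each site
        hap_alleles = np.array(
            [[0 if h[k] == site.alleles[0] else 1
              for k, site in enumerate(block.sites)]
             for h in dist.haplotypes], dtype=np.int8)
        data = hap_alleles[hap_idx]  # (strands, n_sites)
        for k, site in enumerate(block.sites):
            col_sites.append(SiteRecord(site.chrom, site.pos, site.site_id,
                                        site.alleles))
            col_data.append(data[:, k])
    for site in model.unlinked:
        draws = (rng.random(n_strands) < site.freqs[1]).astype(np.int8)
        col_sites.append(SiteRecord(site.chrom, site.pos, site.site_id,
                                    site.alleles))
        col_data.append(draws)

    order = sorted(range(len(col_sites)),
                   key=lambda j: (col_sites[j].chrom, col_sites[j].pos))
    sites = [col_sites[j] for j in order]
    geno = np.stack([col_data[j] for j in order], axis=1)
    samples = [f"S{i + 1:05d}" for i in range(n_samples)]
    return HaplotypeMatrix(samples, sites, geno)
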
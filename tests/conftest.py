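"""Shared fixtures: hand-sized distributions and models whose metrics are
known in closed form."""

import numpy as np
import pytest

from gendyn import (EnvironmentState, GenomeModel, Haploblock,
                    HaplotypeDistribution, SNPSite)


@pytest.fixture
def mixed_dist():
    """Three haplotypes over two sites at {1/2, 1/4, 1/4}: entropy 1.5 bits,
    NIC 0.25 at n = 2."""
    return HaplotypeDistribution(("AC", "AG", "TG"), (0.5, 0.25, 0.25))


@pytest.fixture
def mixed_block(mixed_dist):
    return Haploblock.from_distribution("B1", "chr1", (100, 300), mixed_dist)


@pytest.fixture
def half_snp():
    """An unlinked SNP at p = 1/2: entropy exactly 1 bit."""
    return SNPSite("rs1", "chr1", 5000, ("A", "G"), (0.5, 0.5))


@pytest.fixture
def toy_model(mixed_block, half_snp):
    """One 2-SNP block (s = 1.5) plus one unlinked SNP (s = 1):
    s_Genome = 2.5, n_SNPs = 3, NIC_Genome = 1/6."""
    return GenomeModel((mixed_block,), (half_snp,))


@pytest.fixture
def conserved_block():
    """A fully conserved 4-SNP block: single haplotype, entropy 0, NIC 1."""
    dist = HaplotypeDistribution(("ACGT",), (1.0,))
    return Haploblock.from_distribution("C1", "chr2", (10, 400), dist)


def make_env(te=1.26, mu_tilde=1.0):
    return EnvironmentState.from_te(te, mu_tilde)


def random_dirichlet_block(rng, n, k=None, block_id="R", chrom="chrR",
                           start=1):
    """A random block: k of the 2^n haplotypes with Dirichlet frequencies."""
    from gendyn.simulate import _assemble_block, _block_sites, _distinct_ints

    space = 2 ** n
    k = k or min(8, space)
    codes = _distinct_ints(rng, space, min(k, space))
    freqs = rng.dirichlet(np.full(len(codes), 0.8))
    keep = freqs > 1e-9
    codes, freqs = codes[keep], freqs[keep] / freqs[keep].sum()
    pairs = _block_sites(rng, chrom, block_id, range(n))
    return _assemble_block(block_id, chrom, start, n, codes, freqs, pairs)
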
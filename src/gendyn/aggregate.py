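"""Population-level summaries over a GenomeModel: per-block energy spectra,
NIC histograms, block-size regressions, region energy sums and sign counts.

These are the whole-chromosome views: the energy spectrum lists every block's
NIC and potential along the chromosome (an inverted-Manhattan-style profile
when plotted), the block-size fit regresses block potential on the number of
SNP locations (for fully conserved large blocks its slope is the fixing
potential), and region sums total the potentials of the blocks inside a
genomic interval such as the MHC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats

from . import energetics, infometrics
from .model import (BlockReport, EnvironmentState, GenomeModel, GendynError,
                    ValidationError)

#: |potential| below this counts as exactly balanced in sign_counts
ZERO_TOL = 1e-12


@dataclass(frozen=True)
class SpectrumRow:
    """One block of the genomic energy spectrum."""

    block_id: str
    chrom: str
    midpoint: float
    n: int
    nic: float
    block_potential_GEU: float


@dataclass(frozen=True)
class SizeFit:
    """OLS fit of block potential against block size n."""

    slope_GEU_per_site: float
    intercept_GEU: float
    slope_stderr: float
    min_n: int
    n_blocks_fitted: int


def energy_spectrum(model: GenomeModel, env: EnvironmentState,
                    count_monomorphic: bool = False) -> List[SpectrumRow]:
    """One row per block, ordered by (chrom, midpoint)."""
    rows = []
    for block in model.blocks:
        n = block.effective_n(count_monomorphic)
        rows.append(SpectrumRow(
            block_id=block.block_id,
            chrom=block.chrom,
            midpoint=0.5 * (block.span[0] + block.span[1]),
            n=n,
            nic=infometrics.nic_block(block.distribution, n),
            block_potential_GEU=energetics.block_potential(
                block, env, count_monomorphic),
        ))
    rows.sort(key=lambda r: (r.chrom, r.midpoint, r.block_id))
    return rows


def sign_counts(spectrum: Sequence[SpectrumRow]) -> Tuple[int, int, int]:
    """Partition the spectrum into (positive, negative, zero) potentials;
    zero means |mu| < 1e-12."""
    pos = sum(1 for r in spectrum if r.block_potential_GEU >= ZERO_TOL)
    neg = sum(1 for r in spectrum if r.block_potential_GEU <= -ZERO_TOL)
    return pos, neg, len(spectrum) - pos - neg


def nic_histogram(model: GenomeModel, bin_width: float = 0.05,
                  count_monomorphic: bool = False
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Histogram of block NIC values over [0, 1].

    Bins are right-open except the last (which includes NIC = 1), so the
    counts always sum to the number of blocks.  Returns (counts, edges).
    """
    if not (0.0 < bin_width <= 1.0):
        raise ValidationError(f"bin width must lie in (0,1], got {bin_width}")
    edges = np.arange(0.0, 1.0, bin_width)
    edges = np.append(edges, 1.0)
    nics = [infometrics.nic_block(b.distribution,
                                  b.effective_n(count_monomorphic))
            for b in model.blocks]
    counts, _ = np.histogram(nics, bins=edges)
    return counts, edges


def blocksize_fit(spectrum: Sequence[SpectrumRow], min_n: int = 50) -> SizeFit:
    """Ordinary least squares of block potential on block size n, restricted
    to blocks with n >= min_n (potential per SNP is only stable for large
    blocks)."""
    pts = [(r.n, r.block_potential_GEU) for r in spectrum if r.n >= min_n]
    if len(pts) < 2 or len({n for n, _ in pts}) < 2:
        raise GendynError(
            f"block-size fit needs >= 2 blocks with distinct n >= {min_n}; "
            f"got {len(pts)}")
    x = np.array([n for n, _ in pts], dtype=float)
    y = np.array([mu for _, mu in pts], dtype=float)
    res = stats.linregress(x, y)
    return SizeFit(slope_GEU_per_site=float(res.slope),
                   intercept_GEU=float(res.intercept),
                   slope_stderr=float(res.stderr),
                   min_n=min_n, n_blocks_fitted=len(pts))


def region_energy_sum(model: GenomeModel, env: EnvironmentState,
                      chrom: str, start: int, end: int,
                      include_partial: bool = False,
                      count_monomorphic: bool = False
                      ) -> Tuple[float, int]:
    """Total block potential over [start, end] on *chrom* (1-based inclusive)
    and the number of blocks counted.

    By default only fully contained blocks count (no double counting across
    adjacent regions); ``include_partial`` switches to any-overlap inclusion.
    """
    if start > end:
        raise ValidationError(f"region start {start} > end {end}")
    if chrom not in model.chromosomes:
        raise GendynError(f"unknown chromosome {chrom!r}")
    total, count = 0.0, 0
    for block in model.blocks:
        if block.chrom != chrom:
            continue
        b0, b1 = block.span
        if include_partial:
            hit = b0 <= end and b1 >= start
        else:
            hit = b0 >= start and b1 <= end
        if hit:
            total += energetics.block_potential(block, env, count_monomorphic)
            count += 1
    return total, count


def block_reports(model: GenomeModel, env: EnvironmentState,
                  count_monomorphic: bool = False) -> List[BlockReport]:
    """Full per-block report rows (entropy, NIC, block and haplotype
    potentials), in model order."""
    reports = []
    for block in model.blocks:
        n = block.effective_n(count_monomorphic)
        summ = infometrics.entropy_summary(block.distribution, n)
        pots = energetics.haplotype_potentials(block, env, count_monomorphic)
        reports.append(BlockReport(
            block_id=block.block_id,
            n=n,
            n_total=block.n_total,
            n_dynamic=block.n_dynamic,
            entropy_bits=summ.s_bits,
            nic=summ.nic,
            block_potential_GEU=energetics.block_potential(
                block, env, count_monomorphic),
            haplotype_potentials=[(ap.label, ap.frequency, ap.potential_GEU)
                                  for ap in pots],
        ))
    return reports
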
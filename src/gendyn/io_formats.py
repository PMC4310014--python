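"""Readers and writers bridging standard formats to the domain model.

Supported inputs: phased VCF (via cyvcf2), BED or Haploview-style block
listings, and TSV haplotype-frequency tables.  Outputs are TSV reports.
Internal coordinates are 1-based inclusive (the VCF/HapMap convention);
BED's 0-based half-open spans are converted on read and write.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .model import (GenomeModel, GendynError, Haploblock,
                    HaplotypeDistribution, SNPSite, ValidationError)

log = logging.getLogger("gendyn")

#: allele-index code for a missing call in a HaplotypeMatrix
MISSING = -1

#: significant digits for report TSVs (reproducible diffs)
FLOAT_FMT = "%.9g"
#: full-precision format for frequency tables (round-trip to 1e-9 and below)
EXACT_FMT = "%.17g"


class ParseError(GendynError):
    """A file could not be interpreted in any supported dialect."""


@dataclass(frozen=True)
class SiteRecord:
    """One column of a HaplotypeMatrix: a bi-allelic SNP location."""

    chrom: str
    pos: int  # 1-based
    site_id: str
    alleles: Tuple[str, str]


@dataclass
class HaplotypeMatrix:
    """Phased haplotypes: two strand rows per diploid sample.

    ``genotypes`` is a (2 * n_samples, n_sites) int8 array of allele indices
    into each site's allele pair; missing calls are ``MISSING``.  Strands of
    sample ``i`` are rows ``2*i`` and ``2*i + 1``.
    """

    samples: List[str]
    sites: List[SiteRecord]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (2 * len(self.samples), len(self.sites)):
            raise ValidationError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"2x{len(self.samples)} strands x {len(self.sites)} sites")

    @property
    def n_strands(self) -> int:
        return self.genotypes.shape[0]

    @property
    def strand_ids(self) -> List[str]:
        return [f"{s}_{k}" for s in self.samples for k in (1, 2)]


@dataclass(frozen=True)
class BlockDef:
    """A haploblock interval, 1-based inclusive."""

    block_id: str
    chrom: str
    start: int
    end: int


# ---------------------------------------------------------------------------
# phased VCF
# ---------------------------------------------------------------------------

def read_phased_vcf(path: Union[str, Path], strict: bool = True,
                    drop_multiallelic: bool = False) -> HaplotypeMatrix:
    """Read a phased VCF into a HaplotypeMatrix.

    Only bi-allelic SNP records are accepted; multi-allelic or indel records
    raise unless ``drop_multiallelic`` (then they are excluded with a logged
    warning).  Heterozygous unphased genotypes ("0/1") raise in strict mode;
    otherwise the whole record is dropped.  Homozygous calls are accepted
    regardless of separator (their phase is unambiguous), as are missing
    calls ("./."), which become :data:`MISSING`.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    sites: List[SiteRecord] = []
    columns: List[np.ndarray] = []
    for v in vcf:
        label = f"{v.CHROM}:{v.POS}"
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            if drop_multiallelic:
                log.warning("dropping non-bi-allelic-SNP record %s", label)
                continue
            raise ValidationError(
                f"record {label} is not a bi-allelic SNP "
                "(use drop_multiallelic to exclude such records)")
        col = np.empty(2 * len(samples), dtype=np.int8)
        ok = True
        for i, gt in enumerate(v.genotypes):
            a, b, phased = gt[0], gt[1], gt[-1]
            if a >= 0 and b >= 0 and a != b and not phased:
                if strict:
                    raise ValidationError(
                        f"unphased heterozygous genotype for sample "
                        f"{samples[i]} at record {label}")
                log.warning("dropping record %s: unphased genotype for "
                            "sample %s", label, samples[i])
                ok = False
                break
            col[2 * i] = a if a >= 0 else MISSING
            col[2 * i + 1] = b if b >= 0 else MISSING
        if not ok:
            continue
        sites.append(SiteRecord(v.CHROM, v.POS, v.ID or label,
                                (v.REF, v.ALT[0])))
        columns.append(col)
    geno = (np.stack(columns, axis=1) if columns
            else np.empty((2 * len(samples), 0), dtype=np.int8))
    return HaplotypeMatrix(samples, sites, geno)


def write_phased_vcf(path: Union[str, Path], matrix: HaplotypeMatrix) -> None:
    """Write a HaplotypeMatrix as a minimal phased VCF (v4.2 text)."""
    path = Path(path)
    chroms = dict.fromkeys(s.chrom for s in matrix.sites)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gendyn\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description='
                 '"Genotype">\n')
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        order = sorted(range(len(matrix.sites)),
                       key=lambda j: (matrix.sites[j].chrom,
                                      matrix.sites[j].pos))
        for j in order:
            site = matrix.sites[j]
            calls = []
            for i in range(len(matrix.samples)):
                a, b = matrix.genotypes[2 * i, j], matrix.genotypes[2 * i + 1, j]
                sa = "." if a == MISSING else str(int(a))
                sb = "." if b == MISSING else str(int(b))
                calls.append(f"{sa}|{sb}")
            fh.write(f"{site.chrom}\t{site.pos}\t{site.site_id}\t"
                     f"{site.alleles[0]}\t{site.alleles[1]}\t.\tPASS\t.\tGT\t"
                     + "\t".join(calls) + "\n")


# ---------------------------------------------------------------------------
# block definitions: BED or Haploview-style listings
# ---------------------------------------------------------------------------

_HAPLOVIEW_RE = re.compile(
    r"^BLOCK\s+(?P<id>\w+)[.:]?\s*(?:MARKERS:)?\s*(?P<markers>[\d\s]+)$",
    re.IGNORECASE)


def read_block_definitions(
        path: Union[str, Path],
        marker_map: Optional[Sequence[Tuple[str, int]]] = None
) -> List[BlockDef]:
    """Read haploblock intervals from a BED file or a Haploview-style block
    listing ("BLOCK k. MARKERS: i j ..."), auto-detected.

    BED spans (0-based half-open) are converted to 1-based inclusive.  The
    Haploview dialect lists 1-based marker indices and needs ``marker_map``,
    the ordered (chrom, pos) of every marker.  Overlapping blocks on one
    chromosome are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith(("#", "track"))]
    if not lines:
        raise ParseError(f"{path}: no block definitions found")

    blocks: List[BlockDef] = []
    if lines[0].upper().startswith("BLOCK"):
        if marker_map is None:
            raise ParseError(
                f"{path}: Haploview-style listing needs a marker map "
                "(ordered chrom/pos of every marker)")
        for ln in lines:
            m = _HAPLOVIEW_RE.match(ln)
            if not m:
                raise ParseError(f"{path}: unrecognised Haploview line: {ln!r}")
            idx = [int(tok) for tok in m.group("markers").split()]
            if not idx:
                raise ParseError(f"{path}: block {m.group('id')} lists no "
                                 "markers")
            try:
                positions = [marker_map[i - 1] for i in idx]
            except IndexError:
                raise ParseError(
                    f"{path}: block {m.group('id')} references a marker "
                    f"index beyond the map ({max(idx)} > {len(marker_map)})")
            chroms = {c for c, _ in positions}
            if len(chroms) != 1:
                raise ParseError(f"{path}: block {m.group('id')} spans "
                                 "multiple chromosomes")
            pos = [p for _, p in positions]
            blocks.append(BlockDef(f"B{m.group('id')}", chroms.pop(),
                                   min(pos), max(pos)))
    else:
        for ln in lines:
            fields = ln.split()
            if len(fields) < 3:
                raise ParseError(f"{path}: unrecognised BED line: {ln!r}")
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}: non-integer BED coordinates in "
                                 f"{ln!r}")
            if end0 <= start0:
                raise ParseError(f"{path}: empty BED interval in {ln!r}")
            block_id = fields[3] if len(fields) > 3 else \
                f"{fields[0]}:{start0 + 1}-{end0}"
            blocks.append(BlockDef(block_id, fields[0], start0 + 1, end0))

    by_chrom: dict = {}
    for b in blocks:
        by_chrom.setdefault(b.chrom, []).append(b)
    for chrom, bs in by_chrom.items():
        bs = sorted(bs, key=lambda b: (b.start, b.end))
        for prev, cur in zip(bs, bs[1:]):
            if cur.start <= prev.end:
                raise ValidationError(
                    f"blocks {prev.block_id} and {cur.block_id} overlap on "
                    f"{chrom}")
    return blocks


def write_block_definitions(path: Union[str, Path],
                            blocks: Sequence[BlockDef]) -> None:
    """Write blocks as 4-column BED (converting back to 0-based half-open)."""
    with Path(path).open("w") as fh:
        for b in blocks:
            fh.write(f"{b.chrom}\t{b.start - 1}\t{b.end}\t{b.block_id}\n")


# ---------------------------------------------------------------------------
# matrix + blocks -> GenomeModel
# ---------------------------------------------------------------------------

def build_genome_model(matrix: HaplotypeMatrix,
                       blocks: Sequence[BlockDef],
                       count_monomorphic: bool = False,
                       missing_policy: str = "strand") -> GenomeModel:
    """Assemble a GenomeModel from phased data and block intervals.

    Haplotype strings are formed per block from the strand rows covering the
    block's sites; frequencies are strand counts over complete strands.
    Sites outside every block become unlinked SNPs.  ``missing_policy``:
    "strand" (default) excludes a strand only from blocks where it has a
    missing call; "sample" excludes both strands of any sample with a missing
    call anywhere.  Monomorphic unlinked sites are kept only under
    ``count_monomorphic`` (they are not dynamic degrees of freedom).
    """
    if missing_policy not in ("strand", "sample"):
        raise ValidationError(f"unknown missing policy {missing_policy!r}")
    geno = matrix.genotypes
    if missing_policy == "sample":
        bad = np.unique(np.nonzero(geno == MISSING)[0] // 2)
        if bad.size:
            log.warning("excluding %d sample(s) with missing calls", bad.size)
            keep = np.ones(geno.shape[0], dtype=bool)
            keep[2 * bad] = keep[2 * bad + 1] = False
            geno = geno[keep]
            if geno.shape[0] == 0:
                raise GendynError("no complete samples left")

    pos_index = {(s.chrom, s.pos): j for j, s in enumerate(matrix.sites)}
    assigned: set = set()
    built_blocks: List[Haploblock] = []
    for bd in blocks:
        cols = sorted(j for (chrom, pos), j in pos_index.items()
                      if chrom == bd.chrom and bd.start <= pos <= bd.end)
        if not cols:
            raise GendynError(
                f"block {bd.block_id} covers no site of the input matrix")
        overlap = assigned.intersection(cols)
        if overlap:
            raise ValidationError(
                f"block {bd.block_id} shares sites with another block")
        assigned.update(cols)

        sub = geno[:, cols]
        complete = ~(sub == MISSING).any(axis=1)
        n_excluded = int((~complete).sum())
        if n_excluded:
            log.warning("block %s: excluding %d strand(s) with missing "
                        "calls", bd.block_id, n_excluded)
        sub = sub[complete]
        if sub.shape[0] == 0:
            raise GendynError(
                f"block {bd.block_id} has no complete strand")

        uniq, counts = np.unique(sub, axis=0, return_counts=True)
        site_recs = [matrix.sites[j] for j in cols]
        haps = ["".join(site_recs[k].alleles[row[k]]
                        for k in range(len(cols))) for row in uniq]
        dist = HaplotypeDistribution.from_counts(dict(zip(haps, counts)))

        # per-site marginal allele frequencies over the counted strands
        total = sub.shape[0]
        block_sites = []
        dynamic = 0
        for k, rec in enumerate(site_recs):
            n_alt = int((sub[:, k] == 1).sum())
            p_alt = n_alt / total
            if 0 < n_alt < total:
                dynamic += 1
            block_sites.append(SNPSite(rec.site_id, rec.chrom, rec.pos,
                                       rec.alleles, (1.0 - p_alt, p_alt)))
        n_total = len(cols)
        n_dynamic = dynamic or n_total  # fully monomorphic block fallback
        built_blocks.append(Haploblock(bd.block_id, bd.chrom,
                                       (bd.start, bd.end),
                                       tuple(block_sites), n_total,
                                       n_dynamic, dist))

    unlinked: List[SNPSite] = []
    for j, rec in enumerate(matrix.sites):
        if j in assigned:
            continue
        col = geno[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            log.warning("unlinked site %s has no called strand; skipped",
                        rec.site_id)
            continue
        p_alt = float((col == 1).sum()) / col.size
        if p_alt in (0.0, 1.0) and not count_monomorphic:
            log.debug("unlinked site %s is monomorphic; skipped", rec.site_id)
            continue
        unlinked.append(SNPSite(rec.site_id, rec.chrom, rec.pos,
                                rec.alleles, (1.0 - p_alt, p_alt)))

    return GenomeModel(tuple(built_blocks), tuple(unlinked))


# ---------------------------------------------------------------------------
# frequency tables and reports
# ---------------------------------------------------------------------------

def read_frequency_table(path: Union[str, Path]) -> GenomeModel:
    """Read per-block haplotype frequencies from TSV.

    Required columns: block_id, haplotype, frequency.  Optional: chrom,
    start, end (1-based inclusive); blocks without coordinates get synthetic
    non-overlapping spans on chromosome "un".  Frequencies of each block
    must sum to 1 (tolerance 1e-6).
    """
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"block_id": str, "haplotype": str})
    needed = {"block_id", "haplotype", "frequency"}
    if not needed.issubset(df.columns):
        raise ParseError(f"{path}: frequency table needs columns {needed}")
    has_coords = {"chrom", "start", "end"}.issubset(df.columns)
    blocks: List[Haploblock] = []
    cursor = 1
    for i, (block_id, grp) in enumerate(df.groupby("block_id", sort=False)):
        total = float(grp["frequency"].sum())
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(
                f"block {block_id}: frequencies sum to {total:.9g}, not 1")
        dist = HaplotypeDistribution.from_freqs(
            [str(h) for h in grp["haplotype"]],
            [float(f) for f in grp["frequency"]])
        if has_coords:
            chrom = str(grp["chrom"].iloc[0])
            span = (int(grp["start"].iloc[0]), int(grp["end"].iloc[0]))
        else:
            chrom = "un"
            span = (cursor, cursor + dist.n_sites - 1)
            cursor += dist.n_sites + 1
        blocks.append(Haploblock.from_distribution(str(block_id), chrom,
                                                   span, dist))
    if not blocks:
        raise ParseError(f"{path}: empty frequency table")
    return GenomeModel(tuple(blocks), ())


def write_frequency_table(path: Union[str, Path], model: GenomeModel,
                          header_lines: Sequence[str] = ()) -> None:
    """Write block haplotype frequencies (and unlinked allele frequencies as
    1-site blocks prefixed "snp:") at full precision for lossless
    round-trips."""
    rows = []
    for b in model.blocks:
        for h, p in b.distribution.items():
            rows.append((b.block_id, b.chrom, b.span[0], b.span[1], h, p))
    for s in model.unlinked:
        for a, p in zip(s.alleles, s.freqs):
            if p > 0:
                rows.append((f"snp:{s.site_id}", s.chrom, s.pos, s.pos, a, p))
    df = pd.DataFrame(rows, columns=["block_id", "chrom", "start", "end",
                                     "haplotype", "frequency"])
    _write_tsv(path, df, header_lines, float_format=EXACT_FMT)


def write_reports(path: Union[str, Path], reports: Sequence,
                  header_lines: Sequence[str] = ()) -> None:
    """Write BlockReport rows as a long-format TSV: one line per haplotype,
    block-level columns repeated."""
    rows = []
    for r in reports:
        for hap, freq, pot in r.haplotype_potentials:
            rows.append((r.block_id, r.n, r.n_total, r.n_dynamic,
                         r.entropy_bits, r.nic, r.block_potential_GEU,
                         hap, freq, pot))
    df = pd.DataFrame(rows, columns=[
        "block_id", "n", "n_total", "n_dynamic", "entropy_bits", "nic",
        "block_potential_GEU", "haplotype", "frequency", "potential_GEU"])
    _write_tsv(path, df, header_lines)


def _write_tsv(path, df: pd.DataFrame,
               header_lines: Sequence[str] = (),
               float_format: str = FLOAT_FMT) -> None:
    """Write *df* with '# ' provenance lines; *path* may be a path or an
    open text stream."""
    if hasattr(path, "write"):
        for ln in header_lines:
            path.write(f"# {ln}\n")
        df.to_csv(path, sep="\t", index=False, float_format=float_format)
        return
    with Path(path).open("w") as fh:
        for ln in header_lines:
            fh.write(f"# {ln}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=float_format)
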
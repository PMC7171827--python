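"""Readers for VCF / popmap / BED inputs and the dataset variant summary.

Only biallelic SNP records are loaded; multi-allelic and non-SNP records are
skipped with a logged count. Half-missing genotypes ("./1") are treated as
missing. Phased haplotype columns are filled only when every genotype in the
loaded region carries a phase separator.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datamodel import (
    MISSING,
    GeneAnnotation,
    GenotypeMatrix,
    PopulationMap,
    VariantSummary,
)

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")
_TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


def read_vcf(
    path: str, region: tuple[str, int, int] | None = None
) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF (plain or bgzipped) into a GenotypeMatrix.

    ``region`` is (chrom, start, end) with 1-based inclusive bounds, applied
    while streaming (no index required). An empty region yields an empty
    matrix, not an error.
    """
    vcf = VCF(path)
    samples = list(vcf.samples)
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    geno_rows: list[np.ndarray] = []
    hap_rows: list[np.ndarray] = []
    all_phased = True
    skipped = 0

    for v in vcf:
        if (
            len(v.ALT) != 1
            or len(v.REF) != 1
            or len(v.ALT[0]) != 1
            or v.REF not in _BASES
            or v.ALT[0] not in _BASES
        ):
            skipped += 1
            continue
        if region is not None:
            chrom, start, end = region
            if v.CHROM != chrom or not (start <= v.POS <= end):
                continue
        n = len(samples)
        grow = np.empty(n, dtype=np.int8)
        hrow = np.empty(2 * n, dtype=np.int8)
        for j, call in enumerate(v.genotypes):
            a0, a1, phased = call[0], call[1], call[-1]
            if a0 < 0 or a1 < 0:  # fully or half missing -> missing
                grow[j] = MISSING
                hrow[2 * j] = MISSING
                hrow[2 * j + 1] = MISSING
                continue
            grow[j] = a0 + a1
            hrow[2 * j] = a0
            hrow[2 * j + 1] = a1
            if not phased:
                all_phased = False
        chroms.append(v.CHROM)
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        geno_rows.append(grow)
        hap_rows.append(hrow)

    if skipped:
        logger.info("read_vcf: skipped %d multi-allelic/non-SNP records", skipped)

    n_sites = len(positions)
    gm = GenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        genotypes=(
            np.vstack(geno_rows)
            if n_sites
            else np.empty((0, len(samples)), dtype=np.int8)
        ),
        samples=samples,
        haplotypes=(
            np.vstack(hap_rows)
            if (n_sites and all_phased)
            else None
        ),
        skipped_records=skipped,
    )
    # enforce sorted order (cheap no-op on already-sorted files)
    order = np.lexsort((gm.pos, gm.chrom))
    if not np.array_equal(order, np.arange(n_sites)):
        gm = gm.take_sites(order)
    return gm.validate()


def filter_sites(
    gm: GenotypeMatrix,
    max_missing: float = 0.5,
    biallelic_snv_only: bool = True,
    min_mac: int = 1,
) -> GenotypeMatrix:
    """Site screen: missingness, SNV check and minor-allele count, order kept."""
    called = gm.genotypes != MISSING
    n = gm.n_samples
    miss_frac = 1.0 - called.sum(axis=1) / n if n else np.zeros(gm.n_sites)
    alt = np.where(called, gm.genotypes, 0).sum(axis=1)
    total = 2 * called.sum(axis=1)
    mac = np.minimum(alt, total - alt)
    keep = (miss_frac <= max_missing) & (mac >= min_mac)
    if biallelic_snv_only:
        snv = np.array(
            [r in _BASES and a in _BASES and r != a for r, a in zip(gm.ref, gm.alt)]
        )
        keep &= snv
    return gm.take_sites(np.nonzero(keep)[0])


def variant_summary(gm: GenotypeMatrix) -> VariantSummary:
    """Transition/transversion counts and per-sample genotype class counts.

    "Homozygous" is reported as homozygous for the alternative allele.
    """
    for r, a in zip(gm.ref, gm.alt):
        if r not in _BASES or a not in _BASES or r == a:
            raise ValueError(f"non-SNP alleles {r}->{a}")
    is_ts = np.array([(r, a) in _TRANSITIONS for r, a in zip(gm.ref, gm.alt)])
    n_ts = int(is_ts.sum())
    het = pd.Series((gm.genotypes == 1).sum(axis=0), index=gm.samples, name="het")
    hom = pd.Series((gm.genotypes == 2).sum(axis=0), index=gm.samples, name="hom_alt")
    return VariantSummary(
        n_sites=gm.n_sites,
        n_transitions=n_ts,
        n_transversions=gm.n_sites - n_ts,
        per_sample_hom_alt=hom,
        per_sample_het=het,
    )


def read_popmap(path: str) -> PopulationMap:
    """Read a sample<TAB>population[<TAB>role] TSV."""
    assignments: dict[str, str] = {}
    roles: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 columns")
            sample, pop = fields[0], fields[1]
            if sample in assignments:
                raise ValueError(f"{path}:{lineno}: duplicate sample {sample!r}")
            assignments[sample] = pop
            if len(fields) >= 3 and fields[2]:
                role = fields[2]
                prev = roles.get(pop)
                if prev is not None and prev != role:
                    raise ValueError(
                        f"{path}:{lineno}: conflicting roles for population {pop!r}"
                    )
                roles[pop] = role
    return PopulationMap(assignments, roles)


def read_genes(path: str) -> GeneAnnotation:
    """Read a BED4 (chrom, start, end, gene_id) gene annotation."""
    intervals: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED4 requires 4 columns")
            chrom, start, end, gid = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            intervals.append((chrom, start, end, gid))
    return GeneAnnotation(intervals)


def write_window_stats(stats, path: str) -> None:
    """Write a WindowStats table as TSV (chrom, start, end, n_snps, value)."""
    df = stats.to_frame().rename(columns={stats.name: "value"})
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
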
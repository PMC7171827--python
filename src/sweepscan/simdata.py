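"""Three-population diploid SNP simulator with focal-branch sweeps.

Neutral differentiation follows the Balding-Nichols model: each population's
allele frequency at a site is Beta-distributed around the ancestral frequency
p with variance p(1-p)F, so the drift parameter F plays the role of the
expected F_ST between the population and the ancestral pool. Sites are
independent given frequencies (no linkage by design).

A sweep on the focal branch is injected by (a) drawing the focal frequency in
the sweep region with a larger drift parameter F_sweep, and (b) pushing the
drawn frequency toward its nearer boundary so that the focal heterozygosity
2q(1-q) is scaled by a factor pi_scale. Together these deterministically
produce the two signals the downstream scan detects: elevated focal-branch
differentiation (LSBL) and depressed focal diversity (pi-ratio).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .datamodel import MISSING, ConfigError, GeneAnnotation, GenotypeMatrix, PopulationMap
from .sweep import make_windows

# Transition fraction among simulated ref/alt pairs. The default reproduces a
# dataset-level transition/transversion ratio of 2.53, typical of chicken
# whole-genome SNP calls.
DEFAULT_TSTV = 2.53

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


@dataclass
class PopSpec:
    label: str
    role: str  # focal | contrast | outgroup | none
    n_samples: int
    F: float


@dataclass
class SweepRegion:
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    F_sweep: float
    pi_scale: float


@dataclass
class SimConfig:
    n_chrom: int = 4
    chrom_length: int = 5_000_000
    n_snps_per_chrom: int = 20_000
    pops: list[PopSpec] = field(
        default_factory=lambda: [
            PopSpec("YFC", "focal", 25, 0.10),
            PopSpec("NonYellow", "contrast", 25, 0.10),
            PopSpec("RJF", "outgroup", 10, 0.30),
        ]
    )
    sweep_regions: list[SweepRegion] = field(
        default_factory=lambda: [SweepRegion("chr1", 2_000_000, 2_100_000, 0.6, 0.1)]
    )
    ancestral_freq_dist: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.02
    tstv: float = DEFAULT_TSTV
    seed: int = 0

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    def validate(self) -> "SimConfig":
        if self.n_chrom < 1 or self.chrom_length < 1 or self.n_snps_per_chrom < 1:
            raise ConfigError("n_chrom, chrom_length, n_snps_per_chrom must be >= 1")
        if self.n_snps_per_chrom > self.chrom_length:
            raise ConfigError("more SNPs than base pairs requested")
        if not self.pops:
            raise ConfigError("at least one population required")
        for p in self.pops:
            if not (0.0 < p.F < 1.0):
                raise ConfigError(f"population {p.label!r}: F must be in (0,1), got {p.F}")
            if p.n_samples < 1:
                raise ConfigError(f"population {p.label!r}: n_samples must be >= 1")
        focal_F = {p.F for p in self.pops if p.role == "focal"}
        names = set(self.chrom_names)
        for r in self.sweep_regions:
            if r.chrom not in names:
                raise ConfigError(f"sweep region on unknown chromosome {r.chrom!r}")
            if not (0 <= r.start < r.end <= self.chrom_length):
                raise ConfigError(
                    f"sweep region {r.chrom}:{r.start}-{r.end} outside chromosome bounds"
                )
            if not (0.0 < r.F_sweep < 1.0):
                raise ConfigError("F_sweep must be in (0,1)")
            if focal_F and r.F_sweep <= max(focal_F):
                raise ConfigError("F_sweep must exceed the focal population's F")
            if not (0.0 < r.pi_scale <= 1.0):
                raise ConfigError("pi_scale must be in (0,1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0,1)")
        lo, hi = self.ancestral_freq_dist
        if not (0.0 <= lo < hi <= 1.0):
            raise ConfigError("ancestral_freq_dist bounds must satisfy 0 <= lo < hi <= 1")
        return self


@dataclass
class SimFrequencies:
    """Realized per-population allele frequencies (sites x populations)."""

    chrom: np.ndarray
    pos: np.ndarray  # 1-based
    p_anc: np.ndarray
    freqs: np.ndarray
    pop_labels: list[str]


@dataclass
class SimTruth:
    sweep_regions: list[SweepRegion]
    sweep_windows: list[tuple[str, int, int]]
    sweep_genes: list[str]
    freqs: SimFrequencies


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def _beta_params(p: np.ndarray, F: float) -> tuple[np.ndarray, np.ndarray]:
    k = (1.0 - F) / F
    return p * k, (1.0 - p) * k


def _scale_heterozygosity(q: np.ndarray, pi_scale: float) -> np.ndarray:
    """Move q toward its nearer boundary so q'(1-q') = pi_scale * q(1-q)."""
    disc = np.sqrt(np.clip(1.0 - 4.0 * pi_scale * q * (1.0 - q), 0.0, 1.0))
    low = (1.0 - disc) / 2.0
    return np.where(q <= 0.5, low, 1.0 - low)


def simulate_frequencies(config: SimConfig) -> SimFrequencies:
    """Draw ancestral and per-population allele frequencies.

    Inside a sweep region the focal population uses F_sweep instead of its
    neutral F and the drawn frequency is then pushed toward the nearer
    boundary so its expected heterozygosity is scaled by pi_scale.
    """
    config.validate()
    rng = _rng(config.seed, 0)
    lo, hi = config.ancestral_freq_dist

    chroms, positions = [], []
    for name in config.chrom_names:
        pos = np.sort(
            rng.choice(config.chrom_length, size=config.n_snps_per_chrom, replace=False)
        ) + 1
        chroms.append(np.full(config.n_snps_per_chrom, name, dtype=object))
        positions.append(pos)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions)
    S = len(pos)

    p_anc = rng.uniform(lo, hi, size=S)
    freqs = np.empty((S, len(config.pops)))
    for j, popspec in enumerate(config.pops):
        a, b = _beta_params(p_anc, popspec.F)
        q = rng.beta(a, b)
        if popspec.role == "focal":
            for region in config.sweep_regions:
                in_region = (
                    (chrom == region.chrom)
                    & (pos - 1 >= region.start)
                    & (pos - 1 < region.end)
                )
                if not in_region.any():
                    continue
                a_s, b_s = _beta_params(p_anc[in_region], region.F_sweep)
                q_s = rng.beta(a_s, b_s)
                q[in_region] = _scale_heterozygosity(q_s, region.pi_scale)
        freqs[:, j] = q
    return SimFrequencies(chrom, pos, p_anc, freqs, [p.label for p in config.pops])


def simulate_genotypes(
    freqs: SimFrequencies, config: SimConfig
) -> tuple[GenotypeMatrix, PopulationMap]:
    """Sample phased haplotypes and diploid genotypes from the frequencies.

    Each haplotype allele is an independent Bernoulli draw at the sample's
    population frequency; genotype = allele sum; missingness is applied per
    site x sample (both haplotype alleles of a missing genotype are masked).
    """
    config.validate()
    rng = _rng(config.seed, 1)
    S = len(freqs.pos)

    sample_ids: list[str] = []
    assignments: dict[str, str] = {}
    roles: dict[str, str] = {}
    hap_cols = []
    for j, popspec in enumerate(config.pops):
        q = freqs.freqs[:, j][:, None]
        hap_cols.append((rng.random((S, 2 * popspec.n_samples)) < q).astype(np.int8))
        for i in range(popspec.n_samples):
            sid = f"{popspec.label}_{i + 1:02d}"
            sample_ids.append(sid)
            assignments[sid] = popspec.label
        roles[popspec.label] = popspec.role
    haplotypes = np.concatenate(hap_cols, axis=1)
    genotypes = (haplotypes[:, 0::2] + haplotypes[:, 1::2]).astype(np.int8)

    if config.missing_rate > 0:
        miss = rng.random(genotypes.shape) < config.missing_rate
        genotypes[miss] = MISSING
        hap_miss = np.repeat(miss, 2, axis=1)
        haplotypes[hap_miss] = MISSING

    # ref/alt pair per site; transitions drawn at tstv/(tstv+1)
    t_frac = config.tstv / (config.tstv + 1.0)
    ref = rng.choice(np.array(list("ACGT")), size=S)
    is_ts = rng.random(S) < t_frac
    which_tv = rng.integers(0, 2, size=S)
    alt = np.array(
        [
            _TRANSITION[r] if ts else _TRANSVERSIONS[r][w]
            for r, ts, w in zip(ref, is_ts, which_tv)
        ],
        dtype=object,
    )

    gm = GenotypeMatrix(
        chrom=freqs.chrom.copy(),
        pos=freqs.pos.copy(),
        ref=ref.astype(object),
        alt=alt,
        genotypes=genotypes,
        samples=sample_ids,
        haplotypes=haplotypes,
    ).validate()
    return gm, PopulationMap(assignments, roles)


def tile_genes(
    config: SimConfig, gene_length: int = 10_000, gap: int = 5_000
) -> GeneAnnotation:
    """Fixed-length genes tiled with gaps along every chromosome."""
    intervals = []
    for name in config.chrom_names:
        k = 0
        start = 0
        while start + gene_length <= config.chrom_length:
            intervals.append((name, start, start + gene_length, f"{name}_g{k:04d}"))
            start += gene_length + gap
            k += 1
    return GeneAnnotation(intervals)


def build_truth(
    config: SimConfig,
    freqs: SimFrequencies,
    genes: GeneAnnotation,
    window_size: int = 50_000,
    window_step: int = 25_000,
) -> SimTruth:
    """Truth table: scan windows and genes overlapping any sweep region."""
    ws = make_windows(
        {name: config.chrom_length for name in config.chrom_names},
        size=window_size,
        step=window_step,
    )
    windows: list[tuple[str, int, int]] = []
    for c, s, e in zip(ws.chrom, ws.start, ws.end):
        for r in config.sweep_regions:
            if str(c) == r.chrom and s < r.end and r.start < e:
                windows.append((str(c), int(s), int(e)))
                break
    gene_ids = sorted(
        {
            gid
            for (c, s, e, gid) in genes.intervals
            for r in config.sweep_regions
            if c == r.chrom and s < r.end and r.start < e
        }
    )
    return SimTruth(list(config.sweep_regions), windows, gene_ids, freqs)


@dataclass
class SimResult:
    config: SimConfig
    gm: GenotypeMatrix
    popmap: PopulationMap
    genes: GeneAnnotation
    truth: SimTruth


def simulate_dataset(config: SimConfig) -> SimResult:
    """Full simulation: frequencies, genotypes, toy genes and truth table."""
    freqs = simulate_frequencies(config)
    gm, popmap = simulate_genotypes(freqs, config)
    genes = tile_genes(config)
    truth = build_truth(config, freqs, genes)
    return SimResult(config, gm, popmap, genes, truth)


def write_vcf(gm: GenotypeMatrix, path: str, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a minimal VCF v4.2 with phased GT fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan-simdata\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        hap = gm.haplotypes
        for i in range(gm.n_sites):
            if hap is not None:
                alleles = hap[i]
                gts = [
                    ".|."
                    if alleles[2 * j] == MISSING
                    else f"{alleles[2 * j]}|{alleles[2 * j + 1]}"
                    for j in range(gm.n_samples)
                ]
            else:
                code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
                gts = [code[int(g)] for g in gm.genotypes[i]]
            fh.write(
                f"{gm.chrom[i]}\t{gm.pos[i]}\t.\t{gm.ref[i]}\t{gm.alt[i]}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_simulation(result: SimResult, outdir: str) -> dict[str, str]:
    """Write VCF, popmap TSV, gene BED and truth TSV; returns the paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "sim.vcf"),
        "popmap": os.path.join(outdir, "popmap.tsv"),
        "genes": os.path.join(outdir, "genes.bed"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    contigs = {name: result.config.chrom_length for name in result.config.chrom_names}
    write_vcf(result.gm, paths["vcf"], contigs)

    with open(paths["popmap"], "w") as fh:
        for sid in result.gm.samples:
            pop = result.popmap.assignments[sid]
            role = result.popmap.roles.get(pop, "none")
            fh.write(f"{sid}\t{pop}\t{role}\n")

    with open(paths["genes"], "w") as fh:
        for chrom, start, end, gid in result.genes.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{gid}\n")

    with open(paths["truth"], "w") as fh:
        fh.write("record_type\tchrom\tstart\tend\tgene_id\n")
        for r in result.truth.sweep_regions:
            fh.write(f"region\t{r.chrom}\t{r.start}\t{r.end}\t.\n")
        for c, s, e in result.truth.sweep_windows:
            fh.write(f"window\t{c}\t{s}\t{e}\t.\n")
        for gid in result.truth.sweep_genes:
            fh.write(f"gene\t.\t.\t.\t{gid}\n")
    return paths


def read_truth(path: str) -> tuple[list[tuple[str, int, int]], list[tuple[str, int, int]], list[str]]:
    """Read a truth TSV back as (regions, windows, gene ids)."""
    regions, windows, genes = [], [], []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            kind, chrom, start, end, gid = line.rstrip("\n").split("\t")
            if kind == "region":
                regions.append((chrom, int(start), int(end)))
            elif kind == "window":
                windows.append((chrom, int(start), int(end)))
            elif kind == "gene":
                genes.append(gid)
    return regions, windows, genes
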
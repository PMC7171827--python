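"""Windowed selection-scan statistics.

The scan stage computes, over 50-kb sliding windows with 25-kb steps
(configurable), the Weir & Cockerham (1984) F_ST between population pairs,
the locus-specific branch length

    LSBL(A; B, C) = (F_ST(AB) + F_ST(AC) - F_ST(BC)) / 2

for focal population A against contrast B and outgroup C, nucleotide
diversity pi per population (per-bp, window-length denominator), and the
ratio pi_contrast / pi_focal. Candidate sweep windows are the empirical
top quantile (default 99th percentile) of each statistic, annotated with
overlapping genes, and the headline output is the intersection of the two
tests' gene sets.

Per-site F_ST uses the two-population W&C variance components (a, b, c)
from sample sizes, sample allele frequencies and observed heterozygosity;
windows aggregate as a ratio of averages, sum(a) / sum(a + b + c), which is
the standard windowed form. Negative per-window values are kept (clipping
would break the identity LSBL_A + LSBL_B = F_ST(AB)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .datamodel import (
    MISSING,
    GeneAnnotation,
    GenotypeMatrix,
    OutlierSet,
    PopulationMap,
    WindowSet,
    WindowStats,
)

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZE = 50_000
DEFAULT_WINDOW_STEP = 25_000
DEFAULT_QUANTILE = 0.99
DEFAULT_MIN_SNPS = 10
DEFAULT_MIN_PI = 1e-5


def make_windows(
    chrom_lengths: dict[str, int],
    size: int = DEFAULT_WINDOW_SIZE,
    step: int = DEFAULT_WINDOW_STEP,
) -> WindowSet:
    """Sliding windows [k*step, k*step + size) truncated at chromosome ends.

    A window entirely contained in its predecessor (which happens only for
    trailing truncated windows) is dropped, so each chromosome ends with at
    most one window reaching the chromosome end.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    if not (0 < step <= size):
        raise ValueError("step must satisfy 0 < step <= size (gaps would drop sites)")
    chroms, starts, ends = [], [], []
    for chrom, length in chrom_lengths.items():
        prev_end = -1
        k = 0
        while k * step < length:
            s = k * step
            e = min(s + size, length)
            k += 1
            if e <= prev_end:  # contained in previous window
                continue
            chroms.append(chrom)
            starts.append(s)
            ends.append(e)
            prev_end = e
    return WindowSet(
        chrom=np.array(chroms, dtype=object),
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
        size=size,
        step=step,
    )


@dataclass
class SiteFstComponents:
    """Per-site Weir-Cockerham variance components for one population pair."""

    chrom: np.ndarray
    pos: np.ndarray
    a: np.ndarray  # among-population component
    b: np.ndarray  # among-individuals-within-population component
    c: np.ndarray  # within-individual component
    pair: tuple[str, str]

    def theta(self) -> np.ndarray:
        """Per-site F_ST estimate a / (a + b + c); NaN where undefined."""
        denom = self.a + self.b + self.c
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom != 0, self.a / denom, np.nan)


def _pop_counts(gm: GenotypeMatrix, popmap: PopulationMap, pop: str):
    """(n non-missing individuals, alt frequency, het proportion) per site."""
    cols = gm.sample_index(popmap.samples_in(pop))
    g = gm.genotypes[:, cols]
    called = g != MISSING
    n = called.sum(axis=1).astype(float)
    alt = np.where(called, g, 0).sum(axis=1).astype(float)
    het = np.where(called, g == 1, False).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def site_fst(
    gm: GenotypeMatrix, popmap: PopulationMap, popA: str, popB: str
) -> SiteFstComponents:
    """Weir & Cockerham (1984) two-population variance components per site.

    Sites where either population has fewer than 2 non-missing genotypes are
    flagged missing (NaN components).
    """
    n1, p1, h1 = _pop_counts(gm, popmap, popA)
    n2, p2, h2 = _pop_counts(gm, popmap, popB)
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
    ok = (n1 >= 2) & (n2 >= 2)
    a = np.where(ok, a, np.nan)
    b = np.where(ok, b, np.nan)
    c = np.where(ok, c, np.nan)
    return SiteFstComponents(gm.chrom, gm.pos, a, b, c, (popA, popB))


def windowed_fst(
    components: SiteFstComponents,
    ws: WindowSet,
    min_snps: int = DEFAULT_MIN_SNPS,
) -> WindowStats:
    """Ratio-of-averages windowed F_ST: sum(a) / sum(a+b+c) per window.

    Informative sites are those with finite components and a nonzero
    denominator contribution (sites monomorphic across both populations add
    zero to both sums and do not count toward min_snps).
    """
    denom_site = components.a + components.b + components.c
    finite = np.isfinite(denom_site)
    informative = finite & (denom_site != 0)
    a_safe = np.where(finite, components.a, 0.0)
    d_safe = np.where(finite, denom_site, 0.0)

    slices = ws.site_slices(components.chrom, components.pos)
    n_snps = np.zeros(len(ws), dtype=np.int64)
    value = np.full(len(ws), np.nan)
    for w, idx in enumerate(slices):
        if len(idx) == 0:
            continue
        n = int(informative[idx].sum())
        n_snps[w] = n
        if n < min_snps:
            continue
        denom = d_safe[idx].sum()
        if denom != 0:
            value[w] = a_safe[idx].sum() / denom
    name = f"fst_{components.pair[0]}_{components.pair[1]}"
    return WindowStats(ws, n_snps, value, name)


def lsbl(
    fst_AB: WindowStats, fst_AC: WindowStats, fst_BC: WindowStats, branch: str = "A"
) -> WindowStats:
    """Locus-specific branch length for the requested branch.

    LSBL_A = (F_ST(AB) + F_ST(AC) - F_ST(BC)) / 2, and symmetrically
    LSBL_B = (F_ST(AB) + F_ST(BC) - F_ST(AC)) / 2, so that
    LSBL_A + LSBL_B = F_ST(AB) for every window.
    """
    fst_AB.require_aligned(fst_AC, fst_BC)
    if branch == "A":
        value = (fst_AB.value + fst_AC.value - fst_BC.value) / 2.0
    elif branch == "B":
        value = (fst_AB.value + fst_BC.value - fst_AC.value) / 2.0
    else:
        raise ValueError(f"branch must be 'A' or 'B', got {branch!r}")
    n_snps = np.minimum(
        np.minimum(fst_AB.n_snps, fst_AC.n_snps), fst_BC.n_snps
    )
    return WindowStats(fst_AB.windows, n_snps, value, f"lsbl_{branch}")


def windowed_pi(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    pop: str,
    ws: WindowSet,
    min_snps: int = DEFAULT_MIN_SNPS,
) -> WindowStats:
    """Per-bp nucleotide diversity of one population in each window.

    Per site pi = 2 * c_alt * c_ref / (n_h * (n_h - 1)) over non-missing
    haplotypes (allele counts derived from genotypes when unphased), summed
    over sites in the window and divided by the window length in bp;
    monomorphic and absent positions contribute zero. Sites with fewer than
    two non-missing haplotypes are not counted.
    """
    cols = gm.sample_index(popmap.samples_in(pop))
    g = gm.genotypes[:, cols]
    called = g != MISSING
    n_h = 2.0 * called.sum(axis=1)
    c_alt = np.where(called, g, 0).sum(axis=1).astype(float)
    c_ref = n_h - c_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_site = np.where(n_h >= 2, 2.0 * c_alt * c_ref / (n_h * (n_h - 1.0)), 0.0)
    usable = n_h >= 2

    slices = ws.site_slices(gm.chrom, gm.pos)
    n_snps = np.zeros(len(ws), dtype=np.int64)
    value = np.full(len(ws), np.nan)
    for w, idx in enumerate(slices):
        n = int(usable[idx].sum()) if len(idx) else 0
        n_snps[w] = n
        if n < min_snps:
            continue
        length = float(ws.end[w] - ws.start[w])
        value[w] = pi_site[idx].sum() / length
    return WindowStats(ws, n_snps, value, f"pi_{pop}")


def pi_ratio(
    pi_contrast: WindowStats,
    pi_focal: WindowStats,
    min_pi: float = DEFAULT_MIN_PI,
) -> WindowStats:
    """pi_contrast / pi_focal per window; focal pi below min_pi -> missing."""
    pi_contrast.require_aligned(pi_focal)
    floored = np.isfinite(pi_focal.value) & (pi_focal.value < min_pi)
    if floored.any():
        logger.info(
            "pi_ratio: %d windows with focal pi below floor %g set missing",
            int(floored.sum()),
            min_pi,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        value = np.where(floored, np.nan, pi_contrast.value / pi_focal.value)
    n_snps = np.minimum(pi_contrast.n_snps, pi_focal.n_snps)
    return WindowStats(pi_contrast.windows, n_snps, value, "pi_ratio")


def call_outliers(stats: WindowStats, q: float = DEFAULT_QUANTILE) -> OutlierSet:
    """Windows at or above the empirical q-quantile of the statistic.

    The threshold is the linear-interpolation empirical quantile of the
    non-missing values; ties at the threshold are all included.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("quantile q must be in (0,1)")
    ok = np.isfinite(stats.value)
    if not ok.any():
        raise ValueError(f"all {stats.name} window values are missing")
    vals = stats.value[ok]
    recommended = 100.0 / (1.0 - q)
    if len(vals) < recommended:
        warnings.warn(
            f"{stats.name}: only {len(vals)} non-missing windows for q={q} "
            f"(>= {recommended:.0f} recommended)",
            stacklevel=2,
        )
    threshold = float(np.quantile(vals, q))
    if np.all(vals == vals[0]):
        warnings.warn(
            f"{stats.name}: all window values identical; every window ties at "
            "the threshold",
            stacklevel=2,
        )
    member = ok & (stats.value >= threshold)
    df = stats.to_frame().loc[member].rename(columns={stats.name: "value"})
    return OutlierSet(stats.name, threshold, df.reset_index(drop=True))


def annotate_windows(outliers: OutlierSet, genes: GeneAnnotation) -> OutlierSet:
    """Attach all gene ids overlapping any member window by >= 1 bp."""
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, gid in genes.intervals:
        trees.setdefault(chrom, IntervalTree()).addi(start, end, gid)
    hits: set[str] = set()
    for row in outliers.windows.itertuples(index=False):
        tree = trees.get(str(row.chrom))
        if tree is None:
            continue
        hits.update(iv.data for iv in tree.overlap(int(row.start), int(row.end)))
    return OutlierSet(
        outliers.stat_name,
        outliers.threshold_value,
        outliers.windows,
        tuple(sorted(hits)),
    )


def overlap_genes(
    genes_a: set[str] | tuple[str, ...], genes_b: set[str] | tuple[str, ...]
) -> dict[str, list[str]]:
    """Shared and per-test exclusive gene sets of two outlier scans."""
    a, b = set(genes_a), set(genes_b)
    shared = sorted(a & b)
    if not shared:
        logger.info("overlap_genes: no genes shared between the two tests")
    return {
        "shared": shared,
        "only_a": sorted(a - b),
        "only_b": sorted(b - a),
    }


def manhattan_plot(stats: WindowStats, threshold: float | None, out_path: str) -> None:
    """Genome-wide per-window statistic plot with the outlier cut-off line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = stats.to_frame().dropna(subset=[stats.name])
    fig, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    ticks, labels = [], []
    for chrom in pd.unique(df["chrom"]):
        sub = df[df["chrom"] == chrom]
        x = offset + (sub["start"] + sub["end"]) / 2.0
        ax.scatter(x, sub[stats.name], s=4)
        ticks.append(offset + (sub["end"].max() / 2.0 if len(sub) else 0))
        labels.append(str(chrom))
        offset += sub["end"].max() if len(sub) else 0
    if threshold is not None:
        ax.axhline(threshold, ls=":", color="k", lw=1)
    ax.set_xticks(ticks, labels)
    ax.set_ylabel(stats.name)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
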
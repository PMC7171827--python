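"""Region haplotype patterns: population-ordered reference/alternative matrix.

For a genomic interval (e.g. the BCDO2-style yellow-skin region on chicken
chromosome 24), haplotypes are laid out as rows grouped into population
blocks and coded 0 = reference allele, 1 = alternative allele, missing.
Phased input yields two rows per sample. Unphased input falls back to one
genotype-coded row per sample where heterozygous calls become missing — the
honest unphased representation, since no statistical phasing is performed
here. Cells are a pure function of the VCF record and phase; nothing is
imputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix, HaplotypeMatrix, PopulationMap


def extract_haplotypes(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    region: tuple[str, int, int],
    pop_order: list[str] | None = None,
) -> HaplotypeMatrix:
    """Haplotype matrix over ``region`` (chrom, start, end; 1-based inclusive).

    Rows are grouped by ``pop_order`` (default: population order of first
    appearance) and ordered by sample id within each block.
    """
    chrom, start, end = region
    sub = gm.region(chrom, start, end)
    popmap.check_covers(gm.samples)
    present = popmap.populations
    if pop_order is None:
        pop_order = present
    unknown = [p for p in pop_order if p not in present]
    if unknown:
        raise ValueError(f"unknown populations in pop_order: {unknown}")
    not_covered = [p for p in present if p not in pop_order]
    if not_covered:
        raise ValueError(f"pop_order does not cover populations: {not_covered}")

    phased = sub.haplotypes is not None
    rows: list[np.ndarray] = []
    row_labels: list[str] = []
    blocks: dict[str, tuple[int, int]] = {}
    for pop in pop_order:
        r0 = len(rows)
        for sid in sorted(popmap.samples_in(pop)):
            j = gm.samples.index(sid)
            if phased:
                rows.append(sub.haplotypes[:, 2 * j])
                rows.append(sub.haplotypes[:, 2 * j + 1])
                row_labels += [f"{sid}|1", f"{sid}|2"]
            else:
                g = sub.genotypes[:, j]
                row = np.where(g == 0, 0, np.where(g == 2, 1, MISSING)).astype(np.int8)
                rows.append(row)
                row_labels.append(sid)
        blocks[pop] = (r0, len(rows))
    cells = (
        np.vstack(rows) if rows else np.empty((0, sub.n_sites), dtype=np.int8)
    )
    return HaplotypeMatrix(
        chrom=chrom,
        pos=sub.pos,
        ref=sub.ref,
        alt=sub.alt,
        cells=cells,
        row_labels=row_labels,
        blocks=blocks,
        phased=phased,
    ).validate()


def export_haplotype_matrix(
    hm: HaplotypeMatrix, tsv_path: str, png_path: str | None = None
) -> None:
    """Write the matrix as TSV and optionally a two-color heatmap.

    TSV layout: columns ``haplotype``, ``population``, then one column per
    site labelled ``chrom:pos``; cells 0/1 with '.' for missing.
    """
    pop_of_row = [""] * hm.n_rows
    for pop, (r0, r1) in hm.blocks.items():
        for r in range(r0, r1):
            pop_of_row[r] = pop
    site_cols = [f"{hm.chrom}:{p}" for p in hm.pos]
    with open(tsv_path, "w") as fh:
        fh.write("haplotype\tpopulation\t" + "\t".join(site_cols) + "\n")
        for r in range(hm.n_rows):
            vals = ["." if v == MISSING else str(int(v)) for v in hm.cells[r]]
            fh.write(f"{hm.row_labels[r]}\t{pop_of_row[r]}\t" + "\t".join(vals) + "\n")
    if png_path is not None:
        _heatmap(hm, png_path)


def read_haplotype_matrix(tsv_path: str) -> HaplotypeMatrix:
    """Read back a TSV written by :func:`export_haplotype_matrix`."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    site_cols = list(df.columns[2:])
    chrom = site_cols[0].rsplit(":", 1)[0] if site_cols else ""
    pos = np.array([int(c.rsplit(":", 1)[1]) for c in site_cols], dtype=np.int64)
    cells = np.array(
        [[MISSING if v == "." else int(v) for v in row] for row in df[site_cols].values],
        dtype=np.int8,
    ).reshape(len(df), len(site_cols))
    blocks: dict[str, tuple[int, int]] = {}
    for r, pop in enumerate(df["population"]):
        if pop not in blocks:
            blocks[pop] = (r, r + 1)
        else:
            blocks[pop] = (blocks[pop][0], r + 1)
    labels = list(df["haplotype"])
    phased = any("|" in lab for lab in labels)
    n = len(pos)
    return HaplotypeMatrix(
        chrom=chrom,
        pos=pos,
        ref=np.array(["N"] * n, dtype=object),
        alt=np.array(["N"] * n, dtype=object),
        cells=cells,
        row_labels=labels,
        blocks=blocks,
        phased=phased,
    )


def _heatmap(hm: HaplotypeMatrix, png_path: str, gap_rows: int = 2) -> None:
    """Two-color heatmap (grey = reference, indianred = alternative),
    population blocks separated by white gaps."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    blocks = sorted(hm.blocks.items(), key=lambda kv: kv[1][0])
    rows: list[np.ndarray] = []
    gap = np.full((gap_rows, hm.n_sites), 2, dtype=np.int8)  # 2 -> white gap
    labels_at: list[tuple[float, str]] = []
    for i, (pop, (r0, r1)) in enumerate(blocks):
        if i:
            rows.append(gap)
        labels_at.append((sum(len(r) for r in rows) + (r1 - r0) / 2.0, pop))
        block = hm.cells[r0:r1].copy()
        block[block == MISSING] = 3  # 3 -> missing color
        rows.append(block)
    img = np.vstack(rows) if rows else np.empty((0, hm.n_sites))
    cmap = ListedColormap(["lightgrey", "indianred", "white", "black"])
    fig, ax = plt.subplots(figsize=(10, max(2.0, img.shape[0] * 0.06)))
    ax.imshow(img, cmap=cmap, vmin=0, vmax=3, aspect="auto", interpolation="nearest")
    ax.set_yticks([y for y, _ in labels_at], [p for _, p in labels_at])
    ax.set_xlabel(f"{hm.chrom}: {hm.pos[0]:,} - {hm.pos[-1]:,}" if hm.n_sites else "")
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
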
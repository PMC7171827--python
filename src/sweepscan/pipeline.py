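"""Pipeline configuration and stage runners.

Each stage is a plain function over the library so scripts and tests can
call it directly; the click CLI in :mod:`sweepscan.cli` is a thin wrapper.
Defaults mirror the study design: 50-kb windows with 25-kb steps, top 1%
outliers, PLINK-style ``50 10 0.1`` LD pruning and 100 bootstrap replicates.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import yaml

from . import __version__, haplo, simdata, structure, sweep, vcfio
from .datamodel import ConfigError, GenotypeMatrix, PopulationMap

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str = ""
    popmap: str = ""
    genes: str = ""
    outdir: str = "results"
    window_size: int = sweep.DEFAULT_WINDOW_SIZE
    window_step: int = sweep.DEFAULT_WINDOW_STEP
    quantile: float = sweep.DEFAULT_QUANTILE
    min_snps: int = sweep.DEFAULT_MIN_SNPS
    min_pi: float = sweep.DEFAULT_MIN_PI
    max_missing: float = 0.5
    min_mac: int = 1
    prune_window: int = 50
    prune_step: int = 10
    prune_r2: float = 0.1
    pca_components: int = 10
    bootstrap_reps: int = 100
    haplo_region: str = ""  # "chrom:start-end", 1-based inclusive
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if self.window_step > self.window_size:
            # delegate to make_windows for the canonical message
            sweep.make_windows({}, self.window_size, self.window_step)
        if not (0.0 < self.quantile < 1.0):
            raise ConfigError("quantile must be in (0,1)")
        if self.min_snps < 0 or self.bootstrap_reps < 1 or self.pca_components < 1:
            raise ConfigError("min_snps, bootstrap_reps, pca_components out of range")
        return self

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def parse_region(text: str) -> tuple[str, int, int]:
    """Parse 'chrom:start-end' (1-based inclusive, commas allowed)."""
    try:
        chrom, span = text.rsplit(":", 1)
        start, end = (int(x.replace(",", "")) for x in span.split("-"))
    except ValueError as exc:
        raise ConfigError(f"bad region {text!r}; expected chrom:start-end") from exc
    if start > end:
        raise ConfigError(f"bad region {text!r}: start > end")
    return chrom, start, end


def load_inputs(cfg: PipelineConfig) -> tuple[GenotypeMatrix, PopulationMap]:
    for path in (cfg.vcf, cfg.popmap):
        if not os.path.exists(path):
            raise FileNotFoundError(path)
    gm = vcfio.read_vcf(cfg.vcf)
    popmap = vcfio.read_popmap(cfg.popmap)
    popmap.check_covers(gm.samples)
    return gm, popmap


def run_summarize(cfg: PipelineConfig, gm: GenotypeMatrix) -> dict:
    os.makedirs(cfg.outdir, exist_ok=True)
    summary = vcfio.variant_summary(gm)
    summary.to_frame().to_csv(
        os.path.join(cfg.outdir, "per_sample_counts.tsv"), sep="\t"
    )
    out = {
        "n_sites": summary.n_sites,
        "n_transitions": summary.n_transitions,
        "n_transversions": summary.n_transversions,
        "tstv_ratio": summary.tstv_ratio,
    }
    with open(os.path.join(cfg.outdir, "variant_summary.json"), "w") as fh:
        json.dump(out, fh, indent=2)
    logger.info(
        "variant summary: %d SNPs, Ts/Tv = %.3f", summary.n_sites, summary.tstv_ratio
    )
    return out


def run_structure(
    cfg: PipelineConfig, gm: GenotypeMatrix, popmap: PopulationMap
) -> dict:
    os.makedirs(cfg.outdir, exist_ok=True)
    gm = vcfio.filter_sites(gm, cfg.max_missing, True, cfg.min_mac)
    kept = structure.ld_prune(gm, cfg.prune_window, cfg.prune_step, cfg.prune_r2)
    pruned = gm.take_sites(kept)
    logger.info("LD pruning kept %d of %d sites", len(kept), gm.n_sites)

    res = structure.pca(pruned, min(cfg.pca_components, pruned.n_samples - 1))
    import pandas as pd

    coords = pd.DataFrame(
        res.coordinates,
        index=pruned.samples,
        columns=[f"PC{i + 1}" for i in range(res.coordinates.shape[1])],
    )
    coords.insert(0, "population", [popmap.assignments[s] for s in pruned.samples])
    coords.to_csv(os.path.join(cfg.outdir, "pca_coordinates.tsv"), sep="\t")

    root = None
    try:
        root_pop = popmap.outgroup
        root = sorted(popmap.samples_in(root_pop))[0]
    except ConfigError:
        pass
    tree = structure.bootstrap_support(
        pruned,
        structure.pairwise_distance,
        root_label=root,
        n_reps=cfg.bootstrap_reps,
        seed=cfg.seed,
    )
    structure.write_newick(tree, os.path.join(cfg.outdir, "nj_tree.nwk"))
    return {
        "n_pruned_sites": int(pruned.n_sites),
        "explained_variance_fractions": res.explained_variance_fractions.tolist(),
        "tree": tree,
    }


def run_scan(
    cfg: PipelineConfig,
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    plots: bool = True,
) -> dict:
    os.makedirs(cfg.outdir, exist_ok=True)
    gm = vcfio.filter_sites(gm, cfg.max_missing, True, cfg.min_mac)
    A, B, C = popmap.focal, popmap.contrast, popmap.outgroup
    chrom_lengths: dict[str, int] = {}
    for c, p in zip(gm.chrom, gm.pos):
        chrom_lengths[str(c)] = max(chrom_lengths.get(str(c), 0), int(p))
    ws = sweep.make_windows(chrom_lengths, cfg.window_size, cfg.window_step)

    fst = {
        pair: sweep.windowed_fst(
            sweep.site_fst(gm, popmap, *pair), ws, cfg.min_snps
        )
        for pair in ((A, B), (A, C), (B, C))
    }
    lsbl_focal = sweep.lsbl(fst[(A, B)], fst[(A, C)], fst[(B, C)], branch="A")
    pi_focal = sweep.windowed_pi(gm, popmap, A, ws, cfg.min_snps)
    pi_contrast = sweep.windowed_pi(gm, popmap, B, ws, cfg.min_snps)
    ratio = sweep.pi_ratio(pi_contrast, pi_focal, cfg.min_pi)

    genes = vcfio.read_genes(cfg.genes) if cfg.genes else None
    outliers = {}
    for stats in (lsbl_focal, ratio):
        out = sweep.call_outliers(stats, cfg.quantile)
        if genes is not None:
            out = sweep.annotate_windows(out, genes)
        outliers[stats.name] = out

    for stats in (*fst.values(), lsbl_focal, pi_focal, pi_contrast, ratio):
        vcfio.write_window_stats(
            stats, os.path.join(cfg.outdir, f"windows_{stats.name}.tsv")
        )
    for name, out in outliers.items():
        df = out.windows.copy()
        df.to_csv(
            os.path.join(cfg.outdir, f"outliers_{name}.tsv"), sep="\t", index=False
        )
    overlap = sweep.overlap_genes(
        outliers["lsbl_A"].genes, outliers["pi_ratio"].genes
    )
    import pandas as pd

    rows = [("shared", g) for g in overlap["shared"]]
    rows += [("lsbl_only", g) for g in overlap["only_a"]]
    rows += [("pi_ratio_only", g) for g in overlap["only_b"]]
    pd.DataFrame(rows, columns=["category", "gene_id"]).to_csv(
        os.path.join(cfg.outdir, "candidate_genes.tsv"), sep="\t", index=False
    )
    if plots:
        for stats in (lsbl_focal, ratio):
            sweep.manhattan_plot(
                stats,
                outliers[stats.name].threshold_value,
                os.path.join(cfg.outdir, f"manhattan_{stats.name}.png"),
            )
    logger.info(
        "scan: %d LSBL outlier windows (%d genes), %d pi-ratio outlier windows "
        "(%d genes), %d shared genes",
        len(outliers["lsbl_A"]),
        len(outliers["lsbl_A"].genes),
        len(outliers["pi_ratio"]),
        len(outliers["pi_ratio"].genes),
        len(overlap["shared"]),
    )
    return {
        "windows": ws,
        "fst": fst,
        "lsbl": lsbl_focal,
        "pi_focal": pi_focal,
        "pi_contrast": pi_contrast,
        "pi_ratio": ratio,
        "outliers": outliers,
        "overlap": overlap,
    }


def run_haplo(
    cfg: PipelineConfig, gm: GenotypeMatrix, popmap: PopulationMap
) -> dict:
    os.makedirs(cfg.outdir, exist_ok=True)
    if not cfg.haplo_region:
        raise ConfigError("haplo_region not set")
    region = parse_region(cfg.haplo_region)
    hm = haplo.extract_haplotypes(gm, popmap, region)
    tag = f"{region[0]}_{region[1]}_{region[2]}"
    haplo.export_haplotype_matrix(
        hm,
        os.path.join(cfg.outdir, f"haplotypes_{tag}.tsv"),
        os.path.join(cfg.outdir, f"haplotypes_{tag}.png"),
    )
    return {"haplotypes": hm}


def run_all(cfg: PipelineConfig, plots: bool = True) -> dict:
    """summarize -> structure -> scan -> haplo, with a run manifest."""
    cfg.validate()
    gm, popmap = load_inputs(cfg)
    results: dict = {}
    for name, stage in (
        ("summarize", lambda: run_summarize(cfg, gm)),
        ("structure", lambda: run_structure(cfg, gm, popmap)),
        ("scan", lambda: run_scan(cfg, gm, popmap, plots=plots)),
        ("haplo", lambda: run_haplo(cfg, gm, popmap) if cfg.haplo_region else {}),
    ):
        logger.info("stage %s: start", name)
        try:
            results[name] = stage()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    manifest = {
        "sweepscan_version": __version__,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
    }
    with open(os.path.join(cfg.outdir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return results


def demo_sim_config(seed: int = 0) -> simdata.SimConfig:
    """The demo simulation: three chicken-like populations, one strong sweep.

    4 x 5 Mb chromosomes at 4 SNPs/kb give 796 scan windows, so the top 1%
    holds ~8 windows while the single 100-kb sweep contributes 5 truth
    windows — sized so a real sweep signal can fill the outlier set.
    """
    return simdata.SimConfig(seed=seed)


def run_demo(outdir: str, seed: int = 0, plots: bool = True) -> dict:
    """Simulate a dataset with known truth and run the full pipeline on it."""
    sim_cfg = demo_sim_config(seed)
    result = simdata.simulate_dataset(sim_cfg)
    sim_dir = os.path.join(outdir, "sim")
    paths = simdata.write_simulation(result, sim_dir)
    region = sim_cfg.sweep_regions[0]
    cfg = PipelineConfig(
        vcf=paths["vcf"],
        popmap=paths["popmap"],
        genes=paths["genes"],
        outdir=os.path.join(outdir, "pipeline"),
        haplo_region=f"{region.chrom}:{region.start + 1}-{region.end}",
        seed=seed,
    )
    results = run_all(cfg, plots=plots)
    results["sim"] = result
    results["paths"] = paths
    return results
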
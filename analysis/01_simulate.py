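"""Simulate the study-design dataset: three chicken-like populations
(focal yellow-phenotype group, non-yellow contrast group, red-junglefowl-like
outgroup) with one strong selective sweep on the focal branch.

Writes a phased VCF, population map, toy gene BED and sweep truth table
under results/sim/.
"""

import argparse

from sweepscan import pipeline, simdata


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/sim")
    args = ap.parse_args()

    cfg = pipeline.demo_sim_config(args.seed)
    result = simdata.simulate_dataset(cfg)
    paths = simdata.write_simulation(result, args.outdir)

    print(f"simulated {result.gm.n_sites:,} SNPs x {result.gm.n_samples} samples "
          f"({cfg.n_chrom} x {cfg.chrom_length/1e6:.0f} Mb)")
    for r in cfg.sweep_regions:
        print(f"sweep region {r.chrom}:{r.start:,}-{r.end:,} "
              f"(F_sweep={r.F_sweep}, pi_scale={r.pi_scale})")
    print(f"truth: {len(result.truth.sweep_windows)} sweep windows, "
          f"{len(result.truth.sweep_genes)} sweep genes")
    for k, v in paths.items():
        print(f"  {k}: {v}")


if __name__ == "__main__":
    main()
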
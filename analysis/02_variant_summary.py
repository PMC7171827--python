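"""Dataset-level variant summary of the simulated VCF: site count,
transition/transversion ratio and per-sample heterozygous / homozygous-
alternative genotype counts (results/variant_summary.json and
results/per_sample_counts.tsv)."""

import argparse

from sweepscan import pipeline


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--vcf", default="results/sim/sim.vcf")
    ap.add_argument("--popmap", default="results/sim/popmap.tsv")
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()

    cfg = pipeline.PipelineConfig(vcf=args.vcf, popmap=args.popmap, outdir=args.outdir)
    gm, _ = pipeline.load_inputs(cfg)
    out = pipeline.run_summarize(cfg, gm)
    print(f"{out['n_sites']:,} biallelic SNPs")
    print(f"transitions {out['n_transitions']:,}, transversions "
          f"{out['n_transversions']:,}, Ts/Tv = {out['tstv_ratio']:.3f}")


if __name__ == "__main__":
    main()
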
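import numpy as np
import pytest

from sweepscan import simdata
from sweepscan.datamodel import GenotypeMatrix, PopulationMap


def make_gm(genotypes, chrom=None, pos=None, ref=None, alt=None, samples=None,
            haplotypes=None):
    """Small GenotypeMatrix builder for hand-written tables."""
    g = np.asarray(genotypes, dtype=np.int8)
    S, N = g.shape
    return GenotypeMatrix(
        chrom=np.array(chrom if chrom is not None else ["chr1"] * S, dtype=object),
        pos=np.array(pos if pos is not None else np.arange(1, S + 1), dtype=np.int64),
        ref=np.array(ref if ref is not None else ["A"] * S, dtype=object),
        alt=np.array(alt if alt is not None else ["G"] * S, dtype=object),
        genotypes=g,
        samples=list(samples) if samples is not None else [f"s{i}" for i in range(N)],
        haplotypes=None if haplotypes is None else np.asarray(haplotypes, dtype=np.int8),
    )


def two_pop_map(gm, nA, popA="P1", popB="P2", roles=None):
    assignments = {}
    for i, s in enumerate(gm.samples):
        assignments[s] = popA if i < nA else popB
    return PopulationMap(assignments, roles or {})


@pytest.fixture(scope="session")
def sweep_sim():
    """Small three-population dataset with one strong sweep on chr1."""
    cfg = simdata.SimConfig(
        n_chrom=1,
        chrom_length=1_000_000,
        n_snps_per_chrom=4_000,
        sweep_regions=[simdata.SweepRegion("chr1", 400_000, 500_000, 0.6, 0.1)],
        seed=7,
    )
    return simdata.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def neutral_sim():
    """No sweeps; contrast and outgroup share the focal drift level."""
    cfg = simdata.SimConfig(
        n_chrom=1,
        chrom_length=1_000_000,
        n_snps_per_chrom=4_000,
        pops=[
            simdata.PopSpec("YFC", "focal", 25, 0.10),
            simdata.PopSpec("NonYellow", "contrast", 25, 0.10),
            simdata.PopSpec("RJF", "outgroup", 25, 0.10),
        ],
        sweep_regions=[],
        seed=11,
    )
    return simdata.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full `demo` pipeline run on simulated data (shared across tests)."""
    from click.testing import CliRunner

    from sweepscan.cli import main

    outdir = tmp_path_factory.mktemp("demo")
    runner = CliRunner()
    result = runner.invoke(main, ["demo", "--out", str(outdir), "--seed", "0"])
    return outdir, result
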
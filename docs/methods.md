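# Methods

## Problem and design

`sweepscan` implements a genome-scan workflow for detecting selective sweeps
on one branch of a three-population design: a focal population suspected of
recent selection (here a yellow-phenotype chicken group, "YFC"), a contrast
population without the phenotype ("NonYellow"), and an outgroup
(red-junglefowl-like, "RJF"). Two complementary window statistics flag
candidate regions:

* **LSBL** (locus-specific branch length). For window-level pairwise
  F_ST values, `LSBL(A; B, C) = (F_ST(AB) + F_ST(AC) − F_ST(BC)) / 2`
  isolates differentiation accumulated on the focal branch A. By the same
  algebra `LSBL_A + LSBL_B = F_ST(AB)` holds exactly per window, which the
  tests assert to machine precision.
* **π-ratio**, `π_contrast / π_focal` per window: sweeps depress diversity
  in the focal group, inflating the ratio.

Windows are 50 kb sliding with 25 kb steps. Candidate windows are the
empirical top 1% of each statistic; genes overlapping candidate windows by
≥ 1 bp are the per-test candidate gene sets, and the headline output is
their intersection.

## Estimators and numerical choices

**F_ST.** Per site we compute the two-population Weir & Cockerham (1984)
variance components a (among populations), b (among individuals within
populations) and c (within individuals) from sample sizes, sample allele
frequencies and observed heterozygosity, with per-site sample sizes reduced
by missing genotypes; sites where either population has fewer than two
called genotypes are set missing. Windows aggregate as a ratio of averages,
Σa / Σ(a+b+c), over informative sites (finite components, nonzero
denominator contribution — sites monomorphic in both populations contribute
nothing and do not count toward the SNP minimum). Negative per-window values
are **not** clipped: clipping would break the LSBL additivity identity.
Display-level clipping is left to consumers of the tables.

**π.** Per site, π = 2·c_alt·c_ref / (n_h·(n_h−1)) with n_h the number of
non-missing haplotypes (allele counts are derived from genotypes when the
input is unphased; the estimator only needs counts). The window value is the
sum of site π divided by the **window length in bp** (so invariant and
uncounted positions contribute zero), the convention used by windowed-π
tools such as VCFtools; truncated end-of-chromosome windows use their actual
length.

**π-ratio degenerate denominators.** Windows with focal π below a floor
(default 1e−5 per bp) are set missing rather than producing huge or infinite
ratios; the count of floored windows is logged.

**Window bookkeeping.** Windows are `[k·step, k·step+size)` per chromosome,
truncated at the chromosome end. A trailing truncated window that is wholly
contained in its predecessor is dropped, so each chromosome ends with at
most one window reaching the end (a 100-kb chromosome yields exactly three
50/25-kb windows; 1 Mb yields 39).

**Window SNP minimum.** Windows with fewer than `min_snps` (default 10)
informative sites are set missing before quantiles are taken. The minimum
stabilizes window estimates at the SNP densities we simulate; it is
configurable because real datasets differ.

**Outlier calling.** The threshold is the linear-interpolation empirical
quantile (default q = 0.99) of non-missing window values; all windows with
value ≥ threshold are selected, so ties at the threshold are included
(superset behavior). A warning is emitted when the number of non-missing
windows is small relative to 100/(1−q), or when all values tie.

**Population structure.** LD pruning follows the PLINK
`--indep-pairwise 50 10 0.1` scheme: windows of 50 SNPs advancing by 10,
greedily dropping the later site of any pair with squared genotype
correlation above 0.1; missing genotypes are pairwise-excluded and
zero-variance sites have r² = 0 by definition (they can never be pruned
for LD). PCA standardizes dosages GCTA-style — per-site mean imputation of
missing calls, centering by 2p̂, scaling by √(2p̂(1−p̂)), monomorphic sites
excluded — followed by an SVD of the sample matrix; component signs are
fixed by making the largest-magnitude site loading positive. Pairwise
distances are 1 − IBS (IBS = mean over shared sites of (2 − |g_i − g_j|)/2);
the choice of distance is ours, since only "a neighbor-joining tree rooted
to the outgroup" is prescribed by the design we follow. Neighbor joining is
the standard Saitou–Nei Q-criterion agglomeration with deterministic
first-minimum tie-breaking, rooted at the midpoint of the outgroup's pendant
edge. Internal-edge support is the percentage of site-bootstrap replicates
(resampling sites with replacement, default 100 replicates) whose NJ tree
contains the same bipartition. Negative NJ branch-length estimates are kept
in memory but clamped to zero at Newick serialization (topology untouched).

**Haplotype patterns.** For a region of interest (the BCDO2-style view),
haplotypes are rows grouped into population blocks, coded 0 = reference,
1 = alternative, missing. Phased VCFs give two rows per sample taken
directly from the phase columns; unphased input falls back to one
genotype-coded row per sample with heterozygotes set missing — the honest
representation without statistical phasing, which is out of scope. Rows are
ordered by sample id within blocks. No imputation is ever performed.

## Synthetic data generator

The generator exists so that every stage is testable with known truth; its
defaults define the demo conditions.

* **Neutral model: Balding–Nichols.** Each population's allele frequency at
  a site is Beta-distributed with mean p (the ancestral frequency) and
  variance p(1−p)F, so the drift parameter F plays the role of the expected
  F_ST against the ancestral pool, and the mean pairwise windowed F_ST
  between two populations sharing drift F recovers ≈ F. This is the
  lightest model that gives a controllable genome-wide differentiation
  level; no coalescent machinery is needed for window statistics on
  independent sites.
* **Sweep injection.** Inside a sweep region the focal population draws its
  frequency with a larger drift parameter `F_sweep` (default 0.6) and the
  drawn frequency q is then pushed deterministically toward its nearer
  boundary so that q′(1−q′) = `pi_scale`·q(1−q) (default 0.1). This
  produces, by construction, the two signals the scan detects — elevated
  focal-branch differentiation and ~10× depressed focal heterozygosity —
  without forward simulation of selection.
* **Ancestral frequencies** are Uniform(0.05, 0.95) so monomorphic sites do
  not dominate; sites that end up monomorphic after sampling are retained
  in the VCF and removed by the downstream minor-allele-count filter, which
  exercises that filter.
* **Ref/alt alleles** are drawn with a transition fraction giving a
  dataset-level Ts/Tv of 2.53, typical of chicken whole-genome SNP calls,
  so the variant-summary stage reproduces a realistic ratio.
* **Genotypes** are two independent Bernoulli haplotype draws per
  individual; missingness (default 2%) is applied per site × sample.
  Sites are independent given frequencies: there is **no linkage
  disequilibrium by design**, no recombination map, and no mutation model
  beyond biallelic SNPs. Consequently the LD-pruning stage sees only
  sampling-noise r², and passing tests say nothing about haplotype-based
  statistics on real data.
* **Toy genes** are 10-kb intervals tiled with 5-kb gaps, so window→gene
  annotation has both hit and miss cases; genes overlapping a sweep region
  are recorded as truth.
* **Demo sizing.** The demo simulates 4 × 5 Mb chromosomes at 4 SNPs/kb
  (80,000 SNPs; 25 focal + 25 contrast + 10 outgroup diploids; outgroup
  drift 0.3) with one 100-kb sweep. This yields 796 scan windows, so the
  top 1% holds ~8 windows while the sweep contributes 5 truth windows —
  large enough that a real signal can fill the outlier set, small enough to
  run in seconds. With ~200 SNPs per window, neutral window noise is far
  below the injected sweep signal for both statistics.
* **Determinism.** All randomness flows from one integer seed through named
  `SeedSequence` streams; identical configurations produce byte-identical
  output files.

## What the simulation does and does not validate

Passing the end-to-end tests shows that the estimators are implemented
correctly, that their windowed aggregation and outlier logic behave as
specified, and that the pipeline recovers planted sweeps under idealized
conditions (independent sites, known population structure, no
ascertainment bias, no sequencing error model beyond random missingness).
It does not demonstrate power on real data, where LD, variable SNP density,
background selection and demographic history all matter; nor does it
validate haplotype-phase quality, since phased haplotypes are simulated
directly.

## Limitations

* Two-population W&C components only; no multi-population estimator.
* No haplotype-based selection statistics (iHS, XP-EHH).
* The NJ stage is intended for tens to a few hundred samples (O(n³)).
* Gene annotation is plain interval overlap against a BED; no
  transcript-aware consequence annotation.
* The unphased haplotype-matrix fallback discards heterozygote information
  by construction.
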
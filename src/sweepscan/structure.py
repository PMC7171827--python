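"""Population-structure stage: LD pruning, PCA, 1-IBS distances, NJ tree.

LD pruning follows the PLINK ``--indep-pairwise 50 10 0.1`` scheme: sliding
windows of 50 SNPs advancing by 10, greedily dropping the later member of
any pair whose squared genotype correlation exceeds 0.1. PCA standardizes
dosages GCTA-style, (g - 2p) / sqrt(2p(1-p)) with per-site mean imputation
of missing calls. The neighbor-joining tree (Saitou-Nei Q-criterion,
deterministic first-minimum tie-breaking) is built on 1 - IBS distances and
rooted at the midpoint of the outgroup's pendant edge; internal-edge support
comes from site bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .datamodel import MISSING, DistanceMatrix, GenotypeMatrix


def _window_r2(g: np.ndarray) -> np.ndarray:
    """Pairwise-complete squared correlation between genotype columns.

    ``g`` is (n_sites_in_window, n_samples) with MISSING = -1. Pairs where
    either site has zero variance over the shared samples get r^2 = 0.
    """
    m = (g != MISSING).astype(np.float64)
    g0 = np.where(g == MISSING, 0, g).astype(np.float64)
    n = m @ m.T
    sx = g0 @ m.T  # sx[i, j] = sum of g_i over samples shared with j
    sxy = g0 @ g0.T
    sxx = (g0 * g0) @ m.T
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_x = sx / n
        mean_y = mean_x.T
        cov = sxy / n - mean_x * mean_y
        var_x = sxx / n - mean_x**2
        var_y = var_x.T
        r2 = cov**2 / (var_x * var_y)
    r2 = np.where(np.isfinite(r2), r2, 0.0)
    r2[n < 2] = 0.0
    return r2


def ld_prune(
    gm: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 10,
    r2_max: float = 0.1,
) -> np.ndarray:
    """Greedy windowed LD pruning; returns sorted retained site indices."""
    keep = np.ones(gm.n_sites, dtype=bool)
    # per-chromosome blocks
    if gm.n_sites == 0:
        return np.empty(0, dtype=int)
    change = np.nonzero(gm.chrom[1:] != gm.chrom[:-1])[0] + 1
    block_starts = np.concatenate(([0], change))
    block_ends = np.concatenate((change, [gm.n_sites]))
    for b0, b1 in zip(block_starts, block_ends):
        for w0 in range(b0, b1, step_snps):
            idx = np.nonzero(keep[w0 : min(w0 + window_snps, b1)])[0] + w0
            if len(idx) < 2:
                continue
            r2 = _window_r2(gm.genotypes[idx])
            local_keep = np.ones(len(idx), dtype=bool)
            pos = np.arange(len(idx))
            for i in range(len(idx) - 1):
                if local_keep[i]:
                    local_keep &= ~((r2[i] > r2_max) & (pos > i))
            keep[idx[~local_keep]] = False
    return np.nonzero(keep)[0]


@dataclass
class PCAResult:
    coordinates: np.ndarray  # (n_samples, n_components) PC scores
    explained_variance_fractions: np.ndarray
    n_sites_used: int


def pca(gm: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    """GCTA-style PCA of the standardized genotype matrix.

    Missing genotypes are mean-imputed per site before standardization;
    monomorphic sites are excluded. Component signs are fixed by making the
    largest-magnitude site loading positive.
    """
    g = gm.genotypes.astype(np.float64)
    called = gm.genotypes != MISSING
    n_called = called.sum(axis=1)
    alt = np.where(called, g, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * n_called)
    usable = (n_called > 0) & (p > 0) & (p < 1)
    g = g[usable]
    p = p[usable]
    mean = 2.0 * p
    g = np.where(called[usable], g, mean[:, None])
    x = (g - mean[:, None]) / np.sqrt(2.0 * p * (1.0 - p))[:, None]

    n_samples = gm.n_samples
    m = x.shape[0]
    if n_components > min(n_samples, m):
        raise ValueError(
            f"n_components={n_components} exceeds min(samples={n_samples}, sites={m})"
        )
    # samples x sites, scaled so singular values^2 are covariance eigenvalues
    u, s, vt = np.linalg.svd(x.T / np.sqrt(m), full_matrices=False)
    ev = s**2
    evf = ev / ev.sum()
    coords = u[:, :n_components] * s[:n_components]
    for k in range(n_components):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            coords[:, k] = -coords[:, k]
    return PCAResult(coords, evf[:n_components], m)


def _ibs_distance(genotypes: np.ndarray, labels: list[str]) -> DistanceMatrix:
    m = (genotypes != MISSING).astype(np.float32)
    a1 = ((genotypes == 1) & (genotypes != MISSING)).astype(np.float32)
    a2 = (genotypes == 2).astype(np.float32)
    shared = m.T @ m
    b01 = ((m - a1 - a2).T @ a1)  # pairs of (dosage 0, dosage 1) sites
    b02 = ((m - a1 - a2).T @ a2)
    b12 = a1.T @ a2
    sumdiff = b01 + b01.T + 2.0 * (b02 + b02.T) + b12 + b12.T
    if (shared == 0).any():
        i, j = np.argwhere(shared == 0)[0]
        raise ValueError(
            f"samples {labels[int(i)]!r} and {labels[int(j)]!r} share no "
            "non-missing sites"
        )
    d = (sumdiff / (2.0 * shared)).astype(np.float64)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(list(labels), d).validate()


def pairwise_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """1 - IBS distance: mean over shared sites of |g_i - g_j| / 2."""
    return _ibs_distance(gm.genotypes, gm.samples)


def nj_tree(dm: DistanceMatrix, root_label: str | None = None) -> TreeNode:
    """Saitou-Nei neighbor joining; optionally rooted at the outgroup edge.

    Tie-breaking is deterministic: the first pair (row-major over the current
    node order) attaining the minimal Q value is joined. With a root label,
    the unrooted tree is rerooted at the midpoint of that taxon's pendant
    edge; otherwise the unrooted (trifurcating-root) tree is returned.
    """
    dm.validate()
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if root_label is not None and root_label not in dm.labels:
        raise ValueError(f"root label {root_label!r} not among taxa")
    if len(set(dm.labels)) != n:
        raise ValueError("duplicate taxon labels")

    nodes = [TreeNode(name=lab) for lab in dm.labels]
    d = dm.d.astype(np.float64).copy()
    while len(nodes) > 2:
        k = len(nodes)
        r = d.sum(axis=1)
        q = (k - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)
        if i > j:
            i, j = j, i
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = d[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = float(li)
        child_j.length = float(lj)
        new = TreeNode(children=[child_i, child_j])
        d_new = (d[i] + d[j] - d[i, j]) / 2.0
        d[i] = d_new
        d[:, i] = d_new
        d[i, i] = 0.0
        keep = [x for x in range(k) if x != j]
        d = d[np.ix_(keep, keep)]
        nodes[i] = new
        del nodes[j]
    # attach the remaining node to the last internal node -> trifurcation
    a, b = nodes
    if a.is_tip():
        a, b = b, a
    b.length = float(d[0, 1])
    a.append(b)
    tree = a
    if root_label is not None:
        tree = tree.root_by_outgroup([root_label])
    return tree


def tree_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical tip-name sets.

    Each internal edge splits the taxa in two; the side not containing the
    alphabetically first taxon is used as the canonical representation, so
    rooted and unrooted versions of the same topology compare equal.
    """
    tips = frozenset(t.name for t in tree.tips())
    ref = min(tips)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        if len(clade) < 2 or len(tips - clade) < 2:
            continue
        out.add(clade if ref not in clade else tips - clade)
    return out


def bootstrap_support(
    gm: GenotypeMatrix,
    dm_builder=pairwise_distance,
    root_label: str | None = None,
    n_reps: int = 100,
    seed: int = 0,
) -> TreeNode:
    """NJ tree with internal-edge support from site bootstrap.

    Sites are resampled with replacement ``n_reps`` times; each replicate's
    distance matrix and NJ tree are rebuilt, and each internal edge of the
    full-data tree gets the percentage of replicates containing the same
    bipartition (stored on ``node.support``).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = nj_tree(dm_builder(gm), root_label=root_label)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree_bipartitions(tree)}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        idx = rng.integers(0, gm.n_sites, size=gm.n_sites)
        rep_gm = gm.take_sites(idx)
        rep_tree = nj_tree(dm_builder(rep_gm), root_label=None)
        for bp in tree_bipartitions(rep_tree):
            if bp in counts:
                counts[bp] += 1
    tips = frozenset(t.name for t in tree.tips())
    ref = min(tips)
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        if len(clade) < 2 or len(tips - clade) < 2:
            node.support = None
            continue
        canon = clade if ref not in clade else tips - clade
        node.support = 100.0 * counts.get(canon, 0) / n_reps
    return tree


def write_newick(tree: TreeNode, path: str, clamp_negative: bool = True) -> None:
    """Serialize to Newick; supports become internal-node labels.

    Negative NJ branch-length estimates are clamped to zero (topology kept).
    """
    out = tree.copy()
    for node in out.traverse():
        if clamp_negative and node.length is not None and node.length < 0:
            node.length = 0.0
    out.write(path)
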
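"""Independent brute-force oracles used only by the test suite.

Every function here deliberately re-derives a quantity with the most direct
method available — scalar loops, exhaustive enumeration, sort-and-slice —
so that the vectorized implementations in sweepscan are checked against
logic that shares no code with them.
"""

from __future__ import annotations

import itertools

import numpy as np

MISSING = -1


def wc_fst_components_longhand(gA: list[int], gB: list[int]) -> tuple[float, float, float]:
    """Two-population Weir & Cockerham (1984) components, scalar transcription.

    ``gA``/``gB`` are diploid dosages in {0,1,2}; -1 entries are dropped.
    Returns (a, b, c).
    """
    gA = [g for g in gA if g != MISSING]
    gB = [g for g in gB if g != MISSING]
    n1, n2 = len(gA), len(gB)
    r = 2
    p1 = sum(gA) / (2 * n1)
    p2 = sum(gB) / (2 * n2)
    h1 = sum(1 for g in gA if g == 1) / n1
    h2 = sum(1 for g in gB if g == 1) / n2

    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def pi_site_enumerated(haplotypes: list[int]) -> float:
    """Mean pairwise difference over all haplotype pairs at one site."""
    h = [x for x in haplotypes if x != MISSING]
    pairs = list(itertools.combinations(h, 2))
    return sum(1 for x, y in pairs if x != y) / len(pairs)


def prune_allpairs(
    genotypes: np.ndarray, window_snps: int, step_snps: int, r2_max: float
) -> list[int]:
    """All-pairs greedy LD pruning oracle with loop-based r^2."""

    def r2(i: int, j: int) -> float:
        xs, ys = [], []
        for gi, gj in zip(genotypes[i], genotypes[j]):
            if gi != MISSING and gj != MISSING:
                xs.append(float(gi))
                ys.append(float(gj))
        if len(xs) < 2:
            return 0.0
        mx, my = sum(xs) / len(xs), sum(ys) / len(ys)
        cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / len(xs)
        vx = sum((x - mx) ** 2 for x in xs) / len(xs)
        vy = sum((y - my) ** 2 for y in ys) / len(ys)
        if vx == 0 or vy == 0:
            return 0.0
        return cov * cov / (vx * vy)

    n = len(genotypes)
    kept = [True] * n
    for w0 in range(0, n, step_snps):
        idx = [i for i in range(w0, min(w0 + window_snps, n)) if kept[i]]
        for ii, i in enumerate(idx):
            if not kept[i]:
                continue
            for j in idx[ii + 1 :]:
                if kept[j] and r2(i, j) > r2_max:
                    kept[j] = False
    return [i for i in range(n) if kept[i]]


def quantile_outliers_sortslice(values: np.ndarray, q: float) -> tuple[float, list[int]]:
    """Sort-based empirical quantile and indices at/above it."""
    vals = sorted(float(v) for v in values if np.isfinite(v))
    n = len(vals)
    h = q * (n - 1)
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    threshold = vals[lo] + (h - lo) * (vals[hi] - vals[lo])
    members = [i for i, v in enumerate(values) if np.isfinite(v) and v >= threshold]
    return threshold, members


def overlap_bruteforce(
    windows: list[tuple[str, int, int]], genes: list[tuple[str, int, int, str]]
) -> set[str]:
    """Exhaustive all-pairs window/gene interval overlap (>= 1 bp)."""
    hits = set()
    for wc, ws, we in windows:
        for gc, gs, ge, gid in genes:
            if wc == gc and ws < ge and gs < we:
                hits.add(gid)
    return hits


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """Random binary tree with positive branch lengths and its distances.

    Returns (newick string, labels, distance matrix). Distances are exact
    path lengths, so NJ must recover the topology and branch lengths.
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    # build by random sequential joining; track children and branch lengths
    nodes = {lab: None for lab in labels}
    lengths: dict[str, float] = {}
    children: dict[str, list[str]] = {}
    active = list(labels)
    counter = 0
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        parent = f"n{counter}"
        counter += 1
        children[parent] = [a, b]
        lengths[a] = float(rng.uniform(0.1, 1.0))
        lengths[b] = float(rng.uniform(0.1, 1.0))
        active = [x for x in active if x not in (a, b)] + [parent]
    a, b = active
    # connect final two by a single edge split across both
    root = "root"
    children[root] = [a, b]
    lengths[a] = float(rng.uniform(0.1, 1.0))
    lengths[b] = float(rng.uniform(0.1, 1.0))

    # leaf paths to root
    def path_len_to(node: str, target: str) -> float | None:
        if node == target:
            return 0.0
        for ch in children.get(node, []):
            sub = path_len_to(ch, target)
            if sub is not None:
                return sub + lengths[ch]
        return None

    d = np.zeros((n_taxa, n_taxa))
    # distance via lowest common ancestor: use full path enumeration
    def path(node: str, target: str, acc):
        if node == target:
            return acc
        for ch in children.get(node, []):
            res = path(ch, target, acc + [ch])
            if res is not None:
                return res
        return None

    paths = {lab: path(root, lab, []) for lab in labels}
    for i, li in enumerate(labels):
        for j, lj in enumerate(labels):
            if i >= j:
                continue
            pi, pj = paths[li], paths[lj]
            k = 0
            while k < min(len(pi), len(pj)) and pi[k] == pj[k]:
                k += 1
            dist = sum(lengths[x] for x in pi[k:]) + sum(lengths[x] for x in pj[k:])
            d[i, j] = d[j, i] = dist

    def newick(node: str) -> str:
        if node not in children:
            return node
        inner = ",".join(
            f"{newick(ch)}:{lengths[ch]}" for ch in children[node]
        )
        return f"({inner})"

    return newick(root) + ";", labels, d
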
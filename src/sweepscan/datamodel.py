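"""Core data containers shared by every pipeline stage.

Coordinate conventions: VCF positions are 1-based; all windows and gene
intervals are 0-based half-open internally. Conversion happens only at the
I/O boundary (readers/writers), never inside statistics code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1  # sentinel for missing genotype / haplotype allele

VALID_ROLES = ("focal", "contrast", "outgroup", "none")


class ConfigError(ValueError):
    """Invalid user-supplied configuration."""


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes for a set of samples.

    ``genotypes`` holds alternative-allele dosages in {0, 1, 2} with
    ``MISSING`` (-1) for no-calls, shaped (n_sites, n_samples).
    ``haplotypes``, when present, holds phased alleles in {0, 1, MISSING}
    shaped (n_sites, 2 * n_samples) with sample i occupying columns
    2i and 2i + 1.
    """

    chrom: np.ndarray
    pos: np.ndarray  # 1-based bp
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    samples: list[str]
    haplotypes: np.ndarray | None = None
    skipped_records: int = 0

    @property
    def n_sites(self) -> int:
        return int(self.genotypes.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.genotypes.shape[1])

    def validate(self) -> "GenotypeMatrix":
        """Check structural invariants; raises ValueError on violation."""
        S, N = self.genotypes.shape
        for name in ("chrom", "pos", "ref", "alt"):
            arr = getattr(self, name)
            if len(arr) != S:
                raise ValueError(f"{name} has {len(arr)} entries for {S} sites")
        if len(self.samples) != N:
            raise ValueError(f"{len(self.samples)} sample ids for {N} columns")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotypes outside {0,1,2,missing}")
        # sorted by (chrom, pos), no duplicate site
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(S)):
            raise ValueError("sites not sorted by (chrom, pos)")
        if S > 1:
            same = (self.chrom[1:] == self.chrom[:-1]) & (self.pos[1:] == self.pos[:-1])
            if same.any():
                i = int(np.nonzero(same)[0][0]) + 1
                raise ValueError(f"duplicate site {self.chrom[i]}:{self.pos[i]}")
        if self.haplotypes is not None:
            if self.haplotypes.shape != (S, 2 * N):
                raise ValueError("haplotype matrix shape mismatch")
            h0 = self.haplotypes[:, 0::2]
            h1 = self.haplotypes[:, 1::2]
            both = (h0 != MISSING) & (h1 != MISSING) & (self.genotypes != MISSING)
            if not np.array_equal((h0 + h1)[both], self.genotypes[both]):
                raise ValueError("haplotype allele sums disagree with genotypes")
        return self

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Row subset (no re-validation; caller controls ordering)."""
        idx = np.asarray(idx)
        return replace(
            self,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            genotypes=self.genotypes[idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[idx],
        )

    def region(self, chrom: str, start: int, end: int) -> "GenotypeMatrix":
        """Sites with 1-based position in [start, end] on ``chrom``."""
        mask = (self.chrom == chrom) & (self.pos >= start) & (self.pos <= end)
        return self.take_sites(np.nonzero(mask)[0])

    def sample_index(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in genotype matrix: {missing}")
        return np.array([lookup[s] for s in sample_ids], dtype=int)


@dataclass
class PopulationMap:
    """Sample-to-population labels plus branch-role assignment."""

    assignments: dict[str, str]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pop, role in self.roles.items():
            if role not in VALID_ROLES:
                raise ConfigError(f"unknown role {role!r} for population {pop!r}")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.assignments.values():
            seen.setdefault(pop)
        return list(seen)

    def samples_in(self, pop: str) -> list[str]:
        if pop not in set(self.assignments.values()):
            raise KeyError(f"unknown population {pop!r}")
        return [s for s, p in self.assignments.items() if p == pop]

    def _pop_with_role(self, role: str) -> str:
        pops = [p for p, r in self.roles.items() if r == role]
        if len(pops) != 1:
            raise ConfigError(
                f"exactly one {role!r} population required, found {len(pops)}"
            )
        return pops[0]

    @property
    def focal(self) -> str:
        return self._pop_with_role("focal")

    @property
    def contrast(self) -> str:
        return self._pop_with_role("contrast")

    @property
    def outgroup(self) -> str:
        return self._pop_with_role("outgroup")

    def check_covers(self, samples: Iterable[str]) -> None:
        missing = [s for s in samples if s not in self.assignments]
        if missing:
            raise ValueError(f"samples absent from population map: {missing}")


@dataclass
class GeneAnnotation:
    """Gene intervals, 0-based half-open, possibly overlapping."""

    intervals: list[tuple[str, int, int, str]]

    def __post_init__(self) -> None:
        for chrom, start, end, gene_id in self.intervals:
            if start >= end:
                raise ValueError(f"empty interval for {gene_id}: {start}>={end}")
            if not gene_id:
                raise ValueError(f"empty gene id at {chrom}:{start}-{end}")

    def __len__(self) -> int:
        return len(self.intervals)

    def gene_ids(self) -> list[str]:
        return sorted({g for *_, g in self.intervals})


@dataclass
class VariantSummary:
    """Per-dataset SNP summary: transition/transversion and per-sample counts."""

    n_sites: int
    n_transitions: int
    n_transversions: int
    per_sample_hom_alt: pd.Series
    per_sample_het: pd.Series

    @property
    def tstv_ratio(self) -> float:
        if self.n_transversions == 0:
            return float("nan")
        return self.n_transitions / self.n_transversions

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"hom_alt": self.per_sample_hom_alt, "het": self.per_sample_het}
        )


@dataclass
class WindowSet:
    """Sliding windows per chromosome, 0-based half-open."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    size: int
    step: int

    def __len__(self) -> int:
        return len(self.start)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "start": self.start, "end": self.end})

    def same_windows(self, other: "WindowSet") -> bool:
        return (
            np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.start, other.start)
            and np.array_equal(self.end, other.end)
        )

    def site_slices(self, chrom: np.ndarray, pos: np.ndarray) -> list[np.ndarray]:
        """Indices of sites falling in each window (pos is 1-based).

        A site at 1-based position p lies in window [s, e) iff s <= p-1 < e.
        Sites must be sorted by (chrom, pos).
        """
        out: list[np.ndarray] = []
        pos0 = pos - 1
        # per-chromosome contiguous blocks
        bounds: dict[str, tuple[int, int]] = {}
        if len(chrom):
            change = np.nonzero(chrom[1:] != chrom[:-1])[0] + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(chrom)]))
            bounds = {str(chrom[s]): (int(s), int(e)) for s, e in zip(starts, ends)}
        for c, s, e in zip(self.chrom, self.start, self.end):
            if str(c) not in bounds:
                out.append(np.empty(0, dtype=int))
                continue
            lo, hi = bounds[str(c)]
            block = pos0[lo:hi]
            i0 = int(np.searchsorted(block, s, side="left"))
            i1 = int(np.searchsorted(block, e, side="left"))
            out.append(np.arange(lo + i0, lo + i1))
        return out


@dataclass
class WindowStats:
    """One statistic value per window; NaN marks a missing value."""

    windows: WindowSet
    n_snps: np.ndarray
    value: np.ndarray
    name: str

    def __len__(self) -> int:
        return len(self.value)

    def to_frame(self) -> pd.DataFrame:
        df = self.windows.to_frame()
        df["n_snps"] = self.n_snps
        df[self.name] = self.value
        return df

    def require_aligned(self, *others: "WindowStats") -> None:
        for o in others:
            if not self.windows.same_windows(o.windows):
                raise ValueError(
                    f"window sets of {self.name!r} and {o.name!r} are misaligned"
                )


@dataclass
class OutlierSet:
    """Windows above an empirical quantile threshold, plus overlapping genes."""

    stat_name: str
    threshold_value: float
    windows: pd.DataFrame  # chrom, start, end, n_snps, value
    genes: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.windows)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def validate(self) -> "DistanceMatrix":
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("nonzero diagonal")
        if not np.isfinite(self.d).all():
            raise ValueError("non-finite distances")
        if (self.d < -1e-12).any():
            raise ValueError("negative distances")
        return self


@dataclass
class HaplotypeMatrix:
    """Haplotypes x sites matrix coded 0=reference, 1=alternative, -1=missing.

    Rows are grouped into population blocks (``blocks`` maps population label
    to a half-open row range) in a caller-chosen population order.
    """

    chrom: str
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    cells: np.ndarray  # (n_rows, n_sites)
    row_labels: list[str]
    blocks: dict[str, tuple[int, int]]
    phased: bool

    @property
    def n_rows(self) -> int:
        return int(self.cells.shape[0])

    @property
    def n_sites(self) -> int:
        return int(self.cells.shape[1])

    def validate(self) -> "HaplotypeMatrix":
        if not np.isin(self.cells, (0, 1, MISSING)).all():
            raise ValueError("haplotype cells outside {0,1,missing}")
        if len(self.row_labels) != self.n_rows:
            raise ValueError("row label count mismatch")
        covered = sorted(self.blocks.values())
        edges = [0]
        for r0, r1 in covered:
            edges.append(r1)
        if covered and (covered[0][0] != 0 or covered[-1][1] != self.n_rows):
            raise ValueError("population blocks do not partition rows")
        for (a0, a1), (b0, b1) in zip(covered, covered[1:]):
            if a1 != b0:
                raise ValueError("population blocks do not partition rows")
        if len(self.pos) > 1 and not (np.diff(self.pos) > 0).all():
            raise ValueError("site positions not strictly increasing")
        return self
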
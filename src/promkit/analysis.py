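"""Validation analytics for called promoters.

Three analyses support the promoter-calling method:

* the distribution of TFBS positions relative to vTSSs (binding sites
  cluster tightly around genuine promoters and look uniform around weak
  ones), summarised as a kernel density estimate normalised to unit
  integral;
* the per-gene promoter-count histogram;
* a build-to-build comparison of called promoters (e.g. hg19 vs hg38),
  binning per-promoter position shifts into 0 / 1-10 / 11-100 /
  101-1,000 nt / other and reporting integer percents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .variants import TFBSRecord
from .vtss import CLASS_SINGLE, VTSS

SHIFT_BINS = ("unchanged", "shifted_1_10", "shifted_11_100", "shifted_101_1000", "other")
SHIFT_BIN_LABELS = {
    "unchanged": "Unchanged",
    "shifted_1_10": "Shifted 1-10 nt",
    "shifted_11_100": "Shifted 11-100 nt",
    "shifted_101_1000": "Shifted 101-1,000 nt",
    "other": "Other (larger shift or dropped)",
}


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (printed-table style)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percent(count: float, total: float) -> int:
    """Integer percent under the half-away-from-zero rounding rule."""
    if total == 0:
        return 0
    return round_half_away(100.0 * count / total)


# ---------------------------------------------------------------------------
# TFBS distance to vTSS
# ---------------------------------------------------------------------------


def tfbs_distance_to_vtss(
    sites: Iterable[TFBSRecord],
    promoters: Iterable[VTSS],
    upstream: int = 10_000,
    downstream: int = 1_000,
    reference: str = "midpoint",
) -> list[float]:
    """Signed strand-oriented distances of sites to vTSSs.

    For each (site, promoter) pair on the same chromosome whose site
    reference point falls within the promoter extent, the distance is
    the strand-oriented offset of the site from the vTSS: negative is
    upstream on both strands.  ``reference`` selects the site reference
    point (``midpoint`` or ``start``).
    """
    if reference not in ("midpoint", "start"):
        raise ValueError(f"unknown site reference {reference!r}")
    sites = list(sites)
    out: list[float] = []
    for p in promoters:
        for s in sites:
            if s.chrom != p.chrom:
                continue
            point = (s.start + s.end) / 2.0 if reference == "midpoint" else float(s.start)
            d = point - p.position if p.strand == "+" else p.position - point
            if -upstream <= d <= downstream:
                out.append(d)
    return out


@dataclass
class KDEResult:
    grid: np.ndarray
    density: np.ndarray

    @property
    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def density_at(self, x: float) -> float:
        return float(np.interp(x, self.grid, self.density))

    @property
    def mode(self) -> float:
        return float(self.grid[int(np.argmax(self.density))])


def kde(
    distances: Sequence[float],
    bandwidth: float | str | None = None,
    grid_points: int = 2048,
) -> KDEResult:
    """Gaussian kernel density estimate over the distances.

    Bandwidth defaults to Silverman's rule; the evaluation grid extends
    four bandwidths past the data range so the numerical integral over
    the grid is within [0.99, 1.01] of unity.  Degenerate all-identical
    inputs are jittered by a negligible deterministic amount so the
    estimate stays well defined.
    """
    x = np.asarray(list(distances), float)
    if len(x) < 2:
        raise ValueError("kernel density estimation needs at least 2 points")
    if np.ptp(x) == 0:  # jitter guard for singular covariance
        x = x + np.linspace(-0.5, 0.5, len(x)) * 1e-6 * max(1.0, abs(x[0]))
    from scipy.stats import gaussian_kde

    est = gaussian_kde(x, bw_method=bandwidth if bandwidth else "silverman")
    h = float(np.sqrt(est.covariance[0, 0]))
    lo, hi = x.min() - 4 * h, x.max() + 4 * h
    grid = np.linspace(lo, hi, grid_points)
    return KDEResult(grid=grid, density=est(grid))


# ---------------------------------------------------------------------------
# Promoter-count histogram
# ---------------------------------------------------------------------------


@dataclass
class PromoterCountHistogram:
    counts: dict[int, int]  # promoter count -> number of genes

    @property
    def n_genes(self) -> int:
        return sum(self.counts.values())

    @property
    def fraction_single(self) -> float:
        return self.counts.get(1, 0) / self.n_genes if self.n_genes else 0.0

    @property
    def fraction_le3(self) -> float:
        if not self.n_genes:
            return 0.0
        return sum(v for k, v in self.counts.items() if k <= 3) / self.n_genes


def promoter_count_histogram(
    promoter_sets: Iterable[Sequence] | dict[str, Sequence],
) -> PromoterCountHistogram:
    """Histogram of promoters per gene (counts >= 1).

    Accepts either a mapping gene -> promoters or an iterable of
    per-gene promoter collections; genes with zero promoters are not
    counted.
    """
    if isinstance(promoter_sets, dict):
        promoter_sets = promoter_sets.values()
    counts: dict[int, int] = {}
    for promoters in promoter_sets:
        n = len(promoters)
        if n >= 1:
            counts[n] = counts.get(n, 0) + 1
    return PromoterCountHistogram(dict(sorted(counts.items())))


# ---------------------------------------------------------------------------
# Build-to-build comparison
# ---------------------------------------------------------------------------


@dataclass
class GeneCountEntry:
    gene_id: str
    count_a: int
    count_b: int

    @property
    def count_delta(self) -> int:
        return self.count_b - self.count_a


@dataclass
class PromoterShiftEntry:
    gene_id: str
    promoter_rank: int  # 0 = best supported, then by descending percent
    best_supported: bool
    shift_nt: int | None  # None = dropped (no partner in the other set)

    @property
    def bin(self) -> str:
        s = self.shift_nt
        if s is None or s > 1000:
            return "other"
        if s == 0:
            return "unchanged"
        if s <= 10:
            return "shifted_1_10"
        if s <= 100:
            return "shifted_11_100"
        return "shifted_101_1000"


@dataclass
class BuildComparison:
    gene_entries: list[GeneCountEntry]
    promoter_entries: list[PromoterShiftEntry]
    excluded_genes: list[str]  # present in only one build (ID changed)
    n_promoters_a: int
    n_best_a: int
    n_excluded_promoters: int  # promoters of A in excluded genes

    # ---- gene-level summary -------------------------------------------
    @property
    def n_genes_total(self) -> int:
        return len(self.gene_entries) + len(self.excluded_genes)

    def genes_with_count_change_within(self, k: int) -> int:
        return sum(1 for g in self.gene_entries if abs(g.count_delta) <= k)

    def pct_genes_count_unchanged(self) -> int:
        return percent(self.genes_with_count_change_within(0), self.n_genes_total)

    def pct_genes_count_within(self, k: int) -> int:
        return percent(self.genes_with_count_change_within(k), self.n_genes_total)

    # ---- promoter-level summary ---------------------------------------
    def bin_counts(self, best_only: bool = False) -> dict[str, int]:
        counts = {b: 0 for b in SHIFT_BINS}
        for e in self.promoter_entries:
            if best_only and not e.best_supported:
                continue
            counts[e.bin] += 1
        return counts

    def bin_percents(self, best_only: bool = False) -> dict[str, int]:
        total = self.n_best_a if best_only else self.n_promoters_a
        return {b: percent(c, total) for b, c in self.bin_counts(best_only).items()}

    def table(self):
        """Summary frame: shift bins x (counts, percents) for all/best."""
        import pandas as pd

        rows = []
        all_counts = self.bin_counts(False)
        best_counts = self.bin_counts(True)
        all_pct = self.bin_percents(False)
        best_pct = self.bin_percents(True)
        for b in SHIFT_BINS:
            rows.append(
                {
                    "category": SHIFT_BIN_LABELS[b],
                    "all_promoters": all_counts[b],
                    "pct_all_promoters": all_pct[b],
                    "best_supported": best_counts[b],
                    "pct_best_supported": best_pct[b],
                }
            )
        rows.append(
            {
                "category": "Total",
                "all_promoters": self.n_promoters_a,
                "pct_all_promoters": 100,
                "best_supported": self.n_best_a,
                "pct_best_supported": 100,
            }
        )
        return pd.DataFrame(rows)


def _group_by_gene(promoters: Iterable[VTSS]) -> dict[str, list[VTSS]]:
    groups: dict[str, list[VTSS]] = {}
    for p in promoters:
        groups.setdefault(p.gene_id, []).append(p)
    for gid, plist in groups.items():
        seen = set()
        n_best = 0
        for p in plist:
            if p.position in seen:
                raise ValueError(f"gene {gid}: duplicate promoter position {p.position}")
            seen.add(p.position)
            n_best += p.is_best_supported
        if n_best > 1:
            raise ValueError(f"gene {gid}: more than one best supported promoter")
        # best supported first, then descending percent, then position
        plist.sort(key=lambda p: (not p.is_best_supported, -p.percent, p.position))
    return groups


def compare_builds(
    promoters_a: Iterable[VTSS], promoters_b: Iterable[VTSS]
) -> BuildComparison:
    """Compare two promoter call sets keyed by stable gene IDs.

    Genes present in only one set are excluded (annotation IDs changed
    between builds).  Within each shared gene, promoters are paired
    greedily by nearest position with the best supported promoter
    paired first; unpaired promoters of set A count as dropped.  Shift
    bin counts plus excluded-gene promoters partition all of set A.
    """
    a_by_gene = _group_by_gene(promoters_a)
    b_by_gene = _group_by_gene(promoters_b)

    shared = sorted(set(a_by_gene) & set(b_by_gene))
    excluded = sorted(set(a_by_gene) ^ set(b_by_gene))

    gene_entries = [
        GeneCountEntry(g, len(a_by_gene[g]), len(b_by_gene[g])) for g in shared
    ]
    n_excluded_promoters = sum(
        len(a_by_gene[g]) for g in excluded if g in a_by_gene
    )

    promoter_entries: list[PromoterShiftEntry] = []
    for g in shared:
        partners = [p.position for p in b_by_gene[g]]
        used = [False] * len(partners)
        for rank, pa in enumerate(a_by_gene[g]):
            best_j, best_d = None, None
            for j, pos in enumerate(partners):
                if used[j]:
                    continue
                d = abs(pos - pa.position)
                if best_d is None or d < best_d:
                    best_j, best_d = j, d
            if best_j is not None:
                used[best_j] = True
            promoter_entries.append(
                PromoterShiftEntry(
                    gene_id=g,
                    promoter_rank=rank,
                    best_supported=pa.is_best_supported,
                    shift_nt=best_d,
                )
            )

    n_promoters_a = sum(len(v) for v in a_by_gene.values())
    n_best_a = sum(
        1 for v in a_by_gene.values() for p in v if p.is_best_supported
    )
    return BuildComparison(
        gene_entries=gene_entries,
        promoter_entries=promoter_entries,
        excluded_genes=excluded,
        n_promoters_a=n_promoters_a,
        n_best_a=n_best_a,
        n_excluded_promoters=n_excluded_promoters,
    )


def write_build_report(comparison: BuildComparison, path: str) -> None:
    comparison.table().to_csv(path, sep="\t", index=False)


def write_density_tsv(result: KDEResult, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("distance\tdensity\n")
        for x, y in zip(result.grid, result.density):
            fh.write(f"{x:.3f}\t{y:.8g}\n")
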
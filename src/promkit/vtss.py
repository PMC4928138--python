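"""Virtual TSS calling: cosine-weighted clustering, peaks, selection.

A 3000-nt window slides at single-nucleotide steps over the span of a
gene's TSS evidence.  At each window center c the clustering score is

    score(c) = sum over evidence points t with |pos(t) - c| <= W/2 of
               evidence_score(t) * cos(pi * |pos(t) - c| / W)

so a point at the center contributes its full score, a point at the
window edge contributes nothing, and intermediate offsets are weighted by
the cosine of their relative distance.  Peaks of the profile are the
candidate virtual TSSs (vTSSs).

Selection: each candidate's percent share is its score over the sum of
ALL candidate peak scores.  If the gene's cumulative score falls below a
minimum cut-off, only the most 5' candidate is kept (class ``single``).
Otherwise candidates with >= 8% share are selected; the highest-percent
one (ties broken toward 5') anchors the best supported promoter and the
rest are secondary.  A gene whose selection retains a single candidate is
class ``single``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .tss import TSSCollection

DEFAULT_WINDOW = 3000
DEFAULT_PERCENT_THRESHOLD = 8.0
#: minimum cumulative candidate score for multi-promoter selection;
#: equals three default evidence points. Not an authoritative constant —
#: tune to the evidence weighting in use.
DEFAULT_MIN_CUMULATIVE_SCORE = 15.0
#: absolute tolerance for treating two scores as tied
SCORE_TIE_TOL = 1e-9

CLASS_SINGLE = "single"
CLASS_BEST = "best_supported"
CLASS_SECONDARY = "secondary"


def cosine_weight(distance: int | float, window_length: int = DEFAULT_WINDOW) -> float:
    """Distance weight: 1 at the window center, 0 at the edges.

    Returns ``cos(pi * |distance| / window_length)`` for offsets within
    half a window of the center, 0 outside (by contract).
    """
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    d = abs(distance)
    if d > window_length / 2:
        return 0.0
    return math.cos(math.pi * d / window_length)


@dataclass
class ClusteringProfile:
    """Per-position clustering score over a gene's TSS span."""

    gene_id: str
    chrom: str
    strand: str
    start: int  # genomic coordinate (1-based) of scores[0]
    scores: np.ndarray

    @property
    def end(self) -> int:
        return self.start + len(self.scores) - 1

    def score_at(self, position: int) -> float:
        """Score at a genomic position (0 outside the profiled span)."""
        i = position - self.start
        if 0 <= i < len(self.scores):
            return float(self.scores[i])
        return 0.0


def clustering_profile(
    tss: TSSCollection, window_length: int = DEFAULT_WINDOW
) -> ClusteringProfile:
    """Slide the scoring window over the gene's TSS span at 1-nt steps."""
    if not tss.tss_points:
        raise ValueError(f"gene {tss.gene_id}: no TSS evidence")
    half = window_length / 2
    positions = tss.positions()
    lo = int(math.floor(min(positions) - half))
    hi = int(math.ceil(max(positions) + half))
    n = hi - lo + 1
    scores = np.zeros(n)
    # each evidence point adds a cosine bump of radius W/2 around itself
    for pt in tss.tss_points:
        left = max(lo, int(math.ceil(pt.position - half)))
        right = min(hi, int(math.floor(pt.position + half)))
        centers = np.arange(left, right + 1)
        w = np.cos(np.pi * np.abs(centers - pt.position) / window_length)
        scores[left - lo : right - lo + 1] += pt.evidence_score * w
    np.clip(scores, 0.0, None, out=scores)
    return ClusteringProfile(tss.gene_id, tss.chrom, tss.strand, lo, scores)


@dataclass(frozen=True)
class Candidate:
    """A candidate vTSS: a peak of the clustering profile."""

    position: int
    clustering_score: float


def find_peaks(profile: ClusteringProfile, tol: float = SCORE_TIE_TOL) -> list[Candidate]:
    """All strict local maxima of the profile, sorted by descending score.

    A plateau of (tolerance-)equal maximal scores is reported once, at
    its most 5' position: the smallest coordinate on the + strand, the
    largest on the - strand.
    """
    s = profile.scores
    n = len(s)
    if n == 0:
        return []
    if n == 1:
        return [Candidate(profile.start, float(s[0]))]

    # compress into runs of tolerance-equal values
    runs: list[tuple[int, int]] = []  # [start, end] index ranges
    run_start = 0
    for i in range(1, n):
        if abs(s[i] - s[run_start]) > tol:
            runs.append((run_start, i - 1))
            run_start = i
    runs.append((run_start, n - 1))

    peaks: list[Candidate] = []
    for k, (a, b) in enumerate(runs):
        left_lower = k == 0 or s[runs[k - 1][0]] < s[a]
        right_lower = k == len(runs) - 1 or s[runs[k + 1][0]] < s[a]
        if left_lower and right_lower and s[a] > tol:
            idx = a if profile.strand == "+" else b
            peaks.append(Candidate(profile.start + idx, float(s[idx])))
    if not peaks:  # degenerate flat profile: report the 5'-most position
        idx = 0 if profile.strand == "+" else n - 1
        peaks = [Candidate(profile.start + idx, float(s[idx]))]
    peaks.sort(
        key=lambda c: (
            -c.clustering_score,
            c.position if profile.strand == "+" else -c.position,
        )
    )
    return peaks


@dataclass(frozen=True)
class VTSS:
    """A called virtual TSS and its promoter classification."""

    gene_id: str
    chrom: str
    strand: str
    position: int
    clustering_score: float
    percent: float
    promoter_class: str

    @property
    def is_best_supported(self) -> bool:
        return self.promoter_class in (CLASS_BEST, CLASS_SINGLE)


def _five_prime_first(candidates: Sequence[Candidate], strand: str) -> Candidate:
    if strand == "+":
        return min(candidates, key=lambda c: c.position)
    return max(candidates, key=lambda c: c.position)


def select_promoters(
    candidates: Sequence[Candidate],
    gene_id: str,
    chrom: str,
    strand: str,
    min_cumulative_score: float = DEFAULT_MIN_CUMULATIVE_SCORE,
    percent_threshold: float = DEFAULT_PERCENT_THRESHOLD,
) -> list[VTSS]:
    """Select and classify vTSSs from candidate peaks.

    The percent denominator is the sum over ALL candidate peaks, not
    only the selected ones. Output is ordered by descending percent,
    then 5'-most.
    """
    if not candidates:
        raise ValueError("no candidate vTSSs")
    if not (0 < percent_threshold < 100):
        raise ValueError("percent_threshold must be in (0, 100)")
    total = sum(c.clustering_score for c in candidates)
    percents = {c: 100.0 * c.clustering_score / total for c in candidates}

    def make(c: Candidate, cls: str) -> VTSS:
        return VTSS(
            gene_id, chrom, strand, c.position, c.clustering_score, percents[c], cls
        )

    if total < min_cumulative_score:
        # sparse evidence: the most 5' candidate is the sole vTSS
        return [make(_five_prime_first(candidates, strand), CLASS_SINGLE)]

    kept = [c for c in candidates if percents[c] >= percent_threshold]
    if not kept:  # pathological threshold; fall back to the top candidate
        kept = [max(candidates, key=lambda c: c.clustering_score)]
    if len(kept) == 1:
        return [make(kept[0], CLASS_SINGLE)]

    top = max(percents[c] for c in kept)
    tied = [c for c in kept if top - percents[c] <= SCORE_TIE_TOL]
    best = _five_prime_first(tied, strand)
    out = [
        make(c, CLASS_BEST if c is best else CLASS_SECONDARY) for c in kept
    ]
    out.sort(
        key=lambda v: (
            -v.percent,
            v.position if strand == "+" else -v.position,
        )
    )
    return out


def call_vtss(
    tss: TSSCollection,
    window_length: int = DEFAULT_WINDOW,
    min_cumulative_score: float = DEFAULT_MIN_CUMULATIVE_SCORE,
    percent_threshold: float = DEFAULT_PERCENT_THRESHOLD,
) -> list[VTSS]:
    """Profile, peak-find and select in one call for a single gene."""
    profile = clustering_profile(tss, window_length)
    candidates = find_peaks(profile)
    return select_promoters(
        candidates,
        tss.gene_id,
        tss.chrom,
        tss.strand,
        min_cumulative_score=min_cumulative_score,
        percent_threshold=percent_threshold,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_vtss_bed(vtss_list: Sequence[VTSS], path: str) -> None:
    """BED6: name = gene_id|class, score = percent rounded to 1 decimal."""
    with open(path, "w") as fh:
        for v in vtss_list:
            fh.write(
                f"{v.chrom}\t{v.position - 1}\t{v.position}\t"
                f"{v.gene_id}|{v.promoter_class}\t{v.percent:.1f}\t{v.strand}\n"
            )


def read_vtss_bed(path: str) -> list[VTSS]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")[:6]
            gene_id, _, cls = name.partition("|")
            out.append(
                VTSS(
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    position=int(end),
                    clustering_score=float("nan"),
                    percent=float(score),
                    promoter_class=cls or CLASS_SINGLE,
                )
            )
    return out


VTSS_REPORT_COLUMNS = (
    "gene_id",
    "chromosome",
    "position",
    "clustering_score",
    "percent",
    "best_supported",
    "promoter_class",
)


def write_vtss_report(vtss_list: Sequence[VTSS], path: str) -> None:
    """TSV report mirroring the per-gene promoter table (1-based positions)."""
    with open(path, "w") as fh:
        fh.write("\t".join(VTSS_REPORT_COLUMNS) + "\n")
        for v in vtss_list:
            fh.write(
                f"{v.gene_id}\t{v.chrom}\t{v.position}\t"
                f"{v.clustering_score:g}\t{v.percent:.1f}\t"
                f"{'Yes' if v.is_best_supported else 'No'}\t{v.promoter_class}\n"
            )
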
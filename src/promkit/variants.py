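"""Variant-in-TFBS annotation and gain/loss-of-binding analysis.

Disease-associated variants are intersected with transcription factor
binding site (TFBS) intervals inside promoter windows (by default
-500 to +100 nt around the vTSS, strand-oriented), their site-relative
offsets computed, and the reference versus alternate sequence scanned
with a PWM library to classify each matrix as lost, gained, retained or
score-changed.  Variant combinations (several SNVs applied together) are
supported; indels are accepted for overlap but not rescored.

Site-relative positions are 0-based offsets from the site start, so a
variant at the site's first base has offset 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .match import (
    DEFAULT_CSS_CUTOFF,
    DEFAULT_MSS_CUTOFF,
    MODE_ALL,
    MatchHit,
    PWM,
    scan,
)
from .vtss import VTSS

logger = logging.getLogger(__name__)

DEFAULT_PROMOTER_WINDOW = (-500, 100)
DEFAULT_FLANK = 25
RETAINED_MSS_TOL = 1e-6

STATUS_LOST = "lost"
STATUS_GAINED = "gained"
STATUS_RETAINED = "retained"
STATUS_SCORE_CHANGED = "score_changed"


class UnsupportedVariantError(ValueError):
    """Raised when an indel reaches gain/loss scoring (SNV-only)."""


class RefMismatchError(ValueError):
    """Reference allele disagrees with the supplied sequence."""


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    variant_id: str = ""

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError(f"variant {self.variant_id or self.pos}: empty allele")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def label(self) -> str:
        return self.variant_id or f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class TFBSRecord:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    factor: str = ""
    source: str = "experimental"
    matrix_id: str | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"TFBS {self.factor}: end {self.end} < start {self.start}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class OverlapRecord:
    variant: VariantRecord
    site: TFBSRecord
    site_relative_position: int


def site_relative_position(
    variant_pos: int, site_start: int, site_end: int | None = None
) -> int:
    """0-based offset of a variant within a site (+ strand orientation)."""
    if variant_pos < site_start or (site_end is not None and variant_pos > site_end):
        raise ValueError(
            f"position {variant_pos} outside site [{site_start}, {site_end}]"
        )
    return variant_pos - site_start


def overlap_variants_tfbs(
    variants: Iterable[VariantRecord], sites: Iterable[TFBSRecord]
) -> list[OverlapRecord]:
    """All (variant, site) pairs with site_start <= pos <= site_end.

    Results are sorted by chromosome then position.  A disjoint
    chromosome naming between the two inputs is reported as a warning
    with per-chromosome counts.
    """
    variants = list(variants)
    sites = list(sites)
    trees: dict[str, IntervalTree] = {}
    for s in sites:
        # interval tree is half-open; inclusive end -> end + 1
        trees.setdefault(s.chrom, IntervalTree()).addi(s.start, s.end + 1, s)
    var_chroms = {v.chrom for v in variants}
    site_chroms = set(trees)
    if variants and sites and not (var_chroms & site_chroms):
        logger.warning(
            "no shared chromosomes between variants (%s) and sites (%s)",
            {c: sum(v.chrom == c for v in variants) for c in sorted(var_chroms)},
            {c: len(trees[c]) for c in sorted(site_chroms)},
        )
    out = []
    for v in variants:
        tree = trees.get(v.chrom)
        if tree is None:
            continue
        for iv in tree.at(v.pos):
            site: TFBSRecord = iv.data
            out.append(
                OverlapRecord(v, site, site_relative_position(v.pos, site.start))
            )
    out.sort(key=lambda r: (r.variant.chrom, r.variant.pos, r.site.start))
    return out


def restrict_to_promoter_window(
    variants: Iterable[VariantRecord],
    promoters: Iterable[VTSS],
    window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
) -> list[VariantRecord]:
    """Keep variants within the strand-oriented window around any vTSS.

    The signed distance is ``pos - vTSS`` on the + strand and
    ``vTSS - pos`` on the - strand, so negative means upstream on both
    strands.  The default window keeps -500 <= d <= +100.
    """
    lo, hi = window
    promoters = list(promoters)
    kept = []
    for v in variants:
        for p in promoters:
            if p.chrom != v.chrom:
                continue
            d = v.pos - p.position if p.strand == "+" else p.position - v.pos
            if lo <= d <= hi:
                kept.append(v)
                break
    return kept


def apply_variants(
    sequence: str, sequence_origin: int, variant_set: Sequence[VariantRecord]
) -> str:
    """Substitute alt alleles into a sequence starting at ``sequence_origin``.

    ``sequence_origin`` is the 1-based genomic coordinate of the first
    base.  Every variant must lie within the sequence and its ref allele
    must match (guards against build or coordinate mix-ups).  SNV-only;
    the empty set is the identity.
    """
    seq = list(sequence)
    for v in variant_set:
        if not v.is_snv:
            raise UnsupportedVariantError(
                f"variant {v.label()}: indel rescoring is not supported"
            )
        off = v.pos - sequence_origin
        if not (0 <= off < len(seq)):
            raise ValueError(f"variant {v.label()} outside sequence")
        observed = seq[off].upper()
        if observed != v.ref.upper():
            raise RefMismatchError(
                f"variant {v.label()}: reference allele {v.ref} but sequence "
                f"has {observed} at coordinate {v.pos}"
            )
        seq[off] = v.alt.upper()
    return "".join(seq)


@dataclass(frozen=True)
class GainLossEntry:
    matrix_id: str
    factor: str
    status: str
    ref_hit: MatchHit | None
    alt_hit: MatchHit | None

    @property
    def delta_mss(self) -> float | None:
        if self.ref_hit is None or self.alt_hit is None:
            return None
        return self.alt_hit.mss - self.ref_hit.mss


@dataclass
class GainLossReport:
    variant_set: list[VariantRecord]
    entries: list[GainLossEntry] = field(default_factory=list)

    def by_status(self, status: str) -> list[GainLossEntry]:
        return [e for e in self.entries if e.status == status]

    @property
    def lost(self) -> list[GainLossEntry]:
        return self.by_status(STATUS_LOST)

    @property
    def gained(self) -> list[GainLossEntry]:
        return self.by_status(STATUS_GAINED)


def _pair_hits(
    ref_hits: list[MatchHit], alt_hits: list[MatchHit], length: int
) -> list[tuple[MatchHit | None, MatchHit | None]]:
    """Pair ref and alt hits of one matrix by overlapping same-strand spans."""
    pairs: list[tuple[MatchHit | None, MatchHit | None]] = []
    unused_alt = list(alt_hits)
    for rh in ref_hits:
        best = None
        for ah in unused_alt:
            if ah.strand != rh.strand:
                continue
            if ah.offset < rh.offset + length and rh.offset < ah.offset + length:
                dist = abs(ah.offset - rh.offset)
                if best is None or dist < abs(best.offset - rh.offset):
                    best = ah
        if best is not None:
            unused_alt.remove(best)
        pairs.append((rh, best))
    pairs.extend((None, ah) for ah in unused_alt)
    return pairs


def gain_loss_analysis(
    sequence: str,
    sequence_origin: int,
    variant_set: Sequence[VariantRecord],
    pwm_library: Sequence[PWM],
    cutoffs: dict[str, tuple[float, float]] | None = None,
    default_mss_cutoff: float = DEFAULT_MSS_CUTOFF,
    default_css_cutoff: float = DEFAULT_CSS_CUTOFF,
    retained_tol: float = RETAINED_MSS_TOL,
) -> GainLossReport:
    """Scan reference vs alternate sequence and diff the hit sets.

    All-hits mode is used on both sequences so that secondary sites
    created by the variant (not just the strongest site) are visible.
    The supplied sequence should carry enough flanking context (at least
    the longest matrix length minus one on each side) for sites at the
    region boundary to be scannable.
    """
    alt_sequence = apply_variants(sequence, sequence_origin, variant_set)
    kwargs = dict(
        pwm_library=pwm_library,
        cutoffs=cutoffs,
        mode=MODE_ALL,
        default_mss_cutoff=default_mss_cutoff,
        default_css_cutoff=default_css_cutoff,
    )
    ref_hits = scan({"ref": sequence}, **kwargs)
    alt_hits = scan({"alt": alt_sequence}, **kwargs)
    lengths = {p.matrix_id: len(p) for p in pwm_library}
    factors = {p.matrix_id: p.factor_name for p in pwm_library}

    report = GainLossReport(variant_set=list(variant_set))
    matrix_ids = sorted(
        {h.matrix_id for h in ref_hits} | {h.matrix_id for h in alt_hits}
    )
    for mid in matrix_ids:
        r = [h for h in ref_hits if h.matrix_id == mid]
        a = [h for h in alt_hits if h.matrix_id == mid]
        for rh, ah in _pair_hits(r, a, lengths[mid]):
            if rh is not None and ah is None:
                status = STATUS_LOST
            elif rh is None and ah is not None:
                status = STATUS_GAINED
            elif abs(ah.mss - rh.mss) < retained_tol:
                status = STATUS_RETAINED
            else:
                status = STATUS_SCORE_CHANGED
            report.entries.append(
                GainLossEntry(mid, factors.get(mid, ""), status, rh, ah)
            )
    return report


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_vcf(path: str) -> list[VariantRecord]:
    """Read variants from VCF; multi-allelic records are split per alt."""
    from cyvcf2 import VCF

    out = []
    for rec in VCF(path):
        for alt in rec.ALT:
            out.append(
                VariantRecord(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    variant_id=rec.ID or "",
                )
            )
    return out


def read_tfbs_tsv(path: str) -> list[TFBSRecord]:
    """Read TFBS records from a TSV with 1-based inclusive coordinates.

    Columns: chrom, start, end, factor[, source[, matrix_id]].
    A header line starting with 'chrom' is skipped.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom"):
                continue
            f = line.split("\t")
            out.append(
                TFBSRecord(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    factor=f[3] if len(f) > 3 else "",
                    source=f[4] if len(f) > 4 else "experimental",
                    matrix_id=f[5] if len(f) > 5 else None,
                )
            )
    return out


def read_tfbs_bed(path: str) -> list[TFBSRecord]:
    """Read TFBS records from BED (0-based half-open -> 1-based inclusive)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(
                TFBSRecord(
                    chrom=f[0],
                    start=int(f[1]) + 1,
                    end=int(f[2]),
                    factor=f[3] if len(f) > 3 else "",
                )
            )
    return out


def write_overlaps_tsv(overlaps: Sequence[OverlapRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tvariant_pos\tref\talt\tvariant_id\t"
            "site_start\tsite_end\tfactor\tsite_relative_position\n"
        )
        for r in overlaps:
            v, s = r.variant, r.site
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.variant_id}\t"
                f"{s.start}\t{s.end}\t{s.factor}\t{r.site_relative_position}\n"
            )


def write_gain_loss_tsv(
    reports: Sequence[GainLossReport] | GainLossReport, path: str
) -> None:
    if isinstance(reports, GainLossReport):
        reports = [reports]
    with open(path, "w") as fh:
        fh.write(
            "variant_set_id\tmatrix_id\tfactor\tstatus\t"
            "ref_mss\talt_mss\tref_offset\talt_offset\n"
        )
        for rep in reports:
            set_id = "+".join(v.label() for v in rep.variant_set) or "reference"
            for e in rep.entries:
                rm = f"{e.ref_hit.mss:.6f}" if e.ref_hit else ""
                am = f"{e.alt_hit.mss:.6f}" if e.alt_hit else ""
                ro = str(e.ref_hit.offset) if e.ref_hit else ""
                ao = str(e.alt_hit.offset) if e.alt_hit else ""
                fh.write(
                    f"{set_id}\t{e.matrix_id}\t{e.factor}\t{e.status}\t"
                    f"{rm}\t{am}\t{ro}\t{ao}\n"
                )
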
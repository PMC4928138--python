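"""Transcript models and per-gene TSS evidence collections.

A gene's transcription start sites are taken from its annotated mRNA
models: for each transcript the TSS is the first nucleotide of the most
5' exon (the smallest exon start on the + strand, the largest exon end on
the - strand).  Every retained transcript contributes one evidence point,
by default with score 5; multiple transcripts starting at the same
position contribute separate points.  Mitochondrial genes are excluded
because of their distinct transcription machinery, and genes are filtered
to the requested biotypes (typically protein-coding and miRNA genes).

All genomic coordinates in this package are 1-based inclusive, matching
GTF and the coordinate style of standard genome browsers; conversion to
0-based half-open happens only when writing BED.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: evidence score per evidence source; mRNA-model-derived TSSs score 5
DEFAULT_EVIDENCE_SCORES: dict[str, float] = {"mRNA_model": 5.0}

#: chromosome aliases treated as mitochondrial (matched case-insensitively,
#: with or without a "chr" prefix)
MITOCHONDRIAL_NAMES = frozenset({"m", "mt"})

DEFAULT_BIOTYPES = frozenset({"protein_coding", "miRNA"})


class MalformedRecordError(ValueError):
    """A transcript record violates a structural invariant."""


def _normalize_chrom(name: str) -> str:
    low = name.lower()
    return low[3:] if low.startswith("chr") else low


def is_mitochondrial(chrom: str) -> bool:
    return _normalize_chrom(chrom) in MITOCHONDRIAL_NAMES


@dataclass(frozen=True)
class TranscriptModel:
    """One mRNA model: an ordered chain of exons on a strand.

    Exons are (start, end) pairs, 1-based inclusive, sorted and
    non-overlapping; validation raises :class:`MalformedRecordError`
    naming the transcript.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.exons:
            raise MalformedRecordError(
                f"transcript {self.transcript_id}: no exons"
            )
        if self.strand not in ("+", "-"):
            raise MalformedRecordError(
                f"transcript {self.transcript_id}: bad strand {self.strand!r}"
            )
        prev_end = None
        for start, end in self.exons:
            if end < start:
                raise MalformedRecordError(
                    f"transcript {self.transcript_id}: exon end {end} < start {start}"
                )
            if prev_end is not None and start <= prev_end:
                raise MalformedRecordError(
                    f"transcript {self.transcript_id}: exons overlap or unsorted"
                )
            prev_end = end

    @property
    def tss(self) -> int:
        """First nucleotide of the most 5' exon, strand-aware."""
        if self.strand == "+":
            return self.exons[0][0]
        return self.exons[-1][1]


@dataclass(frozen=True)
class TSSEvidence:
    position: int
    evidence_score: float
    source: str
    transcript_id: str = ""


@dataclass
class TSSCollection:
    """Per-gene multiset of strand-aware TSS evidence points."""

    gene_id: str
    chrom: str
    strand: str
    tss_points: list[TSSEvidence] = field(default_factory=list)

    def positions(self) -> list[int]:
        return [p.position for p in self.tss_points]

    def __len__(self) -> int:
        return len(self.tss_points)


def collect_tss(
    models: Iterable[TranscriptModel],
    allowed_biotypes: Iterable[str] = DEFAULT_BIOTYPES,
    exclude_chroms: Iterable[str] = (),
    evidence_scores: dict[str, float] | None = None,
    exclude_mitochondrial: bool = True,
) -> list[TSSCollection]:
    """Build one TSSCollection per retained gene.

    Genes on excluded chromosomes (mitochondria by default) or with a
    biotype outside ``allowed_biotypes`` are dropped.  Transcripts with
    an empty gene_id are skipped with a warning.  The number of evidence
    points per gene equals its number of retained transcripts.
    """
    allowed = set(allowed_biotypes)
    if not allowed:
        raise ValueError("allowed_biotypes must be non-empty")
    excluded = {_normalize_chrom(c) for c in exclude_chroms}
    scores = dict(DEFAULT_EVIDENCE_SCORES)
    if evidence_scores:
        scores.update(evidence_scores)

    by_gene: dict[str, TSSCollection] = {}
    for model in models:
        if not model.gene_id:
            logger.warning(
                "transcript %s has no gene_id; skipped", model.transcript_id
            )
            continue
        if model.biotype not in allowed:
            continue
        norm = _normalize_chrom(model.chrom)
        if norm in excluded:
            continue
        if exclude_mitochondrial and is_mitochondrial(model.chrom):
            continue
        coll = by_gene.get(model.gene_id)
        if coll is None:
            coll = TSSCollection(model.gene_id, model.chrom, model.strand)
            by_gene[model.gene_id] = coll
        elif coll.chrom != model.chrom or coll.strand != model.strand:
            raise MalformedRecordError(
                f"gene {model.gene_id}: transcripts on different "
                f"chromosomes or strands"
            )
        coll.tss_points.append(
            TSSEvidence(
                position=model.tss,
                evidence_score=scores["mRNA_model"],
                source="mRNA_model",
                transcript_id=model.transcript_id,
            )
        )
    return [by_gene[g] for g in sorted(by_gene)]


# ---------------------------------------------------------------------------
# I/O: GTF/GFF3 (via gffutils), BED12, TSV
# ---------------------------------------------------------------------------

_BIOTYPE_KEYS = (
    "transcript_biotype",
    "gene_biotype",
    "transcript_type",
    "gene_type",
    "biotype",
)


def read_gtf(path: str, strict: bool = False) -> list[TranscriptModel]:
    """Read transcript models from a GTF/GFF3 file (exon features).

    Malformed records are skipped with a warning unless ``strict``.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        tid = (exon.attributes.get("transcript_id") or [""])[0]
        if not tid:
            parents = exon.attributes.get("Parent") or [""]
            tid = parents[0]
        if not tid:
            logger.warning("exon without transcript_id at %s:%s", exon.seqid, exon.start)
            continue
        gid = (exon.attributes.get("gene_id") or [""])[0]
        biotype = "protein_coding"
        for key in _BIOTYPE_KEYS:
            vals = exon.attributes.get(key)
            if vals:
                biotype = vals[0]
                break
        rec = grouped.setdefault(
            tid,
            {
                "gene_id": gid,
                "chrom": exon.seqid,
                "strand": exon.strand,
                "biotype": biotype,
                "exons": [],
            },
        )
        rec["exons"].append((exon.start, exon.end))

    models = []
    for tid, rec in grouped.items():
        try:
            models.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=rec["gene_id"],
                    chrom=rec["chrom"],
                    strand=rec["strand"],
                    exons=tuple(sorted(rec["exons"])),
                    biotype=rec["biotype"],
                )
            )
        except MalformedRecordError as exc:
            if strict:
                raise
            logger.warning("skipping malformed transcript: %s", exc)
    models.sort(key=lambda m: (m.chrom, m.exons[0][0], m.transcript_id))
    return models


def read_bed12(path: str, strict: bool = False) -> list[TranscriptModel]:
    """Read transcript models from BED12 (blocks are exons).

    The name field is ``gene_id|transcript_id``; a bare name serves as
    both.  thickStart/thickEnd are ignored.
    """
    models = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                msg = f"{path}:{ln}: expected 12 BED columns, got {len(f)}"
                if strict:
                    raise MalformedRecordError(msg)
                logger.warning(msg)
                continue
            chrom, chrom_start, _, name, _, strand = f[0], int(f[1]), f[2], f[3], f[4], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            # BED is 0-based half-open; convert blocks to 1-based inclusive
            exons = tuple(
                (chrom_start + st + 1, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            )
            if "|" in name:
                gene_id, tid = name.split("|", 1)
            else:
                gene_id = tid = name
            try:
                models.append(
                    TranscriptModel(tid, gene_id, chrom, strand, exons)
                )
            except MalformedRecordError as exc:
                if strict:
                    raise
                logger.warning("skipping malformed transcript: %s", exc)
    return models


TSS_TSV_COLUMNS = (
    "gene_id",
    "chrom",
    "strand",
    "tss_position",
    "evidence_score",
    "transcript_id",
)


def write_tss_tsv(collections: Sequence[TSSCollection], path: str) -> None:
    """Write TSS evidence points as TSV (positions 1-based)."""
    with open(path, "w") as fh:
        fh.write("\t".join(TSS_TSV_COLUMNS) + "\n")
        for coll in collections:
            for pt in coll.tss_points:
                fh.write(
                    f"{coll.gene_id}\t{coll.chrom}\t{coll.strand}\t"
                    f"{pt.position}\t{pt.evidence_score:g}\t{pt.transcript_id}\n"
                )


def read_tss_tsv(path: str) -> list[TSSCollection]:
    by_gene: dict[str, TSSCollection] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            gid = f[idx["gene_id"]]
            coll = by_gene.setdefault(
                gid,
                TSSCollection(gid, f[idx["chrom"]], f[idx["strand"]]),
            )
            coll.tss_points.append(
                TSSEvidence(
                    position=int(f[idx["tss_position"]]),
                    evidence_score=float(f[idx["evidence_score"]]),
                    source="mRNA_model",
                    transcript_id=f[idx.get("transcript_id", -1)]
                    if "transcript_id" in idx
                    else "",
                )
            )
    return [by_gene[g] for g in sorted(by_gene)]
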
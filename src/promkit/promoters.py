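"""Promoter interval and sequence extraction around called vTSSs.

The promoter of a vTSS spans 10,000 nt upstream through 1,000 nt
downstream of the vTSS, with the vTSS base itself counted as position +1
of the downstream side, so an unclipped promoter is 11,001 nt long.  On
the - strand "upstream" means larger genomic coordinates and the
returned sequence is reverse-complemented, so the vTSS base always sits
at 0-based offset ``upstream`` of the returned sequence.  Intervals are
clipped to the contig and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .vtss import VTSS

DEFAULT_UPSTREAM = 10_000
DEFAULT_DOWNSTREAM = 1_000

_COMPLEMENT = str.maketrans("ACGTacgtNnRYKMrykm", "TGCAtgcaNnYRMKyrmk")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ContigError(KeyError):
    """vTSS refers to a contig missing from the genome."""


@dataclass
class PromoterRecord:
    """An extracted promoter: interval (1-based inclusive) plus sequence.

    ``vtss_offset`` is the 0-based offset of the vTSS base within
    ``sequence`` (equal to ``upstream`` when unclipped).
    """

    gene_id: str
    vtss: VTSS
    start: int
    end: int
    sequence: str
    clipped: bool
    vtss_offset: int

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return len(self.sequence)


def extract_promoter(
    vtss: VTSS,
    genome,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> PromoterRecord:
    """Extract the promoter sequence around one vTSS.

    ``genome`` is a mapping from contig name to sequence supporting
    ``str()`` (a ``pyfaidx.Fasta`` or a plain ``dict`` of strings).
    """
    if vtss.chrom not in genome:
        raise ContigError(f"contig {vtss.chrom!r} not in genome")
    contig = genome[vtss.chrom]
    contig_len = len(contig)
    p = vtss.position
    if not (1 <= p <= contig_len):
        raise ValueError(
            f"vTSS position {p} outside contig {vtss.chrom} (length {contig_len})"
        )
    if vtss.strand == "+":
        lo, hi = p - upstream, p + downstream
    else:
        lo, hi = p - downstream, p + upstream
    clipped = lo < 1 or hi > contig_len
    lo, hi = max(lo, 1), min(hi, contig_len)
    if hi < lo:
        raise ValueError(f"empty promoter interval for {vtss.gene_id}")
    raw = str(contig[lo - 1 : hi]).upper()
    if vtss.strand == "+":
        seq = raw
        offset = p - lo
    else:
        seq = reverse_complement(raw)
        offset = hi - p
    return PromoterRecord(
        gene_id=vtss.gene_id,
        vtss=vtss,
        start=lo,
        end=hi,
        sequence=seq,
        clipped=clipped,
        vtss_offset=offset,
    )


def extract_promoters(
    vtss_list: Iterable[VTSS],
    genome,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> list[PromoterRecord]:
    return [extract_promoter(v, genome, upstream, downstream) for v in vtss_list]


# FASTA header grammar: >gene_id|class|chrom:start-end|strand
def promoter_fasta_header(rec: PromoterRecord) -> str:
    v = rec.vtss
    return f"{rec.gene_id}|{v.promoter_class}|{v.chrom}:{rec.start}-{rec.end}|{v.strand}"


def write_promoters_fasta(records: Sequence[PromoterRecord], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{promoter_fasta_header(rec)}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_promoters_bed(records: Sequence[PromoterRecord], path: str) -> None:
    with open(path, "w") as fh:
        for rec in records:
            v = rec.vtss
            fh.write(
                f"{v.chrom}\t{rec.start - 1}\t{rec.end}\t"
                f"{rec.gene_id}|{v.promoter_class}\t{v.percent:.1f}\t{v.strand}\n"
            )


def read_fasta(path: str) -> dict[str, str]:
    """Plain multi-FASTA reader returning {header: sequence}."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].strip()
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs
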
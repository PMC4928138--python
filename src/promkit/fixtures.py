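"""Deterministic synthetic data: toy genomes, transcripts, PWMs, variants.

The generator emulates the minimal structure the pipeline consumes:

* i.i.d. uniform-ACGT contigs (the simplest null background, so planted
  signal is unambiguous and false-positive rates are interpretable);
* genes whose transcripts start in Gaussian clusters around planted
  centers, each transcript a two-exon mRNA model — the planted cluster
  with the most transcripts is the expected best supported promoter;
* synthetic PWMs with near-degenerate columns whose consensus is
  planted at chosen offsets (reverse-complemented for - strand sites);
* SNVs with a constructed intended effect: ``lossy`` replaces a planted
  consensus base at a maximally informative position with the matrix's
  minimal-frequency base, ``gainy`` restores a deliberately corrupted
  consensus base, ``neutral`` changes background sequence away from any
  planted site.

Everything derives from a single integer seed; the same spec and seed
reproduce byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .match import BASES, PWM, write_cutoffs_tsv, write_matrices_transfac
from .promoters import reverse_complement
from .tss import TranscriptModel
from .variants import VariantRecord

EFFECT_LOSSY = "lossy"
EFFECT_GAINY = "gainy"
EFFECT_NEUTRAL = "neutral"

#: consensus-base frequency of synthetic PWM columns (remainder split
#: evenly); near-degenerate so planted sites score MSS = 1
CONSENSUS_FREQ = 0.91


class FixtureSpecError(ValueError):
    pass


@dataclass(frozen=True)
class ClusterSpec:
    center: int
    spread_sd: float
    n_transcripts: int


@dataclass(frozen=True)
class GeneSpec:
    gene_id: str
    contig: str
    strand: str
    clusters: tuple[ClusterSpec, ...]
    biotype: str = "protein_coding"


@dataclass(frozen=True)
class PWMSpec:
    matrix_id: str
    length: int
    #: per-position column concentration in (0, 1]; 1 = CONSENSUS_FREQ
    #: columns throughout. Scalar profile applied to all positions.
    information_profile: tuple[float, ...] | None = None


@dataclass(frozen=True)
class PlantedSite:
    matrix_id: str
    contig: str
    offset: int  # 0-based start of the site in the contig
    strand: str = "+"


@dataclass(frozen=True)
class PlantedVariantSpec:
    effect: str  # lossy | gainy | neutral
    matrix_id: str | None = None  # site-directed effects name their matrix
    contig: str | None = None  # neutral variants name a contig


@dataclass
class FixtureSpec:
    seed: int
    contigs: tuple[tuple[str, int], ...]
    genes: tuple[GeneSpec, ...] = ()
    pwms: tuple[PWMSpec, ...] = ()
    planted_sites: tuple[PlantedSite, ...] = ()
    variants: tuple[PlantedVariantSpec, ...] = ()

    @classmethod
    def from_json(cls, path: str) -> "FixtureSpec":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            seed=d["seed"],
            contigs=tuple((c["name"], c["length"]) for c in d["contigs"]),
            genes=tuple(
                GeneSpec(
                    g["gene_id"],
                    g["contig"],
                    g["strand"],
                    tuple(
                        ClusterSpec(c["center"], c["spread_sd"], c["n_transcripts"])
                        for c in g["clusters"]
                    ),
                    g.get("biotype", "protein_coding"),
                )
                for g in d.get("genes", [])
            ),
            pwms=tuple(
                PWMSpec(
                    p["matrix_id"],
                    p["length"],
                    tuple(p["information_profile"])
                    if p.get("information_profile")
                    else None,
                )
                for p in d.get("pwms", [])
            ),
            planted_sites=tuple(
                PlantedSite(s["matrix_id"], s["contig"], s["offset"], s.get("strand", "+"))
                for s in d.get("planted_sites", [])
            ),
            variants=tuple(
                PlantedVariantSpec(v["effect"], v.get("matrix_id"), v.get("contig"))
                for v in d.get("variants", [])
            ),
        )


@dataclass
class Fixture:
    """In-memory fixture: sequences, models, PWMs, variants and truth."""

    spec: FixtureSpec
    sequences: dict[str, str]
    models: list[TranscriptModel]
    pwms: list[PWM]
    cutoffs: dict[str, tuple[float, float]]
    variants: list[VariantRecord]
    truth_clusters: list[dict]  # gene_id, contig, strand, center, n, expected_best
    truth_sites: list[dict]  # matrix_id, contig, offset, strand
    truth_variants: list[dict]  # variant_id, effect, matrix_id


def _make_pwm(spec: PWMSpec, rng: np.random.Generator) -> PWM:
    consensus = rng.integers(0, 4, size=spec.length)
    profile = spec.information_profile or (1.0,) * spec.length
    if len(profile) != spec.length:
        raise FixtureSpecError(
            f"{spec.matrix_id}: information_profile length != matrix length"
        )
    freqs = np.empty((spec.length, 4))
    for i, conc in enumerate(profile):
        top = 0.25 + (CONSENSUS_FREQ - 0.25) * conc
        rest = (1.0 - top) / 3.0
        freqs[i] = rest
        freqs[i, consensus[i]] = top
    return PWM(spec.matrix_id, freqs)


def _plant_site(seq: list[str], site: PlantedSite, pwm: PWM) -> None:
    s = pwm.consensus if site.strand == "+" else reverse_complement(pwm.consensus)
    if site.offset < 0 or site.offset + len(s) > len(seq):
        raise FixtureSpecError(
            f"site {site.matrix_id}@{site.contig}:{site.offset} outside contig"
        )
    seq[site.offset : site.offset + len(s)] = list(s)


def _transcripts_for_gene(
    gene: GeneSpec, contig_len: int, rng: np.random.Generator
) -> tuple[list[TranscriptModel], list[dict]]:
    models = []
    truth = []
    best_idx = max(
        range(len(gene.clusters)),
        key=lambda i: (
            gene.clusters[i].n_transcripts,
            # 5'-most wins ties
            -gene.clusters[i].center if gene.strand == "+" else gene.clusters[i].center,
        ),
    )
    t = 0
    for ci, cl in enumerate(gene.clusters):
        drawn: list[int] = []
        for _ in range(cl.n_transcripts):
            tss = int(round(rng.normal(cl.center, cl.spread_sd))) if cl.spread_sd else cl.center
            tss = min(max(tss, 500), contig_len - 500)
            drawn.append(tss)
            if gene.strand == "+":
                exons = ((tss, tss + 149), (tss + 300, tss + 449))
            else:
                exons = ((tss - 449, tss - 300), (tss - 149, tss))
            t += 1
            models.append(
                TranscriptModel(
                    transcript_id=f"{gene.gene_id}.t{t}",
                    gene_id=gene.gene_id,
                    chrom=gene.contig,
                    strand=gene.strand,
                    exons=exons,
                    biotype=gene.biotype,
                )
            )
        truth.append(
            {
                "gene_id": gene.gene_id,
                "contig": gene.contig,
                "strand": gene.strand,
                "center": cl.center,
                # realized center: mean of the TSSs actually drawn — the
                # estimand available to the caller in this replicate
                "realized_center": int(round(float(np.mean(drawn)))),
                "spread_sd": cl.spread_sd,
                "n_transcripts": cl.n_transcripts,
                "expected_best": ci == best_idx,
            }
        )
    return models, truth


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Materialise a fixture spec into in-memory objects.

    Raises :class:`FixtureSpecError` for overlapping planted sites of
    the same matrix or out-of-bounds coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    pwms = [_make_pwm(p, rng) for p in spec.pwms]
    pwm_by_id = {p.matrix_id: p for p in pwms}

    # overlapping same-matrix sites are a spec error
    by_matrix: dict[str, list[PlantedSite]] = {}
    for s in spec.planted_sites:
        if s.matrix_id not in pwm_by_id:
            raise FixtureSpecError(f"planted site references unknown matrix {s.matrix_id}")
        by_matrix.setdefault(s.matrix_id, []).append(s)
    for mid, site_list in by_matrix.items():
        L = len(pwm_by_id[mid])
        spans = sorted(
            (s.contig, s.offset, s.offset + L) for s in site_list
        )
        for (c1, a1, b1), (c2, a2, b2) in zip(spans, spans[1:]):
            if c1 == c2 and a2 < b1:
                raise FixtureSpecError(f"overlapping planted sites for matrix {mid}")

    sequences: dict[str, list[str]] = {
        name: list("".join(rng.choice(list(BASES), size=length)))
        for name, length in spec.contigs
    }

    for site in spec.planted_sites:
        if site.contig not in sequences:
            raise FixtureSpecError(f"planted site on unknown contig {site.contig}")
        _plant_site(sequences[site.contig], site, pwm_by_id[site.matrix_id])

    models: list[TranscriptModel] = []
    truth_clusters: list[dict] = []
    contig_lens = dict(spec.contigs)
    for gene in spec.genes:
        if gene.contig not in sequences:
            raise FixtureSpecError(f"gene {gene.gene_id} on unknown contig {gene.contig}")
        ms, tr = _transcripts_for_gene(gene, contig_lens[gene.contig], rng)
        models.extend(ms)
        truth_clusters.extend(tr)

    # cutoffs chosen so a single lossy/gainy consensus flip crosses the
    # MSS threshold by construction: one flip moves MSS by 1/L, the
    # cutoff sits at the midpoint 1 - 1/(2L); css gate kept permissive
    cutoffs = {
        p.matrix_id: (1.0 - 1.0 / (2 * len(p)), 0.5) for p in pwms
    }

    variants: list[VariantRecord] = []
    truth_variants: list[dict] = []
    sites_by_matrix = {
        mid: sorted(sl, key=lambda s: (s.contig, s.offset))
        for mid, sl in by_matrix.items()
    }
    occupied = [
        (s.contig, s.offset, s.offset + len(pwm_by_id[s.matrix_id]))
        for s in spec.planted_sites
    ]
    for vi, vspec in enumerate(spec.variants, 1):
        vid = f"var{vi}"
        if vspec.effect in (EFFECT_LOSSY, EFFECT_GAINY):
            if not vspec.matrix_id or vspec.matrix_id not in sites_by_matrix:
                raise FixtureSpecError(
                    f"{vspec.effect} variant needs a planted matrix_id"
                )
            site = sites_by_matrix[vspec.matrix_id][0]
            pwm = pwm_by_id[vspec.matrix_id]
            k = int(np.argmax(pwm.information))  # most informative position
            cons = pwm.consensus[k]
            worst = pwm.anti_consensus[k]
            if site.strand == "+":
                pos0 = site.offset + k
                ref_site_base, alt_site_base = cons, worst
            else:
                pos0 = site.offset + (len(pwm) - 1 - k)
                ref_site_base = reverse_complement(cons)
                alt_site_base = reverse_complement(worst)
            if vspec.effect == EFFECT_LOSSY:
                ref, alt = ref_site_base, alt_site_base
            else:
                # corrupt the genome so the variant's alt restores consensus
                sequences[site.contig][pos0] = alt_site_base
                ref, alt = alt_site_base, ref_site_base
            variants.append(
                VariantRecord(site.contig, pos0 + 1, ref, alt, vid)
            )
            truth_variants.append(
                {"variant_id": vid, "effect": vspec.effect, "matrix_id": vspec.matrix_id}
            )
        elif vspec.effect == EFFECT_NEUTRAL:
            contig = vspec.contig or spec.contigs[0][0]
            length = contig_lens[contig]
            for _ in range(1000):
                pos0 = int(rng.integers(0, length))
                clear = all(
                    not (c == contig and a - 30 <= pos0 < b + 30)
                    for c, a, b in occupied
                )
                if clear:
                    break
            else:  # pragma: no cover - pathological spec
                raise FixtureSpecError("no background position free of planted sites")
            ref = sequences[contig][pos0]
            alt = rng.choice([b for b in BASES if b != ref])
            variants.append(VariantRecord(contig, pos0 + 1, ref, str(alt), vid))
            truth_variants.append(
                {"variant_id": vid, "effect": EFFECT_NEUTRAL, "matrix_id": ""}
            )
        else:
            raise FixtureSpecError(f"unknown variant effect {vspec.effect!r}")

    return Fixture(
        spec=spec,
        sequences={k: "".join(v) for k, v in sequences.items()},
        models=models,
        pwms=pwms,
        cutoffs=cutoffs,
        variants=variants,
        truth_clusters=truth_clusters,
        truth_sites=[
            {
                "matrix_id": s.matrix_id,
                "contig": s.contig,
                "offset": s.offset,
                "strand": s.strand,
            }
            for s in spec.planted_sites
        ],
        truth_variants=truth_variants,
    )


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------


def write_fixture(fixture: Fixture, out_dir: str) -> dict[str, Path]:
    """Write FASTA, GTF, TRANSFAC matrices, cutoff TSV, VCF and truth TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "genome.fa",
        "gtf": out / "transcripts.gtf",
        "matrices": out / "matrices.dat",
        "cutoffs": out / "cutoffs.tsv",
        "vcf": out / "variants.vcf",
        "truth_clusters": out / "truth_clusters.tsv",
        "truth_sites": out / "truth_sites.tsv",
        "truth_variants": out / "truth_variants.tsv",
    }

    with open(paths["fasta"], "w") as fh:
        for name in sorted(fixture.sequences):
            fh.write(f">{name}\n")
            seq = fixture.sequences[name]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

    with open(paths["gtf"], "w") as fh:
        for m in fixture.models:
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'gene_biotype "{m.biotype}";'
            )
            start = min(e[0] for e in m.exons)
            end = max(e[1] for e in m.exons)
            fh.write(
                f"{m.chrom}\tfixture\ttranscript\t{start}\t{end}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for es, ee in m.exons:
                fh.write(
                    f"{m.chrom}\tfixture\texon\t{es}\t{ee}\t.\t{m.strand}\t.\t{attrs}\n"
                )

    write_matrices_transfac(fixture.pwms, str(paths["matrices"]))
    write_cutoffs_tsv(fixture.cutoffs, str(paths["cutoffs"]))

    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name in sorted(fixture.sequences):
            fh.write(f"##contig=<ID={name},length={len(fixture.sequences[name])}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(fixture.variants, key=lambda v: (v.chrom, v.pos)):
            fh.write(f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}\t.\t.\t.\n")

    with open(paths["truth_clusters"], "w") as fh:
        fh.write(
            "gene_id\tcontig\tstrand\tcenter\trealized_center\t"
            "spread_sd\tn_transcripts\texpected_best\n"
        )
        for t in fixture.truth_clusters:
            fh.write(
                f"{t['gene_id']}\t{t['contig']}\t{t['strand']}\t{t['center']}\t"
                f"{t['realized_center']}\t"
                f"{t['spread_sd']:g}\t{t['n_transcripts']}\t{int(t['expected_best'])}\n"
            )
    with open(paths["truth_sites"], "w") as fh:
        fh.write("matrix_id\tcontig\toffset\tstrand\n")
        for t in fixture.truth_sites:
            fh.write(f"{t['matrix_id']}\t{t['contig']}\t{t['offset']}\t{t['strand']}\n")
    with open(paths["truth_variants"], "w") as fh:
        fh.write("variant_id\teffect\tmatrix_id\n")
        for t in fixture.truth_variants:
            fh.write(f"{t['variant_id']}\t{t['effect']}\t{t['matrix_id']}\n")
    return paths


# ---------------------------------------------------------------------------
# Canonical small specs used across the test-suite and examples
# ---------------------------------------------------------------------------


def two_cluster_spec(
    seed: int,
    strand: str = "+",
    center_a: int = 30_000,
    center_b: int = 50_000,
    spread_sd: float = 150.0,
    n_major: int = 12,
    n_minor: int = 3,
) -> FixtureSpec:
    """One gene with a 12- vs 3-transcript TSS cluster pair 20 kb apart."""
    return FixtureSpec(
        seed=seed,
        contigs=(("chrT", 80_000),),
        genes=(
            GeneSpec(
                "GENE1",
                "chrT",
                strand,
                (
                    ClusterSpec(center_a, spread_sd, n_major),
                    ClusterSpec(center_b, spread_sd, n_minor),
                ),
            ),
        ),
    )


def gain_loss_spec(seed: int, matrix_length: int = 10) -> FixtureSpec:
    """One planted site plus one lossy and (elsewhere) one gainy variant."""
    return FixtureSpec(
        seed=seed,
        contigs=(("chrT", 2_000),),
        pwms=(
            PWMSpec("M_LOSS", matrix_length),
            PWMSpec("M_GAIN", matrix_length),
        ),
        planted_sites=(
            PlantedSite("M_LOSS", "chrT", 400, "+"),
            PlantedSite("M_GAIN", "chrT", 900, "+"),
        ),
        variants=(
            PlantedVariantSpec(EFFECT_LOSSY, matrix_id="M_LOSS"),
            PlantedVariantSpec(EFFECT_GAINY, matrix_id="M_GAIN"),
        ),
    )
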
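# Methods

This note documents the models and numerical choices behind `promkit`,
in the order the pipeline runs.

## TSS evidence collection

A transcript's TSS is the first nucleotide of its most 5' exon: the
smallest exon start on the + strand, the largest exon end on the −
strand. Every retained transcript contributes one evidence point, so
identical TSS positions from different transcripts are deliberately
kept as separate points — the multiplicity *is* the evidence. Evidence
scores are a per-source map defaulting to 5 for mRNA-model-derived
TSSs; the map is configurable so other evidence types (e.g. CAGE) could
be weighted differently, but none ship with the package.

Genes are filtered to protein-coding and miRNA biotypes by default.
Mitochondrial genes are excluded because mitochondrial transcription is
polycistronic and promoter calling around per-gene TSSs is meaningless
there; the exclusion matches `MT`/`chrM`/`chrMT` case-insensitively and
the list is configurable since chromosome naming varies across
annotation sources. Transcripts without a gene id are skipped with a
warning rather than failing a whole run; structurally malformed records
(end < start, overlapping exons, bad strand) raise a record-level error
naming the transcript.

All genomic coordinates are handled 1-based inclusive internally (the
GTF convention, and the convention of every user-facing report);
conversion to 0-based half-open happens only at BED boundaries. This is
asserted by the round-trip tests.

## vTSS clustering

The clustering score at center *c* is the cosine-weighted sum of
evidence within half a window:
`score(c) = Σ s_t · cos(π·|p_t − c|/W)` for `|p_t − c| ≤ W/2`, with
window `W = 3000` nt. The window slides at 1-nt steps over
`[min(TSS) − W/2, max(TSS) + W/2]`; gene TSS spans are small enough
that exactness costs nothing, and any strided scan's peaks are a subset
of the exact scan's. The implementation accumulates one cosine bump per
evidence point (O(n·W)); a brute-force per-position oracle in the test
suite checks equality to 1e-9 on random TSS sets.

Peaks are strict local maxima; a plateau of tolerance-equal values
(tolerance 1e-9, also used for score ties everywhere) is reported once
at its 5'-most position, consistent with the method's general 5'
preference in tie cases.

Selection: percent share of each candidate = 100 × score / (sum over
**all** candidate peaks). The shared denominator is forced by the
worked two-promoter example, where the two printed shares (46.3 % and
12.2 %) sum to well under 100 %. Candidates with share ≥ 8 % are
selected. If the cumulative candidate score falls below
`min_cumulative_score` the gene keeps only its 5'-most candidate
(class `single`). The highest-share selected candidate (ties 5'-most)
is `best_supported`; a selection that retains exactly one candidate is
also reported as `single`. `min_cumulative_score` defaults to 15 —
three default evidence points — and is an explicitly non-authoritative
configuration knob: no published value exists for it, so it is exposed
and documented rather than hard-coded.

## Promoter extraction

The promoter interval spans 10,000 nt upstream through 1,000 nt
downstream of the vTSS, reading the bounds as a closed interval around
the vTSS base, total length 11,001. The "is the vTSS base upstream or
downstream" off-by-one is not resolvable from the published interval
arithmetic; this package counts the vTSS base as position +1 of the
downstream side, documents it here, and asserts it in tests. On the −
strand the interval is mirrored and the sequence reverse-complemented,
so the vTSS base always sits at 0-based offset `upstream` of the
returned sequence (the `vtss_offset` field reports the actual offset
when contig-boundary clipping shifts it). Ambiguity codes pass through
unchanged. FASTA headers use a fixed grammar
`gene|class|chrom:start-end|strand`.

## Match-style PWM scanning

Count matrices (TRANSFAC flat file or JASPAR PFM, parsed with
Bio.motifs) are regularised with a pseudocount:
`f(i,b) = (n(i,b) + p) / (N(i) + 4p)`, `p = 0.25` by default. The
pseudocount keeps frequencies strictly positive so `ln f` is defined;
its exact value is immaterial for well-populated matrices.

Information vector: `I(i) = Σ_b f·ln(4f)` in natural log. Any fixed log
base rescales Current, Min and Max identically and cancels in the
min–max normalisation (asserted by a log₂ oracle test). The core is
the exhaustive maximal-information 5-window (leftmost on ties);
vendor-curated core definitions are proprietary, so the exhaustive
reconstruction is the rule. Matrices shorter than 5 use all positions.

Scanning evaluates CSS first as a gate, then MSS, on both strands;
windows containing non-ACGT bases are skipped; an all-uniform matrix
(Max = Min) is skipped with a warning. `best_per_sequence` mode keeps
the maximal-MSS hit per (sequence, matrix), ties broken by smaller
offset then + strand — a deterministic ordering so reruns are
identical. Per-matrix cutoff TSVs are accepted; the global fallbacks
(MSS 0.85, CSS 0.75) are non-authoritative defaults, since calibrated
per-matrix profiles (minFP/minSUM style) belong to the matrix vendor.

## Variant annotation

Variants are filtered to a strand-oriented window around vTSSs
(default −500/+100 nt; negative = upstream on both strands), then
overlapped with TFBS intervals (inclusive on both ends; interval-tree
backed, equal to the brute-force all-pairs comparison by test).
Site-relative positions are 0-based offsets from the site start, fixed
by the worked example in which coordinate 113,760,091 in a site
starting at 113,760,083 is "position 8". Multi-allelic VCF records are
split per alt.

Gain/loss analysis substitutes an SNV set into the site sequence
(reference alleles are verified against the sequence and a mismatch is
a hard error naming the coordinate — this guards against genome-build
mix-ups), scans reference and alternate in **all-hits** mode so that
newly created secondary sites are visible, and pairs hits per matrix by
overlapping same-strand spans. Unpaired reference hits are `lost`,
unpaired alternate hits `gained`; paired hits are `retained` when
|ΔMSS| < 1e-6, else `score_changed`. Swapping ref and alt alleles
swaps lost and gained exactly (tested). Indels are accepted for overlap
reporting but rejected from rescoring with a clear error; rescoring
alignment-changing variants is out of scope for this version. Default
flank padding for scanning is 25 nt, expanded to the longest matrix
length − 1 when needed so boundary sites remain scannable.

## Validation analytics

* **TFBS distance to vTSS** uses the site midpoint as reference point
  by default (configurable to `start`; no published convention exists).
  Distances are strand-oriented, negative upstream, restricted to the
  promoter extent.
* **KDE** is a Gaussian kernel estimate (scipy `gaussian_kde`,
  Silverman bandwidth by default) evaluated on a grid extending four
  bandwidths past the data, so the trapezoidal integral over the grid
  lies in [0.99, 1.01]. All-identical inputs receive a negligible
  deterministic jitter to keep the covariance non-singular.
* **Build comparison** pairs promoters within each shared gene greedily
  by nearest position, best supported first (no published pairing rule
  exists; greedy nearest is the simplest deterministic choice). Genes
  present in only one set are excluded, mirroring annotation-ID
  turnover between genome builds; shift bins are 0 / 1–10 / 11–100 /
  101–1,000 / other, and bin counts plus excluded-gene promoters
  partition set A exactly (tested invariant). Percents are rounded
  half-away-from-zero to integers with set-A totals as denominators.

## Synthetic data generator

The generator emulates exactly the structure the pipeline consumes:
i.i.d. uniform-ACGT contigs (the simplest null background, making
planted signal unambiguous and false-positive rates interpretable),
two-exon transcripts whose TSSs are Gaussian draws around planted
cluster centers, near-degenerate PWMs (consensus-base frequency 0.91)
whose consensus is written into the background at planted offsets, and
SNVs with constructed effects. It does not emulate GC structure,
repeats, overlapping genes or alternative splicing, so passing recovery
tests demonstrate correctness of the calling machinery, not performance
on real genomes.

The default study conditions are: two clusters of 12 vs. 3 transcripts,
σ = 150 nt, 20 kb apart, for cluster recovery; matrix length 10 with
uniform information profile for variant effects. For a planted matrix
of length L with equally informative positions, a single consensus flip
moves MSS by exactly 1/L, so the generated cutoff table places each
matrix's MSS cutoff at the midpoint 1 − 1/(2L) (CSS cutoff 0.5, kept
permissive so the matrix-level score decides). Lossy variants flip a
maximal-information consensus base to the matrix's minimal-frequency
base; gainy variants restore a base the generator deliberately
corrupted; neutral variants hit background at least 30 nt from any
planted site.

Truth tables record both the planted cluster center and the *realized*
center (the mean of the TSSs actually drawn in that replicate).
Recovery is measured against the realized center: with only three
transcripts in the minor cluster, the center estimate's sampling error
is σ/√3 ≈ 87 nt, so the realized center — not the asymptotic planted
one — is the estimand a caller can identify from the data. Against the
realized centers, two-cluster recovery within ±σ with correct
best-supported assignment holds in ≥ 95 % of seeded replicates
(measured ≈ 100 %), as does recovery of planted variant effects.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data:
200 random TSS sets for the profile oracle, 200 two-cluster replicates
and 100 gain/loss replicates for recovery, contigs of 2–80 kb. These
sizes give stable statistics for the stochastic checks while keeping a
full run in the tens of seconds.

## Known limitations

* Single-promoter evidence type (mRNA models); no CAGE/EST weighting.
* Indels are not rescored for gain/loss.
* Cross-gene cluster merging and bidirectional promoters are not
  modelled; each gene is clustered independently.
* Default MSS/CSS cutoffs are uncalibrated fallbacks; serious use
  requires per-matrix cutoff tables.
* The build comparison assumes stable gene identifiers; it does not
  attempt liftover or ID mapping.
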
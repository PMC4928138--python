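"""Match-style PWM scanning: matrix and core similarity scores.

A position weight matrix (PWM) holds per-position base frequencies
f(i, b).  The information vector

    I(i) = sum_b f(i, b) * ln(4 f(i, b))        (0 * ln 0 := 0)

weights conserved positions more heavily; I(i) is 0 for a uniform column
and ln 4 for a fully degenerate one.  For a candidate window carrying
base b_i at position i, the matrix similarity score is the min-max
normalised information-weighted sum

    MSS = (Current - Min) / (Max - Min)
    Current = sum_i I(i) f(i, b_i)
    Min     = sum_i I(i) min_b f(i, b)
    Max     = sum_i I(i) max_b f(i, b)

so MSS is 1 exactly on the consensus (per-position argmax) and 0 on the
anti-consensus.  The core similarity score (CSS) is the same statistic
restricted to the core: the 5 consecutive positions with maximal summed
information.  Scanning evaluates CSS first as a gatekeeper, then MSS,
on both strands; ``best_per_sequence`` mode keeps at most one hit per
(sequence, matrix) — the maximal-MSS hit, ties broken by smaller offset
then + strand.

The natural logarithm is used throughout; any fixed log base rescales
Current, Min and Max identically and leaves the scores unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .promoters import reverse_complement

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

CORE_WIDTH = 5
#: global fallback cutoffs used when no per-matrix cutoff is supplied.
#: Non-authoritative defaults; per-matrix profiles (e.g. minFP / minSUM
#: style tables) should be provided where available.
DEFAULT_MSS_CUTOFF = 0.85
DEFAULT_CSS_CUTOFF = 0.75

MODE_ALL = "all_hits"
MODE_BEST = "best_per_sequence"


class MatrixValidationError(ValueError):
    pass


def information_vector(frequencies: np.ndarray) -> np.ndarray:
    """Per-position information content I(i) = sum_b f ln(4f), in nats."""
    f = np.asarray(frequencies, float)
    if f.ndim != 2 or f.shape[1] != 4:
        raise MatrixValidationError("frequencies must be an (L, 4) table")
    sums = f.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise MatrixValidationError("frequency columns must sum to 1 (±1e-6)")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log(4.0 * f), 0.0)
    return terms.sum(axis=1)


def core_positions(information: np.ndarray, width: int = CORE_WIDTH) -> tuple[int, ...]:
    """The ``width`` consecutive positions maximising summed information.

    For matrices shorter than ``width`` the core is all positions.
    Ties resolve to the leftmost window.
    """
    info = np.asarray(information, float)
    L = len(info)
    if L <= width:
        return tuple(range(L))
    window_sums = np.convolve(info, np.ones(width), mode="valid")
    start = int(np.argmax(window_sums))  # argmax is leftmost on ties
    return tuple(range(start, start + width))


@dataclass
class PWM:
    """A positional weight matrix with information vector and core."""

    matrix_id: str
    frequencies: np.ndarray  # (L, 4), columns A C G T
    factor_name: str = ""
    information: np.ndarray = field(init=False)
    core: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, float)
        self.information = information_vector(self.frequencies)
        self.core = core_positions(self.information)

    @classmethod
    def from_counts(
        cls,
        matrix_id: str,
        counts: np.ndarray,
        factor_name: str = "",
        pseudocount: float = 0.25,
    ) -> "PWM":
        """Regularise a count (or frequency) table into a PWM.

        f(i, b) = (n(i, b) + p) / (N(i) + 4p); the pseudocount keeps all
        frequencies strictly positive so ln f is defined everywhere.
        """
        c = np.asarray(counts, float)
        if np.any(c < 0):
            raise MatrixValidationError(f"{matrix_id}: negative counts")
        totals = c.sum(axis=1, keepdims=True)
        if np.any(totals <= 0):
            raise MatrixValidationError(f"{matrix_id}: empty count column")
        freqs = (c + pseudocount) / (totals + 4 * pseudocount)
        return cls(matrix_id, freqs, factor_name)

    def __len__(self) -> int:
        return self.frequencies.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.frequencies, axis=1))

    @property
    def anti_consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmin(self.frequencies, axis=1))

    def is_uniform(self) -> bool:
        """True when Max == Min, i.e. every column is uniform."""
        return bool(
            np.isclose(
                (self.information * self.frequencies.max(axis=1)).sum(),
                (self.information * self.frequencies.min(axis=1)).sum(),
            )
        )


def matrix_similarity(
    window: str, pwm: PWM, positions: Sequence[int] | None = None
) -> float:
    """MSS of one window; ``positions`` restricts to a subset (e.g. core)."""
    if len(window) != len(pwm):
        raise ValueError(
            f"window length {len(window)} != matrix length {len(pwm)}"
        )
    idx = np.arange(len(pwm)) if positions is None else np.asarray(positions, int)
    info = pwm.information[idx]
    f = pwm.frequencies[idx]
    try:
        codes = np.array([_BASE_INDEX[window[i]] for i in idx])
    except KeyError as exc:
        raise ValueError(f"non-ACGT base {exc} in scored window") from exc
    current = float((info * f[np.arange(len(idx)), codes]).sum())
    mn = float((info * f.min(axis=1)).sum())
    mx = float((info * f.max(axis=1)).sum())
    if mx - mn <= 0:
        raise MatrixValidationError(f"{pwm.matrix_id}: uninformative matrix (Max == Min)")
    return (current - mn) / (mx - mn)


def core_similarity(window: str, pwm: PWM) -> float:
    return matrix_similarity(window, pwm, positions=pwm.core)


@dataclass(frozen=True)
class MatchHit:
    """A scored PWM occurrence in a scanned sequence.

    ``offset`` is the 0-based start of the site on the forward strand of
    the scanned sequence, for hits on either strand.
    """

    sequence_id: str
    matrix_id: str
    factor_name: str
    offset: int
    strand: str
    mss: float
    css: float


def _encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3; anything else -> 4 (excluded from scoring)."""
    table = np.full(256, 4, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _scan_one_strand(
    enc: np.ndarray, pwm: PWM, positions: np.ndarray
) -> np.ndarray:
    """Vector of min-max scores at every offset (NaN where a window has N)."""
    L = len(pwm)
    n_off = len(enc) - L + 1
    info = pwm.information[positions]
    # weight table with a NaN column for non-ACGT codes
    w = np.concatenate(
        [pwm.frequencies[positions] * info[:, None], np.full((len(positions), 1), np.nan)],
        axis=1,
    )
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)[:n_off]
    sub = windows[:, positions]
    current = w[np.arange(len(positions))[None, :], sub].sum(axis=1)
    mn = float((info * pwm.frequencies[positions].min(axis=1)).sum())
    mx = float((info * pwm.frequencies[positions].max(axis=1)).sum())
    return (current - mn) / (mx - mn)


def scan(
    sequences: dict[str, str] | Iterable[tuple[str, str]],
    pwm_library: Sequence[PWM],
    cutoffs: dict[str, tuple[float, float]] | None = None,
    mode: str = MODE_ALL,
    default_mss_cutoff: float = DEFAULT_MSS_CUTOFF,
    default_css_cutoff: float = DEFAULT_CSS_CUTOFF,
    strands: str = "both",
) -> list[MatchHit]:
    """Scan sequences with a PWM library on both strands.

    ``cutoffs`` maps matrix_id -> (mss_cutoff, css_cutoff); matrices
    without an entry use the global defaults.  The CSS gate is applied
    first, then the MSS threshold.  Uninformative (all-uniform) matrices
    are skipped with a warning.
    """
    if mode not in (MODE_ALL, MODE_BEST):
        raise ValueError(f"unknown scan mode {mode!r}")
    if not pwm_library:
        raise ValueError("empty PWM library")
    items = sequences.items() if isinstance(sequences, dict) else sequences
    cutoffs = cutoffs or {}
    hits: list[MatchHit] = []
    for seq_id, seq in items:
        enc_fwd = _encode(seq)
        enc_rev = _encode(reverse_complement(seq))
        n = len(seq)
        for pwm in pwm_library:
            if pwm.is_uniform():
                logger.warning("matrix %s is uninformative; skipped", pwm.matrix_id)
                continue
            L = len(pwm)
            if n < L:
                continue
            mss_cut, css_cut = cutoffs.get(
                pwm.matrix_id, (default_mss_cutoff, default_css_cutoff)
            )
            core_idx = np.asarray(pwm.core, int)
            all_idx = np.arange(L)
            per_matrix: list[MatchHit] = []
            strand_list = ["+", "-"] if strands == "both" else [strands]
            for strand in strand_list:
                enc = enc_fwd if strand == "+" else enc_rev
                css = _scan_one_strand(enc, pwm, core_idx)
                with np.errstate(invalid="ignore"):
                    gate = css >= css_cut
                if not gate.any():
                    continue
                mss = _scan_one_strand(enc, pwm, all_idx)
                with np.errstate(invalid="ignore"):
                    keep = gate & (mss >= mss_cut)
                for off in np.flatnonzero(keep):
                    fwd_off = int(off) if strand == "+" else n - int(off) - L
                    per_matrix.append(
                        MatchHit(
                            sequence_id=seq_id,
                            matrix_id=pwm.matrix_id,
                            factor_name=pwm.factor_name,
                            offset=fwd_off,
                            strand=strand,
                            mss=float(mss[off]),
                            css=float(css[off]),
                        )
                    )
            if mode == MODE_BEST and per_matrix:
                per_matrix = [
                    min(per_matrix, key=lambda h: (-h.mss, h.offset, h.strand))
                ]
            hits.extend(per_matrix)
    hits.sort(key=lambda h: (h.sequence_id, h.matrix_id, h.offset, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Matrix and cutoff I/O
# ---------------------------------------------------------------------------


def load_matrices(path: str, fmt: str = "transfac", pseudocount: float = 0.25) -> list[PWM]:
    """Load PWMs from a TRANSFAC flat file or JASPAR PFM file.

    ``fmt`` is ``transfac`` (ID/P0 rows) or ``jaspar`` (``>`` headers with
    4 count rows).  Parsing is delegated to Bio.motifs.
    """
    from Bio import motifs

    fmt_map = {"transfac": "TRANSFAC", "jaspar": "jaspar", "pfm": "pfm"}
    if fmt not in fmt_map:
        raise ValueError(f"unknown matrix format {fmt!r}")
    with open(path) as fh:
        records = motifs.parse(fh, fmt_map[fmt])
    pwms = []
    for m in records:
        counts = np.array([[m.counts[b][i] for b in BASES] for i in range(m.length)])
        matrix_id = getattr(m, "matrix_id", None) or ""
        factor = m.name or ""
        if not matrix_id and hasattr(m, "get"):  # TRANSFAC records are dict-like
            matrix_id = m.get("ID") or m.get("AC") or ""
            bf = m.get("BF") or []
            factor = factor or (bf[0] if isinstance(bf, list) else bf)
        pwms.append(
            PWM.from_counts(matrix_id or factor, counts, factor, pseudocount)
        )
    return pwms


def write_matrices_transfac(pwms: Sequence[PWM], path: str, counts_scale: int = 10_000) -> None:
    """Write PWMs in TRANSFAC flat-file format (frequencies scaled to counts)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f"ID  {pwm.matrix_id}\n")
            fh.write(f"BF  {pwm.factor_name}\n")
            fh.write("P0      A      C      G      T\n")
            for i, row in enumerate(pwm.frequencies, 1):
                vals = "  ".join(f"{v * counts_scale:10.2f}" for v in row)
                fh.write(f"{i:02d}  {vals}\n")
            fh.write("XX\n//\n")


def read_cutoffs_tsv(path: str) -> dict[str, tuple[float, float]]:
    """Read per-matrix cutoffs: columns matrix_id, mss_cutoff, css_cutoff."""
    out: dict[str, tuple[float, float]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 3 or not f[0]:
                continue
            out[f[idx["matrix_id"]]] = (
                float(f[idx["mss_cutoff"]]),
                float(f[idx["css_cutoff"]]),
            )
    return out


def write_cutoffs_tsv(cutoffs: dict[str, tuple[float, float]], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("matrix_id\tmss_cutoff\tcss_cutoff\n")
        for mid in sorted(cutoffs):
            mss, css = cutoffs[mid]
            fh.write(f"{mid}\t{mss:g}\t{css:g}\n")


HITS_TSV_COLUMNS = (
    "sequence_id",
    "matrix_id",
    "factor",
    "offset",
    "strand",
    "mss",
    "css",
)


def write_hits_tsv(hits: Sequence[MatchHit], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(HITS_TSV_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.sequence_id}\t{h.matrix_id}\t{h.factor_name}\t"
                f"{h.offset}\t{h.strand}\t{h.mss:.6f}\t{h.css:.6f}\n"
            )
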
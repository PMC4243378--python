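"""PWM scoring and ordered multi-motif module search.

Scores are MATCH-style matrix-similarity scores: the information-weighted
frequency sum over a window, min-max normalized to [0, 1] so that the PWM
consensus scores 1 and the per-position-worst sequence scores 0. The module
search finds, over both orientations of a segment, the highest-averaging
placement of an ordered set of motifs (RFX5 -> CREB -> NF-Y for the
canonical enhanceosome module) with strictly increasing, non-overlapping
starts on one strand.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
from scipy import stats

from .intervals import ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "PWM",
    "Segment",
    "MotifPlacement",
    "ModuleHit",
    "read_pwm",
    "write_jaspar",
    "pwm_from_consensus",
    "match_score",
    "scan_scores",
    "extract_segments",
    "best_ordered_module",
    "control_segments",
    "compare_score_groups",
]

ALPHABET = "ACGT"
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclasses.dataclass(frozen=True)
class PWM:
    """Position frequency matrix (L x 4, columns A,C,G,T) with information
    vector I(i) = sum_b f(i,b) ln(4 f(i,b))."""

    name: str
    freq: np.ndarray
    info: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freq, dtype=float)
        if f.ndim != 2 or f.shape[1] != 4:
            raise ValueError("frequency matrix must be L x 4")
        if not np.allclose(f.sum(axis=1), 1.0):
            raise ValueError("each position's frequencies must sum to 1")
        if np.any(self.info < -1e-12):
            raise ValueError("information content must be nonnegative")

    @property
    def length(self) -> int:
        return self.freq.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[b] for b in np.argmax(self.freq, axis=1))

    @classmethod
    def from_counts(
        cls, name: str, counts: np.ndarray, pseudocount: float = 0.01
    ) -> "PWM":
        """Counts -> frequencies, then add ``pseudocount`` to every frequency
        cell and renormalize columns (avoids ln 0)."""
        c = np.asarray(counts, dtype=float)
        if c.ndim != 2 or c.shape[1] != 4:
            raise ValueError("count matrix must be L x 4 (columns A,C,G,T)")
        if np.any(c < 0) or np.any(c.sum(axis=1) <= 0):
            raise ValueError("counts must be nonnegative with positive row sums")
        f = c / c.sum(axis=1, keepdims=True)
        f = f + pseudocount
        f /= f.sum(axis=1, keepdims=True)
        info = np.sum(f * np.log(4.0 * f), axis=1)
        return cls(name=name, freq=f, info=np.maximum(info, 0.0))

    def _weights(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(L x 5) weight table (column 4 = per-position minimum, used for N)
        plus the per-position min/max sums."""
        w = self.info[:, None] * self.freq
        wmin = w.min(axis=1)
        wmax = w.max(axis=1)
        wext = np.column_stack([w, wmin])
        return wext, wmin, wmax


def read_pwm(path: str | Path, pseudocount: float = 0.01) -> PWM:
    """Read a JASPAR-format count matrix into a PWM."""
    from Bio import motifs as bio_motifs

    try:
        with open(path) as fh:
            motif = bio_motifs.read(fh, "jaspar")
    except Exception as exc:  # Bio raises bare Exceptions on bad input
        raise ParseError(f"{path}: not a valid JASPAR matrix ({exc})") from exc
    counts = np.array([list(motif.counts[b]) for b in ALPHABET]).T
    name = motif.name or motif.matrix_id or Path(path).stem
    return PWM.from_counts(str(name), counts, pseudocount=pseudocount)


def write_jaspar(name: str, counts: np.ndarray, path: str | Path) -> None:
    """Write an L x 4 count matrix in JASPAR text format."""
    c = np.asarray(counts)
    with open(path, "w") as fh:
        fh.write(f">{name} {name}\n")
        for j, base in enumerate(ALPHABET):
            row = " ".join(f"{v:g}" for v in c[:, j])
            fh.write(f"{base} [ {row} ]\n")


def pwm_from_consensus(
    name: str, consensus: str, strength: float = 0.97, total: int = 100
) -> PWM:
    """Toy PWM concentrated on a consensus string (synthetic; used for
    simulations and tests, not a database-derived motif)."""
    if not 0.25 < strength <= 1.0:
        raise ValueError("strength must be in (0.25, 1]")
    counts = np.full((len(consensus), 4), total * (1 - strength) / 3)
    for i, b in enumerate(consensus.upper()):
        if b not in ALPHABET:
            raise ValueError(f"consensus contains non-ACGT base {b!r}")
        counts[i, ALPHABET.index(b)] = total * strength
    return PWM.from_counts(name, counts)


# ---------------------------------------------------------------------------
# scoring


def match_score(pwm: PWM, window: str) -> float:
    """Matrix-similarity score of one window: (Current-Min)/(Max-Min).

    Case-insensitive; N contributes the per-position minimum so an
    N-containing window never outscores the same window with the worst base.
    """
    if len(window) != pwm.length:
        raise ValueError(
            f"window length {len(window)} != PWM length {pwm.length}"
        )
    wext, wmin, wmax = pwm._weights()
    code = _encode(window)
    current = float(wext[np.arange(pwm.length), code].sum())
    lo, hi = float(wmin.sum()), float(wmax.sum())
    if hi <= lo:
        return 0.0
    return (current - lo) / (hi - lo)


def scan_scores(pwm: PWM, seq: str) -> np.ndarray:
    """Scores at every start offset of ``seq`` (length n-L+1 array)."""
    L = pwm.length
    code = _encode(seq)
    n = len(code)
    if n < L:
        return np.empty(0)
    wext, wmin, wmax = pwm._weights()
    idx = code[np.arange(n - L + 1)[:, None] + np.arange(L)[None, :]]
    current = wext[np.arange(L)[None, :], idx].sum(axis=1)
    lo, hi = wmin.sum(), wmax.sum()
    if hi <= lo:
        return np.zeros(n - L + 1)
    return (current - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# segments


@dataclasses.dataclass(frozen=True)
class Segment:
    """A fixed-length sequence window (default 150 bp) with its origin."""

    source: str
    sequence: str
    chrom: str | None = None
    start: int | None = None
    strand: str = "+"


def _contig_seq(genome, chrom: str) -> str:
    if isinstance(genome, Mapping):
        return str(genome[chrom])
    return str(genome[chrom][:])  # pyfaidx.Fasta


def extract_segments(bis, genome, flank: int = 75) -> list[Segment]:
    """150 bp (2*flank) windows centred on each BI's representative summit.

    Windows truncated by contig ends are dropped with a logged warning.
    ``genome`` is a pyfaidx.Fasta or a chrom -> sequence mapping.
    """
    segments: list[Segment] = []
    for bi in bis:
        chrom = bi.interval.chrom
        contig = _contig_seq(genome, chrom)
        lo, hi = bi.summit - flank, bi.summit + flank
        if lo < 0 or hi > len(contig):
            logger.warning(
                "segment for BI %s dropped: summit %d within %d bp of a "
                "contig end",
                bi.interval,
                bi.summit,
                flank,
            )
            continue
        segments.append(
            Segment(
                source=bi.name,
                sequence=contig[lo:hi].upper(),
                chrom=chrom,
                start=lo,
            )
        )
    return segments


def control_segments(
    genes: Sequence,
    genome,
    n_genes: int = 1000,
    seed: int | np.random.Generator = 0,
    segment_len: int = 150,
    upstream: int = 10_000,
    downstream: int = 150,
) -> list[Segment]:
    """Random control segments from gene promoter windows.

    For each of ``n_genes`` randomly chosen genes, one uniformly random
    ``segment_len`` window is drawn from the strand-oriented
    [TSS - upstream, TSS + downstream) window. Genes whose window exceeds
    the contig are resampled (logged). Deterministic given the seed.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    window_len = upstream + downstream
    order = rng.permutation(len(genes))
    segments: list[Segment] = []
    for gi in order:
        if len(segments) >= n_genes:
            break
        g = genes[gi]
        contig = _contig_seq(genome, g.chrom)
        if g.strand == "+":
            w_lo, w_hi = g.tss - upstream, g.tss + downstream
        else:
            w_lo, w_hi = g.tss - downstream + 1, g.tss + upstream + 1
        if w_lo < 0 or w_hi > len(contig):
            logger.warning("control window for gene %s exceeds contig; resampled", g.gene_id)
            continue
        offset = int(rng.integers(0, window_len - segment_len + 1))
        s_lo = w_lo + offset if g.strand == "+" else w_hi - offset - segment_len
        seq = contig[s_lo : s_lo + segment_len].upper()
        if g.strand == "-":
            seq = revcomp(seq)
        segments.append(
            Segment(
                source=f"control|{g.gene_id}",
                sequence=seq,
                chrom=g.chrom,
                start=s_lo,
                strand=g.strand,
            )
        )
    if len(segments) < n_genes:
        raise ValueError(
            f"only {len(segments)} of {n_genes} requested control segments "
            "could be drawn"
        )
    return segments


# ---------------------------------------------------------------------------
# ordered module search


@dataclasses.dataclass(frozen=True)
class MotifPlacement:
    motif: str
    start: int
    strand: str
    score: float


@dataclasses.dataclass(frozen=True)
class ModuleHit:
    """Best ordered placement of a motif series within one segment."""

    placements: tuple[MotifPlacement, ...]
    order_valid: bool
    avg_score: float


def _best_ordered_one_strand(
    score_arrays: list[np.ndarray], lengths: list[int]
) -> tuple[float, list[int]] | None:
    """Max-sum ordered non-overlapping placement via suffix-max DP.

    Ties resolve to the lexicographically smallest start vector (leftmost
    first motif, then second, ...).
    """
    k = len(score_arrays)
    tail = [0] * (k + 1)
    for m in range(k - 1, -1, -1):
        tail[m] = tail[m + 1] + lengths[m]
    n_starts = [len(s) for s in score_arrays]
    # val[m][j] = S_m[j] + best of motifs m+1.. placed at >= j + L_m
    best: list[np.ndarray] = [None] * k  # suffix max of val
    arg: list[np.ndarray] = [None] * k
    val_prev: np.ndarray | None = None
    for m in range(k - 1, -1, -1):
        # valid starts for motif m: j + tail[m] <= seq length
        seq_len = n_starts[m] + lengths[m] - 1
        limit = seq_len - tail[m] + 1  # number of valid starts
        if limit <= 0:
            return None
        s = score_arrays[m][:limit].copy()
        if m < k - 1:
            nxt_best, _ = best[m + 1], arg[m + 1]
            s += nxt_best[np.arange(limit) + lengths[m]]
        # suffix max with leftmost argmax
        b = np.empty(limit + 1)
        a = np.empty(limit + 1, dtype=int)
        b[limit] = -np.inf
        a[limit] = -1
        for j in range(limit - 1, -1, -1):
            if s[j] >= b[j + 1]:
                b[j], a[j] = s[j], j
            else:
                b[j], a[j] = b[j + 1], a[j + 1]
        best[m], arg[m] = b, a
        val_prev = s
    # reconstruct
    starts: list[int] = []
    pos = 0
    for m in range(k):
        j = int(arg[m][pos])
        starts.append(j)
        pos = j + lengths[m]
    return float(best[0][0]), starts


def best_ordered_module(
    segment: Segment | str, pwms: Sequence[PWM]
) -> ModuleHit:
    """Best same-strand, ordered, non-overlapping placement of ``pwms``.

    Both orientations of the segment are scanned and the one with the higher
    average component score kept (forward wins ties). Reported starts refer
    to the scanned orientation of the segment. The average of the component
    matrix-similarity scores is the module score.
    """
    seq = segment.sequence if isinstance(segment, Segment) else segment
    lengths = [p.length for p in pwms]
    if sum(lengths) > len(seq):
        raise ValueError(
            f"motif lengths sum to {sum(lengths)} > segment length {len(seq)}"
        )
    results = {}
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        arrays = [scan_scores(p, s) for p in pwms]
        res = _best_ordered_one_strand(arrays, lengths)
        if res is not None:
            results[strand] = res
    if not results:
        return ModuleHit(placements=(), order_valid=False, avg_score=0.0)
    best_strand = max(results, key=lambda st: (results[st][0], st == "+"))
    total, starts = results[best_strand]
    s = seq if best_strand == "+" else revcomp(seq)
    placements = tuple(
        MotifPlacement(
            motif=p.name,
            start=j,
            strand=best_strand,
            score=float(scan_scores(p, s[j : j + p.length])[0]),
        )
        for p, j in zip(pwms, starts)
    )
    return ModuleHit(
        placements=placements,
        order_valid=True,
        avg_score=total / len(pwms),
    )


# ---------------------------------------------------------------------------
# group comparison


@dataclasses.dataclass(frozen=True)
class RankTestResult:
    statistic: float
    pvalue: float
    median_a: float
    median_b: float


def compare_score_groups(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> RankTestResult:
    """Two-sided Mann-Whitney U comparison of two score groups."""
    a, b = np.asarray(scores_a, float), np.asarray(scores_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return RankTestResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
    )
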
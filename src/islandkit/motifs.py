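"""PWM scanning at a significance threshold, plus motif clustering /
asymmetry / depletion scoring within intervals.

Scores are log-odds in bits, discretised to integer millibits (1/1000 bit)
so that the exact score distribution can be computed by per-position
convolution and both the scanner and the enumeration oracle share one
scoring definition.  The p-value attached to a hit is the per-position
match probability P(S >= s) under the background model — not a sequence
level E-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import GenomicInterval, GenomeSequence, encode_sequence

MILLIBITS = 1000  # discretisation: integer units of 1/1000 bit
BASES = "ACGT"
_COMPLEMENT_IDX = np.array([3, 2, 1, 0], dtype=np.intp)  # A<->T, C<->G


@dataclass
class Pwm:
    """Per-position base probabilities with background and pseudocount.

    The stored matrix is re-normalised after pseudocount addition so every
    probability is strictly positive and each row sums to 1.
    """

    name: str
    matrix: np.ndarray  # (length, 4), rows sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25, dtype=float)
    )
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (length, 4)")
        if (m < 0).any():
            raise ValueError("PWM matrix entries must be non-negative")
        rowsums = m.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=0.02):
            raise ValueError(f"PWM {self.name!r} rows must sum to ~1, got {rowsums}")
        m = (m + self.pseudocount) / (rowsums + 4 * self.pseudocount)[:, None]
        self.matrix = m
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or (bg <= 0).any():
            raise ValueError("background must be 4 positive frequencies")
        self.background = bg / bg.sum()
        assert np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def log_odds_millibits(self, background: np.ndarray | None = None) -> np.ndarray:
        """Integer log2(p/bg) matrix in millibits; the scoring definition."""
        bg = self.background if background is None else np.asarray(background, float)
        bg = bg / bg.sum()
        lo = np.log2(self.matrix / bg[None, :])
        return np.rint(lo * MILLIBITS).astype(np.int64)

    def reverse_complement(self) -> "Pwm":
        rc = self.matrix[::-1, _COMPLEMENT_IDX]
        return Pwm(self.name + "_rc", rc, self.background, pseudocount=0.0)


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    strand: str
    score_bits: float
    p_value: float
    motif: str = ""


@dataclass
class ScoreDistribution:
    """Exact distribution of integer-millibit log-odds scores under background.

    ``tail[i]`` is P(S >= scores[i]); monotone non-increasing in score.
    ``discretisation_bits`` bounds the score error introduced by rounding
    the matrix to the millibit grid (0.0005 bit per position).
    """

    scores: np.ndarray  # sorted ascending, int64 millibits
    probs: np.ndarray
    tail: np.ndarray
    discretisation_bits: float

    def pvalue(self, score_millibits: int) -> float:
        """P(S >= score) under the background model."""
        i = np.searchsorted(self.scores, score_millibits, side="left")
        if i >= len(self.scores):
            return 0.0
        return float(self.tail[i])

    def threshold(self, alpha: float) -> int:
        """Smallest integer score whose tail probability is <= alpha."""
        ok = self.tail <= alpha
        if not ok.any():
            return int(self.scores[-1]) + 1  # unreachable: no score qualifies
        return int(self.scores[np.argmax(ok)])


def score_distribution(
    pwm: Pwm, background: np.ndarray | None = None, max_length: int = 30
) -> ScoreDistribution:
    """Exact per-position convolution of the integer-score distribution.

    The millibit grid makes the convolution exact for the discretised
    matrix; probabilities come from the background model.
    """
    if len(pwm) > max_length:
        raise ValueError(f"motif length {len(pwm)} exceeds limit {max_length}")
    bg = pwm.background if background is None else np.asarray(background, float)
    bg = bg / bg.sum()
    lo = pwm.log_odds_millibits(bg)
    dist: Dict[int, float] = {0: 1.0}
    for row in lo:
        nxt: Dict[int, float] = {}
        for s, p in dist.items():
            for b in range(4):
                key = s + int(row[b])
                nxt[key] = nxt.get(key, 0.0) + p * bg[b]
        dist = nxt
    scores = np.array(sorted(dist), dtype=np.int64)
    probs = np.array([dist[int(s)] for s in scores], dtype=float)
    tail = probs[::-1].cumsum()[::-1]
    return ScoreDistribution(
        scores=scores,
        probs=probs,
        tail=tail,
        discretisation_bits=len(pwm) * 0.5 / MILLIBITS,
    )


def _symmetrise(freqs: np.ndarray) -> np.ndarray:
    """Strand-symmetric background: average complementary base frequencies."""
    f = np.asarray(freqs, dtype=float)
    at = (f[0] + f[3]) / 2
    cg = (f[1] + f[2]) / 2
    out = np.array([at, cg, cg, at])
    return out / out.sum()


def sequence_background(seq_or_codes) -> np.ndarray:
    """Strand-symmetrised base composition of a sequence (N excluded)."""
    codes = (
        seq_or_codes
        if isinstance(seq_or_codes, np.ndarray)
        else encode_sequence(seq_or_codes)
    )
    counts = np.bincount(codes[codes != 4], minlength=4)[:4].astype(float)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    counts = np.maximum(counts, 1.0)  # guard absent bases
    return _symmetrise(counts / counts.sum())


def _position_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Integer score at every placement; placements touching N get -inf sentinel."""
    L = lo.shape[0]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    scores = np.zeros(n, dtype=np.int64)
    invalid = np.zeros(n, dtype=bool)
    safe = np.where(codes == 4, 0, codes)
    for j in range(L):
        window = safe[j : j + n]
        scores += lo[j][window]
        invalid |= codes[j : j + n] == 4
    scores[invalid] = np.iinfo(np.int64).min
    return scores


def scan_pwm(
    genome_or_seq: GenomeSequence | str,
    pwm: Pwm,
    alpha: float = 5e-5,
    strands: str = "both",
    background: np.ndarray | str = "auto",
) -> List[MotifHit]:
    """Report every position/strand whose match p-value is <= alpha.

    ``background="auto"`` uses the scanned sequence's own (strand
    symmetrised) composition, so scanning a reverse-complemented genome
    yields the same hit multiset at reflected coordinates.
    """
    if isinstance(genome_or_seq, GenomeSequence):
        contigs = genome_or_seq.contigs
    else:
        contigs = {"seq": str(genome_or_seq).upper()}
    if strands not in ("both", "+", "-"):
        raise ValueError("strands must be 'both', '+' or '-'")

    hits: List[MotifHit] = []
    L = len(pwm)
    for contig, seq in contigs.items():
        if len(seq) < L:
            continue
        codes = encode_sequence(seq)
        if isinstance(background, str) and background == "auto":
            bg = sequence_background(codes)
        elif isinstance(background, str):
            raise ValueError(f"unknown background mode {background!r}")
        else:
            bg = _symmetrise(background)
        dist = score_distribution(pwm, bg)
        cutoff = dist.threshold(alpha)
        lo_fwd = pwm.log_odds_millibits(bg)
        strand_matrices = []
        if strands in ("both", "+"):
            strand_matrices.append(("+", lo_fwd))
        if strands in ("both", "-"):
            # scanning the - strand == scanning the reverse-complement matrix
            strand_matrices.append(("-", lo_fwd[::-1][:, _COMPLEMENT_IDX]))
        for strand, lo in strand_matrices:
            scores = _position_scores(codes, lo)
            for i in np.flatnonzero(scores >= cutoff):
                s = int(scores[i])
                hits.append(
                    MotifHit(
                        interval=GenomicInterval(contig, int(i), int(i) + L, strand),
                        strand=strand,
                        score_bits=s / MILLIBITS,
                        p_value=dist.pvalue(s),
                        motif=pwm.name,
                    )
                )
    hits.sort(key=lambda h: (h.interval.contig, h.interval.start, h.strand))
    return hits


def count_hits(hits: Sequence[MotifHit], interval: GenomicInterval) -> int:
    """Number of hits overlapping the query by >= 1 bp."""
    return sum(1 for h in hits if _hit_interval(h).overlaps(interval))


def _hit_interval(h) -> GenomicInterval:
    return getattr(h, "interval", h)


def asymmetry_score(
    island: GenomicInterval, hits: Sequence[MotifHit]
) -> Tuple[int, int, float]:
    """Counts of overlapping hits in the two half-intervals of ``island``
    plus a two-sided Binomial(n, 0.5) p-value.

    A hit spanning the middle goes to the half containing its own midpoint
    (left on a tie).  With zero hits the p-value is NaN.
    """
    if island.length < 2:
        raise ValueError("island must be at least 2 bp")
    mid = island.midpoint
    left = right = 0
    for h in hits:
        iv = _hit_interval(h)
        if not iv.overlaps(island):
            continue
        if iv.midpoint <= mid:
            left += 1
        else:
            right += 1
    n = left + right
    if n == 0:
        return 0, 0, float("nan")
    p = stats.binomtest(left, n, 0.5, alternative="two-sided").pvalue
    return left, right, min(1.0, float(p))


def depletion_flag(
    interval: GenomicInterval, hits: Sequence[MotifHit], max_hits: int
) -> bool:
    """True iff at most ``max_hits`` hits overlap the interval."""
    return count_hits(hits, interval) <= max_hits


def pwm_from_consensus(
    name: str, consensus: str, p_match: float = 0.97, background=None
) -> Pwm:
    """Near-deterministic PWM for a consensus word (testing / simulation aid)."""
    consensus = consensus.upper()
    if set(consensus) - set(BASES):
        raise ValueError("consensus must be over ACGT")
    off = (1.0 - p_match) / 3.0
    m = np.full((len(consensus), 4), off)
    for i, b in enumerate(consensus):
        m[i, BASES.index(b)] = p_match
    kwargs = {} if background is None else {"background": np.asarray(background)}
    return Pwm(name, m, **kwargs)
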
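"""Sliding-window GC / CpG statistics, CpG-island calling and GC-rich
candidate-element discovery.

The island caller scans 200 bp windows at 1 bp resolution, merges runs of
qualifying placements and re-checks each merged span against the criteria.
Element discovery works on 1 kb windows and additionally requires depletion
of activating-motif hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .core import GenomeSequence, GenomicInterval, encode_sequence

DEFAULT_MIN_GC = 0.50
DEFAULT_MIN_OE = 0.60
DEFAULT_MIN_LEN = 200
DEFAULT_MAX_N_FRACTION = 0.10


@dataclass(frozen=True)
class IslandCriteria:
    """Mammalian CpG-island criteria (Gardiner-Garden & Frommer convention)."""

    min_gc: float = DEFAULT_MIN_GC
    min_oe: float = DEFAULT_MIN_OE
    min_len: int = DEFAULT_MIN_LEN

    def satisfied(self, gc: float, oe: float, length: int) -> bool:
        return (
            not np.isnan(gc)
            and gc >= self.min_gc
            and oe >= self.min_oe
            and length >= self.min_len
        )


@dataclass(frozen=True)
class WindowRecord:
    start: int
    gc_fraction: float  # NaN when masked
    cpg_oe: float
    n_fraction: float
    masked: bool


@dataclass
class WindowTrack:
    """Equally stepped per-window GC / CpG O/E / N-fraction records."""

    contig: str
    window_bp: int
    step_bp: int
    starts: np.ndarray
    gc_fraction: np.ndarray
    cpg_oe: np.ndarray
    n_fraction: np.ndarray
    masked: np.ndarray

    def __len__(self) -> int:
        return len(self.starts)

    def records(self) -> List[WindowRecord]:
        return [
            WindowRecord(int(s), float(g), float(o), float(n), bool(m))
            for s, g, o, n, m in zip(
                self.starts, self.gc_fraction, self.cpg_oe, self.n_fraction, self.masked
            )
        ]


@dataclass(frozen=True)
class CpGIslandCall:
    interval: GenomicInterval
    gc_fraction: float
    cpg_oe: float

    @property
    def length_bp(self) -> int:
        return self.interval.length


# ---------------------------------------------------------------------------
# scalar statistics


def gc_fraction(seq: str) -> float:
    """(#G + #C) / (#non-N bases); NaN if every base is N."""
    if len(seq) == 0:
        raise ValueError("empty sequence")
    codes = encode_sequence(seq.upper())
    informative = int(np.count_nonzero(codes != 4))
    if informative == 0:
        return float("nan")
    gc = int(np.count_nonzero((codes == 1) | (codes == 2)))
    return gc / informative


def cpg_observed_expected(seq: str) -> float:
    """CpG O/E = N_CG * L / (N_C * N_G) over non-N positions; 0 when C or G absent."""
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    codes = encode_sequence(seq.upper())
    keep = codes != 4
    n_c = int(np.count_nonzero(codes == 1))
    n_g = int(np.count_nonzero(codes == 2))
    if n_c == 0 or n_g == 0:
        return 0.0
    n_cg = int(np.count_nonzero((codes[:-1] == 1) & (codes[1:] == 2)))
    length = int(np.count_nonzero(keep))
    return n_cg * length / (n_c * n_g)


# ---------------------------------------------------------------------------
# windowed scans (cumulative-sum kernels)


def _cumulative_counts(codes: np.ndarray):
    """Prefix sums of C, G, GC, N indicators and CpG dinucleotide starts."""
    is_c = codes == 1
    is_g = codes == 2
    is_n = codes == 4
    cg_start = np.zeros(len(codes), dtype=bool)
    if len(codes) >= 2:
        cg_start[:-1] = is_c[:-1] & is_g[1:]

    def prefix(x):
        out = np.zeros(len(x) + 1, dtype=np.int64)
        np.cumsum(x, out=out[1:])
        return out

    return prefix(is_c), prefix(is_g), prefix(is_n), prefix(cg_start)


def _window_stats(codes: np.ndarray, starts: np.ndarray, window: int):
    """Vectorised (gc, oe, n_fraction) for every window placement."""
    pc, pg, pn, pcg = _cumulative_counts(codes)
    ends = starts + window
    n_c = pc[ends] - pc[starts]
    n_g = pg[ends] - pg[starts]
    n_n = pn[ends] - pn[starts]
    # CpG starts strictly inside the window (no wrap across the edge)
    n_cg = pcg[np.minimum(ends - 1, len(codes))] - pcg[starts]
    informative = window - n_n
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(informative > 0, (n_c + n_g) / informative, np.nan)
        oe = np.where((n_c > 0) & (n_g > 0), n_cg * informative / (n_c * n_g), 0.0)
    oe = np.where(informative > 1, oe, 0.0)
    n_frac = n_n / window
    return gc, oe, n_frac


def scan_windows(
    genome: GenomeSequence,
    window_bp: int = 1000,
    step_bp: int | None = None,
    max_n_fraction: float = DEFAULT_MAX_N_FRACTION,
) -> Dict[str, WindowTrack]:
    """Per-contig sliding-window GC / CpG O/E track.

    Windows whose N fraction exceeds ``max_n_fraction`` are flagged masked
    and their gc_fraction reported as NaN.
    """
    if step_bp is None:
        step_bp = window_bp
    if window_bp <= 0 or step_bp <= 0:
        raise ValueError("window_bp and step_bp must be positive")
    if step_bp > window_bp:
        import warnings

        warnings.warn("step_bp > window_bp leaves gaps between windows")
    tracks: Dict[str, WindowTrack] = {}
    for contig, seq in genome.contigs.items():
        if window_bp > len(seq):
            raise ValueError(
                f"window {window_bp} exceeds contig {contig!r} length {len(seq)}"
            )
        codes = encode_sequence(seq)
        starts = np.arange(0, len(seq) - window_bp + 1, step_bp, dtype=np.int64)
        gc, oe, n_frac = _window_stats(codes, starts, window_bp)
        masked = n_frac > max_n_fraction
        gc = np.where(masked, np.nan, gc)
        tracks[contig] = WindowTrack(
            contig=contig,
            window_bp=window_bp,
            step_bp=step_bp,
            starts=starts,
            gc_fraction=gc,
            cpg_oe=oe,
            n_fraction=n_frac,
            masked=masked,
        )
    return tracks


# ---------------------------------------------------------------------------
# island calling


def _span_stats(codes: np.ndarray, start: int, end: int):
    seg = codes[start:end]
    n_c = int(np.count_nonzero(seg == 1))
    n_g = int(np.count_nonzero(seg == 2))
    n_n = int(np.count_nonzero(seg == 4))
    informative = len(seg) - n_n
    gc = (n_c + n_g) / informative if informative else float("nan")
    n_cg = int(np.count_nonzero((seg[:-1] == 1) & (seg[1:] == 2)))
    if n_c and n_g and informative > 1:
        oe = n_cg * informative / (n_c * n_g)
    else:
        oe = 0.0
    return gc, oe


def _trim_to_criteria(codes, start, end, criteria: IslandCriteria, step=10):
    """Shrink a merged span until the criteria hold over the full span.

    Trims ``step`` bp at a time from whichever edge has the lower local GC;
    gives up (returns None) if the span drops below min_len.
    """
    while end - start >= criteria.min_len:
        gc, oe = _span_stats(codes, start, end)
        if criteria.satisfied(gc, oe, end - start):
            return start, end, gc, oe
        edge = min(step, (end - start - criteria.min_len) + step)
        left_gc = _span_stats(codes, start, min(start + 50, end))[0]
        right_gc = _span_stats(codes, max(end - 50, start), end)[0]
        if np.isnan(left_gc):
            left_gc = -1.0
        if np.isnan(right_gc):
            right_gc = -1.0
        if left_gc <= right_gc:
            start += edge
        else:
            end -= edge
    return None


def call_cpg_islands(
    genome: GenomeSequence,
    criteria: IslandCriteria = IslandCriteria(),
    window_bp: int = 200,
    step_bp: int = 1,
    max_n_fraction: float = DEFAULT_MAX_N_FRACTION,
) -> List[CpGIslandCall]:
    """Maximal merged runs of qualifying windows, re-checked over each span.

    Returned calls are non-overlapping, sorted, and each satisfies the
    criteria when recomputed from its own sequence.
    """
    calls: List[CpGIslandCall] = []
    for contig, seq in genome.contigs.items():
        if len(seq) < criteria.min_len or len(seq) < window_bp:
            continue
        codes = encode_sequence(seq)
        starts = np.arange(0, len(seq) - window_bp + 1, step_bp, dtype=np.int64)
        gc, oe, n_frac = _window_stats(codes, starts, window_bp)
        ok = (
            ~np.isnan(gc)
            & (gc >= criteria.min_gc)
            & (oe >= criteria.min_oe)
            & (n_frac <= max_n_fraction)
        )
        if not ok.any():
            continue
        # runs of consecutive qualifying placements -> candidate spans
        idx = np.flatnonzero(ok)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_bounds = zip(
            np.concatenate(([0], breaks + 1)), np.concatenate((breaks, [len(idx) - 1]))
        )
        spans = [
            (int(starts[idx[a]]), int(starts[idx[b]]) + window_bp) for a, b in run_bounds
        ]
        # merge overlapping/adjacent spans
        merged = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            trimmed = _trim_to_criteria(codes, s, e, criteria)
            if trimmed is None:
                continue
            ts, te, tgc, toe = trimmed
            calls.append(
                CpGIslandCall(GenomicInterval(contig, ts, te), float(tgc), float(toe))
            )
    calls.sort(key=lambda c: (c.interval.contig, c.interval.start))
    return calls


# ---------------------------------------------------------------------------
# GC-rich element discovery (island criteria + activating-motif depletion)


def find_gc_rich_elements(
    genome: GenomeSequence,
    motif_hits: Sequence,
    window_bp: int = 1000,
    criteria: IslandCriteria = IslandCriteria(),
    max_hits_per_window: int = 2,
    step_bp: int = 100,
    max_n_fraction: float = DEFAULT_MAX_N_FRACTION,
) -> List[GenomicInterval]:
    """Non-overlapping windows satisfying the island criteria and containing
    at most ``max_hits_per_window`` activating-motif hits.

    ``motif_hits`` carries objects with an ``interval`` attribute (or plain
    :class:`GenomicInterval`) computed on the same genome.  Output is ranked
    by CpG O/E descending, ties by GC then leftmost coordinate.
    """
    hit_ivs = [getattr(h, "interval", h) for h in motif_hits]
    by_contig: Dict[str, List[GenomicInterval]] = {}
    for iv in hit_ivs:
        by_contig.setdefault(iv.contig, []).append(iv)
    for ivs in by_contig.values():
        ivs.sort(key=lambda iv: iv.start)

    candidates = []  # (-oe, -gc, contig, start)
    for contig, seq in genome.contigs.items():
        if len(seq) < window_bp:
            continue
        codes = encode_sequence(seq)
        starts = np.arange(0, len(seq) - window_bp + 1, step_bp, dtype=np.int64)
        gc, oe, n_frac = _window_stats(codes, starts, window_bp)
        ok = (
            ~np.isnan(gc)
            & (gc >= criteria.min_gc)
            & (oe >= criteria.min_oe)
            & (n_frac <= max_n_fraction)
        )
        if not ok.any():
            continue
        hits = by_contig.get(contig, [])
        hit_starts = np.array([iv.start for iv in hits], dtype=np.int64)
        hit_ends = np.array([iv.end for iv in hits], dtype=np.int64)
        for i in np.flatnonzero(ok):
            s = int(starts[i])
            e = s + window_bp
            n_hits = int(np.count_nonzero((hit_starts < e) & (hit_ends > s)))
            if n_hits <= max_hits_per_window:
                candidates.append((-float(oe[i]), -float(gc[i]), contig, s))

    candidates.sort()
    chosen: List[GenomicInterval] = []
    taken: Dict[str, List[tuple]] = {}
    for negoe, neggc, contig, s in candidates:
        e = s + window_bp
        if any(s < te and ts < e for ts, te in taken.get(contig, [])):
            continue
        taken.setdefault(contig, []).append((s, e))
        chosen.append(GenomicInterval(contig, s, e))
    return chosen


def audit_island_calls(
    genome: GenomeSequence, calls: Sequence[CpGIslandCall], criteria: IslandCriteria
) -> bool:
    """Self-consistency check: every call satisfies the criteria when its
    statistics are recomputed from sequence."""
    for call in calls:
        seq = genome.fetch(call.interval)
        gc = gc_fraction(seq)
        oe = cpg_observed_expected(seq)
        if not criteria.satisfied(gc, oe, len(seq)):
            return False
    return True
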
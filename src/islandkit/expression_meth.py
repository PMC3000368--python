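"""Promoter CpG-class stratification, RNA-Seq exonic activity scoring,
inactive-promoter stratification by repressor occupancy, and TSS/interval
methylation summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomeSequence, GenomicInterval, encode_sequence
from .enrichment import ReadSet
from .seqscan import _window_stats

HCP, ICP, LCP = "HCP", "ICP", "LCP"


@dataclass(frozen=True)
class CpgClassCriteria:
    """Promoter CpG-class thresholds on 500 bp sub-windows.

    HCP: some sub-window has GC >= hcp_min_gc and O/E >= hcp_min_oe.
    LCP: no sub-window reaches lcp_max_oe.  Everything else is ICP.
    """

    hcp_min_gc: float = 0.55
    hcp_min_oe: float = 0.60
    lcp_max_oe: float = 0.40
    subwindow_bp: int = 500


@dataclass
class PromoterRecord:
    gene_id: str
    contig: str
    tss: int
    strand: str
    exons: List[GenomicInterval] = field(default_factory=list)
    cpg_class: str | None = None
    n_islands_overlapping: int = 0
    expression_score: float = float("nan")
    mark_calls: Dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("promoter strand must be '+' or '-'")
        self.exons = _normalize_exons(self.exons)


def _normalize_exons(exons: Sequence[GenomicInterval]) -> List[GenomicInterval]:
    """Merge overlapping exons; keep coordinate order."""
    if not exons:
        return []
    ex = sorted(exons, key=lambda e: (e.contig, e.start))
    merged = [ex[0]]
    for e in ex[1:]:
        last = merged[-1]
        if e.contig == last.contig and e.start <= last.end:
            merged[-1] = GenomicInterval(
                last.contig, last.start, max(last.end, e.end), last.strand
            )
        else:
            merged.append(e)
    return merged


# ---------------------------------------------------------------------------
# promoter CpG classification


def classify_promoter_cpg(
    genome: GenomeSequence,
    tss: int,
    strand: str,
    contig: str | None = None,
    span: Tuple[int, int] = (-500, 2000),
    criteria: CpgClassCriteria = CpgClassCriteria(),
) -> str:
    """HCP / ICP / LCP class of the strand-oriented promoter span around a TSS.

    The span is relative to the TSS in transcript orientation (negative =
    upstream); it is clipped at contig bounds.  Classification scans every
    500 bp sub-window at 1 bp steps.
    """
    if contig is None:
        if len(genome.contigs) != 1:
            raise ValueError("contig must be given for multi-contig genomes")
        contig = next(iter(genome.contigs))
    seq = genome[contig]
    if strand == "+":
        s, e = tss + span[0], tss + span[1]
    elif strand == "-":
        s, e = tss - span[1] + 1, tss - span[0] + 1
    else:
        raise ValueError("strand must be '+' or '-'")
    s_clip, e_clip = max(0, s), min(len(seq), e)
    if e_clip - s_clip < criteria.subwindow_bp:
        raise ValueError("promoter span shorter than one sub-window after clipping")
    codes = encode_sequence(seq[s_clip:e_clip])
    starts = np.arange(0, len(codes) - criteria.subwindow_bp + 1, dtype=np.int64)
    gc, oe, _ = _window_stats(codes, starts, criteria.subwindow_bp)
    valid = ~np.isnan(gc)
    if not valid.any():
        return LCP
    if ((gc >= criteria.hcp_min_gc) & (oe >= criteria.hcp_min_oe) & valid).any():
        return HCP
    if (oe[valid] < criteria.lcp_max_oe).all():
        return LCP
    return ICP


# ---------------------------------------------------------------------------
# RNA-Seq exonic activity


def expression_score(
    exons: Sequence[GenomicInterval],
    rnaseq: ReadSet,
    window_bp: int = 1000,
    total_reads: int | None = None,
) -> float:
    """Maximum read count in any window of exonic sequence, per million reads.

    Exons are concatenated in the given (transcript) order into a virtual
    coordinate; reads are assigned by their 5' position.  When the exonic
    span is shorter than the window the whole span is used.
    """
    exons = list(exons)
    if not exons:
        raise ValueError("gene has no exons")
    total = rnaseq.total_count if total_reads is None else total_reads
    virtual_positions: List[int] = []
    offset = 0
    for exon in exons:
        if exon.contig in rnaseq.reads:
            pos, _ = rnaseq.reads[exon.contig]
            inside = pos[(pos >= exon.start) & (pos < exon.end)]
            virtual_positions.extend((inside - exon.start + offset).tolist())
        offset += exon.length
    virtual_len = offset
    if not virtual_positions:
        return 0.0
    w = min(window_bp, virtual_len)
    p = np.sort(np.asarray(virtual_positions, dtype=np.int64))
    best = 0
    # max over placements: the maximum changes only at read positions
    for anchor in np.unique(np.minimum(p, virtual_len - w)):
        count = int(np.searchsorted(p, anchor + w) - np.searchsorted(p, anchor))
        best = max(best, count)
    scale = 1e6 / total if total else 0.0
    return best * scale


# ---------------------------------------------------------------------------
# inactive-promoter stratification


def stratify_inactive_hcps(
    promoters: Sequence[PromoterRecord],
    island_lengths: Mapping[str, int] | None = None,
    island_gc: Mapping[str, float] | None = None,
    repressor_mark: str = "Ezh2",
    inactive_threshold: float | None = None,
) -> Dict[str, object]:
    """Compare expression between repressor-positive and -negative HCPs.

    Only HCP promoters containing exactly one CpG island enter the analysis.
    Returns per-group summaries, a two-sided rank-sum comparison of
    expression scores, and a scatter table (island length, GC, group) for
    the inactive subset (expression below ``inactive_threshold``; when None
    the threshold is data-driven: the maximum score seen at LCP promoters,
    or +inf when no LCP exists).
    """
    eligible = [
        p
        for p in promoters
        if p.cpg_class == HCP and p.n_islands_overlapping == 1
    ]
    if inactive_threshold is None:
        lcp_scores = [
            p.expression_score
            for p in promoters
            if p.cpg_class == LCP and not np.isnan(p.expression_score)
        ]
        inactive_threshold = max(lcp_scores) if lcp_scores else float("inf")

    pos = [p for p in eligible if p.mark_calls.get(repressor_mark, False)]
    neg = [p for p in eligible if not p.mark_calls.get(repressor_mark, False)]

    def summary(group: List[PromoterRecord]) -> Dict[str, float] | None:
        if not group:
            return None
        scores = np.array([p.expression_score for p in group], dtype=float)
        return {
            "n": len(group),
            "mean_score": float(np.nanmean(scores)),
            "median_score": float(np.nanmedian(scores)),
        }

    result: Dict[str, object] = {
        "inactive_threshold": float(inactive_threshold),
        f"{repressor_mark}_pos": summary(pos),
        f"{repressor_mark}_neg": summary(neg),
        "rank_sum_p": float("nan"),
    }
    if pos and neg:
        stat = stats.mannwhitneyu(
            [p.expression_score for p in pos],
            [p.expression_score for p in neg],
            alternative="two-sided",
        )
        result["rank_sum_p"] = float(stat.pvalue)

    rows = []
    for p in eligible:
        if p.expression_score <= inactive_threshold:
            rows.append(
                {
                    "gene_id": p.gene_id,
                    "group": f"{repressor_mark}+"
                    if p.mark_calls.get(repressor_mark, False)
                    else f"{repressor_mark}-",
                    "island_length_bp": (island_lengths or {}).get(p.gene_id, np.nan),
                    "island_gc": (island_gc or {}).get(p.gene_id, np.nan),
                    "expression_score": p.expression_score,
                }
            )
    result["inactive_scatter"] = pd.DataFrame(
        rows,
        columns=["gene_id", "group", "island_length_bp", "island_gc", "expression_score"],
    )
    return result


# ---------------------------------------------------------------------------
# methylation


def interval_methylation(
    calls: pd.DataFrame, interval: GenomicInterval
) -> Tuple[float, int]:
    """Coverage-weighted mean methylation level within an interval.

    Returns (level, covered CpG count); level is NaN with zero covered CpGs.
    """
    sel = calls[
        (calls["contig"] == interval.contig)
        & (calls["position"] >= interval.start)
        & (calls["position"] < interval.end)
        & (calls["total"] > 0)
    ]
    n = len(sel)
    if n == 0:
        return float("nan"), 0
    return float(sel["methylated"].sum() / sel["total"].sum()), n


def methylation_composite(
    calls: pd.DataFrame,
    tss_list: Sequence[Tuple[str, int, str]],
    window_bp: int = 200,
    span_bp: int = 10000,
    step_bp: int | None = None,
) -> pd.DataFrame:
    """Mean methylation level in sliding windows across the TSS-centred span.

    ``tss_list`` holds (contig, tss, strand); minus-strand promoters are
    flipped so offsets are in transcript orientation.  Per-CpG levels are
    pooled across genes within each offset window; windows without covered
    CpGs get NaN.  Returns a DataFrame (offset of window start, mean_level,
    n_cpgs) with offsets spanning [-span/2, span/2 - window].
    """
    if step_bp is None:
        step_bp = window_bp // 2
    half = span_bp // 2
    covered = calls[calls["total"] > 0]
    offsets_all: List[np.ndarray] = []
    levels_all: List[np.ndarray] = []
    for contig, tss, strand in tss_list:
        sel = covered[covered["contig"] == contig]
        if sel.empty:
            continue
        rel = sel["position"].to_numpy(dtype=np.int64) - int(tss)
        if strand == "-":
            rel = -rel
        keep = (rel >= -half) & (rel < half)
        if not keep.any():
            continue
        offsets_all.append(rel[keep])
        levels_all.append(
            (sel["methylated"].to_numpy(dtype=float) / sel["total"].to_numpy(dtype=float))[
                keep
            ]
        )
    window_starts = np.arange(-half, half - window_bp + 1, step_bp, dtype=np.int64)
    mean_level = np.full(len(window_starts), np.nan)
    n_cpgs = np.zeros(len(window_starts), dtype=np.int64)
    if offsets_all:
        offs = np.concatenate(offsets_all)
        levs = np.concatenate(levels_all)
        order = np.argsort(offs, kind="stable")
        offs, levs = offs[order], levs[order]
        csum = np.concatenate(([0.0], np.cumsum(levs)))
        for i, ws in enumerate(window_starts):
            lo = np.searchsorted(offs, ws, side="left")
            hi = np.searchsorted(offs, ws + window_bp, side="left")
            if hi > lo:
                n_cpgs[i] = hi - lo
                mean_level[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return pd.DataFrame(
        {"offset": window_starts, "mean_level": mean_level, "n_cpgs": n_cpgs}
    )
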
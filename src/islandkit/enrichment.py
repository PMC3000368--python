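"""ChIP-Seq read densities, randomized-read empirical null, sliding-window
enrichment calling, region merging, promoter mark classification, heat-map
matrices and spreading-extent measurement.

The per-window statistic is the extended-read coverage inside the window
divided by the extension length ("equivalent read count"): its expectation
equals total_reads * window / genome_length, and — unlike an integer read
count — it is fine-grained enough for the empirical tail p-values to be
calibrated at both p<1e-2 and p<1e-3.  The null re-places the same number
of reads uniformly (contig chosen proportional to length, strand Bernoulli
0.5), separately for each dataset, and pools the per-window statistics of
``n_randomizations`` rounds into one empirical distribution.  P-values use
add-one smoothing: (#{null >= observed} + 1) / (N + 1).

No multiple-testing correction is applied beyond the fixed p-threshold;
calls are against the randomized self-background only (no input-chromatin
correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import GenomeSequence, GenomicInterval, contig_lengths

DEFAULT_EXTENSION_BP = 200
DEFAULT_BIN_BP = 25


# ---------------------------------------------------------------------------
# read sets


@dataclass
class ReadSet:
    """Strand-aware mapped-read 5' positions with an extension length.

    ``reads`` maps contig -> (positions int64 array, strands int8 array of
    +1 / -1).  A + read extends [p, p+ext); a - read extends [p-ext, p).
    """

    reads: Dict[str, Tuple[np.ndarray, np.ndarray]]
    extension_bp: int = DEFAULT_EXTENSION_BP
    label: str = ""

    def __post_init__(self) -> None:
        clean = {}
        for contig, (pos, strand) in self.reads.items():
            pos = np.asarray(pos, dtype=np.int64)
            strand = np.asarray(strand, dtype=np.int8)
            if pos.shape != strand.shape:
                raise ValueError("positions and strands must align")
            if not np.isin(strand, (-1, 1)).all():
                raise ValueError("strands must be +1 or -1")
            order = np.argsort(pos, kind="stable")
            clean[contig] = (pos[order], strand[order])
        self.reads = clean

    @property
    def total_count(self) -> int:
        return sum(len(pos) for pos, _ in self.reads.values())

    @classmethod
    def from_tuples(
        cls,
        tuples: Iterable[Tuple[str, int, str]],
        extension_bp: int = DEFAULT_EXTENSION_BP,
        label: str = "",
    ) -> "ReadSet":
        acc: Dict[str, List[Tuple[int, int]]] = {}
        for contig, pos, strand in tuples:
            acc.setdefault(contig, []).append((pos, 1 if strand == "+" else -1))
        reads = {}
        for contig, items in acc.items():
            arr = np.array(items, dtype=np.int64)
            reads[contig] = (arr[:, 0], arr[:, 1].astype(np.int8))
        return cls(reads=reads, extension_bp=extension_bp, label=label)

    def to_tuples(self) -> List[Tuple[str, int, str]]:
        out = []
        for contig, (pos, strand) in self.reads.items():
            for p, s in zip(pos, strand):
                out.append((contig, int(p), "+" if s > 0 else "-"))
        return out

    def extended_intervals(self, contig: str, contig_len: int):
        """Clipped [start, end) extension footprints on one contig."""
        if contig not in self.reads:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        pos, strand = self.reads[contig]
        starts = np.where(strand > 0, pos, pos - self.extension_bp)
        ends = np.where(strand > 0, pos + self.extension_bp, pos)
        starts = np.clip(starts, 0, contig_len)
        ends = np.clip(ends, 0, contig_len)
        keep = ends > starts
        return starts[keep], ends[keep]


def coverage_cumsum(readset: ReadSet, contig: str, contig_len: int) -> np.ndarray:
    """Prefix sums of per-bp extended-read coverage (length contig_len + 1)."""
    starts, ends = readset.extended_intervals(contig, contig_len)
    diff = np.zeros(contig_len + 1, dtype=np.float64)
    np.add.at(diff, starts, 1.0)
    np.add.at(diff, ends, -1.0)
    return np.concatenate(([0.0], np.cumsum(diff)[:-1])).cumsum()


def window_values(
    cumsum: np.ndarray, starts: np.ndarray, window_bp: int, extension_bp: int
) -> np.ndarray:
    """Equivalent-read-count statistic for windows given a coverage cumsum."""
    return (cumsum[starts + window_bp] - cumsum[starts]) / float(extension_bp)


# ---------------------------------------------------------------------------
# density tracks


@dataclass
class DensityTrack:
    """Per-bin counts of extended reads overlapping each bin."""

    contig: str
    bin_bp: int
    counts: np.ndarray
    clipped_reads: int = 0

    def __len__(self) -> int:
        return len(self.counts)


def build_density(
    readset: ReadSet,
    genome_lengths: Mapping[str, int] | GenomeSequence,
    bin_bp: int = DEFAULT_BIN_BP,
) -> Dict[str, DensityTrack]:
    """Each read contributes +1 to every bin its extension footprint overlaps,
    truncated at contig ends (clipped reads are counted, not dropped)."""
    lengths = contig_lengths(genome_lengths)
    tracks = {}
    for contig, contig_len in lengths.items():
        n_bins = -(-contig_len // bin_bp)
        counts = np.zeros(n_bins, dtype=np.int64)
        clipped = 0
        if contig in readset.reads:
            pos, strand = readset.reads[contig]
            raw_starts = np.where(strand > 0, pos, pos - readset.extension_bp)
            raw_ends = np.where(strand > 0, pos + readset.extension_bp, pos)
            clipped = int(np.count_nonzero((raw_starts < 0) | (raw_ends > contig_len)))
            starts = np.clip(raw_starts, 0, contig_len)
            ends = np.clip(raw_ends, 0, contig_len)
            keep = ends > starts
            first_bin = starts[keep] // bin_bp
            last_bin = (ends[keep] - 1) // bin_bp  # inclusive
            diff = np.zeros(n_bins + 1, dtype=np.int64)
            np.add.at(diff, first_bin, 1)
            np.add.at(diff, last_bin + 1, -1)
            counts = np.cumsum(diff[:-1])
        tracks[contig] = DensityTrack(contig, bin_bp, counts, clipped)
    return tracks


# ---------------------------------------------------------------------------
# randomized-read null


@dataclass
class NullModel:
    """Empirical distribution of the per-window statistic under uniform
    re-placement of the same number of reads."""

    window_bp: int
    n_randomizations: int
    seed: int
    total_count: int
    values: np.ndarray  # sorted ascending
    mean: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float))
        self.mean = float(self.values.mean()) if len(self.values) else float("nan")

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def pvalue(self, value: float) -> float:
        """Empirical upper tail with add-one smoothing; monotone in value."""
        n_ge = self.n_samples - int(np.searchsorted(self.values, value, side="left"))
        return (n_ge + 1) / (self.n_samples + 1)

    def pvalues(self, values: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.values, np.asarray(values, float), side="left")
        return (self.n_samples - idx + 1) / (self.n_samples + 1)


def randomize_reads(
    readset: ReadSet,
    genome_lengths: Mapping[str, int] | GenomeSequence,
    rng: np.random.Generator,
) -> ReadSet:
    """Same number of reads placed uniformly: contig proportional to length,
    position uniform, strand Bernoulli 0.5."""
    lengths = contig_lengths(genome_lengths)
    contigs = list(lengths)
    sizes = np.array([lengths[c] for c in contigs], dtype=float)
    n = readset.total_count
    counts = rng.multinomial(n, sizes / sizes.sum())
    reads = {}
    for contig, k in zip(contigs, counts):
        if k == 0:
            continue
        pos = rng.integers(0, lengths[contig], size=k, dtype=np.int64)
        strand = np.where(rng.random(k) < 0.5, 1, -1).astype(np.int8)
        reads[contig] = (pos, strand)
    return ReadSet(reads=reads, extension_bp=readset.extension_bp, label="null")


def build_null(
    readset: ReadSet,
    genome_lengths: Mapping[str, int] | GenomeSequence,
    window_bp: int = 1000,
    n_rand: int = 10,
    seed: int = 0,
) -> NullModel:
    """Pool tiling-window statistics over ``n_rand`` uniform re-placements."""
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    lengths = contig_lengths(genome_lengths)
    rng = np.random.default_rng(seed)
    pooled = []
    for _ in range(n_rand):
        null_reads = randomize_reads(readset, lengths, rng)
        for contig, contig_len in lengths.items():
            if contig_len < window_bp:
                continue
            cs = coverage_cumsum(null_reads, contig, contig_len)
            starts = np.arange(0, contig_len - window_bp + 1, window_bp, dtype=np.int64)
            pooled.append(window_values(cs, starts, window_bp, readset.extension_bp))
    values = np.concatenate(pooled) if pooled else np.empty(0)
    return NullModel(
        window_bp=window_bp,
        n_randomizations=n_rand,
        seed=seed,
        total_count=readset.total_count,
        values=values,
    )


def window_pvalue(count: float, null: NullModel) -> float:
    if count < 0:
        raise ValueError("count must be >= 0")
    return null.pvalue(count)


# ---------------------------------------------------------------------------
# enrichment calling


@dataclass(frozen=True)
class EnrichedWindow:
    interval: GenomicInterval
    value: float
    p_value: float


@dataclass(frozen=True)
class EnrichedRegion:
    interval: GenomicInterval
    p_value: float  # min member-window p
    summit: int  # midpoint of the max-statistic member window

    @property
    def width_bp(self) -> int:
        return self.interval.length


def call_enriched_windows(
    readset: ReadSet,
    genome_lengths: Mapping[str, int] | GenomeSequence,
    window_bp: int = 1000,
    step_bp: int = 200,
    p_threshold: float = 1e-3,
    seed: int = 0,
    n_rand: int = 10,
    null: NullModel | None = None,
) -> List[EnrichedWindow]:
    """Sliding windows whose statistic beats the randomized null at
    p < p_threshold, sorted by coordinate."""
    lengths = contig_lengths(genome_lengths)
    if null is None:
        null = build_null(readset, lengths, window_bp, n_rand, seed)
    out: List[EnrichedWindow] = []
    for contig in sorted(lengths):
        contig_len = lengths[contig]
        if contig_len < window_bp:
            continue
        cs = coverage_cumsum(readset, contig, contig_len)
        starts = np.arange(0, contig_len - window_bp + 1, step_bp, dtype=np.int64)
        vals = window_values(cs, starts, window_bp, readset.extension_bp)
        ps = null.pvalues(vals)
        for i in np.flatnonzero(ps < p_threshold):
            out.append(
                EnrichedWindow(
                    GenomicInterval(contig, int(starts[i]), int(starts[i]) + window_bp),
                    float(vals[i]),
                    float(ps[i]),
                )
            )
    return out


def merge_regions(
    windows: Sequence[EnrichedWindow], gap_bp: int = 1000
) -> List[EnrichedRegion]:
    """Transitive closure of 'distance <= gap_bp': disjoint regions whose
    pairwise gaps exceed gap_bp; region p = min member p, width = span."""
    if not windows:
        return []
    wins = sorted(windows, key=lambda w: (w.interval.contig, w.interval.start))
    regions: List[EnrichedRegion] = []
    cluster: List[EnrichedWindow] = [wins[0]]

    def flush(cluster: List[EnrichedWindow]) -> EnrichedRegion:
        contig = cluster[0].interval.contig
        start = min(w.interval.start for w in cluster)
        end = max(w.interval.end for w in cluster)
        best = max(cluster, key=lambda w: w.value)
        return EnrichedRegion(
            interval=GenomicInterval(contig, start, end),
            p_value=min(w.p_value for w in cluster),
            summit=int(best.interval.midpoint),
        )

    for w in wins[1:]:
        last = cluster[-1].interval
        cur_end = max(x.interval.end for x in cluster)
        same = w.interval.contig == last.contig
        if same and w.interval.start - cur_end <= gap_bp:
            cluster.append(w)
        else:
            regions.append(flush(cluster))
            cluster = [w]
    regions.append(flush(cluster))
    return regions


# ---------------------------------------------------------------------------
# promoter mark classification


@dataclass(frozen=True)
class MarkCall:
    promoter_id: str
    mark: str
    positive: bool
    p_value: float


def classify_promoters(
    promoters: Sequence[Tuple[str, str, int]] | pd.DataFrame,
    readsets: Mapping[str, ReadSet],
    genome_lengths: Mapping[str, int] | GenomeSequence,
    p_threshold: float = 1e-3,
    tss_flank_bp: int = 1000,
    n_rand: int = 10,
    seed: int = 0,
) -> Tuple[pd.DataFrame, Dict[Tuple[str, ...], int]]:
    """Per-promoter positive/negative call for each mark plus Venn counts.

    ``promoters`` is (id, contig, tss) tuples or a DataFrame with those
    columns.  Each mark gets its own null model (built from its own read
    set, with its own derived seed) so differing sequencing depths are
    handled per dataset.  A promoter window is TSS +/- tss_flank_bp,
    clipped at contig ends.  Returns (calls table, overlap counts keyed by
    the sorted tuple of positive marks; bivalent = K4me3 & K27me3 when both
    marks are present).
    """
    if isinstance(promoters, pd.DataFrame):
        prom = [
            (str(r["id"]), str(r["contig"]), int(r["tss"]))
            for _, r in promoters.iterrows()
        ]
    else:
        prom = [(str(i), str(c), int(t)) for i, c, t in promoters]
    lengths = contig_lengths(genome_lengths)
    window_bp = 2 * tss_flank_bp

    seed_seq = np.random.SeedSequence(seed)
    mark_seeds = {
        mark: int(child.generate_state(1)[0])
        for mark, child in zip(sorted(readsets), seed_seq.spawn(len(readsets)))
    }

    records: Dict[str, Dict[str, object]] = {
        pid: {"id": pid, "contig": contig, "tss": tss} for pid, contig, tss in prom
    }
    for mark in sorted(readsets):
        rs = readsets[mark]
        null = build_null(rs, lengths, window_bp, n_rand, mark_seeds[mark])
        cumsums = {}
        for pid, contig, tss in prom:
            contig_len = lengths[contig]
            if contig not in cumsums:
                cumsums[contig] = coverage_cumsum(rs, contig, contig_len)
            s = max(0, tss - tss_flank_bp)
            e = min(contig_len, tss + tss_flank_bp)
            value = (cumsums[contig][e] - cumsums[contig][s]) / rs.extension_bp
            p = null.pvalue(float(value))
            records[pid][f"{mark}_p"] = p
            records[pid][mark] = p < p_threshold
    table = pd.DataFrame(list(records.values()))
    marks = sorted(readsets)
    if {"K4me3", "K27me3"} <= set(marks):
        table["bivalent"] = table["K4me3"] & table["K27me3"]
    overlap: Dict[Tuple[str, ...], int] = {}
    for _, row in table.iterrows():
        key = tuple(m for m in marks if row[m])
        overlap[key] = overlap.get(key, 0) + 1
    return table, overlap


# ---------------------------------------------------------------------------
# heat-map matrices (signal around region midpoints)


def signal_matrix(
    regions: Sequence[EnrichedRegion],
    density: Mapping[str, DensityTrack],
    islands: Sequence[GenomicInterval],
    span_bp: int = 20000,
) -> Tuple[np.ndarray, pd.DataFrame]:
    """One row per region, centred on the region midpoint, covering span_bp.

    Rows are partitioned into island-overlapping vs not, and within each
    group sorted by enrichment width descending (ties by coordinate).
    Rows nearer than span/2 to a contig edge are NaN-padded.  Returns the
    matrix plus row metadata aligned to matrix order.
    """
    if not regions:
        return np.empty((0, 0)), pd.DataFrame(
            columns=["contig", "start", "end", "width_bp", "overlaps_island", "group"]
        )
    bin_bp = next(iter(density.values())).bin_bp
    n_cols = span_bp // bin_bp

    def overlaps_island(region: EnrichedRegion) -> bool:
        return any(region.interval.overlaps(isl) for isl in islands)

    meta = []
    for r in regions:
        meta.append(
            {
                "contig": r.interval.contig,
                "start": r.interval.start,
                "end": r.interval.end,
                "width_bp": r.width_bp,
                "overlaps_island": overlaps_island(r),
                "region": r,
            }
        )
    meta.sort(
        key=lambda m: (
            not m["overlaps_island"],
            -m["width_bp"],
            m["contig"],
            m["start"],
        )
    )
    matrix = np.full((len(meta), n_cols), np.nan)
    for i, m in enumerate(meta):
        track = density[m["contig"]]
        center_bin = int(m["region"].interval.midpoint) // bin_bp
        first = center_bin - n_cols // 2
        for j in range(n_cols):
            b = first + j
            if 0 <= b < len(track.counts):
                matrix[i, j] = track.counts[b]
    df = pd.DataFrame(
        [
            {
                "contig": m["contig"],
                "start": m["start"],
                "end": m["end"],
                "width_bp": m["width_bp"],
                "overlaps_island": m["overlaps_island"],
                "group": 0 if m["overlaps_island"] else 1,
            }
            for m in meta
        ]
    )
    return matrix, df


def gc_matrix(
    genome: GenomeSequence,
    meta: pd.DataFrame,
    span_bp: int = 20000,
    bin_bp: int = DEFAULT_BIN_BP,
) -> np.ndarray:
    """Companion per-column GC-fraction matrix for rows of signal_matrix."""
    from .seqscan import gc_fraction

    n_cols = span_bp // bin_bp
    out = np.full((len(meta), n_cols), np.nan)
    for i, row in meta.reset_index(drop=True).iterrows():
        contig_seq = genome[row["contig"]]
        center = (int(row["start"]) + int(row["end"])) // 2
        first = (center // bin_bp) * bin_bp - (n_cols // 2) * bin_bp
        for j in range(n_cols):
            s = first + j * bin_bp
            e = s + bin_bp
            if 0 <= s and e <= len(contig_seq):
                seg = contig_seq[s:e]
                out[i, j] = gc_fraction(seg)
    return out


# ---------------------------------------------------------------------------
# spreading extent


def spreading_extent(
    positions: Sequence[float],
    values: Sequence[float],
    insert: GenomicInterval | None = None,
    threshold: float = 2.0,
    side: str = "both",
) -> float:
    """Maximum distance from the insert edge at which the signal stays at or
    above threshold, scanning outward contiguously: the first sub-threshold
    point stops the scan.  Returns 0 when the nearest point is already below.

    With ``insert`` given, ``positions`` are genomic coordinates and
    distances are measured from the nearer insert edge (points inside the
    insert are ignored); otherwise positions are already distances.
    """
    pos = np.asarray(positions, dtype=float)
    val = np.asarray(values, dtype=float)
    if pos.shape != val.shape:
        raise ValueError("positions and values must align")
    if insert is None:
        return _extent_one_side(pos, val, threshold)
    left = pos < insert.start
    right = pos >= insert.end
    extents = []
    if side in ("both", "left"):
        extents.append(
            _extent_one_side(insert.start - pos[left], val[left], threshold)
        )
    if side in ("both", "right"):
        extents.append(
            _extent_one_side(pos[right] - insert.end + 1, val[right], threshold)
        )
    return max(extents) if extents else 0.0


def _extent_one_side(distances: np.ndarray, values: np.ndarray, threshold: float):
    order = np.argsort(distances, kind="stable")
    extent = 0.0
    for d, v in zip(distances[order], values[order]):
        if v >= threshold:
            extent = float(d)
        else:
            break
    return extent
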
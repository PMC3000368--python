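"""Synthetic-data generators with serialisable ground truth.

Genomes come from a first-order (dinucleotide) Markov chain so the CpG
observed/expected ratio is controllable independently of GC content;
planted segments use their own chain parameters and motif consensus words
are written at requested positions.  ChIP read sets are a mixture of a
uniform background and fold-weighted placement inside enriched intervals.
Every generator is a pure function of (spec, seed) and returns a truth
record that round-trips through JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import GenomeSequence, GenomicInterval
from .enrichment import ReadSet
from .qpcr import QpcrMeasurement

BASES = "ACGT"


# ---------------------------------------------------------------------------
# specs and truth records


@dataclass(frozen=True)
class MotifPlant:
    consensus: str
    position: int  # offset within the host segment/contig


@dataclass(frozen=True)
class SegmentSpec:
    start: int
    end: int
    gc_target: float
    cpg_oe_target: float
    motif_plants: Tuple[MotifPlant, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("segment needs 0 <= start < end")
        if not (0.0 < self.gc_target < 1.0):
            raise ValueError("gc_target must be in (0, 1)")
        if self.cpg_oe_target < 0:
            raise ValueError("cpg_oe_target must be >= 0")


@dataclass(frozen=True)
class GenomeSpec:
    contig: str
    length: int
    background_gc: float = 0.40
    background_cpg_oe: float = 0.25
    segments: Tuple[SegmentSpec, ...] = ()

    def __post_init__(self) -> None:
        spans = sorted((s.start, s.end) for s in self.segments)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("planted segments must be disjoint")
        for s in self.segments:
            if s.end > self.length:
                raise ValueError("planted segment outside contig bounds")


@dataclass(frozen=True)
class EnrichedSpec:
    start: int
    end: int
    fold: float

    def __post_init__(self) -> None:
        if self.fold < 1.0:
            raise ValueError("fold must be >= 1")


@dataclass(frozen=True)
class ChipSpec:
    """Uniform background at ``background_per_kb`` reads/kb plus fold-weighted
    extra reads inside enriched regions (total is the rounded expectation)."""

    contig: str
    background_per_kb: float = 5.0
    enriched: Tuple[EnrichedSpec, ...] = ()
    read_length: int = 36


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class TruthRecord:
    """Ground truth of one simulation; serialisable to/from JSON."""

    kind: str
    seed: int
    payload: Dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {"kind": self.kind, "seed": self.seed, "payload": _to_jsonable(self.payload)},
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "TruthRecord":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        data = json.loads(text)
        return cls(kind=data["kind"], seed=data["seed"], payload=data["payload"])


# ---------------------------------------------------------------------------
# genome generation


def _markov_rows(gc: float, oe: float) -> np.ndarray:
    """Transition matrix whose stationary GC and CpG O/E approximate targets.

    Base frequencies are (1-gc)/2, gc/2, gc/2, (1-gc)/2; the C row's G entry
    is scaled by the O/E target and the remainder redistributed, which hits
    GC within ~0.03 and O/E within ~0.1 for moderate targets.
    """
    if not (0.0 < gc < 1.0):
        raise ValueError("gc target must be in (0, 1)")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    p_cg = oe * p[2]
    if p_cg >= 1.0:
        raise ValueError(f"infeasible targets: O/E {oe} with GC {gc}")
    rows = np.tile(p, (4, 1))
    c_row = p * (1.0 - p_cg) / (1.0 - p[2])
    c_row[2] = p_cg
    if (c_row < 0).any():
        raise ValueError(f"infeasible targets: O/E {oe} with GC {gc}")
    rows[1] = c_row / c_row.sum()
    return rows


def _markov_sequence(length: int, gc: float, oe: float, rng: np.random.Generator) -> str:
    rows = _markov_rows(gc, oe)
    p0 = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    # draw all uniforms up front, walk the chain with cumulative rows
    cum = rows.cumsum(axis=1)
    u = rng.random(length)
    out = np.empty(length, dtype=np.uint8)
    out[0] = np.searchsorted(p0.cumsum(), u[0], side="right")
    for i in range(1, length):
        out[i] = np.searchsorted(cum[out[i - 1]], u[i], side="right")
    out = np.minimum(out, 3)
    return "".join(BASES[b] for b in out)


def generate_genome(spec: GenomeSpec, seed: int) -> Tuple[GenomeSequence, TruthRecord]:
    """Background chain with planted GC/O:E segments and motif consensus words."""
    rng = np.random.default_rng(seed)
    seq = list(_markov_sequence(spec.length, spec.background_gc, spec.background_cpg_oe, rng))
    planted = []
    for seg in spec.segments:
        sub = _markov_sequence(seg.end - seg.start, seg.gc_target, seg.cpg_oe_target, rng)
        seq[seg.start : seg.end] = sub
        motif_truth = []
        for plant in seg.motif_plants:
            pos = seg.start + plant.position
            word = plant.consensus.upper()
            if pos + len(word) > seg.end:
                raise ValueError("motif plant extends past its segment")
            seq[pos : pos + len(word)] = word
            motif_truth.append({"consensus": word, "start": pos, "end": pos + len(word)})
        planted.append(
            {
                "start": seg.start,
                "end": seg.end,
                "gc_target": seg.gc_target,
                "cpg_oe_target": seg.cpg_oe_target,
                "motifs": motif_truth,
            }
        )
    genome = GenomeSequence({spec.contig: "".join(seq)})
    truth = TruthRecord(
        kind="genome",
        seed=seed,
        payload={
            "contig": spec.contig,
            "length": spec.length,
            "background_gc": spec.background_gc,
            "background_cpg_oe": spec.background_cpg_oe,
            "segments": planted,
        },
    )
    return genome, truth


# ---------------------------------------------------------------------------
# ChIP reads


def generate_reads(
    spec: ChipSpec,
    genome_lengths: Mapping[str, int],
    seed: int,
    extension_bp: int = 200,
    label: str = "",
) -> Tuple[ReadSet, TruthRecord]:
    """Mixture of uniform background and fold-weighted enriched placement.

    Per-bp rate is ``background_per_kb/1000`` outside enriched intervals and
    ``fold`` times that inside; read count is the rounded total expectation,
    split multinomially across segments, positions uniform within segments.
    """
    rng = np.random.default_rng(seed)
    contig_len = dict(genome_lengths)[spec.contig]
    base_rate = spec.background_per_kb / 1000.0

    # partition the contig into background gaps + enriched segments
    segments: List[Tuple[int, int, float]] = []
    cursor = 0
    for reg in sorted(spec.enriched, key=lambda r: r.start):
        if reg.end > contig_len:
            raise ValueError("enriched region outside contig")
        if reg.start > cursor:
            segments.append((cursor, reg.start, 1.0))
        segments.append((reg.start, reg.end, reg.fold))
        cursor = reg.end
    if cursor < contig_len:
        segments.append((cursor, contig_len, 1.0))

    weights = np.array([(e - s) * f for s, e, f in segments], dtype=float)
    expected_total = base_rate * weights.sum()
    total = int(round(expected_total))
    counts = rng.multinomial(total, weights / weights.sum()) if total else np.zeros(
        len(segments), dtype=int
    )
    positions = []
    for (s, e, _), k in zip(segments, counts):
        if k:
            positions.append(rng.integers(s, e, size=k, dtype=np.int64))
    pos = np.concatenate(positions) if positions else np.empty(0, dtype=np.int64)
    strand = np.where(rng.random(len(pos)) < 0.5, 1, -1).astype(np.int8)
    readset = ReadSet(
        reads={spec.contig: (pos, strand)}, extension_bp=extension_bp, label=label
    )
    truth = TruthRecord(
        kind="chip_reads",
        seed=seed,
        payload={
            "contig": spec.contig,
            "background_per_kb": spec.background_per_kb,
            "total_reads": int(total),
            "enriched": [
                {"start": r.start, "end": r.end, "fold": r.fold} for r in spec.enriched
            ],
        },
    )
    return readset, truth


# ---------------------------------------------------------------------------
# RNA-Seq


def generate_rnaseq(
    gene_exons: Mapping[str, Sequence[GenomicInterval]],
    rates: Mapping[str, float],
    total_reads: int,
    seed: int,
    extension_bp: int = 1,
) -> Tuple[ReadSet, TruthRecord]:
    """Gene counts multinomial in rates; positions uniform within exons."""
    rng = np.random.default_rng(seed)
    genes = sorted(gene_exons)
    rate_vec = np.array([max(0.0, float(rates.get(g, 0.0))) for g in genes])
    if (rate_vec < 0).any():
        raise ValueError("rates must be >= 0")
    acc: Dict[str, List[np.ndarray]] = {}
    gene_counts = {}
    if rate_vec.sum() > 0 and total_reads > 0:
        counts = rng.multinomial(total_reads, rate_vec / rate_vec.sum())
    else:
        counts = np.zeros(len(genes), dtype=int)
    for g, k in zip(genes, counts):
        gene_counts[g] = int(k)
        if k == 0:
            continue
        exons = list(gene_exons[g])
        lens = np.array([e.length for e in exons], dtype=float)
        per_exon = rng.multinomial(k, lens / lens.sum())
        for exon, ke in zip(exons, per_exon):
            if ke:
                acc.setdefault(exon.contig, []).append(
                    rng.integers(exon.start, exon.end, size=ke, dtype=np.int64)
                )
    reads = {}
    for contig, chunks in acc.items():
        pos = np.concatenate(chunks)
        strand = np.where(rng.random(len(pos)) < 0.5, 1, -1).astype(np.int8)
        reads[contig] = (pos, strand)
    readset = ReadSet(reads=reads, extension_bp=extension_bp, label="rnaseq")
    truth = TruthRecord(
        kind="rnaseq",
        seed=seed,
        payload={"gene_counts": gene_counts, "rates": {g: float(rates.get(g, 0.0)) for g in genes}},
    )
    return readset, truth


# ---------------------------------------------------------------------------
# methylation


def find_cpg_positions(genome: GenomeSequence, contig: str) -> np.ndarray:
    """0-based positions of the C of every CpG dinucleotide."""
    seq = genome[contig]
    out = []
    i = seq.find("CG")
    while i != -1:
        out.append(i)
        i = seq.find("CG", i + 1)
    return np.asarray(out, dtype=np.int64)


def generate_methylation(
    level_fn,
    cpg_positions: Sequence[int],
    contig: str,
    coverage: int,
    seed: int,
) -> Tuple[pd.DataFrame, TruthRecord]:
    """methylated_count ~ Binomial(coverage, level(position)) per CpG."""
    rng = np.random.default_rng(seed)
    positions = np.asarray(cpg_positions, dtype=np.int64)
    levels = np.array([float(level_fn(int(p))) for p in positions])
    if ((levels < 0) | (levels > 1)).any():
        raise ValueError("levels must be in [0, 1]")
    meth = rng.binomial(coverage, levels) if len(positions) else np.empty(0, dtype=int)
    calls = pd.DataFrame(
        {
            "contig": contig,
            "position": positions,
            "methylated": meth,
            "total": np.full(len(positions), coverage, dtype=np.int64),
        }
    )
    truth = TruthRecord(
        kind="methylation",
        seed=seed,
        payload={
            "contig": contig,
            "coverage": coverage,
            "levels": {int(p): float(l) for p, l in zip(positions, levels)},
        },
    )
    return calls, truth


# ---------------------------------------------------------------------------
# qPCR


def generate_qpcr(
    true_folds: Mapping[str, float],
    cv: float,
    replicates: int,
    seed: int,
    mark: str = "K27me3",
    control_amplicon: str = "neg_ctrl",
    positions: Mapping[str, int] | None = None,
) -> Tuple[List[QpcrMeasurement], TruthRecord]:
    """chip = input * fold * lognormal(0, cv); includes a fold-1 negative control."""
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    folds = dict(true_folds)
    folds.setdefault(control_amplicon, 1.0)
    measurements = []
    for amplicon in sorted(folds):
        for r in range(1, replicates + 1):
            noise = float(np.exp(rng.normal(0.0, cv))) if cv > 0 else 1.0
            input_q = 1.0
            chip_q = input_q * folds[amplicon] * noise
            measurements.append(
                QpcrMeasurement(
                    amplicon=amplicon,
                    mark=mark,
                    replicate=f"rep{r}",
                    chip=chip_q,
                    input_=input_q,
                    is_control=amplicon == control_amplicon,
                    position=(positions or {}).get(amplicon),
                )
            )
    truth = TruthRecord(
        kind="qpcr",
        seed=seed,
        payload={
            "true_folds": {k: float(v) for k, v in folds.items()},
            "cv": cv,
            "replicates": replicates,
            "control_amplicon": control_amplicon,
            "mark": mark,
        },
    )
    return measurements, truth


# ---------------------------------------------------------------------------
# bundled presets


# mixed-composition activating-motif consensi (AP-1 / Oct / E-box-like words);
# deliberately not GC-saturated so chance matches inside GC-rich segments stay rare
ACTIVATING_CONSENSI = ("TGACTCATTA", "ATGCAAATCA", "CAGCTGTTAT")


def preset(name: str) -> GenomeSpec:
    """Bundled fixture genomes.

    - ``zfpm2-like``:      44 kb, one 1.7 kb GC-rich island, motif-free.
    - ``gene-desert-like``: inert 40 kb background.
    - ``arl3-sfxn2-like``: one island whose activating motifs all sit in the
      left half (feeds the asymmetry scorer).
    - ``ecoli-like``:      100 kb low-GC genome with two qualifying 1 kb
      GC-rich plants (one motif-free, one carrying 6 activating motifs) and
      one AT-rich control segment.
    """
    if name == "zfpm2-like":
        return GenomeSpec(
            contig="synth44k",
            length=44_000,
            background_gc=0.40,
            background_cpg_oe=0.25,
            segments=(SegmentSpec(20_000, 21_700, 0.65, 0.85),),
        )
    if name == "gene-desert-like":
        return GenomeSpec(
            contig="desert40k",
            length=40_000,
            background_gc=0.38,
            background_cpg_oe=0.20,
        )
    if name == "arl3-sfxn2-like":
        island_start, island_len = 15_000, 1_600
        plants = tuple(
            MotifPlant(ACTIVATING_CONSENSI[i % 3], 60 + i * 130) for i in range(5)
        )  # all within the left half of the island
        return GenomeSpec(
            contig="asym36k",
            length=36_000,
            background_gc=0.40,
            background_cpg_oe=0.25,
            segments=(
                SegmentSpec(
                    island_start, island_start + island_len, 0.62, 0.80, plants
                ),
            ),
        )
    if name == "ecoli-like":
        clean = SegmentSpec(30_000, 31_000, 0.65, 0.80)
        # motifs tile the whole laden plant so any island-qualifying window
        # overlapping it carries more than max_hits_per_window hits
        laden = SegmentSpec(
            60_000,
            61_000,
            0.65,
            0.80,
            tuple(
                MotifPlant(ACTIVATING_CONSENSI[i % 3], 30 + i * 110) for i in range(9)
            ),
        )
        at_control = SegmentSpec(80_000, 81_000, 0.25, 0.20)
        return GenomeSpec(
            contig="prok100k",
            length=100_000,
            background_gc=0.45,
            background_cpg_oe=0.20,
            segments=(clean, laden, at_control),
        )
    raise ValueError(f"unknown preset {name!r}")


PRESET_NAMES = ("zfpm2-like", "gene-desert-like", "arl3-sfxn2-like", "ecoli-like")
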
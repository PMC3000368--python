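"""Core genomic value types shared by every analysis module.

All coordinates are 0-based, half-open.  Conversions to/from 1-based file
formats happen only at the I/O boundary (:mod:`islandkit.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping

import numpy as np

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# integer encoding used by the numpy kernels: A=0 C=1 G=2 T=3 N=4
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0 C=1 G=2 T=3 N=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval on a named contig.

    ``strand`` is one of ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )

    def distance_to(self, other: "GenomicInterval") -> int:
        """Gap in bp between two intervals on the same contig (0 if touching/overlapping)."""
        if self.contig != other.contig:
            raise ValueError("intervals on different contigs have no distance")
        if self.overlaps(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass
class GenomeSequence:
    """Named contigs of uppercase A/C/G/T/N."""

    contigs: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: Dict[str, str] = {}
        for name, seq in self.contigs.items():
            if not name:
                raise ValueError("contig name must be non-empty")
            seq = seq.upper()
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"contig {name!r} contains invalid characters: {sorted(bad)}"
                )
            clean[name] = seq
        self.contigs = clean

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.contigs)

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def fetch(self, interval: GenomicInterval) -> str:
        """Sequence of an interval; exactly ``end - start`` characters."""
        seq = self.contigs[interval.contig]
        if interval.end > len(seq):
            raise ValueError(
                f"interval {interval.contig}:{interval.start}-{interval.end} "
                f"exceeds contig length {len(seq)}"
            )
        out = seq[interval.start : interval.end]
        if interval.strand == "-":
            out = reverse_complement(out)
        return out

    def reverse_complement(self) -> "GenomeSequence":
        return GenomeSequence(
            {name: reverse_complement(seq) for name, seq in self.contigs.items()}
        )


def clip_interval(
    contig: str, start: int, end: int, contig_length: int, strand: str = "."
) -> GenomicInterval | None:
    """Clip [start, end) to contig bounds; None when nothing remains."""
    s, e = max(0, start), min(end, contig_length)
    if s >= e:
        return None
    return GenomicInterval(contig, s, e, strand)


def contig_lengths(obj: Mapping[str, int] | GenomeSequence) -> Dict[str, int]:
    if isinstance(obj, GenomeSequence):
        return obj.lengths
    return dict(obj)
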
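"""Readers and writers for the external formats the pipeline touches.

FASTA (genomes), BED (intervals and mapped reads), bedGraph / fixed-step
WIG (tracks), TSV (methylation calls, qPCR tables), and a simple tabular
PWM format (``>name`` header, one row per motif position, 4 columns
A C G T).  Everything inside the package is 0-based half-open; 1-based
conventions (WIG) are converted here and nowhere else.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import VALID_BASES, GenomeSequence, GenomicInterval

# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Characters outside A/C/G/T/N (any case) are rejected; duplicate record
    names and empty files are errors.  Record order is preserved.
    """
    path = Path(path)
    contigs: Dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise ValueError(f"duplicate contig name {record.id!r} in {path}")
        seq = str(record.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"contig {record.id!r} in {path} has invalid characters: {sorted(bad)}"
            )
        contigs[record.id] = seq
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequence(contigs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED intervals


def read_intervals(path: str | Path, dialect: str = "bed") -> List[GenomicInterval]:
    """Read intervals from BED (>= 3 columns) or a headered TSV.

    The TSV dialect expects columns ``contig``, ``start``, ``end`` and an
    optional ``strand``.  Both are 0-based half-open on disk.
    """
    path = Path(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        required = {"contig", "start", "end"}
        if not required <= set(df.columns):
            raise ValueError(f"TSV {path} must have columns {sorted(required)}")
        out = []
        for idx, row in df.iterrows():
            strand = str(row["strand"]) if "strand" in df.columns else "."
            out.append(
                _make_interval(str(row["contig"]), int(row["start"]), int(row["end"]),
                               strand, path, idx + 2)
            )
        return out
    if dialect != "bed":
        raise ValueError(f"unknown interval dialect {dialect!r}")

    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            intervals.append(
                _make_interval(fields[0], int(fields[1]), int(fields[2]),
                               strand, path, lineno)
            )
    return intervals


def _make_interval(contig, start, end, strand, path, lineno) -> GenomicInterval:
    if start >= end:
        raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
    return GenomicInterval(contig, start, end, strand)


def write_intervals(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Write intervals as BED6 (name/score columns optional)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            score = scores[i] if scores is not None else 0
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Mapped reads: 4+ column BED-like where `start` is the 5' mapped position


def read_reads(path: str | Path) -> List[Tuple[str, int, str]]:
    """Read mapped-read records ``(contig, 5' position, strand)`` from BED."""
    reads: List[Tuple[str, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: read BED needs >= 3 columns")
            strand = "+"
            if len(fields) >= 6 and fields[5] in "+-":
                strand = fields[5]
            elif len(fields) >= 4 and fields[3] in "+-":
                strand = fields[3]
            reads.append((fields[0], int(fields[1]), strand))
    return reads


def write_reads(reads: Sequence[Tuple[str, int, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig, pos, strand in reads:
            fh.write(f"{contig}\t{pos}\t{pos + 1}\t.\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# Tracks: bedGraph and fixed-step WIG


def write_track(
    values: Sequence[float],
    grid: Sequence[GenomicInterval],
    path: str | Path,
    dialect: str = "bedgraph",
) -> None:
    """Write one value per grid interval.

    NaN values are written as explicit ``nan`` rows, never dropped, so the
    writer/reader pair round-trips losslessly.
    """
    values = list(values)
    grid = list(grid)
    if len(values) != len(grid):
        raise ValueError(f"{len(values)} values for {len(grid)} grid intervals")
    if dialect == "bedgraph":
        with open(path, "w") as fh:
            fh.write("track type=bedGraph\n")
            for iv, v in zip(grid, values):
                fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{_fmt(v)}\n")
    elif dialect == "wig-fixed":
        _write_wig_fixed(values, grid, path)
    else:
        raise ValueError(f"unknown track dialect {dialect!r}")


def _fmt(v: float) -> str:
    return "nan" if (v is None or (isinstance(v, float) and math.isnan(v))) else f"{v:.6f}"


def _write_wig_fixed(values, grid, path) -> None:
    if not grid:
        with open(path, "w") as fh:
            fh.write("track type=wiggle_0\n")
        return
    step = grid[0].length
    with open(path, "w") as fh:
        fh.write("track type=wiggle_0\n")
        prev = None
        for iv, v in zip(grid, values):
            if iv.length != step:
                raise ValueError("wig-fixed requires a uniform grid")
            contiguous = (
                prev is not None
                and prev.contig == iv.contig
                and iv.start == prev.start + step
            )
            if not contiguous:
                # WIG is 1-based: start+1 at the file boundary only
                fh.write(
                    f"fixedStep chrom={iv.contig} start={iv.start + 1} "
                    f"step={step} span={step}\n"
                )
            fh.write(_fmt(v) + "\n")
            prev = iv


def read_track(path: str | Path) -> Tuple[List[GenomicInterval], np.ndarray]:
    """Read a bedGraph or fixed-step WIG track back into (grid, values)."""
    grid: List[GenomicInterval] = []
    values: List[float] = []
    chrom, pos, step, span = None, None, None, None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(part.split("=") for part in line.split()[1:])
                chrom = kv["chrom"]
                pos = int(kv["start"]) - 1
                step = int(kv["step"])
                span = int(kv.get("span", step))
                continue
            fields = line.split("\t")
            if len(fields) >= 4:
                grid.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
                values.append(float(fields[3]))
            else:
                if chrom is None:
                    raise ValueError(f"value line before fixedStep header in {path}")
                grid.append(GenomicInterval(chrom, pos, pos + span))
                values.append(float(fields[0]))
                pos += step
    return grid, np.asarray(values, dtype=float)


# ---------------------------------------------------------------------------
# PWMs: `>name` header then one whitespace row per position, columns A C G T


def read_pwms(path: str | Path) -> Dict[str, np.ndarray]:
    """Read named probability matrices; each row must sum to ~1."""
    pwms: Dict[str, List[List[float]]] = {}
    name = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                name = line[1:].strip()
                if not name:
                    raise ValueError(f"{path}:{lineno}: empty PWM name")
                if name in pwms:
                    raise ValueError(f"{path}:{lineno}: duplicate PWM name {name!r}")
                pwms[name] = []
                continue
            if name is None:
                raise ValueError(f"{path}:{lineno}: matrix row before >name header")
            row = [float(x) for x in line.split()]
            if len(row) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns (A C G T)")
            pwms[name].append(row)
    out = {}
    for nm, rows in pwms.items():
        if not rows:
            raise ValueError(f"PWM {nm!r} has no rows")
        out[nm] = np.asarray(rows, dtype=float)
    return out


def write_pwms(pwms: Dict[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# columns: A C G T\n")
        for name, matrix in pwms.items():
            fh.write(f">{name}\n")
            for row in np.asarray(matrix, dtype=float):
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# Methylation calls and qPCR tables (TSV via pandas)

METH_COLUMNS = ["contig", "position", "methylated", "total"]


def read_methylation(path: str | Path) -> pd.DataFrame:
    """TSV of per-CpG counts: contig, position (0-based C of the CpG), methylated, total."""
    df = pd.read_csv(path, sep="\t")
    missing = set(METH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"methylation TSV {path} missing columns {sorted(missing)}")
    if ((df["methylated"] < 0) | (df["methylated"] > df["total"])).any():
        raise ValueError(f"methylation TSV {path}: need 0 <= methylated <= total")
    return df[METH_COLUMNS].copy()


def write_methylation(df: pd.DataFrame, path: str | Path) -> None:
    df[METH_COLUMNS].to_csv(path, sep="\t", index=False)


def read_qpcr(path: str | Path) -> pd.DataFrame:
    """qPCR table: amplicon, mark, replicate + quantity or Ct columns."""
    df = pd.read_csv(path, sep="\t")
    required = {"amplicon", "mark", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"qPCR TSV {path} missing columns {sorted(missing)}")
    has_quantity = {"chip", "input"} <= set(df.columns)
    has_ct = {"chip_ct", "input_ct"} <= set(df.columns)
    if not (has_quantity or has_ct):
        raise ValueError(
            f"qPCR TSV {path} needs chip/input quantities or chip_ct/input_ct columns"
        )
    return df
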
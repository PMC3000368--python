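"""ChIP-qPCR fold-enrichment quantification.

Fold enrichment is ChIP quantity over an equal mass of input DNA (or, in Ct
mode, E^(input_ct - chip_ct)).  Background normalization divides by the
enrichment of a designated negative genomic control amplicon, per mark and
per replicate, so the control maps to 1.0; a subtraction mode is available
behind a flag.  Replicates are summarised as mean +/- SEM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class QpcrMeasurement:
    """One replicate measurement for one amplicon and one antibody/mark.

    Either ``chip``/``input_`` relative quantities or ``chip_ct``/``input_ct``
    with amplification efficiency ``efficiency`` must be supplied.
    """

    amplicon: str
    mark: str
    replicate: str
    chip: Optional[float] = None
    input_: Optional[float] = None
    chip_ct: Optional[float] = None
    input_ct: Optional[float] = None
    efficiency: float = 2.0
    is_control: bool = False
    position: Optional[int] = None

    def __post_init__(self) -> None:
        quantity_mode = self.chip is not None and self.input_ is not None
        ct_mode = self.chip_ct is not None and self.input_ct is not None
        if not (quantity_mode or ct_mode):
            raise ValueError(
                f"amplicon {self.amplicon!r}: need chip/input quantities or Ct values"
            )
        if quantity_mode and (self.chip <= 0 or self.input_ <= 0):
            raise ValueError(f"amplicon {self.amplicon!r}: quantities must be positive")
        if ct_mode and not (1.0 < self.efficiency <= 2.0):
            raise ValueError(
                f"amplicon {self.amplicon!r}: efficiency must be in (1, 2], "
                f"got {self.efficiency}"
            )


@dataclass(frozen=True)
class EnrichmentResult:
    amplicon: str
    mark: str
    mean_fold: float
    sem: Optional[float]
    n: int
    normalized: bool

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n replicates must be >= 1")
        if self.n == 1 and self.sem is not None:
            raise ValueError("sem must be missing at n = 1")


def fold_enrichment(m: QpcrMeasurement) -> float:
    """ChIP/input ratio; in Ct mode E^(input_ct - chip_ct)."""
    if m.chip is not None and m.input_ is not None:
        return m.chip / m.input_
    return m.efficiency ** (m.input_ct - m.chip_ct)


def normalize_background(
    enrichment: float, control_enrichment: float, mode: str = "divide"
) -> float:
    """Background normalization over a negative genomic control.

    ``divide`` (default) maps the control amplicon to 1.0 and preserves
    positivity; ``subtract`` is the literal alternative reading.
    """
    if control_enrichment <= 0:
        raise ValueError("control enrichment must be positive")
    if mode == "divide":
        return enrichment / control_enrichment
    if mode == "subtract":
        return enrichment - control_enrichment
    raise ValueError(f"unknown normalization mode {mode!r}")


def summarize_replicates(values: Sequence[float]) -> Tuple[float, Optional[float], int]:
    """(mean, SEM, n); SEM = sample sd / sqrt(n), missing at n = 1."""
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("no replicate values")
    n = len(vals)
    mean = sum(vals) / n
    if n == 1:
        return mean, None, 1
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
    return mean, sd / math.sqrt(n), n


def measurements_from_table(df: pd.DataFrame, mode: str = "auto") -> List[QpcrMeasurement]:
    """Build measurements from a qPCR TSV table (see :func:`islandkit.io.read_qpcr`)."""
    has_quantity = {"chip", "input"} <= set(df.columns)
    has_ct = {"chip_ct", "input_ct"} <= set(df.columns)
    if mode == "auto":
        mode = "quantity" if has_quantity else "ct"
    if mode == "quantity" and not has_quantity:
        raise ValueError("quantity mode requires chip and input columns")
    if mode == "ct" and not has_ct:
        raise ValueError("ct mode requires chip_ct and input_ct columns")
    out = []
    for _, row in df.iterrows():
        kwargs = dict(
            amplicon=str(row["amplicon"]),
            mark=str(row["mark"]),
            replicate=str(row["replicate"]),
            is_control=bool(row["is_control"]) if "is_control" in df.columns else False,
        )
        if "position" in df.columns and not pd.isna(row["position"]):
            kwargs["position"] = int(row["position"])
        if mode == "quantity":
            kwargs["chip"] = float(row["chip"])
            kwargs["input_"] = float(row["input"])
        else:
            kwargs["chip_ct"] = float(row["chip_ct"])
            kwargs["input_ct"] = float(row["input_ct"])
            if "efficiency" in df.columns and not pd.isna(row["efficiency"]):
                kwargs["efficiency"] = float(row["efficiency"])
        out.append(QpcrMeasurement(**kwargs))
    return out


def quantify(
    measurements: Sequence[QpcrMeasurement],
    normalize_marks: Sequence[str] = (),
    normalization_mode: str = "divide",
) -> pd.DataFrame:
    """Per-amplicon, per-mark fold enrichment with replicate mean and SEM.

    For marks listed in ``normalize_marks`` each replicate's enrichment is
    normalized over the same replicate's negative-control enrichment before
    averaging (normalize-then-average, matching per-replicate pairing).
    """
    per_rep: dict = {}
    controls: dict = {}
    for m in measurements:
        fe = fold_enrichment(m)
        per_rep.setdefault((m.amplicon, m.mark), []).append((m.replicate, fe))
        if m.is_control:
            controls[(m.mark, m.replicate)] = fe

    rows = []
    for (amplicon, mark), reps in sorted(per_rep.items()):
        normalized = mark in normalize_marks
        values = []
        for replicate, fe in reps:
            if normalized:
                key = (mark, replicate)
                if key not in controls:
                    raise ValueError(
                        f"no negative-control measurement for mark {mark!r} "
                        f"replicate {replicate!r}"
                    )
                fe = normalize_background(fe, controls[key], normalization_mode)
            values.append(fe)
        mean, sem, n = summarize_replicates(values)
        rows.append(
            {
                "amplicon": amplicon,
                "mark": mark,
                "mean_fold": mean,
                "sem": np.nan if sem is None else sem,
                "n": n,
                "normalized": normalized,
            }
        )
    return pd.DataFrame(rows)
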
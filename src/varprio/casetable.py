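"""Bundled clinical validation cohort summary and breakpoint arithmetic.

The package ships a small transcription of the diagnostic findings of
the clinical validation cohort (20 diagnosed cases with event class,
published breakpoint coordinates where available, and prior-testing
status).  It serves two purposes: bookkeeping checks (case counts,
exome-negative diagnoses, SV diagnoses among them) and regression
checks that the breakpoint-to-size arithmetic reproduces every
published SV size from its printed coordinate pair.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import List, Optional, Tuple

import pandas as pd

from .io import format_length, sv_length
from .records import StructuralVariant

_COORD_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)(?:-(?P<end>\d+))?$")


def load_diagnostic_cases() -> pd.DataFrame:
    """The bundled cohort summary as a string-typed table."""
    ref = resources.files("varprio.data").joinpath("diagnostic_cases.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        frame = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    return frame.apply(lambda col: col.str.strip())


def n_cases(frame: Optional[pd.DataFrame] = None) -> int:
    frame = load_diagnostic_cases() if frame is None else frame
    return len(frame)


def n_prior_exome(frame: Optional[pd.DataFrame] = None) -> int:
    """Diagnosed cases whose prior exome sequencing was negative."""
    frame = load_diagnostic_cases() if frame is None else frame
    return int((frame["prior_exome"] == "yes").sum())


def n_sv_in_prior_exome(frame: Optional[pd.DataFrame] = None) -> int:
    """Structural-variant diagnoses among the prior-exome-negative cases."""
    frame = load_diagnostic_cases() if frame is None else frame
    sub = frame[frame["prior_exome"] == "yes"]
    return int(sub["event_class"].str.startswith("sv_").sum())


def _parse_primary_pair(coords: str) -> Optional[Tuple[str, int, int]]:
    primary = coords.split("|")[0].strip()
    m = _COORD_RE.match(primary)
    if not m or m.group("end") is None:
        return None
    return m.group("chrom"), int(m.group("start")), int(m.group("end"))


@dataclass(frozen=True)
class SizeCheck:
    """One published coordinate pair with its recomputed span."""

    case_id: str
    chrom: str
    start_1based: int
    end_1based: int
    computed_bp: int
    display: str
    printed: str


def printed_size_checks() -> List[SizeCheck]:
    """Recompute each published SV size from its breakpoint coordinates.

    Coordinates are 1-based breakpoints as printed; they are converted
    to internal 0-based points and the span measured with
    :func:`varprio.io.sv_length`, then rendered at display precision.
    """
    checks: List[SizeCheck] = []
    for _, row in load_diagnostic_cases().iterrows():
        if not row["printed_size"]:
            continue
        parsed = _parse_primary_pair(row["coordinates"])
        if parsed is None:
            continue
        chrom, start, end = parsed
        sv_type = row["event_class"].removeprefix("sv_")
        sv = StructuralVariant(
            id=row["case_id"], sv_type=sv_type,
            chrom1=chrom, pos1=start - 1, chrom2=chrom, pos2=end - 1,
        )
        bp = sv_length(sv)
        checks.append(
            SizeCheck(
                case_id=row["case_id"], chrom=chrom,
                start_1based=start, end_1based=end,
                computed_bp=bp, display=format_length(bp),
                printed=row["printed_size"],
            )
        )
    return checks
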
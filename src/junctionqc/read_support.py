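"""Long-read junction support: do single reads span a Hi-C gap?

A junction joining truly adjacent contigs should be crossed by many long
reads, each aligning as one primary record anchored on both sides of the
gap. A misjoined junction attracts no such reads — reads from either true
locus end or split at the junction. Split or supplementary fragments never
combine into spanning evidence: a read split across a junction is evidence
against it, not for it.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .errors import FormatError, UndefinedStatisticError
from .layout import GapRecord


@dataclass(frozen=True)
class ReadAlignmentRecord:
    """One alignment record (one PAF line); coordinates 0-based half-open."""

    read_id: str
    read_length: int
    read_start: int
    read_end: int
    strand: str
    target: str
    target_length: int
    target_start: int
    target_end: int
    matches: int = 0
    alignment_length: int = 0
    mapq: int = 60

    def __post_init__(self):
        if not (0 <= self.read_start < self.read_end <= self.read_length):
            raise FormatError(
                f"read interval [{self.read_start},{self.read_end}) outside "
                f"read {self.read_id} of length {self.read_length}"
            )
        if not (0 <= self.target_start < self.target_end <= self.target_length):
            raise FormatError(
                f"target interval [{self.target_start},{self.target_end}) outside "
                f"{self.target} of length {self.target_length}"
            )


class SupportClass(str, Enum):
    UNSUPPORTED = "UNSUPPORTED"  # zero spanning reads: the junction is refuted
    WEAK = "WEAK"  # some, but fewer than strong_min
    SUPPORTED = "SUPPORTED"


@dataclass
class JunctionAssessment:
    scaffold: str
    gap_index: int
    gap_start: int
    gap_end: int
    spanning_count: int
    support_class: SupportClass
    no_data: bool = False

    @property
    def junction_id(self) -> str:
        return f"{self.scaffold}:gap{self.gap_index}"


def spans_junction(
    record: ReadAlignmentRecord,
    gap: GapRecord,
    min_anchor: int = 1000,
    min_mapq: int = 20,
) -> bool:
    """True iff this single record covers the gap with ``min_anchor`` bp
    anchored on both sides and mapping quality at least ``min_mapq``."""
    if record.target != gap.scaffold:
        return False
    return (
        record.mapq >= min_mapq
        and record.target_start <= gap.start - min_anchor
        and record.target_end >= gap.end + min_anchor
    )


def assess_junctions(
    records: list[ReadAlignmentRecord],
    gaps: list[GapRecord],
    min_anchor: int = 1000,
    min_mapq: int = 20,
    strong_min: int = 5,
) -> list[JunctionAssessment]:
    """Count spanning reads per Hi-C gap and classify each junction.

    Classes: UNSUPPORTED (0 reads), WEAK (1 to strong_min-1), SUPPORTED
    (>= strong_min, default 5). Every Hi-C gap gets a row, including gaps
    on scaffolds absent from the alignments (count 0, flagged no-data).
    """
    by_target: dict[str, list[ReadAlignmentRecord]] = {}
    for r in records:
        by_target.setdefault(r.target, []).append(r)
    out = []
    for gap in gaps:
        if gap.source != "HIC":
            continue
        scaffold_records = by_target.get(gap.scaffold)
        count = 0
        if scaffold_records:
            count = sum(
                1 for r in scaffold_records if spans_junction(r, gap, min_anchor, min_mapq)
            )
        if count == 0:
            cls = SupportClass.UNSUPPORTED
        elif count < strong_min:
            cls = SupportClass.WEAK
        else:
            cls = SupportClass.SUPPORTED
        out.append(
            JunctionAssessment(
                scaffold=gap.scaffold,
                gap_index=gap.index,
                gap_start=gap.start,
                gap_end=gap.end,
                spanning_count=count,
                support_class=cls,
                no_data=scaffold_records is None,
            )
        )
    return out


def summarize_support(assessments: list[JunctionAssessment]) -> pd.DataFrame:
    """Counts and percentages per support class over all assessed junctions.

    Percentage = count / total * 100 rounded to the nearest integer (half
    rounds up), matching how junction-verification tables are reported.
    """
    if not assessments:
        raise UndefinedStatisticError("cannot summarize an empty assessment set")
    total = len(assessments)
    rows = []
    for cls in SupportClass:
        n = sum(1 for a in assessments if a.support_class is cls)
        rows.append(
            {
                "class": cls.value,
                "count": n,
                "total": total,
                "percentage": int(n / total * 100 + 0.5),
            }
        )
    return pd.DataFrame(rows)


# -- PAF I/O ------------------------------------------------------------
#
# Minimal reader/writer for the 12 mandatory PAF columns plus SAM-style
# tags; none of the pre-installed libraries parses PAF and the format is a
# plain TSV.


def write_paf(records: list[ReadAlignmentRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.read_id}\t{r.read_length}\t{r.read_start}\t{r.read_end}\t"
                f"{r.strand}\t{r.target}\t{r.target_length}\t{r.target_start}\t"
                f"{r.target_end}\t{r.matches}\t{r.alignment_length}\t{r.mapq}\n"
            )


def read_paf(path: str) -> list[ReadAlignmentRecord]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"PAF line has {len(f)} columns, expected >= 12", lineno)
            out.append(
                ReadAlignmentRecord(
                    read_id=f[0],
                    read_length=int(f[1]),
                    read_start=int(f[2]),
                    read_end=int(f[3]),
                    strand=f[4],
                    target=f[5],
                    target_length=int(f[6]),
                    target_start=int(f[7]),
                    target_end=int(f[8]),
                    matches=int(f[9]),
                    alignment_length=int(f[10]),
                    mapq=int(f[11]),
                )
            )
    return out


def write_support_tsv(
    assessments: list[JunctionAssessment],
    path: str,
    min_anchor: int = 1000,
    min_mapq: int = 20,
    strong_min: int = 5,
) -> None:
    """Per-junction table; the header records the spanning definition used."""
    with open(path, "w") as fh:
        fh.write(
            f"# spanning = single primary record covering gap +/- {min_anchor} bp, "
            f"mapq >= {min_mapq}; SUPPORTED at >= {strong_min} reads\n"
        )
        fh.write("junction\tscaffold\tgap_start\tgap_end\tspanning_reads\tclass\tno_data\n")
        for a in assessments:
            fh.write(
                f"{a.junction_id}\t{a.scaffold}\t{a.gap_start}\t{a.gap_end}\t"
                f"{a.spanning_count}\t{a.support_class.value}\t{int(a.no_data)}\n"
            )


__all__ = [
    "JunctionAssessment",
    "ReadAlignmentRecord",
    "SupportClass",
    "assess_junctions",
    "read_paf",
    "spans_junction",
    "summarize_support",
    "write_paf",
    "write_support_tsv",
]
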
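"""Assembly contiguity statistics and report operations.

Covers the standard scaffold-assembly report: N50 and friends over
scaffolds and unplaced contigs, gap counts and sizes, the per-length-bin
misjoin-rate table, percentage summaries with an explicit rounding mode,
and before/after comparison of two runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError
from .layout import Gap, ScaffoldLayout


def nxx(lengths, fraction: float = 0.5) -> int:
    """Nxx statistic: smallest L such that pieces >= L hold >= fraction of
    the total (cumulative rule over lengths sorted descending). N50 is
    fraction 0.5."""
    lengths = [int(x) for x in lengths]
    if not lengths or min(lengths) <= 0:
        raise UndefinedStatisticError("nxx requires non-empty positive lengths")
    if not 0 < fraction < 1:
        raise UndefinedStatisticError(f"fraction must be in (0, 1), got {fraction}")
    lengths.sort(reverse=True)
    threshold = fraction * sum(lengths)
    acc = 0
    for ln in lengths:
        acc += ln
        if acc >= threshold:
            return ln
    raise AssertionError("unreachable")  # pragma: no cover


@dataclass
class AssemblyStats:
    """The standard per-assembly report fields (bp or counts).

    Scaffold fields are None when the layout has no scaffolds; remaining
    fields are None when there are no unplaced contigs.
    """

    total_assembly_length: int
    total_scaffold_length: int | None
    n_scaffolds: int | None
    scaffold_n50: int | None
    scaffold_mean: float | None
    scaffold_longest: int | None
    scaffold_shortest: int | None
    n_gaps: int | None
    total_gap_size: int | None
    contigs_in_scaffolds: int | None
    remaining_contigs: int | None
    remaining_total_length: int | None
    remaining_n50: int | None
    remaining_mean: float | None
    remaining_max: int | None
    remaining_min: int | None

    def as_dict(self) -> dict:
        return asdict(self)


def summarize(layout: ScaffoldLayout) -> AssemblyStats:
    """Compute every report field from a layout.

    Gap statistics run over gap records only; "remaining" statistics over
    unplaced contigs; total assembly length is the sum of scaffold and
    unplaced lengths.
    """
    scaffold_lengths = sorted(layout.scaffold_lengths().values(), reverse=True)
    gap_lengths = [
        comp.length
        for comps in layout.scaffolds.values()
        for comp in comps
        if isinstance(comp, Gap)
    ]
    remaining = sorted(layout.unplaced.values(), reverse=True)
    n_placements = sum(len([c for c in comps if not isinstance(c, Gap)])
                       for comps in layout.scaffolds.values())

    total_scaffold = sum(scaffold_lengths) if scaffold_lengths else None
    total = (total_scaffold or 0) + sum(remaining)
    return AssemblyStats(
        total_assembly_length=total,
        total_scaffold_length=total_scaffold,
        n_scaffolds=len(scaffold_lengths) or None,
        scaffold_n50=nxx(scaffold_lengths) if scaffold_lengths else None,
        scaffold_mean=float(np.mean(scaffold_lengths)) if scaffold_lengths else None,
        scaffold_longest=scaffold_lengths[0] if scaffold_lengths else None,
        scaffold_shortest=scaffold_lengths[-1] if scaffold_lengths else None,
        n_gaps=len(gap_lengths) if scaffold_lengths else None,
        total_gap_size=sum(gap_lengths) if scaffold_lengths else None,
        contigs_in_scaffolds=n_placements if scaffold_lengths else None,
        remaining_contigs=len(remaining) if remaining else None,
        remaining_total_length=sum(remaining) if remaining else None,
        remaining_n50=nxx(remaining) if remaining else None,
        remaining_mean=float(np.mean(remaining)) if remaining else None,
        remaining_max=remaining[0] if remaining else None,
        remaining_min=remaining[-1] if remaining else None,
    )


def percentage_summary(numerator: int, denominator: int, rounding: str = "nearest") -> int:
    """100 * numerator / denominator with an explicit rounding mode.

    ``nearest`` rounds half up; ``floor`` truncates. Published summary
    tables mix both conventions, so the mode is always a parameter, never a
    hidden default, and report headers name the mode used.
    """
    if denominator <= 0:
        raise UndefinedStatisticError("percentage denominator must be > 0")
    value = 100 * numerator / denominator
    if rounding == "nearest":
        return int(math.floor(value + 0.5))
    if rounding == "floor":
        return int(math.floor(value))
    raise UndefinedStatisticError(f"unknown rounding mode {rounding!r}")


def error_rate_by_contig_length(
    layout: ScaffoldLayout,
    involved_contig_ids: set[str],
    bin_width: int = 50_000,
) -> pd.DataFrame:
    """Misjoin involvement rate per contig-length bin.

    Contigs are binned by length into [k*w, (k+1)*w); each bin reports the
    contig count, the count involved in misjoins, and the floor percentage.
    Bins with no contigs between the first and last occupied bin are
    reported with NA percentage.
    """
    if bin_width <= 0:
        raise UndefinedStatisticError("bin_width must be > 0")
    lengths = layout.contig_lengths()
    bins: dict[int, list[str]] = {}
    for cid, ln in lengths.items():
        bins.setdefault(ln // bin_width, []).append(cid)
    if not bins:
        return pd.DataFrame(
            columns=["bin_start", "bin_end", "n_contigs", "n_involved", "percentage"]
        )
    rows = []
    for k in range(min(bins), max(bins) + 1):
        ids = bins.get(k, [])
        involved = sum(1 for c in ids if c in involved_contig_ids)
        rows.append(
            {
                "bin_start": k * bin_width,
                "bin_end": (k + 1) * bin_width,
                "n_contigs": len(ids),
                "n_involved": involved,
                "percentage": (
                    percentage_summary(involved, len(ids), "floor") if ids else pd.NA
                ),
            }
        )
    return pd.DataFrame(rows)


def compare_runs(before: AssemblyStats, after: AssemblyStats) -> pd.DataFrame:
    """Side-by-side field table with absolute delta and fold change."""
    rows = []
    b, a = before.as_dict(), after.as_dict()
    for fieldname in b:
        bv, av = b[fieldname], a[fieldname]
        delta = fold = None
        if bv is not None and av is not None:
            delta = av - bv
            fold = av / bv if bv else None
        rows.append({"field": fieldname, "before": bv, "after": av,
                     "delta": delta, "fold": fold})
    return pd.DataFrame(rows)


__all__ = [
    "AssemblyStats",
    "compare_runs",
    "error_rate_by_contig_length",
    "nxx",
    "percentage_summary",
    "summarize",
]
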
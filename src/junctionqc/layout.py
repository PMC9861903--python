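"""Scaffold layouts: ordered, oriented contig placements interleaved with gaps.

A :class:`ScaffoldLayout` is the in-memory form of an AGP file: each scaffold
is an ordered list of contig placements and gap records, plus a set of
unplaced contigs. All internal coordinates are 0-based half-open; AGP I/O
converts to and from the 1-based inclusive convention of AGP v2.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import CoordinateError, FormatError

# AGP column-9 linkage evidence <-> internal gap source tags. Sources without
# a mapping are written verbatim (both ends of the round trip are ours).
_SOURCE_TO_EVIDENCE = {"HIC": "proximity_ligation", "OM": "map", "TRUE": "paired-ends"}
_EVIDENCE_TO_SOURCE = {v: k for k, v in _SOURCE_TO_EVIDENCE.items()}


@dataclass(frozen=True)
class ContigPlacement:
    """One oriented piece of a contig placed in a scaffold."""

    contig_id: str
    contig_beg: int  # 0-based, inclusive
    contig_end: int  # 0-based, exclusive
    orientation: str  # "+" or "-"

    def __post_init__(self):
        if not 0 <= self.contig_beg < self.contig_end:
            raise CoordinateError(
                f"invalid placement span [{self.contig_beg}, {self.contig_end}) "
                f"for contig {self.contig_id}"
            )
        if self.orientation not in ("+", "-"):
            raise CoordinateError(f"orientation must be + or -, got {self.orientation!r}")

    @property
    def span(self) -> int:
        return self.contig_end - self.contig_beg


@dataclass(frozen=True)
class Gap:
    """A gap component inside a scaffold (length and provenance only)."""

    length: int
    source: str = "HIC"

    def __post_init__(self):
        if self.length <= 0:
            raise CoordinateError(f"gap length must be positive, got {self.length}")

    @property
    def span(self) -> int:
        return self.length


@dataclass(frozen=True)
class GapRecord:
    """A gap located on a scaffold, in absolute scaffold coordinates."""

    scaffold: str
    index: int  # 0-based junction index within the scaffold
    start: int  # 0-based, inclusive
    end: int  # 0-based, exclusive
    source: str

    @property
    def declared_length(self) -> int:
        return self.end - self.start


@dataclass
class ScaffoldLayout:
    """Scaffolds (ordered components) plus unplaced contigs.

    ``scaffolds`` maps scaffold name to its ordered component list
    (:class:`ContigPlacement` / :class:`Gap`); ``unplaced`` maps contig id to
    contig length.
    """

    scaffolds: dict[str, list[ContigPlacement | Gap]] = field(default_factory=dict)
    unplaced: dict[str, int] = field(default_factory=dict)

    # -- basic geometry -------------------------------------------------

    def scaffold_length(self, name: str) -> int:
        return sum(c.span for c in self.scaffolds[name])

    def scaffold_lengths(self) -> dict[str, int]:
        return {name: self.scaffold_length(name) for name in self.scaffolds}

    def gap_records(self, name: str | None = None) -> list[GapRecord]:
        """Absolute-coordinate gap records for one scaffold or all scaffolds."""
        names = [name] if name is not None else list(self.scaffolds)
        out: list[GapRecord] = []
        for nm in names:
            pos = 0
            idx = 0
            for comp in self.scaffolds[nm]:
                if isinstance(comp, Gap):
                    out.append(GapRecord(nm, idx, pos, pos + comp.length, comp.source))
                    idx += 1
                pos += comp.span
            # idx is the per-scaffold junction counter
        return out

    def placements(self, name: str | None = None) -> list[tuple[str, int, ContigPlacement]]:
        """(scaffold, scaffold_start, placement) triples in scaffold order."""
        names = [name] if name is not None else list(self.scaffolds)
        out = []
        for nm in names:
            pos = 0
            for comp in self.scaffolds[nm]:
                if isinstance(comp, ContigPlacement):
                    out.append((nm, pos, comp))
                pos += comp.span
        return out

    def contig_lengths(self) -> dict[str, int]:
        """Total placed span per contig id, plus unplaced contig lengths."""
        lengths: dict[str, int] = {}
        for _, _, p in self.placements():
            lengths[p.contig_id] = lengths.get(p.contig_id, 0) + p.span
        lengths.update(self.unplaced)
        return lengths

    def total_contig_bases(self) -> int:
        return sum(p.span for _, _, p in self.placements()) + sum(self.unplaced.values())

    def copy(self) -> "ScaffoldLayout":
        return ScaffoldLayout(
            {k: list(v) for k, v in self.scaffolds.items()}, dict(self.unplaced)
        )

    def __eq__(self, other):
        if not isinstance(other, ScaffoldLayout):
            return NotImplemented
        return self.scaffolds == other.scaffolds and self.unplaced == other.unplaced


def build_scaffold_sequence(
    components: list[ContigPlacement | Gap], contig_seqs: dict[str, str]
) -> str:
    """Materialise a scaffold's sequence from contig sequences, N-filling gaps."""
    parts = []
    for comp in components:
        if isinstance(comp, Gap):
            parts.append("N" * comp.length)
        else:
            seq = contig_seqs[comp.contig_id][comp.contig_beg : comp.contig_end]
            if comp.orientation == "-":
                seq = reverse_complement(seq)
            parts.append(seq)
    return "".join(parts)


_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# -- AGP v2.1 I/O -------------------------------------------------------


def write_agp(layout: ScaffoldLayout, path: str) -> None:
    """Write a layout as AGP v2.1.

    Contig placements become component-type ``W`` lines, gaps become ``N``
    lines with ``gap_type`` "scaffold" and linkage evidence in column 9.
    Unplaced contigs are written as singleton objects named after the contig.
    """
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for name, comps in layout.scaffolds.items():
            pos = 0
            for part, comp in enumerate(comps, start=1):
                beg, end = pos + 1, pos + comp.span  # 1-based inclusive
                if isinstance(comp, Gap):
                    evidence = _SOURCE_TO_EVIDENCE.get(comp.source, comp.source)
                    fh.write(
                        f"{name}\t{beg}\t{end}\t{part}\tN\t{comp.length}\t"
                        f"scaffold\tyes\t{evidence}\n"
                    )
                else:
                    fh.write(
                        f"{name}\t{beg}\t{end}\t{part}\tW\t{comp.contig_id}\t"
                        f"{comp.contig_beg + 1}\t{comp.contig_end}\t{comp.orientation}\n"
                    )
                pos += comp.span
        for contig_id, length in layout.unplaced.items():
            fh.write(f"{contig_id}\t1\t{length}\t1\tW\t{contig_id}\t1\t{length}\t+\n")


def read_agp(path: str) -> ScaffoldLayout:
    """Read AGP v2.1 into a :class:`ScaffoldLayout`.

    A single-component object whose name equals its component id is treated
    as an unplaced contig. Unknown-size (``U``) gaps keep their declared
    length.
    """
    scaffolds: dict[str, list[ContigPlacement | Gap]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise FormatError(f"AGP line has {len(f)} columns, expected 9", lineno)
            obj, obj_beg, obj_end, _part, ctype = f[0], int(f[1]), int(f[2]), f[3], f[4]
            comps = scaffolds.setdefault(obj, [])
            if ctype == "W":
                comp = ContigPlacement(f[5], int(f[6]) - 1, int(f[7]), f[8])
            elif ctype in ("N", "U"):
                evidence = f[8]
                comp = Gap(int(f[5]), _EVIDENCE_TO_SOURCE.get(evidence, evidence))
            else:
                raise FormatError(f"unsupported AGP component type {ctype!r}", lineno)
            if obj_end - obj_beg + 1 != comp.span:
                raise FormatError(
                    f"object span {obj_end - obj_beg + 1} != component span {comp.span}",
                    lineno,
                )
            comps.append(comp)
    layout = ScaffoldLayout()
    for obj, comps in scaffolds.items():
        if (
            len(comps) == 1
            and isinstance(comps[0], ContigPlacement)
            and comps[0].contig_id == obj
        ):
            layout.unplaced[obj] = comps[0].span
        else:
            layout.scaffolds[obj] = comps
    return layout


__all__ = [
    "ContigPlacement",
    "Gap",
    "GapRecord",
    "ScaffoldLayout",
    "build_scaffold_sequence",
    "reverse_complement",
    "read_agp",
    "write_agp",
    "replace",
]
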
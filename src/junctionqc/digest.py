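"""In-silico digestion: label positions for nicking-enzyme motifs, CMAP I/O.

Optical genome maps record where a nicking endonuclease (e.g. Nt.BspQI,
motif GCTCTTC) labels a DNA molecule. The in-silico counterpart scans a
sequence for the motif on both strands and reports label positions, which
can then be aligned against consensus maps. Label positions are the 0-based
first base of the motif match; the enzyme's nick offset is chemistry, not
geometry, and is deliberately not applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, JunctionQCError
from .layout import reverse_complement


@dataclass(frozen=True)
class Enzyme:
    """A nicking enzyme: name, recognition motif, nick offset (metadata only)."""

    name: str
    motif: str
    nick_offset: int = 1


@dataclass
class LabelMap:
    """Ordered label positions on one sequence or consensus map, one channel.

    ``labels`` are bp offsets from the sequence start, strictly increasing,
    each in ``[0, length)``.
    """

    map_id: str
    length: float
    channel: str
    labels: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=float)
        if self.labels.size:
            if np.any(np.diff(self.labels) <= 0):
                raise JunctionQCError(f"labels of map {self.map_id} not strictly increasing")
            if self.labels[0] < 0 or self.labels[-1] >= self.length:
                raise JunctionQCError(
                    f"labels of map {self.map_id} outside [0, {self.length})"
                )

    @property
    def n_labels(self) -> int:
        return int(self.labels.size)


def _validate_motif(motif: str) -> None:
    if not motif:
        raise JunctionQCError("empty recognition motif")
    bad = set(motif.upper()) - set("ACGT")
    if bad:
        raise JunctionQCError(f"motif contains non-ACGT characters: {sorted(bad)}")
    if len(motif) < 4:
        raise JunctionQCError(f"motif {motif!r} shorter than 4 bp")


def find_recognition_sites(sequence: str, motif: str) -> list[int]:
    """0-based start positions where the motif or its reverse complement occurs.

    Both orientations are searched on the forward strand (a nicking enzyme
    recognises its site on either strand). Overlapping occurrences are all
    reported; positions are merged, deduplicated and sorted. ``N`` bases
    never match.
    """
    _validate_motif(motif)
    seq = sequence.upper()
    motifs = {motif.upper(), reverse_complement(motif.upper())}
    hits: set[int] = set()
    for m in motifs:
        start = seq.find(m)
        while start != -1:
            hits.add(start)
            start = seq.find(m, start + 1)  # step 1: overlaps all reported
    return sorted(hits)


def condense_sites(sites: list[int], min_label_distance: int) -> list[int]:
    """Collapse runs of sites closer than ``min_label_distance`` to midpoints.

    Scanning left to right, consecutive sites separated by less than the
    threshold accumulate into one run; each run is replaced by the midpoint
    of its first and last member (rounded down). With threshold 0 this is
    the identity.
    """
    if min_label_distance < 0:
        raise JunctionQCError("min_label_distance must be >= 0")
    if min_label_distance == 0 or len(sites) < 2:
        return list(sites)
    out: list[int] = []
    run_start = run_end = sites[0]
    for s in sites[1:]:
        if s - run_end < min_label_distance:
            run_end = s
        else:
            out.append((run_start + run_end) // 2)
            run_start = run_end = s
    out.append((run_start + run_end) // 2)
    return out


def in_silico_digest(
    sequences: dict[str, str],
    enzymes: list[Enzyme],
    min_label_distance: int = 1000,
) -> list[LabelMap]:
    """One LabelMap per (sequence, enzyme), with close-site condensation.

    The default 1 kb condensation emulates the optical resolution limit
    below which adjacent labels are not separable on an instrument.
    """
    maps = []
    for seq_id, seq in sequences.items():
        for enz in enzymes:
            sites = find_recognition_sites(seq, enz.motif)
            labels = condense_sites(sites, min_label_distance)
            maps.append(LabelMap(seq_id, float(len(seq)), enz.name, np.array(labels, float)))
    return maps


# -- CMAP v0.1 I/O ------------------------------------------------------
#
# Tab-separated; positions are written 1-based with one decimal. Maps
# sharing a map id but differing in channel are merged into one CMAP record
# with per-row LabelChannel codes; the final row of each record is the
# map-end sentinel (LabelChannel 0, position = map length).

_CMAP_COLUMNS = (
    "CMapId",
    "ContigLength",
    "NumSites",
    "SiteID",
    "LabelChannel",
    "Position",
    "StdDev",
    "Coverage",
    "Occurrence",
)


def write_cmap(maps: list[LabelMap], path: str) -> None:
    channels = sorted({m.channel for m in maps})
    codes = {ch: i + 1 for i, ch in enumerate(channels)}
    by_id: dict[str, list[LabelMap]] = {}
    for m in maps:
        by_id.setdefault(m.map_id, []).append(m)
    with open(path, "w") as fh:
        fh.write("# CMAP File Version:\t0.1\n")
        fh.write(f"# Label Channels:\t{len(channels)}\n")
        for ch in channels:
            fh.write(f"# Nickase Recognition Site {codes[ch]}:\t{ch}\n")
        fh.write("#h " + "\t".join(_CMAP_COLUMNS) + "\n")
        fh.write("#f int\tfloat\tint\tint\tint\tfloat\tfloat\tfloat\tfloat\n")
        numeric_ids = {mid: i + 1 for i, mid in enumerate(by_id)}
        for mid, group in by_id.items():
            length = max(m.length for m in group)
            rows = [
                (float(pos), codes[m.channel])
                for m in group
                for pos in m.labels
            ]
            rows.sort()
            n = len(rows)
            for sid, (pos, code) in enumerate(rows, start=1):
                fh.write(
                    f"{numeric_ids[mid]}\t{length:.1f}\t{n}\t{sid}\t{code}\t"
                    f"{pos + 1:.1f}\t1.0\t1.0\t1.0\t# {mid}\n"
                )
            fh.write(
                f"{numeric_ids[mid]}\t{length:.1f}\t{n}\t{n + 1}\t0\t"
                f"{length:.1f}\t0.0\t1.0\t0.0\t# {mid}\n"
            )


def read_cmap(path: str) -> list[LabelMap]:
    """Read CMAP v0.1, splitting multi-channel records into per-channel maps.

    Raises :class:`FormatError` (with line number) on non-monotone positions
    or gaps in the SiteID sequence. The trailing LabelChannel-0 sentinel row
    closes each map and carries no label.
    """
    channel_names: dict[int, str] = {}
    records: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# Nickase Recognition Site"):
                    head, _, name = line.partition(":")
                    code = int(head.split()[-1])
                    channel_names[code] = name.strip()
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError("CMAP data line has fewer than 6 columns", lineno)
            cmap_id = fields[0]
            # original map id may ride in a trailing comment field
            name = cmap_id
            if fields[-1].startswith("# "):
                name = fields[-1][2:]
            length = float(fields[1])
            site_id = int(fields[3])
            channel = int(fields[4])
            pos = float(fields[5])
            rec = records.get(cmap_id)
            if rec is None:
                rec = {"name": name, "length": length, "last_sid": 0, "last_pos": -1.0,
                       "labels": {}}
                records[cmap_id] = rec
                order.append(cmap_id)
            if site_id != rec["last_sid"] + 1:
                raise FormatError(
                    f"SiteID {site_id} does not follow {rec['last_sid']}", lineno
                )
            rec["last_sid"] = site_id
            if channel == 0:
                continue  # map-end sentinel
            if pos <= rec["last_pos"]:
                raise FormatError(
                    f"position {pos} not greater than previous {rec['last_pos']}", lineno
                )
            rec["last_pos"] = pos
            rec["labels"].setdefault(channel, []).append(pos - 1.0)  # back to 0-based
    maps = []
    for cmap_id in order:
        rec = records[cmap_id]
        for code in sorted(rec["labels"]):
            maps.append(
                LabelMap(
                    rec["name"],
                    rec["length"],
                    channel_names.get(code, f"channel_{code}"),
                    np.array(rec["labels"][code], float),
                )
            )
    return maps


__all__ = [
    "Enzyme",
    "LabelMap",
    "find_recognition_sites",
    "condense_sites",
    "in_silico_digest",
    "read_cmap",
    "write_cmap",
]
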
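"""Conflict calling: merge breakpoints across enzyme channels, classify them
relative to Hi-C gaps, estimate implied gap sizes, and cut scaffolds.

A conflict is a scaffold coordinate where optical-map evidence contradicts
the scaffold layout. Breakpoints from independent enzyme channels that
cluster at the same coordinate corroborate each other; conflicts close to a
Hi-C-introduced gap are classified as putative scaffolding errors, while a
conflict explained entirely by a mis-sized gap (the map aligns cleanly
across the gap but implies a different physical distance) is classified as
a gap-size discrepancy rather than a structural error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .digest import LabelMap
from .errors import CoordinateError
from .layout import ContigPlacement, Gap, GapRecord, ScaffoldLayout
from .map_align import Breakpoint, MapAlignment


class ConflictClass(str, Enum):
    NEAR_GAP_STRUCTURAL = "NEAR_GAP_STRUCTURAL"
    GAP_SIZE_ONLY = "GAP_SIZE_ONLY"
    INTERNAL = "INTERNAL"


@dataclass
class Conflict:
    """A clustered, optionally classified map/assembly contradiction."""

    scaffold: str
    position: float
    channels: set[str] = field(default_factory=set)
    n_breakpoints: int = 0
    nearest_gap_distance: float = math.inf
    nearest_gap: GapRecord | None = None
    implied_gap: float | None = None
    classification: ConflictClass | None = None

    @property
    def dual_channel(self) -> bool:
        return len(self.channels) >= 2


def merge_channels(
    breakpoints: list[Breakpoint],
    merge_window: float = 50_000,
    min_channels: int = 1,
    min_breakpoints: int = 1,
) -> list[Conflict]:
    """Cluster breakpoints on each scaffold by single linkage.

    Breakpoints within ``merge_window`` of each other (transitively) form one
    cluster; each cluster becomes a Conflict at the median breakpoint
    position with the union of channels. Clusters observed in fewer than
    ``min_channels`` channels or with fewer than ``min_breakpoints``
    members are dropped. The dual-enzyme confirmation logic uses
    ``min_channels=2``; requiring two breakpoints per cluster reflects
    that a genuine incongruence terminates alignments on both sides of
    the junction, while chance terminations arrive alone.
    """
    by_scaffold: dict[str, list[Breakpoint]] = {}
    for b in breakpoints:
        by_scaffold.setdefault(b.ref_id, []).append(b)
    conflicts: list[Conflict] = []
    for scaffold in sorted(by_scaffold):
        bps = sorted(by_scaffold[scaffold], key=lambda b: b.position)
        cluster: list[Breakpoint] = []
        for b in bps + [None]:
            if cluster and (b is None or b.position - cluster[-1].position > merge_window):
                positions = [c.position for c in cluster]
                conf = Conflict(
                    scaffold=scaffold,
                    position=float(np.median(positions)),
                    channels={c.channel for c in cluster},
                    n_breakpoints=len(cluster),
                )
                if len(conf.channels) >= min_channels and conf.n_breakpoints >= min_breakpoints:
                    conflicts.append(conf)
                cluster = []
            if b is not None:
                cluster.append(b)
    return conflicts


def estimate_gap_size(
    alignment: MapAlignment,
    gap: GapRecord,
    query_map: LabelMap,
    ref_map: LabelMap,
    window: float = 60_000,
) -> float | None:
    """Physical gap size implied by an optical-map alignment spanning a gap.

    The optical (query) map measures true physical distances; the scaffold
    declares the gap's filler length. For matched labels on the left flank
    the query-minus-reference offset reflects everything upstream; on the
    right flank it additionally carries the difference between the physical
    gap and the declared one. The implied size is therefore the declared
    length plus the difference of the median offsets of the two flanks
    (medians, because an aligner absorbs a mis-sized gap as a staircase of
    slightly off-register matches right at the junction). Flank offsets are
    taken within ``window`` bp of the gap so that long-range sizing drift
    does not leak in. May be negative (physically overlapping contigs);
    None when a flank has no matched label within the window.
    """
    r = ref_map.labels
    q_oriented = (
        query_map.labels
        if alignment.orientation == "+"
        else query_map.length - query_map.labels[::-1]
    )
    left_offsets = []  # (distance from gap, offset)
    right_offsets = []
    for qi, ri in alignment.pairs:
        pos = r[ri]
        if gap.start - window <= pos <= gap.start:
            left_offsets.append((gap.start - pos, q_oriented[qi] - pos))
        elif gap.end <= pos <= gap.end + window:
            right_offsets.append((pos - gap.end, q_oriented[qi] - pos))
    if not left_offsets or not right_offsets:
        return None

    def outer_median(offsets):
        # the off-register staircase sits right at the gap; the outer half
        # of the flank window is cleanly registered
        offsets.sort(key=lambda t: -t[0])
        keep = offsets[: max(1, len(offsets) // 2)]
        return np.median([o for _, o in keep])

    return float(
        gap.declared_length + outer_median(right_offsets) - outer_median(left_offsets)
    )


def _lookup_map(maps: dict, map_id: str, channel: str) -> LabelMap:
    """Fetch a map keyed either by id or by (id, channel)."""
    if map_id in maps:
        return maps[map_id]
    return maps[(map_id, channel)]


def _spans_gap(alignment: MapAlignment, gap: GapRecord, ref_map: LabelMap) -> bool:
    r = ref_map.labels
    has_left = any(r[ri] <= gap.start for _, ri in alignment.pairs)
    has_right = any(r[ri] >= gap.end for _, ri in alignment.pairs)
    return has_left and has_right


def spans_position(
    alignment: MapAlignment,
    ref_map: LabelMap,
    position: float,
    window: float = 100_000,
    min_anchor_labels: int = 6,
) -> bool:
    """Does this alignment anchor matched labels on both sides of a
    position, each side within ``window``? A cleanly spanning alignment
    certifies local collinearity of map and scaffold."""
    r = ref_map.labels
    left = sum(
        1 for _, ri in alignment.pairs if position - window <= r[ri] <= position
    )
    right = sum(
        1 for _, ri in alignment.pairs if position <= r[ri] <= position + window
    )
    # near a map end the window truncates; ask for most of what exists
    avail_left = int(np.sum((r >= position - window) & (r <= position)))
    avail_right = int(np.sum((r >= position) & (r <= position + window)))
    need_left = min(min_anchor_labels, max(2, int(0.75 * avail_left)))
    need_right = min(min_anchor_labels, max(2, int(0.75 * avail_right)))
    return left >= need_left and right >= need_right


def filter_artifact_conflicts(
    conflicts: list[Conflict],
    alignments: list[MapAlignment],
    ref_maps: dict,
    veto_min_score: float = 30.0,
    window: float = 100_000,
    min_anchor_labels: int = 6,
    end_margin: float = 50_000,
) -> list[Conflict]:
    """Drop conflicts contradicted by a cleanly spanning alignment.

    Sizing noise occasionally severs one chain in one enzyme channel,
    leaving a stray termination; but the same locus is still spanned
    collinearly by the other channel's chain (or another query covering
    the region). A genuine misjoin is spanned by nothing — no single
    alignment can cross foreign material. Conflicts whose position is
    spanned by any sufficiently strong alignment are therefore alignment
    artifacts, not structural findings. This is the dual-enzyme
    cross-check applied as a veto.
    """
    aln_by_ref: dict[str, list[MapAlignment]] = {}
    for a in alignments:
        if a.score < veto_min_score:
            continue
        aln_by_ref.setdefault(a.ref_id, []).append(a)
    # map length per scaffold, for the terminal-fray exclusion
    lengths: dict[str, float] = {}
    for key, m in ref_maps.items():
        name = key[0] if isinstance(key, tuple) else key
        lengths[name] = max(lengths.get(name, 0.0), m.length)
    kept = []
    for c in conflicts:
        # alignments always fray at map termini; a conflict this close to
        # a scaffold end cannot be distinguished from end raggedness
        L = lengths.get(c.scaffold)
        if L is not None and (c.position < end_margin or c.position > L - end_margin):
            continue
        vetoed = any(
            spans_position(
                a,
                _lookup_map(ref_maps, a.ref_id, a.channel),
                c.position,
                window,
                min_anchor_labels,
            )
            for a in aln_by_ref.get(c.scaffold, [])
        )
        if not vetoed:
            kept.append(c)
    return kept


def default_gap_tol(declared_length: float, floor: float = 10_000) -> float:
    """Sizing tolerance for calling a gap mis-sized: max(floor, declared)."""
    return max(floor, declared_length)


def classify_conflicts(
    conflicts: list[Conflict],
    gaps: list[GapRecord],
    alignments: list[MapAlignment],
    query_maps: dict[str, LabelMap],
    ref_maps: dict[str, LabelMap],
    near_distance: float = 50_000,
    gap_tol: float | None = None,
) -> list[Conflict]:
    """Assign each conflict a class relative to Hi-C gaps.

    GAP_SIZE_ONLY: an alignment spans the nearest Hi-C gap with matched
    labels on both sides (the structure is corroborated) but the implied
    physical gap differs from the declared length by more than the
    tolerance. NEAR_GAP_STRUCTURAL: within ``near_distance`` of a Hi-C gap
    and not explained by sizing. INTERNAL: far from any Hi-C gap. The
    tolerance defaults to max(10 kb, declared length) per gap.
    """
    hic_gaps = [g for g in gaps if g.source == "HIC"]
    by_scaffold: dict[str, list[GapRecord]] = {}
    for g in hic_gaps:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    aln_by_ref: dict[str, list[MapAlignment]] = {}
    for a in alignments:
        aln_by_ref.setdefault(a.ref_id, []).append(a)

    for conf in conflicts:
        nearest = None
        nearest_d = math.inf
        for g in by_scaffold.get(conf.scaffold, []):
            d = max(g.start - conf.position, conf.position - g.end, 0.0)
            if d < nearest_d:
                nearest, nearest_d = g, d
        conf.nearest_gap = nearest
        conf.nearest_gap_distance = nearest_d
        implied = None
        if nearest is not None:
            tol = gap_tol if gap_tol is not None else default_gap_tol(nearest.declared_length)
            for a in aln_by_ref.get(conf.scaffold, []):
                rmap = _lookup_map(ref_maps, a.ref_id, a.channel)
                if not _spans_gap(a, nearest, rmap):
                    continue
                est = estimate_gap_size(
                    a, nearest, _lookup_map(query_maps, a.query_id, a.channel), rmap
                )
                if est is not None:
                    implied = est
                    break
            if implied is not None and abs(implied - nearest.declared_length) > tol:
                conf.implied_gap = implied
                conf.classification = ConflictClass.GAP_SIZE_ONLY
                continue
        conf.implied_gap = implied
        if nearest_d <= near_distance:
            conf.classification = ConflictClass.NEAR_GAP_STRUCTURAL
        else:
            conf.classification = ConflictClass.INTERNAL
    return conflicts


def gap_size_report(
    gaps: list[GapRecord],
    alignments: list[MapAlignment],
    query_maps: dict[str, LabelMap],
    ref_maps: dict[str, LabelMap],
) -> list[dict]:
    """Declared vs implied size for every gap any alignment spans."""
    aln_by_ref: dict[str, list[MapAlignment]] = {}
    for a in alignments:
        aln_by_ref.setdefault(a.ref_id, []).append(a)
    rows = []
    for g in gaps:
        estimates = []
        for a in aln_by_ref.get(g.scaffold, []):
            est = estimate_gap_size(
                a,
                g,
                _lookup_map(query_maps, a.query_id, a.channel),
                _lookup_map(ref_maps, a.ref_id, a.channel),
            )
            if est is not None:
                estimates.append(est)
        rows.append(
            {
                "scaffold": g.scaffold,
                "gap_index": g.index,
                "start": g.start,
                "end": g.end,
                "declared": g.declared_length,
                "implied": float(np.mean(estimates)) if estimates else None,
                "n_estimates": len(estimates),
            }
        )
    return rows


# -- scaffold cutting ---------------------------------------------------


def cut_at_conflicts(
    layout: ScaffoldLayout,
    conflicts: list[Conflict],
    classes_to_cut: set[ConflictClass] = frozenset({ConflictClass.NEAR_GAP_STRUCTURAL}),
    near_distance: float = 50_000,
) -> ScaffoldLayout:
    """Split scaffolds at confirmed conflicts, returning a new layout.

    A conflict within ``near_distance`` of a gap removes that gap and
    splits the scaffold there (the gap filler is dropped). An INTERNAL
    conflict splits the containing contig placement at the conflict
    coordinate into two components. Total contig bases are conserved;
    output scaffolds are renumbered ``<name>.1``, ``<name>.2``, ...
    """
    cuts_by_scaffold: dict[str, list[Conflict]] = {}
    for c in conflicts:
        if c.classification in classes_to_cut:
            cuts_by_scaffold.setdefault(c.scaffold, []).append(c)

    out = ScaffoldLayout(unplaced=dict(layout.unplaced))
    for name, comps in layout.scaffolds.items():
        cuts = cuts_by_scaffold.get(name)
        if not cuts:
            out.scaffolds[name] = list(comps)
            continue
        length = sum(c.span for c in comps)
        # component start offsets
        starts = []
        pos = 0
        for comp in comps:
            starts.append(pos)
            pos += comp.span
        # resolve each conflict to a cut instruction
        gap_cuts: set[int] = set()  # component indices of gaps to remove
        contig_cuts: dict[int, list[int]] = {}  # comp index -> offsets within
        for c in sorted(cuts, key=lambda c: c.position):
            if not 0 <= c.position <= length:
                raise CoordinateError(
                    f"conflict at {c.position} outside scaffold {name} (length {length})"
                )
            # nearest gap on this scaffold, any source (the junction being cut)
            best_idx, best_d = None, math.inf
            for idx, comp in enumerate(comps):
                if isinstance(comp, Gap):
                    d = max(starts[idx] - c.position, c.position - (starts[idx] + comp.span), 0.0)
                    if d < best_d:
                        best_idx, best_d = idx, d
            if best_idx is not None and best_d <= near_distance:
                gap_cuts.add(best_idx)
            else:
                # split inside the containing contig placement
                for idx, comp in enumerate(comps):
                    if isinstance(comp, ContigPlacement) and (
                        starts[idx] < c.position < starts[idx] + comp.span
                    ):
                        contig_cuts.setdefault(idx, []).append(int(c.position - starts[idx]))
                        break
        # sweep components, starting a new scaffold after each cut
        pieces: list[list[ContigPlacement | Gap]] = [[]]
        for idx, comp in enumerate(comps):
            if idx in gap_cuts:
                pieces.append([])
                continue
            if idx in contig_cuts:
                p: ContigPlacement = comp
                offsets = sorted(set(contig_cuts[idx]))
                bounds = [0] + offsets + [p.span]
                sub = []
                for lo, hi in zip(bounds[:-1], bounds[1:]):
                    if p.orientation == "+":
                        sub.append(
                            ContigPlacement(p.contig_id, p.contig_beg + lo, p.contig_beg + hi, "+")
                        )
                    else:
                        sub.append(
                            ContigPlacement(p.contig_id, p.contig_end - hi, p.contig_end - lo, "-")
                        )
                pieces[-1].append(sub[0])
                for s in sub[1:]:
                    pieces.append([s])
                continue
            pieces[-1].append(comp)
        # strip leading/trailing gaps, drop empties, renumber
        final = []
        for piece in pieces:
            while piece and isinstance(piece[0], Gap):
                piece.pop(0)
            while piece and isinstance(piece[-1], Gap):
                piece.pop()
            if piece:
                final.append(piece)
        if len(final) == 1:
            out.scaffolds[name] = final[0]
        else:
            for i, piece in enumerate(final, start=1):
                out.scaffolds[f"{name}.{i}"] = piece
    return out


# -- TSV I/O ------------------------------------------------------------


def write_conflicts_tsv(conflicts: list[Conflict], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "scaffold\tposition\tchannels\tn_breakpoints\tnearest_gap_distance\t"
            "implied_gap\tclassification\n"
        )
        for c in conflicts:
            d = "inf" if math.isinf(c.nearest_gap_distance) else f"{c.nearest_gap_distance:.0f}"
            ig = "" if c.implied_gap is None else f"{c.implied_gap:.1f}"
            cls = "" if c.classification is None else c.classification.value
            fh.write(
                f"{c.scaffold}\t{c.position:.1f}\t{','.join(sorted(c.channels))}\t"
                f"{c.n_breakpoints}\t{d}\t{ig}\t{cls}\n"
            )


__all__ = [
    "Conflict",
    "ConflictClass",
    "classify_conflicts",
    "cut_at_conflicts",
    "default_gap_tol",
    "estimate_gap_size",
    "gap_size_report",
    "merge_channels",
    "filter_artifact_conflicts",
    "spans_position",
    "write_conflicts_tsv",
]
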
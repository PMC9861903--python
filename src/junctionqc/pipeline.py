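"""End-to-end validation: digest scaffolds, align optical maps, call and
classify conflicts, cut, and report before/after statistics.

The driver wires the modules together the way the analysis is meant to be
run: in-silico digests of the observed (Hi-C-style) scaffolds are the
alignment references; optical consensus maps — simulated from the true
chromosomes, or read from CMAP — are the queries; alignment terminations
become breakpoints, breakpoints merge into conflicts across enzyme
channels, conflicts are classified against the Hi-C gaps, confirmed
structural conflicts cut the layout, and junctions are independently
assessed by long-read spanning support.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import assembly_stats, conflict, digest, map_align, read_support, synthetic_data
from .layout import ScaffoldLayout, build_scaffold_sequence


@dataclass
class ValidationResult:
    ref_maps: dict  # (scaffold, channel) keyed LabelMaps of the scaffold digests
    query_maps: dict  # (chromosome, channel) keyed optical maps
    alignments: list
    breakpoints: list
    conflicts: list
    cut_layout: ScaffoldLayout
    stats_before: assembly_stats.AssemblyStats
    stats_after: assembly_stats.AssemblyStats
    assessments: list = field(default_factory=list)
    support_summary: object = None


def digest_layout(
    layout: ScaffoldLayout,
    contigs: dict[str, str],
    enzymes: list[digest.Enzyme],
    min_label_distance: int = 1000,
) -> dict:
    """In-silico digest of every scaffold, keyed (scaffold, enzyme name)."""
    seqs = {
        name: build_scaffold_sequence(comps, contigs)
        for name, comps in layout.scaffolds.items()
    }
    maps = digest.in_silico_digest(seqs, enzymes, min_label_distance)
    return {(m.map_id, m.channel): m for m in maps}


def run_validation(
    dataset: synthetic_data.SimulatedDataset,
    align_params: map_align.AlignParams | None = None,
    *,
    min_label_distance: int = 1000,
    merge_window: float = 50_000,
    near_distance: float = 50_000,
    min_channels: int = 1,
    min_breakpoints: int = 1,
    strong_min: int = 5,
    min_anchor: int = 1000,
    min_mapq: int = 20,
    rng: np.random.Generator | None = None,
) -> ValidationResult:
    """Run the full validation on a simulated dataset."""
    cfg = dataset.config
    params = align_params or map_align.AlignParams()
    gt = dataset.ground_truth
    enzymes = cfg.enzyme_objects()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)

    ref_maps = digest_layout(gt.observed_layout, dataset.contigs, enzymes,
                             min_label_distance)

    # optical consensus maps of the true chromosomes, one per enzyme channel
    query_maps = {}
    for chrom, seq in dataset.genome.items():
        for enz in enzymes:
            query_maps[(chrom, enz.name)] = synthetic_data.simulate_label_map(
                seq, enz, cfg, rng, map_id=chrom, min_label_distance=min_label_distance
            )

    alignments = []
    for (chrom, channel), qmap in query_maps.items():
        for (scaffold, ref_channel), rmap in ref_maps.items():
            if channel != ref_channel:
                continue
            alignments.extend(map_align.align_maps(qmap, rmap, params))

    ref_by_id = {}
    for (scaffold, channel), m in ref_maps.items():
        ref_by_id.setdefault(channel, {})[scaffold] = m
    breakpoints = []
    for channel, refs in ref_by_id.items():
        channel_alns = [a for a in alignments if a.channel == channel]
        channel_queries = {
            chrom: m for (chrom, ch), m in query_maps.items() if ch == channel
        }
        breakpoints.extend(
            map_align.detect_breakpoints(channel_alns, channel_queries, refs, params)
        )

    conflicts = conflict.merge_channels(
        breakpoints, merge_window, min_channels, min_breakpoints
    )
    # artifact veto: a conflict spanned collinearly by any strong alignment
    # (typically the other enzyme channel's chain) is not structural
    conflicts = conflict.filter_artifact_conflicts(conflicts, alignments, ref_maps)
    gaps = gt.observed_layout.gap_records()
    conflicts = conflict.classify_conflicts(
        conflicts, gaps, alignments, query_maps, ref_maps, near_distance
    )

    cut = conflict.cut_at_conflicts(
        gt.observed_layout, conflicts,
        {conflict.ConflictClass.NEAR_GAP_STRUCTURAL, conflict.ConflictClass.INTERNAL},
        near_distance,
    )
    stats_before = assembly_stats.summarize(gt.observed_layout)
    stats_after = assembly_stats.summarize(cut)

    assessments = read_support.assess_junctions(
        dataset.reads, gaps, min_anchor, min_mapq, strong_min
    )
    summary = read_support.summarize_support(assessments) if assessments else None

    return ValidationResult(
        ref_maps=ref_maps,
        query_maps=query_maps,
        alignments=alignments,
        breakpoints=breakpoints,
        conflicts=conflicts,
        cut_layout=cut,
        stats_before=stats_before,
        stats_after=stats_after,
        assessments=assessments,
        support_summary=summary,
    )


def score_against_truth(
    result: ValidationResult,
    dataset: synthetic_data.SimulatedDataset,
    tolerance: float = 50_000,
) -> dict:
    """Recall/precision of conflict calling and junction support vs truth.

    A misjoin is detected when a NEAR_GAP_STRUCTURAL conflict lies within
    ``tolerance`` of its recorded junction. A conflict is false when it is
    farther than ``tolerance`` from every misjoined junction.
    """
    gt = dataset.ground_truth
    truth = synthetic_data.junction_truth(gt)
    gaps = gt.observed_layout.gap_records()
    misjoined_positions = {
        (g.scaffold, g.start): truth[f"{g.scaffold}:gap{g.index}"] is False
        for g in gaps
    }
    structural = [
        c for c in result.conflicts
        if c.classification == conflict.ConflictClass.NEAR_GAP_STRUCTURAL
    ]
    detected = 0
    for rec in gt.misjoin_records:
        sites = synthetic_data.affected_junctions(gt, rec) or [
            (rec.scaffold, rec.position)
        ]
        hit = any(
            c.scaffold == sc and abs(c.position - pos) <= tolerance
            for c in structural
            for sc, pos in sites
        )
        detected += hit
    bad_positions = [
        (sc, pos) for (sc, pos), mis in misjoined_positions.items() if mis
    ]
    good_positions = [
        (sc, pos) for (sc, pos), mis in misjoined_positions.items() if not mis
    ]
    false_conflicts = 0
    at_correct_junction = 0
    for c in result.conflicts:
        near_bad = any(
            c.scaffold == sc and abs(c.position - pos) <= tolerance
            for sc, pos in bad_positions
        )
        if near_bad:
            continue
        false_conflicts += 1
        if any(
            c.scaffold == sc and abs(c.position - pos) <= tolerance
            for sc, pos in good_positions
        ):
            at_correct_junction += 1

    support = {a.junction_id: a for a in result.assessments}
    correct_total = correct_supported = 0
    misjoined_total = misjoined_unsupported = 0
    for jid, ok in truth.items():
        a = support.get(jid)
        if a is None:
            continue
        if ok:
            correct_total += 1
            correct_supported += a.support_class is read_support.SupportClass.SUPPORTED
        else:
            misjoined_total += 1
            misjoined_unsupported += (
                a.support_class is read_support.SupportClass.UNSUPPORTED
            )
    return {
        "n_misjoins": len(gt.misjoin_records),
        "misjoins_detected": detected,
        "false_conflicts": false_conflicts,
        "conflicts_at_correct_junctions": at_correct_junction,
        "n_conflicts": len(result.conflicts),
        "correct_junctions": correct_total,
        "correct_supported": correct_supported,
        "misjoined_junctions": misjoined_total,
        "misjoined_unsupported": misjoined_unsupported,
        "n50_before": result.stats_before.scaffold_n50,
        "n50_after": result.stats_after.scaffold_n50,
    }


__all__ = ["ValidationResult", "digest_layout", "run_validation", "score_against_truth"]
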
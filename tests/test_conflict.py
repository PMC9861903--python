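"""Conflict merging, classification, gap-size estimation and cutting."""

import numpy as np
import pytest

from junctionqc.conflict import (
    Conflict,
    ConflictClass,
    classify_conflicts,
    cut_at_conflicts,
    default_gap_tol,
    estimate_gap_size,
    merge_channels,
)
from junctionqc.digest import Enzyme, in_silico_digest
from junctionqc.errors import CoordinateError
from junctionqc.layout import ContigPlacement, Gap, GapRecord, ScaffoldLayout
from junctionqc.map_align import AlignParams, Breakpoint, align_maps
from junctionqc import assembly_stats


def bp(scaffold, pos, channel="BSPQI", query="q", side="right", score=50.0):
    return Breakpoint(scaffold, float(pos), channel, query, side, score)


def brute_single_linkage(positions, window):
    """Reference clustering: union-find over all pairs within the window."""
    n = len(positions)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= window:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


class TestMergeChannels:
    def test_nearby_breakpoints_merge_across_channels(self):
        conflicts = merge_channels(
            [bp("s", 100_000, "BSPQI"), bp("s", 110_000, "BSSSI")], 50_000
        )
        assert len(conflicts) == 1
        assert conflicts[0].channels == {"BSPQI", "BSSSI"}
        assert conflicts[0].dual_channel

    def test_distant_breakpoints_stay_separate(self):
        conflicts = merge_channels([bp("s", 100_000), bp("s", 500_000)], 50_000)
        assert len(conflicts) == 2

    def test_min_channels_filters_single_channel_clusters(self):
        conflicts = merge_channels(
            [bp("s", 100_000, "BSPQI"), bp("s", 110_000, "BSPQI")],
            50_000,
            min_channels=2,
        )
        assert conflicts == []

    @pytest.mark.parametrize("seed", range(10))
    def test_cluster_count_matches_brute_force_single_linkage(self, seed):
        rng = np.random.default_rng(seed)
        positions = rng.uniform(0, 2_000_000, rng.integers(2, 40))
        window = 50_000
        conflicts = merge_channels([bp("s", x) for x in positions], window)
        assert len(conflicts) == brute_single_linkage(list(positions), window)


@pytest.fixture()
def gap_fixture():
    """Two 400 kb contigs joined by a 100 bp filler; the true physical gap
    is 20 kb. Noise-free maps on both sides; the long flanks let one
    chain absorb the mis-sized junction instead of resetting there."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    left = "".join(bases[rng.integers(0, 4, 400_000)])
    right = "".join(bases[rng.integers(0, 4, 400_000)])
    gap_seq = "".join(bases[rng.integers(0, 4, 20_000)])
    chromosome = left + gap_seq + right
    scaffold_seq = left + "N" * 100 + right
    enz = Enzyme("BSSSI", "CACGAG")
    (qmap,) = in_silico_digest({"chrom": chromosome}, [enz], 1000)
    (rmap,) = in_silico_digest({"scaf": scaffold_seq}, [enz], 1000)
    gap = GapRecord("scaf", 0, 400_000, 400_100, "HIC")
    # gap sizing uses a sizing-tolerant alignment pass: a grossly mis-sized
    # gap must not sever the chain before its size can be measured
    alns = align_maps(qmap, rmap, AlignParams(xdrop=250.0))
    return qmap, rmap, gap, alns


class TestEstimateGapSize:
    def test_zero_noise_recovers_true_gap_exactly(self, gap_fixture):
        qmap, rmap, gap, alns = gap_fixture
        spanning = [a for a in alns if estimate_gap_size(a, gap, qmap, rmap) is not None]
        assert spanning
        assert estimate_gap_size(spanning[0], gap, qmap, rmap) == pytest.approx(
            20_000, abs=1e-6
        )

    def test_declared_equal_true_returns_declared(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        left = "".join(bases[rng.integers(0, 4, 120_000)])
        right = "".join(bases[rng.integers(0, 4, 120_000)])
        gap_seq = "N" * 5000  # declared == true: same sequence both sides
        seq = left + gap_seq + right
        enz = Enzyme("BSSSI", "CACGAG")
        (qmap,) = in_silico_digest({"m": seq}, [enz], 1000)
        rmap = qmap
        gap = GapRecord("m", 0, 120_000, 125_000, "HIC")
        alns = align_maps(qmap, rmap, AlignParams(xdrop=250.0))
        est = estimate_gap_size(alns[0], gap, qmap, rmap)
        assert est == pytest.approx(5000, abs=1e-6)

    def test_absent_when_one_side_unmatched(self, gap_fixture):
        qmap, rmap, gap, alns = gap_fixture
        a = alns[0]
        off_gap = GapRecord("scaf", 1, 810_000, 810_100, "HIC")
        assert estimate_gap_size(a, off_gap, qmap, rmap) is None


class TestClassifyConflicts:
    def test_near_gap_without_spanning_alignment_is_structural(self):
        gaps = [GapRecord("s", 0, 100_000, 100_100, "HIC")]
        conflicts = [Conflict("s", 90_000.0)]
        classify_conflicts(conflicts, gaps, [], {}, {}, near_distance=50_000)
        assert conflicts[0].classification is ConflictClass.NEAR_GAP_STRUCTURAL
        assert conflicts[0].nearest_gap_distance == pytest.approx(10_000)

    def test_far_from_any_gap_is_internal(self):
        gaps = [GapRecord("s", 0, 1_000_000, 1_000_100, "HIC")]
        conflicts = [Conflict("s", 700_000.0)]
        classify_conflicts(conflicts, gaps, [], {}, {}, near_distance=50_000)
        assert conflicts[0].classification is ConflictClass.INTERNAL

    def test_spanned_but_missized_gap_is_gap_size_only(self, gap_fixture):
        qmap, rmap, gap, alns = gap_fixture
        conflicts = [Conflict("scaf", 390_000.0)]
        classify_conflicts(
            conflicts,
            [gap],
            alns,
            {"chrom": qmap},
            {"scaf": rmap},
            near_distance=50_000,
            gap_tol=10_000,
        )
        assert conflicts[0].classification is ConflictClass.GAP_SIZE_ONLY
        assert conflicts[0].implied_gap == pytest.approx(20_000, abs=1e-6)

    def test_default_gap_tol(self):
        assert default_gap_tol(100) == 10_000
        assert default_gap_tol(25_000) == 25_000


def two_contig_layout():
    layout = ScaffoldLayout()
    layout.scaffolds["s1"] = [
        ContigPlacement("c1", 0, 600_000, "+"),
        Gap(100, "HIC"),
        ContigPlacement("c2", 0, 400_000, "+"),
    ]
    return layout


class TestCutAtConflicts:
    def test_no_conflicts_is_identity(self):
        layout = two_contig_layout()
        assert cut_at_conflicts(layout, []) == layout

    def test_near_gap_cut_splits_and_conserves_bases(self):
        layout = two_contig_layout()
        c = Conflict("s1", 590_000.0, classification=ConflictClass.NEAR_GAP_STRUCTURAL)
        cut = cut_at_conflicts(layout, [c])
        assert len(cut.scaffolds) == 2
        assert all(
            len([x for x in comps if isinstance(x, ContigPlacement)]) == 1
            for comps in cut.scaffolds.values()
        )
        assert cut.total_contig_bases() == layout.total_contig_bases()

    def test_internal_cut_splits_the_contig(self):
        layout = two_contig_layout()
        c = Conflict("s1", 300_000.0, classification=ConflictClass.INTERNAL)
        cut = cut_at_conflicts(
            layout, [c], {ConflictClass.INTERNAL}, near_distance=50_000
        )
        assert cut.total_contig_bases() == layout.total_contig_bases()
        placements = [p for _, _, p in cut.placements()]
        assert {(p.contig_id, p.contig_beg, p.contig_end) for p in placements} == {
            ("c1", 0, 300_000),
            ("c1", 300_000, 600_000),
            ("c2", 0, 400_000),
        }

    def test_conflict_outside_scaffold_raises(self):
        layout = two_contig_layout()
        c = Conflict("s1", 9e9, classification=ConflictClass.NEAR_GAP_STRUCTURAL)
        with pytest.raises(CoordinateError):
            cut_at_conflicts(layout, [c])

    @pytest.mark.parametrize("seed", range(5))
    def test_cutting_never_increases_n50(self, seed):
        rng = np.random.default_rng(seed)
        layout = ScaffoldLayout()
        pos = 0
        comps = []
        for i in range(8):
            ln = int(rng.integers(100_000, 500_000))
            if comps:
                comps.append(Gap(100, "HIC"))
            comps.append(ContigPlacement(f"c{i}", 0, ln, "+"))
        layout.scaffolds["s"] = comps
        length = layout.scaffold_length("s")
        conflicts = [
            Conflict(
                "s",
                float(rng.uniform(0, length)),
                classification=ConflictClass.NEAR_GAP_STRUCTURAL,
            )
            for _ in range(int(rng.integers(1, 4)))
        ]
        cut = cut_at_conflicts(layout, conflicts)
        before = assembly_stats.summarize(layout)
        after = assembly_stats.summarize(cut)
        assert after.scaffold_n50 <= before.scaffold_n50
        assert after.n_scaffolds >= before.n_scaffolds
        assert cut.total_contig_bases() == layout.total_contig_bases()
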
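"""Ground-truthed simulation: determinism, misjoin edits, noise models."""

import numpy as np
import pytest
from dataclasses import replace

import junctionqc.synthetic_data as sd
from junctionqc.digest import Enzyme, find_recognition_sites, condense_sites
from junctionqc.errors import ConfigurationError
from junctionqc.layout import ContigPlacement, Gap


SMALL = sd.SimulationConfig(
    seed=3,
    genome_length=1_200_000,
    n_chromosomes=2,
    n_contigs=12,
    min_contig_length=40_000,
    misjoins=(),
)


class TestConfigValidation:
    def test_default_config_is_valid(self):
        sd.SimulationConfig().validate()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"genome_length": 100_000},  # shorter than contigs demand
            {"hic_gap_fill": 0},
            {"label_miss_rate": 1.5},
            {"sizing_sd_coeff": -1},
            {"misjoins": ((sd.MisjoinType.INVERSION, 40),)},  # >= junctions
        ],
    )
    def test_invariant_violations_named(self, kwargs):
        with pytest.raises(ConfigurationError, match="invariant"):
            sd.SimulationConfig(**kwargs).validate()


class TestGenerateGenome:
    def test_seed_determinism_byte_identical(self, tmp_path):
        a = sd.generate_genome(SMALL)
        b = sd.generate_genome(SMALL)
        pa, pb = tmp_path / "a.fa", tmp_path / "b.fa"
        sd.write_fasta(a, str(pa))
        sd.write_fasta(b, str(pb))
        assert pa.read_bytes() == pb.read_bytes()

    def test_record_count_and_total_length(self):
        cfg = replace(SMALL, genome_length=5_000_000, n_contigs=40)
        genome = sd.generate_genome(cfg)
        assert len(genome) == 2
        total = sum(len(s) for s in genome.values())
        assert 4_950_000 <= total <= 5_050_000

    def test_base_composition_uniform(self):
        cfg = sd.SimulationConfig(
            seed=1, genome_length=1_000_000, n_chromosomes=1, n_contigs=8,
            misjoins=(),
        )
        seq = sd.generate_genome(cfg)["chr1"]
        for base in "ACGT":
            assert abs(seq.count(base) / len(seq) - 0.25) < 0.01


class TestFragmentAndScaffold:
    def test_no_misjoins_layouts_agree_up_to_gap_lengths(self):
        genome = sd.generate_genome(SMALL)
        _, gt = sd.fragment_and_scaffold(genome, SMALL)
        for chrom, comps in gt.true_layout.scaffolds.items():
            obs = gt.observed_layout.scaffolds[chrom.replace("chr", "scaffold_")]
            assert [c.contig_id for c in comps if isinstance(c, ContigPlacement)] == [
                c.contig_id for c in obs if isinstance(c, ContigPlacement)
            ]
            assert all(
                g.length == SMALL.hic_gap_fill and g.source == "HIC"
                for g in obs
                if isinstance(g, Gap)
            )
        assert all(sd.junction_truth(gt).values())

    def test_contigs_reassemble_chromosomes_with_gaps_removed(self):
        genome = sd.generate_genome(SMALL)
        contigs, gt = sd.fragment_and_scaffold(genome, SMALL)
        for chrom, comps in gt.true_layout.scaffolds.items():
            seq = genome[chrom]
            pos = 0
            for c in comps:
                if isinstance(c, ContigPlacement):
                    assert contigs[c.contig_id] == seq[pos : pos + c.span]
                pos += c.span
            assert pos == len(seq)

    def test_single_inversion_flips_exactly_one_placement(self):
        cfg = replace(SMALL, misjoins=((sd.MisjoinType.INVERSION, 1),))
        genome = sd.generate_genome(cfg)
        _, gt = sd.fragment_and_scaffold(genome, cfg)
        orientations = [
            p.orientation for _, _, p in gt.observed_layout.placements()
        ]
        assert orientations.count("-") == 1
        assert len(gt.misjoin_records) == 1
        assert gt.misjoin_records[0].type is sd.MisjoinType.INVERSION

    def test_requested_edit_mix_yields_distinct_records(self):
        cfg = sd.SimulationConfig(seed=11)  # 40 contigs, 4+2+2 misjoins
        genome = sd.generate_genome(cfg)
        _, gt = sd.fragment_and_scaffold(genome, cfg)
        assert len(gt.misjoin_records) == 8
        junctions = {(r.scaffold, r.junction_index) for r in gt.misjoin_records}
        assert len(junctions) == 8

    def test_misjoin_coordinates_sit_at_gap_boundaries(self):
        cfg = sd.SimulationConfig(seed=5)
        genome = sd.generate_genome(cfg)
        _, gt = sd.fragment_and_scaffold(genome, cfg)
        gap_starts = {
            (g.scaffold, g.start) for g in gt.observed_layout.gap_records()
        }
        for r in gt.misjoin_records:
            assert (r.scaffold, r.position) in gap_starts

    def test_contig_multiset_and_bases_conserved(self):
        cfg = sd.SimulationConfig(seed=9)
        genome = sd.generate_genome(cfg)
        _, gt = sd.fragment_and_scaffold(genome, cfg)
        true_ids = sorted(
            p.contig_id for _, _, p in gt.true_layout.placements()
        )
        obs_ids = sorted(
            p.contig_id for _, _, p in gt.observed_layout.placements()
        )
        assert true_ids == obs_ids
        assert (
            gt.true_layout.total_contig_bases()
            == gt.observed_layout.total_contig_bases()
        )


class TestSimulateLabelMap:
    ENZ = Enzyme("BSSSI", "CACGAG")

    def _seq(self, n=300_000, seed=0):
        rng = np.random.default_rng(seed)
        return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])

    def test_zero_noise_equals_in_silico_digest(self):
        seq = self._seq()
        cfg = replace(SMALL, sizing_sd_coeff=0.0, label_miss_rate=0.0,
                      false_label_rate=0.0)
        m = sd.simulate_label_map(seq, self.ENZ, cfg, min_label_distance=1000)
        truth = condense_sites(find_recognition_sites(seq, "CACGAG"), 1000)
        np.testing.assert_array_equal(m.labels, np.array(truth, float))

    def test_total_dropout_gives_empty_map(self):
        cfg = replace(SMALL, label_miss_rate=1.0, false_label_rate=0.0)
        m = sd.simulate_label_map(self._seq(), self.ENZ, cfg)
        assert m.n_labels == 0

    def test_positions_strictly_increasing_under_noise(self):
        cfg = replace(SMALL, sizing_sd_coeff=900.0, false_label_rate=2.0)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            m = sd.simulate_label_map(self._seq(), self.ENZ, cfg, rng)
            assert np.all(np.diff(m.labels) > 0)

    def test_label_retention_is_binomial(self):
        """Mean retained-label fraction over many seeds concentrates at
        1 - miss_rate (within 3 binomial standard errors)."""
        seq = self._seq(150_000, seed=2)
        truth = len(condense_sites(find_recognition_sites(seq, "CACGAG"), 1000))
        cfg = replace(SMALL, sizing_sd_coeff=0.0, label_miss_rate=0.1,
                      false_label_rate=0.0)
        kept = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            kept += sd.simulate_label_map(
                seq, self.ENZ, cfg, rng, min_label_distance=1000
            ).n_labels
        frac = kept / (truth * n_seeds)
        se = np.sqrt(0.1 * 0.9 / (truth * n_seeds))
        assert abs(frac - 0.9) < max(3 * se, 0.02)


class TestSimulateReadAlignments:
    def test_read_inside_one_contig_gives_single_record(self):
        cfg = replace(SMALL, read_coverage=2.0)
        ds = sd.simulate_dataset(cfg)
        # every record of a read entirely within one placement is alone
        by_read = {}
        for r in ds.reads:
            by_read.setdefault(r.read_id, []).append(r)
        placements = ds.ground_truth.observed_layout.placements()
        singles = 0
        for recs in by_read.values():
            if len(recs) == 1:
                r = recs[0]
                inside = any(
                    name == r.target and start <= r.target_start and
                    r.target_end <= start + p.span
                    for name, start, p in placements
                )
                singles += inside
        assert singles > 0

    def test_no_single_record_spans_a_misjoined_junction(self):
        cfg = sd.SimulationConfig(seed=21)
        ds = sd.simulate_dataset(cfg)
        truth = sd.junction_truth(ds.ground_truth)
        gaps = ds.ground_truth.observed_layout.gap_records()
        anchor = cfg.min_anchor_read
        for g in gaps:
            if truth[f"{g.scaffold}:gap{g.index}"]:
                continue
            spanning = [
                r
                for r in ds.reads
                if r.target == g.scaffold
                and r.target_start <= g.start - anchor
                and r.target_end >= g.end + anchor
            ]
            assert spanning == []

    def test_correct_junction_receives_ample_spanning_reads(self):
        cfg = replace(SMALL, read_coverage=30.0, read_length_median=15_000)
        ds = sd.simulate_dataset(cfg)
        gaps = ds.ground_truth.observed_layout.gap_records()
        counts = []
        for g in gaps:
            n = sum(
                1
                for r in ds.reads
                if r.target == g.scaffold
                and r.target_start <= g.start - 1000
                and r.target_end >= g.end + 1000
            )
            counts.append(n)
        assert min(counts) >= 5

    def test_nonpositive_coverage_rejected(self):
        cfg = replace(SMALL, read_coverage=0.0)
        genome = sd.generate_genome(cfg)
        _, gt = sd.fragment_and_scaffold(genome, cfg)
        with pytest.raises(ConfigurationError):
            sd.simulate_read_alignments(gt, cfg)

    def test_paf_output_deterministic(self, tmp_path):
        from junctionqc.read_support import write_paf

        cfg = replace(SMALL, read_coverage=1.0)
        a = sd.simulate_dataset(cfg).reads
        b = sd.simulate_dataset(cfg).reads
        pa, pb = tmp_path / "a.paf", tmp_path / "b.paf"
        write_paf(a, str(pa))
        write_paf(b, str(pb))
        assert pa.read_bytes() == pb.read_bytes()
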
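"""Ground-truthed simulation of a Hi-C-scaffolded assembly and its evidence.

The generator emulates the statistical structure the validation pipeline
assumes: a genome is fragmented into contigs; a Hi-C-style scaffolder joins
the contigs of each chromosome with a fixed-length N filler (the true gap
sizes are unknown to it) and is made to commit a configurable number of
misjoins (translocation, inversion, chimeric fusion); optical consensus
maps are simulated from the *true* chromosomes with interval-sizing noise,
label dropout and false labels; and long-read alignments are drawn from the
true genome, splitting wherever a read's true locus is discontiguous in the
observed layout. Every edit is recorded, so recall and precision of the
downstream conflict calling can be scored exactly.
"""

from __future__ import annotations

import json
import math
from bisect import bisect_right
from dataclasses import dataclass, field, asdict
from enum import Enum

import numpy as np

from .digest import Enzyme, LabelMap, condense_sites, find_recognition_sites
from .errors import ConfigurationError
from .layout import ContigPlacement, Gap, ScaffoldLayout
from .read_support import ReadAlignmentRecord


class MisjoinType(str, Enum):
    TRANSLOCATION = "TRANSLOCATION"  # two non-adjacent placements swapped
    INVERSION = "INVERSION"  # one placement's orientation flipped
    FUSION = "FUSION"  # contig runs exchanged between two scaffolds


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the simulated study, with realistic defaults.

    Defaults describe a desk-scale experiment: a 5 Mb diploid-free genome in
    2 chromosomes, 40 contigs scaffolded Hi-C-style with a 100 bp fixed
    filler, 8 injected misjoins, two nicking enzymes (Nt.BspQI GCTCTTC and
    Nb.BssSI CACGAG), sqrt-length optical sizing noise of 400 bp/sqrt(kb),
    10% label dropout, 0.5 false labels per 100 kb, and 30x long reads with
    a 15 kb median length.
    """

    seed: int = 0
    genome_length: int = 5_000_000
    n_chromosomes: int = 2
    n_contigs: int = 40
    min_contig_length: int = 50_000
    misjoins: tuple = (
        (MisjoinType.TRANSLOCATION, 4),
        (MisjoinType.INVERSION, 2),
        (MisjoinType.FUSION, 2),
    )
    hic_gap_fill: int = 100
    true_gap_mean: float = 600.0
    true_gap_sd: float = 200.0
    enzymes: tuple = (("BSPQI", "GCTCTTC", 1), ("BSSSI", "CACGAG", 1))
    sizing_sd_coeff: float = 400.0  # bp per sqrt(kb)
    label_miss_rate: float = 0.10
    false_label_rate: float = 0.5  # expected false labels per 100 kb
    read_length_median: int = 15_000
    read_length_sigma: float = 0.55  # lognormal shape
    read_coverage: float = 30.0
    min_anchor_read: int = 1000

    def enzyme_objects(self) -> list[Enzyme]:
        return [Enzyme(name, motif, offset) for name, motif, offset in self.enzymes]

    def total_misjoins(self) -> int:
        return sum(count for _, count in self.misjoins)

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.n_contigs < self.n_chromosomes:
            raise ConfigurationError(
                "violated invariant: n_contigs >= n_chromosomes >= 1"
            )
        if self.genome_length < self.n_contigs * self.min_contig_length:
            raise ConfigurationError(
                "violated invariant: genome_length >= n_contigs * min_contig_length"
            )
        if self.hic_gap_fill <= 0:
            raise ConfigurationError("violated invariant: hic_gap_fill > 0")
        if not 0 <= self.label_miss_rate <= 1:
            raise ConfigurationError("violated invariant: label_miss_rate in [0, 1]")
        if self.false_label_rate < 0 or self.sizing_sd_coeff < 0:
            raise ConfigurationError(
                "violated invariant: false_label_rate >= 0 and sizing_sd_coeff >= 0"
            )
        if self.total_misjoins() >= self.n_contigs - self.n_chromosomes:
            raise ConfigurationError(
                "violated invariant: total misjoin count < number of junctions "
                "(n_contigs - n_chromosomes)"
            )


@dataclass(frozen=True)
class MisjoinRecord:
    """One injected scaffolding edit, located in the observed layout."""

    type: MisjoinType
    scaffold: str
    junction_index: int
    position: int  # 0-based scaffold coordinate of the first gap-filler base
    contigs: tuple  # contig ids involved in the edit
    junction_pair: tuple  # (left contig id, right contig id) at the recorded junction


@dataclass
class GroundTruth:
    """Everything needed to score the pipeline against the simulation."""

    true_layout: ScaffoldLayout  # chromosomes: contigs + true gap sizes
    observed_layout: ScaffoldLayout  # Hi-C-style scaffolds with misjoins
    misjoin_records: list[MisjoinRecord]
    true_gap_sizes: dict  # (left contig id, right contig id) -> true gap bp
    chromosome_of: dict = field(default_factory=dict)  # contig id -> chromosome name


def _rng(config: SimulationConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(config.seed)


# -- genome and layout --------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def generate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, str]:
    """Uniform-composition chromosomes totalling ``genome_length``."""
    config.validate()
    rng = _rng(config, rng)
    base = config.genome_length // config.n_chromosomes
    out = {}
    for i in range(config.n_chromosomes):
        length = base + (config.genome_length % config.n_chromosomes if i == 0 else 0)
        seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
        out[f"chr{i + 1}"] = seq
    return out


def _partition_chromosome(length, k, config, rng):
    """Alternating contig/gap spans on one chromosome: k contigs, k-1 gaps."""
    gaps = []
    if k > 1:
        gaps = np.maximum(
            1, np.rint(rng.normal(config.true_gap_mean, config.true_gap_sd, k - 1))
        ).astype(int)
    remaining = length - int(np.sum(gaps))
    extra = remaining - k * config.min_contig_length
    if extra < 0:
        raise ConfigurationError(
            "violated invariant: chromosome too short for requested contigs"
        )
    cuts = np.sort(rng.uniform(0, extra, k - 1)) if k > 1 else np.empty(0)
    parts = np.diff(np.concatenate([[0.0], cuts, [float(extra)]]))
    contig_lengths = (np.floor(parts) + config.min_contig_length).astype(int)
    contig_lengths[-1] += remaining - int(np.sum(contig_lengths))
    return list(contig_lengths), list(gaps)


def fragment_and_scaffold(
    sequences: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], GroundTruth]:
    """Fragment the genome into contigs and build true + observed layouts.

    The true layout reproduces each chromosome (contigs interleaved with
    true-size gap regions); the observed layout joins the same contigs with
    the fixed Hi-C gap filler and applies exactly the requested misjoins.
    """
    config.validate()
    rng = _rng(config, rng)
    names = list(sequences)
    lengths = [len(sequences[n]) for n in names]
    # contigs per chromosome, proportional to length (each chromosome >= 1)
    total_len = sum(lengths)
    alloc = [max(1, int(round(config.n_contigs * ln / total_len))) for ln in lengths]
    while sum(alloc) > config.n_contigs:
        alloc[int(np.argmax(alloc))] -= 1
    while sum(alloc) < config.n_contigs:
        alloc[int(np.argmin(alloc))] += 1

    contigs: dict[str, str] = {}
    true_layout = ScaffoldLayout()
    observed = ScaffoldLayout()
    true_gap_sizes: dict = {}
    chromosome_of: dict = {}
    counter = 0
    for chrom, k in zip(names, alloc):
        seq = sequences[chrom]
        contig_lengths, gap_lengths = _partition_chromosome(len(seq), k, config, rng)
        true_comps: list = []
        obs_comps: list = []
        pos = 0
        prev_id = None
        for j, cl in enumerate(contig_lengths):
            counter += 1
            cid = f"contig_{counter:04d}"
            contigs[cid] = seq[pos : pos + cl]
            chromosome_of[cid] = chrom
            placement = ContigPlacement(cid, 0, cl, "+")
            if j > 0:
                true_comps.append(Gap(gap_lengths[j - 1], "TRUE"))
                obs_comps.append(Gap(config.hic_gap_fill, "HIC"))
                true_gap_sizes[(prev_id, cid)] = int(gap_lengths[j - 1])
            true_comps.append(placement)
            obs_comps.append(ContigPlacement(cid, 0, cl, "+"))
            pos += cl + (gap_lengths[j] if j < len(gap_lengths) else 0)
            prev_id = cid
        true_layout.scaffolds[chrom] = true_comps
        observed.scaffolds[chrom.replace("chr", "scaffold_")] = obs_comps

    gt = GroundTruth(true_layout, observed, [], true_gap_sizes, chromosome_of)
    _apply_misjoins(gt, config, rng)
    return contigs, gt


def _placement_slots(comps):
    """Indices into the component list that hold placements, in order."""
    return [i for i, c in enumerate(comps) if isinstance(c, ContigPlacement)]


def _apply_misjoins(gt: GroundTruth, config: SimulationConfig, rng) -> None:
    obs = gt.observed_layout
    frozen: set[str] = set()
    pending: list[tuple[MisjoinType, tuple, tuple]] = []  # (type, involved, pair)

    def slot_ok(scaffold, k, relax=False):
        comps = obs.scaffolds[scaffold]
        slots = _placement_slots(comps)
        if not 1 <= k < len(slots):
            return False
        cur = comps[slots[k]].contig_id
        left = comps[slots[k - 1]].contig_id
        # a frozen slot content may never move again (it anchors an earlier
        # record); a frozen left neighbour is only avoided when possible
        return cur not in frozen and (relax or left not in frozen)

    def random_slot(min_slots=2, relax=False):
        candidates = [
            (name, k)
            for name, comps in obs.scaffolds.items()
            if len(_placement_slots(comps)) >= min_slots
            for k in range(1, len(_placement_slots(comps)))
        ]
        rng.shuffle(candidates)
        for name, k in candidates:
            if slot_ok(name, k, relax):
                yield name, k

    edits = [(t, 1) for t, n in config.misjoins for _ in range(int(n))]
    for mtype, _ in edits:
      mtype = MisjoinType(mtype)
      placed = False
      for relax in (False, True):
        if placed:
            break
        if mtype is MisjoinType.INVERSION:
            for name, k in random_slot(relax=relax):
                comps = obs.scaffolds[name]
                slots = _placement_slots(comps)
                p = comps[slots[k]]
                obs.scaffolds[name][slots[k]] = ContigPlacement(
                    p.contig_id, p.contig_beg, p.contig_end, "-"
                )
                left = comps[slots[k - 1]].contig_id
                frozen.update({p.contig_id, left})
                pending.append((mtype, (p.contig_id,), (left, p.contig_id)))
                placed = True
                break
        elif mtype is MisjoinType.TRANSLOCATION:
            for name1, k1 in random_slot(relax=relax):
                for name2, k2 in random_slot(relax=relax):
                    if name1 == name2 and abs(k1 - k2) < 2:
                        continue
                    c1 = obs.scaffolds[name1]
                    c2 = obs.scaffolds[name2]
                    s1 = _placement_slots(c1)
                    s2 = _placement_slots(c2)
                    p1, p2 = c1[s1[k1]], c2[s2[k2]]
                    if p1.contig_id == p2.contig_id:
                        continue
                    c1[s1[k1]], c2[s2[k2]] = p2, p1
                    left1 = c1[s1[k1 - 1]].contig_id
                    left2 = c2[s2[k2 - 1]].contig_id
                    frozen.update({p1.contig_id, p2.contig_id, left1, left2})
                    pending.append(
                        (mtype, (p1.contig_id, p2.contig_id), (left1, p2.contig_id))
                    )
                    placed = True
                    break
                if placed:
                    break
        elif mtype is MisjoinType.FUSION:
            for name1, k1 in random_slot(min_slots=3, relax=relax):
                for name2, k2 in random_slot(min_slots=3, relax=relax):
                    if name1 == name2:
                        continue
                    c1 = obs.scaffolds[name1]
                    c2 = obs.scaffolds[name2]
                    s1 = _placement_slots(c1)
                    s2 = _placement_slots(c2)
                    # exchange tails starting at placement slots k1 / k2;
                    # the gap component just before each tail becomes the
                    # new (misjoined) junction
                    head1, tail1 = c1[: s1[k1] - 1], c1[s1[k1] :]
                    head2, tail2 = c2[: s2[k2] - 1], c2[s2[k2] :]
                    left1 = c1[s1[k1 - 1]].contig_id
                    left2 = c2[s2[k2 - 1]].contig_id
                    first1 = tail1[0].contig_id
                    first2 = tail2[0].contig_id
                    obs.scaffolds[name1] = head1 + [Gap(config.hic_gap_fill, "HIC")] + tail2
                    obs.scaffolds[name2] = head2 + [Gap(config.hic_gap_fill, "HIC")] + tail1
                    frozen.update({left1, left2, first1, first2})
                    pending.append((mtype, (left1, first2, left2, first1), (left1, first2)))
                    placed = True
                    break
                if placed:
                    break
      if not placed:
            raise ConfigurationError(
                "could not place the requested misjoins without interference; "
                "reduce the misjoin count or increase n_contigs"
            )

    # locate each recorded junction pair in the final layout
    adjacency: dict[tuple, tuple] = {}
    for name, comps in obs.scaffolds.items():
        slots = _placement_slots(comps)
        pos = 0
        starts = []
        for c in comps:
            starts.append(pos)
            pos += c.span
        gap_count = 0
        gap_index_of_comp = {}
        for i, c in enumerate(comps):
            if isinstance(c, Gap):
                gap_index_of_comp[i] = gap_count
                gap_count += 1
        for a, b in zip(slots[:-1], slots[1:]):
            gap_comps = [i for i in range(a + 1, b) if isinstance(comps[i], Gap)]
            if len(gap_comps) != 1:
                continue
            gi = gap_comps[0]
            adjacency[(comps[a].contig_id, comps[b].contig_id)] = (
                name,
                gap_index_of_comp[gi],
                starts[gi],
            )
    for mtype, involved, pair in pending:
        name, junction_index, position = adjacency[pair]
        gt.misjoin_records.append(
            MisjoinRecord(mtype, name, junction_index, int(position), involved, pair)
        )


def junction_truth(gt: GroundTruth) -> dict[str, bool]:
    """Per observed Hi-C junction: is the joined pair truly adjacent?

    A junction is correct iff its flanking placements are consecutive
    contigs of the same chromosome in true order, co-oriented with the true
    arrangement. Keyed by ``scaffold:gap<index>``.
    """
    out: dict[str, bool] = {}
    for name, comps in gt.observed_layout.scaffolds.items():
        slots = _placement_slots(comps)
        gap_count = 0
        for a, b in zip(slots[:-1], slots[1:]):
            pa, pb = comps[a], comps[b]
            fwd = (
                (pa.contig_id, pb.contig_id) in gt.true_gap_sizes
                and pa.orientation == "+"
                and pb.orientation == "+"
            )
            rev = (
                (pb.contig_id, pa.contig_id) in gt.true_gap_sizes
                and pa.orientation == "-"
                and pb.orientation == "-"
            )
            out[f"{name}:gap{gap_count}"] = fwd or rev
            gap_count += 1
    return out


# -- optical map simulation ---------------------------------------------


def simulate_label_map(
    sequence: str,
    enzyme: Enzyme,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    map_id: str = "map",
    min_label_distance: int = 0,
) -> LabelMap:
    """A noisy consensus label map of one sequence for one enzyme.

    Starts from the exact in-silico site list; each inter-label interval of
    true length L receives additive Gaussian noise with SD
    ``sizing_sd_coeff * sqrt(L/1000)``; each label is dropped independently
    with ``label_miss_rate``; false labels arrive as a homogeneous point
    process at ``false_label_rate`` per 100 kb. Output positions are
    strictly increasing.
    """
    config.validate()
    rng = _rng(config, rng)
    length = float(len(sequence))
    sites = np.array(
        condense_sites(find_recognition_sites(sequence, enzyme.motif), min_label_distance),
        dtype=float,
    )
    if sites.size:
        intervals = np.diff(sites)
        if config.sizing_sd_coeff > 0 and intervals.size:
            sd = config.sizing_sd_coeff * np.sqrt(intervals / 1000.0)
            intervals = np.maximum(1.0, intervals + rng.normal(0.0, sd))
        positions = np.concatenate([[sites[0]], sites[0] + np.cumsum(intervals)])
        if config.label_miss_rate > 0:
            positions = positions[rng.random(positions.size) >= config.label_miss_rate]
    else:
        positions = sites
    n_false = rng.poisson(config.false_label_rate * length / 100_000.0)
    if n_false:
        positions = np.concatenate([positions, rng.uniform(0, length, n_false)])
    positions = np.sort(positions)
    positions = positions[(positions >= 0) & (positions < length)]
    # enforce strict monotonicity after merging channels of noise
    for i in range(1, positions.size):
        if positions[i] <= positions[i - 1]:
            positions[i] = positions[i - 1] + 1e-3
    positions = positions[positions < length]
    return LabelMap(map_id, length, enzyme.name, positions)


# -- read alignment simulation ------------------------------------------

_MIN_FRAGMENT = 50  # bp; slivers below this are not emitted as records


def simulate_read_alignments(
    gt: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[ReadAlignmentRecord]:
    """Long-read alignments drawn from the true genome, in observed coords.

    Read lengths are lognormal around ``read_length_median``; starts are
    uniform; total yield reaches ``read_coverage`` fold. A read is emitted
    as one record per maximal run of contigs that remain contiguous (same
    order and orientation, separated by a single gap) in the observed
    layout; where the observed layout breaks the read's true locus — any
    misjoin — the read splits into separate records mapped to each part's
    observed position. A junction joining truly adjacent contigs therefore
    acquires single-record spanning reads, and a misjoined junction none.
    """
    config.validate()
    if config.read_coverage <= 0:
        raise ConfigurationError("violated invariant: read_coverage > 0")
    rng = _rng(config, rng)

    # observed placement lookup
    obs_start: dict[str, tuple[str, int, str]] = {}
    obs_slot: dict[str, tuple[str, int]] = {}
    scaffold_len = gt.observed_layout.scaffold_lengths()
    for name, comps in gt.observed_layout.scaffolds.items():
        slots = _placement_slots(comps)
        pos = 0
        starts = []
        for c in comps:
            starts.append(pos)
            pos += c.span
        for slot_idx, ci in enumerate(slots):
            p = comps[ci]
            obs_start[p.contig_id] = (name, starts[ci], p.orientation)
            obs_slot[p.contig_id] = (name, slot_idx)

    # true chromosome structure
    chrom_segments: dict[str, list[tuple[int, int, str]]] = {}
    chrom_length: dict[str, int] = {}
    for chrom, comps in gt.true_layout.scaffolds.items():
        pos = 0
        segs = []
        for c in comps:
            if isinstance(c, ContigPlacement):
                segs.append((pos, pos + c.span, c.contig_id))
            pos += c.span
        chrom_segments[chrom] = segs
        chrom_length[chrom] = pos

    chroms = list(chrom_length)
    weights = np.array([chrom_length[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    target = config.read_coverage * sum(chrom_length.values())

    def observed_adjacent(c1: str, c2: str) -> bool:
        n1, s1 = obs_slot[c1]
        n2, s2 = obs_slot[c2]
        if n1 != n2:
            return False
        o1 = obs_start[c1][2]
        o2 = obs_start[c2][2]
        if s2 == s1 + 1:
            return o1 == "+" and o2 == "+"
        if s2 == s1 - 1:
            return o1 == "-" and o2 == "-"
        return False

    records: list[ReadAlignmentRecord] = []
    emitted = 0.0
    read_no = 0
    mu = math.log(config.read_length_median)
    while emitted < target:
        read_no += 1
        length = int(rng.lognormal(mu, config.read_length_sigma))
        length = max(500, length)
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        L = chrom_length[chrom]
        s = int(rng.integers(0, max(1, L - 1)))
        e = min(L, s + length)
        emitted += e - s
        qlen = e - s
        read_id = f"read_{read_no:06d}"
        segs = chrom_segments[chrom]
        seg_starts = [a for a, _, _ in segs]
        i0 = max(0, bisect_right(seg_starts, s) - 1)
        overlapped = []
        for a, b, cid in segs[i0:]:
            if a >= e:
                break
            if b > s:
                overlapped.append((a, b, cid))
        # group into observed-contiguous runs
        runs: list[list[tuple[int, int, str]]] = []
        for seg in overlapped:
            if runs and observed_adjacent(runs[-1][-1][2], seg[2]):
                runs[-1].append(seg)
            else:
                runs.append([seg])
        for run in runs:
            a0, b0, c0 = run[0]
            a1, b1, c1 = run[-1]
            a = max(s, a0)
            b = min(e, b1)
            if b - a < _MIN_FRAGMENT:
                continue
            scaffold, start0, orient0 = obs_start[c0]
            _, start1, _ = obs_start[c1]
            if orient0 == "+":
                tstart = start0 + (a - a0)
                tend = start1 + (b - a1)
                strand = "+"
            else:
                tstart = start1 + (b1 - b)
                tend = start0 + (b0 - a)
                strand = "-"
            records.append(
                ReadAlignmentRecord(
                    read_id=read_id,
                    read_length=qlen,
                    read_start=a - s,
                    read_end=b - s,
                    strand=strand,
                    target=scaffold,
                    target_length=scaffold_len[scaffold],
                    target_start=int(tstart),
                    target_end=int(tend),
                    matches=b - a,
                    alignment_length=b - a,
                    mapq=60,
                )
            )
    return records


# -- dataset bundle and writers -----------------------------------------


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: dict[str, str]
    contigs: dict[str, str]
    ground_truth: GroundTruth
    reads: list[ReadAlignmentRecord]


def simulate_dataset(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedDataset:
    """Genome, contigs, layouts with misjoins, and read alignments, one call."""
    rng = _rng(config, rng)
    genome = generate_genome(config, rng)
    contigs, gt = fragment_and_scaffold(genome, config, rng)
    reads = simulate_read_alignments(gt, config, rng)
    return SimulatedDataset(config, genome, contigs, gt, reads)


def write_fasta(sequences: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_misjoins_bed(records: list[MisjoinRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.scaffold}\t{r.position}\t{r.position + 1}\t"
                f"{r.type.value}:{','.join(r.contigs)}\t0\n"
            )


def write_ground_truth_json(gt: GroundTruth, config: SimulationConfig, path: str) -> None:
    payload = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "misjoins": [
            {
                "type": r.type.value,
                "scaffold": r.scaffold,
                "junction_index": r.junction_index,
                "position": r.position,
                "contigs": list(r.contigs),
            }
            for r in gt.misjoin_records
        ],
        "true_gap_sizes": {f"{a}|{b}": v for (a, b), v in gt.true_gap_sizes.items()},
        "junction_truth": junction_truth(gt),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=str)


__all__ = [
    "GroundTruth",
    "affected_junctions",
    "MisjoinRecord",
    "MisjoinType",
    "SimulatedDataset",
    "SimulationConfig",
    "fragment_and_scaffold",
    "generate_genome",
    "junction_truth",
    "simulate_dataset",
    "simulate_label_map",
    "simulate_read_alignments",
    "write_fasta",
    "write_ground_truth_json",
    "write_misjoins_bed",
]


def affected_junctions(gt: GroundTruth, record: MisjoinRecord) -> list[tuple]:
    """All observed-layout junctions disrupted by one misjoin edit.

    A single edit (swap, flip, tail exchange) can disturb several
    junctions; they are found as the gaps adjacent to any placement of a
    contig involved in the edit. Returns (scaffold, gap start) pairs.
    """
    out = []
    involved = set(record.contigs)
    for name, comps in gt.observed_layout.scaffolds.items():
        slots = _placement_slots(comps)
        starts = []
        pos = 0
        for c in comps:
            starts.append(pos)
            pos += c.span
        for a, b in zip(slots[:-1], slots[1:]):
            if {comps[a].contig_id, comps[b].contig_id} & involved:
                gaps = [i for i in range(a + 1, b) if isinstance(comps[i], Gap)]
                if gaps:
                    out.append((name, starts[gaps[0]]))
    return out
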
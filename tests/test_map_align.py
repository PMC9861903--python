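"""Label-map alignment: scoring, DP optimality, breakpoint extraction."""

import numpy as np
import pytest

from junctionqc.digest import LabelMap
from junctionqc.map_align import (
    AlignParams,
    align_maps,
    detect_breakpoints,
    interval_penalty,
)

INF = float("inf")


def brute_force_best(q, r, p: AlignParams) -> float:
    """Exhaustive optimum over all monotone matchings with bounded skips.

    Enumerates every chain of (query, reference) index pairs whose steps
    advance by at most ``lookback`` on each side, scoring steps exactly as
    the DP does; the best chain score is the local-alignment optimum.
    """
    nq, nr = len(q), len(r)
    best = 0.0

    def step(i0, j0, i1, j1):
        pen = interval_penalty(q[i1] - q[i0], r[j1] - r[j0], p.sigma)
        return (
            p.match_bonus
            - pen
            - (j1 - j0 - 1) * p.miss_penalty
            - (i1 - i0 - 1) * p.false_penalty
        )

    def extend(i, j, score):
        nonlocal best
        best = max(best, score)
        for a in range(1, min(p.lookback, nq - 1 - i) + 1):
            for b in range(1, min(p.lookback, nr - 1 - j) + 1):
                extend(i + a, j + b, score + step(i, j, i + a, j + b))

    for i in range(nq):
        for j in range(nr):
            extend(i, j, 0.0)
    return best


def dp_matrix_best(q, r, p: AlignParams) -> float:
    from junctionqc.map_align import _dp_fill

    S, _, _ = _dp_fill(np.asarray(q, float), np.asarray(r, float), p)
    return float(S.max())


def make_map(map_id, positions, length=None, channel="E"):
    positions = np.asarray(positions, float)
    return LabelMap(map_id, float(length or positions[-1] + 5000), channel, positions)


class TestIntervalPenalty:
    def test_exact_match_is_zero(self):
        assert interval_penalty(5000, 5000, 123.0) == 0.0

    def test_hand_evaluated_value(self):
        assert interval_penalty(6000, 5000, 400) == pytest.approx(1.25)

    def test_symmetric_in_sign_of_difference(self):
        for q, r in [(6000, 5000), (300, 900), (10_500, 10_000)]:
            assert interval_penalty(q, r, 400) == pytest.approx(
                interval_penalty(2 * r - q, r, 400)
            )

    def test_sigma_zero_forbids_mismatch(self):
        assert interval_penalty(5000, 5000, 0.0) == 0.0
        assert interval_penalty(5001, 5000, 0.0) == INF


class TestAlignMaps:
    def test_self_alignment_is_perfect(self):
        rng = np.random.default_rng(1)
        positions = np.cumsum(rng.uniform(1500, 5000, 12)) + 500
        q = make_map("q", positions)
        r = make_map("r", positions)
        p = AlignParams()
        alns = align_maps(q, r, p)
        assert len(alns) == 1
        a = alns[0]
        assert len(a.pairs) == 12
        assert a.score == pytest.approx(11 * p.match_bonus)
        assert (
            a.query_left_unaligned
            == a.query_right_unaligned
            == a.ref_left_unaligned
            == a.ref_right_unaligned
            == 0
        )

    def test_one_removed_label_costs_one_miss(self):
        rng = np.random.default_rng(2)
        positions = np.cumsum(rng.uniform(1500, 5000, 14)) + 500
        r = make_map("r", positions)
        q = make_map("q", np.delete(positions, 6), length=r.length)
        p = AlignParams()
        alns = align_maps(q, r, p)
        a = alns[0]  # best alignment skips exactly the removed label
        assert len(a.pairs) == 13
        assert a.score == pytest.approx(12 * p.match_bonus - p.miss_penalty)

    def test_orientation_symmetry(self):
        rng = np.random.default_rng(5)
        positions = np.sort(rng.uniform(0, 100_000, 15))
        r = make_map("r", positions, length=100_000)
        q_fwd = make_map("q", positions, length=100_000)
        q_rev = make_map("qr", np.sort(100_000 - positions), length=100_000)
        p = AlignParams()
        fwd = align_maps(q_fwd, r, p)
        rev = align_maps(q_rev, r, p)
        assert fwd and rev
        assert fwd[0].score == pytest.approx(rev[0].score)
        assert fwd[0].orientation == "+"
        assert rev[0].orientation == "-"

    @pytest.mark.parametrize("seed", range(10))
    def test_dp_equals_exhaustive_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        nq, nr = rng.integers(4, 9, size=2)
        q = np.sort(rng.uniform(0, 40_000, nq))
        r = np.sort(rng.uniform(0, 40_000, nr))
        p = AlignParams(lookback=8)
        assert dp_matrix_best(q, r, p) == pytest.approx(
            brute_force_best(q, r, p), abs=1e-9
        )


class TestDetectBreakpoints:
    def _junction_fixture(self):
        """Reference = map of chromosome A then chromosome B; query = full
        map of chromosome A extending past the junction."""
        rng = np.random.default_rng(11)
        a = np.cumsum(rng.uniform(1500, 4000, 60))
        # chromosome B gets a distinct interval scale so no chance chain of
        # A's trailing labels can shadow the junction
        b = np.cumsum(rng.uniform(6000, 11_000, 60))
        junction = a[39] + 2500  # ref keeps only A's first 40 labels
        ref_positions = np.concatenate([a[:40], junction + b])
        ref = make_map("scaf", ref_positions, length=ref_positions[-1] + 5000)
        query = make_map("chrA", a, length=a[-1] + 5000)
        return query, ref, junction

    def test_breakpoint_near_constructed_junction(self):
        query, ref, junction = self._junction_fixture()
        p = AlignParams()
        alns = align_maps(query, ref, p)
        bps = detect_breakpoints(alns, {"chrA": query}, {"scaf": ref}, p)
        assert len(bps) == 1
        # within one label interval of the junction
        assert abs(bps[0].position - junction) < 5000
        assert bps[0].side == "right"

    def test_map_end_termination_emits_nothing(self):
        rng = np.random.default_rng(4)
        positions = np.cumsum(rng.uniform(1500, 5000, 20)) + 800
        q = make_map("q", positions)
        r = make_map("r", positions)
        p = AlignParams()
        alns = align_maps(q, r, p)
        assert detect_breakpoints(alns, {"q": q}, {"r": r}, p) == []

    def test_trailing_k_larger_than_remainder_blocks_breakpoint(self):
        query, ref, _ = self._junction_fixture()
        p = AlignParams(trailing_k=200)
        alns = align_maps(query, ref, p)
        assert detect_breakpoints(alns, {"chrA": query}, {"scaf": ref}, p) == []

    def test_collinear_resumption_is_not_a_conflict(self):
        """A chain split across a mis-sized gap resumes collinearly and
        must not produce breakpoints."""
        rng = np.random.default_rng(3)
        left = np.cumsum(rng.uniform(1500, 4000, 40))
        right = np.cumsum(rng.uniform(1500, 4000, 40))
        # query: physical truth with a 12 kb gap; ref: same with 100 bp gap
        q_pos = np.concatenate([left, left[-1] + 12_000 + right])
        r_pos = np.concatenate([left, left[-1] + 100 + right])
        q = make_map("q", q_pos, length=q_pos[-1] + 5000)
        r = make_map("r", r_pos, length=r_pos[-1] + 5000)
        p = AlignParams()
        alns = align_maps(q, r, p)
        bps = detect_breakpoints(alns, {"q": q}, {"r": r}, p)
        assert bps == []


def test_noise_never_increases_expected_score():
    """Adding sizing noise of larger scale lowers the mean optimal score."""
    rng = np.random.default_rng(7)
    base = np.cumsum(rng.uniform(1500, 4000, 40))
    p = AlignParams()
    means = []
    for coeff in (0.0, 400.0, 900.0):
        scores = []
        for seed in range(15):
            noise_rng = np.random.default_rng(seed)
            intervals = np.diff(np.concatenate([[0.0], base]))
            sd = coeff * np.sqrt(intervals / 1000.0)
            noisy = np.cumsum(np.maximum(1.0, intervals + noise_rng.normal(0, sd, len(intervals))))
            q = make_map("q", noisy, length=noisy[-1] + 5000)
            r = make_map("r", base, length=base[-1] + 5000)
            alns = align_maps(q, r, p)
            scores.append(max((a.score for a in alns), default=0.0))
        means.append(np.mean(scores))
    assert means[0] >= means[1] >= means[2]
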
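"""Label-map alignment by dynamic programming with a sizing-error model.

Optical maps and in-silico digests are compared as ordered label lists. Two
maps of the same locus agree in their inter-label interval lengths up to
sizing noise, missing labels and false labels, so alignment is a local DP
over label indices: matching a pair of labels extends the chain with a
bonus minus a sizing penalty on the implied intervals, and skipped labels
on either side pay per-label penalties. Where a scaffold's structure
contradicts the map, chains end internally on both maps — the signature of
a misjoin — and those terminations are emitted as breakpoint candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .digest import LabelMap

INF = float("inf")


@dataclass(frozen=True)
class AlignParams:
    """Scoring and calling parameters for label-map alignment.

    sigma is the sizing-error scale in bp per sqrt(kb): an interval of true
    length L is expected to be measured with SD sigma*sqrt(L/1000), so the
    sizing penalty of a matched interval pair is roughly its squared
    z-score. Score units are arbitrary; defaults separate signal from noise
    with margin on realistic label densities and are all exposed here.
    """

    sigma: float = 400.0
    match_bonus: float = 2.2
    miss_penalty: float = 3.0  # per skipped reference label
    false_penalty: float = 3.0  # per skipped query label
    lookback: int = 5
    min_matched_labels: int = 9
    min_score: float = 12.0
    trailing_k: int = 5  # unaligned labels on both maps defining a breakpoint
    xdrop: float = 12.0  # score drop from the running peak that splits a chain
    # breakpoint gates: only confident, dense alignments may claim an
    # incongruence; chance chains between unrelated label maps are either
    # short (score capped by the X-drop scale) or sparse
    breakpoint_min_score: float = 25.0
    breakpoint_min_density: float = 0.6  # matched fraction of spanned labels
    # a termination is suppressed when any same-query segment resumes
    # downstream collinearly — within this tolerance of where the broken
    # chain would have continued. Such a resumption means the chain was
    # split by sizing noise or a mis-sized gap, not by a rearrangement.
    continuation_tol: float = 20_000.0  # bp
    continuation_min_score: float = 20.0  # credibility floor for the resuming segment

    def __post_init__(self):
        if min(self.miss_penalty, self.false_penalty, self.sigma) < 0:
            raise ValueError("penalties and sigma must be >= 0")
        if self.lookback < 1 or self.trailing_k < 1:
            raise ValueError("lookback and trailing_k must be >= 1")


@dataclass
class MapAlignment:
    """A monotone matching between query and reference label indices.

    ``pairs`` are (query index, reference index) in the *oriented* query
    frame (indices into the reversed label list when orientation is "-"),
    strictly increasing in both coordinates. Unaligned flank counts refer to
    the same frame; because matched pairs increase in both coordinates, the
    "left" flank of the oriented query faces the "left" flank of the
    reference.
    """

    query_id: str
    ref_id: str
    orientation: str
    pairs: list[tuple[int, int]]
    score: float
    query_left_unaligned: int = 0
    query_right_unaligned: int = 0
    ref_left_unaligned: int = 0
    ref_right_unaligned: int = 0
    channel: str = ""


@dataclass(frozen=True)
class Breakpoint:
    """An internal alignment termination: candidate structural conflict."""

    ref_id: str
    position: float  # reference bp of the last matched label on the broken side
    channel: str
    query_id: str
    side: str  # "left" or "right" in reference orientation
    score: float


def interval_penalty(q_len: float, r_len: float, sigma: float) -> float:
    """Squared sizing discrepancy of a matched interval pair, in score units.

    ``(q_len - r_len)^2 / (sigma^2 * max(r_len, 1000)/1000)`` — the squared
    z-score under the sqrt-length sizing model, with the reference interval
    floored at 1 kb so very short intervals do not dominate. Zero iff the
    intervals agree; symmetric in the sign of the difference. sigma = 0
    forbids any mismatch (returns +inf).
    """
    if q_len < 0 or r_len < 0:
        raise ValueError("interval lengths must be >= 0")
    diff = q_len - r_len
    if sigma == 0:
        return 0.0 if diff == 0 else INF
    return diff * diff / (sigma * sigma * max(r_len, 1000.0) / 1000.0)


try:  # the jitted kernel is ~20x faster; the numpy path is the reference
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _dp_fill_py(q: np.ndarray, r: np.ndarray, p: AlignParams):
    """Fill the local-alignment score matrix and backpointers.

    S[i, j] is the best score of a chain ending with query label i matched
    to reference label j (0 for a chain that starts there). Backpointers
    store the (a, b) step taken, 0 meaning chain start.
    """
    nq, nr = len(q), len(r)
    S = np.zeros((nq, nr))
    back_a = np.zeros((nq, nr), dtype=np.int16)
    back_b = np.zeros((nq, nr), dtype=np.int16)
    sig2 = p.sigma * p.sigma
    for i in range(1, nq):
        best = np.full(nr, -INF)
        ba = np.zeros(nr, dtype=np.int16)
        bb = np.zeros(nr, dtype=np.int16)
        for a in range(1, min(p.lookback, i) + 1):
            dq = q[i] - q[i - a]
            skip_q = (a - 1) * p.false_penalty
            for b in range(1, min(p.lookback, nr - 1) + 1):
                dr = r[b:] - r[:-b]  # dr[j-b] = r[j] - r[j-b]
                if sig2 == 0:
                    pen = np.where(dr == dq, 0.0, INF)
                else:
                    pen = (dq - dr) ** 2 / (sig2 * np.maximum(dr, 1000.0) / 1000.0)
                cand = (
                    S[i - a, :-b]
                    + p.match_bonus
                    - pen
                    - (b - 1) * p.miss_penalty
                    - skip_q
                )
                upd = cand > best[b:]
                if np.any(upd):
                    best[b:][upd] = cand[upd]
                    ba[b:][upd] = a
                    bb[b:][upd] = b
        pos = best > 0
        S[i, pos] = best[pos]
        back_a[i, pos] = ba[pos]
        back_b[i, pos] = bb[pos]
    return S, back_a, back_b


if _HAVE_NUMBA:

    @_njit(cache=False)
    def _dp_kernel(q, r, sigma, match_bonus, miss_penalty, false_penalty, lookback):
        nq, nr = len(q), len(r)
        S = np.zeros((nq, nr))
        back_a = np.zeros((nq, nr), dtype=np.int16)
        back_b = np.zeros((nq, nr), dtype=np.int16)
        sig2 = sigma * sigma
        for i in range(1, nq):
            amax = min(lookback, i)
            for j in range(1, nr):
                bmax = min(lookback, j)
                best = 0.0
                ba = 0
                bb = 0
                for a in range(1, amax + 1):
                    dq = q[i] - q[i - a]
                    for b in range(1, bmax + 1):
                        dr = r[j] - r[j - b]
                        if sig2 == 0.0:
                            if dq != dr:
                                continue
                            pen = 0.0
                        else:
                            d = dq - dr
                            denom = dr if dr > 1000.0 else 1000.0
                            pen = d * d / (sig2 * denom / 1000.0)
                        cand = (
                            S[i - a, j - b]
                            + match_bonus
                            - pen
                            - (b - 1) * miss_penalty
                            - (a - 1) * false_penalty
                        )
                        if cand > best:
                            best = cand
                            ba = a
                            bb = b
                if best > 0.0:
                    S[i, j] = best
                    back_a[i, j] = ba
                    back_b[i, j] = bb
        return S, back_a, back_b

    def _dp_fill(q, r, p):
        return _dp_kernel(
            np.ascontiguousarray(q, dtype=np.float64),
            np.ascontiguousarray(r, dtype=np.float64),
            float(p.sigma),
            float(p.match_bonus),
            float(p.miss_penalty),
            float(p.false_penalty),
            int(p.lookback),
        )

else:  # pragma: no cover
    _dp_fill = _dp_fill_py


def _step_scores(pairs, q, r, p: AlignParams) -> np.ndarray:
    """Score of each chain step (between consecutive matched pairs)."""
    out = np.empty(len(pairs) - 1)
    for k in range(1, len(pairs)):
        (i0, j0), (i1, j1) = pairs[k - 1], pairs[k]
        pen = interval_penalty(q[i1] - q[i0], r[j1] - r[j0], p.sigma)
        out[k - 1] = (
            p.match_bonus
            - pen
            - (j1 - j0 - 1) * p.miss_penalty
            - (i1 - i0 - 1) * p.false_penalty
        )
    return out


def _xdrop_segments(pairs, steps: np.ndarray, p: AlignParams):
    """Split a chain into maximal sub-chains by the X-drop rule.

    Walking the chain, a segment ends at its running score peak whenever the
    cumulative score falls more than ``xdrop`` below that peak — the
    signature of the chain having paid its way across a region where the
    maps disagree (e.g. a misjoin) on accumulated score. Trailing descents
    are trimmed to the peak. Each returned segment carries its summed score.
    """
    segments = []
    start = 0  # pair index where the current segment starts
    cum = 0.0
    peak = 0.0
    peak_idx = 0
    for k, s in enumerate(steps):
        cum += s
        j = k + 1  # pair index after this step
        if cum > peak:
            peak, peak_idx = cum, j
        if peak - cum >= p.xdrop:
            segments.append((start, peak_idx, peak))
            start = j
            cum = 0.0
            peak = 0.0
            peak_idx = j
        elif cum < 0:
            # Kadane restart: a segment never begins with a losing prefix
            start = j
            cum = 0.0
            peak = 0.0
            peak_idx = j
    segments.append((start, peak_idx, peak))
    return [
        (pairs[a : b + 1], score)
        for a, b, score in segments
        if b > a
    ]


def _traceback(back_a, back_b, visited, i, j):
    """Trace a chain from its endpoint, stopping at any cell already on a
    previously traced chain (the shared remainder was handled when that
    chain was processed). Every DP cell is traversed at most once across
    all tracebacks, bounding the total work."""
    pairs = []
    while not visited[i, j]:
        visited[i, j] = True
        pairs.append((i, j))
        a = back_a[i, j]
        if a == 0:
            break
        i, j = i - a, j - back_b[i, j]
    pairs.reverse()
    return pairs


def align_maps(query: LabelMap, ref: LabelMap, params: AlignParams | None = None
               ) -> list[MapAlignment]:
    """Local alignments of a query label map against a reference label map.

    Both query orientations are scored. All chain endpoints with score >=
    ``min_score`` are traced back; alignments with >= ``min_matched_labels``
    pairs are accepted greedily by score, non-overlapping on the query (one
    query label belongs to at most one alignment; a reference region may
    attract several queries, e.g. both haplotypes).
    """
    p = params or AlignParams()
    r = np.asarray(ref.labels, dtype=float)
    q_fwd = np.asarray(query.labels, dtype=float)
    q_rev = query.length - q_fwd[::-1]  # reversed map coordinates
    if len(q_fwd) < 2 or len(r) < 2:
        return []

    frames = {}
    cand_scores = []
    cand_ij = []
    cand_orient = []
    for orient, q in (("+", q_fwd), ("-", q_rev)):
        frames[orient] = _dp_fill(q, r, p)
        S = frames[orient][0]
        ii, jj = np.nonzero(S >= p.min_score)
        cand_scores.append(S[ii, jj])
        cand_ij.append((ii, jj))
        cand_orient.append(orient)
    all_scores = np.concatenate(cand_scores) if cand_scores else np.empty(0)
    sizes = [len(s) for s in cand_scores]
    order = np.argsort(all_scores)[::-1]

    nq, nr = len(q_fwd), len(r)
    # per-orientation claims: strand-symmetric label maps mean an inverted
    # segment's true alignment lives in the other orientation and must not
    # be blocked by forward-frame coverage
    claimed = {o: np.zeros(nq, dtype=bool) for o in ("+", "-")}
    visited = {o: np.zeros(frames[o][0].shape, dtype=bool) for o in frames}
    results: list[MapAlignment] = []
    for flat in order:
        block = 0 if flat < sizes[0] else 1
        k = int(flat) - (0 if block == 0 else sizes[0])
        orient = cand_orient[block]
        i = int(cand_ij[block][0][k])
        j = int(cand_ij[block][1][k])
        if visited[orient][i, j]:
            continue  # endpoint lies on an already-processed chain
        S, back_a, back_b = frames[orient]
        chain = _traceback(back_a, back_b, visited[orient], i, j)
        if len(chain) < 2:
            continue
        q = q_fwd if orient == "+" else q_rev
        steps = _step_scores(chain, q, r, p)
        for pairs, seg_score in _xdrop_segments(chain, steps, p):
            if len(pairs) < p.min_matched_labels or seg_score < p.min_score:
                continue
            lo_o, hi_o = pairs[0][0], pairs[-1][0]
            if orient == "-":
                lo, hi = nq - 1 - hi_o, nq - 1 - lo_o
            else:
                lo, hi = lo_o, hi_o
            # claim only the segment's query labels: the chain may have
            # paid its way across foreign material whose true alignment
            # lies in another candidate
            if claimed[orient][lo : hi + 1].any():
                continue
            claimed[orient][lo : hi + 1] = True
            results.append(
                MapAlignment(
                    query_id=query.map_id,
                    ref_id=ref.map_id,
                    orientation=orient,
                    pairs=pairs,
                    score=float(seg_score),
                    query_left_unaligned=pairs[0][0],
                    query_right_unaligned=nq - 1 - pairs[-1][0],
                    ref_left_unaligned=pairs[0][1],
                    ref_right_unaligned=nr - 1 - pairs[-1][1],
                    channel=ref.channel or query.channel,
                )
            )
    results.sort(key=lambda a: -a.score)
    return results


def detect_breakpoints(
    alignments: list[MapAlignment],
    query_maps: dict[str, LabelMap] | None,
    ref_maps: dict[str, LabelMap],
    params: AlignParams | None = None,
    explain: bool = False,
) -> list[Breakpoint] | tuple[list[Breakpoint], list[dict]]:
    """Breakpoints from alignments that terminate internally on both maps.

    A side of an alignment (left or right, in reference orientation) emits a
    breakpoint when at least ``trailing_k`` labels remain beyond the
    alignment end on *both* the query and the reference on that side: the
    two maps keep going but stop agreeing, which is the misjoin signature.
    Terminations at a map end emit nothing. The breakpoint is placed at the
    reference position of the last matched label on the broken side —
    conservative and always label-anchored.

    A termination is suppressed when another segment of the same query and
    orientation resumes *collinearly* — at the reference position where the
    broken chain would have continued, within ``continuation_tol``. Such a
    resumption means the chain was merely split by sizing noise or a
    mis-sized gap, not interrupted by a rearrangement. Genuine conflicts
    are then established at the clustering stage, where a junction is
    expected to collect terminations from both of its flanks.
    """
    p = params or AlignParams()

    def _query_map(aln):
        if query_maps is None:
            return None
        return query_maps.get(aln.query_id) or query_maps.get(
            (aln.query_id, aln.channel)
        )

    # segment endpoints per (query, ref, orientation) for continuation
    # checks; only accepted segments are credible explanations of a split
    starts: dict[tuple, list[tuple[int, int]]] = {}
    ends: dict[tuple, list[tuple[int, int]]] = {}
    for aln in alignments:
        if aln.score < p.continuation_min_score:
            continue
        key = (aln.query_id, aln.ref_id, aln.orientation)
        starts.setdefault(key, []).append(aln.pairs[0])
        ends.setdefault(key, []).append(aln.pairs[-1])

    def _continuation(aln, pair, side) -> bool:
        """Does any same-key segment resume where this chain would have
        continued? Collinear resumption = split, not conflict."""
        qmap = _query_map(aln)
        key = (aln.query_id, aln.ref_id, aln.orientation)
        i, j = pair
        ref_labels = ref_maps[aln.ref_id].labels
        bp_pos = float(ref_labels[j])
        if qmap is None:
            # fall back to an index-proximity check when query positions
            # are unavailable
            pool = starts.get(key, []) if side == "right" else ends.get(key, [])
            return any(
                0 < abs(i2 - i) <= 2 * p.trailing_k
                and 0 < abs(j2 - j) <= 2 * p.trailing_k
                for i2, j2 in pool
            )
        q_pos = qmap.labels
        nq = qmap.n_labels
        to_orig = (lambda x: x) if aln.orientation == "+" else (lambda x: nq - 1 - x)
        sign = 1.0 if aln.orientation == "+" else -1.0
        pool = starts.get(key, []) if side == "right" else ends.get(key, [])
        for i2, j2 in pool:
            ahead = (i2 > i and j2 > j) if side == "right" else (i2 < i and j2 < j)
            if not ahead:
                continue
            expected = bp_pos + sign * (q_pos[to_orig(i2)] - q_pos[to_orig(i)])
            if abs(float(ref_labels[j2]) - expected) <= p.continuation_tol:
                return True
        return False

    out: list[Breakpoint] = []
    verdicts: list[dict] = []
    for aln_idx, aln in enumerate(alignments):
        reasons_aln = []
        if aln.score < p.breakpoint_min_score:
            reasons_aln.append("score")
        q_span = aln.pairs[-1][0] - aln.pairs[0][0] + 1
        r_span = aln.pairs[-1][1] - aln.pairs[0][1] + 1
        if len(aln.pairs) / max(q_span, r_span) < p.breakpoint_min_density:
            reasons_aln.append("density")
        if reasons_aln and not explain:
            continue
        ref = ref_maps[aln.ref_id]
        key = (aln.query_id, aln.ref_id, aln.orientation)
        for side, q_un, r_un, pair in (
            ("left", aln.query_left_unaligned, aln.ref_left_unaligned, aln.pairs[0]),
            ("right", aln.query_right_unaligned, aln.ref_right_unaligned, aln.pairs[-1]),
        ):
            if q_un < p.trailing_k or r_un < p.trailing_k:
                continue
            reasons = list(reasons_aln)
            if _continuation(aln, pair, side):
                reasons.append("continuation")
            if explain:
                verdicts.append(
                    {
                        "ref": aln.ref_id,
                        "position": float(ref.labels[pair[1]]),
                        "channel": aln.channel,
                        "query": aln.query_id,
                        "orientation": aln.orientation,
                        "side": side,
                        "score": aln.score,
                        "emitted": not reasons,
                        "suppressed_by": reasons,
                    }
                )
            if not reasons:
                out.append(
                    Breakpoint(
                        ref_id=aln.ref_id,
                        position=float(ref.labels[pair[1]]),
                        channel=aln.channel,
                        query_id=aln.query_id,
                        side=side,
                        score=aln.score,
                    )
                )
    if explain:
        return out, verdicts
    return out


# -- TSV / BED writers --------------------------------------------------


def _encode_pairs(pairs: list[tuple[int, int]]) -> str:
    """Run-length encode co-linear (+1,+1) runs of matched index pairs."""
    runs = []
    start = prev = pairs[0]
    for cur in pairs[1:]:
        if cur == (prev[0] + 1, prev[1] + 1):
            prev = cur
            continue
        runs.append((start, prev))
        start = prev = cur
    runs.append((start, prev))
    return ",".join(
        f"{a[0]}-{b[0]}:{a[1]}-{b[1]}" if a != b else f"{a[0]}:{a[1]}" for a, b in runs
    )


def write_alignments_tsv(alignments: list[MapAlignment], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("query\tref\tchannel\torientation\tscore\tn_pairs\tpairs\n")
        for a in alignments:
            fh.write(
                f"{a.query_id}\t{a.ref_id}\t{a.channel}\t{a.orientation}\t"
                f"{a.score:.3f}\t{len(a.pairs)}\t{_encode_pairs(a.pairs)}\n"
            )


def write_breakpoints_bed(breakpoints: list[Breakpoint], path: str) -> None:
    """0-based half-open BED; name = channel:query:side, score = alignment score."""
    with open(path, "w") as fh:
        for b in sorted(breakpoints, key=lambda b: (b.ref_id, b.position)):
            start = int(b.position)
            fh.write(
                f"{b.ref_id}\t{start}\t{start + 1}\t{b.channel}:{b.query_id}:{b.side}\t"
                f"{b.score:.1f}\n"
            )


def read_breakpoints_bed(path: str) -> list[Breakpoint]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            ref_id, start, _end, name, score = line.rstrip("\n").split("\t")[:5]
            channel, query_id, side = name.split(":")
            out.append(Breakpoint(ref_id, float(start), channel, query_id, side, float(score)))
    return out


__all__ = [
    "AlignParams",
    "Breakpoint",
    "MapAlignment",
    "align_maps",
    "detect_breakpoints",
    "interval_penalty",
    "read_breakpoints_bed",
    "write_alignments_tsv",
    "write_breakpoints_bed",
]
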
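# Methods

## Problem and model

Hi-C scaffolding orders and orients contigs statistically from chromatin
contact frequencies, and therefore occasionally joins sequences that are
not adjacent in the genome (misplacement, misorientation, chimeric fusion).
Optical genome mapping images long DNA molecules labelled at
nicking-enzyme recognition motifs, producing ordered label-position maps
that measure physical structure directly. `junctionqc` implements the
validation logic that compares the two: scaffolds are digested in silico
into label maps, optical consensus maps are aligned to them, positions
where the label patterns stop agreeing are called as conflicts, conflicts
are classified relative to the gaps the scaffolder introduced, confirmed
misjoins are cut, and every Hi-C junction is independently tested for
long-read spanning support.

The package ships a first-class synthetic-data generator so the whole
pipeline can be exercised with exact ground truth: recall and precision of
conflict calling are measurable because every injected misjoin is
recorded.

## In-silico digestion

A label is placed at the 0-based first base of every exact occurrence of
the enzyme motif or its reverse complement on the forward strand (a
nicking enzyme recognises its site on either strand; `N` never matches).
The enzyme's nick offset is chemistry, not geometry, and is not applied:
conflict calling needs consistent positions across sequences and maps.
Site runs closer than `min_label_distance` (default 1000 bp, emulating the
optical resolution limit) are collapsed left-to-right to the midpoint of
the run. CMAP v0.1 is read and written with positions 1-based at one
decimal, multi-channel records carrying per-row channel codes and a
LabelChannel-0 map-end sentinel.

## Label-map alignment

Maps are aligned as ordered label lists by a local dynamic programme over
label indices. Matching query label *i* to reference label *j* after a
previous pair earns `match_bonus` minus a sizing penalty
`(Δ)² / (σ² · max(r,1000)/1000)` on the implied interval pair (the squared
z-score under the square-root-length sizing model, with the reference
interval floored at 1 kb), minus `miss_penalty`/`false_penalty` per
skipped reference/query label (at most `lookback` per step). Both query
orientations are scored; a jitted kernel computes the matrix, with a
pure-numpy reference implementation kept alongside.

Chains are segmented by an X-drop rule: a segment ends at its running
score peak whenever the cumulative score falls `xdrop` below that peak —
the signature of a chain paying its way across a region where the maps
disagree. Segments are accepted greedily by score, non-overlapping on the
query per orientation (per orientation because label maps are
strand-symmetric: an inverted segment's true alignment lives in the other
orientation and must not be blocked by forward coverage). One reference
region may attract several queries (e.g. both haplotypes).

### Why the scoring constants are what they are

With sizing noise of σ = 400 bp/√kb on labels spaced ~2 kb, two unrelated
label maps "match" a surprising fraction of the time: the per-interval
information content is below one nat, and a local aligner with a generous
match bonus accumulates score through unrelated material. Two properties
restore control. First, `match_bonus` (2.2) is set so genuine chains gain
roughly +1 per step while the best chance chains drift near zero — their
segment scores are then capped on the X-drop scale instead of growing
linearly. Second, breakpoints are only accepted under corroboration (next
section). `miss_penalty`/`false_penalty` (3.0) price a skipped label
around its log-odds under 10% dropout, and `lookback` = 5 tolerates runs
of four consecutive missing labels, which at 10% dropout still occur a few
times per hundred maps.

## Breakpoints and artifact suppression

An accepted alignment end emits a breakpoint when at least `trailing_k`
(5) labels remain beyond it on **both** maps — the maps keep going but
stop agreeing — and the alignment passes the confidence gates
(score ≥ 25, matched fraction of the spanned label range ≥ 0.6). The
breakpoint sits at the reference position of the last matched label:
conservative and always label-anchored.

Two artifact classes are suppressed:

* **Collinear continuation.** If another segment of the same query and
  orientation resumes where the broken chain would have continued (within
  `continuation_tol` = 20 kb of the extrapolated position), the chain was
  split by sizing noise or a mis-sized gap, not a rearrangement, and the
  end is silent. Resumption elsewhere — the displaced-material signature —
  keeps the breakpoint.
* **Cross-channel spanning veto.** After clustering, any conflict whose
  position is still spanned collinearly by a strong alignment (score ≥ 30,
  at least 6 matched labels within 100 kb on each side, scaled down near
  map ends) is discarded: one enzyme channel's chain may fray, but the
  other channel — statistically independent — still spans the locus,
  whereas no single alignment can span genuinely foreign material. This is
  the dual-enzyme cross-check applied as a veto rather than a requirement,
  so single-channel evidence still counts at junctions the sparser channel
  cannot resolve. Conflicts within 50 kb of a scaffold end are not called
  at all: alignments always fray at map termini.

## Conflicts, classification, cutting

Breakpoints on a scaffold are clustered by single linkage within
`merge_window` (50 kb); each cluster becomes one conflict at the median
position with the union of enzyme channels (dual-channel support is
flagged; requiring it is optional and off by default). Conflicts are
classified against Hi-C gaps: within `near_distance` (50 kb) of a gap and
not explained by sizing → `NEAR_GAP_STRUCTURAL`; spanned cleanly but with
an implied physical size departing from the declared length by more than
`max(10 kb, declared)` → `GAP_SIZE_ONLY`; otherwise `INTERNAL`. Structural
and internal conflicts cut the layout — a near-gap cut removes the gap
filler and splits the scaffold, an internal cut splits the containing
contig — conserving contig bases exactly and never increasing scaffold
N50.

Implied gap sizes are computed from the difference of query-minus-
reference offsets between the two flanks of a gap, using the outer half of
a 60 kb window per side: an aligner absorbs a mis-sized gap as a staircase
of slightly off-register matches at the junction, so nearest-label
distances are biased while outer-flank offsets are clean. The estimate is
exact at zero noise and unbiased under the sizing model. Measuring a
grossly mis-sized gap requires a sizing-tolerant alignment pass (large
`xdrop`), since the standard parameters deliberately sever chains at such
discrepancies.

## Read support

A Hi-C junction is supported by a read only if a *single primary* record
covers the gap with `min_anchor` (1 kb) aligned on both sides at mapping
quality ≥ 20; split fragments never combine — a read split across a
junction is evidence against it. Junctions are classed UNSUPPORTED (0
spanning reads), WEAK (1–4) or SUPPORTED (≥ `strong_min` = 5), and
summarised as counts with percentages rounded to the nearest integer.

## Assembly statistics

N50 (and general Nxx) follows the cumulative-sum convention on lengths
sorted descending. The summary covers total/scaffold/unplaced lengths and
counts, gap counts and sizes, and per-length-bin misjoin involvement with
floor percentages. Published summary tables mix rounding conventions, so
`percentage_summary` takes the mode (`nearest` or `floor`) as an explicit
argument, never a hidden default.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
with defaults that define the standard experiment:

* genome: 5 Mb in 2 chromosomes, uniform base composition;
* contigs: 40, minimum 50 kb, partitioning each chromosome; true
  inter-contig gaps are Normal(600, 200) bp (a plausible scale for gaps a
  proximity-ligation scaffolder closes between long-read contigs; no
  published value exists) — the observed layout replaces every gap with a
  fixed 100 bp filler tagged "HIC", reproducing the user-determined fixed
  gap length behaviour of Hi-C scaffolders;
* misjoins: 4 translocations (two non-adjacent placements swapped), 2
  inversions (one placement flipped), 2 fusions (tails exchanged between
  scaffolds), placed so edits do not interfere with each other's recorded
  junctions; every edit is recorded with the contigs involved, and
  `junction_truth` labels each observed junction correct or misjoined from
  first principles;
* optical maps: per enzyme channel (Nt.BspQI GCTCTTC, Nb.BssSI CACGAG),
  starting from the exact digest of the *true* chromosome; each interval
  gets Gaussian noise with SD 400·√(L/1000) bp, labels drop independently
  at 10%, false labels arrive at 0.5 per 100 kb;
* reads: lognormal lengths (median 15 kb, shape 0.55 — a long-read-like
  distribution), uniform starts, 30× coverage, emitted directly as PAF in
  observed-scaffold coordinates and split wherever the read's true locus
  is discontiguous in the observed layout, so no external aligner is
  needed. A junction joining truly adjacent contigs acquires
  single-record spanning reads; a misjoined junction acquires none by
  construction.

What the generator does **not** model: sequence-level read errors,
optical-molecule assembly (consensus maps are produced directly), Hi-C
contact matrices, repeats and low-complexity sequence, haplotypes.
Passing tests therefore demonstrate the validation logic under the stated
noise model, not performance on repeat-rich real genomes, where both
chance alignment and read mapping are harder.

## Problem sizes and determinism

The standard experiment (5 Mb, two channels) validates in a few seconds;
the null experiment repeats it over twenty seeds. All randomness flows
through `numpy.random.Generator` seeded from the configuration, and every
writer is byte-deterministic for a fixed seed. Degenerate inputs (empty
maps, empty assessments, zero denominators, coordinates outside their
scaffold) raise typed errors (`ConfigurationError`, `FormatError`,
`CoordinateError`, `UndefinedStatisticError`).

## Known limitations

* Detection power is bounded by label density: with σ = 400 bp/√kb, a
  junction is only callable when a flank carries roughly 15+ labels, so
  misjoins between very short contigs may be visible in the dense channel
  only, or not at all. The acceptance experiment's 7–8 of 8 recall
  reflects this physics, not a tuning target.
* Misjoins within ~50 kb of a scaffold end are excluded by the
  terminal-fray margin.
* A misjoin whose displaced material happens to resume collinearly within
  20 kb of the expected continuation would be suppressed as a noise split;
  with megabase-scale displacement this is vanishingly rare.
* The conflict caller reports both raw breakpoint and clustered conflict
  counts, since published conflict counts do not define their unit.
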
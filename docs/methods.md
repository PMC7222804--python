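# Methods

## Problem and overall procedure

Animal mitochondrial genomes deposit the light (L) strand as the reference
sequence; the heavy (H) strand is its reverse complement. `mtcpg` maps two
kinds of CpG signal on both strands of such genomes:

1. **CpG islands** — contiguous regions that satisfy the classic
   composition criteria (observed/expected CpG ratio ≥ 0.6, %C+%G ≥ 50,
   length ≥ 200 bp), found with a sliding window;
2. **CpG-rich regions** — maximal-scoring segments of a running sum that
   rewards CG dinucleotides and penalises everything else, which
   deliberately over-predicts and therefore also captures short CpG
   clusters in tRNA genes and replication origins.

Detections made on the H strand are mapped back into reference coordinates
(`pos' = L − pos + 1` applied to both ends), attributed to annotated
features by ≥ 1 bp overlap, and aggregated into per-gene, per-strand
CpG-site count tables and cross-species comparisons.

The observed/expected ratio over a window or region of length N is

    obs/exp = N_CpG · N / (N_C · N_G)

with the convention that it is 0 when C or G is absent. Because the
reverse complement of CG is CG, genome-wide CpG counts are strand
symmetric; per-strand differences in the tables arise from windowing and
edge effects, not from the statistic itself.

## Island caller

A window of `window` bp (default 100) advances by `shift` bp (default 1).
Each window's %C+%G and obs/exp are attributed to its **midpoint** base
(`start + window//2`); a base passes when both attributed values meet the
thresholds, and maximal runs of passing bases of at least `min_length` bp
(default 200) become islands. Island-level `cg_sum`, %C+%G and obs/exp are
then recomputed over the island subsequence — those are the values
reported, rounded half-up to 2 decimals.

Notes on this design:

* Thresholds are **inclusive** (≥ 0.6, ≥ 50 %, ≥ 200 bp). Published
  island tables contain rows sitting exactly on these bounds (a 200 bp
  island; a 50.00 %C+%G island), so strict inequalities would be wrong.
* Midpoint attribution leaves the first and last `window//2` bases of a
  linear sequence without a verdict. This is the mechanism that makes
  island calls near the sequence ends differ between the two strands.
  The alternative `cover` attribution (every base of a passing window is
  flagged) is available via `ScanParams(attribution="cover")` or
  `--attribution cover`; `scripts/emboss_diff.py` compares either
  convention against the original EMBOSS implementations when those are
  installed.
* Emitted islands are not re-filtered on their recomputed aggregate
  statistics. In practice aggregates of called islands satisfy the
  thresholds comfortably; re-filtering would silently diverge from the
  reference tools' behaviour.
* Sequences are treated as linear by default. `circular=True` also
  evaluates windows spanning the origin; an island that itself spans the
  origin is reported as two runs (a known limitation).
* Flagged runs separated by even a single unflagged base are distinct
  islands; there is no merge-gap parameter.

## Running-sum region seeker

Every position that starts a CG contributes `+cpg_score` (default +17);
every other position contributes `-gap_penalty` (default −1). The detector
reports maximal-scoring segments whose total reaches `threshold` (default
17, inclusive; `strict=True` switches to a strict inequality) by recursive
subdivision: find the best segment of the range (Kadane's algorithm; ties
resolve to the leftmost start, then the shortest segment), report it if it
passes, then recurse into the left and right flanks. Child segments never
out-score their parent, which gives threshold monotonicity: raising the
threshold can only remove regions.

Maximal segments necessarily begin at the C of a CG and end at the G of
one — trimming a penalty position off either end would raise the score —
so a lone CG in depleted background scores exactly 17 and is reported
under the inclusive default. That is intended: this detector's purpose is
sensitivity, and per-region CpG counts summed per strand are the
strand-total statistics of the comparative tables. With the default
constants a region tolerates runs of up to 16 non-CG positions between
CpGs before it pays to split, which is what lets ~16 bp regions with 3
CpGs inside tRNA clusters surface as single regions.

## Annotation and summaries

A region is attributed to every annotated feature it overlaps by at least
1 bp. Regions overlapping ≥ 2 features are *multi-feature*: they appear
once in the multi-feature table and contribute their whole CpG count to
the strand total, but to no single gene's cell — the same separation the
comparative literature draws between per-gene counts and boundary-spanning
clusters. Regions overlapping nothing (or only explicitly intergenic
annotations) count under an `intergenic region` row. This makes the
bookkeeping conservative: each region contributes exactly once, and the
strand total always equals the seeker's `region_sites()` for that strand
(asserted in tests).

Origin-wrapping features (e.g. a vertebrate D-loop spanning the sequence
origin) are split into two spans for overlap queries but remain one
feature; locus names are canonicalised through a bundled synonym map
(`tRNA-Trp` → `TRNW`, `s-rRNA` → `12s rRNA`, ...), with unmapped names
passed through and warned about.

## Synthetic genomes

The generator emulates what the detectors care about in a mitochondrial
genome: overall size (default 16 500 bp), CpG-depleted background
composition (default GC 0.40, obs/exp 0.25 — typical of the genomes this
kind of scan is run on), planted islands of controlled contrast, and the
canonical vertebrate gene order (22 tRNAs, 2 rRNAs, 13 protein genes,
D-loop, O_L between TRNN and TRNC) for annotation tests.

The background is a first-order Markov chain constructed analytically:
with target composition π = ((1−gc)/2, gc/2, gc/2, (1−gc)/2) over
(A, C, G, T), the C→G transition is set to `oe·π_G`, the G-column of the
other rows is rescaled by β = (1 − oe·π_C)/(1 − π_C), and every row's
remaining mass is spread over the other bases proportionally to π. One can
check that π is then *exactly* stationary, so empirical GC and obs/exp hit
their targets up to sampling noise for any feasible (gc, oe) pair;
`oe = 0` forcibly generates zero CGs. Islands are planted by regenerating
a slice with island-specific (gc, oe) — replacement, not insertion, so all
truth coordinates stay stable. All randomness flows through
`numpy.random.default_rng([seed, stream])`; no global state, and identical
specs give byte-identical FASTA.

What the generator does **not** emulate: codon structure and amino-acid
constraints of real protein genes, strand-asymmetric composition
(GC-skew) of real mtDNA, tRNA secondary-structure sequence bias, and
NUMT-like repeats. Passing recovery tests therefore demonstrate detector
correctness on genomes with realistic first-order composition, not
performance on every idiosyncrasy of real sequences.

## Detectability margins for planted islands

A planted island of length ℓ with composition (gc, oe) is recovered iff a
≥ 200-base run of window midpoints passes both thresholds. Window %C+%G
has standard deviation ≈ √(gc·(1−gc)·100) ≈ 5 percentage points, so
islands planted near gc 0.55 sit ≈ 1 sd above the 50 % threshold and
*will* occasionally dip below it somewhere along the run, splitting or
eroding the call — no correct detector can achieve certain recall there.
The recovery tests therefore plant at ℓ = 600, gc = 0.62, oe = 1.4: a
single interior dip still leaves a ≥ 200 bp fragment (so recall stays 1.0)
while total misses would need two well-placed dips, which has negligible
probability. Boundary accuracy is ± window bp in the absence of interior
dips and is asserted tightly only for deterministic plants (alternating
CG blocks); for stochastic plants the tests assert containment within
truth ± window and the acceptance script reports the measured mean
boundary error (typically ≈ 40–50 bp).

## Numerical and edge-case conventions

* Coordinates are 1-based inclusive everywhere inside the package and in
  reports; BED converts at the boundary (0-based half-open).
* Characters outside {A, C, G, T} are normalised to N; N is neither C nor
  G and never forms a CpG.
* Report percentages and ratios are rounded half-up to 2 decimals;
  internal values stay unrounded.
* A CG spanning the linear-sequence end is not counted (linear mode);
  `circular=True` counts it and scores the wrap position.
* Degenerate inputs: empty FASTA, zero-length sequences, windows longer
  than the genome, features outside the genome and overlapping planted
  islands all raise typed errors (`InputFormatError`, `CoordinateError`,
  `ParameterError`).

## Problem sizes used by the test suite and acceptance script

The property suite runs the detectors against brute-force oracles on 200
random genomes of 10–2000 bp each, strand-symmetry and coordinate
involution checks on 1000 random instances, generator fidelity over
25–50 seeds of 16.5 kb, and planted recovery over 20 seeds with two
islands per genome — sizes chosen so the whole suite completes in well
under two minutes while keeping every estimate's sampling error far below
the asserted tolerances. `scripts/acceptance.py` re-runs the same study
from scratch in a few seconds.

## Known limitations

* Exact reproduction of published island tables depends on the original
  tools' undocumented edge conventions; the two attribution rules and the
  differential script bound that uncertainty but cannot remove it without
  the original binaries and the reference sequences (which users must
  fetch themselves — see `scripts/fetch_references.py`).
* Circular mode does not merge an island that spans the origin into one
  wrapped interval.
* Group comparisons (vertebrate vs invertebrate means) are descriptive;
  no statistical test or phylogenetic correction is attempted.
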
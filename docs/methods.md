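# Methods

This note records the models, algorithms, parameter choices and known
limitations of `nanomap`. It describes what the code does and why; every
number quoted as a result elsewhere is computed by the test suite or by
`scripts/acceptance.py`, not here.

## In-silico digestion

A nicking endonuclease cuts one strand, but after nick translation the
fluorescent label is visible on the molecule regardless of which strand
carried the site. The scanner therefore reports the union of forward-strand
and reverse-complement motif occurrences, as 0-based positions of the
occurrence's leftmost base (the platform literature does not fix a
convention; this one is pinned and tested). Overlapping occurrences count
separately; windows containing `N` never match.

Optical resolution is modelled by merging: maximal chains of sites whose
successive gaps are all strictly below `resolution_bp` (default 500)
collapse to a single label at the midpoint of the chain's extremes. This
rule is idempotent and guarantees all output gaps ≥ `resolution_bp`; the
strictness of the comparison and the midpoint representative are module
decisions (only "closer than the resolution" is externally given). Label
density consequently never exceeds nick density.

Aggregate densities over a sequence collection are pooled counts over
pooled length, never the mean of per-record densities, making them
invariant to how a genome is split into records.

The shipped enzyme catalog contains only Nt.BspQ1 → `GCTCTTC`; other
enzymes' recognition sequences must be supplied by the caller. Enzyme
selection minimizes |label density − target| with a default target of 10
per 100 kb; the expected whole-genome fluctuation band around a pilot
estimate is ±15 %.

## Synthetic genomes

`simulate_genome` draws i.i.d. bases at a configurable GC content (default
0.41, typical of teleost fish genomes) and plants motif copies at Poisson
spacings on top of the background occurrences. Planting rates are solved
analytically: the double-strand background rate is `2·p(motif|GC)` per bp,
thinned by `exp(-rate·resolution)` for the resolution merge; single copies
raise label density, and close pairs (two sites 12–490 bp apart, which
merge into one label) raise nick density without raising label density,
so both a target label density and a target nick density can be matched.
A rescan after planting warns when the realized density misses the target
(e.g. when the target lies below the background rate, which planting
cannot fix). Realized densities fluctuate with sampling, roughly ±1 per
100 kb at 2 Mb.

## Molecule length law

Lengths follow a log-normal truncated at `min_len` (default 100 kb, the
platform's validity filter). Only the minimum, the N50 (~176 kb) and a
heavy tail are externally constrained, so the log-sd is fixed at 0.55 and
the log-mean is calibrated by root-finding on the closed form
`E[X·1(X≥a)] = exp(μ+σ²/2)·Φ((μ+σ²−ln a)/σ)`: the distribution's N50 is
the length t at which the upper-tail mass halves, and μ is chosen so that
t equals the target. Sampled N50 lands within a few percent of the target
at realistic dataset sizes. Intervals are placed uniformly; sampling stops
once the summed length reaches `depth × genome length`.

## Measurement error model

`corrupt_molecule` applies, in order:

1. **false negatives** — each true label dropped with probability
   `fn_prob` (default 0.15);
2. **false positives** — Poisson(`fp_rate`·length/10⁵) uniform labels
   (default 1.5 per 100 kb);
3. **sizing noise** — every inter-label gap (including both flanks)
   perturbed by N(0, s₀²·gap) with s₀ = 5 bp^½ and re-accumulated, the
   standard square-root error law for fluorescent length measurement;
4. **stretch** — one multiplicative factor per molecule,
   N(`stretch_mean`, `stretch_sd`²) (defaults 1.008 and 0.01): molecules
   are uniformly stretched relative to the nominal pixel calibration, so a
   500 bp nominal pixel reads out as ~504 bp;
5. **pixel quantization** — positions rounded to the `bpp` grid (500 bp;
   0 disables);
6. **resolution merge** — as in digestion, pooling truth origins.

The composition order is a modeling choice (the error sources are known,
their composition is not); truth correspondence (which observed label
derives from which true labels, or none) is carried through every stage,
so false-positive and false-negative rates can be validated exactly.
Chimeric molecules and unlabelled-molecule dropout are not modelled.

Molecules whose *observed* length falls below `min_len` are rejected, as
on the real platform, where the validity filter necessarily acts on
measured lengths; sizing noise therefore cannot leak sub-100 kb molecules
into a dataset.

`validate_rates` counts observed labels with no true origin per unit
length, and dropped true labels over all true labels. Note the realized
FP rate sits slightly below the planted rate (~1.4 vs 1.5/100 kb) because
false labels that land within one resolution of another label merge into
it — a physical effect, not an estimator bias.

## Alignment scoring

Ordered-label alignment is a local DP over "query label i matched to
reference label j" states. Matching consecutively after (p, t) scores

    bonus − (Δr−Δq)²/(2·s₀²·max(Δr, res)) − c_FN·(j−t−1) − c_FP·(i−p−1)

with `c_FN = −ln(fn_penalty_prob)` (a reference label missing from the
query) and `c_FP = −ln(fp_penalty_rate·res/10⁵)` (the log-probability of a
false query label within one resolution window). `bonus` defaults to
`c_FN + c_FP`, so matching two labels always beats skipping both and the
vendor-style `-FP 1.5 -FN 0.15` parameters are meaningful as rates. Any
cell may start a chain (local alignment — consensus maps cover sequences
partially); both orientations are scored, ties prefer forward; the
predecessor window `max_skip` (8) bounds consecutive skips. The DP is
verified exactly against exhaustive enumeration of all monotone pairings
on small instances.

The **mapping length ratio** divides the aligned query span by the query's
total length. The span extends beyond the terminal matched labels by half
the gap to the next unmatched label, or by the full flank when no further
label exists — so a fully matched query scores exactly 1.0, while flanking
unlabelled DNA motivates calling alignments "thorough" already at ≥ 0.95.
Queries need ≥ 7 labels ("more than 6") to be aligned at all. Confidence
is the score margin over the best alignment disjoint from the winner's
reference span. In batch mode only each query's highest-confidence hit is
kept.

**Estimators.** The FP rate is unmatched query labels strictly inside
aligned spans per unit span; it underestimates the planted rate by a
further ~0.1–0.2/100 kb because some false labels are absorbed by merges
or matched to FN-emptied reference sites. The effective bases-per-pixel is
the origin-constrained least-squares slope of matched query gaps on
reference gaps times the nominal pixel size; it recovers planted stretch
to a few tenths of a percent.

## Consensus assembly

Overlap-layout-consensus over label patterns:

1. **Candidates.** An inverted index of quantized 3-gap fingerprints
   (500 bp bins, ±1 bin per gap, both orientations) proposes molecule
   pairs; over-popular fingerprints are skipped and each molecule keeps at
   most `max_candidates_per_mol` (80) best-sharing partners. The filter
   needs only to catch a fraction of each molecule's true strong overlaps,
   since chaining is redundant at working depths.
2. **Distance & clustering.** Candidate pairs are scored by the overlap DP
   (both orientations); distance = 1 − score/(bonus·min label count),
   clamped to [0, 1]; non-candidates get distance 1. Hierarchical
   clustering cut at `cluster_cut` (0.5) groups molecules; the default
   linkage is *single*, because molecules tile a contiguous genome and the
   correct clustering notion is connected components of the overlap graph
   (average linkage fragments a uniform tiling arbitrarily; it remains
   available as an option). Clusters below `min_molecules_per_map` (3) are
   discarded.
3. **Layout.** The longest molecule seeds the frame. Molecules are placed
   best-link-first through the candidate graph; each placement is decided
   by a *vote* of up to `max_place_checks` already-placed neighbours
   (pair alignments gated on score ≥ 25, ≥ 5 matched pairs, an orientation
   margin ≥ 4 over the opposite orientation, and a total-least-squares
   scale within 5 % of unity): the majority orientation wins and offsets
   must agree within 20 kb; at least two agreeing links are required
   whenever the molecule has more than one candidate neighbour, because a
   single spurious high-scoring link could otherwise teleport the molecule
   and seed a misassembled arm. Two further teleport defences apply: a
   placement that does not extend the current layout span must match at
   least half the molecule's labels (an interior molecule is necessarily a
   near-duplicate of covered territory), and a single-link placement must
   be confirmed by a witness molecule adjacent to both partners whose two
   independent placements agree. Placements are *unit-scale* signed affine
   maps — fitting a free scale per chained link suffers regression
   dilution that compounds multiplicatively along the layout. These
   defences make misassembly rare but not impossible: with ~17 labels per
   molecule, the score distributions of true and spurious overlaps overlap,
   and occasional layouts still fold; such maps surface as poorly aligning
   consensus rather than silent errors.
4. **Offset adjustment.** Chained offsets accumulate alignment noise as a
   random walk; every retained overlap link measures a relative offset
   free of that walk, so a weighted graph-Laplacian least-squares solve
   redistributes the error over the whole layout.
5. **Refinement.** Each molecule is re-aligned to the pooled consensus and
   its placement re-fitted — here with a free (total-least-squares) scale,
   which is safe against an averaged consensus and absorbs the molecule's
   own stretch — followed by another offset adjustment (two rounds by
   default).
6. **Peak calling.** Anchored labels are pooled, histogrammed at 100 bp
   and convolved with a Gaussian kernel (`kde_bandwidth` 500 bp). Local
   maxima become candidate labels; support is the number of distinct
   molecules with a label within the kernel scale of the peak, and a peak
   needs support ≥ `min_peak_support_frac` (0.25) of the local molecule
   coverage (and ≥ 2 molecules wherever coverage permits). The called
   position is the median of the labels at the apex; peaks closer than the
   resolution merge, keeping the better-supported one.
7. **Purge & merge.** Thin coverage or label-sparse stretches can break a
   region into several maps. Redundancy is judged at the molecule level —
   a map most of whose member molecules align well to a longer kept map
   re-assembles an already-covered locus. Near-complete duplicates (≥ 80 %
   of sampled molecules redundant) are purged first so junk cannot graft
   itself onto a good map; maps whose consensus patterns align well are
   then fused (the shorter map's placements transformed into the longer
   one's frame and re-refined); a stricter purge (≥ 60 %) mops up.

All stages are deterministic given input order and parameters; ties break
on molecule id. The result is a set of consensus maps with per-label
molecule support and mean depth.

**Depth titration** subsamples molecules without replacement to a target
total length and re-assembles with identical parameters. Within a
replicate the subsets are nested (prefixes of one random order), so depth
effects are not confounded with resampling noise across depths.

## Problem sizes used in the tests

The packaged tests exercise the pipeline at desk scale: unit tests on
genomes of 0.4–1 Mb, the round-trip and recovery checks on 5 Mb genomes at
80–100X (a few thousand molecules), and the titration on a 10 Mb genome at
20–80X across three replicates. These sizes keep the full suite in the
tens of minutes while leaving every stage's statistics (hundreds of labels,
thousands of molecules) well out of the small-sample regime.

## What the simulation does and does not show

The generator reproduces the *measured statistics* of a real nanochannel
run — length law, label density, FP/FN rates, sizing noise, stretch,
resolution — on genomes of i.i.d. background with Poisson-planted sites.
It does not reproduce long repeats, segmental duplications, heterozygous
structural variation, fragile-site breakage, chimeric molecules, or
locus-dependent labelling efficiency. Passing the recovery tests therefore
shows the pipeline's correctness and noise robustness, not its performance
on repeat-rich real genomes, where clustering purity and layout voting
would face genuinely ambiguous overlaps. Consensus coordinates also retain
a smooth residual warp (hundreds of bp over megabases) from accumulated
placement noise; accuracy statements are made through alignment-based
(piecewise) coordinate mappings, as is standard for map-to-sequence
comparison.

## Numerical and degenerate-input decisions

- Positions are floats in bp; formats round to 0.1 bp and writers are
  byte-deterministic.
- Molecules with < 2 labels cannot be placed and are reported as
  discarded; a cluster of one molecule yields that molecule as its map.
- `apply_resolution` on an empty list returns an empty list; digesting an
  empty record collection reports densities as absent rather than 0.
- Sizing noise floors perturbed gaps at 1 bp to preserve label order;
  stretch factors are floored at 0.5.
- The DP treats `s₀ = 0` as an effectively exact sizing requirement
  (guarded denominator) rather than dividing by zero.
- Seeds: every stochastic entry point takes a seed or Generator;
  per-molecule streams derive from (seed, molecule index) so datasets are
  reproducible molecule by molecule.
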
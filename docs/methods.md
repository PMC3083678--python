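# Methods notes

This note records the modelling and numerical decisions behind `landbound`,
the reasoning where a choice was genuinely open, and what the shipped tests
do and do not demonstrate.

## The simulator

**Model.** A bounded `grid_width x grid_height` lattice (default 100 x 100)
with exactly one diploid, hermaphroditic, selectively neutral individual per
cell.  Generations are synchronous and non-overlapping.  For every cell of
the new generation, two parents are drawn independently from the previous
generation; each transmits one uniformly chosen allele per locus (loci are
unlinked), and every transmitted allele mutates with probability `mu` to an
allelic state never seen before at that locus (infinite alleles).  There is
no selection, no sex, no overlapping generations, and density is perfectly
regulated at one individual per cell.

**Dispersal.** A parent for cell `(x, y)` is drawn from a bivariate normal
centered on the cell with independent per-axis scale `sigma`, rounded to the
nearest cell.  The Euclidean parent-offspring distance is therefore
(before rounding) Rayleigh distributed with mean `delta = sigma*sqrt(pi/2)`
and standard deviation `sigma*sqrt(2 - pi/2)`; the user-facing parameter is
`delta`, the mean dispersal distance in cells.  Draws that fall outside the
lattice are rejected and the whole draw is repeated — the landscape is
bounded, not toroidal, and clamping would artificially inflate edge density.
The focal cell itself is always acceptable, so the rejection loop
terminates.  Because the two parent draws are independent, an individual can
be drawn twice: selfing is allowed, the simplest rule consistent with a
hermaphroditic lattice model.

**Barrier.** The active barrier splits the lattice along its two midlines
into four equal quadrants (`quadrant = (x >= W/2) + 2*(y >= H/2)`,
0-based cells, so the vertical line sits at map coordinate `W/2 - 0.5`).
Permeability is enforced per attempted parent draw: a drawn parent in a
foreign quadrant is kept with probability `b`, otherwise both coordinates
are redrawn.  `b = 0` makes the quadrants completely independent
demes from the moment of imposition; `b = 1` is distributionally identical
to no barrier.  The generation clock restarts at 0 when the barrier is
imposed, and the generation-0 export is the pre-barrier state.

**Mutation bookkeeping.** Each of the `W*H*L*2` transmissions per
generation is an independent Bernoulli(`mu`) trial.  The kernel walks this
stream with exact geometric skips (`floor(log U / log(1-mu))`), so the cost
of mutation handling is proportional to the number of mutations, not the
number of transmissions, without changing the distribution.  New allele IDs
are consecutive per locus; `next_allele_id` never decreases, which makes the
infinite-alleles freshness guarantee testable.

**Randomness.** One master seed drives everything.  Replicate `r` derives
three independent streams (burn-in, post-barrier, sampling) via
`SeedSequence(master, spawn_key=(r, phase))`.  Matched-seed comparisons
across permeabilities re-use the same burn-in lattice and the same
post-barrier stream, so the `b = 0` and `b = 0.03` trajectories differ only
through the barrier's effect on accepted draws.  The per-generation kernel
is JIT-compiled (numba) and consumes the generator in a fixed order, so runs
are exactly reproducible.

**Burn-in and equilibrium diagnostics.** Starting from identical
homozygotes, the lattice runs `burn_in_generations` steps (20,000 at
`mu = 1e-4`, 80,000 at `mu = 2.5e-5` in the shipped presets — low mutation
rates equilibrate more slowly).  `run_burn_in` records lattice-wide allele
number and gene diversity at checkpoints and logs an advisory warning when
the end state deviates more than three standard deviations from the
panmictic expectations (Ewens sum for the allele count, `theta/(1+theta)`
with Stewart's variance for diversity).  The warning is advisory because
strong spatial structure (small `delta`) legitimately raises both: a
`delta = 1` lattice holds many more, more localised alleles than a panmictic
population of the same size.

**What the generator does and does not emulate.** It reproduces the
statistical signatures that matter for boundary detection — equilibrium
diversity set by `theta = 4*N*mu`, isolation by distance controlled by
`delta`, and the progressive among-quadrant divergence after barrier
imposition — under ideal conditions: uniform sampling, no genotyping error,
no missing data, perfectly codominant loci, stationary demography, and a
barrier that appears instantaneously.  Passing benchmarks here therefore
bounds a method's performance from above; real data add noise sources the
generator deliberately omits.

## Summary statistics

- **Gene diversity** uses Nei's unbiased correction
  `(2n/(2n-1)) * (1 - sum p^2)` per locus, averaged over loci — standard
  for samples of a few hundred gene copies.
- **F_ST** is the Weir-Cockerham (1984) variance-components estimator among
  the four quadrant groups, per allele and locus, with the global value the
  ratio of summed components.  Negative per-locus estimates are retained in
  the sums (truncation would bias the global ratio).  Groups with fewer
  than two sampled individuals are excluded with a warning.  The tests
  verify the moment formulas against an independently coded three-level
  ANOVA (mean-squares) route to 1e-10.  Note that under spatial structure
  the quadrants are not panmictic demes, so these values are descriptive
  indices, not literal island-model parameters.
- **IBD** regresses pairwise genetic distance on log Euclidean distance
  between individuals.  The default genetic distance is Rousset's
  a-statistic estimated from gene identities,
  `a_ij = (Q_w - Q_ij)/(1 - Q_w)` with `Q_w` the sample-wide
  within-individual identity; `1 - proportion of shared alleles` is the
  configurable alternative.  Published slope values for such simulations
  depend on the (unreported) distance metric, so the package's tests assert
  the slope *ordering* across conditions and the significance pattern, not
  specific slope values.  One consequence worth knowing: Rousset's
  a-statistic is identity-normalised — its IBD slope estimates neighbourhood
  size, essentially independent of the mutation rate — so only the
  non-normalised allele-sharing distance reproduces the diversity-scaled
  ordering of slopes across mutation rates; the full-scale ordering check
  uses it for that reason.  Significance is a one-sided Mantel test (positive
  association), 999 permutations of individuals, seedable; the permutation
  p-value includes the observed statistic (`(1 + k)/(1 + n_perm)`).

## Monmonier tracing

The neighbour graph is the Delaunay triangulation of sample coordinates
(duplicate coordinates are jittered by ~1e-6 with a warning; collinear
point sets are a geometry error).  Edge weights are the chosen genetic
distance, either raw or — the default for simulated landscapes — the
residual from a linear regression of genetic on geographic distance over
the graph's edges, which removes the isolation-by-distance trend before
tracing.

A barrier seeds at the largest-weight edge not crossed by any previous
barrier and grows from both ends: entering a triangle by crossing an edge,
it exits through the larger-weight one of the two remaining edges, with
ties broken toward the lexicographically smallest node pair (runs are fully
deterministic).  An end stops on reaching the convex hull, revisiting a
Voronoi vertex (loop closure), or finding all candidate edges already
crossed (meeting an existing barrier).  Geometrically a barrier is the
chain of Voronoi segments dual to the crossed edges; hull crossings are
drawn as finite outward rays and all segments are clipped to the landscape
for scoring.  The original software's exact distance metric and stopping
rule are not published; these choices are explicit substitutes.

## Wombling

For every allele at every locus, each individual carries a dosage (0, 0.5,
1).  Dosages are interpolated onto the raster by local-linear kernel
regression: at each pixel a weighted plane `(1, dx, dy)` is fitted and its
intercept taken.  Because the smoother is linear and reproduces constants,
the allele surfaces of a locus sum to exactly 1 at every pixel (tested to
1e-9).  Estimates may leave [0, 1] slightly near data edges; they are used
as-is, since clamping was observed to zero the gradients of rare localised
alleles over most of the map and thereby distort the candidate quantiles.
Pixels whose kernel neighbourhood is empty inherit the nearest informative
estimate and are flagged; a degenerate local system falls back to the
kernel-weighted mean.

The default kernel is Gaussian with scale `bandwidth/2`, truncated at three
scales; a uniform disc of radius `bandwidth` is the alternative.  Gradients
are central finite differences (one-sided at borders) with true pixel
spacing.  The systemic function is the mean Euclidean gradient norm over
all alleles.  Candidate boundary elements are selected per allele as the
pixels whose gradient norm strictly exceeds that allele's upper
`p`-quantile (`p = 0.3` flags the top 30%) — the only reading under which
the published significance test, Binomial(`n`, `p`) over the `n` alleles of
the data set, has success probability `p`.  A pixel is a significant
boundary element when its candidate count `c` satisfies
`P(X >= c) <= alpha` exactly (upper tail, no continuity correction, no
multiple-testing adjustment across pixels).

**Known behavioural caveat.**  For rare, spatially localised alleles the
truncated kernel produces exact-zero gradient plateaus, the upper quantile
collapses to zero, and the strict inequality then flags far fewer than
`p·100%` of pixels.  Candidate counts become underdispersed relative to
Binomial(`n`, `p`) and the test turns *conservative*: on strongly
IBD-structured pre-barrier data (`delta = 1`), where most alleles are rare
and localised, this implementation typically reports **no** significant
elements, whereas the software it emulates notoriously reported spurious
wide boundary areas on the same kind of data.  We scanned truncation radii
(3-6 scales and untruncated) and found no setting that reproduces those
false positives without flooding the map with significant pixels under
strong differentiation; the conservative default is retained as the
statistically defensible variant.  The same conservativeness makes the
significance mask marginal even on strongly differentiated data: thousands
of generations after an impermeable barrier (`delta = 11`, `mu = 1e-4`)
the detected elements are always precisely on the midlines, but candidate
counts sit right at the binomial threshold, so individual replicates can
return near-empty masks.  On weakly structured data (`delta = 11`) the
implementation does reproduce the documented generation-0 false positives
(border-extrapolation artifacts).

## Correctness scoring

Cluster output is correct after barrier imposition iff exactly four
clusters are estimated and the hard assignment (Q-matrices hardened by
argmax, ties to the lower index) equals the quadrant partition up to label
permutation; at generation 0 a single cluster is required.  Near-misses
(right boundaries, wrong K) count as incorrect.

Edge-method output has no K; published comparisons judged it by visual
inspection.  The package replaces that with a quantified surrogate chosen
to match the visual protocol's semantics ("were the two imposed boundaries
traced, and nothing grossly elsewhere?"):

- Detected elements are grouped (one group per traced barrier path;
  the significance mask forms a single group).  A group is *aligned* when
  at least 80% of its elements lie within `tolerance` (default 5 cells) of
  a true midline; other groups are *stray*.
- Generation > 0: correct iff at least one aligned group exists and the
  aligned elements cover at least 10% of the length of *each* midline
  within the tolerance.  Stray groups do not void correctness: the tracing
  protocol requests a fixed number of barriers (default 4), so weak
  supernumerary paths are inevitable even on perfectly detected crosses,
  and the published protocol scored such outputs as correct.  The 10%
  floor requires each boundary to be positively indicated while accepting
  that significance masks legitimately mark boundaries as patchy zones
  rather than continuous lines.
- Generation 0: correct iff nothing was detected at all.  Barrier paths
  whose clipped length falls below `min_path_length` (default 10 cells)
  count as no detection — the tracing algorithm always draws something, so
  a minimum-length rule is needed for "no boundary found" to be expressible.

All thresholds are parameters of `score_edges` / `MethodSpec`.

## Problem sizes in the shipped tests

Unit and property tests run on small lattices (8x8 to 40x40, hundreds to a
few thousand generations) where closed-form oracles apply.  The
published-scale checks in `tests/test_acceptance.py` and
`scripts/acceptance.py` run the full 100x100 landscape with 20 loci and the
full 20,000/80,000-generation burn-ins, but with 3 replicates for summary
statistics (5 for edge-method correctness) instead of the original 25 —
the comparison tolerances (three published SDs; 4-out-of-5 correctness)
absorb the extra Monte-Carlo noise of the reduced replicate counts.

## Limitations

- No overlapping generations, selection, sex-specific dispersal,
  continuous space, or more than the two fixed barrier lines.
- The wombling boundary test is conservative under strong isolation by
  distance (see above); it should not be used to argue that the original
  software would find nothing on such data.
- Monmonier's algorithm is reimplemented from its published description;
  distance metric, tie-breaking and stopping details are package choices.
- External clustering programs are not executed; only their exported
  memberships are scored.
- Percent-correct tables at 3-5 replicates carry binomial sampling error of
  tens of percentage points per cell; they reproduce patterns, not
  percentages.
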
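# Methods

This note documents the models and procedures implemented in `emscape`,
the numerical conventions they rely on, what the synthetic generators do
and do not emulate, and the design decisions made where the methods
literature leaves choices open.

## Incidence data and frequency accounting

The core container is a boolean species × site matrix tagged with an age
class. Adults (dbh ≥ 5 cm) and juveniles (dbh < 5 cm) are separate
matrices over the same site set; the *total* layer is their element-wise
union. Species and site identifiers are kept in input order; empty rows
and columns are retained in the data model and dropped (with logging) only
by the analyses that cannot use them.

Frequencies follow the conventions of the published survey table:
AF = row sum; RF = 100·AF/N sites, rounded **half-up** to integer percent
for reporting (so 31/32 → 97, 30/32 → 94, 29/32 → 91) while the unrounded
value is retained; CRF is the running sum of unrounded RF down the
AF-descending order with ties kept in input order. CRF is therefore a
prefix sum of RF, not a share of total occurrences; the two definitions
differ whenever species occupy more than one site, and the prefix-sum
form is the one this package commits to.

Age-class-exclusive accounting needs only the per-layer frequencies: a
species with total AF = 1 recorded in both layers is necessarily recorded
in both layers at that single site, so the single-site splits
(both / adult-only / juvenile-only layer) are well defined from AF triples
alone, and the same function backs both the matrix-based and the
table-based entry points.

### The packaged frequency table

`table1_fixture()` ships a transcription of the published 101-species
frequency and trait table (32 permanent monitoring sites). Growth form is
annotated from the table's markers (shrub, mistletoe, liana; unmarked
species are trees), origin from the published exotics list, and
conservation priority from the published priority list; dispersal mode is
not tabulated per species in the source and ships as `unknown`. The
transcription reproduces every printed summary statistic: 101 species,
41 families, 77 genera, 7 exotics (93% native), 8 priority species,
13 adult-only natives, 26 regeneration-only species (3 exotic), 9
single-site both-layer, 10 single-site adult-only and 17 single-site
regeneration-only species, and 36 singletons. The typeset CRF digits in
the source are corrupted and were not transcribed; CRF is recomputed.

## Elements of metacommunity structure

### Ordination

Reciprocal averaging is computed as the first non-trivial correspondence
axis: with `P = X/ΣX`, row masses `r`, column masses `c`, the SVD of the
standardized residual `(P − rcᵀ)/√(rcᵀ)` gives site scores `v₁/√c` and
species scores `u₁/√r` (standard coordinates, weighted mean 0). This is
algebraically the leading non-trivial eigenvector of the site-averaging
operator `D_c⁻¹XᵀD_r⁻¹X`, which the tests verify against a dense
eigendecomposition at 1e−8.

Conventions: the sign is fixed so that site scores correlate
non-negatively with input column order (ties: first score ≤ last); equal
scores are broken by a stable sort preserving input order; matrices whose
residual has no positive singular value (all-ones, single row/column,
empty row/column) raise a degenerate-ordination error. Matrices made of
disconnected blocks have a tied leading eigenspace: scores are then
block indicators and the axis is defined only up to rotation within that
eigenspace, which the oracle tests skip.

### Statistics

* **Embedded absences** — 0-cells strictly between the first and last
  presence of each species row along the ordinated site order, plus the
  same count down each site column along the species order. Counting both
  directions follows the MATLAB lineage of the method; a row-only mode is
  provided (`mode="rows"`).
* **Replacements** — on the range-filled matrix (every species range made
  contiguous), the count over unordered species pairs × unordered site
  pairs of mutual substitutions; computed as Σ_{i<k} a_ik·a_ki with
  a_ik = #sites where species i is present and k absent.
* **Boundary counts** — per site, the number of species ranges whose first
  or last occupied site falls there. A one-site range contributes both of
  its endpoints to its single site, so counts always sum to 2 × species.
* **Morisita's index** — MI = n·Σb(b−1)/(B(B−1)) over the boundary tallies
  b with total B; the chi-square statistic Σ(b−B/n)²/(B/n), df = n−1, is
  referred to its upper tail when MI ≥ 1 (clumping) and its lower tail
  when MI < 1 (hyperdispersion).

### Null model and tests

The "random 0" null fixes each site's observed richness and fills the
column with that many species drawn uniformly without replacement from
the pool. Every null replicate is **re-ordinated before counting** — the
observed statistics are ordination-dependent, so comparing them to
unordinated nulls would bias the z scores. Nulls can lose species that are
never drawn (rows dropped, as for the observed matrix); a degenerate null
replicate is redrawn. The default is 1000 iterations at α = 0.05, with a
mandatory seed in the CLI.

`montecarlo_test` reports z = (obs − null mean)/null sd (sample sd,
ddof = 1) and the two-tailed normal p = 2(1 − Φ(|z|)); an exact two-sided
permutation p with the +1 continuity correction is available
(`exact_p=True`). Sign conventions: *negative* z for embedded absences is
the "positive coherence" branch (fewer gaps than chance); *positive* z for
replacements is positive turnover.

### Classification

The decision tree: coherence not significant → random; significant with
more absences than chance → checkerboard. Otherwise turnover decides:
significantly positive → Clementsian (MI > 1, chi-square significant),
evenly spaced (MI < 1, significant) or Gleasonian (chi-square not
significant); significantly negative → the nested structures, with the
same trichotomy; not significant → the corresponding quasi structure,
with the sub-type chosen by the **sign** of the turnover z.

One deliberate refinement: the nested (and quasi-nested) sub-branch
evaluates Morisita's index on **species-loss boundaries** — one count per
species, the range endpoint on the species-poorer side of the axis, with
the poorer side read from the site-richness gradient so the label is
invariant under site-order reversal. In a perfectly nested matrix every
range shares its endpoint at the richest site; a both-endpoint tally would
therefore always be maximally clumped and the clumped/random/evenly-spaced
distinction among nested structures would be undecidable. Only the spacing
of species loss discriminates them, which is what the nested branch of the
framework describes. The positive-turnover branch keeps the both-endpoint
tally.

### Calibration

`coherence_rejection_rate` draws observed matrices from the random-0 null
itself and measures the two-tailed rejection rate of the coherence test — a
type-I error check. The packaged experiment uses a 15-species × 10-site
richness template (site richness 3–8), 10 000 replicates at 99 null
iterations, and lands within 0.05 ± 0.02. Sizes were chosen so the whole
experiment runs in minutes on one core; the rate is insensitive to the
richness template in the ranges tried.

## Synthetic metacommunities

Generators build each idealized structure in its natural row/column order,
apply cell-flip noise, then randomly permute rows and columns — so
recovering the label genuinely exercises the ordination, not just the
counters. All are seed-reproducible. Defaults (30 species × 20 sites)
match the recovery experiments.

* **clementsian** — block-diagonal compartments (balanced splits of
  species and sites).
* **gleasonian** — contiguous ranges of iid random width (20–45% of the
  gradient) at iid random positions. A draw whose realized boundaries are
  significantly clumped or evenly spaced (Morisita chi-square p < 0.25 in
  the built order) has, by definition, realized a different idealized
  pattern and is redrawn.
* **evenly_spaced** — equal-width ranges (≈ n/3) with maximally staggered
  starts.
* **nested_\*** — ranges share the rich-side end; widths set the loss
  boundaries: a few discrete width classes (clumped), iid uniform widths
  (random; conditioned, like the Gleasonian generator, on the realized
  loss boundaries being non-significant), or widths spread evenly over
  1..n (evenly spaced).
* **checkerboard** — species pairs that never co-occur, with no
  compositional gradient. Randomly placed exclusive pairs still contain
  incidental gradient structure that reciprocal averaging exploits as well
  in the observed matrix as in its nulls, which hides the exclusion; the
  idealized checkerboard has *no* gradient, so the generator starts from
  balanced exclusive pairs (per-species range size ≈ √(2(n+1))−1 cells,
  the size maximizing the span-versus-fill contrast) and anneals
  single-presence moves — preserving pair exclusivity, per-species fill
  and site coverage — to minimize the leading correspondence eigenvalue,
  i.e. the amount of one-dimensional gradient left in the matrix.
* **random** — iid Bernoulli occupancy at a configurable fill (default
  0.3, comparable to the structured generators' mean fill).

At zero noise each generator is recovered as its own label in ≥ 90% of
seeds (50 seeds, 200 null iterations; most structures 98–100%). The
residual misclassification is intrinsic to the decision tree: a Gleasonian
matrix must pass two significance tests and then *fail* the boundary
chi-square, which happens at rate ≈ 1 − α even for perfectly calibrated
draws, and the ordination's occasional local misordering concentrates a
few filled-range endpoints on the same site.

What the generators do **not** emulate: real surveys have uneven species
prevalence (the null draws species equiprobably, matching the random-0
assumption rather than field data), spatial autocorrelation between
sites, observation error correlated within sites, and mixtures of
structures across compartments. Passing recovery tests therefore shows the
machinery identifies clean idealized patterns at survey-like sizes, not
that any field matrix of this size yields an unambiguous label.

## Landscape metrics

Raster conventions follow the FRAGSTATS definitions the printed equations
abbreviate: patches are 8-connected components of one class; like-pair
joins (AI) and inter-class edges (LSI, IJI) are counted under rook
adjacency, each cell pair once; perimeters and the total edge length E*
include raster-boundary and nodata edges (a switch excludes the boundary).
Two printed equations omit square roots that their own "equals 1 for a
compact square" interpretation requires; the implemented forms are the
standard raster ones, LSI = 0.25·E*/√A and SHAPE = 0.25·P/√a, which make a
solid square exactly 1.

Choices worth noting:

* AI's maximum join count uses the compact-block rule (n = ⌊√a⌋,
  m = a − n²: 2n(n−1), +2m−1 if 0 < m ≤ n, +2m−2 if m > n); a single-cell
  class reports AI = 100 by convention. Landscape AI is the area-weighted
  mean of class AIs.
* IJI is NaN (never 0) when fewer than three classes are present or the
  focal class shares no edge.
* ENN_MN takes, per patch, the minimum centre-to-centre distance between
  its edge cells and those of any other same-class patch, and averages the
  per-patch minima; NaN with fewer than two patches.
* SHEI is 0 for a single-class landscape.
* Water and urban classes are accepted in rasters but masked out of the
  per-site report by default, and a circular mask utility clips buffers
  (cells whose centres fall within the radius); geo-referencing beyond the
  cell size is out of scope.
* PARA is scale-dependent (halves when the cell size doubles); SHAPE is
  scale-free. Both are reported for the focal native-forest patch, by
  default the largest one.

## Community similarity

Jaccard similarity on incidence (two empty communities defined as
identical, J = 1); pairwise overlap uses the **Morisita–Horn** form,
which is well defined for 0/1 data, instead of the abundance-based
Morisita index the name usually denotes — with incidence-only input the
classic form's unbiased correction is unavailable. Distances are haversine
great circles (Earth radius 6371 km). The combined site matrix prints
distances (km, 1 decimal) below the diagonal and overlap (2 decimals)
above, rows ordered by distance from a reference site (the first site by
default).

## Known limitations

* Only the first ordination axis is used; metacommunities structured along
  two gradients are outside the classification's scope (and are exactly
  what the checkerboard generator exploits).
* The normal approximation for Monte-Carlo p-values is adequate at the
  default 1000 iterations but coarse below ~100; use the exact permutation
  option for small runs.
* The boundary chi-square assumes independent boundary placement; for very
  small B (few species) its tails are discrete and conservative.
* Raster metrics assume square cells and treat the grid as planar; no
  projection handling.
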
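# Methods

## Scope and model overview

`astrotile` analyses the branch morphology and territory organization of
cultured astrocytes. Mature astrocytes co-cultured with neurons ramify
into deep multi-order branch trees and *tile*: each cell occupies an
exclusive territory, and branches only rarely touch or extend over
("override") branches of a neighbouring cell. The package implements the
measurement side (skeletonization, branch-graph extraction, topological
branch orders, branch counts/lengths, bounding-rectangle coverage,
tiling-violation statistics, time-course statistics) and, because no
imaging data are publicly deposited for this preparation, a synthetic
ground-truth generator that reproduces the qualitative phenomenology:
tiled territories under contact repulsion, overlapping territories
without it, and excitotoxic retraction with exploratory regrowth.

## The growth model

The generator is an agent-based tip-extension model on a continuous 2-D
plane. It is deliberately phenomenological — cultured astrocytes are
observed to extend branches into unoccupied space, and the model encodes
exactly that observation as a candidate-rejection rule rather than a
force field:

* Somata are placed by dart throwing at a minimum spacing
  (`soma_min_spacing`); each cell starts `primaries_per_cell` tips at
  evenly spaced headings.
* At every step each active tip draws up to `n_candidate_dirs` candidate
  headings (previous heading + Gaussian noise, s.d. `angle_noise_sd`)
  and extends by `step_length` along the first acceptable one. A
  candidate is rejected when the new segment would leave the field or,
  with repulsion on, pass within `avoid_radius` of any other cell's
  existing segments. A tip with no acceptable candidate stalls
  permanently — stalled tips are never reactivated, which keeps the
  simulation monotone and reproducible.
* With probability `branch_prob` per step a tip becomes a branch point:
  two daughter tips diverge by `divergence_angle` and immediately attempt
  their first extension.
* Self-avoidance (on by default) applies the same rejection against the
  cell's *own* segments at radius 0.75 x `avoid_radius`, with two
  exemptions that make branching geometrically possible: (i) a tip
  ignores its own trailing ancestor segments (a branch cannot avoid the
  trail it is extending), and (ii) segments younger than the few steps
  two diverging siblings need to separate by the self-avoidance radius
  are invisible. The reduced self radius lets sibling branches at the
  divergence angle coexist; the inter-cell radius is never relaxed, so
  the minimum distance between segments of different cells is a hard
  `avoid_radius` under repulsion.

Segment proximity queries use a uniform spatial hash (cell size
`avoid_radius + step_length`, one bucket per segment midpoint, 3x3
neighbourhood search) with exact segment-segment distances, compiled
with numba.

Deep branch orders arise naturally in this model: every successful
branch event adds one junction along the surviving lineage, so order
grows at roughly `branch_prob` per step for lineages that keep finding
space, while crowded daughters stall after a few steps and remain as
short spurs.

### Presets

* `tiled-DIV15` (defaults of `GrowthParams`): 9 cells on a 512 x 512
  field, spacing 130 px, 5 primaries, step 2 px, heading noise 0.30 rad,
  branch probability 0.25/step, divergence 1.2 rad, avoidance radius
  4 px, 7 candidates, 120 steps, repulsion and self-avoidance on. This
  is the mature-culture analogue: it reliably produces cells with
  maximum topological order in the 30s–50s (well past 20), mean
  per-cell tiling-violation percentages indistinguishable from zero at
  epsilon = 1, and runs in a few seconds per culture.
* `neutral`: identical but with inter-cell repulsion off — territories
  interpenetrate freely and nearly every branch violates the tiling.
* `sparse-validation`: a deliberately sparse 3-cell configuration
  (avoidance radius 8 px, branch probability 0.06, heading noise 0.15)
  whose inter-branch spacing exceeds the rendered line width; used to
  validate the image round trip (see below).

No growth rates, branch probabilities or avoidance distances are
quantified for the real preparation; all preset values are calibration
choices of this package, fixed once to satisfy the qualitative targets
above, and documented here as such.

### Excitotoxic retraction

`apply_retraction` models the glutamate-excitotoxicity phenotype. Each
of `n_rounds` rounds removes every terminal branch independently with
probability `terminal_prune_prob`; junctions left with a single child
are re-fused so branch counts stay meaningful. With `exploration` on,
surviving tips then wander: with probability `explore_prob` a tip
appends `explore_steps` neutral (non-avoiding) random-walk steps, using
the culture's own step length and doubled heading noise. Defaults
(prune 0.5, 2 rounds, exploration on) reproduce the qualitative
excitotoxicity pattern on the tiled preset: branch count, total length
and maximum order drop; the bounding-rectangle coverage area changes by
only a few percent (pruning removes distal *terminal* segments while
exploration partially restores reach); and the violation percentage
rises from ~0% to several percent because exploratory growth ignores
neighbours.

### Rendering and marker tables

`render_image` rasterizes skeletons at a given line width (skeleton
pixels dilated with a disk; even widths round to the next odd width),
adds optional Gaussian noise over a constant background, and emits a
noise-free 16-bit label image; pixels covered by more than one cell get
the reserved label 65535.

`generate_marker_table` draws per-cell marker intensities (GLAST, GLT1,
GAT3, AQP4 by default) from a Gaussian copula with lognormal marginals:
`X = exp(mu + sigma * Z)` with `sigma^2 = log(1 + cv^2)`, `Z` correlated
Gaussian scores with the requested correlation matrix (eigendecomposition
factor, so positive semi-definite targets are accepted and anything else
is rejected). The default target uses the weak (< 0.5) pairwise
correlations reported for these transporters (0.23–0.46); the GAT3–AQP4
pair is not reported anywhere, so 0.30 is used as a same-order filler.
Pearson correlations on the log scale recover the target to within
+/- 0.05 at n = 2000.

## Image pipeline

* **Binarization**: strict `intensity > threshold`; Otsu (256 bins) when
  no fixed threshold is given; constant images are rejected.
* **Thinning**: scikit-image's homotopic skeletonization, followed by a
  cleanup pass that deletes pixels of residual filled 2x2 blocks when
  deletion preserves local 8-connectivity (a "simple point" test). X-shaped
  branch crossings leave an *irreducible* 2x2 block — provably no pixel
  can be removed without locally disconnecting an arm — and these are
  accepted downstream as junction clusters. `extract_graph` still
  rejects inputs containing any *reducible* 2x2 block, which indicates
  an unthinned mask.
* **Graph extraction**: pixels are classified by 8-neighbour count
  (1 endpoint, 2 path, >= 3 junction); 8-adjacent junction pixels fuse
  into one node (spurious micro-branches at crossings would otherwise
  appear); path chains are traced into branch polylines. Lengths are
  step sums: 1 per orthogonal, sqrt(2) per diagonal step — the
  convention of ImageJ's skeleton analysis. A path pixel whose both
  neighbours lie in one junction cluster is absorbed into the cluster
  (avoids 2-pixel self-loops); pure pixel rings become a self-loop edge
  on an anchor node of kind `cycle`.
* **Cleanup**: terminal branches shorter than 3 px (configurable) are
  dropped — the deterministic stand-in for the manual skeleton editing
  used with real images.
* **Cell assignment**: soma seeds snap to the nearest skeleton pixel
  (<= 5 px; a node is inserted mid-branch if needed); a multi-source
  Dijkstra assigns every branch to the geodesically nearest soma, so a
  branch threading between somata stays with its own tree (Euclidean
  Voronoi would not guarantee this). Ties break to the lower cell id and
  are flagged; unreachable branches are reported unassigned.

### Round-trip accuracy

On `sparse-validation` cultures rendered at width 3 without noise, the
full pipeline recovers per-cell total branch length to within +/- 10%
(typically -4 to -8%). The systematic small deficit has three understood
sources: thinning smooths sub-pixel heading wiggle, erodes roughly half
a line width at each terminal tip, and shortens paths through fused
junction clusters. Dense cultures rendered at widths comparable to their
branch spacing merge neighbouring branches into blobs and cannot be
recovered faithfully — that is a property of the imaging model, not of
the graph extraction, and is why round-trip validation uses the sparse
configuration.

## Morphometry

Topological branch order counts branching events between the cell body
and a branch: branches incident to the soma have order 1 and crossing
any junction adds 1. (The alternative convention that primaries are
order 0 exists; order 1 is used consistently here and in the synthetic
ground truth.) Orders are assigned by a Dijkstra with 0/1 node-crossing
weights, which on trees equals breadth-first assignment and on the rare
cycles produced by skeletonization artifacts gives each branch the
minimum order over its approach paths; cycle branches are flagged
rather than rejected. Branch count is the number of graph edges
(matching skeleton-analysis output); the coverage proxy is the
axis-aligned bounding rectangle of the cell's skeleton pixels,
`(max_row - min_row + 1) * (max_col - min_col + 1)` — rotated minimal
rectangles are deliberately not used.

## Tiling violations

A branch *violates the tiling* when any of its pixels lies within
Chebyshev distance epsilon of a pixel of another cell; epsilon = 1
(overlap or 8-adjacency) operationalizes "touch or override", and
epsilon is exposed because the original manual criterion is not
recoverable. Both summary flavours are computed: branch-level
percentage per cell, and cell-level violating-branch counts plus the
percentage of cells with at least one violation. A violating branch is
counted once regardless of how many partner cells it touches (partners
are still listed). Self-overlaps — a branch within epsilon of a
*non-adjacent* branch of the same cell (sharing no node) — are counted
separately and excluded from the between-cell statistic. Detection uses
per-cell dilated occupancy masks and an ownership image; it is exact and
matches an all-pairs pixel comparison on every tested culture.

## Statistics

`mean_sem` uses the sample s.d. (ddof = 1); n = 1 returns s.e.m. 0 with
a degeneracy flag. Marker correlation matrices are computed within each
replicate image and then averaged unweighted across images.
One-way ANOVA (scipy) is combined with Tukey HSD (equal n) or the
Tukey–Kramer form `q = |mi - mj| / sqrt((MSW/2)(1/ni + 1/nj))` for
unequal n, with adjusted p-values from the studentized-range
distribution. The studentized-range CDF is computed in-package by
direct numerical integration (240-point Gauss–Legendre for the inner
normal-range integral, adaptive quadrature over the chi distribution of
the pooled s.d.); it agrees with an independent implementation
(`scipy.stats.studentized_range`, which uses a different algorithm) to
better than 1e-6 and reproduces published 5% critical points at their
printed precision. Shapiro–Wilk normality reports are available but
never gate any analysis. The family-wise type-I error of the procedure
calibrates to the nominal 5% (within [0.025, 0.075] over 500 null
simulations in the test suite).

## Determinism and problem sizes

Every generator is a pure function of `(params, seed)` (PCG64). The CLI
derives stage seeds from the single `--seed` via
`numpy.random.SeedSequence`, and reruns are byte-identical. The shipped
study sizes — 9-cell cultures, 20 replicate seeds for culture-level
comparisons, 500 null simulations for calibration, n = 2000 for copula
recovery — were chosen so each check completes in seconds to a few
minutes on one CPU while keeping Monte-Carlo error well inside the
tolerances tested.

## What the synthetic data do and do not show

The generator reproduces the *qualitative* structure of the real
preparation: multi-order branching from somata, repulsion-driven tiling,
neutral-growth overlap, retraction phenotypes, weakly correlated marker
intensities. It does not emulate image noise statistics of fluorescence
microscopy, sub-resolution spongiform processes, variable branch
thickness, soma shapes, uneven illumination, or 3-D structure. Passing
tests therefore certify the correctness and calibration of the
*measurement pipeline* and the internal consistency of the growth model
— not quantitative agreement with any real culture's absolute branch
counts or lengths.

## Known limitations

* SWC export is exact for trees; cycle-closing links (possible in
  image-derived graphs) are dropped in SWC and preserved only in the CSV
  edge list.
* The rendered line width is effectively odd (disk dilation).
* Geodesic cell assignment requires the rendered cells not to merge into
  one connected blob; at tiled densities with wide lines, neighbouring
  cells can bridge and assignment quality degrades gracefully via the
  ambiguous/unassigned flags.
* Bounding-rectangle coverage is axis-aligned and thus not
  rotation-invariant for a single cell (only the multiset of areas over
  a culture is, under 90-degree rotations).
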
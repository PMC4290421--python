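# Methods

## Model

### Branches as conservation features

A rooted phylogeny with branch lengths is decomposed into one feature
per edge. The root's own subtending edge is excluded: standard newick
gives it no defined length, and a zero-length root edge would contribute
nothing to any length-weighted statistic. With this convention the sum
of feature lengths equals Faith's PD of the whole tree, which the test
suite asserts exactly against a direct edge sum. Branch ids are assigned
by preorder traversal with children in newick file order, so the id ↔
descendant-set mapping is reproducible across runs and can be joined to
raster layers on disk.

Taxa that lack molecular data are grafted at the *stem node* of a named
sibling: the new tip becomes an additional child of the sibling's parent
node, creating or extending a polytomy. An alternative reading — insert
a new zero-length bifurcation along the sibling's edge — exists; we
implement the polytomy form because it is the more literal one, and the
grafted `branch_length` is exposed so either convention's numerical
consequences can be emulated. With the default length 0 the graft
provably conserves total PD and can only increase the occurrence
probability of branches on the stem-to-root path.

### Branch occurrence probability

The probability that branch *i* occurs in cell *j* is the union
probability over its descendant species,
`B_ij = 1 − Π_n (1 − P_nj)`, treating species occurrences within a cell
as independent. Independence is part of the model, not an approximation
knob: no covariance option is offered. Tip layers are copied bitwise
from the species rasters rather than recomputed, so they are exactly the
model inputs.

Numerics: the complement product is evaluated as `−expm1(Σ log1p(−P))`.
This avoids catastrophic cancellation when probabilities approach 1 and
handles `P = 1` exactly (the log-sum is −∞, so `B = 1`). Internal layers
are clipped to [0, 1] to remove last-ulp excursions. Equivalence between
this tip-product form and the recursive child-subtree combination
`B_parent = 1 − Π_child (1 − B_child)` is asserted to 1e−12, and all
layers are checked against Monte-Carlo union-event frequencies and the
Fréchet bounds `max_n P_nj ≤ B_ij ≤ min(1, Σ_n P_nj)`.

### Rasters, NoData, and masks

Grids are row-major, 0-based, origin top-left; cells are treated as
equal-area planning units and geometry metadata is carried through
uninterpreted (no reprojection or area weighting). Probability zero and
NoData are distinct: zero is "absent but rankable", NoData is "outside
the analysis". Assembling a stack applies the union of per-layer NoData
to all layers. Values outside [0, 1] beyond 1e−9 are an error rather
than clamped, to surface upstream distribution-model scaling mistakes.

Tenure masks are integer rasters whose levels are removed in ascending
order; the set of levels must be declared up front and undeclared values
are an error. Level 0 conventionally means cleared/outside territory;
whether it is excluded from the analysis entirely or merely ranked first
is the caller's choice (`outside_levels`), because both uses are
legitimate: ranking cleared land first integrates already-lost portions
of distributions, excluding it restricts the statistic to remaining
vegetation.

### Greedy removal engine

The engine removes, per iteration, the `warp` cells with the lowest
marginal loss among the remaining cells of the lowest still-populated
mask level, then updates each feature's remaining representation
`S_i` by subtracting the removed cells' probabilities. Key choices:

- **Rules.** Core-area: `max_i w_i B_ij / S_i`; additive-benefit:
  `Σ_i w_i B_ij / S_i`. The additive rule uses benefit-function
  exponent 1 (the plain sum of proportional losses); core-area is the
  default/reference rule. Weights default to branch lengths so greedy
  loss aligns with the PD-retention statistic; arbitrary nonnegative
  per-branch weights are accepted (e.g. down-weighting non-endemic
  branches).
- **Warp semantics.** Losses are computed once per batch and the batch
  removed together; losses are *not* recomputed inside a batch. A batch
  never spans mask levels, which makes level dominance exact. warp = 1
  recovers the classic fully re-evaluating greedy, which the engine is
  tested against for exact order equality.
- **`S_i = 0`.** A fully lost feature contributes 0, not ∞ — it cannot
  be harmed further; this also prevents division blow-ups late in the
  removal.
- **Ties.** Broken by lowest flat cell index, stated in the config so
  runs are bit-reproducible; the engine contains no randomness.
- **Out of scope, loudly.** Cost layers, connectivity and condition
  layers are not options; passing such arguments raises instead of
  being ignored.

Ranks are reported as the fraction of cells removed before a cell, so
the best cells have ranks near 1.

### PD retention and scenarios

`PD_remaining = [Σ_i L_i (Σ_j∈q B_ij / Σ_j∈Q B_ij)] / Σ_i L_i`. A branch
with zero total representation makes the fraction undefined; this is an
error by default, or the branch can be dropped with a warning. For a
star tree with equal branch lengths the statistic reduces to the
unweighted mean of species remaining-distribution fractions (tested).

Denominator conventions are explicit metadata and differ by purpose:
retention curves and protected-PD default to Q = the analyzable cells
(e.g. remaining vegetation); per-branch tenure summaries default to the
full modelled distribution including cleared cells, so lineages whose
ranges were largely cleared register as poorly protected. Reports always
state the convention used.

Curves store one point per warp batch, computed by incremental
subtraction (verified against from-scratch recomputation to 1e−9);
queries between stored points interpolate linearly. A
`minimum.accumulate` pass guards against last-ulp upticks so stored
curves are exactly non-increasing.

Expansion scenarios count cells, not hectares: a "5% expansion" adds
⌈0.05 · #protected⌉ best-ranked unprotected cells, taking the ranking
from a run in which reserves were forced last (checked, error
otherwise). The reported gain is validated against an independent
from-scratch retention difference.

Vulnerability classes relative to a protected tenure category:
`outside_parks` if a branch has zero representation in any park level,
then `<1%`, `1–5%`, `>5%` of its distribution protected. Shares exactly
at 0.01 or 0.05 go to the less vulnerable class (the boundary assignment
is otherwise arbitrary; it is documented and tested). The park-level set
is a separate parameter from the protected set because "in a park" and
"fully protected" genuinely differ when parks contain development zones.

## Synthetic data

The generator emulates the three inputs of a real analysis:

- **Tree:** pure-birth (Yule) with unit speciation rate. The simulator
  stops at the final speciation event, which would leave that cherry
  with zero-length tip edges; by memorylessness one Exp(nλ) interval is
  added to every tip edge, so all branch lengths are positive.
  Ultrametricity is not required by any downstream computation.
- **Species layers:** isotropic Gaussian occurrence surfaces
  `p_max · exp(−d²/2σ²)`, peak 0.9 (distribution models rarely output
  certainty), range width σ lognormal with median 0.15 of the short
  grid side (ranges overlap within clades without blanketing the
  landscape). With phylogenetic signal on (default), range centres
  evolve by 2-D Brownian motion along the tree and are rescaled to the
  central 70% of the grid, so sister species have nearby, overlapping
  ranges and internal branch layers show realistic nestedness (checked
  statistically over 50 seeds). An optional prevalence target rescales
  layer means, erroring if that would push probabilities above 1.
- **Tenure:** levels with target area fractions, realized to exact cell
  counts (largest-remainder rounding; any fraction shortfall becomes
  level 0), grown as contiguous regions from random seed cells or
  scattered at random. Defaults emulate a heavily cleared landscape:
  60% cleared, 23% unprotected vegetation, 9% park development zone,
  8% park protected zone.

Everything is fully determined by one seed. What the generator does
*not* emulate: spatially structured model error, covariate-driven range
shapes, anisotropic or fragmented ranges, real tenure geometry, or
non-equal-area cells. Passing tests therefore demonstrate the
correctness of the propagation/ranking/evaluation machinery and the
qualitative behaviour of rankings (e.g. beating random selection), not
calibration against any real landscape.

## Problem sizes and tolerances in the test suite

Structural identities (tip copies, PD sums, hierarchy dominance,
determinism) are exact. Dual-route numerical checks use 1e−12
(propagation) and 1e−9 (accumulated retention). The greedy engine is
compared to a from-scratch oracle for *exact* order equality on
instances up to 100 cells × 20 branches at warp 1 and 5. The Monte-Carlo
check of branch layers uses 50 seeded instances (3–10 tips, grids up to
6×6) at 10⁵ draws per cell with tolerance `3·se + 0.005`; the absolute
allowance accounts for the several thousand simultaneous comparisons,
for which a bare 3σ band has an expected false-failure count well above
one. Ranking-quality checks use ten 15-species 30×30 landscapes, the
best 10% of cells against 20 random sets each. The acceptance script
runs the same 15-species 30×30 study conditions end to end.

## Known limitations

- Greedy removal is a heuristic; it does not solve the optimal reserve
  selection problem, and the additive rule is implemented only with
  exponent 1.
- Within-cell independence between species is assumed, not tested;
  positively associated species make branch probabilities
  overestimates.
- Cells are equal-area planning units; no cost, connectivity or
  boundary-effect weighting.
- Rasters must be pre-aligned; no resampling or reprojection is
  performed, and vector tenure data must be rasterized upstream.
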
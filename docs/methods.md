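# Methods

## Network representation

A mitochondrial network is an undirected multigraph whose **unit edges**
are the minimal, indivisible constituents of the organelle.  Two sources
produce the same container:

* **Images.** Every skeleton pixel is a node; every 8-adjacent pixel
  pair is a unit edge, except that a diagonal adjacency is dropped when
  the two pixels share a foreground 4-neighbour.  Without that pruning
  every diagonal step of a thinned raster forms a spurious 3-cycle,
  inflating loop counts.  Degree-2 chain pixels are first-class nodes;
  this is what places empirical mean degrees in the 1.4–1.8 range (a
  junction-only graph could not produce them).
* **Simulation.** Every cluster of fused tube tips is a node; every
  tube is a unit edge between its two tips' nodes.  Self-loops (a tube
  fused to itself) and parallel edges are legitimate.

**Metrics.** ⟨k⟩ averages the degree over all nodes, including isolated
degree-0 pixels if present (configurable; cluster counts always exclude
them).  Clusters are components with ≥ 1 edge; N_g is the edge count of
the largest.  **Loops** are the minimum-weight cycle basis of each
component after collapsing maximal degree-2 chains into weighted
super-edges, so the number of loops equals the cycle rank E − V + C and
a pure cycle reports its full length; for rank ≥ 2 components the basis
is computed on a subdivided simple graph (networkx's minimum cycle
basis does not accept multigraphs; subdivision preserves the weighted
cycle space exactly).  **Branches** are maximal degree-2 chains whose
ends have degree ≠ 2 with at least one end of degree 1; an isolated
path counts once.  Whether loop sizes should count pixels or collapsed
unit edges is not externally fixed; unit-edge counting is used
consistently for images and simulations, so the two sources are
directly comparable.

## Image pipeline

Intensities are normalized to [0, 1] on load regardless of bit depth.
Preprocessing masks user-supplied exclusion regions (legends, non-
mitochondrial structures) and selects the stain channel; which regions
to mask is deliberately explicit user input, not guessed.  Binarization
uses Otsu's global threshold on a 256-bin histogram (deterministic and
parameter-free); thinning uses scikit-image's topology-preserving
skeletonization, which is idempotent on thin curves and preserves
component count and per-component cycle rank; components are labeled
with 8-connectivity throughout (4-connectivity would shatter thinned
filaments at diagonal steps).  Adaptive thresholding, illumination
correction and 3-D stacks are out of scope.

## Synthetic micrographs

The generator renders toy networks (paths, cycles, 3-armed stars, theta
graphs, isolated edges — plus tadpoles when rendering simulated graphs)
at a fixed scale of `px_per_edge` (default 8) pixels of stroke per unit
edge, placed on a collision-free shelf layout with seeded jitter.
Geometry is corner-compensated for a measured, deterministic property
of the thinning operator: every 90° corner of a 1–3 px stroke loses
exactly one skeleton pixel, so e.g. a loop of c edges is drawn as a
square ring of side 2c + 2 whose skeleton keeps exactly 8c pixels.
Pixel sizes therefore map back to toy edges by integer rounding, and
round-trips (component count, cycle rank, loop sizes, branch lengths)
are exact on clean renderings at stroke widths 1–3.  Limits that follow
from the geometry: rings need a hole that survives dilation (a 1-edge
loop cannot be drawn at stroke 3), and a theta needs a strictly
shortest chain (three equal chains have no non-colliding bow heights at
this scale) — the renderer raises a descriptive error rather than
silently distorting topology.  Noise (additive Gaussian), blur and
legend/extra-channel artifacts are applied after rasterization.

What the generator does *not* emulate: point-spread functions, photon
(shot) noise, uneven illumination, out-of-focus light, filament
curvature, crossing filaments and densely entangled regions.  Passing
round-trip tests therefore certifies the pipeline's correctness on
well-separated thin structures, not segmentation robustness on real
micrographs — on real data the quality of the threshold and masking
dominates.

## The fission–fusion model

N unit edges carry 2N tips.  Nodes hold 1–3 tips (degree ≥ 4 is
excluded by construction, matching its negligible observed frequency);
X1, X2, X3 count nodes of degree 1, 2, 3, with the invariant
X1 + 2·X2 + 3·X3 = 2N.  Two reversible reactions act: tip-to-tip
(X1+X1 ⇌ X2, rates a1/b1) and tip-to-side (X1+X2 ⇌ X3, rates a2/b2).
Fission rates are fixed (b1 = 0.01 per node per unit time,
b2 = 1.5·b1); the dimensionless ratios C1 = a1/b1 and C2 = a2/b2 are
the free parameters.  The model is well-mixed: reactant agents are
sampled uniformly with no spatial structure, self-fusion of a tube's
own two tips is allowed (loops must be formable), and mass (edge
count) is conserved — no mitophagy or biogenesis.

**Gillespie scheme.** Exponential waiting times at the total
propensity; the channel is chosen proportionally; reactants uniformly
among eligible agents (an X3 node's detaching tip uniformly among its
three).  "5N steps" is interpreted as 5N reaction *events* (the
algorithm's natural unit); stationarity of the summaries between 5N and
10N events is verified by test.  Runs are bit-reproducible: per-run
seeds derive from a master seed via a seed sequence and are recorded in
the output.

**Propensity conventions.** The propensity combinatorics of the
original formulation of this model family are ambiguous, so three
conventions are implemented in the simulator and mirrored exactly in
the mean-field oracle:

| name | tip-tip fusion | tip-side fission |
|---|---|---|
| `pairwise` | a1·X1·(X1−1)/2 | b2·X3 |
| `squared` | a1·X1² | b2·X3 |
| `triple-fission` | a1·X1·(X1−1)/2 | 3·b2·X3 |

(all share fission b1·X2 and tip-side fusion a2·X1·X2; the `squared`
fusion term is zeroed when X1 < 2, where no physical pair exists).
`scripts/calibrate_conventions.py` ranks the conventions against the
reference condition table; `squared` is closest (mean absolute ⟨k⟩
error 0.146 vs 0.189/0.214) and ships as the default.  **Known
limitation:** no convention reproduces the reference tables in full.
The reference ⟨k⟩/fraction pairs are mutually inconsistent, and the
small-N conditions (ALS, N = 103 and 72) are irreconcilable with *any*
count-based mass-action kinetics, whose fusion propensities scale down
with N while the reported values do not.  `docs/calibration.md` and
`results/calibration.csv` quantify this per convention and per
condition; the quantitative-reproduction acceptance test records these
deviations rather than masking them.

## Mean-field oracle

Setting each reaction's net flux to zero gives closed balance relations
(for `squared`: X2 = C1·X1², X3 = C2·X1·X2) under the tip-conservation
constraint; substitution yields a single strictly increasing cubic in
X1 on [0, 2N], solved by bracketed root finding (Brent), so the unique
non-negative root cannot be missed and the conservation residual is
below 1e-9·2N.  The oracle's role is consistency: stochastic ensemble
means must agree with it within Monte-Carlo error at large N (they do,
within 3 SE at N = 2000 with 200 repetitions), and it provides instant
⟨k⟩ estimates for grid design.  It carries no finite-size corrections
beyond the pair term and no dynamics.

## Phase-space fitting

The scan simulates an ensemble per cell of a log-spaced (C1, C2) grid
(defaults cover C1 ∈ [1e-5, 5e-3], C2 ∈ [1e-6, 5e-4], the span of all
reference fitted values; log spacing equalizes relative resolution).
Cells are cached on disk keyed by (N, C1, C2, reps, events, seed,
convention), making scans resumable and locally refinable.  The default
is 100 repetitions per cell, reducible for desk-scale runs.

**Misfit.** The default metric is SE-normalized:
((k_sim−k_obs)/σ_k)² + ((g_sim−g_obs)/σ_g)², with σ the cell's
Monte-Carlo standard error (floored at 1e-3 / 1e-4).  This weighs each
observable by its actual precision; an unweighted relative-error metric
(available as `misfit="relative"`) lets N_g/N sampling noise swamp the
far more precisely measured ⟨k⟩ and degrades parameter recovery.  Ties
break toward smaller (C1, C2), lexicographically.  Observations farther
than 3 SE outside the grid's attained range in *both* metrics raise an
error rather than returning a boundary cell.

**Recovery validation.** The procedure is validated by self-consistency:
ensembles simulated at known grid cells are fitted back through an
independently scanned grid.  The experiment uses C1 ∈ [2e-4, 2e-3],
C2 ∈ [5e-5, 5e-4] at N = 500 — the identifiable region containing every
reference fitted value.  This region is chosen a priori from the
mean-field sensitivity: below C2·N ≈ a few ×10⁻², X3 ≈ 0 and C2 leaves
no signature in (⟨k⟩, N_g/N), so no method could recover it there.
With 20 cells, 20 repetitions each, recovery within one grid step is
100% across tested seeds.

**Condition comparison** re-simulates at the two fitted cells (seeded
by cell, so identical conditions compare identically) and reports
C-ratios, steady-state species fractions and their normal/diseased
ratios; the distribution report pools loop/branch/cluster sizes across
an ensemble and summarizes the normal-minus-diseased shift of each
mean.

## Problem sizes in tests

The test suite exercises the acceptance-scale conditions directly: the
HD-scale ensembles run the full 100 repetitions of 5N events
(N = 2664/2150), oracle agreement uses N = 2000 with 200 repetitions,
the phase-space monotonicity check a 6×6 grid at N = 500 with 20
repetitions, and the recovery experiment the sizes above.  These sizes
were chosen so the whole suite completes in about a minute on one CPU
while keeping Monte-Carlo error well below the asserted margins.
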
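# Methods

`pallidotrace` quantifies how the axons of direct-pathway (dMSN, GFP-labeled)
and indirect-pathway (iMSN, RFP-labeled) striatal projection neurons converge
in the external globus pallidus (GPe), starting from traced fiber polylines in
parasagittal sections. This note records the models, the defaults and their
units, the numerical choices, and what the synthetic-data generator does and
does not emulate.

## Coordinate and data model

All coordinates are millimeters from bregma: `rc` (rostrocaudal, rostral
positive — the GPe arborizations sit near rc ≈ −0.45 mm), `dv` (dorsoventral,
dorsal positive), `ml` (mediolateral, lateral positive). A dataset is a set of
parasagittal sections, each an (rc, dv) plane at a fixed `ml_center` with a
polygonal GPe outline; fibers are 2-D polylines within one section, with
optional bouton (varicosity) arc-length positions; somata carry full 3-D
positions. Tracing depth inside a section (20 µm by default) is discarded:
every point of a section lives at its `ml_center`. Adjacent-section
superposition (the GFP and RFP channels were traced in physically adjacent
sections) merges an explicit list of pairs; the merged section takes the
midpoint ml, the polygon union of the two masks, and the summed thickness.
The midpoint rule is a documented choice — nothing in the data dictates how a
superimposed pair should be assigned a common ml.

SWC was adopted for trace geometry because it is the standard interchange
format for neuronal morphology. Polyline vertices are type-2 (axon) nodes;
varicosities are written as type-7 nodes (the SWC custom-type range) at their
interpolated position, parented to the preceding vertex, so ordinary SWC
viewers render them and the arc-length offset reconstructs exactly on read.
Round trips are lossless to better than 1e-9 mm (12 significant digits).

## Density gridding

The GPe of each section is divided into axis-aligned square boxes
(`box_size` = 0.04 mm, the study's 40 µm × 40 µm grid) and each varicose
fiber contributes the exact Euclidean length of its intersection with each
box. Implementation: every segment's crossing parameters with the lattice
lines and with the mask polygon's edges are merged into one sorted parameter
list (Liang–Barsky-style parametric clipping); each sub-interval is assigned
to the box containing its midpoint, and sub-intervals outside the mask are
dropped. Consequences:

- total grid mass equals the mask-clipped varicose polyline length to
  floating-point accuracy (verified against an independent polygon clipper);
- boxes are half-open `[x, x+s) × [y, y+s)`, so a vertex on a shared edge is
  counted once (in the higher-index box);
- the lattice origin is the floor of the mask bounding box to `box_size`
  multiples. The study does not state its lattice alignment; anchoring on
  absolute multiples of the box size makes grids of both channels — and of
  halved box sizes — share nested boundaries.

Kernel density estimation is deliberately absent: the study's method is box
counting, and the box grid is also the unit of the overlap classification.

## Two-component arborization fit

Each channel's density is summarized by a two-component 3-D Gaussian mixture
fitted to the grid's box centers weighted by their fiber length. The weighted
EM maximizes `Σᵢ wᵢ log Σₖ πₖ N(xᵢ; μₖ, Σₖ)`; responsibilities are multiplied
by the weights in the M-step, which makes the fit identical to unweighted EM
on weight-fold repeated points (asserted to 1e-9 mm in tests, and
cross-checked against scikit-learn's EM on repeated points). Numerical
choices, none of which the study reports, are therefore documented decisions:

- K = 2 components, fixed: the study fits exactly two arborizations; no
  model selection.
- Full covariances with a ridge of 1e-6 mm² added to the diagonal each
  M-step. The few distinct ml values (one per section) otherwise drive the
  ml variance toward singularity.
- Initialization splits the weighted points at the weighted median rc and
  seeds each component with its half's moments — deterministic, and aligned
  with the rostrocaudal arrangement of the two arborizations. Random
  restarts are available (`n_restarts`); the best final likelihood wins.
- Convergence when the weighted log-likelihood improves by less than `tol`
  (1e-8, absolute) or after `max_iter` (500) iterations; the likelihood is
  checked to be non-decreasing.
- The rostral component (larger mean rc) is labeled `#1`, the caudal `#2`;
  ties within 1e-9 mm fall back to dv, then ml, then weight.

The Mahalanobis-distance-1 region around a fitted mean is the ellipsoid
`(x−μ)ᵀΣ⁻¹(x−μ) ≤ 1`, with principal axes the covariance eigenvectors and
semi-axes `√eigenvalue`; its mass is `chi2(3).cdf(1) ≈ 0.1987`, i.e. the
"about 20%" enclosed by the unit ellipsoid of a trivariate Gaussian. Section
overlays use the exact plane–ellipsoid intersection (Schur complement of the
precision matrix).

## Convergence statistics

Per mouse, the four labeled centers give two within-channel distances (G1–G2,
R1–R2) and two cross-channel distances (G1–R1, G2–R2). Across a cohort the
within values form one sample and the cross values the other (2n vs 2n
values for n mice — the study reports only "n = 6 mice", so this pooling is a
documented choice, with per-mouse averaging available), compared by a
two-sample Kolmogorov–Smirnov test. The exact p-value is used whenever
`n·m ≤ 10⁴` — at the study's 12-vs-12 sizes the asymptotic approximation is
unreliable — with the asymptotic formula as fallback above that.

Projection-area overlap binarizes each box by channel presence (fiber length
strictly greater than `presence_threshold`, default 0 mm) and classifies
occupied boxes as GFP-only / RFP-only / both; percentages are over occupied
boxes only, and per-class areas are `count × box_size²`. Cohort summaries are
unweighted per-mouse means ± SD (n−1 denominator). Projection extents are
per-axis ranges of mask-clipped varicose vertices; the ml extent spans the
touched sections' centers.

## Topography regression

Per mouse and channel, the soma cloud's per-axis mean is paired with the
fitted arborization center of each label. Following the study's plotting
convention the soma (infection) center is the dependent variable and the
arborization center the regressor, so with an identity topographic map the
expected slope is 1. GFP and RFP contribute one point each per mouse and are
pooled per panel (12 points for 6 mice); per-channel regressions are also
computed. Ordinary least squares with Pearson r and its two-sided t(n−2)
p-value; regressions with fewer than 3 points are flagged under-powered.

## Synthetic mice

No traced dataset accompanies the study, so the generator is the package's
ground truth and its defaults are calibrated to the study's reported
quantities:

- **Somata**: Gaussian clouds of 29 GFP and 23 RFP cells (reported means
  28.7 and 22.8) around `soma_center` (0.5, −2.8, 2.0) mm with per-axis SD
  (0.13, 0.20, 0.13) mm, chosen so the expected sample range at n ≈ 25
  (≈ 3.9 SD) reproduces the reported soma ranges (≈ 0.5, 0.8, 0.5 mm).
- **Arborizations**: two components at the topographic image of the soma
  centroid ± (0.1, 0.1, 0) mm, i.e. defaults (−0.35, −3.2, 1.9) and
  (−0.55, −3.4, 1.9) — inside the reported rc ranges of arborizations #1
  (−0.3…−0.5) and #2 (−0.4…−0.6). Per-axis SDs (0.06, 0.09, 0.09) mm were
  back-derived from the reported projection extents (range of a large vertex
  cloud ≈ center separation + ≈ 7 SD). The RFP covariance is 1.5× the GFP
  covariance and the RFP field carries 350 fibers vs 150 GFP fibers; these
  two asymmetries reproduce the reported overlap breakdown (simulated
  ≈ 59/30/10% RFP-only/both/GFP-only vs reported 58.2/31.5/10.2%). A tenth
  of GFP fibers are non-varicose (the study traced some bouton-free GFP
  fibers); all RFP fibers are varicose.
- **Topography**: per-axis affine maps from soma centroid to arborization
  mid-center; defaults are identity-slope dv and ml maps and a zero-slope rc
  map, matching the reported strong dv/ml correlations and absent rc
  correlation. Cohorts jitter the injection center per mouse (default SD
  0.15 mm per axis).
- **Fibers**: each fiber draws a mixture component, fixes its ml from the
  component's ml marginal (which selects its section), and walks in the
  section plane as a stationary AR(1) (Ornstein–Uhlenbeck-like) process
  whose stationary law is the component's in-plane Gaussian. Every vertex is
  therefore marginally distributed as the configured mixture — fiber-length
  density, not just point counts, follows the ground truth — while fibers
  remain realistic contiguous squiggles that exercise polyline gridding.
  The AR(1) coefficient is set so the mean step is `fiber_step` (0.01 mm);
  fiber lengths are exponential with mean 1.5 mm; varicosities fall at
  exponential arc-length spacings (mean 0.01 mm), the simplest memoryless
  choice since the study reports no bouton statistics.
- **Region mask**: an ellipse (semi-axes 0.6 × 0.8 mm) around the
  arborization mid-center stands in for the GPe outline — synthetic, not an
  atlas contour.
- **Randomness**: one master seed per mouse, split into named substreams
  (somata / fibers / varicosities), so regenerating one part never perturbs
  another; identical config + seed is bit-identical.

What the generator does **not** emulate: curvature and branching statistics
of real axons (the OU walk has no branches and no directional persistence
beyond position autocorrelation), true 3-D fibers crossing section
boundaries, tracing errors and missed fibers, section-to-section registration
error, and any non-Gaussian structure of real arborizations. Passing tests
therefore demonstrate that the analysis recovers known mixture/topography
structure from realistic *volumes* of polyline data — not that real GPe
fields are two-Gaussian.

## Problem sizes and determinism

Default-size mice (150 + 350 fibers, 1.5 mm mean length, 20 µm sections) are
used where single-cohort quantities are computed (overlap percentages,
extents, demo pipeline, the 20-mouse recovery study). Replicate-heavy
studies (100-replicate KS direction, 50-replicate overlap ordering and
topography) use a reduced preset (`small_config()`: 60 + 120 fibers, 0.8 mm
mean length, 40 µm sections) with identical geometry, chosen so hundreds of
cohorts run in minutes while each mouse still yields several hundred
occupied boxes per channel. Every random quantity flows from an explicit
seed through named substreams; the pipeline's `report.json` is
byte-deterministic given (config, seed).

## Known limitations

- The fit assumes exactly two Gaussian components; a mouse whose field is
  effectively unimodal (the study notes one such animal) still receives a
  two-component description — convergence diagnostics (iterations, final
  likelihood, converged flag) are reported instead of any constraint.
- The exact KS p-value treats the 2n pooled distances as independent
  samples; distances sharing a mouse are in fact weakly dependent. The
  study's reported p-value is likewise a single number over pooled distances,
  but per-mouse pooling options are provided.
- Mask clipping treats each section's polygon as exact; there is no
  smoothing or registration across sections.
- With zero-radius or near-singular covariances the Mahalanobis region
  degenerates; the EM ridge keeps fitted covariances ≥ 1e-6 mm² so section
  ellipses always exist near the component center.
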
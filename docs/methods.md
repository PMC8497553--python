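# Methods

This note documents the models, conventions, numerical choices and known
limitations of `paleodiv`. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is asserted that the
code does not check.

## Time-scaled trees and LTT

Ages are stored in Ma before present (larger = older) everywhere; branch
lengths in Myr are derived (`parent_age − child_age`). Trees must be binary
and singly rooted; extant tips sit at age 0, fossil tips at age > 0.
Zero-length *terminal* branches are tolerated (a fossil tip can sit exactly
at its parent's age); internal durations must be strictly positive.

**Edge-crossing convention.** An edge with parent age `a_p` and child age
`a_c` crosses slice `t` iff `a_p > t ≥ a_c`. Consequences: a fossil tip is
still counted (and carries an interpolated value) at exactly its own age and
disappears at the next younger slice; internal nodes are never double
counted; the count at exactly the root age is defined as 1 (the stem), 2
immediately younger. This one convention is shared by the LTT counters, the
interpolation tables, and the disparity series, which is what makes the
"non-missing cells per column = lineage count" invariant exact.

**Percent lineage loss** is `(max count in a peak window − min count in a
younger trough window) / max count in the peak window`. The windows default
to 38.0–33.9 Ma (latest-Eocene peak) and 33.9–27.0 Ma (Oligocene trough) but
are configuration, not constants: appropriate windows depend on the fauna
under study.

## The random-tree null

The null ensemble holds three things fixed — tip labels, tip ages, root
age — and randomizes everything else:

1. *Topology*: sequential random addition (tip k+1 grafted onto one of the
   2k−1 edges of the current tree, including the root stem, uniformly). This
   gives the exact uniform distribution over rooted binary labeled
   topologies; a random-join (coalescent) scheme was rejected because it is
   uniform over *ranked* topologies instead.
2. *Node ages*: in preorder, each internal node's age is uniform between the
   maximum tip age in its subtree and its parent's age. The interval is
   always non-empty, so no rejection is needed in exact arithmetic; in
   floating point, very deep chains of ancestors above the oldest tip can
   shrink the interval below float resolution, and such draws are clamped to
   the interior or — in the rare irreparable case — rejected and redrawn.

This direct sampler replaces a much heavier randomization scheme (random
topologies time-scaled by a Bayesian engine under fixed tip-age and root-age
constraints) that targets the same ensemble of "random topology, random
branch lengths, preserved tip ages". Because the node-age distribution is
not identical in detail, null summaries (e.g. the mean percent loss of
roughly 10–20% for study-shaped tip spectra) should be read as approximate
characterizations of the sampling-only expectation, not as exact
reproductions of any particular published null.

## Dental topographic metrics

Meshes are `trimesh.Trimesh` objects in mm, occlusal side up (+z). Mesh
preparation (cropping at the occlusal basin for ariaDNE/OPCR, at the crown
cervix for RFI; simplification to 8,000/10,000 triangles; smoothing) is
assumed done upstream; the synthetic generator emits surfaces at those face
budgets so parameter regimes match.

* **RFI** = `ln(√A₃D / √A₂D)`. The 2-D outline area is the area of the
  union of the projected face triangles (shapely), not the summed projected
  face areas, so overhanging enamel does not double-count. Checks: flat
  disc → 0 (machine precision); hemisphere → ln √2 within 0.01 at ~10⁴
  faces; invariant to isotropic scaling, translation, rotation about z.
* **OPCR**: face-based orientation, azimuth bins of 45° anchored at 0°,
  adjacency via shared edges, minimum patch size 3 faces, 8 rotations of
  5.625°, arithmetic mean. Faces with vertical normals (horizontal surface)
  carry no azimuth and are excluded; an all-horizontal mesh is an error, not
  a zero. Face/vertex basis and minimum patch size follow the convention of
  the widely used patch-counting software; they are parameters, and per-mesh
  numerical equality with any specific implementation is not claimed.
  Surfaces whose normals sit exactly on bin boundaries are genuinely
  degenerate (float noise decides the bin); the test fixtures therefore
  orient analytic solids mid-bin.
* **ariaDNE**: the mesh is rescaled to unit total surface area; for each
  vertex, all vertices within 4ε (Euclidean) are weighted by
  `exp(−d²/ε²)`; the weighted covariance of the neighbourhood gives the
  surface-variation curvature `κ = λ_min / (λ₁+λ₂+λ₃)` (0 on a plane); the
  energy is `Σ κ·a_v` over non-boundary vertices, `a_v` = one third of
  incident face area on the normalized mesh. ε defaults to 0.1, interpreted
  on the unit-area mesh (the normalized-area reading of the reference
  method's bandwidth; a bounding-box reading would differ by a constant
  factor for a given shape family). The implementation reproduces the
  method's qualitative contract — plane ≈ 0, sphere > plane, sharper cusps
  > blunter cusps at fixed footprint, scale invariance, determinism — and is
  *not* claimed to be numerically identical to the original MATLAB script.

Species means are arithmetic means over specimens per species.

## Morphospace

OPCR is ln-transformed before any multivariate treatment (patch counts are
count data). The PCA is the eigendecomposition of the correlation matrix,
computed as an SVD of the z-scored (mean 0, sd 1, ddof = 1) matrix. PC signs
are pinned — RFI loading on PC1 ≥ 0, ln-OPCR loading on PC2 ≥ 0 — because
eigenvector signs are arbitrary and downstream centroid paths should not
flip between runs. Projection of new data reuses the fitting center/scale.

## Multi-regime Brownian motion, AICc, ASR

A regime painting assigns every edge a rate matrix through its clade tag;
the model space is all set partitions of the clade tags. Edges without a
clade tag (stems, backbone) are assigned regime 0 — a fit needs a total
painting, and which regime absorbs the stems is a modelling choice the user
can override by tagging those edges explicitly.

Rate-matrix constraints for bivariate data: `unconstrained` (full symmetric
PSD, parameterized by a Cholesky factor with log-diagonal, so every proposal
is PSD), `diagonal` (independent per-trait rates), `equal` (one shared
rate). Parameter counts: 3/2/1 per regime respectively, plus p root states.

The likelihood is computed by Gaussian belief propagation over the tree
(O(n·p³)): tip messages are point masses; combining two children with
covariances A, B contributes the density of their mean difference under
N(0, A+B); the root state is profiled out analytically (its MLE is the GLS
root). The test suite verifies this route against an independently built
dense (n·p × n·p) covariance — per-regime shared-path matrices combined with
Kronecker products — and `scipy.stats.multivariate_normal`, to 10⁻⁶ on all
≤8-tip fixtures (observed agreement ~10⁻¹³).

Optimization is L-BFGS-B on the log-Cholesky parameters, with dispersed
random restarts (log-parameters jittered by N(0,1)); parameters are clipped
at e^±40 to keep proposals finite. "Replicates" of the model test rerun the
whole candidate suite from fresh starting points with fresh seeds, because
replicate disagreement in this kind of analysis reflects optimizer
stochasticity; when replicates (or ΔAICc < 2 near-ties) disagree, ancestral
states are computed once per selected model and averaged.

AICc uses n = number of tips: `AICc = −2lnL + 2k + 2k(k+1)/(n−k−1)`
(infinite when n ≤ k+1, which correctly eliminates overparameterized models
on small trees).

Ancestral states are conditional expectations of internal-node values given
the tips under the fitted Gaussian — a GLS reconstruction built from the
same per-regime shared-path machinery (a 10⁻¹⁰ ridge stabilizes the tip
covariance solve). The root estimate equals the fitted root state.

## Time slices and disparity

Interpolated value on edge (parent `a_p, v_p`; child `a_c, v_c`) at slice
`t`: `v_p + (v_c − v_p)·(a_p − t)/(a_p − a_c)` for `a_p > t ≥ a_c`, NA
otherwise; a zero-length terminal branch contributes its child value at its
age only. Edge rows follow the package's deterministic preorder numbering
(an explicit mapping table is available via `TimeScaledTree.edge_table`,
since edge numbering schemes differ between tree libraries). Edge exclusion
(e.g. stems not attributable to the study region) removes rows before any
summarization and rejects unknown identifiers.

Per-slice metrics on the PC1–PC2 cloud: SoV uses sample variance (ddof = 1;
undefined at n = 1); SoR is max−min per axis; SR2DHA is the square root of
the *convex* hull area (undefined below 3 non-collinear points) — a
concave-hull concavity argument is accepted for interface compatibility and
ignored with a warning in the convex regime, since a sufficiently large
concavity setting is exactly the convex hull; MST uses
`scipy.sparse.csgraph` (0 at n = 1). Clade-summed series treat "no crossing
lineages" as 0 and "lineages present but metric undefined" as missing, so an
undefined hull is never silently read as zero disparity.

Centroid paths sum Euclidean distances between centroids of adjacent
populated slices; the rate divides by the elapsed time between the first and
last populated slice in the window. Pulse localization
(`largest_drop`) uses the largest decrease between *consecutive grid
slices* whose older member has at least a minimum number of lineages
(default 10 in the shipped experiment) — hull areas of very small clouds
fluctuate too much to localize anything, and a decline accumulated across a
gap is not a single-step drop.

The packaged end-to-end experiment (`pulse_disparity_experiment`) also
preconditions itself on *pre-treatment* power, judged on the unpulsed data
alone: at least 25 lineages must cross the pulse age, and the largest
natural background drop must be under 0.3 of the disparity level at the
pulse slice — otherwise removing the high-PC1 tail is not resolvable from
noise by design, and the candidate simulation is redrawn. Under these
conditions the detected drop slice matched the programmed pulse age in
60/60 validation seeds.

Per-slice trait distributions are summarized with a Gaussian KDE
(scipy default bandwidth) on a grid spanning the data ±3 bandwidths; slices
with < 2 values or all-identical values are flagged degenerate and reported
raw.

## Synthetic data

The generator's defaults emulate the study system the package was designed
around: a composite tree of roughly 300+ tips with ~60% extinct tips and a
root near 76.16 Ma. Birth 0.22, death 0.175 and fossil-recovery 0.32 (per
lineage per Myr) were chosen once to land in that regime; because a
supercritical birth–death process conditioned on survival is heavily
size-skewed, draws can additionally be conditioned on an observed tip-count
window (`min_tips`/`max_tips`), the standard practice in tree simulators.

The FBD simulator runs the process forward from the fixed root age (two
daughter processes), thins fossil samples onto branches at the Poisson
recovery rate, and reduces to the observed tree: extant tips plus, for each
extinct lineage with samples but no observed descendants, a fossil tip at
its most recent sample age; sampled ancestors are dropped and unifurcations
suppressed. A programmed extinction pulse kills each lineage alive at the
pulse age with the configured probability, leaving a fossil tip at that age
with probability `pulse_fossilization` — emulating a well-sampled extinction
horizon followed by a gap. A *trait-selective* pulse
(`apply_trait_selective_pulse`) instead truncates the crossing edges whose
interpolated trait value is in the chosen tail, which is what the
end-to-end disparity-collapse experiment uses.

BM traits are simulated by preorder Gaussian increments with per-edge regime
rate matrices; the function returns the truth at *every* node so recovery
experiments compare estimates to simulated truth rather than to themselves.

Tooth crowns are sum-of-Gaussian-bump height fields over an elliptical base,
triangulated on a grid clipped to the ellipse at a configurable face budget.
Cusp bumps sit on a ring; bump width shrinks with cusp count so neighbouring
cusps remain distinct features, and is divided by the sharpness parameter.
What the family does emulate: graded, controllable complexity/relief/
sharpness with the right metric orderings (OPCR ↑ cusps, RFI ↑ relief,
ariaDNE ↑ sharpness — rank correlation 1 across 5-level sweeps). What it
does not: real crown anatomy (crests, basins, wear facets, enamel
thickness), closed cervix margins, or scanner physics — passing tests on
this family shows the metrics respond correctly to shape factors, not that
they reproduce any particular specimen's published values.

## Pipeline

`run_pipeline` executes simulate → dtm → pca → asr → slice (→ null) into a
run directory with a JSON manifest. One global seed fans out to per-stage
seeds via `SeedSequence.spawn`, so each stage is independently reproducible.
A stage is skipped when its configuration hash matches the manifest and its
outputs exist; when a stage runs, everything downstream runs too. CSVs use
UTF-8, comma delimiters and literal `NA` for missing cells.

## Problem sizes

The shipped experiments run at: 100 simulated FBD trees × 100 random ages
for the LTT oracle; 200 fifty-point clouds for the geometry oracles; ≤8-tip
trees × 2-clade paintings for the likelihood oracle; 20 seeds × ~100-tip
trees for regime recovery; one ~200-tip tree for ASR recovery; 500 random
trees for the null-separation experiment; analytic meshes at ~10⁴ faces.
These sizes give stable pass/fail behaviour across seeds while keeping the
default suite fast; all are parameters, not limits.

## Known limitations

* The null ensemble's node-age distribution is uniform-conditional, not the
  posterior of any Bayesian time-scaling; null means are approximate.
* ariaDNE matches the reference method's contract, not its bitwise output;
  OPCR patch counts depend on documented conventions (bins anchored at 0°,
  min patch 3, face basis) that other software may set differently.
* Regime paintings are clade-constant; no within-clade rate shifts, no OU or
  early-burst models, no measurement-error variance.
* Concave hulls are not implemented; the concavity argument exists only to
  accept convex-regime settings.
* The FBD simulator drops sampled ancestors; trees with sampled ancestors
  must be converted upstream.
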
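# Methods

This note documents the models and procedures implemented in `nvuquant`,
the reasoning behind the open design choices, what the synthetic generator
does and does not emulate, and the numerical conventions. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Capillary counting model

A capillary bed is abstracted as a node–segment network: branch points
(*nodes*) with valence *n* = number of incident vessel segments, and
*segments* (capillaries) connecting them. Within a counting probe the
capillary count is taken as

    N_cap = Σ_n [(n − 2)/2 · N_node(n)] + 1,  n ∈ {3, 4}.

For a closed connected graph this equals the cyclomatic number
E − V + 1 (first Betti number): each valence-3 node contributes ½, each
valence-4 node 1, and the +1 restores the single spanning component. The
package applies the +1 **once per disector**, not once per valence class —
only that convention satisfies the cyclomatic identity, which the suite
verifies exactly on hundreds of random closed multigraphs. The literal
per-valence-class alternative is selectable
(`capillary_count_eq1(..., plus_one="per_valence")`) for sensitivity
analysis.

Conventions around the identity's edge cases:

* **Open-ended (degree-1) skeleton ends** are not a valence class; they are
  excluded from tallies and reported separately (`open_end_count`) for
  diagnostics.
* **Valence ≥ 5** (not part of the counting model): the default policy
  decomposes a k-valent node into **k − 2** virtual 3-valent nodes. Each
  3-valent node contributes ½ and a k-valent node must contribute
  (k − 2)/2, so k − 2 is the unique count that preserves the cyclomatic
  identity (expanding a k-node into a chain of 3-nodes adds one node and
  one edge per step, leaving E − V unchanged). A "clip to 4" policy is
  selectable; both log when triggered.
* The **capillary definition** is a mean segment diameter ≤ 10 µm. After
  classification, a node whose capillary valence falls to 2 is a
  pass-through, not a branch point: it is dropped from tallies and its two
  capillary segments count as one.

## 2. Vessel-graph extraction

Threshold (Otsu by default; fixed and half-max available) → 3D thinning
(`skimage.morphology.skeletonize`) → graph:

* Skeleton voxels with ≥ 3 skeleton neighbors (26-connectivity) are branch
  voxels; 26-adjacent branch voxels merge into one node at their centroid.
* Maximal non-branch paths become segments; their ordered voxel positions,
  extended to the endpoint node centroids, form the centerline polyline.
* **Spur pruning** removes open-ended segments shorter than 3 µm (default):
  noise-induced skeleton whiskers otherwise inflate valences.
* **Junction fusing** contracts internode segments shorter than
  `junction_fuse_length` (2 µm default; 4 µm in the validation scenes):
  thinning renders one 4-valent junction as two nearby 3-valent clusters,
  and fat junctions can leave a short self-loop ring. Contracting the short
  link (and deleting self-loops shorter than ~3× the fuse length, well
  below any real capillary loop) restores the true local topology. Real
  capillary segments are an order of magnitude longer than both thresholds.
* Valence-2 nodes left by either step are dissolved by concatenating their
  two segments.

Diameters: per-segment mean of 2 × the Euclidean distance transform
sampled along the centerline, with the transform computed in physical
units (anisotropic voxel spacing). On a rendered 4 µm tube at 0.25 µm
voxels the estimate is within half a voxel-equivalent of truth.

## 3. Sampling design and fractionator

`SamplingDesign` carries the fractionator constants. Reference values
(hemi-section sampling 1/53.5; 143.95 µm × 111.52 µm counting frame;
25 µm section thickness; 0.25 µm optical z-interval; five disectors per
section, two sections per subject) are the package defaults. The quoted
frame area 16,052.65 µm² is the rounded value of the exact product
16,053.304 µm², which the package uses.

Probes are placed systematically-uniformly-random: a grid with steps
(sx, sy), sx·sy = A_step, from a uniform random offset; each frame gets a
uniform random z-start within [0, t − h]. Counting rule: +x/+y faces
include, −x/−y faces exclude, objects counted by centroid; the z-window is
half-open. This makes an object on a face shared by two adjacent frames
count exactly once.

Two properties of the estimator worth making explicit, both verified by
simulation in the suite:

* **The +1 term is a per-disector offset.** Summing N_cap over F frames
  adds F before scaling, so the fractionator overestimates the true loop
  count by ≈ F·R/(true total), R the combined reciprocal fraction. The
  estimator is intended for (and validated in) the regime of tens of
  branch nodes per frame, where this offset is ≈ 1–2%.
* **tsf = h/t with no guard zones** is unbiased only when objects are
  uniformly distributed over the section depth. The validation generator
  makes node depth uniform by construction (full-tile jitter); with real
  tissue lost caps / cutting artifacts this choice would need guard zones.

The recovery simulation (`recovery.fractionator_capillary_recovery`) builds
subjects of two flat cortical slabs (1144 × 352 × 10 µm, ≈ 1,220 branch
nodes each), samples one slab (ssf = ½) with a 5 × 2 frame grid
(10 disectors/subject, asf ≈ 0.67, tsf = 0.8), tallies truth nodes per
frame, and compares the scaled total with the summed cyclomatic numbers.
Node margins equal the frame extent so every node's inclusion probability
is exactly asf; the slab/step geometry makes the SUR grid emit exactly the
configured frame count (uniform subsampling of a larger grid, which the
placement op supports, would otherwise need an asf correction). These
simulations run at graph level; imaging-scale fidelity of the node counts
is established separately by the exact-recovery tests on rendered scenes.

Pericyte totals use the same design with the soma count Q per frame and no
+1. The per-capillary ratio is the quotient of the two totals (undefined,
and an error, at zero capillaries).

## 4. End-foot coverage (intensity ratio)

The *iso-surface* is the capillary surface shell: vessel-mask voxels not
surviving `shell_thickness` erosions (thickness 1 = exactly the surface
voxels; default 2 voxels ≈ 0.5 µm laterally — the shell thickness is not
prescribed by the measurement definition, so it is exposed in config). The
contact percentage is 100 · ΣAQP4 / ΣSTL over the shell, by default after
max-intensity projection over z of both channels and the shell ("2D
reconstruction"); a 3D mode sums raw shell voxels for sensitivity
analysis. The 2D mode is the default because it is nearly insensitive to
the shell thickness (a projected shell column reads the same stain either
way), and on noiseless equal-gain scenes it recovers the generator's wall
coverage fraction to well under 1 percentage point.

Documented confound, pinned by a test: the measure is an **intensity**
ratio. Doubling AQP4 gain doubles the result; values > 100% are reported
with a flag, never clipped, so gain miscalibration stays visible. No
background subtraction is applied by default. Under shot noise plus
background the absolute percentage is compressed (background adds to both
sums; PSF blur attenuates the thin AQP4 shell more than the solid vessel),
so noisy absolute values sit below the geometric coverage — group
*contrasts* are preserved, which is what the statistics consume. Vessel-free
frames have no denominator; they are skipped and logged, and subject means
are taken over the remaining frames.

## 5. Plaque load

Percent of ROI area above threshold, after removing objects smaller than
10 µm² (configurable; 0 disables). Otsu on the ROI histogram is the default
"automatic" operator standing in for the unspecified interactive
thresholding such measurements usually inherit; a fixed threshold is
available and is what the validation sweep uses (midway between section
background and deposit amplitude), because a global Otsu threshold is
unreliable when the positive class is ≪ 1% of pixels. The threshold and
method are recorded in every result. Brightfield (dark-on-light) images are
handled by an invert flag. Thresholds outside the intensity range return
0%/100% with a warning rather than failing.

## 6. Statistics

* Subject mean over its sampled disectors is the unit of analysis; groups
  report mean ± SEM (sd/√n, ddof = 1; SEM of an n = 1 group is missing,
  with a warning).
* One-way ANOVA (classical between/within decomposition) + Tukey HSD
  (statsmodels) for plaque load. k = 2 reduces to the squared pooled-t,
  which the suite asserts.
* Two-way factorial ANOVA via OLS with type-II sums of squares (invariant
  to factor order and equal to type-I/III on balanced layouts) + Sidak
  pairwise comparisons: cell-mean t statistics with the pooled residual
  MSE and df, adjusted as p_adj = 1 − (1 − p)^m within the comparison
  family. The F statistics are cross-checked against an explicit
  least-squares model-comparison oracle to 1e−8.
* The factor parameterization of the published-style 2 × 2 × 2 design is
  ambiguous, so the pipeline emits both layouts: genotype × exposure within
  each survival time, and exposure × survival within each genotype.
* n = 3 subjects per group (the demo default, for fidelity to typical
  designs) is analyzable but under-powered; the run log flags it, and a
  measurement-level power test shows the intended coverage contrast is
  detected ≥ 80% of the time only at n = 6.

## 7. The synthetic generator

What it emulates:

* **Network**: a jittered 3D lattice with randomized edge deletion
  restricted to non-spanning-tree edges (connectivity is preserved by
  construction), driving node degrees to a target valence mix; a
  maximum-matching re-addition pass rebalances the realized valence-4
  fraction to the binomially drawn target. Degenerate densities collapse
  to a single open tube. Radii default to ≈ 1.4–2.6 µm (diameters ≈ 3–5 µm,
  comfortably under the 10 µm capillary cutoff and resolvable at the
  default voxel sizes); a config fraction injects > 10 µm vessels to
  exercise the classifier. Rarely a node cannot shed its last excess edge
  without disconnecting the lattice and stays at valence 5; tallies fold
  such nodes in by the decomposition policy.
* **Rendering**: tubes voxelized by distance-to-centerline with per-segment
  radii; pericyte somata as wall bumps (hemisphere-scale spheres seated on
  the wall surface, echoed in the lectin channel, with a nuclear blob at
  the centroid); AQP4 as the wall voxel layer masked by a smooth
  longitudinal random field thresholded at the global quantile, so the
  realized covered wall fraction equals the target to voxel resolution;
  Gaussian PSF blur; Poisson shot noise on signal + background plus
  additive Gaussian read noise. Default voxel spacing (0.5, 0.5, 0.25) µm,
  the z-interval matching the acquisition default.
* **Plaque sections**: random disks accumulated inside an elliptical
  cortex-stand-in ROI until the realized area fraction is within ±0.5
  percentage points of target (proportionally tighter below 5%), with the
  final disk shrunk to the remaining deficit.

What it does not emulate — hence what passing tests do *not* show about
real data: realistic point-spread functions (a Gaussian stands in for the
objective PSF), depth-dependent attenuation and shadowing, tissue
deformation and lost caps, stain heterogeneity along vessels, touching or
overlapping pericytes, vascular anatomy beyond a perturbed lattice
(no arterioles/venules, no diameter taper), and chromogen optics for the
plaque images. Stain intensity distributions are free parameters of the
generator, not claims about tissue.

## 8. Numerical conventions and problem sizes

* Coordinates: 0-based voxel indices; physical position = index × spacing;
  arrays are [z, y, x]; positions and spacings are quoted (x, y, z).
* All randomness flows through `numpy.random.default_rng` seeds; the
  pipeline derives per-subject substream seeds from the master seed via
  `SeedSequence`, so runs are byte-identical per seed (asserted by test).
* Validation problem sizes (chosen as the package's working scale):
  240-node networks for valence-mix checks; 18-node rendered scenes
  (96 × 96 × 96–80 voxels) for extraction recovery; 50 two-slab subjects
  (≈ 2,400 nodes each) for fractionator recovery; 50 thin scenes with 10
  somata for pericyte recovery; 3-tube scenes at four coverage targets;
  512² plaque sections at four burden levels; 1,000 null replicates for
  the type-I error check; an 8-group × 3-subject demo study.

## 9. Known limitations

* The iso-surface voxel count is a digital-perimeter quantity: it
  converges to the shell's mid-radius surface area, not the outer surface
  (≈ 12% smaller at r = 2 µm with 0.25 µm voxels). The coverage *ratio* is
  unaffected (both stains are summed over the same shell).
* Exact graph recovery holds for well-separated tubes; when inter-tube
  clearance approaches the voxel size, thinning bridges neighboring tubes
  and inflates loop counts. The generator's margins/jitter defaults keep
  clearance ≈ 2 µm or more.
* The fractionator's +1-per-disector offset makes sparse designs (few
  nodes per frame) biased upward; the design helpers target dozens of
  nodes per frame.
* Coverage percentages under default noise are compressed relative to the
  geometric coverage (see §4); comparisons should be within-protocol.
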
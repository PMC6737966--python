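# Methods

This note documents the models, estimators, and parameter choices behind
`mitomorph`, in the order data flows through the pipeline.

## Label volumes and conventions

A `LabelVolume` is a 3D integer grid indexed `(z, y, x)` with z the
slice/cutting axis, per-axis spacing in nanometres, and a label table
mapping every nonzero ID to a semantic class.  Keeping the slice axis
explicit puts all anisotropy on one known axis; the DCN-like geometry
(8.5 × 8.5 × 100 nm) has an anisotropy ratio near 12 and is handled
throughout.  Voxel `(z, y, x)` has its centre at `((z+0.5)·dz, (y+0.5)·dy,
(x+0.5)·dx)`.  Internally all lengths are nm; volumes and areas convert to
µm³/µm² only at reporting boundaries.

Spacing is never guessed: reading fails unless spacing arrives as an
argument or as file metadata (JSON sidecar for TIFF, attributes for HDF5).
Likewise, grid labels missing from the table abort the load unless a
permissive flag maps them to an explicit `unannotated` class — silent
class misassignment would corrupt compartment statistics downstream.

## Connected components

Mitochondria are extracted per semantic class as 3D connected components
(`scipy.ndimage.label`).  Default foreground connectivity is 26: human
tracers connect oblique profiles that may share only voxel corners between
consecutive sections.  6- and 18-connectivity are available.  Components
are renumbered by their lexicographically smallest `(z, y, x)` voxel, so
object IDs are stable across runs and platforms.  Components with any
voxel on a volume face are flagged `touches_boundary`; they are measured
and included by default (no exclusion rule is imposed) and can be dropped
via `MeasureConfig(exclude_boundary=True)`.  No minimum-size filter is
applied by default; `min_voxels` exists for noise-injected scenes.

## Volume

Exact: `n_voxels · dx·dy·dz`, no estimation.  This makes the voxel count
of a phantom an independently recomputable oracle for the generator's
voxel-centre inclusion rule.

## Surface area

Two estimators:

* **mesh** (reporting default).  The binary mask is padded, smoothed with
  an isotropic *physical-space* Gaussian of σ = 0.8 × the largest spacing
  component, and triangulated with marching cubes using the true
  anisotropic spacing.  Two details matter:

  1. *Physical, not index-space, smoothing.*  On thick-section data the
     staircase artefacts are wide in-plane annuli at each slice edge;
     bevelling them requires blurring at the slice-thickness scale along
     every axis.  Index-space smoothing (σ in voxels per axis) leaves the
     staircase intact and overestimates a sphere's area by ~10–19% at
     100 nm sections regardless of radius.
  2. *Volume-matched iso-level.*  Gaussian smoothing of an indicator
     function shifts the iso-surface inward on convex objects by roughly
     σ²·(mean curvature), which would bias small-object areas low.  The
     iso-level is therefore chosen as the quantile of the smoothed field
     at which the enclosed voxel count equals the object's exact voxel
     count.  This cancels the shift to first order at negligible cost.

  With these choices, voxelised spheres of radius ≥ 12 × the coarsest
  spacing recover the analytic area within ~1.7% at all four supported
  geometries (4 nm isotropic through 8.5 × 8.5 × 100 nm), and typical
  capsule phantoms within ~2%.  If smoothing washes a tiny object below
  any attainable level (single voxels), the raw mask is meshed at level
  0.5 instead — degenerate inputs never fail.

* **voxel_faces** (diagnostic).  Sum of exposed voxel-face areas, each
  face weighted by its physical area (`dx·dy`, `dx·dz`, or `dy·dz`).
  Transparent and exact for axis-aligned boxes, but it over-estimates
  curved surfaces by up to ~50% (1.5× for a sphere at isotropic voxels),
  so it serves as an upper-bound cross-check, never the reported value.

## Mitochondrial complexity index

`MCI = SA³ / (16 π² V²)` (default) — dimensionless and scale-invariant,
with a sphere at `9/(4π) ≈ 0.7162`; the isoperimetric inequality
(`SA³ ≥ 36 π V²`) makes the sphere the minimiser, so every honestly
measured object must satisfy `MCI ≥ 9/(4π)` up to estimator error (the
test suite enforces a −0.02 tolerance).  A normalised variant
`SA³ / (36 π V²)` (sphere = 1) is available via `mci(..., variant=
"normalized")`.

## Extent

Voxel centres in physical coordinates are projected on the first principal
axis (largest-eigenvalue eigenvector of their covariance); extent is the
max-minus-min span in µm.  A single voxel has extent 0.  For a capsule of
tip-to-tip length L the measured extent converges to L minus about one
voxel pitch (centres, not surfaces, are projected).

## Compartment assignment

Compartments are identified morphologically in the source tracings; the
computable proxy here is label-mask overlap.  Because a voxel holds one
label, an organelle carves a cavity out of its host compartment in a label
volume; the compartment's *region* is recovered by hole-filling the
compartment class mask on a local crop around each mitochondrion.  The
mitochondrion is assigned to the compartment class containing the largest
fraction of its voxels if that fraction reaches the threshold (default
0.5, majority rule); otherwise it stays `unassigned`.  `extends_beyond`
flags any voxel outside the winning region — large dendritic mitochondria
commonly extend past the synaptic area.  Assignment is invariant to
permutations of the label IDs and accepts either a carved single volume or
a separate uncarved compartment-mask volume.

## Distances, contacts, terminal spanning

All distances use voxel centres with per-axis physical scaling
(anisotropy-aware Euclidean distance transforms).  A surface-to-surface
gap is approximated as the minimum centre-to-centre distance minus one
mean voxel pitch, clamped at zero: sub-voxel surface localisation is
beyond the data's resolution.  Contact detection reports, per object pair
of the two requested classes within the gap threshold (default 30 nm, a
literature-scale figure for close appositions, not validated against any
particular annotator's visual judgement), the minimum gap and the area of
the first object's exposed surface lying within the threshold of the
second.  The area includes the facing surface plus a one-to-two-voxel
perimeter band (that band genuinely lies within the threshold); contacts
are reported per pair, not split into patches.

A presynaptic terminal is counted as *synaptically contacting* a dendrite
when its surface comes within `proximity_nm` (default 20 nm, the scale of
a synaptic cleft) of the dendrite's surface; a dendritic mitochondrion is
credited with *spanning* that terminal when it approaches the contact zone
within `proximity_nm + mito_reach_nm` (default 500 nm).  `mito_reach_nm`
deliberately covers both readings of "traversing" a synapse — direct
apposition versus residence in the spanned dendritic segment — and both
knobs are explicit parameters.

## Group statistics

`mean ± s.e.m.` with `sem = sd(n−1)/√n`; an n = 1 group reports s.e.m. as
missing with a warning.  The unpaired two-sample *t*-test defaults to the
classic pooled-variance Student form (df = n₁+n₂−2), matching the common
desk-software default of the era the reference statistics come from;
Welch's form (Welch–Satterthwaite df) is available by flag and is
recommended when group variances differ strongly, as they do for the
long-tailed cortex and DCN postsynaptic volumes.  The statistic and df are
computed from first principles; only the t-distribution tail probability
comes from SciPy, and the implementation is cross-checked against
`scipy.stats.ttest_ind` to 1e-10 in the tests.  Both groups constant and
equal yields p = 1 by convention (logged).  No multiple-testing correction
is applied by default — comparisons are per-pair — with a Bonferroni
option for the cross-region family.  Histograms use fixed-width bins
(configurable width and origin) with an optional log-spaced mode for
long-tailed groups; report generation is a pure function of its inputs, so
serialised reports are byte-identical across runs.

## Synthetic phantoms

The generator exists because the reference measurements come from manual
tracing that cannot be reproduced computationally; synthetic scenes with
closed-form ground truth are the only way to validate every stage at desk
scale.

* **Shapes.**  Mitochondria are capsules (spherocylinders): presynaptic
  phantoms near-spherical (tip-to-tip/diameter aspect drawn uniformly from
  1.0–1.6), postsynaptic phantoms elongated (2.5–6.0), mirroring the
  small-and-short versus long-and-filamentous morphology of the two
  populations.  Spheres, ellipsoids (Thomsen surface approximation,
  p = 1.6075), and branched tubes (MCI stress phantoms; no closed-form
  area) are also available.
* **Voxelisation.**  A voxel is included iff its centre lies inside the
  continuous shape — unambiguous and exactly invertible, which keeps
  voxel-count volume an exact oracle.  Anti-aliasing was rejected because
  it would break that exactness.
* **Volume distributions.**  Per-object volumes are log-normal (the
  published right-skewed histograms motivate the shape), parameterised so
  the arithmetic mean equals the region's group mean and the sd equals
  s.e.m.·√n; only mean ± s.e.m. is published, so the distribution family
  is a modelling choice.  The cortex postsynaptic group is a
  three-component log-normal mixture (weights 0.5/0.3/0.2, component
  means 0.18/1.0/2.5 µm³, component cv 0.3) representing its described
  subpopulations — one in the NA/CA1 size range, two of them 3–10× larger
  — with the mixture mean equal to the printed 0.89 µm³ exactly.  Draws
  below the resolvability floor (a sphere of 1.5 × the coarsest spacing)
  are redrawn; for the shipped presets this is vanishingly rare.
* **Scene layout.**  Each mitochondrion sits inside its own compartment
  phantom — the same capsule inflated by 40 nm (at least 1.5 voxels per
  axis, so the compartment encloses the organelle even across 100 nm
  sections).  Cells are shelf-packed into a compact grid with a one-voxel
  border; capsules are axis-aligned along x, which keeps bounding boxes
  (and memory) tight.  The NA-like preset at 4 nm voxels is the largest
  scene, ~840 megavoxels, generated and measured in a few minutes within
  ~4 GB.
* **Multi-synapse scene.**  A dendrite tube (radius 400 nm) contacted by
  n bouton spheres (radius 300 nm, 8 nm cleft, 1.5 µm pitch) holds one
  mitochondrion (radius 200 nm) spanning the first `round(fraction · n)`
  boutons; the manifest records exactly which, providing the end-to-end
  oracle for spanning counts.
* **Boundary jitter.**  Emulates tracing variability: per step, surface
  voxels erode with probability ½ and eligible neighbours are annexed with
  probability ½.  Organelles may grow into their host compartment or
  background; compartments only into background — labels never bleed into
  another object's interior.  Amplitude 0 is the identity.  Region presets
  ship with jitter 0 (the reference tracings are deliberate human work);
  jitter is a robustness knob for tests, which show compartment assignment
  stays correct under 1-voxel jitter.
* **Reproducibility.**  Seeds are mandatory wherever randomness exists;
  the manifest records the seed, every shape specification, analytic
  volume/surface/MCI/extent, true compartment, and realized voxel counts,
  and is checked for completeness (one entry per nonzero label) on every
  generation.

### What the phantoms do and do not show

The phantoms reproduce the *statistical* structure of the traced data
(group sizes, per-object volume distributions, voxel geometries,
compartment containment) and the *geometric* regimes that stress the
estimators (anisotropy, elongation, sub-resolution caps).  They do not
emulate EM grayscale, cristae, true mitochondrial branching networks,
tracing errors beyond surface jitter, or the spatial packing of real
neuropil.  Passing tests therefore demonstrate that the measurement
pipeline is unbiased and well-calibrated on known geometry at realistic
sampling — not that any particular biological tracing is correct.

## Numerical choices and degenerate inputs

* Tie-breaking: component IDs by lexicographic minimum voxel; compartment
  ties below threshold resolve to `unassigned`, above threshold to a fixed
  class order (deterministic either way).
* Single-voxel objects: volume exact, extent 0, mesh estimator falls back
  to the unsmoothed mask; never an error.
* Zero-variance t-tests: p = 1 when means are equal (logged), p = 0
  otherwise.
* Histograms always cover the data maximum, so counts sum to n.
* All generator and measurement randomness flows through
  `numpy.random.default_rng` with explicit seeds.

## Problem sizes used in validation

The shipped validation runs the four region presets at their full group
sizes (67+56, 200+50, 324+55, 85+32 objects) and native voxel geometries;
property checks use 20³ random masks (component oracle, 100 masks),
≤ 32³ contact scenes (50 scenes), spheres of radius 12–24 × spacing, and
1000-replicate null calibration for the t-test.  These sizes were chosen
so the whole suite validates every claim at the cohort scale the group
statistics refer to while remaining a desk-scale computation.
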
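# Methods

## Pipeline model and assumptions

The package implements connectivity-based parcellation of a seed nucleus as
a fixed six-stage composition per subject: streamline selection →
ROI-restricted track-density imaging → relative thresholding →
mean-normalization → winner-takes-all labelling → hypothesis-driven merge.
The underlying assumptions are those of the classic hard-segmentation
approach: (i) the streamline count through a voxel is a usable proxy for
connection density; (ii) after normalizing each target's cluster to unit
mean over its suprathreshold support, densities of differently-sized bundles
are comparable; (iii) each seed voxel is dominated by a single target
("winner takes all"), so a hard partition is meaningful.

Streamlines are consumed, never generated: inputs are TCK tractograms with
points in world millimetres (RAS) plus NIfTI masks. Transforms to the common
grid are affine; nonlinear warps are out of scope (the resampling function
is the extension point — it only needs a point mapping).

## Coordinate and rasterization conventions

- Voxel indexing is 0-based; integer voxel `i` owns the half-open interval
  `[i − 0.5, i + 0.5)` along each axis (voxel-centre convention). Streamline
  points stay in world mm everywhere; conversion to voxel space happens only
  at rasterization.
- "A streamline passes through a voxel" means geometric segment/cell
  intersection, not point membership. The rasterizer collects every crossing
  of an integer coordinate plane along the polyline (vectorized), sorts the
  crossing parameters, and reads the cell at each interval midpoint — an
  exact enumeration equivalent to a 3-D DDA but without per-segment Python
  loops. It is validated against two independent references: a brute-force
  per-cell slab-clipping oracle (exact; set equality required) and a dense
  point-sampling oracle at 0.01-voxel steps (a lower bound by construction:
  it misses cells whose chord is shorter than the step, ~0.5% of cells on
  random polylines, so the check is subset-plus-verified-residual rather
  than equality).
- Per-streamline contribution to a TDI voxel is binary: a streamline
  re-entering a voxel still counts once. TDI counts streamlines, not sample
  points. Whether the original hard-segmentation tooling counted binarily
  per voxel is not documented anywhere we know of; binary counting is this
  package's documented choice.
- Streamline–mask intersection for selection is traversal-based, not
  endpoint-based: tracts are extracted from a whole-brain tractogram
  "between" regions, which is an intersection semantics.

## Thresholds and normalization

- "25% of a cluster's intensity" is implemented as 25% of the cluster's
  maximum voxel intensity, inclusive (`x ≥ 0.25·max`). Among the plausible
  readings (of max, of range, of total) only the maximum is scale-free per
  cluster. The fraction is a config parameter (`cluster_threshold_fraction`).
- Mean normalization divides by the mean over positive (suprathreshold)
  voxels only. Including structural zeros would make the normalizer depend
  on ROI size, defeating the purpose of comparable density values. An
  all-zero cluster is dropped from the competition with a logged warning
  rather than crashing the subject.
- Winner-takes-all breaks exact ties by the configured target order
  (earliest wins) and reports the tie count. The diffuse pass-through target
  (dentate) is deliberately last in the default order, so a compartmental
  cluster wins any exact tie against it; silent arbitrariness is avoided by
  reporting every tie.
- MPM thresholds are inclusive (≥), so a cluster present in exactly 75% of
  subjects survives the 75% threshold. Nestedness of the 25/50/75% masks is
  then a theorem, which the tests assert rather than assume.

## Statistics

- SDI = 100·ν/V_ROI with ν the cluster voxel count and V_ROI the seed voxel
  count, both in subject space. Because the merge is a disjoint union, SDI
  is exactly additive: SDI(pRN) = SDI(cortex) + SDI(olive).
- LI = (L − R)/(L + R) on hemispheric volumes; |LI| > 0.1 is the descriptive
  cut-off for calling a direction (positive left, negative right).
- The laterality test is a paired sign-flip permutation test: per subject
  the left-minus-right difference vector is kept or negated as a whole, so
  flips are shared across clusters within a permutation; per permutation the
  maximum |t| over clusters forms the familywise null (t-max). Defaults:
  50,000 permutations, α = 0.05, two-sided. Sampled p-values use the add-one
  estimator (1 + b)/(m + 1), which cannot return 0. An exhaustive mode
  enumerates all 2ⁿ sign patterns for n ≤ 20 and returns exact proportions;
  note that for a two-sided statistic the fully-flipped pattern always
  reproduces |t_obs|, so the smallest attainable exhaustive p is 2/2ⁿ, not
  1/2ⁿ. Clusters with all-zero differences are defined to have t = 0 and
  p = 1. Calibration (20 subjects × 4 clusters, 1,000 simulated null
  datasets × 2,000 permutations) puts the familywise error at ~4–5% at
  α = 0.05, and power ≈ 100% for a planted effect of d = 1.5.

## The phantom: what it emulates and what it does not

The synthetic cohort exists so that every stage has an exact oracle. Design:

- A 40³ grid of 1 mm voxels; an ellipsoidal nucleus of ≈880 voxels.
- The nucleus is partitioned by greedy half-space carving along "pole"
  directions: an unplanted anterior buffer cap (30%), a dorsomedial
  interposed territory (20%, matching the small magnocellular share),
  a lateral cortical territory (30%) and a ventral olivary remainder (20%).
  Every territory is convex by construction.
- Compartmental bundles are built from *exit columns*: each territory voxel
  belongs to one column along the target's axis-aligned exit direction; each
  column carries the same number of streamlines (default multiplicity 6)
  entering at the deepest voxel, running along voxel centres out of the
  nucleus, then bending to a random point in the target mask. This makes the
  in-ROI density of each cluster exactly constant at zero jitter — the
  planted winner dominates everywhere, and recovery is exactly 100% in the
  noiseless limit. Exit directions are chosen compatible with the carving
  poles so a column never crosses a foreign territory inside the nucleus.
- The dentate bundle is diffuse and convergent: one straight ray from every
  nucleus voxel to a compact anterior target. Its pass-through density
  piles up in the anterior buffer cap; the cluster's own 25%-of-max
  threshold then removes it from the planted territories, and its normalized
  value stays well below 1 on compartment voxels (measured ≤ 0.85 across
  seeds at zero noise). This reproduces the qualitative behaviour of a
  fibre system that traverses the nucleus without defining a compartment.
- Noise: isotropic Gaussian jitter (default sd 0.5 mm) on interior points,
  a 10% fraction of spurious streamlines (half routed through an exclusion
  box — removed by selection — and half connecting mismatched
  territory/target pairs — true confounds), and per-subject rigid affine
  perturbations (0.02 rad, 0.5 mm) whose exact inverses are stored as the
  to-common transforms. Under these defaults, recovery is ≈98–99% per
  subject.

What the phantom does *not* emulate: curved fibre trajectories, tracking
biases (length/curvature priors, seeding density), partial-volume and
registration error (the to-common transforms are exact inverses, so group
alignment is perfect unless deliberately degraded), and any diffusion signal
model. Passing tests therefore demonstrate the correctness of selection,
counting, thresholding, labelling, mapping and statistics — not robustness
to tractography artefacts beyond the modelled jitter/spurious fractions.

## Problem sizes and runtime choices

Desk-scale defaults keep every experiment deterministic and fast: 5 subjects
per hemisphere (the pipeline is subject-count agnostic), ≈1,900 streamlines
per subject, 2,000 permutations per calibration dataset (50,000 for the
single confirmatory laterality run), 1,000 null datasets for familywise
calibration and 500 for power. The super-resolution factor defaults to 1 on
the phantom's 1 mm grid; the 1.25 mm → 1 mm super-resolved TDI of real
acquisitions is exposed as `--supersample`/config rather than hard-coded.

## Known limitations

- Affine-only spatial normalization; no warp estimation or application.
- Hypothesis-driven targets only; no data-driven (k-means-style) clustering.
- COG conventions differ across ecosystems (mm vs voxel, template
  resolution); the package reports both voxel-index and world-mm COGs and
  takes no position on external conventions.
- The tie-break rule makes label maps depend on the configured target order
  in the measure-zero event of exact density ties; the tie count in every
  report makes this auditable.
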
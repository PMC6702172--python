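# rnparc — connectivity-based parcellation of the red nucleus

`rnparc` parcellates a subcortical seed nucleus (designed around the human
red nucleus, RN) into connectivity-defined subregions from diffusion-MRI
streamline tractography. It is aimed at neuroimaging researchers who already
have whole-brain tractograms and region masks and want a reproducible,
tested implementation of the classic hypothesis-driven pipeline: target-wise
tract selection, track-density clusters, winner-takes-all hard segmentation,
group maximum-probability maps, and laterality statistics.

## Method

Per subject, with a seed mask, one mask per connectivity target (cerebral
cortex, inferior olivary complex, and the bilateral dentate and interposed
cerebellar nuclei), and exclusion (ROA) masks:

1. **Selection** — keep streamlines whose voxel traversal intersects the
   seed AND at least one include mask of the target AND no exclusion mask.
2. **Track-density imaging (TDI)** — each voxel's intensity is the number of
   distinct streamlines passing through it (exact segment/cell intersection,
   optionally on a super-resolved grid), restricted to the seed ROI.
3. **Thresholding** — each cluster is thresholded at 25% of its maximum
   intensity to suppress spurious tracking.
4. **Normalization** — each cluster is divided by the mean intensity of its
   suprathreshold voxels, making densities comparable across targets.
5. **Winner-takes-all** — every seed voxel is assigned to the target with
   the highest normalized density (hard segmentation; ties are broken by the
   configured target order and counted).
6. **Merge** — cortex and olive clusters form the putative parvocellular
   part (pRN), the interposed cluster the putative magnocellular part (mRN);
   the dentate cluster is excluded (its fibres may traverse the RN without
   synapsing).

At the group level, subject label maps are resampled (nearest-neighbour)
onto a common grid, binarized per cluster and averaged into maximum
probability maps (MPMs, percent of subjects per voxel), thresholded at
25/50/75%; volumes and centres of gravity are extracted per thresholded
mask. Quantities:

- **SDI** (streamline density index): `SDI = 100 · ν / V_ROI`, the cluster's
  voxel count as a percentage of the seed ROI volume.
- **LI** (lateralization index): `LI = (L − R) / (L + R)` of a cluster's
  hemispheric volumes; positive values mean left-lateralization.
- **t-max permutation test**: per cluster, a paired t statistic on
  left-minus-right differences; the null is built from random per-subject
  sign flips (shared across clusters within a permutation; 50,000 by
  default), and the maximum |t| across clusters per permutation gives
  familywise-corrected two-sided p-values.

Because real cohorts need external data, the package ships a synthetic
cohort generator (`rnparc.phantom`) that plants a known topographic
partition of the nucleus — a small dorsomedial interposed territory (~20%
of the nucleus), cortical and olivary territories splitting the remaining
compartmentalized volume, and a diffuse dentate bundle passing through —
with configurable jitter, spurious streamlines and per-subject affine
perturbations, so the entire pipeline is testable against ground truth.

## Worked example

Simulate a bilateral 5-subject phantom cohort and run the full pipeline:

```bash
rnparc run-all results/demo --seed 42
```

or step by step via the analysis drivers:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_parcellate_subjects.py
python analysis/03_group_maps.py
python analysis/04_laterality_stats.py
```

which prints, for the default phantom:

```
left: recovery of planted territories 98.5% (min 97.9%); mean SDI pRN 49.4%, mRN 20.0%
right: recovery of planted territories 98.4% (min 97.2%); mean SDI pRN 49.4%, mRN 19.9%
volumes (mm^3) of the 75%-thresholded MPMs:
side         left  right
cortex      255.0  255.0
dentate     116.0  108.0
interposed  175.0  174.0
olive       174.0  175.0
50000 sign-flip permutations, alpha 0.05, t-max correction
  cortex       mean LI -0.0008  t -0.459  p_corr 1.0000  (not lateralized)
  ...
```

Reading the numbers: winner-takes-all labels recover ≥97% of the planted
compartmentalized voxels under 0.5 mm streamline jitter and 10% spurious
streamlines; the recovered magnocellular (mRN) SDI matches the planted 20%
territory; MPM volumes are nearly symmetric across the two independently
simulated hemispheres, and accordingly no cluster shows significant
lateralization.

The CLI also exposes the stages individually: `rnparc simulate`, `rnparc
tdi` (TDI of a TCK on a reference grid, with `--supersample`), `rnparc
parcellate`, `rnparc group`, `rnparc laterality`. Exit codes: 0 success,
2 configuration error, 3 data error.

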
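# Methods

## Problem and approach

Low-dose CT (LDCT) lung-screening programmes need acquisition-level quality
assurance at a scale no radiology department can review by hand. Two
quantities capture most protocol drift: the **scan range** (how far the
scanned z-range extends beyond — or fails to reach — the lung parenchyma)
and the **image noise** (dose- and reconstruction-dependent HU mottle).
`ldctqa` measures both from organ segmentation masks, with no user
interaction, and aggregates per-scan results into cohort summaries.

## Canonical geometry

All arrays are reoriented at load time to a fixed convention: axis 0
increases toward the patient's right, axis 1 toward the back (posterior),
axis 2 toward the head (cranial). NIfTI affines and DICOM orientation tags
drive the reorientation (via nibabel's orientation machinery); nothing
downstream ever consults metadata again. The z-increment `dz` is taken from
inter-slice positions (modal distance) when a DICOM series provides them,
falling back to the thickness tag, because distance along z — not the
nominal reconstructed thickness — is what converts slice counts to
millimetres.

## Coverage

The five lobe masks are each reduced to their largest connected component
(removing stray mis-segmented voxels) and unioned into one lung mask.
Then, along the cranio-caudal axis:

* **overscan** (caudal/cranial) = number of slices strictly outside the
  lung's slice range × `dz`, with a *zero-margin* convention — no tolerance
  band is subtracted, so the value is continuous and maximally sensitive;
* **underscan** is flagged when lung tissue occupies the first or last
  slice; in that direction overscan is 0 by construction.

A scan ending exactly at the lung boundary is therefore reported as
underscan with zero overscan, and one empty slice beyond the lung yields
overscan `dz`. Alerting thresholds are deliberately site configuration
(`QAConfig`), not constants: small deviations are expected from respiratory
motion and scout-view uncertainty.

## Aortic-blood noise

Blood is homogeneous at CT scale, so the HU spread inside aortic blood is
noise, not anatomy. The extraction chain prioritizes precision over recall
— omitting lumen voxels is harmless, while wall/valve/calcification voxels
would bias the estimate:

1. largest connected component of the aorta mask (26-connectivity);
2. slice-wise in-plane erosion to a metric margin, default **3.0 mm**,
   comfortably beyond the ~1.9 mm mean aortic wall thickness. The erosion
   runs `n = ceil(margin / min(dx, dy))` iterations of a 3×3 square
   element, which guarantees the Euclidean in-plane margin in every
   direction at the cost of slight over-erosion;
3. removal of cranial slices one at a time until the 3-D mask splits into
   two (or more) components — this cuts through the aortic arch — keeping
   the **dorsal** component, i.e. the one with the most-posterior centroid
   (whole-component centroids, robust to tortuous vessels; if more than two
   components appear, the most posterior wins). A mask that never splits
   (no arch in range) passes through unchanged;
4. trimming to the lung's cranio-caudal slice interval, so only slices
   containing lung tissue contribute. "Slices containing lung" is read as
   the lung's slice *interval*; for a connected lung the two readings
   coincide. The interval trim also removes lumen above the apex.

Noise over the surviving voxels: mean `mu_raw`, sample standard deviation
`sigma_raw` (n−1 denominator; the distinction from the population SD is
negligible at realistic lumen sizes but fixed for reproducibility), and

    sigma_norm = sigma_raw * sqrt(v_raw / v_norm),   v_norm = 1 mm^3

where `v_raw = dx·dy·dz` from spacing metadata. `sigma_norm` is
voxel-size-independent: averaging k voxels divides Gaussian noise by
√k while multiplying voxel volume by k. It remains comparable only within
one reconstruction kernel. A minimum of 100 lumen voxels (configurable)
guards against degenerate lumens; below it noise is reported as
unavailable rather than unstable.

`effective_mas = mAs / pitch` is provided as a metadata utility; the
theoretical σ ∝ 1/√mAs dose law is exercised as a phantom property test
(halving simulated mAs scales injected σ by √2 and `sigma_norm` tracks it).

## Integrity checks

Pre-flight, side-effect-free checks mirror failure modes seen in screening
archives: implausible HU (minimum below a configurable −19,000 HU floor,
the signature of corrupted rescale data), inter-slice distances deviating
more than 10% from the modal distance, missing DICOM rescale tags, and
unresolved orientation. Flags mark a scan for review; they never mutate it.

## Synthetic phantoms

The phantom generator emulates exactly the features the pipeline measures:

* two elliptic-cylinder lungs partitioned into five lobes by planar z-cuts
  (enough to exercise lobe merging; no anatomical fidelity claimed);
* a candy-cane aorta — descending limb (posterior), semicircular arch,
  ascending limb (anterior) — rasterized as a tube around a sampled
  centerline via a Euclidean distance transform, with a blood lumen
  (default radius 9 mm) inside a wall (default 1.9 mm, the population mean
  wall thickness);
* configurable empty cranial/caudal margins (slices without lung) with
  exactly known distances, and optional forced edge-touching lungs to
  exercise underscan flags;
* piecewise-constant tissue HUs (lung −800, blood 40, wall 50, soft tissue
  30, air −1000) plus i.i.d. additive Gaussian noise of known σ.

Gaussian noise stands in for CT quantum noise; this is adequate because the
pipeline measures only second moments. What phantoms do **not** emulate —
noise power spectra and kernel correlations, partial-volume boundaries,
contrast variation, motion, calcifications — means passing tests establish
the correctness of the *geometry and arithmetic* of the method, not
segmentation robustness on clinical data (that is what reader review of
masks is for).

The arch is placed *above* the lung apex so that the arch split and the
lung-interval trim are independently exercisable; consequently the cranial
gap must host the arch (default 20 slices × 2 mm), making default cranial
"overscan" larger than typical clinical values, while the caudal default
(16 × 2 mm = 32 mm) matches the caudal overscan scale reported for
screening cohorts. The default noise σ of 25 HU corresponds to a
normalized noise in the mid-30s HU at the default 2.88 mm³ voxel — the
scale observed in screening data.

Default grids are deliberately compact (96×96×110 at 1.2×1.2×2.0 mm;
64×64×80 variants in the test suite; a 150×150×160 straight-tube variant
whose extracted lumen exceeds 10⁵ voxels for noise-estimator checks). At
10⁵ voxels the SD of the SD estimate is ≈0.22%, so the 2% recovery
tolerance is an ~9σ bound, and the compact cohorts (200 phantoms for
coverage, 100 for lumen purity) give exact-geometry checks in about a
minute each.

## Cohort statistics

Rating tallies (6 = Perfect … 1 = Insufficient) report cumulative at-least
proportions with **Clopper–Pearson** exact 95% intervals, computed from
beta quantiles: lower = B(α/2; k, n−k+1), upper = B(1−α/2; k+1, n−k), with
the closed-form boundaries (α/2)^(1/n) at k = n and 1−(α/2)^(1/n) at k = 0.
An independent tail-sum bisection oracle verifies the quantile route to
1e-6 in the tests. Stored values are full precision; display rounding is
one decimal for tally percentages and two decimals for cohort rates.

Cohort summaries report *conditional* directional overscan means (over
scans where that overscan is > 0 — so directional means are not additive),
underscan rates (caudal, cranial, both), normalized-noise mean ± SD with
scans lacking a noise value excluded and counted, and the mean fraction of
slices without lung. Subgroup hypothesis testing is out of scope; records
carry enough fields for external tools.

## Orchestration

`run_scan` soft-fails per stage: an unusable lumen or too-small sample is
recorded in the report (noise "unavailable" with the failing step's name)
while coverage is still delivered; only an unreadable volume is a hard
error. This keeps batch runs alive across individual corrupt scans.
`flag_exceptions` reduces a report to pass/review using configured
thresholds — any underscan or integrity flag always reviews. JSON is the
primary artifact and round-trips losslessly; the one-page PDF is derived
and optional.

## Known limitations

* Orientation checking is metadata-driven; a volume stored with *wrong but
  self-consistent* orientation metadata cannot be detected.
* The erosion margin slightly over-erodes relative to an exact Euclidean
  disk erosion (square structuring element) — intentional, precision over
  recall.
* `sigma_norm` comparability across reconstruction kernels is not
  addressed; no harmonization is attempted.
* The external neural segmenter is a soft dependency invoked behind an
  adapter; its quality is not scored here.
* Enhanced multi-frame DICOM and PACS/DIMSE networking are unsupported.
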
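# ldctqa

Automated quality assurance for low-dose chest CT (LDCT) lung screening:
**scan-range coverage** and **in-vivo image noise**, measured from organ
segmentation masks with no user interaction.

Screening programmes acquire thousands of LDCT studies; manual protocol
review does not scale. `ldctqa` quantifies, per scan:

* **Overscanning** — how far the scanned z-range extends beyond the lung
  parenchyma, caudally and cranially: `slices beyond the lung × dz` (mm),
  zero-margin convention.
* **Underscanning** — lung tissue reaching the first or last slice
  (possible truncation), flagged per direction.
* **Noise** — the standard deviation of Hounsfield units within
  descending-aortic blood, a large homogeneous in-vivo volume, normalized
  for voxel size:

  σ_norm = σ_raw · √(v_raw / 1 mm³)

  The aortic-blood mask is distilled from an aorta segmentation by keeping
  the largest component, eroding in-plane to a ≥ 3.0 mm margin (beyond the
  ~1.9 mm wall), cutting cranial slices until the mask splits and keeping
  the dorsal (most-posterior) component, and trimming to the lung's slice
  interval.

Per-scan results serialize to JSON (optionally a one-page PDF) and
aggregate into cohort summaries with exact Clopper–Pearson confidence
intervals for rating tallies. A synthetic phantom generator — lungs, a
candy-cane aorta with wall, known scan margins, known injected noise —
makes every stage verifiable against ground truth. Segmentation masks come
from an external segmenter behind a pluggable adapter (TotalSegmentator
backend optional) or from NIfTI label files; masks are never resampled.

## Worked example

```python
import ldctqa as q

# a synthetic chest: known margins (16 and 20 slices at dz = 2 mm), 25 HU noise
vol, truth = q.generate_phantom(q.PhantomSpec(seed=0))

seg = q.segment(vol, backend="phantom-truth", truth=truth)
report = q.run_scan(vol, segmentation=seg, scan_id="demo")

cov, nz = report.coverage, report.noise
print(f"caudal overscan  {cov.caudal_overscan_mm:.1f} mm")
print(f"cranial overscan {cov.cranial_overscan_mm:.1f} mm")
print(f"underscan caudal={cov.underscan_caudal} cranial={cov.underscan_cranial}")
print(f"sigma_raw {nz.sigma_raw:.2f} HU -> sigma_norm {nz.sigma_norm:.2f} HU "
      f"({nz.n_voxels} lumen voxels, v_raw {nz.v_raw:.2f} mm3)")
```

prints

```
caudal overscan  32.0 mm
cranial overscan 40.0 mm
underscan caudal=False cranial=False
sigma_raw 25.18 HU -> sigma_norm 42.74 HU (6001 lumen voxels, v_raw 2.88 mm3)
```

The coverage distances equal the phantom's constructed margins exactly
(16 × 2 mm caudally, 20 × 2 mm cranially), and the recovered σ_raw matches
the injected 25 HU to within sampling error; σ_norm is larger than σ_raw
because the 2.88 mm³ voxel is coarser than the 1 mm³ reference.

From a shell, the same pipeline runs as:

```sh
ldct-qa phantom --seed 0 --out phantom/            # volume + truth masks
ldct-qa run --input phantom/volume.nii.gz --masks phantom/ --out qa/
ldct-qa cohort --records qa/ --out summary.json
```

Rating tallies for reader studies:

```python
tally = q.tally_ratings([6]*16 + [5]*73 + [4]*8 + [3]*1)  # n = 98
print(tally.formatted_rows()[1])
# Nearly Perfect\t73\t90.8% [CI: 83.3-95.7%]
```

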
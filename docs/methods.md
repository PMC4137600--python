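# Methods

## The segmentation model

The pipeline treats GTV delineation on CT as a morphological set
problem. A dual-range intensity mask is used rather than a single
threshold because tumor and surrounding-tissue HU distributions
generally overlap: keeping the union of both ranges deliberately
over-includes tissue and defers the separation to geometry. Erosion with
a structuring element of physical radius `r` removes every voxel within
`r` of the mask complement, so any attachment neck of half-thickness
below `r` is severed and the tumor becomes its own connected component.
Union-find labeling (path halving, union by size) then enumerates
components; a volume window filters out structures that are far too
small (noise specks, vessels) or too large (chest wall, whole-lung
regions). Dilation by the *same* element approximately inverts the
erosion on the selected component; intersecting the dilated set with the
original mask keeps the result inside thresholded tissue.

Assumptions: the tumor's post-erosion volume must fall inside the
configured window while no confounder's does; the two HU ranges must
cover the tumor interior (holes in the stage-1 mask erode into real
volume loss); and attachments must be thinner than the erosion radius
somewhere along their cross-section (a broad-based wall attachment is a
documented failure mode — erosion then cannot disconnect it, and the
selection inherits wall tissue or fails the window).

### Boundary and tie-break conventions

- Out-of-bounds voxels are background for erosion, and dilation is
  clipped to the grid: the scanned field of view is never extrapolated.
- Intensity ranges are closed intervals; the single-threshold baseline
  (`threshold_baseline`) keeps voxels *strictly above* the threshold.
- The structuring-element radius in mm is converted to per-axis voxel
  radii by round-half-up, giving an ellipsoidal (anisotropy-aware) ball;
  a radius that rounds to zero on every axis degrades to `{origin}` with
  a warning.
- Labels are assigned in ascending order of each region's first voxel in
  x-fastest scan order, making label maps and downstream selection
  bit-reproducible.
- When several regions survive the volume filter and neither a seed nor
  the localization box disambiguates, the largest survivor is selected
  and a warning lists all of them.
- The dilated-and-masked result can graze mask fragments that are not
  connected to the tumor; only the connected component containing the
  selected pre-dilation region is returned, so the GTV is always a
  single component.

### Successive localization

The phase-to-phase tracking rule is: segment phase 0 unrestricted
(seeded if a seed is given); for each later phase, only candidates whose
centroid falls inside the previous GTV's bounding box expanded by
`localization_margin_mm` (default 15 mm, chosen to cover typical
respiratory excursions) are eligible. If none qualifies the phase falls
back to unrestricted selection and flags `localization_fallback` in its
diagnostics rather than failing, since an empty box more often means the
margin was too tight than that the target vanished.

### Click-seeded mode

A single voxel "click" inside the tumor replaces the tumor HU range by
the min/max of intensities in a cube of half-width
`seed_neighborhood_halfwidth` (default 2 voxels) around the seed, and
selection prefers the surviving region containing the seed, falling back
to the nearest-centroid region within `localization_margin_mm`. In
uniform background the derived range degenerates to a narrow band and
the run fails with an explicit no-target error. The surround range is
not altered by seeding.

### 2-D mode

The identical pipeline can run per axial slice (2-D elements, 2-D
labeling) with the results stacked. The volume window is then applied to
per-slice slab volumes (`n_pixels · dx·dy·dz / 1000`, i.e. area × slice
thickness), so 2-D configurations should state per-slice windows.
Selection is per slice; slices with no survivor contribute empty planes,
and stacked results are not guaranteed to be 3-D-connected.

## Parameters

| parameter | unit | default | role |
|---|---|---|---|
| `tumor_range`, `surround_range` | HU | — (per study) | stage-1 mask = union of both closed intervals |
| `volume_min_cc`, `volume_max_cc` | cc | — (per study) | window on *post-erosion* region volumes |
| `radius_mm` | mm | — (per study) | erosion **and** dilation radius |
| `element_shape` | — | `ball` | ellipsoidal ball respects anisotropic spacing; `box` available |
| `connectivity` | — | `face` | face-only maximizes the disconnecting power of erosion |
| `mode` | — | `3d` | `2d` applies the pipeline per slice |
| `seed_neighborhood_halfwidth` | voxels | 2 | HU-range estimation cube in seeded mode |
| `localization_margin_mm` | mm | 15 | bounding-box expansion / seed distance limit |

There are no canonical values for the HU ranges, the volume window or
the radius: they are study inputs, chosen from prior knowledge of the
lesion (a prior CT of the same patient, typical tumor volumes). The
phantom suite ships matched configurations — e.g. soft-tissue ranges
(−150, 150) HU, window [30, 200] cc and radius 4 mm for the 6-cm sphere
— as worked examples of that choice, not as recommendations for
clinical data. The pipeline itself contains no randomness; identical
input and configuration give voxel-identical output.

## The synthetic phantom

`phantom_synth` emulates a bench validation: an anthropomorphic chest
section — a soft-tissue cylinder (+40 HU) with a coaxial lung cavity
(−800 HU) — holding a water-equivalent sphere (0 HU, default 6 cm
diameter) that moves rigidly on a known waveform over 10 phases
(labels 0–90% of the cycle), with additive Gaussian noise (default
σ = 20 HU) seeded per (rng_seed, phase). The default grid is
120×120×64 voxels at 1.5×1.5×2.5 mm — a desk-scale stand-in for a
512×512, 2.5-mm-slice thoracic protocol. The sinusoidal waveform is
`amplitude · cos(2π·p/100)`, whose 10-phase samples hit both extremes,
so the sampled COG span is exactly twice the amplitude. Voxelization is
center-in-sphere; ground truth is the exact voxelized sphere (plus the
attachment neck up to the wall, when configured), and the truth
trajectory carries analytic centers with voxelized volumes. Suite cases
add the classical failure-mode geometries: a wall-attached sphere
(3-mm-radius tissue neck), a diaphragm-like dome of tumor-equal HU, and
a small (1.5 cm) low-contrast (−400 HU) sphere.

What the phantom does **not** emulate: partial-volume blur at tissue
interfaces, reconstruction and motion artifacts, irregular breathing,
tumor deformation, and heterogeneous lesion texture. Passing the
phantom tests therefore demonstrates the correctness of the
morphological machinery and the tracking logic under known geometry, not
clinical-grade accuracy on patient scans, where threshold overlap
between tumor and vasculature/atelectasis is the dominant difficulty.

With the default noise level the tissue classes are separated by many
standard deviations, so the stage-1 mask — and hence the whole run — is
in practice identical across noise seeds; the multi-seed validation
guards the claim rather than averaging away variance.

## Error metrics and validation bounds

Overlap: Dice `2|A∩B|/(|A|+|B|)`, sensitivity `|A∩B|/|A|` (A = truth),
PPV `|A∩B|/|B|`. Both-empty pairs score 1 (agreement on absence),
exactly-one-empty pairs 0. Report tables append mean and *sample*
(n−1) standard-deviation rows; with a single case the SD row is 0 and
flagged via `DataFrame.attrs["sd_defined"]`.

Trajectory error compares motion profiles, not absolute positions: per
phase, the COG displacement from the phase-0 COG is computed for
estimate and truth, and the relative error is
`‖d_est − d_true‖ / max(‖d_true‖, ε)` with ε one voxel diagonal
(≈ 3.2 mm at the default spacing); phases with `‖d_true‖ < ε` are
flagged, where the quotient is effectively an absolute error in units
of ε. Volume error is `|v_est − v_true| / v_true`. The validation bound
is taken on the *maximum* over phases (and noise realizations), the
stricter of the reasonable normalizations.

Measured on the baseline phantom (five realizations), the pipeline
stays within 0.3% volume error and 1.5% COG-displacement error — the
5% bound asserted by the acceptance suite holds with a wide margin.
Residual error is purely discretization: the digital opening of the
voxelized sphere by the rounded voxel ball loses a thin crescent of
boundary voxels (≈0.08% of the volume at the default grid; the
intersection step guarantees no voxel is ever added), and the COG of a
voxelized sphere quantizes as the center crosses voxel boundaries.

## Problem sizes

Unit and property tests run on small random grids (12×12×8 to 16×16×8)
against brute-force double-loop and flood-fill oracles; end-to-end
tests and the acceptance script use the full default phantom grid
(120×120×64, ≈0.9 M voxels), where one phase segments in under a
second and the five-realization validation completes in about half a
minute.

## Known limitations

- Broad-based wall attachments (necks thicker than any admissible
  erosion radius) cannot be disconnected morphologically; the boundary
  placed there is a geometric convention, not tissue evidence.
- The volume filter assumes the tumor is the only structure in its
  post-erosion volume window near the search region; two similar-volume
  candidates are disambiguated only by seed or localization box,
  otherwise by the documented largest-volume rule.
- NIfTI affines are reduced to zooms + translation; oblique orientations
  are not resampled. DICOM reading assumes one consistent orientation
  per series (mixed orientations raise a format error).
- The 2-D mode trades the 3-D volume prior for per-slice slab windows
  and can fragment along z; it exists for single-slice and quick-look
  use.
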
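# mpsl4d

Contour-free segmentation of a gross target volume (GTV) across the
breathing phases of a 4D CT series, with motion quantification and
overlap-metric validation, for radiotherapy-planning workflows.

Respiration-correlated (4D) CT reconstructs ~10 volumes per breathing
cycle; delineating the tumor on every phase by hand is slow, and
deformable-registration propagation needs a manual contour on one phase
to start from. `mpsl4d` implements an alternative that needs no prior
contour: **morphological processing with successive localization**. Per
phase:

1. a binary mask keeps voxels whose intensity lies in either of two
   Hounsfield-unit (HU) ranges — one for the tumor, one for surrounding
   tissue whose intensities overlap it: `M = {v : I(v) ∈ [t₁,t₂] ∪ [s₁,s₂]}`;
2. the mask is **eroded**, `M ⊖ B = {x : x+b ∈ M ∀ b ∈ B}`, with a
   structuring element `B` built from a physical radius in mm, which
   disconnects the tumor from wall/diaphragm attachments;
3. the disjoint regions are labeled by **union-find** connected-component
   labeling and their volumes computed;
4. regions with volumes outside a plausible tumor window
   `[V_min, V_max]` are discarded, and one survivor is selected (click
   seed, localization box, or largest-in-window);
5. the selected region is **dilated** by the same element,
   `A ⊕ B = {a+b : a ∈ A, b ∈ B}`, restoring the tumor to its
   approximate original size, and intersected with the stage-1 mask so
   dilation never annexes background.

Across phases, *successive localization* restricts candidates to the
previous phase's GTV bounding box expanded by a margin, tracking the
target through the cycle. The center of geometry (COG) of the per-phase
GTV gives the motion trajectory; Dice, sensitivity and positive
predictive value (PPV) quantify agreement with ground truth. A built-in
synthetic 4D chest phantom (lung-HU cavity in a body shell, moving
water-HU sphere, optional wall attachment and diaphragm analog, seeded
noise) provides known ground truth for validation.

## Worked example

```python
import numpy as np
from mpsl4d import (generate_phantom, segment_series, compute_trajectory,
                    trajectory_error, max_errors, overlap_metrics)
from mpsl4d.phantom_synth import suite_case

case = suite_case("baseline", rng_seed=1)          # 6-cm sphere, 10 mm z-motion
series, truth_masks, truth_traj = generate_phantom(case.spec)
results = segment_series(series, case.config)

dices = [overlap_metrics(t, r.gtv_mask).dice
         for t, r in zip(truth_masks, results)]
print(f"Dice vs ground truth: mean {np.mean(dices):.4f}, min {min(dices):.4f}")

est = compute_trajectory(results, series.phase_labels)
err = trajectory_error(est, truth_traj,
                       eps_mm=float(np.linalg.norm(case.spec.spacing)))
mv, md = max_errors(err)
print(f"max relative volume error:           {100*mv:.2f}%")
print(f"max relative COG-displacement error: {100*md:.2f}%")
```

prints

```
Dice vs ground truth: mean 0.9990, min 0.9988
max relative volume error:           0.24%
max relative COG-displacement error: 1.42%
```

i.e. on the baseline phantom the pipeline recovers the moving 6-cm
sphere almost voxel-exactly in all 10 phases, its volume is tracked to
within 0.3% and its COG motion profile to within 1.5% of the analytic
ground truth.

The same workflow is available from the shell:

```sh
mpsl4d phantom  --spec baseline --seed 7 --out phantom/
mpsl4d segment  --input phantom/ --config cfg.yaml --out seg/
mpsl4d evaluate --truth phantom/ --test seg/ \
    --truth-traj phantom/truth_trajectory.csv \
    --test-traj seg/trajectory.csv --out eval/
```

where `cfg.yaml` holds the pipeline parameters
(`tumor_range: [-150, 150]`, `volume_min_cc: 30`, `radius_mm: 4.0`, ...).

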
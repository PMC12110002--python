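# dbsfuse

Rigid multimodal fusion of a postoperative high-resolution, narrow-FOV
cone-beam CT volume with a preoperative T2-weighted MRI, for reviewing and
programming **directional deep brain stimulation (dDBS)** electrodes. The
segmented contacts that steer the stimulation field are visible only in the
high-resolution CT-like volume; the stimulation target (the subthalamic
nucleus) only on T2 MRI. Fusing the two lets the contacts be judged inside
the anatomical target.

Because the modalities share little anatomy, registration is
semi-automated, mirroring the clinical protocol:

1. **centered initialization** — superimpose the two volume centers;
2. **landmark rigid fit** — closed-form least-squares (Kabsch/Horn) fit
   `argmin_T Σᵢ ‖T(fᵢ) − mᵢ‖²` over corresponding points picked on
   structures visible in both modalities (the semicircular canals);
3. **mutual-information refinement** — gradient descent on a Mattes
   mutual-information metric `−MI = −Σ p(f,m) ln [p(f,m)/(p(f)p(m))]`
   estimated from a 1% random voxel sample with B-spline Parzen windows
   (learning rate 0.33, ≤ 30 iterations, single resolution);
4. **evaluation** — target registration error
   `TREᵢ = ‖T(fᵢ) − mᵢ‖₂` (mm, mean ± sample SD) on a held-out landmark
   set, before and after refinement;
5. **electrode-oriented MPR** — oblique reformation along the electrode
   axis, window/level mapped and alpha-blended.

No patient data is required anywhere: a synthetic two-modality phantom
module generates ground-truth-linked volume pairs, landmark files and
electrode geometry, so the whole pipeline is testable end to end.
See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
from dbsfuse import PhantomSpec, run_phantom_trial, RegistrationParams

trial = run_phantom_trial(PhantomSpec(seed=7), RegistrationParams(seed=7))
pre, post = trial["tre_pre"], trial["tre_post"]
print(f"pre-registration  TRE: {pre.mean_mm:.2f} +/- {pre.sd_mm:.2f} mm")
print(f"post-registration TRE: {post.mean_mm:.2f} +/- {post.sd_mm:.2f} mm")
print(f"mutual information: {trial['result'].mutual_information:.3f} nats "
      f"after {trial['result'].iterations_run} iterations")
```

prints

```
pre-registration  TRE: 0.81 +/- 0.00 mm
post-registration TRE: 0.06 +/- 0.03 mm
mutual information: 0.249 nats after 12 iterations
```

One synthetic subject is generated (unknown rigid motion ≤ 5°/5 mm between
the two acquisitions), the landmark initialization is degraded by a 1 mm
RMS offset emulating imperfect manual picks, and mutual-information
descent pulls the alignment back: the error on landmarks never shown to
the optimizer drops from 0.81 mm to 0.06 mm, well below the 1 mm voxel of
the coarse volume.

The same workflow is available from the shell:

```sh
dbsfuse simulate --seed 7 --out subject7            # phantom bundle (NIfTI + .fcsv + truth)
dbsfuse register --fixed subject7/fixed_mr.nii.gz --moving subject7/moving_ct.nii.gz \
    --init-landmarks-fixed subject7/init_fixed.fcsv \
    --init-landmarks-moving subject7/init_moving.fcsv \
    --out-transform T.txt
dbsfuse evaluate --transform T.txt --fixed-landmarks subject7/eval_fixed.fcsv \
    --moving-landmarks subject7/eval_moving.fcsv --out tre.json
dbsfuse mpr --fixed subject7/fixed_mr.nii.gz --moving subject7/moving_ct.nii.gz \
    --transform T.txt --distal 8,2,-8 --proximal 16,8,18 --out fused.png
dbsfuse run --config pipeline.yaml                  # all stages + run report
```

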
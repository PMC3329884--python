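# featwarp

Feature-based deformable image registration for 2-D and 3-D medical
images, aimed at image-guided radiation therapy problems such as aligning
respiratory phases of a 4D CT or tracking organ deformation between
sessions.  Instead of optimising an intensity-similarity cost, the method
derives the transformation directly from automatically detected and
matched tissue features, so no iterative optimisation is needed:

1. **Detect** — feature points are selected on the template and the
   target image from the gradient energy in a local neighbourhood,
   restricted to a tissue intensity window (e.g. bone > 100, soft tissue
   0–100 in CT numbers).
2. **Associate** — each point carries a 192-component SIFT-style
   signature: orientation histograms of the gradient, built over the 8
   octants of its 8×8×8 neighbourhood, with eight 45° bins per coordinate
   plane.  Points are matched by the least-squares score
   S = Σ_α |(∇I)_α − (∇I′)_α|²; a match is accepted only when the ratio
   κ = S₁/S₂ of the two best scores is below 50%, and a bidirectional
   pass keeps only pairs whose reverse match returns the original point.
3. **Interpolate** — the surviving pairs are control points for a
   thin-plate spline f(x) = a₁ + a·x + Σ w_i U(|p_i − x|) with
   U(r) = r² log r², solved from L·(W|a)ᵀ = Y with L = [[K, P], [Pᵀ, 0]].
   The spline is evaluated on the target grid to give a dense
   displacement vector field and a backward-warped template.

The package also ships digital deformation phantoms — textured CT-like
bodies with embedded spherical markers, warped by the analytic harmonic
map x′ = (1 + b cos m q)·x or by smooth Gaussian-lobe fields with exact
ground truth — plus evaluation tools for displacement-error maps and
marker residual (target-registration-error) statistics.  See
`docs/methods.md` for the full model description and design choices.

## Worked example

Register a 170×170 textured phantom slice (2 mm pixels) to a copy
deformed by the harmonic map with b = 0.12, m = 1 (≈16 mm peak
displacement), then compare the recovered field with the analytic ground
truth inside the body:

```python
from featwarp.experiments import harmonic_phantom_experiment
import json

report = harmonic_phantom_experiment(seed=1)
print(json.dumps(report, indent=1))
```

```json
{
 "mean_error_mm": 1.081395279163296,
 "max_error_mm": 5.3208870085012405,
 "pct_pixels_error_gt_10mm": 0.0,
 "pct_pixels_error_gt_2mm": 14.082574529125608,
 "n_pixels": 16034,
 "pre_registration_mean_mm": 5.233578887068739,
 "peak_displacement_mm": 15.960663033412402,
 "stages": {
  "detected_template": 217,
  "detected_target": 218,
  "forward_matches": 138,
  "surviving_matches": 109,
  "n_control_points": 109
 }
}
```

Reading the output: 217/218 feature points were detected on the two
images; 138 forward associations passed the κ-ratio test, of which 109
survived the bidirectional check and served as TPS control points.  Over
the 16 034 in-body pixels, the mean displacement error against the
analytic ground truth is 1.08 mm (down from 5.23 mm before registration),
the worst pixel is off by 5.3 mm, and no pixel exceeds 1 cm.

The same pipeline is available on files from the shell:

```sh
featwarp phantom --mode 2d --size 170 --spacing 2.0 --seed 1 \
    --deform harmonic:b=0.12,m=1 \
    --out-template t.mha --out-target g.mha --out-truth truth.mha
featwarp register --template t.mha --target g.mha \
    --out-field dvf.mha --out-warped warped.mha
featwarp evaluate --estimated dvf.mha --truth truth.mha --report report.json
```

`featwarp detect / describe / match / warp` expose the individual stages;
every command echoes its effective configuration as a JSON log line.

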
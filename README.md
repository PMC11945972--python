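# pupilloc

Pupil center localization for near-infrared periocular images that stays
accurate when the image is defocus-blurred.

Eye trackers used for driver-fatigue monitoring capture eyes that drift off
the camera's focal plane; the resulting blur diffuses the pupil boundary and
breaks methods that fit circles or ellipses to edge points. `pupilloc`
implements a double-constraint pipeline that never touches edges:

1. **Grayscale constraint — rough ROI.** The pupil occupies the lowest-gray
   mode of the histogram regardless of blur. The segmentation threshold is
   the valley to the right of the darkest significant histogram mode; the
   binarized foreground's per-row and per-column integral projections bound
   the pupil, and the rectangle is expanded by 1/20 of the image long side.
2. **Geometric constraint — region refinement.** After opening, 8-connected
   labeling and glint-hole filling, every candidate region is scored with
   the pupil shape index

   *w* = λ₁ · I_minor / I_major + λ₂ / (1 + ΔFittingError),  λ₁ = 0.6, λ₂ = 0.4,

   where I_minor / I_major is the eigenvalue ratio of the region's
   second-central-moment matrix and ΔFittingError is the normalized
   symmetric difference between the region and its moment-equivalent
   ellipse. The highest-index region is the pupil.
3. **Geometric moments — center and size.** With the region as a binary
   density, M_ij = Σ Σ xⁱ yʲ f(x, y) gives the sub-pixel center
   (x_c, y_c) = (M₁₀/M₀₀, M₀₁/M₀₀) and the equivalent-circle radius
   √(M₀₀/π), in one O(P) pass over the P region pixels.

The package ships a ground-truthed synthetic NIR eye-image generator
(elliptical pupil, iris, sclera, skin, corneal glints, eyebrow distractor,
Gaussian defocus surrogate mapping z ∈ [0, 20] cm to σ ∈ [0, 6] px) and a
blur-stratified evaluation harness (Euclidean error; accuracy with the
1 %-of-long-side correctness criterion).

## Worked example

```bash
pupilloc simulate --n 2 --levels 0,10,20 --out-dir demo --seed 42
pupilloc locate demo -o demo/results.csv
pupilloc eval demo/results.csv demo/manifest.csv --report demo/report.json
```

`locate` writes one row per image:

```
filename,status,xc,yc,radius,w
eye_z0_0000.png,ok,332.020,272.038,27.909,0.8992
eye_z0_0001.png,ok,330.451,271.163,18.195,0.8609
eye_z10_0002.png,ok,270.759,251.873,15.858,0.8602
...
```

`xc, yc` are the sub-pixel pupil center (image frame), `radius` the
equivalent-circle radius in pixels, and `w` the winning region's shape index
(near 1 for a clean circular pupil). `eval` joins predictions to the
ground-truth manifest and prints per-defocus-level statistics:

```
  z_cm     n  mean_err_px  accuracy
     0     2        0.000     1.000
    10     2        0.500     1.000
    20     2        0.352     1.000
overall n=6 mean_err=0.284 accuracy=1.000
```

Mean error is the average Euclidean distance to the true centers;
accuracy is the fraction of images located within 1 % of the long side
(6.4 px at 640×480).

The same pipeline is available as a library:

```python
from pupilloc import locate_pupil, load_gray_image

res = locate_pupil(load_gray_image("eye.png"))
print(res.xc, res.yc, res.radius, res.w, res.status)
```

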
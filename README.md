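# cartidiff

Quantitative analysis of contrast-enhanced CT of articular cartilage.

Cationic iodinated contrast agents bind electrostatically to the negatively
charged glycosaminoglycans of cartilage, so the iodine a cartilage layer
takes up from an immersion bath reports on proteoglycan content — a
candidate imaging biomarker for early (post-traumatic) osteoarthritis.
`cartidiff` implements the full analysis chain for such experiments at two
scales, together with a synthetic-phantom generator that simulates the
underlying diffusion physics and imaging geometry so every step can be
validated against known ground truth:

* **Calibration** — ordinary least-squares fit of the affine map
  `attenuation = a + b·c` between iodine concentration `c` (mgI/mL) and
  attenuation (gray levels at the microCT scale, HU at the clinical scale),
  and its inverse `c = (attenuation − a)/b`.
* **Uptake kinetics (planar microCT)** — baseline subtraction, ROI means,
  fits of the saturating exponential `A(t) = a(1 − e^(−t/τ))` (the
  single-time-constant surrogate of Fickian slab diffusion), the saturation
  time `τ95 = 5τ`, depth profiles from articular surface to tidemark, and
  layer (superficial/mid/deep) summaries.
* **Volumetric analysis (clinical CT)** — fiducial-based rigid registration
  (Kabsch), trilinear resampling, pre/post subtraction, threshold +
  connected-component segmentation of the iodine enhancement, voxelwise
  conversion to concentration, cylindrical-VOI statistics, and cartilage
  volume/thickness morphometry.
* **Washout kinetics** — exponential decay fits `c(t) = a_w e^(−b_w t)` and
  the washout time `t_w = ln(a_w/(0.05·ref))/b_w`.
* **Tissue distinguishability** — Cohen's d, two-sample Mann–Whitney and
  Kolmogorov–Smirnov tests over connective/bone/cartilage attenuation
  samples, plus a one-sample normality check.
* **Synthetic data** — a conservative finite-volume solver for 1-D Fickian
  diffusion into a slab from a finite, depleting bath with partition
  coefficient κ at the surface (exact spectral time propagation, Richardson
  spatial extrapolation), a planar radiograph renderer, a paired pre/post
  CT phantom with known rigid motion, and washout curve simulation.

## Worked example

```python
import numpy as np
from cartidiff.synthetic import SlabDiffusionConfig, solve_slab_diffusion
from cartidiff.pipeline import microct_study, ct_study, washout_study

# physics: a 0.5 mL, 10 mgI/mL bath over a 2 mm cartilage layer (0.157 mL),
# partition coefficient 6.34 -> equilibrium plateau 21.2 mgI/mL
field = solve_slab_diffusion(SlabDiffusionConfig())
print(field.depth_mean()[-1])        # 21.20  (mgI/mL in cartilage at 26 h)
print(field.c_bath[-1])              # 3.3432 (depleted bath)

res = microct_study(seed=1)
print(res["tau95_h"], res["c24_mgi_ml"], res["relative_c24"])
# 1.99 h saturation time, 20.93 mgI/mL at 24 h, cartilage/bath ratio 6.45

ct = ct_study(seed=1)
print(ct["dice"], ct["voi_mean_concentration_mgi_ml"], ct["thickness_mm"])
# 0.971 segmentation Dice vs ground truth, 9.85 mgI/mL recovered from a
# true 10 mgI/mL map, 2.29 mm mean thickness (truth 2.39 mm)

print(washout_study(seed=1)["washout_time_h"])
# 311.5 h to fall to 5% of the post-immersion concentration
```

Interpretation: the cartilage ends up roughly six times more concentrated
than its bath (electrostatic partitioning), saturates on a ~2 h timescale,
and the volumetric chain recovers the phantom's iodine map, volume and
thickness to within a few percent at a contrast-to-noise ratio of ~5.

A thin CLI exposes the same steps
(`cartidiff simulate-plug|simulate-ct|fit-calibration|fit-uptake|register|
segment|morphometry|washout|tissue-stats|report`), each with `--seed` and
`--out`.

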
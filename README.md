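# patchtrack

Kinematic analysis of root growth from time-lapse micrographs.

Growing roots elongate because cells leaving the apical meristem pass
through a zone of rapid expansion. Where that elongation zone sits, how
long it is, and how fast material within it expands are *kinematic*
phenotypes: they describe the motion of root material without reference
to the forces that cause it. `patchtrack` measures them from an ordinary
time series of grayscale images (e.g. 120 frames at 30 s intervals from a
horizontal microscope at 1450 px mm⁻¹) by:

1. **Patch tracking.** Many small circular image patches ("disks") are
   placed every 10 px along a user-seeded midline anchored at the
   quiescent center (QC). For each consecutive frame pair, the affine
   transform `T = (v, ∇v)` — translation plus a velocity-gradient matrix
   that lets the patch stretch and rotate — is found by iteratively
   minimizing the intensity-constancy residual
   `D_t I = I(T·dx̃ + x, t+1) − I(x̃, t)` with a Gauss–Newton step
   `dT = −D_t I · M†`, where `M = ∇I ⊗ dx̃`. Iteration stops when
   ‖dT‖ < 10⁻⁶ px (typically ≤ 6 iterations). Each tracked disk yields
   one (position, velocity) sample relative to the tracked QC disk —
   roughly 15,000 samples per one-hour stack.
2. **Velocity-profile fitting.** The point cloud is fit by Nelder–Mead
   with the four-parameter flexible logistic of Morris & Silk,

   v(x) = v_f · [1 + e^(−k(x−x₀))]^(−1/n),

   with final rate `v_f` (mm h⁻¹), steepness `k` (mm⁻¹), reference
   position `x₀` (mm from the QC) and asymmetry exponent `n`.
3. **Trait extraction.** Differentiating v(x) gives the bell-shaped
   relative elemental growth rate profile, REGR(x) = 100·dv/dx (% h⁻¹).
   Four traits summarize it: the maximum REGR, its axial position
   (`x₀ − ln n / k`), the elongation-zone length (where REGR exceeds 20%
   of its maximum) and the average growth rate (= v_f).

A synthetic-stack generator with exact ground truth — a textured,
elongating root whose material moves under a prescribed flexible-logistic
field — is included as first-class, tested code and underpins the whole
validation story.

## Worked example

Render a short synthetic acquisition (20 frames, coarse 400 px mm⁻¹
optics so 520 px of midline span the whole growth zone) and analyze it:

```sh
patchtrack simulate --out demo --frames 20 --resolution 400 --span 520 --noise 0.01
patchtrack run --stack demo/stack --points demo/seeds.csv --resolution 400 --out demo/analysis
```

which prints

```
samples: 1007  dropped: 0
max REGR 24.58 %/h at 0.350 mm; zone 0.588 mm; rate 0.1000 mm/h
```

Reading: 1007 (position, velocity) samples were tracked (53 disks × 19
frame pairs, none dropped); the fitted REGR profile peaks at 24.6 % h⁻¹
at 0.350 mm from the QC; material expands at more than 20% of that peak
over 0.588 mm of root; and the root as a whole elongates at 0.100 mm h⁻¹.
The generator's ground truth was v_f = 0.1 mm h⁻¹, k = 10 mm⁻¹,
x₀ = 0.35 mm, n = 1, for which the closed-form traits are 25 % h⁻¹,
0.35 mm, 0.577 mm and 0.1 mm h⁻¹ — every trait is recovered within a few
percent even from this short stack, and within <1% from the full
120-frame default.

`demo/analysis/` also contains `velocity_points.csv` (the point cloud),
`disk_coordinates.csv`, `fitted_velocity.csv`, `regr_profile.csv`,
`traits.csv`, a `qc_plot.png` of cloud + fit + REGR curve, and
`run_log.json` with per-disk drop reasons and fit diagnostics.

For real data, `--stack` takes a directory of single-page TIFFs (frames
in lexicographic order) or one multi-page TIFF, and `--points` a CSV of
10–12 midline seed coordinates whose first row marks the QC. `patchtrack
fit --cloud points.csv` refits an existing point cloud, so the kinematic
model is reusable with other trackers' outputs.

## Library use

```python
from patchtrack import (SyntheticSpec, render_stack, interpolate_midline,
                        TrackingConfig, track_stack,
                        fit_flexible_logistic, extract_traits)
import numpy as np

stack = render_stack(SyntheticSpec())          # default 120-frame stack
midline = interpolate_midline(stack.seed_points, 100)
out = track_stack(stack.frames, midline, TrackingConfig())
x = np.array([s.station_mm for s in out.samples])
v = np.array([s.axial_velocity_mm_h for s in out.samples])
fit = fit_flexible_logistic(x, v, qc_referenced=True)
print(extract_traits(fit.params))
```

See `docs/methods.md` for the model, its assumptions, the numerical
choices and known limitations.
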
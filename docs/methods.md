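# Methods

## The measurement problem

A root elongates because material between the quiescent center (QC) and
any point further up the root expands. Watching a fixed point on the
image therefore confuses two things: the motion of the material and the
growth of everything between it and the QC. The kinematic view resolves
this by tracking identified pieces of material (a Lagrangian description)
and reporting their axial velocity *relative to the QC* as a function of
their current distance from the QC. In a steadily growing root this
velocity profile is sigmoidal: near zero in the meristem, rising steeply
through the elongation zone, and saturating at the root's overall
elongation rate in mature tissue. Its spatial derivative — the relative
elemental growth rate, REGR(x) = 100·dv/dx in % h⁻¹ — is the local
expansion rate of the material at x, and is the profile the biology
cares about.

## Patch motion model and solver

Pixel intensities I(x, t) act as endogenous fiducial marks (cell walls,
air spaces). Under constant illumination and a stationary camera, the
material derivative of intensity vanishes for correct tracking:
D_t I = v·∇I + ∂I/∂t = 0. Because growing tissue stretches and (in a
bending root) rotates, a patch around x moves to first order as

    d  →  d + ∇v·d + v

for in-patch offsets d, giving six unknowns T = (v, ∇v) per patch per
frame pair. Writing M = ∇I ⊗ (1, dx, dy) over the patch, the residual
r(T) = I(T·d̃ + x, t+1) − I(x̃, t) is driven to zero by Gauss–Newton
iteration from the identity transform: dT = −M†·r, T ← T + dT, stopping
when the update norm drops below 10⁻⁶ px or after `max_iter` (default
50, at which point the disk is dropped and logged).

Numerical choices, each config-exposed:

* **Shared pre-smoothing, consistent gradient.** Both frames of a pair
  are Gaussian-smoothed once (σ = 0.5 px) and the template gradient is
  taken by central differences of the *same* smoothed frame the residual
  samples. Consistency matters: if the gradient is smoothed but the
  residual is not (or vice versa), the fixed Jacobian M disagrees with
  the residual's true slope and the iteration's contraction degrades
  from ~6 to ~9 iterations at the 10⁻⁶ px threshold. σ was set at
  0.5 px after measuring warp-recovery bias across 20 textures: the blur
  does not commute with stretch, and σ = 1 px costs up to 2% relative
  parameter error on constructed warps versus 0.36% at σ = 0.5, while
  noise robustness (1% read noise) is indistinguishable.
* **Bicubic warp sampling.** Sub-pixel samples are cubic-spline
  interpolated from coefficients prefiltered once per frame pair;
  bilinear is available (`--bilinear`) but measured ~50× less accurate
  on constructed warps (worst cases slightly above 1% relative error).
  Template and target are sampled with the same scheme so an identical
  frame pair gives an exactly zero residual at the identity — with mixed
  schemes a static stack shows spurious sub-pixel motion.
* **Fixed Jacobian.** M (and its pseudo-inverse) is evaluated once per
  disk per pair, on the un-warped template. A singular-value condition
  number above 10⁸ flags a textureless patch, which is dropped.
* **Update norm.** dT mixes px (translation) with dimensionless gradient
  entries; the gradient part is scaled by the disk radius so the whole
  6-vector norm is in pixel units, making the 10⁻⁶ px threshold
  meaningful for all six parameters.

## Geometry and referencing

The midline is the piecewise-linear curve through the user's 10–12 seed
points, resampled to 100 points equally spaced in arc length; the first
point is the QC exactly. (Resampling an already equally-spaced polyline
is idempotent to machine precision; on a generic curved polyline the
fixed point is approached only up to the chord/arc difference at seed
corners, below 0.01 px in practice.) Disks of radius 15 px (≈ 10 µm at
1450 px mm⁻¹) sit at stations 0, 10, 20, … px along the midline.

Each disk's velocity is the translation component of its transform minus
the *tracked QC disk's* translation, projected on the local midline
tangent (central difference of the neighboring midline points, oriented
away from the QC). Subtracting the QC disk makes velocities immune to
whole-root drift in the frame; if the QC disk itself fails to track, the
frame pair is skipped. Between pairs the midline is advected by the
translation of the nearest tracked disk and re-resampled, so stations
remain arc-length positions from the QC as the root grows; a
`fixed_midline` flag holds the frame-0 midline instead.

## Velocity profile, fitting, traits

The flexible logistic v(x) = v_f·[1 + e^(−k(x−x₀))]^(−1/n) is evaluated
in log space (np.logaddexp) so huge |k(x−x₀)| cannot overflow, and its
derivative is analytic:

    REGR(x) = 100·(v_f·k/n)·u·(1+u)^(−1/n−1),  u = e^(−k(x−x₀)),

peaking at x₀ − ln(n)/k.

Fitting minimizes the unweighted SSE over the cloud with Nelder–Mead on
(log v_f, log k, x₀, log n). The starting point is data-driven (v_f from
the 95th velocity percentile; x₀ where a moving median first crosses
v_f/2; k from 4·slope/v_f there; n = 1), with three restarts jittered by
a seeded RNG; the best SSE wins. Samples are canonically sorted before
fitting, so the result is exactly invariant to input order. A cloud with
no velocity spread (e.g. a static stack) short-circuits to a degenerate
result with v_f ≈ mean velocity and a warning.

**QC-referenced fitting.** Tracked velocities are relative to the QC
disk, so the model prediction for a sample at x is v(x;θ) − v(0;θ), not
v(x;θ). The difference only matters when the profile's apical tail has
not vanished at the QC (for the default synthetic truth, v(0) is 2.9% of
v_f); ignoring it drags the correlated (k, x₀, n) parameters far along
their ridge (measured: −7%, −16%, −35% respectively) while barely moving
the traits. The pipeline therefore fits with `qc_referenced=True`; the
bare `fit_flexible_logistic` default fits v(x) directly.

Traits: maximum REGR and its position come from the closed-form peak
(position clipped at the QC); the elongation zone is bounded by the two
solutions of REGR = 0.2·max, found with bracketed Brent root-finding
(xtol 10⁻¹²) on either side of the peak, the apical bound clipped at
x = 0 and flagged when the profile is still above threshold at the QC.
The average growth rate is reported as v_f, the model's plateau; note
that the area under REGR from the QC is strictly v_f − v(0), which
coincides with v_f only when the tail has vanished at the QC — the
conservation test verifies the former identity.

## Synthetic acquisitions

The generator renders what the tracker was built for: a dark, textured
root on a bright backlit field, elongating under a prescribed
flexible-logistic field. Material trajectories solve dx/dt = v(x) with
an adaptive RK integrator (rtol 10⁻¹⁰; a separate constant-velocity mode
avoids the stiff large-k limit), cross-checked in tests against an
independent fixed-step RK4 integrator to 10⁻⁶ mm. A band-limited random
texture (Gaussian-blurred white noise, scale 3 px) is laid down in
material coordinates inside a tube-with-hemispherical-tip mask (soft
2 px edge), advected per frame by the inverted material map, sampled by
cubic interpolation and topped with Gaussian read noise (σ = 0.01 of the
intensity range — ordinary CMOS-camera noise). The image frame holds
mature tissue approximately fixed, so the QC drifts apically through the
series, exercising the QC-relative referencing. An optional
constant-curvature mode bends the axis to exercise the rotation part of
the transform.

Defaults mirror the reference acquisition: truth (0.1 mm h⁻¹, 10 mm⁻¹,
0.35 mm, 1) — wild-type-like magnitudes — 120 frames at 30 s, 1450
px mm⁻¹, and a 1250 px midline span giving 126 disks and ≈ 15,000
velocity samples per stack. Identical specs (seeds included) render
bit-identical stacks, and every stack ships its ground truth: the
generating parameters, v(x) at the disk stations, and per-frame tracer
trajectories.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: cellular morphology (only texture statistics),
illumination drift, focus changes, root-hair or lateral-root clutter,
out-of-plane motion, and tracking across genuinely non-affine
deformation. It also extends the logistic field through the QC, where a
real root's velocity is identically zero; this is exactly the regime the
QC-referenced fit handles.

## Problem sizes and runtime

The default synthetic stack is 120 frames of 200 × 1731 px; rendering
takes ~10 s and tracking ~25 s on one CPU, so the flagship end-to-end
recovery (all four parameters and traits within 5% of truth; measured
< 1%) runs once per test session. Unit and property tests use a 6-frame
stack at coarser resolution (400 px mm⁻¹) that still spans the entire
sigmoid. The full suite runs in well under a minute; the acceptance
script in about half a minute.

## Known limitations

* One root per stack; no camera-motion compensation beyond the
  QC-relative reference; no automatic midline or QC detection.
* Disks whose patches leave the field of view, lose texture, or fail to
  converge are dropped (and logged), not extrapolated.
* The affine patch model linearizes the motion; per-frame motions much
  larger than a few pixels, or stretches beyond a few percent, exceed
  the basin the identity-initialized solver is designed for.
* The fitted parameter vector is meaningful only when the cloud spans
  both the low- and high-velocity ends of the sigmoid; on a truncated
  span the (v_f, k, n) directions are ill-determined and the fit
  reports failure rather than a spurious optimum.
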
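"""Synthetic time-lapse stacks of an elongating, textured root.

Frames emulate the acquisition geometry the tracker is designed for: a
backlit root (dark, textured tissue on a bright background) imaged every
``interval_s`` seconds at ``resolution_px_mm`` px/mm.  Material points on
the axis move relative to the quiescent center (QC) under a prescribed
flexible-logistic velocity field, obtained by integrating dx/dt = v(x)
for each material coordinate.  The image frame of reference keeps mature
tissue approximately stationary, so the QC itself drifts apically across
the series — which exercises the tracker's QC-relative referencing.

Every stack carries exact ground truth: the generating parameters, the
velocity profile at the disk stations, and per-frame tracer trajectories.
Identical specs (including seeds) produce bit-identical stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.integrate import solve_ivp

from .kinematics import LogisticParams, velocity_model

__all__ = [
    "SyntheticSpec",
    "SyntheticStack",
    "displacement_map",
    "material_trajectories",
    "render_stack",
    "write_synthetic",
    "WILDTYPE_TRUTH",
]

#: Default ground truth mirroring wild-type Arabidopsis magnitudes:
#: final rate 0.1 mm/h, steepness 10 mm^-1, half-rise 0.35 mm, symmetric.
WILDTYPE_TRUTH = LogisticParams(v_f=0.1, k=10.0, x0=0.35, n=1.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic acquisition.

    Defaults reproduce the reference acquisition conditions: 120 frames at
    30 s intervals (1 h), 1450 px/mm, and a midline span of 1250 px
    (~0.86 mm) that yields 126 tracking disks at the standard 10 px
    spacing — about 15,000 velocity samples per stack.
    """

    truth: LogisticParams = WILDTYPE_TRUTH
    frames: int = 120
    interval_s: float = 30.0
    resolution_px_mm: float = 1450.0
    root_width_px: float = 120.0
    midline_span_px: float = 1250.0
    texture_seed: int = 0
    texture_scale_px: float = 3.0
    noise_sigma: float = 0.01
    curvature_radius_px: float | None = None
    constant_velocity_mm_h: float | None = None
    tip_offset_px: float = 100.0  # QC-to-tip distance along the axis

    def __post_init__(self) -> None:
        if self.frames < 2:
            raise ValueError("need at least 2 frames")
        for name in ("interval_s", "resolution_px_mm", "root_width_px",
                     "midline_span_px", "texture_scale_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _velocity_px_s(spec: SyntheticSpec, x_px: np.ndarray) -> np.ndarray:
    """Axial velocity field in px/s at positions given in px from the QC."""
    if spec.constant_velocity_mm_h is not None:
        c = spec.constant_velocity_mm_h * spec.resolution_px_mm / 3600.0
        return np.full_like(np.asarray(x_px, dtype=float), c)
    v_mm_h = velocity_model(spec.truth, np.asarray(x_px, float) / spec.resolution_px_mm)
    return v_mm_h * spec.resolution_px_mm / 3600.0


def material_trajectories(
    spec: SyntheticSpec, x0_px: np.ndarray, times_s: np.ndarray
) -> np.ndarray:
    """Integrate dx/dt = v(x) for each material start position.

    Returns an array of shape ``(len(times_s), len(x0_px))`` of positions
    in px from the QC origin.  Uses an adaptive RK integrator at tight
    tolerance; the constant-velocity mode is evaluated in closed form.
    """
    x0_px = np.asarray(x0_px, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    if spec.constant_velocity_mm_h is not None:
        c = spec.constant_velocity_mm_h * spec.resolution_px_mm / 3600.0
        return x0_px[None, :] + c * times_s[:, None]
    t_max = float(times_s.max())
    if t_max == 0.0:
        return np.tile(x0_px, (len(times_s), 1))
    sol = solve_ivp(
        lambda t, x: _velocity_px_s(spec, x),
        (0.0, t_max), x0_px, t_eval=times_s,
        rtol=1e-10, atol=1e-6, method="RK45", vectorized=False,
    )
    if not sol.success:
        raise RuntimeError(f"trajectory integration failed: {sol.message}")
    return sol.y.T


def displacement_map(truth: LogisticParams, t: float,
                     resolution_px_mm: float = 1450.0):
    """Return the monotone material map x0 -> x(t) in mm.

    ``x0`` is the position (mm from the QC) of a material point at time 0;
    the returned callable gives its position after ``t`` seconds of growth
    under the flexible-logistic field ``truth``.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    spec = SyntheticSpec(truth=truth, resolution_px_mm=resolution_px_mm)

    def mapper(x0_mm):
        x0_mm = np.atleast_1d(np.asarray(x0_mm, dtype=float))
        pos = material_trajectories(
            spec, x0_mm * resolution_px_mm, np.array([0.0, t])
        )[-1]
        out = pos / resolution_px_mm
        return out if out.size > 1 else float(out[0])

    return mapper


@dataclass
class SyntheticStack:
    """A rendered stack plus its exact ground truth."""

    frames: np.ndarray  # (F, H, W) float32 in [0, 1]
    seed_points: np.ndarray  # (S, 2) midline seeds (x, y) on frame 0; row 0 = QC
    spec: SyntheticSpec
    truth_velocity: pd.DataFrame  # station_px, station_mm, v_true_mm_h
    tracers: pd.DataFrame  # frame, tracer_id, station0_px, station_px, x_lab, y_lab
    qc_frame0: tuple[float, float] = (0.0, 0.0)


def _root_profile(m: np.ndarray, halfw: float, tip_m: float) -> np.ndarray:
    """Half-width of the root at material axial coordinate m (rounded tip)."""
    tipc = tip_m + halfw
    prof = np.full_like(m, halfw, dtype=float)
    cap = m < tipc
    prof[cap] = np.sqrt(np.clip(halfw**2 - (m[cap] - tipc) ** 2, 0.0, None))
    prof[m < tip_m] = 0.0
    return prof


def render_stack(spec: SyntheticSpec) -> SyntheticStack:
    """Render the full synthetic time series with ground-truth tables.

    A band-limited random texture (Gaussian-blurred white noise at
    ``texture_scale_px``) is laid down in material coordinates inside the
    root mask; each frame samples it at the advected material positions by
    cubic interpolation, then adds Gaussian read noise.
    """
    halfw = spec.root_width_px / 2.0
    tip_m = -float(spec.tip_offset_px)
    duration = (spec.frames - 1) * spec.interval_s
    if spec.constant_velocity_mm_h is not None:
        drift_end = 0.0
        growth_px = abs(spec.constant_velocity_mm_h) * spec.resolution_px_mm \
            * duration / 3600.0
    else:
        drift_end = spec.truth.v_f * spec.resolution_px_mm * duration / 3600.0
        growth_px = drift_end
    qc_x0 = float(np.ceil(-tip_m + drift_end + 45.0))
    width = int(np.ceil(qc_x0 + spec.midline_span_px + growth_px + 48.0))
    height = int(np.ceil(spec.root_width_px + 80.0))
    yc = height / 2.0

    times = np.arange(spec.frames) * spec.interval_s
    m_lo = tip_m - 60.0
    m_hi = width - qc_x0 + drift_end + 60.0
    mgrid = np.arange(m_lo, m_hi + 2.0, 2.0)
    traj = material_trajectories(spec, mgrid, times)  # (F, M) px from QC
    if spec.constant_velocity_mm_h is not None:
        drift = np.zeros(spec.frames)
    else:
        # hold the far (mature) end of the field approximately fixed in the
        # image so the QC drifts apically, as mature tissue does not move
        drift = traj[:, -1] - mgrid[-1]

    # material-frame image: texture inside the root mask, bright background
    rng = np.random.default_rng(spec.texture_seed)
    mtex = np.arange(m_lo, m_hi + 1.0, 1.0)
    field_img = rng.standard_normal((height, len(mtex)))
    field_img = ndimage.gaussian_filter(field_img, spec.texture_scale_px)
    field_img /= field_img.std()
    tissue = np.clip(0.45 + 0.16 * field_img, 0.03, 0.9)
    prof = _root_profile(mtex, halfw, tip_m)
    dist = prof[None, :] - np.abs(np.arange(height)[:, None] - yc)
    alpha = np.clip(dist / 2.0 + 0.5, 0.0, 1.0)  # 2 px soft edge
    background = 0.9
    material_img = alpha * tissue + (1.0 - alpha) * background

    if spec.curvature_radius_px is None:
        arc = np.arange(width, dtype=float)[None, :] - qc_x0  # lab arc coord s
        arc = np.broadcast_to(arc, (height, width))
        radial = np.arange(height, dtype=float)[:, None] - yc
        radial = np.broadcast_to(radial, (height, width))
    else:
        R = float(spec.curvature_radius_px)
        cx, cy = qc_x0, yc + R
        X, Y = np.meshgrid(np.arange(width, dtype=float),
                           np.arange(height, dtype=float))
        r = np.hypot(X - cx, Y - cy)
        theta = np.arctan2(Y - cy, X - cx)
        arc = R * (theta + np.pi / 2.0)
        radial = r - R

    frames = np.empty((spec.frames, height, width), dtype=np.float32)
    rows = radial + yc
    for j in range(spec.frames):
        smap = traj[j] - drift[j]  # lab arc position of each material point
        mcoord = np.interp(arc.ravel(), smap, mgrid).reshape(arc.shape)
        cols = mcoord - mtex[0]
        img = ndimage.map_coordinates(
            material_img, [rows.ravel(), cols.ravel()], order=3, mode="nearest"
        ).reshape(arc.shape)
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
        frames[j] = np.clip(img, 0.0, 1.0)

    # midline seeds on frame 0 (11 points from the QC to the span end)
    seed_s = np.linspace(0.0, spec.midline_span_px, 11)
    if spec.curvature_radius_px is None:
        seeds = np.column_stack([qc_x0 + seed_s, np.full_like(seed_s, yc)])
    else:
        R = float(spec.curvature_radius_px)
        th = -np.pi / 2.0 + seed_s / R
        seeds = np.column_stack([qc_x0 + R * np.cos(th),
                                 yc + R + R * np.sin(th)])

    stations = np.arange(0.0, spec.midline_span_px + 1e-9, 10.0)
    truth_velocity = pd.DataFrame(
        {
            "station_px": stations,
            "station_mm": stations / spec.resolution_px_mm,
            "v_true_mm_h": np.asarray(
                velocity_model(spec.truth, stations / spec.resolution_px_mm)
            )
            if spec.constant_velocity_mm_h is None
            else np.full_like(stations, spec.constant_velocity_mm_h),
        }
    )

    tr = material_trajectories(spec, stations, times)  # (F, S)
    recs = []
    for j in range(spec.frames):
        s_lab = tr[j] - drift[j]
        if spec.curvature_radius_px is None:
            xs, ys = qc_x0 + s_lab, np.full_like(s_lab, yc)
        else:
            R = float(spec.curvature_radius_px)
            th = -np.pi / 2.0 + s_lab / R
            xs, ys = qc_x0 + R * np.cos(th), yc + R + R * np.sin(th)
        for i, st0 in enumerate(stations):
            recs.append((j, i, st0, tr[j, i], xs[i], ys[i]))
    tracers = pd.DataFrame(
        recs,
        columns=["frame", "tracer_id", "station0_px", "station_px",
                 "x_lab", "y_lab"],
    )

    return SyntheticStack(
        frames=frames, seed_points=seeds, spec=spec,
        truth_velocity=truth_velocity, tracers=tracers,
        qc_frame0=(qc_x0, yc),
    )


def write_synthetic(out_dir: str | Path, stack: SyntheticStack) -> dict[str, Path]:
    """Write a rendered stack as single-page TIFFs plus ground-truth CSVs."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack_dir = out / "stack"
    stack_dir.mkdir(exist_ok=True)
    for j, frame in enumerate(stack.frames):
        tifffile.imwrite(stack_dir / f"frame_{j:03d}.tif", frame)
    seeds_path = out / "seeds.csv"
    pd.DataFrame(stack.seed_points, columns=["x", "y"]).to_csv(
        seeds_path, index=False
    )
    truth_path = out / "ground_truth_velocity.csv"
    stack.truth_velocity.to_csv(truth_path, index=False)
    tracer_path = out / "ground_truth_tracers.csv"
    stack.tracers.to_csv(tracer_path, index=False)
    params_path = out / "ground_truth_params.csv"
    p = stack.spec.truth
    pd.DataFrame(
        [{"v_f_mm_h": p.v_f, "k_per_mm": p.k, "x0_mm": p.x0, "n": p.n}]
    ).to_csv(params_path, index=False)
    return {
        "stack": stack_dir, "seeds": seeds_path, "truth": truth_path,
        "tracers": tracer_path, "params": params_path,
    }


def small_demo_spec(**overrides) -> SyntheticSpec:
    """A scaled-down spec (short span, few frames) for quick examples."""
    base = SyntheticSpec(frames=8, midline_span_px=500.0, root_width_px=90.0)
    return replace(base, **overrides)
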
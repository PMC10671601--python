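"""End-to-end pipeline: stack -> point cloud -> fitted profile -> traits.

Outputs written per run:

* ``velocity_points.csv``  — the raw point cloud (one row per disk per
  frame pair, in px/frame and mm/h units)
* ``disk_coordinates.csv`` — every disk center per frame
* ``fitted_velocity.csv``  — fitted sigmoid on a dense position grid
* ``regr_profile.csv``     — analytic REGR profile on the same grid
* ``traits.csv``           — fitted parameters, the four kinematic traits
  and fit diagnostics (one row)
* ``qc_plot.png``          — point cloud + fitted velocity + REGR curve
* ``run_log.json``         — parameters, dropped-disk tally, diagnostics
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import interpolate_midline
from .io import ImageStack, RunConfig, read_seed_points, read_stack
from .kinematics import (FitError, FitResult, KinematicTraits, extract_traits,
                         regr_profile, velocity_model)
from .kinematics import fit_flexible_logistic
from .tracking import TrackingConfig, TrackOutput, track_stack

__all__ = ["PipelineResult", "run_pipeline", "run_on_stack", "fit_point_cloud"]

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    status: int
    fit: FitResult | None
    traits: KinematicTraits | None
    n_samples: int
    n_dropped: int
    out_dir: Path


def _tracking_config(config: RunConfig) -> TrackingConfig:
    return TrackingConfig(
        disk_spacing_px=config.disk_spacing_px,
        disk_radius_px=config.disk_radius_px,
        threshold_px=config.threshold_px,
        max_iter=config.max_iter,
        smooth_sigma_px=config.smooth_sigma_px,
        interp_order=1 if config.bilinear_sampling else 3,
        midline_count=config.midline_count,
        advance_midline=not config.fixed_midline,
        resolution_px_mm=config.resolution_px_mm,
        interval_s=config.interval_s,
    )


def samples_to_frame(samples) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "disk_id": s.disk_id,
                "frame": s.frame_index,
                "station_px": s.station_px,
                "velocity_px_frame": s.axial_velocity_px,
                "station_mm": s.station_mm,
                "velocity_mm_h": s.axial_velocity_mm_h,
            }
            for s in samples
        ]
    )


def fit_point_cloud(cloud: pd.DataFrame, seed: int = 0) -> tuple[FitResult, KinematicTraits]:
    """Fit the flexible logistic to a point-cloud table and derive traits.

    ``cloud`` needs columns ``station_mm`` and ``velocity_mm_h`` (the
    format written by the tracking stage, but any tracker's output works).
    """
    fit = fit_flexible_logistic(
        cloud["station_mm"].to_numpy(), cloud["velocity_mm_h"].to_numpy(),
        seed=seed, qc_referenced=True,
    )
    traits = extract_traits(fit.params) if not fit.degenerate else None
    if traits is None:
        log.warning("degenerate fit: traits undefined (flat velocity cloud)")
    return fit, traits


def _write_fit_outputs(out: Path, fit: FitResult, traits: KinematicTraits | None,
                       x_max_mm: float) -> None:
    xs = np.linspace(0.0, max(x_max_mm, 1e-3), 400)
    pd.DataFrame(
        {"x_mm": xs, "v_mm_h": velocity_model(fit.params, xs)}
    ).to_csv(out / "fitted_velocity.csv", index=False)
    pd.DataFrame(
        {"x_mm": xs, "regr_pct_h": regr_profile(fit.params, xs)}
    ).to_csv(out / "regr_profile.csv", index=False)
    row = {
        "v_f": fit.params.v_f, "k": fit.params.k, "x0": fit.params.x0,
        "n": fit.params.n,
        "max_regr_pct_h": traits.max_regr if traits else np.nan,
        "max_regr_pos_mm": traits.max_regr_position if traits else np.nan,
        "zone_length_mm": traits.zone_length if traits else np.nan,
        "avg_rate_mm_h": traits.avg_growth_rate if traits else np.nan,
        "sse": fit.sse, "n_samples": fit.n_samples,
    }
    pd.DataFrame([row]).to_csv(out / "traits.csv", index=False)


def _qc_plot(out: Path, cloud: pd.DataFrame, fit: FitResult) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(cloud["station_mm"], cloud["velocity_mm_h"], ".",
            ms=2, alpha=0.25, color="0.4", label="velocity samples")
    xs = np.linspace(0.0, float(cloud["station_mm"].max()), 400)
    ax.plot(xs, velocity_model(fit.params, xs), "r-", lw=2, label="fit")
    ax.set_xlabel("position from QC (mm)")
    ax.set_ylabel("axial velocity (mm/h)")
    ax2 = ax.twinx()
    ax2.plot(xs, regr_profile(fit.params, xs), "b--", lw=1.5, label="REGR")
    ax2.set_ylabel("REGR (% / h)", color="b")
    ax.legend(loc="upper left")
    fig.tight_layout()
    fig.savefig(out / "qc_plot.png", dpi=120)
    plt.close(fig)


def run_on_stack(stack: ImageStack, seed_points: np.ndarray,
                 config: RunConfig) -> tuple[TrackOutput, pd.DataFrame]:
    """Track a loaded stack and return the tracker output and point cloud."""
    midline = interpolate_midline(seed_points, config.midline_count)
    output = track_stack(stack.frames, midline, _tracking_config(config))
    return output, samples_to_frame(output.samples)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    Returns status 0 on success, 2 on fit failure, 3 when the fit is
    degenerate (e.g. a static stack); outputs computed up to the failure
    point are still written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack = read_stack(config.stack_path, config.interval_s,
                       config.resolution_px_mm)
    seeds = read_seed_points(config.seeds_path)
    output, cloud = run_on_stack(stack, seeds, config)

    cloud.to_csv(out / "velocity_points.csv", index=False)
    pd.DataFrame(
        output.disk_records,
        columns=["frame", "disk_id", "x", "y", "station_px"],
    ).to_csv(out / "disk_coordinates.csv", index=False)

    status = 0
    fit = None
    traits = None
    fit_error = ""
    try:
        fit, traits = fit_point_cloud(cloud, seed=config.seed)
        if fit.degenerate:
            status = 3
    except (FitError, ValueError) as exc:
        status = 2
        fit_error = str(exc)
        log.error("velocity-profile fit failed: %s", fit_error)
    if fit is not None:
        _write_fit_outputs(out, fit, traits, float(cloud["station_mm"].max()))
        _qc_plot(out, cloud, fit)

    drop_counts: dict[str, int] = {}
    for d in output.dropped:
        drop_counts[d.reason] = drop_counts.get(d.reason, 0) + 1
    run_log = {
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in asdict(config).items()
        },
        "n_frames": stack.n_frames,
        "n_samples": int(len(cloud)),
        "n_dropped": len(output.dropped),
        "dropped_by_reason": drop_counts,
        "dropped": [
            {"frame": d.frame_index, "disk_id": d.disk_id, "reason": d.reason}
            for d in output.dropped
        ],
        "status": status,
        "fit": (
            {
                "v_f": fit.params.v_f, "k": fit.params.k,
                "x0": fit.params.x0, "n": fit.params.n,
                "sse": fit.sse, "degenerate": fit.degenerate,
            }
            if fit is not None else {"error": fit_error}
        ),
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
    return PipelineResult(
        status=status, fit=fit, traits=traits, n_samples=len(cloud),
        n_dropped=len(output.dropped), out_dir=out,
    )
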
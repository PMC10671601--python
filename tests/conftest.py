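"""Shared fixtures: textured patches, constructed warps, synthetic stacks."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from patchtrack.geometry import Disk, interpolate_midline
from patchtrack.kinematics import extract_traits, fit_flexible_logistic
from patchtrack.synthetic import SyntheticSpec, render_stack
from patchtrack.tracking import TrackingConfig, track_stack


@pytest.fixture(scope="session")
def texture() -> np.ndarray:
    """A 101x101 band-limited random texture (the kind of intensity pattern
    root tissue presents: smooth variation at a few-pixel scale)."""
    rng = np.random.default_rng(7)
    tex = ndimage.gaussian_filter(rng.standard_normal((101, 101)), 3.0)
    return 0.5 + 0.16 * tex / tex.std()


@pytest.fixture(scope="session")
def center_disk() -> Disk:
    return Disk(center=np.array([50.0, 50.0]), radius=15.0, station=0.0)


def make_warped_frame(tex: np.ndarray, v: np.ndarray, G: np.ndarray,
                      center: np.ndarray) -> np.ndarray:
    """Construct frame1 so that the patch motion about `center` is exactly
    d -> d + G d + v (the inverse map is applied when resampling)."""
    h, w = tex.shape
    A = np.eye(2) + G
    Ainv = np.linalg.inv(A)
    X, Y = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    d = np.stack([X - center[0], Y - center[1]], axis=-1)
    src = d @ Ainv.T - (Ainv @ v) + center
    return ndimage.map_coordinates(
        tex, [src[..., 1].ravel(), src[..., 0].ravel()], order=3,
        mode="nearest",
    ).reshape(h, w)


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """A quick-to-render stack that still spans the whole sigmoid: coarser
    optics (400 px/mm) let 520 px of midline cover 1.3 mm of root."""
    return SyntheticSpec(frames=6, midline_span_px=520.0,
                         resolution_px_mm=400.0, root_width_px=60.0,
                         tip_offset_px=40.0)


@pytest.fixture(scope="session")
def small_stack(small_spec):
    return render_stack(small_spec)


@pytest.fixture(scope="session")
def default_run():
    """Flagship end-to-end artifact: the full default 120-frame stack,
    tracked and fitted once per session (QC-referenced fit, as in the
    pipeline)."""
    spec = SyntheticSpec()
    stack = render_stack(spec)
    midline = interpolate_midline(stack.seed_points, 100)
    output = track_stack(stack.frames, midline, TrackingConfig())
    x = np.array([s.station_mm for s in output.samples])
    v = np.array([s.axial_velocity_mm_h for s in output.samples])
    fit = fit_flexible_logistic(x, v, qc_referenced=True)
    traits = extract_traits(fit.params)
    return {
        "spec": spec, "stack": stack, "output": output,
        "x": x, "v": v, "fit": fit, "traits": traits,
    }
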
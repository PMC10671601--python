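"""Affine patch tracking between consecutive frames.

Each circular patch is followed from frame *n* to frame *n+1* under an
intensity-constancy constraint: growth may translate, stretch and rotate
the patch, so the motion of an in-patch offset ``d`` is modelled to first
order as ``d -> d + G d + v`` with translation ``v`` (px/frame) and
velocity-gradient matrix ``G`` (frame^-1).  The six parameters are found
by Gauss-Newton iteration on the material-derivative residual

    D_t I(d) = I_{n+1}(x_c + d + G d + v) - I_n(x_c + d)

with the Jacobian ``M`` formed once per patch from the spatial intensity
gradient of frame *n* over the un-warped template; the gradient (and
hence the pseudo-inverse of ``M``) is fixed across iterations.  Both
frames are lightly Gaussian-smoothed before the solve and the gradient is
taken on the same smoothed frame the residual samples, which keeps the
fixed Jacobian consistent with the residual and the iteration tightly
contractive.  The update norm that gates convergence is the Euclidean
norm of the 6-vector ``(dv, r * dG)`` with the dimensionless gradient
entries scaled by the disk radius so the whole norm is in pixel units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import Disk, Midline, axial_component, interpolate_midline, place_disks

__all__ = [
    "TrackingError",
    "OutOfBoundsError",
    "DegeneratePatchError",
    "PatchTransform",
    "TrackResult",
    "VelocitySample",
    "DroppedDisk",
    "TrackingConfig",
    "TrackOutput",
    "PreparedPair",
    "prepare_frame_pair",
    "intensity_gradient",
    "solve_patch_transform",
    "track_stack",
    "convert_units",
]

log = logging.getLogger(__name__)


class TrackingError(RuntimeError):
    pass


class OutOfBoundsError(TrackingError):
    """Patch (or its warp) leaves the image bounds."""


class DegeneratePatchError(TrackingError):
    """Patch lacks intensity texture; the normal equations are rank-deficient."""


@dataclass
class PatchTransform:
    """Six-parameter affine patch motion: translation plus velocity gradient.

    The linear part applied to in-patch offsets is ``I + gradient``; the
    identity transform therefore has zero translation and zero gradient.
    """

    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))
    gradient: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))

    @classmethod
    def identity(cls) -> "PatchTransform":
        return cls()

    def warp_offsets(self, offsets: np.ndarray) -> np.ndarray:
        """Map in-patch offsets d -> d + G d + v."""
        return offsets + offsets @ self.gradient.T + self.translation

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.translation, self.gradient.ravel()])


@dataclass
class TrackResult:
    transform: PatchTransform
    iterations: int
    converged: bool
    final_update_norm: float
    residual_rms: float = np.nan
    residual_sse_history: list[float] = field(default_factory=list)


@dataclass
class VelocitySample:
    """One (axial position, axial velocity) measurement for one disk and
    one consecutive frame pair, in raw pixel units and converted units."""

    disk_id: int
    frame_index: int
    station_px: float
    axial_velocity_px: float
    station_mm: float
    axial_velocity_mm_h: float


@dataclass
class DroppedDisk:
    frame_index: int
    disk_id: int
    reason: str


@dataclass
class TrackingConfig:
    """Parameters of the tracking stage.

    Defaults follow the acquisition setup the method was designed around:
    disks every 10 px on the midline, convergence when the update norm
    drops below 1e-6 px.
    """

    disk_spacing_px: float = 10.0
    disk_radius_px: float = 15.0
    threshold_px: float = 1e-6
    max_iter: int = 50
    smooth_sigma_px: float = 0.5
    interp_order: int = 3  # 3 = bicubic (default), 1 = bilinear
    cond_limit: float = 1e8
    midline_count: int = 100
    advance_midline: bool = True
    resolution_px_mm: float = 1450.0
    interval_s: float = 30.0


def intensity_gradient(frame: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Spatial intensity gradient of a frame.

    Central differences on a lightly Gaussian-smoothed copy (``sigma`` in
    px; 0 disables smoothing).  Returns an (H, W, 2) array whose last axis
    is (dI/dx, dI/dy) with x = column, y = row.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or min(frame.shape) < 3:
        raise ValueError("frame must be a 2-D array at least 3x3")
    if sigma > 0:
        frame = ndimage.gaussian_filter(frame, sigma, mode="nearest")
    gy, gx = np.gradient(frame)
    return np.stack([gx, gy], axis=-1)


@dataclass
class PreparedPair:
    """Per-frame-pair precomputation shared by all disks of the pair."""

    smoothed_n: np.ndarray
    coeffs_n: np.ndarray  # spline coefficients (the smoothed frame for order 1)
    coeffs_n1: np.ndarray
    grad: np.ndarray  # intensity gradient of smoothed_n, (H, W, 2)
    interp_order: int


def prepare_frame_pair(
    frame_n: np.ndarray,
    frame_n1: np.ndarray,
    smooth_sigma: float = 0.5,
    interp_order: int = 3,
) -> PreparedPair:
    """Smooth both frames, take the template gradient and prefilter both
    frames for repeated sub-pixel sampling.

    Template and target are sampled with the same interpolation scheme so
    that an identical frame pair yields an exactly zero residual at the
    identity transform (no spurious sub-pixel motion).
    """
    f0 = np.asarray(frame_n, dtype=float)
    f1 = np.asarray(frame_n1, dtype=float)
    if smooth_sigma > 0:
        f0 = ndimage.gaussian_filter(f0, smooth_sigma, mode="nearest")
        f1 = ndimage.gaussian_filter(f1, smooth_sigma, mode="nearest")
    gy, gx = np.gradient(f0)
    grad = np.stack([gx, gy], axis=-1)
    if interp_order > 1:
        coeffs_n = ndimage.spline_filter(f0, order=interp_order, mode="mirror")
        coeffs_n1 = ndimage.spline_filter(f1, order=interp_order, mode="mirror")
    else:
        coeffs_n, coeffs_n1 = f0, f1
    return PreparedPair(smoothed_n=f0, coeffs_n=coeffs_n, coeffs_n1=coeffs_n1,
                        grad=grad, interp_order=interp_order)


def _sample(img: np.ndarray, xy: np.ndarray, order: int,
            prefiltered: bool = False) -> np.ndarray:
    """Interpolate an image at sub-pixel (x, y) positions."""
    coords = np.stack([xy[:, 1], xy[:, 0]])  # map_coordinates wants (row, col)
    return ndimage.map_coordinates(
        img, coords, order=order, mode="mirror" if prefiltered else "nearest",
        prefilter=not prefiltered,
    )


def _check_bounds(xy: np.ndarray, shape: tuple[int, int]) -> None:
    h, w = shape
    if (
        xy[:, 0].min() < 0
        or xy[:, 1].min() < 0
        or xy[:, 0].max() > w - 1
        or xy[:, 1].max() > h - 1
    ):
        raise OutOfBoundsError("patch leaves the image bounds")


def solve_patch_transform(
    frame_n: np.ndarray,
    frame_n1: np.ndarray,
    disk: Disk,
    threshold: float = 1e-6,
    max_iter: int = 50,
    *,
    smooth_sigma: float = 0.5,
    interp_order: int = 3,
    cond_limit: float = 1e8,
    prepared: PreparedPair | None = None,
) -> TrackResult:
    """Solve for the affine transform matching a disk's patch across frames.

    Parameters
    ----------
    prepared : optional output of :func:`prepare_frame_pair`, shared across
        the disks of one frame pair (``frame_n``/``frame_n1`` are then only
        used for their shape).

    Raises
    ------
    OutOfBoundsError
        if the template or its warp leaves either frame.
    DegeneratePatchError
        if the patch is too textureless to constrain the six parameters.
    """
    if prepared is None:
        prepared = prepare_frame_pair(frame_n, frame_n1, smooth_sigma,
                                      interp_order)
    f0, grad = prepared.smoothed_n, prepared.grad
    order = prepared.interp_order

    d = disk.offsets
    template_xy = disk.center + d
    _check_bounds(template_xy, f0.shape)
    template = _sample(prepared.coeffs_n, template_xy, order,
                       prefiltered=order > 1)
    gx = _sample(grad[..., 0], template_xy, 1)
    gy = _sample(grad[..., 1], template_xy, 1)
    # M = grad(I) (x) (1, dx, dy): one row of six per patch pixel, ordered to
    # match the parameter vector (vx, vy, G00, G01, G10, G11).
    M = np.column_stack(
        [gx, gy, gx * d[:, 0], gx * d[:, 1], gy * d[:, 0], gy * d[:, 1]]
    )
    sv = np.linalg.svd(M, compute_uv=False)
    if sv[-1] <= 0 or sv[0] / sv[-1] > cond_limit:
        raise DegeneratePatchError(
            f"patch at {disk.center} is textureless "
            f"(cond={sv[0] / max(sv[-1], 1e-300):.2e})"
        )
    pinv = np.linalg.pinv(M)

    # radius scaling puts the dimensionless gradient entries on a pixel scale
    scale = np.array([1.0, 1.0] + [disk.radius] * 4)
    transform = PatchTransform.identity()
    update_norm = np.inf
    residual = template * 0.0
    iterations = 0
    sse_history: list[float] = []
    for iterations in range(1, max_iter + 1):
        warped_xy = disk.center + transform.warp_offsets(d)
        _check_bounds(warped_xy, f0.shape)
        residual = _sample(prepared.coeffs_n1, warped_xy, order,
                           prefiltered=order > 1) - template
        sse_history.append(float(residual @ residual))
        dT = -pinv @ residual
        transform.translation = transform.translation + dT[:2]
        transform.gradient = transform.gradient + dT[2:].reshape(2, 2)
        update_norm = float(np.linalg.norm(dT * scale))
        if update_norm < threshold:
            break
    converged = update_norm < threshold
    return TrackResult(
        transform=transform,
        iterations=iterations,
        converged=converged,
        final_update_norm=update_norm,
        residual_rms=float(np.sqrt(np.mean(residual**2))),
        residual_sse_history=sse_history,
    )


def convert_units(
    station_px: float, velocity_px_frame: float, resolution: float, interval: float
) -> tuple[float, float]:
    """Convert (px, px/frame) to (mm, mm/h) given resolution (px/mm) and
    frame interval (s)."""
    if resolution <= 0 or interval <= 0:
        raise ValueError("resolution and interval must be positive")
    return (
        station_px / resolution,
        velocity_px_frame / resolution * (3600.0 / interval),
    )


def _advance_midline(
    midline: Midline,
    disks: list[Disk],
    translations: dict[int, np.ndarray],
    count: int,
) -> Midline:
    """Advect each midline vertex by the translation of the nearest tracked
    disk, then re-resample to equal arc-length spacing."""
    tracked = sorted(translations)
    stations = np.array([disks[i].station for i in tracked])
    moves = np.stack([translations[i] for i in tracked])
    idx = np.abs(midline.arc_length[:, None] - stations[None, :]).argmin(axis=1)
    new_pts = midline.points + moves[idx]
    return interpolate_midline(new_pts, count)


@dataclass
class TrackOutput:
    samples: list[VelocitySample]
    dropped: list[DroppedDisk]
    disk_records: list[tuple[int, int, float, float, float]]
    """(frame, disk_id, x, y, station_px) for every placed disk."""


def track_stack(frames: np.ndarray, midline0: Midline, config: TrackingConfig
                ) -> TrackOutput:
    """Track disks through every consecutive frame pair of a stack.

    For each pair (n, n+1), fresh disks are placed at the standard stations
    on the current midline, each disk's transform is solved, and axial
    velocities relative to the tracked QC disk are emitted as
    :class:`VelocitySample` records.  The midline is then advected to frame
    n+1 (unless ``config.advance_midline`` is off) and the process repeats.
    Disks that leave the frame, lack texture or fail to converge are
    dropped and logged; if the QC disk itself fails, the whole frame pair
    is skipped because no reference is available.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (frames, H, W) stack with at least 2 frames")
    midline = midline0
    samples: list[VelocitySample] = []
    dropped: list[DroppedDisk] = []
    disk_records: list[tuple[int, int, float, float, float]] = []

    for n in range(frames.shape[0] - 1):
        disks = place_disks(midline, config.disk_spacing_px, config.disk_radius_px)
        prepared = prepare_frame_pair(
            frames[n], frames[n + 1], config.smooth_sigma_px,
            config.interp_order,
        )
        translations: dict[int, np.ndarray] = {}
        for disk in disks:
            disk_records.append(
                (n, disk.disk_id, float(disk.center[0]), float(disk.center[1]),
                 disk.station)
            )
            try:
                res = solve_patch_transform(
                    frames[n], frames[n + 1], disk,
                    threshold=config.threshold_px, max_iter=config.max_iter,
                    cond_limit=config.cond_limit, prepared=prepared,
                )
            except OutOfBoundsError:
                dropped.append(DroppedDisk(n, disk.disk_id, "out_of_bounds"))
                continue
            except DegeneratePatchError:
                dropped.append(DroppedDisk(n, disk.disk_id, "degenerate_patch"))
                continue
            if not res.converged:
                dropped.append(DroppedDisk(n, disk.disk_id, "no_convergence"))
                continue
            translations[disk.disk_id] = res.transform.translation
        if 0 not in translations:
            log.warning("frame pair %d: QC disk failed to track; pair skipped", n)
            dropped.append(DroppedDisk(n, 0, "qc_untracked_pair_skipped"))
            continue
        qc_move = translations[0]
        for disk in disks:
            if disk.disk_id not in translations:
                continue
            v_ax = axial_component(
                translations[disk.disk_id], disk, midline, qc_move
            )
            st_mm, v_mm_h = convert_units(
                disk.station, v_ax, config.resolution_px_mm, config.interval_s
            )
            samples.append(
                VelocitySample(
                    disk_id=disk.disk_id, frame_index=n,
                    station_px=disk.station, axial_velocity_px=v_ax,
                    station_mm=st_mm, axial_velocity_mm_h=v_mm_h,
                )
            )
        if config.advance_midline:
            midline = _advance_midline(
                midline, disks, translations, config.midline_count
            )
    return TrackOutput(samples=samples, dropped=dropped, disk_records=disk_records)
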
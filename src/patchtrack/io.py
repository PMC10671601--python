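"""Stack and seed-point I/O plus run configuration."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = ["FormatError", "ImageStack", "RunConfig", "read_stack",
           "read_seed_points"]

log = logging.getLogger(__name__)


class FormatError(ValueError):
    pass


@dataclass
class ImageStack:
    """Ordered grayscale frames with acquisition metadata."""

    frames: np.ndarray  # (F, H, W) float32 in [0, 1]
    interval_s: float = 30.0
    resolution_px_mm: float = 1450.0

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


@dataclass
class RunConfig:
    """Everything a full pipeline run needs.

    Defaults mirror the reference acquisition: 10 px disk spacing,
    convergence threshold 1e-6 px, 30 s frame interval, 1450 px/mm.
    """

    stack_path: Path = None  # type: ignore[assignment]
    seeds_path: Path = None  # type: ignore[assignment]
    out_dir: Path = Path("patchtrack_out")
    disk_spacing_px: float = 10.0
    disk_radius_px: float = 15.0
    threshold_px: float = 1e-6
    max_iter: int = 50
    resolution_px_mm: float = 1450.0
    interval_s: float = 30.0
    seed: int = 0
    fixed_midline: bool = False
    bilinear_sampling: bool = False  # default is bicubic warp sampling
    smooth_sigma_px: float = 0.5
    midline_count: int = 100
    extra: dict = field(default_factory=dict)


def _to_unit_float(arr: np.ndarray) -> np.ndarray:
    """Convert a frame to float32 intensities in [0, 1]."""
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return (arr.astype(np.float32) - info.min) / float(info.max - info.min)
    out = arr.astype(np.float32)
    if out.size and out.max() > 1.0 + 1e-6:
        out = out / float(out.max())
    return out


def read_stack(path: str | Path, interval_s: float = 30.0,
               resolution_px_mm: float = 1450.0) -> ImageStack:
    """Read a directory of single-page TIFFs (lexicographic frame order) or
    one multi-page TIFF into a float32 stack scaled to [0, 1]."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in {".tif", ".tiff"}
        )
        if not files:
            raise FormatError(f"no TIFF files in {path}")
        frames = []
        shape = None
        for f in files:
            try:
                arr = tifffile.imread(f)
            except Exception as exc:  # noqa: BLE001 - name the offending file
                raise OSError(f"unreadable TIFF file: {f}") from exc
            if arr.ndim != 2:
                raise FormatError(f"{f} is not a single-page grayscale image")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise FormatError(
                    f"mixed frame dimensions: {f} is {arr.shape}, expected {shape}"
                )
            frames.append(_to_unit_float(arr))
        stack = np.stack(frames)
    else:
        try:
            arr = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001
            raise OSError(f"unreadable TIFF file: {path}") from exc
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise FormatError(f"{path}: expected a multi-page grayscale TIFF")
        stack = _to_unit_float(arr)
    log.info("loaded %d frames of shape %s", stack.shape[0], stack.shape[1:])
    return ImageStack(frames=stack, interval_s=interval_s,
                      resolution_px_mm=resolution_px_mm)


def read_seed_points(path: str | Path) -> np.ndarray:
    """Read midline seed points from a 2-column CSV (header x,y; row 0 = QC)."""
    df = pd.read_csv(path)
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise FormatError(f"seed CSV must have columns x,y; missing {missing}")
    pts = df[["x", "y"]].to_numpy(dtype=float)
    if len(pts) < 2:
        raise FormatError("need at least two seed points")
    return pts
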
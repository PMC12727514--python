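"""In-memory model and disk format for co-registered interferometry stacks.

A stack is an ordered series of (height map, grayscale image) frame pairs
with timestamps, a pixel size, and disjoint region masks separating the
reactive calcite surface from the inert quartz reference strip. Height
maps are float32 nanometres; NaN encodes invalid interferometry pixels
and is skipped (with the pixel count reported) by all downstream
statistics. On disk a stack is a directory of two multi-frame TIFFs, a
frame-time CSV, a mask TIFF and a JSON metadata sidecar — all plain,
vendor-neutral formats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

HEIGHT_TIF = "height_nm.tif"
GRAY_TIF = "grayscale.tif"
TIMES_CSV = "frame_times.csv"
MASKS_TIF = "region_masks.tif"
CELLFREE_TIF = "final_cellfree_nm.tif"
META_JSON = "stack_meta.json"

MASK_CALCITE = 1
MASK_QUARTZ = 2


@dataclass
class ImageStack:
    """Co-registered height/grayscale time series with region masks."""

    heights: np.ndarray  # (n_frames, ny, nx) float32, nm
    grayscale: np.ndarray  # (n_frames, ny, nx) uint16
    times_h: np.ndarray  # (n_frames,) float64, hours
    pixel_size_um: float
    calcite_mask: np.ndarray  # (ny, nx) bool
    quartz_mask: np.ndarray  # (ny, nx) bool
    final_cellfree_height: np.ndarray | None = None  # (ny, nx) float32, nm

    @property
    def n_frames(self) -> int:
        return self.heights.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape[1:]

    @property
    def frame_interval_h(self) -> float:
        return float(np.median(np.diff(self.times_h)))

    def validate(self) -> None:
        ny, nx = self.shape
        if self.grayscale.shape != self.heights.shape:
            raise ValueError("height and grayscale stacks differ in shape")
        if len(self.times_h) != self.n_frames:
            raise ValueError(
                f"frame count ({self.n_frames}) does not match number of "
                f"timestamps ({len(self.times_h)})"
            )
        if self.n_frames > 1 and not np.all(np.diff(self.times_h) > 0):
            raise ValueError("frame times must be strictly increasing")
        for name, m in (("calcite_mask", self.calcite_mask), ("quartz_mask", self.quartz_mask)):
            if m is None:
                raise ValueError(f"missing {name}")
            if m.shape != (ny, nx):
                raise ValueError(f"{name} shape {m.shape} != frame shape {(ny, nx)}")
        if np.any(self.calcite_mask & self.quartz_mask):
            raise ValueError("calcite and quartz masks overlap")
        if self.final_cellfree_height is not None and self.final_cellfree_height.shape != (ny, nx):
            raise ValueError("final cell-free map shape mismatch")


def write_stack(stack: ImageStack, out_dir: str | Path) -> Path:
    """Write a stack losslessly to a directory of TIFF/CSV/JSON files."""
    stack.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / HEIGHT_TIF, stack.heights.astype(np.float32), photometric="minisblack")
    tifffile.imwrite(out / GRAY_TIF, stack.grayscale.astype(np.uint16), photometric="minisblack")
    pd.DataFrame(
        {"frame_index": np.arange(stack.n_frames), "time_h": stack.times_h}
    ).to_csv(out / TIMES_CSV, index=False, float_format="%.17g")
    masks = np.zeros(stack.shape, dtype=np.uint8)
    masks[stack.calcite_mask] = MASK_CALCITE
    masks[stack.quartz_mask] = MASK_QUARTZ
    tifffile.imwrite(out / MASKS_TIF, masks)
    if stack.final_cellfree_height is not None:
        tifffile.imwrite(out / CELLFREE_TIF, stack.final_cellfree_height.astype(np.float32))
    meta = {
        "pixel_size_um": stack.pixel_size_um,
        "height_units": "nm",
        "time_units": "h",
        "n_frames": stack.n_frames,
        "mask_codes": {"calcite": MASK_CALCITE, "quartz": MASK_QUARTZ},
    }
    (out / META_JSON).write_text(json.dumps(meta, indent=2))
    return out


def read_stack(in_dir: str | Path) -> ImageStack:
    """Read a stack written by :func:`write_stack`; round-trip is lossless."""
    d = Path(in_dir)
    for required in (HEIGHT_TIF, GRAY_TIF, TIMES_CSV, MASKS_TIF, META_JSON):
        if not (d / required).exists():
            raise FileNotFoundError(f"stack directory {d} is missing {required}")
    heights = tifffile.imread(d / HEIGHT_TIF)
    gray = tifffile.imread(d / GRAY_TIF)
    if heights.ndim == 2:  # single-frame stacks round-trip too
        heights = heights[None]
        gray = gray[None]
    times = pd.read_csv(d / TIMES_CSV, float_precision="round_trip")
    if len(times) != heights.shape[0]:
        raise ValueError(
            f"TIFF frame count ({heights.shape[0]}) does not match "
            f"frame-time CSV rows ({len(times)})"
        )
    meta = json.loads((d / META_JSON).read_text())
    masks = tifffile.imread(d / MASKS_TIF)
    cellfree_path = d / CELLFREE_TIF
    cellfree = tifffile.imread(cellfree_path) if cellfree_path.exists() else None
    stack = ImageStack(
        heights=heights,
        grayscale=gray,
        times_h=times["time_h"].to_numpy(),
        pixel_size_um=float(meta["pixel_size_um"]),
        calcite_mask=masks == MASK_CALCITE,
        quartz_mask=masks == MASK_QUARTZ,
        final_cellfree_height=cellfree,
    )
    stack.validate()
    return stack
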
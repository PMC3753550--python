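"""Calibrated image-stack and table I/O.

The universal in-memory container is :class:`ImageStack`: a T×Y×X (or
T×Z×Y×X) intensity array with physical calibration (μm/px, s/frame and,
for volumetric data, μm between z sections).  Axis order is always time
first, then the optional z axis, then rows (y, increasing apical→basal in
sagittal views), then columns (x).  Positions and distances reported by
the analysis modules are in μm; pixel indices are 0-based and internal.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

logger = logging.getLogger("apicoquant")

MIN_SPATIAL_DIM = 8


@dataclass(frozen=True)
class ImageStack:
    """A calibrated grayscale movie, T(Z)YX.

    Parameters
    ----------
    data:
        3-D ``(T, Y, X)`` or 4-D ``(T, Z, Y, X)`` non-negative array.
    pixel_size_um:
        Lateral pixel size in μm/px, > 0.
    frame_interval_s:
        Time between frames in seconds, > 0.
    z_spacing_um:
        Spacing between z sections in μm; required iff ``data`` is 4-D.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    z_spacing_um: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        object.__setattr__(self, "data", arr)
        if arr.ndim not in (3, 4):
            raise ValueError(
                f"stack must be 3-D (T,Y,X) or 4-D (T,Z,Y,X); got shape {arr.shape}"
            )
        if arr.shape[0] < 1:
            raise ValueError("stack must contain at least one frame")
        if min(arr.shape[-2:]) < MIN_SPATIAL_DIM:
            raise ValueError(
                f"spatial dimensions must be ≥ {MIN_SPATIAL_DIM} px; got {arr.shape[-2:]}"
            )
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError(f"stack dtype must be numeric, got {arr.dtype}")
        if np.issubdtype(arr.dtype, np.floating):
            if not np.isfinite(arr).all():
                raise ValueError("stack contains non-finite intensities")
        if arr.size and arr.min() < 0:
            raise ValueError("stack contains negative intensities")
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not (self.frame_interval_s > 0):
            raise ValueError(
                f"frame_interval_s must be > 0, got {self.frame_interval_s}"
            )
        if arr.ndim == 4:
            if self.z_spacing_um is None or not (self.z_spacing_um > 0):
                raise ValueError(
                    "4-D stacks require z_spacing_um > 0, got "
                    f"{self.z_spacing_um}"
                )

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[0])

    @property
    def has_z(self) -> bool:
        return self.data.ndim == 4

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=float) * self.frame_interval_s

    def frame(self, t: int) -> np.ndarray:
        """Frame ``t`` as float64 (2-D, or 3-D for volumetric stacks)."""
        return np.asarray(self.data[t], dtype=np.float64)

    def with_data(self, data: np.ndarray) -> "ImageStack":
        """New stack with the same calibration but different pixels."""
        return ImageStack(
            data=data,
            pixel_size_um=self.pixel_size_um,
            frame_interval_s=self.frame_interval_s,
            z_spacing_um=self.z_spacing_um,
        )


def read_stack(
    path: str | Path,
    *,
    pixel_size_um: float,
    frame_interval_s: float,
    z_spacing_um: float | None = None,
) -> ImageStack:
    """Read a grayscale multi-page TIFF into a calibrated :class:`ImageStack`.

    A single 2-D image is promoted to a T=1 stack.  RGB / multi-sample
    TIFFs are rejected: the analysis operates on single-channel data and a
    silent channel collapse would be a data error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        axes = series.axes.upper()
        if "S" in axes or "C" in axes:
            raise ValueError(
                f"{path}: RGB/multi-channel TIFF (axes {axes!r}); "
                "split channels into separate grayscale files"
            )
        arr = series.asarray()
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim not in (3, 4):
        raise ValueError(f"{path}: cannot interpret array of shape {arr.shape}")
    stack = ImageStack(
        data=arr,
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
        z_spacing_um=z_spacing_um if arr.ndim == 4 else None,
    )
    logger.info(
        "read_stack: %s shape=%s dtype=%s px=%.4g um frame=%.4g s",
        path, arr.shape, arr.dtype, pixel_size_um, frame_interval_s,
    )
    return stack


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write the stack as a multi-page grayscale TIFF (dtype preserved)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.data, photometric="minisblack")


def write_results_table(
    records: Sequence[Mapping[str, object]],
    path: str | Path,
    *,
    fieldnames: Sequence[str] | None = None,
) -> None:
    """Write keyed rows as CSV, full float precision, input row order.

    All rows must share the same key set; pass ``fieldnames`` to write a
    header-only file for an empty sequence.
    """
    records = list(records)
    if fieldnames is None:
        if not records:
            raise ValueError("fieldnames required to write an empty table")
        fieldnames = list(records[0].keys())
    keyset = set(fieldnames)
    for i, rec in enumerate(records):
        if set(rec.keys()) != keyset:
            raise ValueError(
                f"row {i} keys {sorted(rec.keys())} do not match schema "
                f"{sorted(keyset)}"
            )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(fieldnames)
        for rec in records:
            writer.writerow([_format_cell(rec[k]) for k in fieldnames])


def _format_cell(value: object) -> object:
    # repr round-trips Python floats exactly; everything else is written as-is
    if isinstance(value, (float, np.floating)):
        return repr(float(value))
    if isinstance(value, np.integer):
        return int(value)
    return value
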
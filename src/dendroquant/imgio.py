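"""Image reading/writing, brightness normalization, and z-projection.

Conventions: arrays are indexed ``(z, row, col)`` for stacks and
``(row, col)`` for planar images; channels are stored separately, never
interleaved.  Binary masks are boolean, with white (255) meaning
"included".  Normalized brightness lives on an image-independent [0, 1]
scale obtained by dividing by the dtype maximum, so that a fixed
threshold such as 0.4 means the same thing for every image of a given
bit depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .calibration import Calibration

__all__ = [
    "Stack",
    "Projection",
    "read_stack",
    "read_mask",
    "write_image",
    "max_intensity_projection",
    "normalize_brightness",
]


@dataclass
class Stack:
    """A multichannel z-stack: one ``(z, row, col)`` array per channel."""

    channels: dict[str, np.ndarray]
    calibration: Calibration
    bit_depth: int = 16

    def __post_init__(self) -> None:
        shapes = {name: arr.shape for name, arr in self.channels.items()}
        if not shapes:
            raise ValueError("stack must contain at least one channel")
        first = next(iter(shapes.values()))
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, arr in self.channels.items():
            if arr.ndim != 3:
                raise ValueError(f"channel {name!r} is not 3D (z, row, col)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")

    @property
    def n_slices(self) -> int:
        return next(iter(self.channels.values())).shape[0]


@dataclass
class Projection:
    """A 2D per-channel image with normalized brightness in [0, 1]."""

    pixels: np.ndarray
    calibration: Calibration
    channel: str = "chan0"

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("projection must be 2D")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("projection values must lie in [0, 1]")


def _infer_bit_depth(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    raise ValueError(f"unsupported sample format {arr.dtype}; expected uint8/uint16")


def read_stack(
    path: str | Path,
    calibration: Calibration,
    channel: str = "chan0",
    bit_depth: int | None = None,
) -> Stack:
    """Read a single-channel TIFF z-stack (multi-page = z).

    A 2D TIFF is promoted to a one-slice stack.  Multi-channel
    acquisitions are handled as one file per channel; read each file and
    merge the resulting ``channels`` dicts.
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # truncated / unreadable: no partial object
        raise OSError(f"cannot read TIFF stack {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3 or arr.size == 0:
        raise OSError(f"{path}: truncated or unsupported TIFF (shape {arr.shape})")
    depth = bit_depth if bit_depth is not None else _infer_bit_depth(arr)
    return Stack(channels={channel: arr}, calibration=calibration, bit_depth=depth)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a black-and-white PNG/TIFF mask; white = included."""
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise OSError(f"cannot read mask {path}: {exc}") from exc
    if arr.ndim == 3:  # RGB(A) export of a b/w drawing
        arr = arr[..., :3].max(axis=-1)
    return np.asarray(arr) > (np.iinfo(arr.dtype).max // 2 if arr.dtype.kind == "u" else 0)


def write_image(path: str | Path, image: np.ndarray | Projection) -> None:
    """Write a TIFF (grayscale image or stack) or a PNG (boolean mask).

    Boolean arrays are written as 0/255 PNG or TIFF depending on the
    suffix; integer arrays round-trip exactly at their dtype.
    ``Projection`` objects are written as 16-bit TIFF (value × 65535).
    """
    path = Path(path)
    if isinstance(image, Projection):
        image = np.round(image.pixels * 65535).astype(np.uint16)
    if image.dtype == bool:
        image = image.astype(np.uint8) * 255
    if path.suffix.lower() == ".png":
        iio.imwrite(path, image)
    else:
        tifffile.imwrite(path, image)


def max_intensity_projection(stack: Stack, channel: str = "chan0") -> Projection:
    """Maximum-intensity projection over z, per channel.

    Each output pixel is the maximum over all optical sections at that
    (row, col); brightness is then normalized to [0, 1] by the stack's
    bit depth.
    """
    if channel not in stack.channels:
        raise KeyError(f"unknown channel {channel!r}; have {sorted(stack.channels)}")
    voxels = stack.channels[channel]
    if voxels.shape[0] < 1:
        raise ValueError("stack has no slices")
    mip = voxels.max(axis=0)
    pixels = normalize_brightness(mip, bit_depth=stack.bit_depth)
    return Projection(pixels=pixels, calibration=stack.calibration, channel=channel)


def normalize_brightness(
    image: np.ndarray,
    bit_depth: int | None = None,
    max_value: float | None = None,
) -> np.ndarray:
    """Map raw intensities to [0, 1] by dividing by the dtype maximum.

    The divisor is ``2**bit_depth - 1`` (or an explicit ``max_value``),
    never the image's own maximum, so the scale is image-independent.
    """
    if max_value is None:
        if bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16, or pass max_value explicitly")
        max_value = float(2**bit_depth - 1)
    arr = np.asarray(image, dtype=float)
    if arr.max(initial=0.0) > max_value:
        raise ValueError(
            f"image values exceed declared maximum {max_value} (max {arr.max()})"
        )
    if arr.min(initial=0.0) < 0:
        raise ValueError("image contains negative values")
    return arr / max_value
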
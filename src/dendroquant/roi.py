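"""Observation-path ROIs grown from 1-pixel dendrite skeleton curves.

A dendrite of interest is marked by a hand-drawn 1-px-wide white curve
("skeleton curve") on a black background.  The analysis ROI — the
"observation path" — is obtained by growing the curve by a fixed radius
to both sides (default 95 px, i.e. a 191-px-wide band for a straight
curve), and the dendrite length is the traced length of the skeleton in
micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from pathlib import Path

import numpy as np
from scipy import ndimage

from .calibration import Calibration
from .imgio import read_mask

__all__ = ["SkeletonCurve", "ObservationPath", "grow_skeleton", "skeleton_length"]

DEFAULT_GROW_RADIUS_PX = 95


@dataclass
class SkeletonCurve:
    """A 1-px-wide (possibly branched) curve as a boolean pixel mask."""

    mask: np.ndarray
    calibration: Calibration

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("skeleton mask must be 2D")
        if not self.mask.any():
            raise ValueError("skeleton is empty")

    @classmethod
    def from_png(cls, path: str | Path, calibration: Calibration) -> "SkeletonCurve":
        return cls(mask=read_mask(path), calibration=calibration)

    @classmethod
    def from_coords(
        cls,
        coords: np.ndarray,
        shape: tuple[int, int],
        calibration: Calibration,
    ) -> "SkeletonCurve":
        mask = np.zeros(shape, dtype=bool)
        coords = np.asarray(coords, dtype=int)
        mask[coords[:, 0], coords[:, 1]] = True
        return cls(mask=mask, calibration=calibration)

    @property
    def coords(self) -> np.ndarray:
        return np.argwhere(self.mask)


@dataclass
class ObservationPath:
    """ROI band around a skeleton, plus the skeleton's physical length."""

    mask: np.ndarray
    grow_radius_px: int
    skeleton: SkeletonCurve
    length_um: float


def grow_skeleton(
    skeleton: SkeletonCurve, radius_px: int = DEFAULT_GROW_RADIUS_PX
) -> ObservationPath:
    """Grow a skeleton curve into an observation-path mask.

    The mask contains every pixel whose Euclidean distance to the
    nearest skeleton pixel is at most ``radius_px`` (clipped at the
    image border), so a straight curve grown by r yields a band
    2r + 1 pixels wide.
    """
    if radius_px < 0:
        raise ValueError("radius_px must be >= 0")
    if radius_px == 0:
        mask = skeleton.mask.copy()
    else:
        dist = ndimage.distance_transform_edt(~skeleton.mask)
        mask = dist <= radius_px
    return ObservationPath(
        mask=mask,
        grow_radius_px=int(radius_px),
        skeleton=skeleton,
        length_um=skeleton_length(skeleton),
    )


# Neighbor steps considered when tracing: orthogonal first, then diagonal.
_ORTHO = ((0, 1), (1, 0))
_DIAG = ((1, 1), (1, -1))


def skeleton_length(skeleton: SkeletonCurve) -> float:
    """Traced length of a skeleton in micrometres.

    Adjacent pixel pairs contribute one step each: 1 px for orthogonal
    neighbors, √2 px for diagonal ones.  A diagonal adjacency that is
    shortcut by an orthogonal skeleton pixel (the two pixels share an
    orthogonal neighbor on the curve) is not counted, so a clean
    8-connected curve is measured as its chain length; branches are
    summed and loop edges counted once.  The pixel total is converted to
    µm with the curve's calibration.
    """
    pts = set(map(tuple, np.argwhere(skeleton.mask)))
    total_px = 0.0
    for r, c in pts:
        for dr, dc in _ORTHO:
            if (r + dr, c + dc) in pts:
                total_px += 1.0
        for dr, dc in _DIAG:
            q = (r + dr, c + dc)
            if q not in pts:
                continue
            # skip if the diagonal is bridged by an orthogonal curve pixel
            if (r + dr, c) in pts or (r, c + dc) in pts:
                continue
            total_px += sqrt(2.0)
    return total_px * skeleton.calibration.pixel_size_um
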
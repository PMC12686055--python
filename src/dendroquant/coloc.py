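"""Pixel-intensity colocalization and intensity-ratio measures.

Colocalization of two fluorescence channels is quantified by Pearson's
correlation coefficient (PCC) over the paired pixel intensities inside
a region of interest: 1 means complete colocalization, 0 no relation,
−1 mutual exclusion.  Two ratio measures accompany it: the
membrane/diffuse ratio (mean intensity along two plasma-membrane lines
over the mean along a mid-dendrite line, from a single focal plane) and
the expression ratio (mean intensity in an ROI over transfected cells
versus an ROI over untransfected cells in the same image).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ColocResult", "LineProfile", "pcc", "membrane_diffuse_ratio", "expression_ratio"]


@dataclass
class ColocResult:
    pcc: float
    n_pixels: int


@dataclass
class LineProfile:
    """Line means used for the membrane/diffuse ratio."""

    membrane_means: tuple[float, float]
    center_mean: float
    ratio: float


def pcc(chan_a: np.ndarray, chan_b: np.ndarray, roi: np.ndarray | None = None) -> ColocResult:
    """Pearson correlation of two channels over an ROI.

    ``roi`` is a boolean mask (white = included); pass ``None`` for the
    full frame.  A constant channel inside the ROI has no defined
    correlation and raises rather than silently returning 0.
    """
    a = np.asarray(chan_a, dtype=float)
    b = np.asarray(chan_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"channel shapes differ: {a.shape} vs {b.shape}")
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != a.shape:
            raise ValueError("roi shape must match channels")
        a, b = a[roi], b[roi]
    else:
        a, b = a.ravel(), b.ravel()
    if a.size < 3:
        raise ValueError(f"need >= 3 ROI pixels, got {a.size}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant channel within ROI: correlation undefined")
    r = stats.pearsonr(a, b).statistic
    return ColocResult(pcc=float(r), n_pixels=int(a.size))


def _line_mean(plane: np.ndarray, line: np.ndarray) -> float:
    """Mean intensity along a 1-px line sampled at nearest pixels."""
    coords = np.rint(np.asarray(line, dtype=float)).astype(int)
    if coords.size == 0:
        raise ValueError("empty line")
    rows, cols = coords[:, 0], coords[:, 1]
    if (
        rows.min() < 0
        or cols.min() < 0
        or rows.max() >= plane.shape[0]
        or cols.max() >= plane.shape[1]
    ):
        raise ValueError("line extends outside the image")
    return float(plane[rows, cols].mean())


def membrane_diffuse_ratio(
    plane: np.ndarray,
    membrane_lines: tuple[np.ndarray, np.ndarray],
    center_line: np.ndarray,
) -> LineProfile:
    """Membrane/diffuse intensity ratio from hand-placed lines.

    The two membrane-line means are averaged into one membrane value;
    the ratio is that value over the mid-dendrite (diffuse) line mean.
    Invariant under global multiplicative intensity scaling.
    """
    plane = np.asarray(plane, dtype=float)
    m1, m2 = (_line_mean(plane, line) for line in membrane_lines)
    center = _line_mean(plane, center_line)
    if center == 0:
        raise ValueError("center-line mean is zero; ratio undefined")
    return LineProfile(
        membrane_means=(m1, m2),
        center_mean=center,
        ratio=((m1 + m2) / 2.0) / center,
    )


def expression_ratio(
    image: np.ndarray,
    roi_expressing: np.ndarray,
    roi_nonexpressing: np.ndarray,
) -> float:
    """Mean-intensity ratio: transfected cells / untransfected cells.

    Both ROIs are boolean masks over the same image.  When expression
    of the construct does not change the stained structure, the
    expected ratio is 1.
    """
    img = np.asarray(image, dtype=float)
    expr = np.asarray(roi_expressing, dtype=bool)
    ref = np.asarray(roi_nonexpressing, dtype=bool)
    if expr.shape != img.shape or ref.shape != img.shape:
        raise ValueError("ROI shapes must match the image")
    if not expr.any() or not ref.any():
        raise ValueError("both ROIs must be non-empty")
    denom = img[ref].mean()
    if denom == 0:
        raise ValueError("reference ROI mean is zero; ratio undefined")
    return float(img[expr].mean() / denom)
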
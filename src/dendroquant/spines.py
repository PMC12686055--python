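"""Dendritic-spine retention filters, classification, and density.

Protrusions detected on a dendrite are retained as spines only when
their geometry is plausible: volume ≥ 0.020 µm³, length between 0.1 and
5 µm, and maximal width ≤ 3 µm (boundaries inclusive).  Retained spines
are then classified, in fixed order: *mushroom* when the head diameter
is ≥ 0.35 µm and the head/neck ratio ≥ 1.1; otherwise *stubby* when the
volume is ≥ 0.040 µm³; all remaining spines are *thin*.  Densities are
counts per µm of dendrite, total and per class.

Volume thresholds are specified in µm³; equivalent voxel counts depend
on the voxel volume of a given acquisition and are derived, not stored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .calibration import Calibration

__all__ = [
    "ProtrusionMeasure",
    "SpineRules",
    "SpineCensus",
    "filter_protrusions",
    "classify_spine",
    "spine_density",
    "measure_protrusions",
]

CLASSES = ("thin", "stubby", "mushroom")


@dataclass
class ProtrusionMeasure:
    """Geometric descriptors of one dendritic protrusion (µm / µm³)."""

    length_um: float
    max_width_um: float
    volume_um3: float
    head_diameter_um: float
    neck_diameter_um: float
    id: int | str | None = None

    def __post_init__(self) -> None:
        for name in ("length_um", "max_width_um", "volume_um3", "head_diameter_um", "neck_diameter_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def volume_voxels(self, voxel_volume_um3: float) -> float:
        return self.volume_um3 / voxel_volume_um3

    @property
    def head_neck_ratio(self) -> float:
        if self.neck_diameter_um == 0:
            if self.head_diameter_um == 0:
                return 1.0  # degenerate point protrusion: no head either
            raise ValueError("neck diameter is zero with a nonzero head: ratio undefined")
        return self.head_diameter_um / self.neck_diameter_um


@dataclass(frozen=True)
class SpineRules:
    """Retention and classification thresholds (all inclusive)."""

    min_volume_um3: float = 0.020
    min_length_um: float = 0.1
    max_length_um: float = 5.0
    max_width_um: float = 3.0
    mushroom_min_head_um: float = 0.35
    mushroom_min_head_neck_ratio: float = 1.1
    stubby_min_volume_um3: float = 0.040

    def __post_init__(self) -> None:
        if not self.min_length_um < self.max_length_um:
            raise ValueError("min_length_um must be < max_length_um")
        for name in (
            "min_volume_um3",
            "min_length_um",
            "max_width_um",
            "mushroom_min_head_um",
            "mushroom_min_head_neck_ratio",
            "stubby_min_volume_um3",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    def min_volume_voxels(self, voxel_volume_um3: float) -> float:
        return self.min_volume_um3 / voxel_volume_um3

    def stubby_min_volume_voxels(self, voxel_volume_um3: float) -> float:
        return self.stubby_min_volume_um3 / voxel_volume_um3


@dataclass
class SpineCensus:
    """Retained spines with classes and per-µm densities."""

    retained: list[tuple[ProtrusionMeasure, str]]
    dendrite_length_um: float
    density_total: float
    density_per_class: dict[str, float]


def filter_protrusions(
    measures: list[ProtrusionMeasure], rules: SpineRules = SpineRules()
) -> list[ProtrusionMeasure]:
    """Keep protrusions whose geometry qualifies them as spines."""
    return [
        m
        for m in measures
        if m.volume_um3 >= rules.min_volume_um3
        and rules.min_length_um <= m.length_um <= rules.max_length_um
        and m.max_width_um <= rules.max_width_um
    ]


def classify_spine(measure: ProtrusionMeasure, rules: SpineRules = SpineRules()) -> str:
    """Assign a retained spine to mushroom, stubby, or thin (in that order)."""
    if (
        measure.head_diameter_um >= rules.mushroom_min_head_um
        and measure.head_neck_ratio >= rules.mushroom_min_head_neck_ratio
    ):
        return "mushroom"
    if measure.volume_um3 >= rules.stubby_min_volume_um3:
        return "stubby"
    return "thin"


def spine_density(
    measures: list[ProtrusionMeasure],
    dendrite_length_um: float,
    rules: SpineRules = SpineRules(),
) -> SpineCensus:
    """Filter, classify, and express spine counts per µm of dendrite."""
    if not dendrite_length_um > 0:
        raise ValueError("dendrite_length_um must be > 0")
    retained = [(m, classify_spine(m, rules)) for m in filter_protrusions(measures, rules)]
    per_class = {
        cls: sum(1 for _, c in retained if c == cls) / dendrite_length_um
        for cls in CLASSES
    }
    return SpineCensus(
        retained=retained,
        dendrite_length_um=dendrite_length_um,
        density_total=len(retained) / dendrite_length_um,
        density_per_class=per_class,
    )


def measure_protrusions(
    segmentation: np.ndarray,
    shaft_mask: np.ndarray,
    calibration: Calibration,
    section_thickness_um: float = 0.4,
) -> list[ProtrusionMeasure]:
    """Measure protrusions on a 2D binary dendrite segmentation.

    ``segmentation`` is the thresholded dendrite (shaft + protrusions);
    ``shaft_mask`` marks the shaft.  Each connected component of
    ``segmentation & ~shaft_mask`` is one protrusion.  Per protrusion:

    * length: maximal Euclidean distance of a protrusion pixel from the
      shaft surface, in µm;
    * width profile: pixel count per unit-distance band from the shaft
      (a discrete chord perpendicular to the outgrowth axis);
    * head diameter: maximal band width in the distal half;
    * neck diameter: minimal band width between base and head band;
    * volume: pixel area × section thickness (2D mode).

    Protrusions touching the image border cannot be measured reliably;
    they are excluded with a warning.
    """
    seg = np.asarray(segmentation, dtype=bool)
    shaft = np.asarray(shaft_mask, dtype=bool)
    if seg.shape != shaft.shape:
        raise ValueError("segmentation and shaft_mask shapes differ")
    px = calibration.pixel_size_um
    dist_from_shaft = ndimage.distance_transform_edt(~shaft)
    labels, n = ndimage.label(seg & ~shaft, structure=ndimage.generate_binary_structure(2, 2))
    measures: list[ProtrusionMeasure] = []
    n_excluded = 0
    # report protrusions in order of position along the shaft, not scan order
    order = sorted(
        range(1, n + 1), key=lambda pid: np.nonzero(labels == pid)[1].mean()
    )
    for pid in order:
        comp = labels == pid
        rr, cc = np.nonzero(comp)
        if (
            rr.min() == 0
            or cc.min() == 0
            or rr.max() == seg.shape[0] - 1
            or cc.max() == seg.shape[1] - 1
        ):
            n_excluded += 1
            continue
        d = dist_from_shaft[comp]
        length_px = float(d.max())
        bands = np.ceil(d).astype(int)  # band k: distance in (k-1, k]
        max_band = bands.max()
        widths = np.bincount(bands, minlength=max_band + 1)[1:].astype(float)
        if widths.size == 0:
            continue
        max_width = float(widths.max())
        distal = widths[widths.size // 2 :]
        head = float(distal.max())
        head_band = widths.size // 2 + int(np.argmax(distal))  # 0-based band index
        neck = float(widths[: head_band + 1].min()) if head_band >= 0 else head
        measures.append(
            ProtrusionMeasure(
                id=len(measures) + 1,
                length_um=length_px * px,
                max_width_um=max_width * px,
                volume_um3=float(comp.sum()) * px * px * section_thickness_um,
                head_diameter_um=head * px,
                neck_diameter_um=neck * px,
            )
        )
    if n_excluded:
        warnings.warn(
            f"{n_excluded} protrusion(s) touching the image border were excluded",
            stacklevel=2,
        )
    return measures
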
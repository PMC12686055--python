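"""Physical pixel/voxel calibration.

All geometric quantities in this package are reported in micrometres;
the :class:`Calibration` carries the conversion factors from pixel and
optical-section units.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Calibration:
    """Pixel and z-step size of an acquisition.

    Parameters
    ----------
    pixel_size_um:
        Lateral (xy) size of one pixel in micrometres.
    z_step_um:
        Spacing between consecutive optical sections in micrometres.
        Irrelevant for purely 2D analyses; defaults to 0.2 µm, a common
        confocal step size.
    """

    pixel_size_um: float
    z_step_um: float = 0.2

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not self.z_step_um > 0:
            raise ValueError(f"z_step_um must be > 0, got {self.z_step_um}")

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2

    @property
    def voxel_volume_um3(self) -> float:
        return self.pixel_size_um**2 * self.z_step_um
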
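"""Spatial and temporal calibration shared across the toolkit."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Calibration:
    """Pixel pitch and frame rate of a recording.

    Attributes
    ----------
    um_per_px:
        Physical size of one pixel in micrometres. The default of 25 µm/px
        corresponds to a ~4.3 × 4.3 cm field of view on a 2 k sensor, fine
        enough to resolve individual appendages.
    fps:
        Acquisition rate in frames per second (typically 25 or 40).
    """

    um_per_px: float = 25.0
    fps: float = 25.0

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def mm_per_px(self) -> float:
        return self.um_per_px / 1000.0

    @property
    def px_per_mm(self) -> float:
        return 1000.0 / self.um_per_px

    def px_to_mm(self, v):
        return np.asarray(v, dtype=float) * self.mm_per_px

    def mm_to_px(self, v):
        return np.asarray(v, dtype=float) * self.px_per_mm

    def px2_to_mm2(self, v):
        return np.asarray(v, dtype=float) * self.mm_per_px**2

    def mm2_to_px2(self, v):
        return np.asarray(v, dtype=float) * self.px_per_mm**2
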
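"""Shared container types for image data.

An :class:`ImageStack` is an ordered sequence of 2D intensity grids — the
frames of a TIRF time-lapse, the planes of a confocal z-stack, or the
channels of a multi-channel tile — together with the physical calibration
needed to convert pixel measurements into nanometres and seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageStack", "RoiMask"]

#: A region of interest: boolean 2D array, True inside the ROI.
RoiMask = np.ndarray


@dataclass
class ImageStack:
    """Ordered 2D intensity grids with physical calibration.

    Parameters
    ----------
    data
        Array of shape ``(n_planes, height, width)``.  Planes are time
        points for a movie, z-slices for a stack, channels for a
        multi-channel tile; the axis meaning is carried by context.
    pixel_size_nm
        Lateral calibration, nanometres per pixel.
    frame_interval_s
        Time between planes in seconds (movies only).
    """

    data: np.ndarray
    pixel_size_nm: float | None = None
    frame_interval_s: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError(f"expected 2D or 3D array, got shape {self.data.shape}")

    @property
    def n_planes(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __len__(self) -> int:
        return self.n_planes

    def __getitem__(self, i) -> np.ndarray:
        return self.data[i]
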
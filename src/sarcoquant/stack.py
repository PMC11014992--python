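"""Calibrated image stacks.

An :class:`ImageStack` is the universal input of the pipeline: a z-ordered
set of 2D intensity planes plus the physical pixel size in micrometres.
All area measurements downstream are ``pixel count × pixel_size_um²``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageStack", "max_project"]


@dataclass
class ImageStack:
    """A z-ordered stack of 2D intensity planes with pixel calibration.

    Parameters
    ----------
    planes : ndarray, shape (n_planes, height, width)
        Non-negative intensity grids; all planes share dimensions.
    pixel_size_um : float
        Physical size of one pixel edge in micrometres (> 0).
    channel_name : str
        Free-text channel label (e.g. ``"MitoTracker"``, ``"TMRE"``).
    """

    planes: np.ndarray
    pixel_size_um: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.planes.ndim == 2:
            self.planes = self.planes[np.newaxis]
        if self.planes.ndim != 3:
            raise ValueError(
                f"planes must be a (n_planes, h, w) array, got ndim={self.planes.ndim}"
            )
        if self.planes.shape[0] < 1:
            raise ValueError("stack must contain at least one plane")
        if not np.isfinite(self.pixel_size_um) or self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")

    @property
    def n_planes(self) -> int:
        return int(self.planes.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of each plane."""
        return (int(self.planes.shape[1]), int(self.planes.shape[2]))

    @property
    def pixel_area_um2(self) -> float:
        """Area of one pixel in µm² — the 'cluster resolution' used for areas."""
        return float(self.pixel_size_um) ** 2

    def plane(self, index: int) -> np.ndarray:
        return self.planes[index]

    def max_projection(self) -> np.ndarray:
        """Per-pixel maximum intensity across all z-planes."""
        return self.planes.max(axis=0)


def max_project(stack: ImageStack) -> np.ndarray:
    """Max-intensity z-projection: per-pixel maximum across planes."""
    return stack.max_projection()


@dataclass
class InstanceLabelMap:
    """2D integer grid: 0 = background/noise, k >= 1 = instance id.

    Instance ids are consecutive from 1. Carries the pixel calibration of
    the source image so that areas can be computed downstream.
    """

    labels: np.ndarray
    pixel_size_um: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label map must have an integer dtype")

    @property
    def n_instances(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def binary_mask(self) -> np.ndarray:
        return self.labels > 0

    def pixel_counts(self) -> np.ndarray:
        """Pixel count per instance id 1..n_instances."""
        return np.bincount(self.labels.ravel(), minlength=self.n_instances + 1)[1:]
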
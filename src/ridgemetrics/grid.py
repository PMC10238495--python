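"""The universal 2D image carrier with physical pixel sizes.

Every stage of the pipeline passes grayscale or binary fields around as a
:class:`PixelGrid`: a 2D array plus the pixel pitch in micrometres.  The
origin is the top-left corner, ``x`` runs along columns and ``y`` along rows,
matching the convention of the acquisition software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PixelGrid"]


@dataclass
class PixelGrid:
    """A 2D scalar field on a regular grid with physical pixel sizes (µm).

    Parameters
    ----------
    values
        2D array of pixel values (grayscale intensities or a binary mask).
    dx, dy
        Physical pixel pitch in µm along columns (x) and rows (y).
    """

    values: np.ndarray
    dx: float = 1.0
    dy: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"PixelGrid values must be 2D, got shape {self.values.shape}")
        if self.values.size == 0:
            raise ValueError("PixelGrid values must be non-empty")
        if not (self.dx > 0 and self.dy > 0):
            raise ValueError(f"pixel sizes must be positive, got dx={self.dx}, dy={self.dy}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("PixelGrid values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def x_coords(self) -> np.ndarray:
        """Physical x coordinate (µm) of each column."""
        return np.arange(self.values.shape[1]) * self.dx

    def y_coords(self) -> np.ndarray:
        """Physical y coordinate (µm) of each row."""
        return np.arange(self.values.shape[0]) * self.dy

    def with_values(self, values: np.ndarray) -> "PixelGrid":
        """A new grid with the same pixel sizes and different values."""
        return PixelGrid(values, self.dx, self.dy)


def as_grid(img, dx: float = 1.0, dy: float = 1.0) -> PixelGrid:
    """Coerce an array or PixelGrid to a PixelGrid."""
    if isinstance(img, PixelGrid):
        return img
    return PixelGrid(np.asarray(img, dtype=float), dx, dy)
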
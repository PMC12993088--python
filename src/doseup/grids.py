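"""2D dose-grid container.

A :class:`DoseGrid` is the universal currency of the pipeline: a 2D map of
absorbed dose in Gy on a regular square-pixel raster, together with the pixel
pitch and the physical position of pixel (0, 0).

Coordinate conventions
----------------------
Matrices are row-major.  Physical ``x`` (left-right) increases with the column
index, physical ``y`` (target-gun) increases with the row index.  All stored
positions refer to *pixel centers*; ``origin_mm`` is the (x, y) position of the
center of pixel ``(0, 0)`` relative to the beam axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DoseGrid", "centered_origin"]


def centered_origin(shape: tuple[int, int], spacing_mm: float) -> tuple[float, float]:
    """Origin placing the grid's physical center on the beam axis."""
    n_rows, n_cols = shape
    return (-(n_cols - 1) / 2.0 * spacing_mm, -(n_rows - 1) / 2.0 * spacing_mm)


@dataclass
class DoseGrid:
    """A 2D absorbed-dose map [Gy] with square pixels.

    Parameters
    ----------
    values
        2D array of non-negative doses in Gy.
    spacing_mm
        Pixel pitch in mm (square pixels).
    origin_mm
        (x, y) of the center of pixel (0, 0) relative to the beam axis, mm.
        Defaults to a beam-axis-centered grid.
    """

    values: np.ndarray
    spacing_mm: float
    origin_mm: tuple[float, float] | None = None
    unit: str = field(default="Gy")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("values must be a non-empty 2D matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("values must be finite")
        if (self.values < 0).any():
            raise ValueError("dose values must be non-negative")
        if not self.spacing_mm > 0:
            raise ValueError("spacing_mm must be positive")
        if self.origin_mm is None:
            self.origin_mm = centered_origin(self.values.shape, self.spacing_mm)
        self.origin_mm = (float(self.origin_mm[0]), float(self.origin_mm[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinates of all pixel centers.

        Returns two arrays of shape ``values.shape``: x and y in mm.
        """
        n_rows, n_cols = self.values.shape
        x = self.origin_mm[0] + np.arange(n_cols) * self.spacing_mm
        y = self.origin_mm[1] + np.arange(n_rows) * self.spacing_mm
        xx, yy = np.meshgrid(x, y)
        return xx, yy

    def same_frame(self, other: "DoseGrid", tol: float = 1e-6) -> bool:
        """Whether two grids share pixel raster geometry (spacing and origin)."""
        return (
            abs(self.spacing_mm - other.spacing_mm) <= tol
            and abs(self.origin_mm[0] - other.origin_mm[0]) <= tol
            and abs(self.origin_mm[1] - other.origin_mm[1]) <= tol
        )

    def copy(self) -> "DoseGrid":
        return DoseGrid(self.values.copy(), self.spacing_mm, self.origin_mm, self.unit)
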
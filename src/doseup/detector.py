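"""Checkerboard ionization-chamber array geometry and measurement forward model.

The OCTAVIUS-1500-class array places air-filled chambers on every other node of
a square grid (checkerboard), so that nearest neighbors sit on the diagonals.
Measuring a high-resolution dose field with such an array involves two losses:
the finite chamber area averages the local dose (volume-averaging effect), and
only half of the grid nodes carry a chamber.  ``forward_model`` emulates both,
plus measurement noise: 3x3 average pooling of the high-resolution grid,
Gaussian noise relative to the slice maximum, and zeroing of non-chamber nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grids import DoseGrid

__all__ = [
    "DetectorLayout",
    "ForwardModelConfig",
    "ArrayMeasurement",
    "build_layout",
    "diagonal_pitch",
    "forward_model",
]


@dataclass
class DetectorLayout:
    """Geometry of a checkerboard chamber array.

    ``chamber_mask[i, j]`` is True where a chamber sits on grid node (i, j);
    the checkerboard phase is "corners active": chambers at even ``i + j``.
    """

    n_rows: int
    n_cols: int
    grid_pitch_mm: float
    chamber_mask: np.ndarray
    chamber_size_mm: float
    name: str = ""

    def __post_init__(self) -> None:
        self.chamber_mask = np.asarray(self.chamber_mask, dtype=bool)
        if self.chamber_mask.shape != (self.n_rows, self.n_cols):
            raise ValueError("chamber_mask shape must be (n_rows, n_cols)")
        if not self.grid_pitch_mm > 0:
            raise ValueError("grid_pitch_mm must be positive")
        ii, jj = np.indices((self.n_rows, self.n_cols))
        if not np.array_equal(self.chamber_mask, (ii + jj) % 2 == 0):
            raise ValueError("chamber_mask must be a corners-active checkerboard")

    @property
    def n_chambers(self) -> int:
        return int(self.chamber_mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)


@dataclass
class ForwardModelConfig:
    """Volume-averaging + noise model of the array measurement.

    pool_kernel
        Side of the average-pooling block (odd); 3 maps a 1.67 mm dose grid
        onto the 5 mm chamber pitch.
    noise_sigma_rel
        Gaussian noise standard deviation as a fraction of the slice maximum.
        The default 0.005 mirrors the ~0.5% statistical noise floor of a
        high-quality Monte Carlo dose calculation.
    """

    pool_kernel: int = 3
    noise_sigma_rel: float = 0.005
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pool_kernel < 1 or self.pool_kernel % 2 == 0:
            raise ValueError("pool_kernel must be odd and >= 1")
        if self.noise_sigma_rel < 0:
            raise ValueError("noise_sigma_rel must be non-negative")


@dataclass
class ArrayMeasurement:
    """A sparse array reading: a low-resolution grid zeroed off-chamber."""

    grid: DoseGrid
    layout: DetectorLayout

    def __post_init__(self) -> None:
        if self.grid.values.shape != self.layout.shape:
            raise ValueError("measurement grid shape must equal layout shape")
        if np.any(self.grid.values[~self.layout.chamber_mask] != 0.0):
            raise ValueError("non-chamber entries must be exactly zero")


_PRESETS = {
    # 53x53 nodes at 5 mm pitch, 4.4 mm square sensitive area, 1405 chambers
    "OD1500": dict(n_rows=53, n_cols=53, grid_pitch_mm=5.0, chamber_size_mm=4.4),
}


def build_layout(
    name: str | None = "OD1500",
    *,
    n_rows: int | None = None,
    n_cols: int | None = None,
    grid_pitch_mm: float | None = None,
    chamber_size_mm: float | None = None,
) -> DetectorLayout:
    """Build a checkerboard layout from a preset name or explicit geometry.

    Chambers occupy nodes with even row+column index, so all four corners of
    the grid are active; on an odd-by-odd grid this phase yields
    ``ceil(n_rows * n_cols / 2)`` chambers (1405 for the 53x53 preset).
    """
    if name is not None and n_rows is None:
        try:
            params = dict(_PRESETS[name])
        except KeyError:
            raise ValueError(
                f"unknown detector preset {name!r}; known: {sorted(_PRESETS)}"
            ) from None
    else:
        if n_rows is None or n_cols is None or grid_pitch_mm is None:
            raise ValueError("explicit layouts need n_rows, n_cols and grid_pitch_mm")
        params = dict(
            n_rows=n_rows,
            n_cols=n_cols,
            grid_pitch_mm=grid_pitch_mm,
            chamber_size_mm=chamber_size_mm
            if chamber_size_mm is not None
            else 0.88 * grid_pitch_mm,
        )
        name = name or f"custom{n_rows}x{n_cols}"
    ii, jj = np.indices((params["n_rows"], params["n_cols"]))
    mask = (ii + jj) % 2 == 0
    return DetectorLayout(chamber_mask=mask, name=name, **params)


def diagonal_pitch(layout: DetectorLayout) -> float:
    """Nearest-neighbor distance between diagonally adjacent chambers [mm].

    For a checkerboard on pitch ``p`` this is ``p * sqrt(2)`` (7.07 mm for the
    5 mm preset, i.e. 7.1 mm at one-decimal precision; the axial
    chamber-to-chamber distance is ``2 p`` = 10 mm).
    """
    if layout.n_chambers < 2:
        raise ValueError("diagonal pitch undefined for fewer than 2 chambers")
    # distance between chambers (0,0) and (1,1), present in every >=2x2 board
    return math.hypot(layout.grid_pitch_mm, layout.grid_pitch_mm)


def forward_model(
    highres: DoseGrid,
    layout: DetectorLayout,
    cfg: ForwardModelConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ArrayMeasurement:
    """Simulate an array measurement of a high-resolution dose distribution.

    Each chamber reads the arithmetic mean of its aligned
    ``pool_kernel x pool_kernel`` block of high-resolution pixels (block center
    collocated with the chamber center), plus Gaussian noise with standard
    deviation ``noise_sigma_rel * max(highres)``; nodes without a chamber read
    exactly zero.  Noisy readings are clamped at zero so the measurement stays
    a valid dose map.  With ``noise_sigma_rel = 0`` the operation is
    deterministic and exact.
    """
    cfg = cfg or ForwardModelConfig()
    k = cfg.pool_kernel
    n_rows, n_cols = layout.shape
    if highres.values.shape != (k * n_rows, k * n_cols):
        raise ValueError(
            f"highres shape {highres.values.shape} incompatible with "
            f"{k}x pooling onto a {n_rows}x{n_cols} layout"
        )
    if abs(highres.spacing_mm * k - layout.grid_pitch_mm) > 1e-6:
        raise ValueError("highres spacing x pool_kernel must equal the grid pitch")

    pooled = highres.values.reshape(n_rows, k, n_cols, k).mean(axis=(1, 3))
    if cfg.noise_sigma_rel > 0:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        sigma = cfg.noise_sigma_rel * float(highres.values.max())
        pooled = pooled + rng.normal(0.0, sigma, size=pooled.shape)
        np.clip(pooled, 0.0, None, out=pooled)
    pooled[~layout.chamber_mask] = 0.0

    # chamber (i,j) center collocated with highres pixel (k*i+(k-1)/2, ...)
    off = (k - 1) / 2.0 * highres.spacing_mm
    origin = (highres.origin_mm[0] + off, highres.origin_mm[1] + off)
    grid = DoseGrid(pooled, spacing_mm=layout.grid_pitch_mm, origin_mm=origin)
    return ArrayMeasurement(grid=grid, layout=layout)
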
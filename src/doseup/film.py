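"""Radiochromic (EBT3) film calibration and scan-to-dose conversion.

Film pieces are scanned at 72 dpi / 16 bit per color channel; only the red
channel carries the dosimetric signal.  Pixel values are mapped to the
calibration abscissa t = log10(px / 2^16) — the log-transmittance, zero at
full transmission and negative for darkened film — and a third-order
polynomial D(t) = p1 t^3 + p2 t^2 + p3 t + p4 fitted on replicate-averaged
calibration exposures converts t to absorbed dose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import DoseGrid

__all__ = [
    "FilmScan",
    "FilmCalibration",
    "px_to_t",
    "fit_calibration",
    "apply_calibration",
    "read_scan",
]

_FULL_SCALE = 2**16


@dataclass
class FilmScan:
    """A 16-bit red-channel film scan."""

    px: np.ndarray
    dpi: float = 72.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.px = np.asarray(self.px)
        if self.px.ndim != 2 or self.px.size == 0:
            raise ValueError("px must be a non-empty 2D matrix")
        if (self.px <= 0).any() or (self.px > _FULL_SCALE).any():
            raise ValueError("pixel values must lie in (0, 2^16]")
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")

    @property
    def spacing_mm(self) -> float:
        return 25.4 / self.dpi


@dataclass
class FilmCalibration:
    """Cubic calibration D(t) = p1 t^3 + p2 t^2 + p3 t + p4 with its t-domain."""

    p1: float
    p2: float
    p3: float
    p4: float
    t_domain: tuple[float, float]

    def dose(self, t: np.ndarray) -> np.ndarray:
        return np.polyval([self.p1, self.p2, self.p3, self.p4], t)


def px_to_t(px) -> np.ndarray | float:
    """Calibration abscissa t = log10(px / 2^16), strictly increasing in px.

    t(2^16) = 0 (full transmission); darker film gives more negative t.
    """
    px = np.asarray(px, dtype=float)
    if (px <= 0).any():
        raise ValueError("pixel values must be positive")
    t = np.log10(px / _FULL_SCALE)
    return float(t) if t.ndim == 0 else t


def fit_calibration(doses, t_values) -> FilmCalibration:
    """Least-squares cubic fit of dose against replicate-averaged t values.

    ``t_values`` may be one abscissa per dose point, or a (n_points, n_reps)
    matrix of replicates which is averaged along its last axis before
    fitting.  Requires at least 4 distinct t values.
    """
    doses = np.asarray(doses, dtype=float)
    t = np.asarray(t_values, dtype=float)
    if t.ndim == 2:
        t = t.mean(axis=1)
    if doses.shape != t.shape or doses.ndim != 1:
        raise ValueError("doses and t_values must match, one entry per dose point")
    if np.unique(t).size < 4:
        raise ValueError("cubic calibration needs at least 4 distinct t values")
    p1, p2, p3, p4 = np.polyfit(t, doses, 3)
    return FilmCalibration(p1, p2, p3, p4, (float(t.min()), float(t.max())))


def apply_calibration(scan: FilmScan, cal: FilmCalibration) -> DoseGrid:
    """Convert a film scan to a dose map via the fitted cubic.

    t values outside the calibration domain are clipped to it; negative fitted
    doses are clamped to zero.  The output pixel pitch is 25.4/dpi mm.
    """
    t = px_to_t(scan.px)
    n_clipped = int(((t < cal.t_domain[0]) | (t > cal.t_domain[1])).sum())
    if n_clipped:
        import logging

        logging.getLogger(__name__).info(
            "apply_calibration: clipped %d pixels to the calibration domain",
            n_clipped,
        )
    t = np.clip(t, cal.t_domain[0], cal.t_domain[1])
    dose = np.clip(cal.dose(t), 0.0, None)
    return DoseGrid(dose, spacing_mm=scan.spacing_mm)


def read_scan(path, dpi: float = 72.0) -> FilmScan:
    """Read a film scan from a 16-bit TIFF; channel 0 is used as red."""
    import tifffile

    arr = tifffile.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    arr = arr.astype(np.int64)
    arr[arr == 0] = 1  # dead pixels: darkest representable value
    return FilmScan(px=arr, dpi=dpi)
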
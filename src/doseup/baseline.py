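"""Reference upsampling: checkerboard hole-filling + bilinear interpolation.

This is the conventional processing chain for checkerboard array measurements:
missing grid nodes are first filled from their axial chamber neighbors
(diagonal neighbors are never used), and the resulting dense low-resolution
grid is then bilinearly interpolated to the target pitch (5 mm -> 1.67 mm,
53x53 -> 159x159 for the standard array).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .detector import ArrayMeasurement
from .grids import DoseGrid

__all__ = ["fill_checkerboard", "bilinear_upsample", "bilinear_predict"]


def fill_checkerboard(m: ArrayMeasurement) -> DoseGrid:
    """Fill the non-chamber holes of a checkerboard measurement.

    Every hole is replaced by the mean of its *available* axial neighbors
    (up/down along target-gun, left/right along left-right) — up to four in
    the interior, three on edges, two in non-chamber corners.  Chamber values
    pass through unchanged.  When only a single opposite pair exists this
    reduces to the two-neighbor mean; averaging all axial pairs keeps the rule
    symmetric and direction-free.
    """
    mask = m.layout.chamber_mask
    v = m.grid.values
    num = np.zeros_like(v)
    cnt = np.zeros(v.shape)
    for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        src_v = np.roll(v, (di, dj), axis=(0, 1))
        src_m = np.roll(mask, (di, dj), axis=(0, 1)).astype(float)
        # rolled-in wrap rows/cols are not real neighbors
        if di == 1:
            src_v, src_m = src_v.copy(), src_m.copy()
            src_v[0], src_m[0] = 0, 0
        elif di == -1:
            src_v, src_m = src_v.copy(), src_m.copy()
            src_v[-1], src_m[-1] = 0, 0
        if dj == 1:
            src_v, src_m = src_v.copy(), src_m.copy()
            src_v[:, 0], src_m[:, 0] = 0, 0
        elif dj == -1:
            src_v, src_m = src_v.copy(), src_m.copy()
            src_v[:, -1], src_m[:, -1] = 0, 0
        num += src_v * src_m
        cnt += src_m
    holes = ~mask
    if np.any(cnt[holes] == 0):
        raise ValueError("hole with no axial chamber neighbor cannot be filled")
    filled = v.copy()
    filled[holes] = num[holes] / cnt[holes]
    return DoseGrid(filled, m.grid.spacing_mm, m.grid.origin_mm)


def bilinear_upsample(dense: DoseGrid, factor: int) -> DoseGrid:
    """Bilinearly upsample a dense grid by an integer factor per axis.

    Output pixel (factor*i + (factor-1)/2, factor*j + (factor-1)/2) is
    collocated with input pixel (i, j), so both grids share the same physical
    center and extent (53x53 at 5 mm -> 159x159 at 1.67 mm).  Interior output
    values are the standard two-pass linear interpolation on the four
    surrounding input centers; the outer fringe beyond the hull of input
    centers replicates the nearest interior value (edge clamp).
    """
    if not (isinstance(factor, (int, np.integer)) and factor >= 1):
        raise ValueError("factor must be a positive integer")
    f = int(factor)
    n_rows, n_cols = dense.values.shape
    out_rows, out_cols = f * n_rows, f * n_cols
    # fractional input-index coordinates of output pixel centers
    u = (np.arange(out_rows) - (f - 1) / 2.0) / f
    w = (np.arange(out_cols) - (f - 1) / 2.0) / f
    uu, ww = np.meshgrid(u, w, indexing="ij")
    out = ndimage.map_coordinates(
        dense.values, [uu, ww], order=1, mode="nearest"
    )
    spacing = dense.spacing_mm / f
    shift = (f - 1) * dense.spacing_mm / (2.0 * f)
    origin = (dense.origin_mm[0] - shift, dense.origin_mm[1] - shift)
    return DoseGrid(np.clip(out, 0.0, None), spacing, origin)


def bilinear_predict(m: ArrayMeasurement, factor: int = 3) -> DoseGrid:
    """Full baseline chain: hole filling followed by bilinear upsampling."""
    return bilinear_upsample(fill_checkerboard(m), factor)
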
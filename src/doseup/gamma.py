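"""2D gamma-index analysis with local or global dose criterion.

For every reference point r the gamma index is the minimum, over evaluated
positions e within a search radius, of

    sqrt( (|D_e - D_r| / dD(r))^2 + (||e - r|| / dta)^2 )

with dD(r) = dose_pct% of the local reference dose (local criterion) or of the
reference maximum (global).  Points below the suppression threshold (percent
of the reference maximum) are excluded from the statistics; gamma <= 1 passes.

The evaluated distribution is bilinearly interpolated onto a sub-grid
(``eval_upsample_factor`` per axis) and the minimization runs over all
sub-grid nodes within ``search_radius_factor * dta_mm`` of the reference
point, visited in order of increasing distance with early termination once
the distance term alone exceeds every remaining candidate minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import DoseGrid

__all__ = ["GammaCriteria", "GammaResult", "gamma_map", "passing_rate", "gamma_histogram"]


@dataclass
class GammaCriteria:
    """Dose/distance criteria of the gamma analysis.

    ``dose_pct`` percent dose-difference criterion, ``dta_mm`` distance to
    agreement; ``local`` selects the local-dose normalization;
    ``threshold_pct`` suppresses reference points below this percentage of the
    reference maximum.
    """

    dose_pct: float = 2.0
    dta_mm: float = 2.0
    local: bool = True
    threshold_pct: float = 10.0
    search_radius_factor: float = 3.0
    eval_upsample_factor: int = 10

    def __post_init__(self) -> None:
        if self.dose_pct <= 0 or self.dta_mm <= 0:
            raise ValueError("dose_pct and dta_mm must be positive")
        if not 0 <= self.threshold_pct < 100:
            raise ValueError("threshold_pct must lie in [0, 100)")
        if self.eval_upsample_factor < 1:
            raise ValueError("eval_upsample_factor must be >= 1")


@dataclass
class GammaResult:
    """Gamma map (NaN at suppressed points) and pass statistics."""

    gamma_values: np.ndarray
    evaluated_count: int
    passed_count: int
    criteria: GammaCriteria

    @property
    def passing_rate_pct(self) -> float:
        if self.evaluated_count == 0:
            raise ValueError("all reference points suppressed")
        return 100.0 * self.passed_count / self.evaluated_count


def gamma_map(
    evaluated: DoseGrid, reference: DoseGrid, crit: GammaCriteria | None = None
) -> GammaResult:
    """Compute the gamma map of ``evaluated`` against ``reference``.

    Both grids live in the same physical coordinate system but may have
    different spacings and origins; reference positions are snapped to the
    fine evaluation lattice (at most half a fine pixel).  Suppressed
    reference points — below the threshold,
    or with zero local dose under the local criterion — are NaN in the map
    and excluded from the counts.
    """
    crit = crit or GammaCriteria()
    ref = reference.values
    ref_max = float(ref.max())
    if ref_max <= 0:
        raise ValueError("reference maximum must be positive")

    # fine sub-grid over the evaluated distribution
    F = int(crit.eval_upsample_factor)
    fine_spacing = evaluated.spacing_mm / F
    ne_r, ne_c = evaluated.values.shape
    fi = np.arange((ne_r - 1) * F + 1) / F
    fj = np.arange((ne_c - 1) * F + 1) / F
    fine = ndimage.map_coordinates(
        evaluated.values, np.meshgrid(fi, fj, indexing="ij"), order=1, mode="nearest"
    )

    # reference point positions expressed in fine-grid index space
    nr, nc = ref.shape
    rx = reference.origin_mm[0] + np.arange(nc) * reference.spacing_mm
    ry = reference.origin_mm[1] + np.arange(nr) * reference.spacing_mm
    # each reference point snaps to its nearest fine node; the positional
    # error is at most half a fine pixel (evaluated spacing / (2 F))
    base_j = (rx - evaluated.origin_mm[0]) / fine_spacing
    base_i = (ry - evaluated.origin_mm[1]) / fine_spacing
    bi = np.rint(base_i).astype(int)
    bj = np.rint(base_j).astype(int)
    bii, bjj = np.meshgrid(bi, bj, indexing="ij")

    suppressed = ref < crit.threshold_pct / 100.0 * ref_max
    if crit.local:
        suppressed |= ref <= 0
        denom = crit.dose_pct / 100.0 * ref
    else:
        denom = np.full_like(ref, crit.dose_pct / 100.0 * ref_max)
    active = ~suppressed
    r_dose = ref[active]
    r_denom = denom[active]
    r_i = bii[active]
    r_j = bjj[active]

    # search offsets sorted by radius
    max_off = int(np.floor(crit.search_radius_factor * crit.dta_mm / fine_spacing))
    oi, oj = np.meshgrid(np.arange(-max_off, max_off + 1), np.arange(-max_off, max_off + 1), indexing="ij")
    dist2_mm = (oi.ravel() ** 2 + oj.ravel() ** 2) * fine_spacing**2
    keep = dist2_mm <= (crit.search_radius_factor * crit.dta_mm) ** 2 + 1e-12
    order = np.argsort(dist2_mm[keep], kind="stable")
    offs_i = oi.ravel()[keep][order]
    offs_j = oj.ravel()[keep][order]
    dist_term = dist2_mm[keep][order] / crit.dta_mm**2

    g2 = np.full(r_dose.shape, np.inf)
    h, w = fine.shape
    for k in range(offs_i.size):
        dterm = dist_term[k]
        if dterm >= g2.max():
            break
        ii = r_i + offs_i[k]
        jj = r_j + offs_j[k]
        valid = (ii >= 0) & (ii < h) & (jj >= 0) & (jj < w)
        if not valid.any():
            continue
        de = fine[ii[valid], jj[valid]]
        cand = ((de - r_dose[valid]) / r_denom[valid]) ** 2 + dterm
        g2v = g2[valid]
        g2[valid] = np.minimum(g2v, cand)
    gamma = np.sqrt(g2)

    gamma_full = np.full(ref.shape, np.nan)
    gamma_full[active] = gamma
    evaluated_count = int(active.sum())
    passed_count = int((gamma <= 1.0 + 1e-12).sum())
    return GammaResult(gamma_full, evaluated_count, passed_count, crit)


def passing_rate(result: GammaResult) -> float:
    """Percentage of non-suppressed reference points with gamma <= 1."""
    return result.passing_rate_pct


def gamma_histogram(
    result: GammaResult, cap: float = 4.0, bins: int = 40
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of gamma values, truncated at ``cap``.

    Values above the cap are accumulated in the terminal bin.  Returns
    (counts, bin_edges); counts sum to the evaluated count.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    vals = result.gamma_values[np.isfinite(result.gamma_values)]
    edges = np.linspace(0.0, cap, bins + 1)
    counts, _ = np.histogram(np.minimum(vals, cap), bins=edges)
    return counts, edges
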
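"""Synthetic generation of training data for array super-resolution.

Real training data for the upsampling network would require Monte-Carlo dose
simulations of MLC-shaped photon fields.  This module provides a desk-scale
analytic surrogate that reproduces the *statistical recipe* of such a dataset:

1. random sampling of machine parameters (field-shape strategy, gantry /
   collimator / couch angles, monitor units, nominal energy, source-detector
   distance) from the stated mixture distributions;
2. rendering of each field as a stack of 2D dose slices: binary MLC-aperture
   fluence, rotated by the collimator angle and magnified by the
   detector-distance ratio, convolved with an energy-dependent Gaussian
   penumbra kernel plus a broad scatter tail, and multiplied by a smooth
   random phantom-heterogeneity modulation;
3. extraction of training pairs: a random high-resolution submatrix, one of
   the 8 square symmetries as augmentation, and the detector forward model
   (3x3 average pooling + noise + checkerboard masking) applied to obtain the
   low-resolution input.

Pairs carry the identifier of the simulation they came from so that the
train / validation split can be made on simulations, never on pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, stats

from .detector import ArrayMeasurement, ForwardModelConfig, build_layout, forward_model
from .grids import DoseGrid
from .symmetry import D4, d4_apply

__all__ = [
    "BeamSetup",
    "FieldShape",
    "PhantomModulation",
    "TrainingPair",
    "GenerationConfig",
    "scaled_profile",
    "sample_setup",
    "sample_strategy",
    "SimResult",
    "generate_field_shape",
    "make_phantom",
    "render_dose",
    "render_simulation",
    "extract_training_pairs",
    "split_dataset",
    "generate_dataset",
]

STRATEGIES = ("spot", "rectangular", "random")


@dataclass
class BeamSetup:
    """Machine parameters of one simulated irradiation."""

    energy_MV: float
    gantry_deg: float
    collimator_deg: float
    couch_deg: float
    mu: float
    ssd_mm: float = 800.0
    sdd_mm: float = 800.0


@dataclass
class FieldShape:
    """An MLC aperture: per-leaf edge positions plus jaw box, at isocenter scale.

    Leaf ``i`` projects to the y-interval
    ``[y0 + i * leaf_width_mm, y0 + (i+1) * leaf_width_mm]`` with
    ``y0 = -n_leaves * leaf_width_mm / 2``.  A closed leaf pair has
    ``left == right``.
    """

    leaf_width_mm: float
    left_bank: np.ndarray
    right_bank: np.ndarray
    jaw_x: tuple[float, float]
    jaw_y: tuple[float, float]
    strategy: str

    def __post_init__(self) -> None:
        self.left_bank = np.asarray(self.left_bank, dtype=float)
        self.right_bank = np.asarray(self.right_bank, dtype=float)
        if self.left_bank.shape != self.right_bank.shape:
            raise ValueError("leaf banks must have equal length")
        if np.any(self.left_bank > self.right_bank + 1e-9):
            raise ValueError("left bank must not exceed right bank")

    @property
    def n_leaves(self) -> int:
        return self.left_bank.size

    @property
    def y0_mm(self) -> float:
        return -self.n_leaves * self.leaf_width_mm / 2.0

    def aperture_bbox(self) -> tuple[float, float, float, float]:
        """(x_lo, x_hi, y_lo, y_hi) of the open aperture clipped by the jaws."""
        open_leaves = np.nonzero(self.right_bank > self.left_bank)[0]
        if open_leaves.size == 0:
            return (0.0, 0.0, 0.0, 0.0)
        x_lo = max(float(self.left_bank[open_leaves].min()), self.jaw_x[0])
        x_hi = min(float(self.right_bank[open_leaves].max()), self.jaw_x[1])
        y_lo = max(self.y0_mm + open_leaves[0] * self.leaf_width_mm, self.jaw_y[0])
        y_hi = min(
            self.y0_mm + (open_leaves[-1] + 1) * self.leaf_width_mm, self.jaw_y[1]
        )
        return (x_lo, x_hi, y_lo, y_hi)

    def contains(self, x: float, y: float) -> bool:
        """Brute-force point-in-aperture test (closed intervals)."""
        if not (self.jaw_x[0] <= x <= self.jaw_x[1]):
            return False
        if not (self.jaw_y[0] <= y <= self.jaw_y[1]):
            return False
        idx = int(math.floor((y - self.y0_mm) / self.leaf_width_mm))
        idx = min(max(idx, 0), self.n_leaves - 1)
        return bool(self.left_bank[idx] <= x <= self.right_bank[idx])


@dataclass
class PhantomModulation:
    """Smooth random map of relative electron density in [0.01, 20].

    The density field enters the dose surrogate only through a bounded
    multiplicative factor (see :func:`render_dose`), emulating the profile
    deformation that inhomogeneous buildup geometries imprint on a dose slice.
    """

    density_field: np.ndarray
    correlation_length_mm: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.density_field = np.asarray(self.density_field, dtype=float)
        if np.any(self.density_field < 0.01) or np.any(self.density_field > 20):
            raise ValueError("relative electron density must lie in [0.01, 20]")


@dataclass
class TrainingPair:
    """(masked low-res input, high-res target) with split provenance."""

    input: ArrayMeasurement
    target: DoseGrid
    sim_id: int
    augmentation: int = 0


@dataclass
class GenerationConfig:
    """All knobs of the data-generation recipe.

    Defaults encode the study recipe: field-shape strategy mixture
    67/22/11 (spot / rectangular / random), gantry 20% at 0 else uniform
    +-18 deg, collimator mixed over five equally likely branches, couch 90%
    at 0, MU uniform 50-150, nominal energy from a generalized-extreme-value
    law GEV(loc 7, scale 6, shape 0.1) truncated to ``energy_bounds``, SSD
    800 mm, SDD uniform 800-1200 mm with slices stepped by one pixel (5/3 mm)
    in depth, and a 330 mm maximum field size.
    """

    # field-shape strategies
    strategy_probs: tuple[float, float, float] = (0.67, 0.22, 0.11)
    max_field_mm: float = 330.0
    min_field_mm: float = 10.0
    leaf_width_mm: float = 5.0
    spot_points: tuple[int, int] = (3, 12)
    # angles
    gantry_zero_prob: float = 0.2
    gantry_span_deg: float = 18.0
    couch_zero_prob: float = 0.9
    collimator_sigma_deg: float = 11.25
    # beam
    mu_range: tuple[float, float] = (50.0, 150.0)
    energy_loc: float = 7.0
    energy_scale: float = 6.0
    energy_shape: float = 0.1
    energy_bounds: tuple[float, float] = (4.0, 25.0)
    ssd_mm: float = 800.0
    sdd_range_mm: tuple[float, float] = (800.0, 1200.0)
    gy_per_mu: float = 0.01
    # surrogate renderer
    penumbra_sigma_mm: tuple[float, float] = (2.0, 6.0)
    scatter_frac: float = 0.08
    scatter_sigma_mm: float = 15.0
    mod_strength: float = 0.3
    correlation_length_mm: float = 30.0
    angle_mod_strength: float = 0.05
    # geometry and dataset shape
    lowres_size: int = 53
    pool_kernel: int = 3
    render_size: int = 199
    noise_sigma_rel: float = 0.005
    n_sims: int = 16
    slices_per_sim: int = 8
    pairs_per_sim: int = 4
    val_fraction: float = 0.15

    def __post_init__(self) -> None:
        if abs(sum(self.strategy_probs) - 1.0) > 1e-9:
            raise ValueError("strategy_probs must sum to 1")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.render_size < self.target_size:
            raise ValueError("render_size must be >= target_size")

    @property
    def target_size(self) -> int:
        return self.lowres_size * self.pool_kernel

    @property
    def spacing_mm(self) -> float:
        """High-resolution pixel pitch: detector pitch / pooling kernel."""
        return 5.0 / self.pool_kernel * (self.grid_pitch_mm / 5.0)

    grid_pitch_mm: float = 5.0
    slice_step_mm: float = 5.0 / 3.0


def scaled_profile(n_sims: int = 200, pairs_per_sim: int = 4) -> GenerationConfig:
    """Reduced-geometry profile for CPU-scale runs: 27x27 input -> 81x81 target.

    Fields are confined to 90 mm so the smaller rendered area still covers
    them after magnification; everything else keeps the standard recipe.
    """
    return GenerationConfig(
        lowres_size=27,
        render_size=99,
        max_field_mm=90.0,
        correlation_length_mm=20.0,
        slices_per_sim=2,
        n_sims=n_sims,
        pairs_per_sim=pairs_per_sim,
    )


# --------------------------------------------------------------------------
# parameter sampling
# --------------------------------------------------------------------------


def _sample_gantry_like(rng: np.random.Generator, zero_prob: float, span: float) -> float:
    if rng.random() < zero_prob:
        return 0.0
    return float(rng.uniform(-span, span))


def _sample_collimator(rng: np.random.Generator, sigma: float) -> float:
    branch = rng.integers(5)
    if branch == 0:
        return float(rng.uniform(-180.0, 180.0))
    if branch == 1:
        return 0.0
    if branch == 2:
        return float(rng.choice([-90.0, 90.0, 180.0]))
    if branch == 3:
        return float(rng.choice([-135.0, -45.0, 45.0, 135.0]))
    center = rng.choice([-135.0, -90.0, -45.0, 0.0, 45.0, 90.0, 135.0, 180.0])
    return float(rng.normal(center, sigma))


_GEV_CACHE: dict = {}


def _gev(cfg: GenerationConfig):
    key = (cfg.energy_shape, cfg.energy_loc, cfg.energy_scale, cfg.energy_bounds)
    if key not in _GEV_CACHE:
        # scipy's shape parameter c is the negative of the usual GEV shape xi
        dist = stats.genextreme(
            c=-cfg.energy_shape, loc=cfg.energy_loc, scale=cfg.energy_scale
        )
        lo, hi = cfg.energy_bounds
        _GEV_CACHE[key] = (dist, float(dist.cdf(lo)), float(dist.cdf(hi)))
    return _GEV_CACHE[key]


def _sample_energy(cfg: GenerationConfig, rng: np.random.Generator) -> float:
    # truncation by inverse-CDF restriction to [F(lo), F(hi)]
    dist, c_lo, c_hi = _gev(cfg)
    u = rng.uniform(c_lo, c_hi)
    lo, hi = cfg.energy_bounds
    return float(np.clip(dist.ppf(u), lo, hi))


def sample_strategy(cfg: GenerationConfig, rng: np.random.Generator) -> str:
    """Draw a field-shape strategy from the configured mixture."""
    return STRATEGIES[int(rng.choice(3, p=cfg.strategy_probs))]


def sample_setup(cfg: GenerationConfig, rng: np.random.Generator) -> BeamSetup:
    """Draw one machine-parameter set from the configured distributions."""
    gantry = _sample_gantry_like(rng, cfg.gantry_zero_prob, cfg.gantry_span_deg)
    if rng.random() < cfg.couch_zero_prob:
        couch = 0.0
    else:
        couch = _sample_gantry_like(rng, cfg.gantry_zero_prob, cfg.gantry_span_deg)
    collimator = _sample_collimator(rng, cfg.collimator_sigma_deg)
    mu = float(rng.uniform(*cfg.mu_range))
    energy = _sample_energy(cfg, rng)
    # base SDD leaves room for the depth-stepped slice stack
    hi = cfg.sdd_range_mm[1] - (cfg.slices_per_sim - 1) * cfg.slice_step_mm
    sdd = float(rng.uniform(cfg.sdd_range_mm[0], max(hi, cfg.sdd_range_mm[0])))
    sdd = cfg.sdd_range_mm[0] + round((sdd - cfg.sdd_range_mm[0]) / cfg.slice_step_mm) * cfg.slice_step_mm
    return BeamSetup(
        energy_MV=energy,
        gantry_deg=gantry,
        collimator_deg=collimator,
        couch_deg=couch,
        mu=mu,
        ssd_mm=cfg.ssd_mm,
        sdd_mm=sdd,
    )


# --------------------------------------------------------------------------
# field shapes
# --------------------------------------------------------------------------


def generate_field_shape(
    strategy: str,
    rng: np.random.Generator,
    cfg: GenerationConfig | None = None,
    max_extent_mm: float | None = None,
) -> FieldShape:
    """Generate an MLC aperture with one of the three shape strategies.

    ``rectangular``: one random open rectangle (all open leaves share edges);
    ``spot``: random in-field points, each leaf row opened to the minimal
    interval covering its points; ``random``: independent per-leaf edges.
    All edges stay within ``max_extent_mm`` (default: the configured maximum
    field size) in both axes.
    """
    cfg = cfg or GenerationConfig()
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown field strategy {strategy!r}; known: {STRATEGIES}")
    half = (max_extent_mm if max_extent_mm is not None else cfg.max_field_mm) / 2.0
    w = cfg.leaf_width_mm
    n_leaves = max(2, int(math.ceil(2 * half / w)))
    y0 = -n_leaves * w / 2.0
    left = np.zeros(n_leaves)
    right = np.zeros(n_leaves)

    if strategy == "rectangular":
        wx = rng.uniform(cfg.min_field_mm, 2 * half)
        wy = rng.uniform(cfg.min_field_mm, 2 * half)
        cx = rng.uniform(-(half - wx / 2), half - wx / 2) if wx < 2 * half else 0.0
        cy = rng.uniform(-(half - wy / 2), half - wy / 2) if wy < 2 * half else 0.0
        x_lo, x_hi = cx - wx / 2, cx + wx / 2
        y_lo, y_hi = cy - wy / 2, cy + wy / 2
        for i in range(n_leaves):
            leaf_lo, leaf_hi = y0 + i * w, y0 + (i + 1) * w
            if leaf_hi > y_lo and leaf_lo < y_hi:
                left[i], right[i] = x_lo, x_hi
        jaw_x, jaw_y = (x_lo, x_hi), (y_lo, y_hi)
    elif strategy == "spot":
        k = int(rng.integers(cfg.spot_points[0], cfg.spot_points[1] + 1))
        pts = rng.uniform(-half, half, size=(k, 2))
        rows = np.clip(np.floor((pts[:, 1] - y0) / w).astype(int), 0, n_leaves - 1)
        for i in np.unique(rows):
            sel = pts[rows == i, 0]
            left[i], right[i] = sel.min(), sel.max()
        jaw_x = (float(pts[:, 0].min()), float(pts[:, 0].max()))
        jaw_y = (float(pts[:, 1].min()), float(pts[:, 1].max()))
    else:  # random
        a = rng.uniform(-half, half, size=n_leaves)
        b = rng.uniform(-half, half, size=n_leaves)
        left, right = np.minimum(a, b), np.maximum(a, b)
        # a random fraction of leaf pairs is parked closed
        closed = rng.random(n_leaves) < rng.uniform(0.0, 0.5)
        left[closed] = right[closed]
        jx = np.sort(rng.uniform(-half, half, size=2))
        jy = np.sort(rng.uniform(-half, half, size=2))
        jaw_x, jaw_y = (float(jx[0]), float(jx[1])), (float(jy[0]), float(jy[1]))

    return FieldShape(
        leaf_width_mm=w,
        left_bank=left,
        right_bank=right,
        jaw_x=jaw_x,
        jaw_y=jaw_y,
        strategy=strategy,
    )


# --------------------------------------------------------------------------
# surrogate dose renderer
# --------------------------------------------------------------------------


def make_phantom(
    shape: tuple[int, int],
    spacing_mm: float,
    correlation_length_mm: float,
    rng: np.random.Generator,
) -> PhantomModulation:
    """Smooth log-normal relative-electron-density map, clipped to [0.01, 20]."""
    z = rng.standard_normal(shape)
    z = ndimage.gaussian_filter(z, correlation_length_mm / spacing_mm, mode="reflect")
    sd = z.std()
    if sd > 0:
        z = z / sd
    density = np.clip(10.0 ** (1.1 * z), 0.01, 20.0)
    return PhantomModulation(density, correlation_length_mm)


def _penumbra_sigma_mm(cfg: GenerationConfig, energy_MV: float) -> float:
    lo, hi = cfg.penumbra_sigma_mm
    e_lo, e_hi = cfg.energy_bounds
    t = np.clip((energy_MV - e_lo) / max(e_hi - e_lo, 1e-9), 0.0, 1.0)
    return lo + (hi - lo) * float(t)


def render_dose(
    field: FieldShape,
    setup: BeamSetup,
    phantom: PhantomModulation | None = None,
    out_shape: tuple[int, int] = (159, 159),
    spacing_mm: float = 5.0 / 3.0,
    cfg: GenerationConfig | None = None,
) -> DoseGrid:
    """Render one 2D dose slice of an MLC-shaped field at the detector plane.

    The dose is ``MU-proportional amplitude x smoothed aperture fluence x
    smooth modulation``: the binary aperture (evaluated in the MLC plane after
    undoing collimator rotation and the SDD/SSD magnification) is convolved
    with a two-component Gaussian kernel — a narrow, energy-dependent
    penumbra core and a broad low-amplitude scatter tail — and multiplied by
    the phantom-heterogeneity factor and a small gantry/couch-dependent tilt.
    """
    cfg = cfg or GenerationConfig()
    mag = setup.sdd_mm / setup.ssd_mm
    n_rows, n_cols = out_shape
    extent_x = n_cols * spacing_mm
    extent_y = n_rows * spacing_mm
    bbox = field.aperture_bbox()
    if (bbox[1] - bbox[0]) * mag > extent_x + 1e-6 or (
        bbox[3] - bbox[2]
    ) * mag > extent_y + 1e-6:
        raise ValueError("aperture (after magnification) exceeds the rendered area")

    x = (np.arange(n_cols) - (n_cols - 1) / 2.0) * spacing_mm
    y = (np.arange(n_rows) - (n_rows - 1) / 2.0) * spacing_mm
    xx, yy = np.meshgrid(x, y)
    # detector-plane coords -> MLC-plane coords: demagnify, undo collimator
    theta = math.radians(setup.collimator_deg)
    xm = (np.cos(theta) * xx + np.sin(theta) * yy) / mag
    ym = (-np.sin(theta) * xx + np.cos(theta) * yy) / mag

    idx = np.clip(
        np.floor((ym - field.y0_mm) / field.leaf_width_mm).astype(int),
        0,
        field.n_leaves - 1,
    )
    # a closed leaf pair (left == right) transmits nothing; without the
    # strict-width condition a pixel center sitting exactly on the shared
    # edge coordinate would paint a spurious one-pixel line
    fluence = (
        (field.right_bank[idx] > field.left_bank[idx])
        & (xm >= field.left_bank[idx])
        & (xm <= field.right_bank[idx])
        & (xm >= field.jaw_x[0])
        & (xm <= field.jaw_x[1])
        & (ym >= field.jaw_y[0])
        & (ym <= field.jaw_y[1])
    ).astype(float)

    sigma_core = _penumbra_sigma_mm(cfg, setup.energy_MV) * mag / spacing_mm
    sigma_tail = cfg.scatter_sigma_mm * mag / spacing_mm
    core = ndimage.gaussian_filter(fluence, sigma_core, mode="constant")
    tail = ndimage.gaussian_filter(fluence, sigma_tail, mode="constant")
    dose = (1.0 - cfg.scatter_frac) * core + cfg.scatter_frac * tail
    dose *= setup.mu * cfg.gy_per_mu

    if phantom is not None:
        factor = np.clip(
            1.0 + cfg.mod_strength * np.tanh(np.log10(phantom.density_field)),
            1.0 - cfg.mod_strength,
            1.0 + cfg.mod_strength,
        )
        if factor.shape != dose.shape:
            zoom = (dose.shape[0] / factor.shape[0], dose.shape[1] / factor.shape[1])
            factor = ndimage.zoom(factor, zoom, order=1)
        dose *= factor
    if cfg.angle_mod_strength > 0 and (setup.gantry_deg != 0 or setup.couch_deg != 0):
        xn = xx / (extent_x / 2.0)
        yn = yy / (extent_y / 2.0)
        tilt = 1.0 + cfg.angle_mod_strength * (
            (setup.gantry_deg / cfg.gantry_span_deg) * xn
            + (setup.couch_deg / cfg.gantry_span_deg) * yn
        )
        dose *= np.clip(tilt, 0.0, None)

    return DoseGrid(np.clip(dose, 0.0, None), spacing_mm)


@dataclass
class SimResult:
    """One surrogate simulation: its parameters and depth-stepped slice stack."""

    sim_id: int
    setup: BeamSetup
    field: FieldShape
    slices: list[DoseGrid] = field(default_factory=list)


def render_simulation(
    cfg: GenerationConfig, rng: np.random.Generator, sim_id: int
) -> SimResult:
    """Sample parameters and render one stack of dose slices."""
    setup = sample_setup(cfg, rng)
    strategy = sample_strategy(cfg, rng)
    # confine the aperture so the deepest (most magnified) slice still fits
    mag_max = (setup.sdd_mm + (cfg.slices_per_sim - 1) * cfg.slice_step_mm) / cfg.ssd_mm
    extent = cfg.render_size * cfg.spacing_mm
    max_extent = min(cfg.max_field_mm, 0.95 * extent / mag_max)
    fieldshape = generate_field_shape(strategy, rng, cfg, max_extent_mm=max_extent)
    phantom = make_phantom(
        (cfg.render_size, cfg.render_size),
        cfg.spacing_mm,
        cfg.correlation_length_mm,
        rng,
    )
    slices = []
    for s in range(cfg.slices_per_sim):
        slice_setup = replace(setup, sdd_mm=setup.sdd_mm + s * cfg.slice_step_mm)
        slices.append(
            render_dose(
                fieldshape,
                slice_setup,
                phantom,
                out_shape=(cfg.render_size, cfg.render_size),
                spacing_mm=cfg.spacing_mm,
                cfg=cfg,
            )
        )
    return SimResult(sim_id=sim_id, setup=setup, field=fieldshape, slices=slices)


# --------------------------------------------------------------------------
# training-pair extraction and splitting
# --------------------------------------------------------------------------


def extract_training_pairs(
    slices: list[DoseGrid],
    cfg: GenerationConfig,
    rng: np.random.Generator,
    sim_id: int = 0,
) -> list[TrainingPair]:
    """Extract ``pairs_per_sim`` augmented training pairs from a slice stack.

    Each pair: a uniformly placed ``target_size``-square submatrix of a random
    slice, one of the 8 square symmetries applied, and the detector forward
    model (with the configured noise) as the low-resolution input.
    """
    t = cfg.target_size
    for s in slices:
        if s.values.shape[0] < t or s.values.shape[1] < t:
            raise ValueError(f"slice {s.values.shape} smaller than {t}x{t}")
    layout = build_layout(
        None, n_rows=cfg.lowres_size, n_cols=cfg.lowres_size, grid_pitch_mm=cfg.grid_pitch_mm
    )
    fm_cfg = ForwardModelConfig(
        pool_kernel=cfg.pool_kernel, noise_sigma_rel=cfg.noise_sigma_rel
    )
    pairs = []
    for _ in range(cfg.pairs_per_sim):
        s = slices[int(rng.integers(len(slices)))]
        i0 = int(rng.integers(s.values.shape[0] - t + 1))
        j0 = int(rng.integers(s.values.shape[1] - t + 1))
        g = int(rng.integers(8))
        sub = d4_apply(s.values[i0 : i0 + t, j0 : j0 + t], g)
        target = DoseGrid(np.ascontiguousarray(sub), cfg.spacing_mm)
        measurement = forward_model(target, layout, fm_cfg, rng=rng)
        pairs.append(
            TrainingPair(input=measurement, target=target, sim_id=sim_id, augmentation=g)
        )
    return pairs


def split_dataset(
    pairs: list[TrainingPair],
    val_fraction: float,
    rng: np.random.Generator,
) -> tuple[list[TrainingPair], list[TrainingPair]]:
    """Split pairs into train/validation with disjoint simulation identifiers.

    The number of validation simulations is ``round(val_fraction * n_sims)``;
    all pairs of a simulation land on the same side.
    """
    sim_ids = sorted({p.sim_id for p in pairs})
    if len(sim_ids) < 2:
        raise ValueError("need at least 2 distinct sim_ids to split")
    n_val = int(round(val_fraction * len(sim_ids)))
    order = list(rng.permutation(len(sim_ids)))
    val_ids = {sim_ids[i] for i in order[:n_val]}
    train = [p for p in pairs if p.sim_id not in val_ids]
    val = [p for p in pairs if p.sim_id in val_ids]
    return train, val


def generate_dataset(
    cfg: GenerationConfig, seed: int = 0
) -> tuple[list[TrainingPair], dict]:
    """Run the full recipe: ``n_sims`` simulations, pairs, and a manifest.

    All randomness flows from ``seed``; the result is bit-reproducible for a
    fixed (seed, config).
    """
    rng = np.random.default_rng(seed)
    pairs: list[TrainingPair] = []
    manifest: dict = {"seed": seed, "n_sims": cfg.n_sims, "pairs": []}
    for sim_id in range(cfg.n_sims):
        sim = render_simulation(cfg, rng, sim_id)
        new = extract_training_pairs(sim.slices, cfg, rng, sim_id=sim_id)
        for p in new:
            manifest["pairs"].append(
                {"sim_id": p.sim_id, "augmentation": p.augmentation,
                 "strategy": sim.field.strategy}
            )
        pairs.extend(new)
    return pairs, manifest
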
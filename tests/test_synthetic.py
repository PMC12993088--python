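"""Synthetic data generation: sampling distributions, renderer, pair extraction."""

import numpy as np
import pytest
from scipy import stats

from doseup import (
    BeamSetup,
    GenerationConfig,
    d4_apply,
    extract_training_pairs,
    generate_dataset,
    generate_field_shape,
    make_phantom,
    render_dose,
    render_simulation,
    sample_setup,
    sample_strategy,
    scaled_profile,
    split_dataset,
)
from doseup.synthetic import TrainingPair, _sample_energy


CFG = GenerationConfig()


def _binomial_band(p, n, k=3.0):
    sd = np.sqrt(p * (1 - p) / n)
    return p - k * sd, p + k * sd


# ---------------------------------------------------------------- sampling laws


def test_strategy_mixture_frequencies():
    rng = np.random.default_rng(11)
    n = 100_000
    draws = [sample_strategy(CFG, rng) for _ in range(n)]
    for name, p in zip(("spot", "rectangular", "random"), CFG.strategy_probs):
        lo, hi = _binomial_band(p, n)
        assert lo < draws.count(name) / n < hi


def test_machine_parameter_distributions():
    rng = np.random.default_rng(13)
    n = 30_000
    setups = [sample_setup(CFG, rng) for _ in range(n)]
    gantry = np.array([s.gantry_deg for s in setups])
    couch = np.array([s.couch_deg for s in setups])
    mu = np.array([s.mu for s in setups])
    energy = np.array([s.energy_MV for s in setups])
    sdd = np.array([s.sdd_mm for s in setups])

    lo, hi = _binomial_band(0.2, n)
    assert lo < (gantry == 0.0).mean() < hi
    nz = gantry[gantry != 0.0]
    assert -18.0 <= nz.min() and nz.max() <= 18.0
    # uniform part: mean ~ 0, sd ~ 18/sqrt(3)
    assert abs(nz.mean()) < 0.25
    assert abs(nz.std() - 18.0 / np.sqrt(3)) < 0.2

    # couch: 90% exactly zero, else the gantry procedure which itself
    # returns zero with probability 20% -> P(0) = 0.9 + 0.1 * 0.2 = 0.92
    lo, hi = _binomial_band(0.92, n)
    assert lo < (couch == 0.0).mean() < hi

    assert 50.0 <= mu.min() and mu.max() <= 150.0
    assert abs(mu.mean() - 100.0) < 0.5

    assert 4.0 <= energy.min() and energy.max() <= 25.0
    # mode of the truncated extreme-value law sits near the 7 MV location
    hist, edges = np.histogram(energy, bins=42, range=(4.0, 25.0))
    mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
    assert 5.0 < mode < 9.0

    assert 800.0 <= sdd.min() and sdd.max() <= 1200.0
    # detector distances snap to the depth-step raster
    steps = (sdd - 800.0) / CFG.slice_step_mm
    assert np.allclose(steps, np.round(steps), atol=1e-9)


def test_energy_respects_custom_bounds():
    cfg = GenerationConfig(energy_bounds=(6.0, 10.0))
    rng = np.random.default_rng(17)
    e = np.array([_sample_energy(cfg, rng) for _ in range(2000)])
    assert 6.0 <= e.min() and e.max() <= 10.0


def test_energy_matches_truncated_gev_quantiles():
    # empirical quantiles against the exact truncated distribution
    rng = np.random.default_rng(19)
    e = np.sort([_sample_energy(CFG, rng) for _ in range(20_000)])
    dist = stats.genextreme(c=-0.1, loc=7.0, scale=6.0)
    c_lo, c_hi = dist.cdf(4.0), dist.cdf(25.0)
    for q in (0.1, 0.25, 0.5, 0.75, 0.9):
        want = dist.ppf(c_lo + q * (c_hi - c_lo))
        got = e[int(q * len(e))]
        assert got == pytest.approx(want, abs=0.25)


def test_collimator_branch_structure():
    rng = np.random.default_rng(23)
    n = 30_000
    coll = np.array(
        [sample_setup(CFG, rng).collimator_deg for _ in range(n)]
    )
    # exact-zero branch: 1/5 plus the 1/8 * 1/5 chance of the discrete-normal
    # hitting its 0-center exactly is negligible; cardinal branch adds thirds
    lo, hi = _binomial_band(0.2, n)
    assert lo < (coll == 0.0).mean() < hi
    for v in (-90.0, 90.0, 180.0):
        lo, hi = _binomial_band(0.2 / 3, n)
        assert lo < (coll == v).mean() < hi
    for v in (-135.0, -45.0, 45.0, 135.0):
        lo, hi = _binomial_band(0.2 / 4, n)
        assert lo < (coll == v).mean() < hi


# ---------------------------------------------------------------- field shapes


def test_rectangular_field_is_a_rectangle():
    rng = np.random.default_rng(29)
    f = generate_field_shape("rectangular", rng, CFG)
    open_rows = f.right_bank > f.left_bank
    assert open_rows.any()
    assert np.unique(f.left_bank[open_rows]).size == 1
    assert np.unique(f.right_bank[open_rows]).size == 1


def test_spot_field_matches_point_construction_oracle():
    # replay the generator's draws and rebuild the aperture independently
    for seed in range(20):
        k = 5
        cfg = GenerationConfig(spot_points=(k, k))
        f = generate_field_shape("spot", np.random.default_rng(seed), cfg)
        r = np.random.default_rng(seed)
        assert int(r.integers(k, k + 1)) == k
        half = cfg.max_field_mm / 2.0
        pts = r.uniform(-half, half, size=(k, 2))
        # every sampled point lies inside the aperture
        for x, y in pts:
            assert f.contains(x, y)
        # jaws equal the point bounding box
        assert f.jaw_x == pytest.approx((pts[:, 0].min(), pts[:, 0].max()))
        assert f.jaw_y == pytest.approx((pts[:, 1].min(), pts[:, 1].max()))
        # each open leaf row spans exactly the min..max of its points
        rows = np.clip(np.floor((pts[:, 1] - f.y0_mm) / 5.0).astype(int),
                       0, f.n_leaves - 1)
        for i in np.unique(rows):
            sel = pts[rows == i, 0]
            assert f.left_bank[i] == pytest.approx(sel.min())
            assert f.right_bank[i] == pytest.approx(sel.max())


def test_spot_field_single_point_collapses_to_point():
    cfg = GenerationConfig(spot_points=(1, 1))
    rng = np.random.default_rng(37)
    f = generate_field_shape("spot", rng, cfg)
    x_lo, x_hi, y_lo, y_hi = f.aperture_bbox()
    assert x_lo == x_hi and y_lo == y_hi


def test_field_extent_respects_maximum():
    rng = np.random.default_rng(41)
    for strategy in ("spot", "rectangular", "random"):
        for _ in range(25):
            f = generate_field_shape(strategy, rng, CFG)
            x_lo, x_hi, y_lo, y_hi = f.aperture_bbox()
            assert -165.0 <= x_lo <= x_hi <= 165.0
            assert -165.0 <= y_lo <= y_hi <= 165.0


def test_contains_matches_bank_geometry():
    rng = np.random.default_rng(43)
    f = generate_field_shape("random", rng, CFG)
    probe = np.random.default_rng(47)
    for _ in range(200):
        x, y = probe.uniform(-170, 170, size=2)
        idx = int(np.floor((y - f.y0_mm) / f.leaf_width_mm))
        idx = min(max(idx, 0), f.n_leaves - 1)
        want = (
            f.jaw_x[0] <= x <= f.jaw_x[1]
            and f.jaw_y[0] <= y <= f.jaw_y[1]
            and f.left_bank[idx] <= x <= f.right_bank[idx]
        )
        assert f.contains(x, y) == want


def test_unknown_strategy_rejected():
    with pytest.raises(ValueError, match="unknown field strategy"):
        generate_field_shape("circle", np.random.default_rng(0), CFG)


def test_crossed_banks_rejected():
    from doseup import FieldShape

    with pytest.raises(ValueError, match="left bank"):
        FieldShape(5.0, [1.0, 0.0], [0.0, 1.0], (-10, 10), (-10, 10), "random")


# ---------------------------------------------------------------- renderer


def _square_field(side_mm):
    n = max(2, int(np.ceil(side_mm / 5.0)) + 4)
    left = np.zeros(n)
    right = np.zeros(n)
    y0 = -n * 5.0 / 2
    for i in range(n):
        leaf_lo, leaf_hi = y0 + i * 5.0, y0 + (i + 1) * 5.0
        if leaf_hi > -side_mm / 2 and leaf_lo < side_mm / 2:
            left[i], right[i] = -side_mm / 2, side_mm / 2
    from doseup import FieldShape

    return FieldShape(5.0, left, right, (-side_mm / 2, side_mm / 2),
                      (-side_mm / 2, side_mm / 2), "rectangular")


def _setup(**kw):
    base = dict(energy_MV=7.0, gantry_deg=0.0, collimator_deg=0.0,
                couch_deg=0.0, mu=100.0, ssd_mm=800.0, sdd_mm=800.0)
    base.update(kw)
    return BeamSetup(**base)


def test_closed_field_renders_zero():
    from doseup import FieldShape

    f = FieldShape(5.0, np.zeros(4), np.zeros(4), (-10, 10), (-10, 10), "random")
    d = render_dose(f, _setup(), out_shape=(51, 51))
    assert d.values.max() == 0.0


def test_dose_is_linear_in_monitor_units():
    f = _square_field(50.0)
    d1 = render_dose(f, _setup(mu=50.0), out_shape=(81, 81))
    d2 = render_dose(f, _setup(mu=100.0), out_shape=(81, 81))
    nz = d1.values > 1e-9
    assert np.allclose(d2.values[nz] / d1.values[nz], 2.0, atol=1e-9)


def test_central_axis_dose_scale():
    # broad open field: center dose ~ MU x 0.01 Gy/MU
    f = _square_field(100.0)
    d = render_dose(f, _setup(mu=100.0), out_shape=(121, 121))
    assert d.values[60, 60] == pytest.approx(1.0, rel=0.05)


def test_field_width_scales_with_magnification():
    # the 50% isodose width equals the aperture width times SDD/SSD
    f = _square_field(60.0)
    for sdd in (800.0, 1000.0, 1200.0):
        d = render_dose(f, _setup(sdd_mm=sdd), out_shape=(159, 159))
        profile = d.values[79]
        half = profile.max() / 2.0
        above = np.nonzero(profile >= half)[0]
        # linear interpolation at both crossings for sub-pixel width
        i0, i1 = above[0], above[-1]
        x = d.spacing_mm
        lo = i0 - (profile[i0] - half) / (profile[i0] - profile[i0 - 1])
        hi = i1 + (profile[i1] - half) / (profile[i1] - profile[i1 + 1])
        width = (hi - lo) * x
        # the discretized aperture includes both boundary pixel centers,
        # widening the rendered field by up to one pixel
        assert width == pytest.approx(60.0 * sdd / 800.0, abs=2 * x)


def test_collimator_rotation_rotates_the_field():
    # a 90-degree collimator rotation equals rotating the rendered image
    rngf = np.random.default_rng(53)
    f = generate_field_shape("random", rngf, CFG, max_extent_mm=80.0)
    d0 = render_dose(f, _setup(), out_shape=(81, 81))
    d90 = render_dose(f, _setup(collimator_deg=90.0), out_shape=(81, 81))
    diff0 = np.abs(d90.values - np.rot90(d0.values, k=1)).max()
    diff1 = np.abs(d90.values - np.rot90(d0.values, k=-1)).max()
    assert min(diff0, diff1) < 0.02 * d0.values.max()


def test_oversized_aperture_rejected():
    f = _square_field(300.0)
    with pytest.raises(ValueError, match="exceeds the rendered area"):
        render_dose(f, _setup(), out_shape=(81, 81))


def test_phantom_density_bounds():
    rng = np.random.default_rng(59)
    ph = make_phantom((99, 99), 5 / 3, 20.0, rng)
    assert ph.density_field.min() >= 0.01
    assert ph.density_field.max() <= 20.0


def test_phantom_modulation_is_bounded():
    rng = np.random.default_rng(61)
    f = _square_field(50.0)
    ph = make_phantom((81, 81), 5 / 3, 20.0, rng)
    plain = render_dose(f, _setup(), out_shape=(81, 81))
    mod = render_dose(f, _setup(), ph, out_shape=(81, 81))
    nz = plain.values > 1e-9
    ratio = mod.values[nz] / plain.values[nz]
    assert ratio.min() >= 0.7 - 1e-9
    assert ratio.max() <= 1.3 + 1e-9


# ---------------------------------------------------------------- pairs & split


def test_extract_pairs_forward_model_consistency():
    cfg = scaled_profile(n_sims=1, pairs_per_sim=3)
    cfg = GenerationConfig(**{**cfg.__dict__, "noise_sigma_rel": 0.0})
    rng = np.random.default_rng(67)
    sim = render_simulation(cfg, rng, 0)
    pairs = extract_training_pairs(sim.slices, cfg, rng, sim_id=0)
    assert len(pairs) == 3
    for p in pairs:
        assert p.target.shape == (81, 81)
        assert p.input.grid.values.shape == (27, 27)
        # noiseless: the input is exactly the masked pooled target
        pooled = p.target.values.reshape(27, 3, 27, 3).mean(axis=(1, 3))
        pooled[~p.input.layout.chamber_mask] = 0.0
        assert np.allclose(p.input.grid.values, pooled, atol=1e-12)


def test_extract_pairs_submatrix_of_some_slice():
    cfg = scaled_profile(n_sims=1, pairs_per_sim=4)
    cfg = GenerationConfig(**{**cfg.__dict__, "noise_sigma_rel": 0.0})
    rng = np.random.default_rng(71)
    sim = render_simulation(cfg, rng, 0)
    pairs = extract_training_pairs(sim.slices, cfg, rng, sim_id=0)
    t = cfg.target_size
    for p in pairs:
        # undo the recorded augmentation, then find the submatrix in a slice
        from doseup import d4_inverse

        sub = d4_apply(p.target.values, d4_inverse(p.augmentation))
        found = False
        for s in sim.slices:
            v = s.values
            for i0 in range(v.shape[0] - t + 1):
                hit = np.nonzero(
                    np.all(np.abs(v[i0 : i0 + 1, : t] - sub[:1, :t]) < 1e-12, axis=1)
                )[0]
                for j0 in range(v.shape[1] - t + 1):
                    if np.array_equal(v[i0 : i0 + t, j0 : j0 + t], sub):
                        found = True
                        break
                if found:
                    break
            if found:
                break
        assert found


def test_split_sizes_follow_rounded_fraction():
    def pairs_for(n_sims, per=4):
        from doseup import DoseGrid
        from doseup.detector import build_layout
        from doseup import ArrayMeasurement

        lay = build_layout(None, n_rows=3, n_cols=3, grid_pitch_mm=5.0)
        vals = np.zeros((3, 3))
        out = []
        for sid in range(n_sims):
            for _ in range(per):
                m = ArrayMeasurement(DoseGrid(vals.copy() + 0, 5.0), lay)
                out.append(TrainingPair(m, DoseGrid(np.ones((9, 9)), 5 / 3), sid))
        return out

    rng = np.random.default_rng(73)
    tr, va = split_dataset(pairs_for(20), 0.15, rng)
    assert len({p.sim_id for p in va}) == 3
    tr, va = split_dataset(pairs_for(320), 0.15, rng)
    assert len({p.sim_id for p in va}) == 48


def test_split_is_disjoint_on_simulations():
    cfg = scaled_profile(n_sims=8, pairs_per_sim=2)
    pairs, _ = generate_dataset(cfg, seed=79)
    rng = np.random.default_rng(79)
    tr, va = split_dataset(pairs, 0.25, rng)
    assert not ({p.sim_id for p in tr} & {p.sim_id for p in va})
    assert len(tr) + len(va) == len(pairs)


def test_split_needs_two_sims():
    lone = [TrainingPair.__new__(TrainingPair) for _ in range(2)]
    for p in lone:
        p.sim_id = 0
    with pytest.raises(ValueError, match="2 distinct sim_ids"):
        split_dataset(lone, 0.5, np.random.default_rng(0))


def test_generate_dataset_reproducible_and_manifested():
    cfg = scaled_profile(n_sims=3, pairs_per_sim=2)
    p1, m1 = generate_dataset(cfg, seed=5)
    p2, m2 = generate_dataset(cfg, seed=5)
    assert len(p1) == 6
    assert m1["pairs"] == m2["pairs"]
    for a, b in zip(p1, p2):
        assert np.array_equal(a.target.values, b.target.values)
        assert np.array_equal(a.input.grid.values, b.input.grid.values)
    strategies = {m["strategy"] for m in m1["pairs"]}
    assert strategies <= {"spot", "rectangular", "random"}


def test_invalid_config_rejected():
    with pytest.raises(ValueError, match="sum to 1"):
        GenerationConfig(strategy_probs=(0.5, 0.5, 0.5))
    with pytest.raises(ValueError, match="val_fraction"):
        GenerationConfig(val_fraction=0.0)
    with pytest.raises(ValueError, match="render_size"):
        GenerationConfig(render_size=100, lowres_size=53)
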
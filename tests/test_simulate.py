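import numpy as np
import pytest
from scipy import stats

from smtrack import (RodCellGeometry, SimulationParams, simulate_cell_scene,
                     simulate_stack, simulate_two_color)
from smtrack.simulate import defocus_correction_factor, render_gaussian


def noiseless(**kw):
    return SimulationParams(bg_mean=0.0, bg_std=0.0, **kw)


def test_intensity_conservation_without_bleaching():
    # with no noise and no bleaching every frame's total equals sum(n0)*isingle
    p = noiseless(num_spots=5, num_frames=4, diffusion_coeff=0.0,
                  max_stoichiometry=4, seed=1)
    stack, truth = simulate_stack(p)
    expected = truth.initial_stoichiometries.sum() * p.isingle
    for t in range(p.num_frames):
        assert stack.frames[t].sum() == pytest.approx(expected, rel=0.01)


def test_render_gaussian_integral_is_exact():
    frame = np.zeros((64, 64))
    render_gaussian(frame, 30.3, 28.8, 5000.0, 1.5)
    assert frame.sum() == pytest.approx(5000.0, rel=1e-6)


def test_bleaching_monotone_and_partial_fraction_bounds():
    p = SimulationParams(num_spots=8, num_frames=40, diffusion_coeff=0.0,
                         max_stoichiometry=6, p_bleach_per_frame=0.15, seed=3)
    _, truth = simulate_stack(p)
    for _, g in truth.table.groupby("spot_id"):
        n = g.sort_values("frame")["n_active"].to_numpy()
        assert np.all(np.diff(n) <= 0)
    # a dead focus (n_active 0, no partial) never reappears
    dead = truth.table[(truth.table.n_active == 0) & (truth.table.partial == 0)]
    assert dead.empty
    assert (truth.table.partial >= 0).all()
    # partial fraction from k simultaneous bleaches is < k
    assert (truth.table.partial < truth.table.groupby("spot_id")["n_active"]
            .transform("max") + 1).all()


def test_ensemble_exponential_bleach_decay():
    # active fluorophore count tracks n_total*(1-p)^t within 3-sigma binomial
    p = SimulationParams(num_spots=60, frame_size=(256, 256), num_frames=25,
                         diffusion_coeff=0.0, p_bleach_per_frame=0.1,
                         stoichiometries=[10] * 60, min_separation=5.0, seed=4)
    _, truth = simulate_stack(p)
    n_tot = 600
    by_frame = truth.table.groupby("frame")["n_active"].sum()
    for t in range(p.num_frames):
        mean = n_tot * (1 - 0.1) ** t
        sd = np.sqrt(n_tot * (1 - 0.1) ** t * (1 - (1 - 0.1) ** t) + 1e-9)
        assert abs(by_frame.get(t, 0) - mean) <= 3 * sd + 3


def test_step_length_distribution_matches_input_diffusion():
    p = noiseless(num_spots=100, frame_size=(512, 512), num_frames=101,
                  diffusion_coeff=1.0, isingle=1.0, min_separation=2.0,
                  edge_margin=120.0, seed=5)
    _, truth = simulate_stack(p)
    steps = []
    for _, g in truth.table.groupby("spot_id"):
        pos = g.sort_values("frame")[["x_true", "y_true"]].to_numpy() * p.pixel_size
        steps.append(np.diff(pos, axis=0))
    steps = np.vstack(steps)
    assert steps.size >= 2e4
    var_target = 2 * p.diffusion_coeff * p.frame_interval
    for axis in (0, 1):
        assert steps[:, axis].var() == pytest.approx(var_target, rel=0.05)
        assert stats.normaltest(steps[:, axis]).pvalue > 1e-3


def test_seeded_runs_are_bit_reproducible():
    p = SimulationParams(num_frames=3, max_stoichiometry=3,
                         p_bleach_per_frame=0.1, seed=99)
    s1, t1 = simulate_stack(p)
    s2, t2 = simulate_stack(p)
    np.testing.assert_array_equal(s1.frames, s2.frames)
    assert t1.table.equals(t2.table)


def test_explicit_positions_and_stoichiometries_are_honored():
    pos = [(20.0, 20.0), (40.0, 40.0)]
    p = noiseless(num_spots=2, num_frames=1, diffusion_coeff=0.0,
                  initial_positions=pos, stoichiometries=[2, 5], seed=0)
    stack, truth = simulate_stack(p)
    np.testing.assert_allclose(truth.positions(0), pos)
    assert stack.frames[0].sum() == pytest.approx(7 * p.isingle, rel=0.01)


def test_frame_too_small_rejected():
    with pytest.raises(ValueError):
        SimulationParams(frame_size=(4, 4)).validate()


def test_cell_scene_midplane_masked_intensity():
    # in-focus limit: masked integral recovers n*isingle once the (purely
    # lateral) mask-leak correction from the same model is applied
    geom = RodCellGeometry()
    p = noiseless(num_frames=1, seed=11)
    stack, mask, truth = simulate_cell_scene(150, geom, p, midplane_only=True)
    corr = defocus_correction_factor(geom, p, n_samples=3000, seed=2,
                                     midplane_only=True)
    masked = stack.frames[0][mask.labels == 1].sum()
    assert masked * corr == pytest.approx(150 * p.isingle, rel=0.02)
    assert (truth.table.n_active == 1).all()


def test_cell_scene_zero_emitters_is_background_only():
    geom = RodCellGeometry()
    p = SimulationParams(num_frames=1, seed=12)
    stack, mask, _ = simulate_cell_scene(0, geom, p)
    inside = stack.frames[0][mask.labels == 1]
    assert inside.mean() == pytest.approx(p.bg_mean, abs=4 * p.bg_std / np.sqrt(inside.size))


def test_cell_geometry_must_fit_frame():
    geom = RodCellGeometry(length_um=30.0)
    with pytest.raises(ValueError, match="fit"):
        simulate_cell_scene(1, geom, SimulationParams(num_frames=1, seed=0))


def test_defocus_correction_exceeds_one():
    corr = defocus_correction_factor(RodCellGeometry(), SimulationParams(),
                                     n_samples=500, seed=3)
    assert 1.0 < corr < 2.0


def test_two_color_shared_positions():
    p = SimulationParams(num_spots=6, num_frames=1, diffusion_coeff=0.0, seed=21)
    sl, sr, tl, tr, n_shared = simulate_two_color(p, p, colocalized_fraction=0.5)
    assert n_shared == 3
    np.testing.assert_allclose(tl.positions(0)[:3], tr.positions(0)[:3])
    # non-shared foci are apart by at least the layout separation
    d = np.hypot(*(tl.positions(0)[3:] - tr.positions(0)[3:]).T)
    assert (d >= p.min_separation).all()


def test_two_color_frame_geometry_must_match():
    a = SimulationParams(frame_size=(64, 64))
    b = SimulationParams(frame_size=(128, 128))
    with pytest.raises(ValueError, match="geometry"):
        simulate_two_color(a, b, 1.0)
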
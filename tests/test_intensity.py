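import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smtrack import (CellMask, Focus, ImageStack, SimulationParams, Trajectory,
                     chung_kennedy, copy_number, estimate_isingle,
                     simulate_stack, stoichiometry)
from smtrack.intensity import pool_intensities, stoichiometries


def traj_from_intensities(values, start_frame=0, traj_id=0):
    foci = [Focus(frame=start_frame + k, x=10.0, y=10.0, intensity=float(v),
                  width_x=1.3, width_y=1.3, snr=1.0)
            for k, v in enumerate(values)]
    return Trajectory(id=traj_id, foci=foci)


# Isingle ---------------------------------------------------------------------

def test_point_mass_sample_returns_that_value():
    est = estimate_isingle(np.full(50, 14_000.0))
    assert est.value == 14_000.0 and est.half_width == 0.0


def test_kde_peak_against_brute_force_oracle():
    # bimodal: n values at I, n/10 values at 2I -> peak near I
    rng = np.random.default_rng(0)
    sample = np.concatenate([rng.normal(10_000, 500, 200),
                             rng.normal(20_000, 500, 20)])
    est = estimate_isingle(sample, bandwidth=0.7)

    # independent oracle: direct sum of Gaussian kernels on a dense grid
    sigma = 0.7 * sample.std(ddof=1)
    grid = np.linspace(0, sample.max(), 5000)
    dens = np.exp(-0.5 * ((grid[:, None] - sample[None, :]) / sigma) ** 2).sum(axis=1)
    oracle_peak = grid[np.argmax(dens)]
    assert est.value == pytest.approx(oracle_peak, rel=0.02)
    assert abs(est.value - 10_000) < 3000  # dominated by the lower mode


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.floats(min_value=0.1, max_value=100.0))
def test_kde_peak_is_scale_equivariant(c):
    rng = np.random.default_rng(1)
    sample = rng.normal(5_000, 400, 80)
    base = estimate_isingle(sample).value
    scaled = estimate_isingle(c * sample).value
    assert scaled == pytest.approx(c * base, rel=0.01)


def test_too_few_values_rejected():
    with pytest.raises(ValueError):
        estimate_isingle(np.ones(5))


def test_pool_intensities_last_half_restriction():
    trajs = [traj_from_intensities([1.0] * 10, start_frame=0),
             traj_from_intensities([2.0] * 10, start_frame=90, traj_id=1)]
    allv = pool_intensities(trajs, num_frames=100)
    late = pool_intensities(trajs, num_frames=100, use_last_half=True)
    assert allv.size == 20 and late.size == 10
    assert (late == 2.0).all()


# stoichiometry ---------------------------------------------------------------

def test_linear_extrapolation_hand_example():
    # line through points 2-4 evaluated at the first frame
    t = traj_from_intensities([40_000, 30_000, 20_000, 10_000])
    r = stoichiometry(t, isingle=10_000)
    assert r.initial_intensity == pytest.approx(40_000)
    assert r.stoichiometry == pytest.approx(4.0)
    assert r.rounded == 4 and r.extrapolated


def test_constant_trace_at_isingle_is_one():
    r = stoichiometry(traj_from_intensities([10_000.0] * 6), isingle=10_000)
    assert r.stoichiometry == pytest.approx(1.0) and r.rounded == 1


def test_three_point_trajectory_fits_all_points():
    r = stoichiometry(traj_from_intensities([30_000, 20_000, 10_000]),
                      isingle=10_000)
    assert r.extrapolated
    assert r.initial_intensity == pytest.approx(30_000)


def test_short_trajectory_falls_back_to_first_intensity():
    r = stoichiometry(traj_from_intensities([25_000, 10_000]), isingle=10_000)
    assert not r.extrapolated
    assert r.initial_intensity == pytest.approx(25_000)


def test_stoichiometry_linearity_in_isingle():
    t = traj_from_intensities([40_000, 30_000, 20_000, 10_000])
    assert stoichiometry(t, 5_000).stoichiometry == pytest.approx(
        2 * stoichiometry(t, 10_000).stoichiometry)


def test_only_early_trajectories_get_stoichiometries():
    trajs = [traj_from_intensities([1e4] * 5, start_frame=0, traj_id=0),
             traj_from_intensities([1e4] * 5, start_frame=10, traj_id=1)]
    res = stoichiometries(trajs, isingle=1e4)
    assert [r.traj_id for r in res] == [0]


def test_invalid_isingle_rejected():
    with pytest.raises(ValueError):
        stoichiometry(traj_from_intensities([1.0] * 4), isingle=0.0)


# Chung-Kennedy ---------------------------------------------------------------

def test_ck_constant_trace_unchanged():
    x = np.full(20, 7.0)
    np.testing.assert_allclose(chung_kennedy(x, window=3), x)


def test_ck_ideal_step_passes_through_unchanged():
    x = np.array([1.0] * 10 + [5.0] * 10)
    np.testing.assert_allclose(chung_kennedy(x, window=4), x)


def test_ck_noisy_step_recovers_plateaus_without_overshoot():
    rng = np.random.default_rng(2)
    x = np.array([10.0] * 50 + [2.0] * 50) + rng.normal(0, 0.5, 100)
    y = chung_kennedy(x, window=8)
    assert y[10:40].mean() == pytest.approx(10.0, abs=0.3)
    assert y[60:90].mean() == pytest.approx(2.0, abs=0.3)
    # never overshoots beyond the plateau levels (up to the noise envelope)
    assert y.max() <= x[:50].max() + 1e-9
    assert y.min() >= x[50:].min() - 1e-9
    # step position preserved to +/- 1 frame
    cross = np.flatnonzero(y < 6.0)[0]
    assert abs(cross - 50) <= 1


def test_ck_window_validation():
    with pytest.raises(ValueError):
        chung_kennedy(np.ones(10), window=0)
    with pytest.raises(ValueError):
        chung_kennedy(np.ones(3), window=5)


# copy number -----------------------------------------------------------------

def test_copy_number_unbiased_on_in_focus_noiseless_scene():
    # emitters rendered in focus, mask covering the interior, correction 1
    p = SimulationParams(bg_mean=0.0, bg_std=0.0, num_spots=12, num_frames=1,
                         diffusion_coeff=0.0, edge_margin=25.0,
                         min_separation=4.0, seed=31)
    stack, _ = simulate_stack(p)
    labels = np.zeros(p.frame_size, dtype=np.int64)
    labels[12:116, 12:116] = 1
    counts = copy_number(stack, CellMask(labels), isingle=p.isingle)
    assert counts[1] == pytest.approx(12.0, rel=0.01)


def test_copy_number_empty_region_is_zero_within_noise():
    rng = np.random.default_rng(4)
    frames = np.round(np.clip(rng.normal(500, 120, (1, 64, 64)), 0, None))
    stack = ImageStack(frames, 0.12, 0.005)
    labels = np.zeros((64, 64), dtype=np.int64)
    labels[20:30, 20:30] = 1
    counts = copy_number(stack, CellMask(labels), isingle=10_000.0)
    assert abs(counts[1]) < 3 * 120 * np.sqrt(100) / 10_000.0


def test_copy_number_shape_mismatch_rejected():
    stack = ImageStack(np.zeros((1, 32, 32)), 0.12, 0.005)
    with pytest.raises(ValueError):
        copy_number(stack, CellMask(np.zeros((16, 16), dtype=np.int64)), 1.0)
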
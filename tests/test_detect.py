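import numpy as np
import pytest

from smtrack import (DetectionParams, SimulationParams, detect_frame,
                     find_candidates, gaussian_mask_localize, measure_focus,
                     simulate_stack)
from smtrack.simulate import render_gaussian

from conftest import render_spot


def test_constant_frame_has_no_candidates(default_detection):
    assert find_candidates(np.full((64, 64), 500.0), default_detection) == []


def test_default_simulation_yields_ten_seeds(default_frame, default_detection):
    frame, truth = default_frame
    seeds = find_candidates(frame, default_detection)
    assert len(seeds) == 10
    gt = truth.positions(0)
    for x, y in seeds:
        assert np.hypot(gt[:, 0] - x, gt[:, 1] - y).min() < 2.0


def test_merged_pair_gives_single_seed(default_detection):
    frame = np.full((64, 64), 500.0)
    render_gaussian(frame, 31.0, 32.0, 10_000.0, 1.33)
    render_gaussian(frame, 32.5, 32.0, 10_000.0, 1.33)  # separation 1.5 px
    seeds = find_candidates(frame, default_detection)
    assert len(seeds) == 1


def test_localization_of_noiseless_subpixel_center(default_detection):
    frame = render_spot(x0=30.30, y0=33.70)
    focus = gaussian_mask_localize(frame, (30, 34), default_detection)
    assert focus.converged
    assert focus.x == pytest.approx(30.30, abs=0.05)
    assert focus.y == pytest.approx(33.70, abs=0.05)


def test_localization_of_on_pixel_center_is_exact(default_detection):
    frame = render_spot(x0=32.0, y0=32.0)
    focus = gaussian_mask_localize(frame, (32, 32), default_detection)
    assert focus.x == pytest.approx(32.0, abs=1e-6)
    assert focus.y == pytest.approx(32.0, abs=1e-6)


def test_measured_widths_match_rendered_psf(default_detection):
    frame = render_spot(x0=32.0, y0=32.0, sigma=1.33)
    focus = gaussian_mask_localize(frame, (32, 32), default_detection)
    # second moments of a 5-px-truncated Gaussian sit slightly below sigma
    assert focus.width_x == pytest.approx(1.33, abs=0.15)
    assert focus.width_y == pytest.approx(1.33, abs=0.15)


def test_measure_flat_frame_is_zero(default_detection):
    intensity, snr, bg = measure_focus(np.full((64, 64), 700.0), (32.0, 32.0),
                                       default_detection)
    assert intensity == 0.0 and snr == 0.0 and bg == 700.0


def test_measure_recovers_integrated_brightness(default_detection):
    frame = render_spot(x0=32.25, y0=31.6, total=12_345.0, background=800.0)
    intensity, snr, bg = measure_focus(frame, (32.25, 31.6), default_detection)
    assert intensity == pytest.approx(12_345.0, rel=0.01)
    assert bg == pytest.approx(800.0, rel=0.01)


def test_measure_intensity_is_linear_in_brightness(default_detection):
    i1, _, _ = measure_focus(render_spot(total=8000.0), (32.0, 32.0),
                             default_detection)
    i2, _, _ = measure_focus(render_spot(total=16_000.0), (32.0, 32.0),
                             default_detection)
    assert i2 == pytest.approx(2 * i1, rel=0.01)


def test_detect_frame_finds_all_default_foci(default_frame, default_detection):
    frame, truth = default_frame
    foci = detect_frame(frame, default_detection)
    assert len(foci) == 10
    gt = truth.positions(0)
    errs = [np.hypot(gt[:, 0] - f.x, gt[:, 1] - f.y).min() for f in foci]
    assert max(errs) < 0.5
    assert all(f.snr >= default_detection.snr_filter_cutoff for f in foci)


def test_infinite_snr_cutoff_rejects_everything(default_frame):
    frame, _ = default_frame
    params = DetectionParams(snr_filter_cutoff=np.inf)
    assert detect_frame(frame, params) == []


def test_raising_snr_cutoff_never_adds_foci(default_frame):
    frame, _ = default_frame
    counts = [len(detect_frame(frame, DetectionParams(snr_filter_cutoff=c)))
              for c in (0.0, 0.4, 0.8, 1.2, 2.0)]
    assert counts == sorted(counts, reverse=True)


def test_translation_equivariance(default_frame, default_detection):
    frame, _ = default_frame
    shifted = np.roll(frame, (3, 5), axis=(0, 1))
    orig = sorted((f.x, f.y) for f in detect_frame(frame, default_detection))
    moved = sorted((f.x - 5, f.y - 3) for f in detect_frame(shifted, default_detection))
    np.testing.assert_allclose(np.asarray(orig), np.asarray(moved), atol=1e-9)


def test_background_only_frames_are_mostly_empty(default_detection):
    rng = np.random.default_rng(8)
    counts = [len(detect_frame(
        np.round(np.clip(rng.normal(500, 120, (128, 128)), 0, None)),
        default_detection)) for _ in range(10)]
    assert np.mean(counts) <= 1.0


def test_localization_errors_are_subpixel():
    # >95% of matched detections within 0.5 px of ground truth
    errs = []
    det = DetectionParams()
    for seed in (101, 102, 103):
        stack, truth = simulate_stack(SimulationParams(num_frames=3, seed=seed))
        for t in range(3):
            gt = truth.positions(t)
            for f in detect_frame(stack.frames[t], det, t):
                d = np.hypot(gt[:, 0] - f.x, gt[:, 1] - f.y).min()
                if d <= 2.0:
                    errs.append(d)
    errs = np.asarray(errs)
    assert errs.size >= 80
    assert np.mean(errs < 0.5) > 0.95


def test_seed_near_edge_is_discarded(default_detection):
    frame = np.full((64, 64), 500.0)
    render_gaussian(frame, 3.0, 30.0, 50_000.0, 1.33)  # inside the edge zone
    assert find_candidates(frame, default_detection) == []
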
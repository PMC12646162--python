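"""Extract a pipette-tip trajectory from a bright-field image stack.

Renders a moving Gaussian blob (the tip seen at low magnification) with
Poisson background noise, then recovers its sub-pixel centroid per frame.
"""

import numpy as np

from trichomech import synthio, track_centroid
from trichomech.trajectory import TrackedTrajectory

n = 60
t = np.arange(n) / 50.0
truth = TrackedTrajectory(t, 14.0 + 33.0 * t * 0.5, np.full(n, 32.0),
                          frame_rate=50.0)
stack = synthio.gen_blob_image_stack(truth, blob_sd_px=2.0,
                                     peak_intensity=400.0, background=20.0,
                                     pixel_size_um=1.0, seed=1)

traj = track_centroid(stack, pixel_size=1.0, frame_rate=50.0)
err = np.hypot(traj.x - truth.x, traj.y - truth.y)

print(f"frames tracked    : {len(traj)} ({traj.n_missing} missing)")
print(f"RMS tracking error: {np.sqrt(np.mean(err**2)):.4f} px")
print(f"first positions   : {traj.x[:3].round(3)} um (truth {truth.x[:3].round(3)})")
print()
print("Sub-0.1 px tracking error at this noise level means position noise")
print("of ~0.1 um at typical magnification - tens of nanonewtons once")
print("multiplied by a 0.1 uN/um spring constant.")
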
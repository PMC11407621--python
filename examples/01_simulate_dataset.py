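"""Generate a small synthetic lensless recording and inspect its ground truth.

The simulator renders point-source neurons at known positions and depths
onto a bare-sensor field of view, with spontaneous firing before the
stimulus and three assigned activity patterns after it.
"""

import numpy as np

from lensroi import SimulationConfig, simulate_dataset

# a reduced schedule (5 min pre + 15 min post at 10 fps) keeps this quick;
# drop the frame counts to get the full 45,000-frame design
config = SimulationConfig(n_pre_frames=3000, n_post_frames=9000, seed=1)
dataset = simulate_dataset(config)

print(f"frames: {dataset.frames.shape} at {config.fps} fps")
print(f"baseline segment: first {dataset.frames.n_baseline_frames} frames")
print(f"spike matrix: {dataset.spikes.shape}, total spikes {dataset.spikes.sum()}")
print("neurons (x, y, z_px, pattern):")
for n in dataset.neurons[:5]:
    print(f"  ({n.x_px:2d}, {n.y_px:3d}, {n.z_px}, {n.pattern})")
print(f"  ... {len(dataset.neurons)} total")

# deeper neurons spread their light over more pixels with a dimmer peak,
# so depth (z, in pixels; 7.5 um each) controls how detectable a source is
depths = [n.z_px for n in dataset.neurons]
print(f"depth range: {min(depths)}-{max(depths)} px "
      f"({min(depths) * config.pixel_pitch_um:.0f}-"
      f"{max(depths) * config.pixel_pitch_um:.0f} um from the sensor)")
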
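"""Local beating frequency and phase maps from a synthetic time-lapse.

Generates a 10 s, 30 fps recording of a culture beating at 120 bpm with a
linear phase lag of 1 degree of cycle per pixel and 10% noise, then
recovers block-wise frequency and phase maps by temporal peak detection.
"""

import numpy as np

from strainavoid import BeatingVideoSpec, beating_maps, generate_beating_video

spec = BeatingVideoSpec(
    frames=300, fps=30.0, frame_size=(64, 128),
    base_frequency=120.0, phase_gradient=1.0, noise_level=0.1, seed=1,
)
stack = generate_beating_video(spec)
maps = beating_maps(stack, fps=spec.fps)

print(f"valid blocks        : {int(maps.valid.sum())}/{maps.valid.size}")
print(f"median frequency    : {maps.median_frequency():.2f} Hz "
      f"(generator: {spec.base_frequency/60:.2f} Hz)")
_, cols = maps.block_centers()
slope = np.polyfit(cols, np.nanmean(maps.phase_deg, axis=0), 1)[0]
print(f"phase-lag slope     : {slope:.2f} deg/px (generator: {spec.phase_gradient} deg/px)")
print("phase increases along x: the wave of contraction travels across the field")
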
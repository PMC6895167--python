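"""Stream a scan through the double-buffer layer with dropped messages.

One projection image per message; a quarter of the messages are dropped.
Missing angles are zero-filled in the filtered buffer, so backprojection
simply ignores them — the slice survives with proportionally reduced
intensity.
"""

import numpy as np

import slicestream as ss

geom = ss.make_parallel_geometry(n_angles=48, det_rows=64, det_cols=64, pixel_size=1.0)
sphere = ss.Phantom([ss.Ellipsoid((0, 0, 0), (16, 16, 16), density=0.05)])
frames, flat, dark = ss.simulate_acquisition([sphere], geom)

messages, drop_log = ss.publish_frames(frames, drop_prob=0.25, seed=42)
completed, buffer = ss.assemble(messages, geom)
f = buffer.drop_count / geom.n_angles

plane = ss.axial_plane(0.0, n=48, voxel_size=1.0)
xs = np.arange(48) - 23.5
fov = np.hypot(xs[:, None], xs[None, :]) <= 23.5

with_drops = ss.backproject_slice(ss.preprocess_frame(completed[0], flat, dark), plane)
no_drops = ss.backproject_slice(ss.preprocess_frame(frames[0], flat, dark), plane)
ratio = with_drops.values[fov].mean() / no_drops.values[fov].mean()

print(f"messages sent {len(messages)}, dropped {buffer.drop_count} "
      f"(fraction f = {f:.3f})")
print(f"slice mean ratio with/without drops: {ratio:.4f}  (expected 1 - f = {1 - f:.4f})")
print("Dropped projections are effectively ignored; intensity scales by (1 - f).")
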
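"""Reconstruct an arbitrarily oriented slice from one simulated scan.

Builds a two-ellipsoid phantom, simulates a 180-degree parallel-beam
scan with flat/dark fields, runs the preprocessing chain (flat/dark,
negative log, ramp filter) and backprojects both an axial and a tilted
slice directly — no full volume is ever reconstructed.
"""

import numpy as np

import slicestream as ss

geom = ss.make_parallel_geometry(n_angles=96, det_rows=64, det_cols=96, pixel_size=1.0)
phantom = ss.Phantom(
    [
        ss.Ellipsoid(center=(5, -3, 0), semi_axes=(22, 16, 18), z_rotation=0.4, density=0.03),
        ss.Ellipsoid(center=(0, 4, 5), semi_axes=(8, 8, 8), density=0.02),
    ]
)

frames, flat, dark = ss.simulate_acquisition([phantom], geom)
filtered = ss.preprocess_frame(frames[0], flat, dark)

axial = ss.backproject_slice(filtered, ss.axial_plane(0.0, n=96, voxel_size=1.0))
tilted_plane = ss.SlicePlane(
    base=[0, 0, 0],
    u_dir=[1, 0, 0],
    v_dir=[0, np.cos(0.5), np.sin(0.5)],  # tilted 0.5 rad out of the axial plane
    n=96,
    voxel_size=1.0,
)
tilted = ss.backproject_slice(filtered, tilted_plane)

grid = ss.slice_grid(ss.axial_plane(0.0, 96, 1.0))
inner = np.hypot(grid[..., 0] - 8, grid[..., 1] + 6) < 4  # ellipsoid-1 core, clear of the sphere
recovered = axial.values[inner].mean()
print(f"axial slice:  mean over the first ellipsoid's core {recovered:.4f} "
      f"(true density 0.0300)")
print(f"tilted slice: {tilted.values.shape[0]}x{tilted.values.shape[1]} raster, "
      f"value range [{tilted.values.min():.4f}, {tilted.values.max():.4f}]")
print("Both slices cost n^2 * N_phi detector samples each — the full volume was never needed.")
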
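import numpy as np
import pytest

import slicestream as ss


@pytest.fixture()
def small_geom() -> ss.ScanGeometry:
    return ss.make_parallel_geometry(32, 32, 32, 1.0)


@pytest.fixture()
def sphere_phantom() -> ss.Phantom:
    return ss.Phantom([ss.Ellipsoid(center=(0, 0, 0), semi_axes=(10, 10, 10), density=1.0)])


@pytest.fixture()
def filtered_sphere(small_geom, sphere_phantom) -> ss.ProjectionFrame:
    sino = ss.analytic_sinogram(sphere_phantom, small_geom)
    return ss.ramp_filter(sino)


def _smooth_blob(cx: float, cy: float, rot: float, n_shells: int = 20) -> ss.Phantom:
    """Nested concentric shells approximating a smooth in-plane profile."""
    shells = []
    for i in range(n_shells):
        f = 1.0 - i / n_shells
        shells.append(
            ss.Ellipsoid(
                center=(cx, cy, 0.0),
                semi_axes=(14 * f, 10 * f, 1e4),
                z_rotation=rot,
                density=1.0 / n_shells,
            )
        )
    return ss.Phantom(shells)


@pytest.fixture()
def smooth_blob_factory():
    return _smooth_blob


# ---------------------------------------------------------------------------
# The standard wicking fixture: one seeded end-to-end run shared by the
# analysis and acceptance tests (the sequence is deterministic by contract).

WICKING_SEED = 3
WICKING_N_FRAMES = 15
WICKING_Z_BOTTOM = -40.0
WICKING_Z_TOP = 40.0


@pytest.fixture(scope="session")
def wicking_run():
    geom = ss.make_parallel_geometry(60, 72, 96, 2.5)
    params = ss.WickingParams(seed=WICKING_SEED)
    phantoms, heights = ss.make_wicking_sequence(params, WICKING_N_FRAMES)
    frames, flat, dark = ss.simulate_acquisition(phantoms, geom)
    planes = [
        ss.axial_plane(WICKING_Z_BOTTOM, 72, 2.5),
        ss.axial_plane(WICKING_Z_TOP, 72, 2.5),
    ]
    config = ss.PipelineConfig(
        geometry=geom,
        planes=planes,
        preview_shape=(16, 16, 16),
        preview_bin=4,
        bottom_plane=0,
        top_plane=1,
    )
    artifacts = ss.run_live(config, frames, flat=flat, dark=dark)
    return {
        "geom": geom,
        "params": params,
        "phantoms": phantoms,
        "heights": heights,
        "frames": frames,
        "flat": flat,
        "dark": dark,
        "config": config,
        "artifacts": artifacts,
    }
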
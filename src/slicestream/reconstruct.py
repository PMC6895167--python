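"""Voxel-driven backprojection onto arbitrary slice planes.

Restricting FBP to a slice: because the parallel-beam system matrix has
only N_φ nonzeros per column, the reconstructed value of any single
voxel is a weighted sum of N_φ filtered detector samples.  A whole
n × n oblique slice therefore costs Θ(n²·N_φ) interpolation samples —
independent of the full volume size — which is what makes on-demand
slice reconstruction real-time.

Sampling is bilinear on the detector with zero contribution outside it;
the continuous backprojection integral over [0, π) is discretised with
the global scale π/N_φ.  The angle loop always runs in ascending order
so results are deterministic run to run.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import map_coordinates

from .frames import FrameState, ProjectionFrame
from .geometry import ScanGeometry, SlicePlane, project_point, slice_grid

__all__ = [
    "SliceImage",
    "VolumeImage",
    "backproject_slice",
    "fbp_volume",
    "reconstruct_preview",
    "partition_backproject",
    "reset_sample_count",
    "sample_count",
]

# Instrumented count of detector interpolation samples, for verifying the
# Θ(n²·N_φ) locality of slice-restricted backprojection.
_SAMPLE_COUNT = 0


def reset_sample_count() -> None:
    global _SAMPLE_COUNT
    _SAMPLE_COUNT = 0


def sample_count() -> int:
    return _SAMPLE_COUNT


@dataclasses.dataclass
class SliceImage:
    """n×n reconstructed slice with its plane and source-frame tag."""

    values: np.ndarray
    plane: SlicePlane
    frame_id: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.plane.n, self.plane.n):
            raise ValueError(
                f"slice raster {self.values.shape} does not match plane n={self.plane.n}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("slice values must be finite")


@dataclasses.dataclass
class VolumeImage:
    """Reconstructed volume on a grid centred on the world origin."""

    values: np.ndarray
    voxel_size: float
    frame_id: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("volume must be 3-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")


def _accumulate(frame: ProjectionFrame, points: np.ndarray, angle_indices) -> np.ndarray:
    """Unscaled backprojection sum over the given angles at world points.

    ``points`` has shape ``(M, 3)``; returns shape ``(M,)``.  One bilinear
    detector sample per (point, angle); off-detector samples contribute 0.
    """
    global _SAMPLE_COUNT
    geom = frame.geometry
    acc = np.zeros(points.shape[0])
    for k in angle_indices:  # ascending, fixed order: deterministic sums
        coord = project_point(geom, int(k), points)
        acc += map_coordinates(
            frame.data[k],
            np.stack([coord.r, coord.u]),
            order=1,
            mode="constant",
            cval=0.0,
        )
        _SAMPLE_COUNT += points.shape[0]
    return acc


def backproject_slice(frame: ProjectionFrame, plane: SlicePlane) -> SliceImage:
    """Reconstruct one arbitrarily oriented slice from a filtered frame.

    value(i,j) = (π/N_φ) · Σ_k bilinear(frame[k], projection of grid point)
    """
    frame.require_state(FrameState.FILTERED)
    pts = slice_grid(plane).reshape(-1, 3)
    acc = _accumulate(frame, pts, range(frame.geometry.n_angles))
    values = (np.pi / frame.geometry.n_angles) * acc.reshape(plane.n, plane.n)
    return SliceImage(values=values, plane=plane, frame_id=frame.frame_id)


def fbp_volume(
    frame: ProjectionFrame, shape: tuple[int, int, int], voxel_size: float
) -> VolumeImage:
    """Full-grid FBP with the identical sampling rule as backproject_slice.

    This is the reference against which slice restriction is validated;
    it costs Θ(N³·N_φ) and is never needed in the live path.
    """
    frame.require_state(FrameState.FILTERED)
    if any(s < 1 for s in shape):
        raise ValueError(f"shape must be positive, got {shape}")
    nx, ny, nz = shape
    xs = (np.arange(nx) - (nx - 1) / 2.0) * voxel_size
    ys = (np.arange(ny) - (ny - 1) / 2.0) * voxel_size
    zs = (np.arange(nz) - (nz - 1) / 2.0) * voxel_size
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    acc = _accumulate(frame, pts, range(frame.geometry.n_angles))
    values = (np.pi / frame.geometry.n_angles) * acc.reshape(shape)
    return VolumeImage(values=values, voxel_size=voxel_size, frame_id=frame.frame_id)


def _binned_geometry(geom: ScanGeometry, bin_factor: int) -> ScanGeometry:
    """Geometry of the mean-binned detector, keeping world coordinates fixed.

    The binned centre and centre-of-rotation offset are re-derived so that
    a world point projects to consistent coordinates on both rasters.
    """
    rb, cb = geom.det_rows // bin_factor, geom.det_cols // bin_factor
    # original continuous column u maps to binned column (u - (b-1)/2)/b
    b = bin_factor
    cor_b = (geom.det_center_col + geom.cor_offset - (b - 1) / 2.0) / b - (cb - 1) / 2.0
    return ScanGeometry(
        n_angles=geom.n_angles,
        angles=geom.angles,
        det_rows=rb,
        det_cols=cb,
        pixel_size=geom.pixel_size * b,
        cor_offset=cor_b,
    )


def reconstruct_preview(
    frame: ProjectionFrame, shape: tuple[int, int, int], bin_factor: int = 1
) -> VolumeImage:
    """Low-resolution 3D preview: mean-bin the detector, then coarse FBP.

    The preview is recomputed whenever a data frame completes; it guides
    slice placement and is never the quantitative product.
    """
    frame.require_state(FrameState.FILTERED)
    if bin_factor < 1:
        raise ValueError("bin_factor must be >= 1")
    geom = frame.geometry
    if bin_factor > min(geom.det_rows, geom.det_cols):
        raise ValueError(
            f"bin_factor {bin_factor} exceeds detector {geom.det_rows}x{geom.det_cols}"
        )
    if bin_factor == 1:
        return fbp_volume(frame, shape, geom.pixel_size)
    b = bin_factor
    rb, cb = geom.det_rows // b, geom.det_cols // b
    cropped = frame.data[:, : rb * b, : cb * b]
    binned = cropped.reshape(geom.n_angles, rb, b, cb, b).mean(axis=(2, 4))
    bgeom = _binned_geometry(geom, b)
    bframe = ProjectionFrame(
        data=binned, state=FrameState.FILTERED, geometry=bgeom, frame_id=frame.frame_id
    )
    # field of view of the coarse grid matches the binned detector raster
    voxel = bgeom.pixel_size * min(cb / shape[0], cb / shape[1], rb / shape[2])
    return fbp_volume(bframe, shape, voxel)


def partition_backproject(
    frame: ProjectionFrame, plane: SlicePlane, n_parts: int
) -> SliceImage:
    """Backproject in contiguous angle groups and sum the partial slices.

    This is the distributed form: each group's unscaled sum could live on
    its own device; linearity of backprojection makes the summed result
    identical (up to summation order) to the monolithic one.  The π/N_φ
    scale is applied once, after the partials are combined.
    """
    frame.require_state(FrameState.FILTERED)
    n_phi = frame.geometry.n_angles
    if not 1 <= n_parts <= n_phi:
        raise ValueError(f"n_parts must lie in [1, {n_phi}], got {n_parts}")
    pts = slice_grid(plane).reshape(-1, 3)
    groups = np.array_split(np.arange(n_phi), n_parts)
    total = np.zeros(pts.shape[0])
    for group in groups:
        if group.size == 0:
            continue  # an empty group contributes an all-zero partial
        total += _accumulate(frame, pts, group)
    values = (np.pi / n_phi) * total.reshape(plane.n, plane.n)
    return SliceImage(values=values, plane=plane, frame_id=frame.frame_id)
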
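"""Parallel-beam scan geometry and arbitrarily oriented slice planes.

Coordinate conventions used throughout the package:

* The world origin sits on the rotation axis at detector mid-height.
  Lengths are physical units (the unit of ``pixel_size``, typically µm).
* Detector indices are 0-based.  A continuous detector coordinate ``q``
  maps to pixel index by round-half-even; pixel ``i`` spans
  ``[i - 0.5, i + 0.5)``.
* Projection angles cover a 180° scan, uniform over ``[0, π)``.
* ``cor_offset`` is the signed horizontal shift, in detector pixels, of
  the rotation-axis image on the detector.  It is a pure translation
  (no axis tilt).

For angle θ and world point ``p = (x, y, z)`` the parallel ray hits the
detector at continuous coordinates::

    u = (-x sinθ + y cosθ) / pixel_size + (det_cols - 1)/2 + cor_offset
    r =  z / pixel_size + (det_rows - 1)/2
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ScanGeometry",
    "SlicePlane",
    "DetectorCoord",
    "make_parallel_geometry",
    "project_point",
    "slice_grid",
    "save_geometry",
    "load_geometry",
    "axial_plane",
]

#: orthonormality slack below which plane axes are silently re-normalised;
#: above it the plane is rejected.
_ORTHO_TOL = 1e-6


@dataclasses.dataclass(frozen=True)
class ScanGeometry:
    """Description of a parallel-beam circular scan.

    Attributes
    ----------
    n_angles : int
        Number of projection angles N_φ.
    angles : np.ndarray
        Strictly increasing angles in radians, all in ``[0, π)``.
    det_rows, det_cols : int
        Detector raster (rows = vertical, cols = horizontal).
    pixel_size : float
        Physical size of a detector pixel (length/pixel).
    cor_offset : float
        Horizontal shift of the rotation-axis image on the detector,
        in pixels (signed).
    """

    n_angles: int
    angles: np.ndarray
    det_rows: int
    det_cols: int
    pixel_size: float
    cor_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.n_angles < 1:
            raise ValueError(f"n_angles must be >= 1, got {self.n_angles}")
        if self.det_rows < 1 or self.det_cols < 1:
            raise ValueError(
                f"detector raster must be >= 1x1, got {self.det_rows}x{self.det_cols}"
            )
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        angles = np.asarray(self.angles, dtype=float)
        object.__setattr__(self, "angles", angles)
        if angles.shape != (self.n_angles,):
            raise ValueError("angles length must equal n_angles")
        if np.any(angles < 0) or np.any(angles >= np.pi):
            raise ValueError("angles must lie in [0, pi)")
        if self.n_angles > 1 and np.any(np.diff(angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if not np.isfinite(self.cor_offset):
            raise ValueError("cor_offset must be finite")

    @property
    def det_center_col(self) -> float:
        return (self.det_cols - 1) / 2.0

    @property
    def det_center_row(self) -> float:
        return (self.det_rows - 1) / 2.0


@dataclasses.dataclass(frozen=True)
class DetectorCoord:
    """Continuous detector coordinates (pixels).

    ``u`` is the column coordinate, ``r`` the row coordinate.  Values may
    lie off the physical detector; the interpolation policy of the
    backprojector decides what off-detector samples contribute.
    """

    u: np.ndarray | float
    r: np.ndarray | float

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.r))):
            raise ValueError("detector coordinates must be finite")


@dataclasses.dataclass(frozen=True)
class SlicePlane:
    """An arbitrarily oriented square reconstruction plane.

    The plane is spanned by the orthonormal in-plane axes ``u_dir`` and
    ``v_dir`` and centred on ``base``; it carries an ``n`` × ``n`` voxel
    grid with spacing ``voxel_size``.  The slice raster is fixed per
    session regardless of orientation.
    """

    base: np.ndarray
    u_dir: np.ndarray
    v_dir: np.ndarray
    n: int
    voxel_size: float

    def __post_init__(self) -> None:
        base = np.asarray(self.base, dtype=float).reshape(3)
        u = np.asarray(self.u_dir, dtype=float).reshape(3)
        v = np.asarray(self.v_dir, dtype=float).reshape(3)
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if abs(nu - 1.0) > _ORTHO_TOL or abs(nv - 1.0) > _ORTHO_TOL:
            raise ValueError(
                f"plane axes must be unit vectors (|u|={nu:.3g}, |v|={nv:.3g})"
            )
        u = u / nu
        v = v / nv
        dot = float(u @ v)
        if abs(dot) > _ORTHO_TOL:
            raise ValueError(f"plane axes must be orthogonal (u.v={dot:.3g})")
        # Gram-Schmidt clean-up of sub-tolerance error.
        v = v - dot * u
        v = v / np.linalg.norm(v)
        object.__setattr__(self, "base", base)
        object.__setattr__(self, "u_dir", u)
        object.__setattr__(self, "v_dir", v)
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.u_dir, self.v_dir)


def make_parallel_geometry(
    n_angles: int,
    det_rows: int,
    det_cols: int,
    pixel_size: float,
    cor_offset: float = 0.0,
) -> ScanGeometry:
    """Uniform 180° parallel-beam geometry with ``angles[k] = k·π/n_angles``."""
    if n_angles < 1 or det_rows < 1 or det_cols < 1:
        raise ValueError("counts must be positive")
    if not pixel_size > 0:
        raise ValueError("pixel_size must be positive")
    angles = np.arange(n_angles, dtype=float) * (np.pi / n_angles)
    return ScanGeometry(
        n_angles=n_angles,
        angles=angles,
        det_rows=det_rows,
        det_cols=det_cols,
        pixel_size=float(pixel_size),
        cor_offset=float(cor_offset),
    )


def project_point(
    geom: ScanGeometry, angle_index: int, p: np.ndarray
) -> DetectorCoord:
    """Project world point(s) onto the detector for one scan angle.

    ``p`` may be a single 3-vector or an ``(..., 3)`` array; ``u``/``r``
    then carry the leading shape.
    """
    if not 0 <= angle_index < geom.n_angles:
        raise IndexError(
            f"angle_index {angle_index} out of range [0, {geom.n_angles})"
        )
    p = np.asarray(p, dtype=float)
    theta = geom.angles[angle_index]
    x, y, z = p[..., 0], p[..., 1], p[..., 2]
    u = (-x * np.sin(theta) + y * np.cos(theta)) / geom.pixel_size
    u = u + geom.det_center_col + geom.cor_offset
    r = z / geom.pixel_size + geom.det_center_row
    return DetectorCoord(u=u, r=r)


def slice_grid(plane: SlicePlane) -> np.ndarray:
    """World coordinates of the plane's voxel centres, shape ``(n, n, 3)``.

    ``grid[i, j] = base + (i-(n-1)/2)·vs·u_dir + (j-(n-1)/2)·vs·v_dir``,
    centred on ``base`` (for odd ``n`` the centre point equals ``base``).
    """
    n = plane.n
    offs = (np.arange(n) - (n - 1) / 2.0) * plane.voxel_size
    grid = (
        plane.base[None, None, :]
        + offs[:, None, None] * plane.u_dir[None, None, :]
        + offs[None, :, None] * plane.v_dir[None, None, :]
    )
    return grid


def axial_plane(z: float, n: int, voxel_size: float) -> SlicePlane:
    """Horizontal slice plane at height ``z`` (convenience constructor)."""
    return SlicePlane(
        base=np.array([0.0, 0.0, z]),
        u_dir=np.array([1.0, 0.0, 0.0]),
        v_dir=np.array([0.0, 1.0, 0.0]),
        n=n,
        voxel_size=voxel_size,
    )


# -- serialisation ----------------------------------------------------------
# Flat YAML config: n_angles, det_rows, det_cols, pixel_size_um, cor_offset_px.

def save_geometry(geom: ScanGeometry, path: str | Path) -> None:
    doc = {
        "n_angles": int(geom.n_angles),
        "det_rows": int(geom.det_rows),
        "det_cols": int(geom.det_cols),
        "pixel_size_um": float(geom.pixel_size),
        "cor_offset_px": float(geom.cor_offset),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_geometry(path: str | Path) -> ScanGeometry:
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    return make_parallel_geometry(
        n_angles=int(doc["n_angles"]),
        det_rows=int(doc["det_rows"]),
        det_cols=int(doc["det_cols"]),
        pixel_size=float(doc["pixel_size_um"]),
        cor_offset=float(doc.get("cor_offset_px", 0.0)),
    )


def plane_to_dict(plane: SlicePlane) -> dict:
    """JSON-serialisable description of a slice plane (sidecar records)."""
    return {
        "base": [float(c) for c in plane.base],
        "u_dir": [float(c) for c in plane.u_dir],
        "v_dir": [float(c) for c in plane.v_dir],
        "n": int(plane.n),
        "voxel_size": float(plane.voxel_size),
    }


def plane_from_dict(doc: dict) -> SlicePlane:
    return SlicePlane(
        base=np.asarray(doc["base"], dtype=float),
        u_dir=np.asarray(doc["u_dir"], dtype=float),
        v_dir=np.asarray(doc["v_dir"], dtype=float),
        n=int(doc["n"]),
        voxel_size=float(doc["voxel_size"]),
    )


def parse_plane_spec(spec: str, n: int, voxel_size: float) -> SlicePlane:
    """Parse a ``"bx,by,bz;ux,uy,uz;vx,vy,vz"`` command-line plane spec."""
    try:
        parts = [
            np.array([float(c) for c in chunk.split(",")]) for chunk in spec.split(";")
        ]
        base, u, v = parts
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise ValueError(f"cannot parse plane spec {spec!r}") from exc
    return SlicePlane(base=base, u_dir=u, v_dir=v, n=n, voxel_size=voxel_size)
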
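"""Synthetic phantoms with closed-form parallel-beam sinograms.

Everything here exists so the reconstruction chain can be validated
against analytic ground truth:

* ellipsoid phantoms whose line integrals have a closed form (the root
  gap of a quadratic), giving exact sinograms for any scan geometry;
* a dynamic "wicking" sequence that emulates water rising through the
  pore space of a vertical fibre bundle (a spun yarn imaged end-on),
  with a seeded per-pore fill jitter and recorded front heights;
* acquisition simulation (flat/dark fields, Beer-Lambert attenuation,
  optional seeded Poisson noise) and the sequence-mode timing
  arithmetic of a hardware-triggered scan series.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .frames import FrameState, ProjectionFrame
from .geometry import ScanGeometry

__all__ = [
    "Ellipsoid",
    "Phantom",
    "WickingParams",
    "TimingRecord",
    "analytic_sinogram",
    "voxelize",
    "make_wicking_sequence",
    "simulate_acquisition",
    "scan_timing",
]


@dataclasses.dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid, optionally rotated about z, with additive density.

    ``density`` is attenuation per unit length; negative values are legal
    (nested contrast is built by stacking ellipsoids additively).
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    z_rotation: float = 0.0
    density: float = 1.0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError(f"semi_axes must be positive, got {self.semi_axes}")
        if not math.isfinite(self.density):
            raise ValueError("density must be finite")


@dataclasses.dataclass(frozen=True)
class Phantom:
    """Ordered list of ellipsoids; densities add where they overlap."""

    ellipsoids: tuple[Ellipsoid, ...] = ()

    def __init__(self, ellipsoids=()):
        object.__setattr__(self, "ellipsoids", tuple(ellipsoids))

    def __add__(self, other: "Phantom") -> "Phantom":
        return Phantom(self.ellipsoids + other.ellipsoids)


def _rotate_xy(x, y, angle):
    """Rotate (x, y) by ``angle`` about z (counter-clockwise)."""
    c, s = math.cos(angle), math.sin(angle)
    return c * x - s * y, s * x + c * y


def analytic_sinogram(phantom: Phantom, geom: ScanGeometry) -> ProjectionFrame:
    """Exact line-integral frame of a phantom: the reconstruction oracle.

    For every angle and detector pixel centre, the parallel ray is
    intersected with each ellipsoid; the chord length is the gap between
    the real roots of the resulting quadratic, and densities weight the
    chords additively.  Returned frame is in the ``line_integral`` state.
    """
    rows = np.arange(geom.det_rows, dtype=float)
    cols = np.arange(geom.det_cols, dtype=float)
    # world offsets of the ray through each detector pixel centre
    q = (cols - geom.det_center_col - geom.cor_offset) * geom.pixel_size  # (C,)
    z = (rows - geom.det_center_row) * geom.pixel_size  # (R,)

    data = np.zeros((geom.n_angles, geom.det_rows, geom.det_cols))
    for k, theta in enumerate(geom.angles):
        st, ct = math.sin(theta), math.cos(theta)
        # ray origin: q·(-sinθ, cosθ, 0) + (0, 0, z); direction (cosθ, sinθ, 0)
        ox = -q * st  # (C,)
        oy = q * ct  # (C,)
        acc = np.zeros((geom.det_rows, geom.det_cols))
        for ell in phantom.ellipsoids:
            cx, cy, cz = ell.center
            ax, ay, az = ell.semi_axes
            # into the ellipsoid frame: translate, rotate by -z_rotation, scale
            rx, ry = _rotate_xy(ox - cx, oy - cy, -ell.z_rotation)
            dx, dy = _rotate_xy(ct, st, -ell.z_rotation)
            opx = rx / ax  # (C,)
            opy = ry / ay  # (C,)
            opz = (z - cz) / az  # (R,)
            dpx, dpy = dx / ax, dy / ay
            a = dpx * dpx + dpy * dpy  # scalar, > 0 for horizontal rays
            b = 2.0 * (opx * dpx + opy * dpy)  # (C,)
            c = (opx * opx + opy * opy)[None, :] + (opz * opz)[:, None] - 1.0
            disc = b[None, :] ** 2 - 4.0 * a * c  # (R, C)
            chord = np.sqrt(np.maximum(disc, 0.0)) / a
            acc += ell.density * chord
        data[k] = acc
    return ProjectionFrame(data=data, state=FrameState.LINE_INTEGRAL, geometry=geom)


def _volume_grid(shape: tuple[int, int, int], voxel_size: float):
    """Voxel-centre coordinate axes of a volume centred on the world origin."""
    nx, ny, nz = shape
    xs = (np.arange(nx) - (nx - 1) / 2.0) * voxel_size
    ys = (np.arange(ny) - (ny - 1) / 2.0) * voxel_size
    zs = (np.arange(nz) - (nz - 1) / 2.0) * voxel_size
    return xs, ys, zs


def voxelize(phantom: Phantom, shape: tuple[int, int, int], voxel_size: float) -> np.ndarray:
    """Densities sampled at voxel centres, shape ``(nx, ny, nz)``.

    A voxel's value is the sum of densities of all ellipsoids containing
    its centre (boundary counts as inside).
    """
    if any(s < 1 for s in shape):
        raise ValueError(f"shape must be positive, got {shape}")
    xs, ys, zs = _volume_grid(shape, voxel_size)
    vol = np.zeros(shape)
    for ell in phantom.ellipsoids:
        cx, cy, cz = ell.center
        ax, ay, az = ell.semi_axes
        gx, gy = np.meshgrid(xs - cx, ys - cy, indexing="ij")
        rx, ry = _rotate_xy(gx, gy, -ell.z_rotation)
        horiz = (rx / ax) ** 2 + (ry / ay) ** 2  # (nx, ny)
        vert = ((zs - cz) / az) ** 2  # (nz,)
        inside = horiz[:, :, None] + vert[None, None, :] <= 1.0
        vol += ell.density * inside
    return vol


# -- wicking sequence -------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class WickingParams:
    """Parameters of the rising-water fibre-bundle sequence.

    Lengths share the unit of the scan geometry (typically µm); the front
    rises ``front_speed`` per frame starting from ``start_height``.
    ``fill_jitter`` ∈ [0, 1) delays individual pores by a seeded random
    fraction of one frame's rise, emulating the irregular pore-by-pore
    filling of a real yarn.
    """

    n_fibers: int = 10
    fiber_radius: float = 16.0
    bundle_radius: float = 90.0
    water_density: float = 0.02
    fiber_density: float = 0.02
    front_speed: float = 20.0
    start_height: float = -100.0
    fill_jitter: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")
        if self.fiber_radius <= 0 or self.bundle_radius <= 0:
            raise ValueError("radii must be positive")
        if self.front_speed <= 0:
            raise ValueError("front_speed must be positive")
        if not 0.0 <= self.fill_jitter < 1.0:
            raise ValueError("fill_jitter must lie in [0, 1)")


def _pack_discs(
    rng: np.random.Generator,
    n: int,
    r_max: float,
    clearance: float,
    existing: np.ndarray | None = None,
    existing_clearance: float = 0.0,
    max_tries: int = 4000,
) -> np.ndarray:
    """Seeded sequential packing of up to ``n`` disc centres in a disc.

    Centres stay within radius ``r_max``, at least ``clearance`` apart
    and ``existing_clearance`` away from ``existing`` centres.  If the
    disc jams before ``n`` are placed, fewer are returned (deterministic
    under the generator's state).
    """
    placed: list[np.ndarray] = []
    for _ in range(max_tries):
        if len(placed) == n:
            break
        rho = r_max * math.sqrt(rng.random())
        ang = 2.0 * math.pi * rng.random()
        cand = np.array([rho * math.cos(ang), rho * math.sin(ang)])
        if placed and np.min(np.linalg.norm(np.array(placed) - cand, axis=1)) < clearance:
            continue
        if existing is not None and existing.size:
            if np.min(np.linalg.norm(existing - cand, axis=1)) < existing_clearance:
                continue
        placed.append(cand)
    return np.array(placed) if placed else np.empty((0, 2))


def make_wicking_sequence(
    params: WickingParams, n_frames: int
) -> tuple[list[Phantom], np.ndarray]:
    """Phantom per frame plus the ground-truth front height per frame.

    Frame ``t`` has front height ``h(t) = start_height + t·front_speed``.
    Fibres are fixed parallel "cylinders" (ellipsoids with a very large
    vertical semi-axis) inside ``bundle_radius``; each pore column fills
    with water up to ``h(t)`` minus its seeded jitter lag.  The filled
    part of a pore is represented as a stack of squat ellipsoids (one per
    frame's rise) capped by a slightly narrower moving tip, so the water
    region grows monotonically from frame to frame.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    p = params
    fiber_r_max = p.bundle_radius - p.fiber_radius
    if fiber_r_max < 0:
        raise ValueError("fibres do not fit inside the bundle radius")
    if p.n_fibers * p.fiber_radius**2 > p.bundle_radius**2:
        raise ValueError("fibres do not fit inside the bundle radius")

    rng = np.random.default_rng(p.seed)
    pore_r = 0.8 * p.fiber_radius
    fiber_xy = _pack_discs(
        rng, p.n_fibers, fiber_r_max, clearance=2.05 * p.fiber_radius
    )
    if len(fiber_xy) < p.n_fibers:
        raise ValueError("fibres do not fit inside the bundle radius")
    tall = 1e3 * p.bundle_radius
    fibers = [
        Ellipsoid(
            center=(x, y, 0.0),
            semi_axes=(p.fiber_radius, p.fiber_radius, tall),
            density=p.fiber_density,
        )
        for x, y in fiber_xy
    ]

    # pore columns in the interstitial space, clear of every fibre
    pore_xy = _pack_discs(
        rng,
        p.n_fibers,
        p.bundle_radius - pore_r,
        clearance=2.05 * pore_r,
        existing=fiber_xy,
        existing_clearance=p.fiber_radius + pore_r + 1.0,
    )
    n_pores = len(pore_xy)
    lags = p.fill_jitter * p.front_speed * rng.random(max(n_pores, 1))[:n_pores]

    seg = p.front_speed  # vertical semi-axis of one water segment
    z_low = p.start_height - 3.0 * seg  # column bottom, below the imaged region

    heights = p.start_height + p.front_speed * np.arange(n_frames, dtype=float)
    phantoms: list[Phantom] = []
    for h in heights:
        ells = list(fibers)
        for (x, y), lag in zip(pore_xy, lags):
            h_p = h - lag
            if h_p <= z_low:
                continue
            # fixed lattice of squat segments up to h_p - seg …
            top_center = h_p - seg
            n_seg = int(math.floor((top_center - z_low) / seg))
            for j in range(1, n_seg + 1):
                ells.append(
                    Ellipsoid(
                        center=(x, y, z_low + j * seg),
                        semi_axes=(pore_r, pore_r, seg),
                        density=p.water_density,
                    )
                )
            # … plus the moving tip (slightly narrower so the region it
            # sweeps is always inside the lattice laid down next frame)
            if top_center > z_low:
                ells.append(
                    Ellipsoid(
                        center=(x, y, top_center),
                        semi_axes=(0.85 * pore_r, 0.85 * pore_r, seg),
                        density=p.water_density,
                    )
                )
        phantoms.append(Phantom(ells))
    return phantoms, heights


def crossing_frame(heights: np.ndarray, probe_height: float) -> int | None:
    """First frame index whose front height reaches ``probe_height``."""
    hits = np.nonzero(np.asarray(heights) >= probe_height)[0]
    return int(hits[0]) if hits.size else None


# -- acquisition simulation -------------------------------------------------


def simulate_acquisition(
    sequence: list[Phantom],
    geom: ScanGeometry,
    flat_level: float = 1000.0,
    dark_level: float = 20.0,
    noise_seed: int | None = None,
) -> tuple[list[ProjectionFrame], np.ndarray, np.ndarray]:
    """Raw detector frames for a phantom sequence, plus flat/dark references.

    ``raw = dark + (flat - dark) · exp(-sinogram)`` per Beer-Lambert; with
    ``noise_seed`` set, detected counts are Poisson-sampled (seeded, so
    frames are bit-identical across runs).  Flat/dark reference images are
    returned noiseless.
    """
    if not flat_level > dark_level or dark_level < 0:
        raise ValueError(
            f"need flat_level > dark_level >= 0, got {flat_level}, {dark_level}"
        )
    flat = np.full((geom.det_rows, geom.det_cols), float(flat_level))
    dark = np.full((geom.det_rows, geom.det_cols), float(dark_level))
    rng = np.random.default_rng(noise_seed) if noise_seed is not None else None
    frames = []
    for t, phantom in enumerate(sequence):
        sino = analytic_sinogram(phantom, geom)
        raw = dark_level + (flat_level - dark_level) * np.exp(-sino.data)
        if rng is not None:
            raw = rng.poisson(raw).astype(float)
        frames.append(
            ProjectionFrame(data=raw, state=FrameState.RAW, geometry=geom, frame_id=t)
        )
    return frames, flat, dark


# -- sequence-mode timing ---------------------------------------------------


@dataclasses.dataclass(frozen=True)
class TimingRecord:
    """Scan time (beam-on acquisition) and scan period (trigger to trigger)."""

    scan_time: float
    scan_period: float

    def __post_init__(self) -> None:
        if not self.scan_time > 0 or self.scan_period < self.scan_time:
            raise ValueError("need scan_period >= scan_time > 0")


def scan_timing(
    n_proj: int, exposure: float, scan_range: float = 180.0, trigger_every: float = 720.0
) -> TimingRecord:
    """Sequence-mode timing: continuous rotation, hardware trigger every
    ``trigger_every`` degrees starting a ``scan_range``-degree scan of
    ``n_proj`` exposures.

    ``scan_time = n_proj·exposure``;
    ``scan_period = scan_time · trigger_every / scan_range``.
    """
    if n_proj < 1 or exposure <= 0 or scan_range <= 0:
        raise ValueError("n_proj, exposure, scan_range must be positive")
    if trigger_every < scan_range:
        raise ValueError(
            f"trigger_every ({trigger_every}) must be >= scan_range ({scan_range})"
        )
    scan_time = n_proj * exposure
    return TimingRecord(
        scan_time=scan_time, scan_period=scan_time * (trigger_every / scan_range)
    )
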
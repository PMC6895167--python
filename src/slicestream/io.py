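"""File formats: HDF5 projection stacks, float TIFF slices, CSV series.

Layouts
-------
* projection HDF5: ``/projections`` (``[N_φ, rows, cols]`` for one frame or
  ``[n_frames, N_φ, rows, cols]`` for a sequence), ``/flat``, ``/dark``,
  ``/angles``.
* slices: 32-bit float TIFF next to a ``.json`` sidecar carrying the
  plane description and source frame id.
* volumes: HDF5 ``/volume`` with a ``voxel_size`` attribute.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .frames import FrameState, ProjectionFrame
from .geometry import ScanGeometry, plane_from_dict, plane_to_dict
from .reconstruct import SliceImage, VolumeImage

__all__ = [
    "save_projections_hdf5",
    "load_projections_hdf5",
    "save_slice_tiff",
    "load_slice_tiff",
    "save_volume_hdf5",
    "write_uptake_csv",
]


def save_projections_hdf5(
    path: str | Path,
    frames: list[ProjectionFrame] | ProjectionFrame,
    flat: np.ndarray | None = None,
    dark: np.ndarray | None = None,
) -> None:
    if isinstance(frames, ProjectionFrame):
        frames = [frames]
    geom = frames[0].geometry
    data = np.stack([f.data for f in frames])
    if data.shape[0] == 1:
        data = data[0]
    with h5py.File(path, "w") as f:
        f.create_dataset("projections", data=data)
        f.create_dataset("angles", data=geom.angles)
        if flat is not None:
            f.create_dataset("flat", data=flat)
        if dark is not None:
            f.create_dataset("dark", data=dark)
        f["projections"].attrs["state"] = frames[0].state.value
        f["projections"].attrs["pixel_size"] = geom.pixel_size
        f["projections"].attrs["cor_offset"] = geom.cor_offset


def load_projections_hdf5(
    path: str | Path,
) -> tuple[list[ProjectionFrame], np.ndarray | None, np.ndarray | None]:
    with h5py.File(path, "r") as f:
        data = f["projections"][()]
        angles = f["angles"][()]
        state = FrameState(f["projections"].attrs.get("state", "raw"))
        pixel_size = float(f["projections"].attrs.get("pixel_size", 1.0))
        cor = float(f["projections"].attrs.get("cor_offset", 0.0))
        flat = f["flat"][()] if "flat" in f else None
        dark = f["dark"][()] if "dark" in f else None
    if data.ndim == 3:
        data = data[None]
    geom = ScanGeometry(
        n_angles=data.shape[1],
        angles=angles,
        det_rows=data.shape[2],
        det_cols=data.shape[3],
        pixel_size=pixel_size,
        cor_offset=cor,
    )
    frames = [
        ProjectionFrame(data=d, state=state, geometry=geom, frame_id=i)
        for i, d in enumerate(data)
    ]
    return frames, flat, dark


def save_slice_tiff(path: str | Path, image: SliceImage) -> None:
    path = Path(path)
    tifffile.imwrite(path, image.values.astype(np.float32))
    sidecar = {"plane": plane_to_dict(image.plane), "frame_id": int(image.frame_id)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_slice_tiff(path: str | Path) -> SliceImage:
    path = Path(path)
    values = tifffile.imread(path).astype(float)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return SliceImage(
        values=values,
        plane=plane_from_dict(sidecar["plane"]),
        frame_id=int(sidecar["frame_id"]),
    )


def save_volume_hdf5(path: str | Path, volume: VolumeImage) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("volume", data=volume.values.astype(np.float32))
        ds.attrs["voxel_size"] = volume.voxel_size
        ds.attrs["frame_id"] = int(volume.frame_id)


def write_uptake_csv(path: str | Path, rows: list[dict]) -> None:
    """Per-frame analysis table (frame, time_s, counts, fractions, state)."""
    if not rows:
        Path(path).write_text("")
        return
    fieldnames = list(rows[0].keys())
    with open(path, "w", newline="") as f:
        writer = csv.DictWriter(f, fieldnames=fieldnames)
        writer.writeheader()
        writer.writerows(rows)
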
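"""The live loop: stream → assemble → preprocess → slice → analyse.

``run_live`` drives the whole chain exactly as it runs at the beamline:
frames arrive as ordered messages (possibly with drops), every completed
frame is flat/dark-corrected, log- or Paganin-converted and ramp-
filtered, the configured slices and the low-resolution preview are
reconstructed from it, and the uptake analysis plus feedback state
machine advance one step.  Everything is deterministic under fixed
seeds, and the outputs of the live loop equal the batch pipeline applied
to the assembled frames — the streaming layer adds no arithmetic.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

import numpy as np

from . import io as sio
from .analysis import (
    FeedbackState,
    UptakeSeries,
    feedback_step,
    material_fraction,
    otsu_threshold,
)
from .frames import ProjectionFrame
from .geometry import ScanGeometry, SlicePlane
from .preprocess import FilterSpec, PaganinSpec, preprocess_frame
from .reconstruct import SliceImage, VolumeImage, backproject_slice, reconstruct_preview
from .streaming import assemble, publish_frames

__all__ = ["PipelineConfig", "RunArtifacts", "run_live"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """One configuration surface for the whole live loop."""

    geometry: ScanGeometry
    planes: list[SlicePlane]
    filter_spec: FilterSpec = dataclasses.field(default_factory=FilterSpec)
    paganin: PaganinSpec | None = None
    floor: float = 1e-6
    preview_shape: tuple[int, int, int] = (32, 32, 32)
    preview_bin: int = 1
    # streaming
    drop_prob: float = 0.0
    decimate: int = 1
    seed: int = 0
    # analysis: monitored planes (indices into `planes`) and thresholds
    bottom_plane: int = 0
    top_plane: int = -1
    rise: float = 0.02
    plateau_tol: float = 0.005
    plateau_window: int = 5
    n_bins: int = 256
    frame_period: float = 1.0  # seconds between completed frames
    output_dir: str | None = None


@dataclasses.dataclass
class RunArtifacts:
    """Everything one live run produced, stamped with source frame ids."""

    slices: list[list[SliceImage]]  # [frame][plane]
    previews: list[VolumeImage]
    frames: list[ProjectionFrame]  # assembled, filtered frames
    drop_log: list[tuple[int, int]]
    bottom: UptakeSeries | None
    top: UptakeSeries | None
    states: list[FeedbackState]
    threshold: float | None
    timings: list[dict]


def run_live(
    config: PipelineConfig,
    frames: list[ProjectionFrame],
    flat: np.ndarray | None = None,
    dark: np.ndarray | None = None,
) -> RunArtifacts:
    """Run the full live pipeline over a source of raw frames.

    ``frames`` are raw detector frames (one per scan); they are published
    through the streaming layer (honouring ``drop_prob``/``decimate``
    under ``seed``), reassembled with zero-fill, and processed per
    completed frame.  The segmentation threshold is Otsu's, computed once
    on the bottom slice of the first (dry) frame and held constant.
    """
    geom = config.geometry
    if flat is None:
        flat = np.ones((geom.det_rows, geom.det_cols))
    if dark is None:
        dark = np.zeros((geom.det_rows, geom.det_cols))

    messages, drop_log = publish_frames(
        frames, drop_prob=config.drop_prob, seed=config.seed, decimate=config.decimate
    )
    assembled, _buffer = assemble(messages, geom)

    out_slices: list[list[SliceImage]] = []
    previews: list[VolumeImage] = []
    filtered_frames: list[ProjectionFrame] = []
    times: list[float] = []
    bottom_counts: list[int] = []
    top_counts: list[int] = []
    states: list[FeedbackState] = []
    timings: list[dict] = []
    threshold: float | None = None
    state = FeedbackState()
    slice_area = None

    for step, raw in enumerate(assembled):
        stage = "preprocess"
        try:
            t0 = time.perf_counter()
            filtered = preprocess_frame(
                raw,
                flat,
                dark,
                filter_spec=config.filter_spec,
                paganin=config.paganin,
                floor=config.floor,
            )
            t1 = time.perf_counter()
            stage = "slice"
            images = [backproject_slice(filtered, plane) for plane in config.planes]
            t2 = time.perf_counter()
            stage = "preview"
            preview = reconstruct_preview(
                filtered, config.preview_shape, config.preview_bin
            )
            t3 = time.perf_counter()
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(
                f"stage {stage!r} failed on frame {raw.frame_id}: {exc}"
            ) from exc
        timings.append(
            {
                "frame_id": raw.frame_id,
                "process_s": t1 - t0,
                "slice_s": t2 - t1,
                "preview_s": t3 - t2,
            }
        )
        filtered_frames.append(filtered)
        out_slices.append(images)
        previews.append(preview)

        if config.planes:
            bottom_img = images[config.bottom_plane]
            top_img = images[config.top_plane]
            if threshold is None:
                # constant threshold from the dry first frame
                threshold = otsu_threshold(bottom_img, n_bins=config.n_bins)
                slice_area = bottom_img.values.size
            bc, _ = material_fraction(bottom_img, threshold)
            tc, _ = material_fraction(top_img, threshold)
            bottom_counts.append(bc)
            top_counts.append(tc)
            times.append(step * config.frame_period)
            bottom_series = UptakeSeries.from_counts(
                times, bottom_counts, slice_area, threshold
            )
            top_series = UptakeSeries.from_counts(
                times, top_counts, slice_area, threshold
            )
            state = feedback_step(
                state,
                bottom_series,
                top_series,
                rise=config.rise,
                plateau_tol=config.plateau_tol,
                plateau_window=config.plateau_window,
            )
            states.append(state)

    bottom_series = (
        UptakeSeries.from_counts(times, bottom_counts, slice_area, threshold)
        if times
        else None
    )
    top_series = (
        UptakeSeries.from_counts(times, top_counts, slice_area, threshold)
        if times
        else None
    )

    artifacts = RunArtifacts(
        slices=out_slices,
        previews=previews,
        frames=filtered_frames,
        drop_log=drop_log,
        bottom=bottom_series,
        top=top_series,
        states=states,
        threshold=threshold,
        timings=timings,
    )
    if config.output_dir is not None:
        _write_artifacts(config, artifacts)
    return artifacts


def reslice_active(frame: ProjectionFrame, plane: SlicePlane) -> SliceImage:
    """On-demand re-slice of the stored active frame with a new plane.

    This is the interactive trigger: between frame completions the user
    rotates or translates a plane and the same data path serves it.
    """
    return backproject_slice(frame, plane)


def _write_artifacts(config: PipelineConfig, artifacts: RunArtifacts) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for images in artifacts.slices:
        for p, image in enumerate(images):
            sio.save_slice_tiff(
                out / f"frame{image.frame_id:04d}_slice{p}.tif", image
            )
    for preview in artifacts.previews:
        sio.save_volume_hdf5(out / f"frame{preview.frame_id:04d}_preview.h5", preview)
    rows = []
    if artifacts.bottom is not None:
        for i in range(len(artifacts.bottom)):
            rows.append(
                {
                    "frame": artifacts.frames[i].frame_id,
                    "time_s": artifacts.bottom.times[i],
                    "count_bottom": int(artifacts.bottom.counts[i]),
                    "count_top": int(artifacts.top.counts[i]),
                    "state": artifacts.states[i].state.value,
                }
            )
    sio.write_uptake_csv(out / "uptake.csv", rows)
    import json

    trace = {
        "n_frames": len(artifacts.frames),
        "frame_ids": [f.frame_id for f in artifacts.frames],
        "drops": [list(d) for d in artifacts.drop_log],
        "threshold": artifacts.threshold,
        "timings": artifacts.timings,
    }
    (out / "trace.json").write_text(json.dumps(trace, indent=1))
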
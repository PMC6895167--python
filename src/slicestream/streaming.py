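"""Streamed projection delivery and the double-buffer assembly contract.

The detector backend publishes one message per projection image.  The
transport guarantees ordered, at-most-once delivery but not completeness:
messages may be dropped.  The assembler keeps two frame buffers — the
*passive* one fills as messages arrive; when a frame completes (first
message of the next frame, or end of stream) the missing angles are
zero-filled and the passive buffer atomically becomes the *active* one,
from which all reconstructions are served.  A zero projection simply
contributes nothing to a backprojection, so dropped images are
effectively ignored (at the price of missing-angle artefacts and a
proportional intensity reduction when many are lost).

Transport here is an in-process message list honouring the published
guarantees; real sockets are out of scope.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable, Sequence

import numpy as np

from .frames import FrameState, ProjectionFrame
from .geometry import ScanGeometry

__all__ = [
    "StreamMessage",
    "FrameBuffer",
    "ProtocolError",
    "publish_frames",
    "assemble",
    "buffer_bytes",
]


class ProtocolError(RuntimeError):
    """A message violated the ordered at-most-once publisher contract."""


@dataclasses.dataclass(frozen=True)
class StreamMessage:
    """One projection image in flight."""

    frame_index: int
    angle_index: int
    payload: np.ndarray

    def __post_init__(self) -> None:
        if self.frame_index < 0 or self.angle_index < 0:
            raise ValueError("indices must be non-negative")


@dataclasses.dataclass
class FrameBuffer:
    """Active/passive double buffer for streamed frames.

    ``active`` only ever changes by a completed passive frame replacing it
    wholesale; readers between completion callbacks always see one
    consistent frame.  ``drop_count`` accumulates zero-filled angles.
    """

    geometry: ScanGeometry
    active: ProjectionFrame | None = None
    passive: np.ndarray | None = None
    passive_frame_index: int | None = None
    received_mask: np.ndarray | None = None
    drop_count: int = 0

    def _start_frame(self, frame_index: int) -> None:
        g = self.geometry
        self.passive = np.zeros((g.n_angles, g.det_rows, g.det_cols))
        self.received_mask = np.zeros(g.n_angles, dtype=bool)
        self.passive_frame_index = frame_index

    def _complete_frame(self) -> ProjectionFrame:
        # missing angles are already zero-filled by construction
        missing = tuple(int(a) for a in np.nonzero(~self.received_mask)[0])
        self.drop_count += len(missing)
        frame = ProjectionFrame(
            data=self.passive,
            state=FrameState.RAW,
            geometry=self.geometry,
            frame_id=self.passive_frame_index,
            missing_angles=missing,
        )
        self.active = frame  # atomic swap: one assignment
        self.passive = None
        self.received_mask = None
        return frame


def publish_frames(
    frames: Sequence[ProjectionFrame],
    drop_prob: float = 0.0,
    seed: int = 0,
    decimate: int = 1,
) -> tuple[list[StreamMessage], list[tuple[int, int]]]:
    """Serialise frames into an ordered at-most-once message stream.

    Messages appear in ``(frame_index, angle_index)`` order; each image is
    independently dropped with probability ``drop_prob`` under ``seed``,
    and the drop log lists the dropped ``(frame, angle)`` pairs.  With
    ``decimate`` = N only every Nth frame is forwarded (a stream-splitter
    load-shedding knob); decimated frames do not appear in the drop log.
    """
    if not 0.0 <= drop_prob < 1.0:
        raise ValueError(f"drop_prob must lie in [0, 1), got {drop_prob}")
    if decimate < 1:
        raise ValueError("decimate must be >= 1")
    rng = np.random.default_rng(seed)
    messages: list[StreamMessage] = []
    drop_log: list[tuple[int, int]] = []
    for f, frame in enumerate(frames):
        if f % decimate != 0:
            continue
        for a in range(frame.data.shape[0]):
            if drop_prob > 0.0 and rng.random() < drop_prob:
                drop_log.append((f, a))
                continue
            messages.append(
                StreamMessage(frame_index=f, angle_index=a, payload=frame.data[a])
            )
    return messages, drop_log


def assemble(
    messages: Iterable[StreamMessage],
    geom: ScanGeometry,
    on_frame_complete: Callable[[ProjectionFrame], None] | None = None,
) -> tuple[list[ProjectionFrame], FrameBuffer]:
    """Rebuild frames from an ordered message stream with zero-fill.

    A frame is declared complete when the first message of a later frame
    arrives or the stream ends; missing angles stay zero and are counted
    in ``buffer.drop_count``.  ``on_frame_complete`` fires exactly once
    per completed frame, after the atomic active-buffer swap.  Messages
    that violate the publisher's lexicographic order raise
    :class:`ProtocolError` with the offending indices.
    """
    buf = FrameBuffer(geometry=geom)
    completed: list[ProjectionFrame] = []
    last_angle = -1
    for msg in messages:
        if msg.angle_index >= geom.n_angles:
            raise ProtocolError(
                f"angle_index {msg.angle_index} outside geometry "
                f"(frame {msg.frame_index})"
            )
        if buf.passive_frame_index is None:
            buf._start_frame(msg.frame_index)
            last_angle = -1
        elif msg.frame_index > buf.passive_frame_index:
            frame = buf._complete_frame()
            completed.append(frame)
            if on_frame_complete is not None:
                on_frame_complete(frame)
            buf._start_frame(msg.frame_index)
            last_angle = -1
        elif msg.frame_index < buf.passive_frame_index:
            raise ProtocolError(
                f"frame {msg.frame_index} after frame {buf.passive_frame_index} "
                f"(angle {msg.angle_index}): frames intermixed"
            )
        if msg.angle_index <= last_angle:
            raise ProtocolError(
                f"angle {msg.angle_index} after angle {last_angle} in frame "
                f"{msg.frame_index}: order violated"
            )
        buf.passive[msg.angle_index] = msg.payload
        buf.received_mask[msg.angle_index] = True
        last_angle = msg.angle_index
    if buf.passive_frame_index is not None:
        frame = buf._complete_frame()
        completed.append(frame)
        if on_frame_complete is not None:
            on_frame_complete(frame)
    return completed, buf


def buffer_bytes(
    det_rows: int,
    det_cols: int,
    n_proj: int,
    n_buffers: int = 2,
    bytes_per_value: int = 4,
) -> int:
    """Exact memory footprint of the projection buffers, in bytes.

    E.g. a 2016×2016 detector, 400 projections, double-buffered in single
    precision needs 2016²·400·2·4 B ≈ 13 GB (decimal).
    """
    for v in (det_rows, det_cols, n_proj, n_buffers, bytes_per_value):
        if v < 0:
            raise ValueError("arguments must be non-negative")
    return int(det_rows) * int(det_cols) * int(n_proj) * int(n_buffers) * int(bytes_per_value)
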
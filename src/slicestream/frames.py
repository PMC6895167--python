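"""The projection data frame and its processing-state tag.

One scan yields one *data frame*: N_φ projection images on the detector
raster.  The frame moves through a fixed processing chain,

    raw → transmission → line_integral → filtered

and every operation checks the tag of its input, so a frame can never be
ramp-filtered twice or backprojected before filtering.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np

from .geometry import ScanGeometry

__all__ = ["FrameState", "ProjectionFrame"]


class FrameState(enum.Enum):
    RAW = "raw"
    TRANSMISSION = "transmission"
    LINE_INTEGRAL = "line_integral"
    FILTERED = "filtered"


_ORDER = [
    FrameState.RAW,
    FrameState.TRANSMISSION,
    FrameState.LINE_INTEGRAL,
    FrameState.FILTERED,
]


@dataclasses.dataclass
class ProjectionFrame:
    """N_φ projection images plus processing state.

    Attributes
    ----------
    data : np.ndarray
        Shape ``(n_angles, det_rows, det_cols)``, float.
    state : FrameState
        Position in the raw → transmission → line_integral → filtered chain.
    geometry : ScanGeometry
        The scan geometry the raster belongs to.
    frame_id : int
        Provenance tag (index of the scan in a sequence).
    missing_angles : tuple[int, ...]
        Angles whose projection was never delivered (zero-filled by the
        streaming layer).  Preprocessing keeps them zero in the filtered
        data so backprojection effectively ignores them.
    """

    data: np.ndarray
    state: FrameState
    geometry: ScanGeometry
    frame_id: int = 0
    missing_angles: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        g = self.geometry
        expected = (g.n_angles, g.det_rows, g.det_cols)
        if self.data.shape != expected:
            raise ValueError(
                f"frame data shape {self.data.shape} does not match geometry {expected}"
            )
        if isinstance(self.state, str):
            self.state = FrameState(self.state)

    def require_state(self, state: FrameState) -> None:
        if self.state is not state:
            raise ValueError(
                f"frame is in state {self.state.value!r}, expected {state.value!r}"
            )

    def advance(self, data: np.ndarray, new_state: FrameState) -> "ProjectionFrame":
        """New frame with ``data`` and the next processing state.

        Transitions must move forward along the chain.
        """
        if _ORDER.index(new_state) <= _ORDER.index(self.state):
            raise ValueError(
                f"illegal state transition {self.state.value} -> {new_state.value}"
            )
        return ProjectionFrame(
            data=data,
            state=new_state,
            geometry=self.geometry,
            frame_id=self.frame_id,
            missing_angles=self.missing_angles,
        )
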
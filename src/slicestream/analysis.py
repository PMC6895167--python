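"""On-line quantification of reconstructed slices: wicking-front feedback.

The feedback loop for a liquid-uptake experiment monitors two axial
slices near the bottom and top of the imaged region.  Each reconstructed
slice is segmented into air vs material (fibre + water) with a constant
grey-level threshold, determined once by Otsu's method on the first
(dry) frame.  The material pixel count per slice over time is the uptake
series; the liquid front's arrival is the first sudden rise of that
series above its dry baseline, and saturation is a plateau of both
series.  Those two events drive the start/stop recording state machine.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np

from .reconstruct import SliceImage

__all__ = [
    "UptakeSeries",
    "FeedbackState",
    "RecordingState",
    "otsu_threshold",
    "material_fraction",
    "detect_front_arrival",
    "feedback_step",
]


@dataclasses.dataclass
class UptakeSeries:
    """Per-frame material counts for one monitored slice.

    ``fractions`` are counts normalised by the slice area n²; both arrays
    share the frame axis with ``times`` (seconds).
    """

    times: np.ndarray
    counts: np.ndarray
    fractions: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if not (len(self.times) == len(self.counts) == len(self.fractions)):
            raise ValueError("times/counts/fractions must have equal length")

    def __len__(self) -> int:
        return len(self.times)

    @classmethod
    def from_counts(
        cls, times, counts, slice_area: int, threshold: float
    ) -> "UptakeSeries":
        counts = np.asarray(counts)
        return cls(
            times=np.asarray(times, dtype=float),
            counts=counts,
            fractions=counts / float(slice_area),
            threshold=threshold,
        )


class RecordingState(enum.Enum):
    IDLE = "idle"
    RECORDING = "recording"
    STOPPED = "stopped"


@dataclasses.dataclass(frozen=True)
class FeedbackState:
    """Start/stop recording state; transitions only idle→recording→stopped."""

    state: RecordingState = RecordingState.IDLE
    arrival_frame: int | None = None


def otsu_threshold(image: SliceImage | np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold: the histogram-bin edge maximising between-class
    variance over the image's value range.

    Pixels at or above the returned edge are "material".  Raises on a
    constant image (the histogram is degenerate and no split exists).
    """
    values = image.values if isinstance(image, SliceImage) else np.asarray(image)
    values = values.ravel()
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise ValueError("constant image: Otsu threshold is undefined")
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    # The criterion w0·w1·(μ0-μ1)² equals (m0·w1 - m1·w0)²/(w0·w1) with
    # zeroth/first histogram moments, and is invariant under the affine
    # map from bin index to bin centre — so it is evaluated in exact
    # integer arithmetic over bin indices.  This makes the maximiser (and
    # the first-edge tie-break over splits through empty bins) exact
    # rather than dependent on floating-point summation order.
    total_w = int(counts.sum())
    total_m = int((counts * np.arange(n_bins)).sum())
    best_i, best_num, best_den = None, 0, 1
    w0 = m0 = 0
    for i in range(n_bins - 1):
        w0 += int(counts[i])
        m0 += int(counts[i]) * i
        w1 = total_w - w0
        if w0 == 0 or w1 == 0:
            continue
        num = (m0 * w1 - (total_m - m0) * w0) ** 2
        den = w0 * w1
        if best_i is None or num * best_den > best_num * den:
            best_i, best_num, best_den = i, num, den
    return float(edges[best_i + 1])


def material_fraction(
    image: SliceImage | np.ndarray, threshold: float
) -> tuple[int, float]:
    """Pixels at or above threshold (ties count as material) and their fraction."""
    values = image.values if isinstance(image, SliceImage) else np.asarray(image)
    count = int(np.count_nonzero(values >= threshold))
    return count, count / values.size


def detect_front_arrival(
    series: UptakeSeries, rise: float = 0.02, window: int = 5
) -> int | None:
    """First frame whose material fraction exceeds the dry baseline by ``rise``.

    The baseline is the median fraction over the first ``window`` frames;
    returns ``None`` if the series never rises that much.
    """
    if window < 1 or rise <= 0:
        raise ValueError("window must be >= 1 and rise > 0")
    frac = series.fractions
    if len(frac) < window:
        raise ValueError(f"series length {len(frac)} shorter than window {window}")
    baseline = float(np.median(frac[:window]))
    hits = np.nonzero(frac - baseline >= rise)[0]
    return int(hits[0]) if hits.size else None


def _is_plateau(series: UptakeSeries, tol: float, window: int) -> bool:
    frac = series.fractions
    if len(frac) < window:
        return False
    recent = frac[-window:]
    return float(recent.max() - recent.min()) <= tol


def feedback_step(
    state: FeedbackState,
    bottom: UptakeSeries,
    top: UptakeSeries,
    rise: float = 0.02,
    plateau_tol: float = 0.005,
    plateau_window: int = 5,
) -> FeedbackState:
    """Advance the start/stop state machine on the latest uptake series.

    idle → recording when the front arrives in the bottom slice (baseline
    window = ``plateau_window``); recording → stopped when, over the last
    ``plateau_window`` frames, neither slice's fraction has changed by
    more than ``plateau_tol``.  Otherwise the state is unchanged.
    """
    if len(bottom) != len(top):
        raise ValueError("bottom and top series must have equal length")
    if state.state is RecordingState.IDLE:
        if len(bottom) >= plateau_window:
            arrival = detect_front_arrival(bottom, rise=rise, window=plateau_window)
            if arrival is not None:
                return FeedbackState(
                    state=RecordingState.RECORDING, arrival_frame=arrival
                )
        return state
    if state.state is RecordingState.RECORDING:
        if _is_plateau(bottom, plateau_tol, plateau_window) and _is_plateau(
            top, plateau_tol, plateau_window
        ):
            return FeedbackState(
                state=RecordingState.STOPPED, arrival_frame=state.arrival_frame
            )
        return state
    return state
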
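"""Raw frame → filtered line-integral frame.

The chain is flat/dark correction, negative log (or single-distance
Paganin phase retrieval in place of the log), then the row-wise ramp
filter.  Filtering is the operator C of the FBP factorisation
x = AᵀC b: every detector row of every projection is convolved with the
band-limited ramp kernel independently, so the work is trivially
parallel across rows and projections.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .frames import FrameState, ProjectionFrame

__all__ = [
    "FilterSpec",
    "PaganinSpec",
    "flat_dark_correct",
    "negative_log",
    "paganin_filter",
    "ramp_filter",
    "ramp_kernel",
    "preprocess_frame",
]

logger = logging.getLogger(__name__)

_FILTER_NAMES = ("ram-lak", "shepp-logan")


@dataclasses.dataclass(frozen=True)
class FilterSpec:
    """Row filter: kernel family, padding policy and Nyquist cutoff."""

    name: str = "ram-lak"
    cutoff: float = 1.0  # fraction of Nyquist kept

    def __post_init__(self) -> None:
        if self.name not in _FILTER_NAMES:
            raise ValueError(f"unknown filter {self.name!r}; choose from {_FILTER_NAMES}")
        if not 0.0 < self.cutoff <= 1.0:
            raise ValueError(f"cutoff must lie in (0, 1], got {self.cutoff}")


@dataclasses.dataclass(frozen=True)
class PaganinSpec:
    """Single-distance phase retrieval for a homogeneous object.

    delta/beta are the refractive decrement and absorption index of the
    material, ``distance`` the propagation length, ``wavelength`` and
    ``pixel_size`` in the same length unit.
    """

    delta: float
    beta: float
    distance: float
    wavelength: float
    pixel_size: float

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.distance <= 0 or self.wavelength <= 0 or self.pixel_size <= 0:
            raise ValueError("distance, wavelength, pixel_size must be positive")


def flat_dark_correct(
    raw: ProjectionFrame,
    flat: np.ndarray,
    dark: np.ndarray,
    floor: float = 1e-6,
) -> ProjectionFrame:
    """Normalise raw counts to transmission: ``(raw-dark)/(flat-dark)``.

    Output is clamped to ``[floor, ∞)`` so the subsequent log stays
    bounded on dead pixels.  Pixels where ``flat <= dark`` get their
    denominator replaced by ``floor`` and a warning is logged.
    """
    raw.require_state(FrameState.RAW)
    flat = np.asarray(flat, dtype=float)
    dark = np.asarray(dark, dtype=float)
    shape = raw.data.shape[1:]
    if flat.shape != shape or dark.shape != shape:
        raise ValueError(
            f"flat/dark raster {flat.shape}/{dark.shape} does not match frame {shape}"
        )
    denom = flat - dark
    bad = denom <= 0
    if np.any(bad):
        logger.warning(
            "flat <= dark at %d pixel(s); denominator floored", int(bad.sum())
        )
        denom = np.where(bad, floor, denom)
    out = (raw.data - dark[None]) / denom[None]
    out = np.maximum(out, floor)
    return raw.advance(out, FrameState.TRANSMISSION)


def negative_log(frame: ProjectionFrame) -> ProjectionFrame:
    """Beer-Lambert: transmission → line integrals via ``-ln``."""
    frame.require_state(FrameState.TRANSMISSION)
    if np.any(frame.data <= 0):
        # flat_dark_correct clamps to a positive floor, so this indicates
        # a broken caller, not bad data
        raise AssertionError("transmission values must be positive")
    return frame.advance(-np.log(frame.data), FrameState.LINE_INTEGRAL)


def paganin_filter(frame: ProjectionFrame, spec: PaganinSpec) -> ProjectionFrame:
    """Single-distance phase retrieval; replaces the negative log.

    Per projection image I/I₀ (transmission)::

        T = -(1/μ) ln( F⁻¹[ F[I/I₀] / (1 + (λ d δ / 4π β) |k|²) ] ),  μ = 4πβ/λ

    with |k| the angular spatial frequency for the detector pixel size.
    The zero-frequency gain is exactly 1, so the image mean is preserved
    before the log.  Output values are thickness-scaled line integrals.
    """
    frame.require_state(FrameState.TRANSMISSION)
    lam, d = spec.wavelength, spec.distance
    mu = 4.0 * math.pi * spec.beta / lam
    coeff = lam * d * spec.delta / (4.0 * math.pi * spec.beta)
    n_ang, rows, cols = frame.data.shape
    kr = 2.0 * math.pi * np.fft.fftfreq(rows, d=spec.pixel_size)
    kc = 2.0 * math.pi * np.fft.fftfreq(cols, d=spec.pixel_size)
    denom = 1.0 + coeff * (kr[:, None] ** 2 + kc[None, :] ** 2)
    spec_im = np.fft.fft2(frame.data, axes=(1, 2)) / denom[None]
    filtered = np.real(np.fft.ifft2(spec_im, axes=(1, 2)))
    filtered = np.maximum(filtered, 1e-12)  # guard the log against ringing
    out = -(1.0 / mu) * np.log(filtered)
    return frame.advance(out, FrameState.LINE_INTEGRAL)


# -- ramp filtering ---------------------------------------------------------


def _next_pow_two(n: int) -> int:
    return 1 << (n - 1).bit_length()


def ramp_kernel(length: int, pixel_size: float) -> np.ndarray:
    """Discrete Ram-Lak kernel on lags ``-length//2+1 … length//2``, wrapped.

    The spatial sequence is 1/4 at lag 0, ``-1/(π m)²`` at odd lags and 0
    at even lags, scaled by 1/pixel_size; this sampling of the ideal ramp
    avoids the DC bias of sampling |ν| directly.  The infinite sequence
    sums to zero; truncation reintroduces a small DC residual (the lag
    tail ~2/(π²·length)), which is subtracted uniformly so the discrete
    kernel keeps the ramp's exact zero DC gain.  Returned as a length-
    ``length`` array in FFT (wrapped) order.
    """
    f = np.zeros(length)
    f[0] = 0.25
    odd = np.arange(1, length // 2 + 1, 2)
    f[odd] = -1.0 / (np.pi * odd) ** 2
    f[-odd] = -1.0 / (np.pi * odd) ** 2
    f -= f.sum() / length
    return f / pixel_size


def _ramp_response(n_cols: int, pixel_size: float, spec: FilterSpec) -> tuple[np.ndarray, int]:
    pad = _next_pow_two(max(2 * n_cols, 16))
    resp = np.real(np.fft.fft(ramp_kernel(pad, pixel_size)))
    nu = np.fft.fftfreq(pad)  # cycles/sample, Nyquist at 0.5
    if spec.name == "shepp-logan":
        resp = resp * np.sinc(nu)  # ramp × sinc window
    resp[np.abs(nu) > 0.5 * spec.cutoff] = 0.0
    return resp, pad


def ramp_filter(frame: ProjectionFrame, spec: FilterSpec | None = None) -> ProjectionFrame:
    """Apply the band-limited ramp to every detector row of every projection.

    Rows are zero-padded to a power of two at least twice the row length
    (killing circular-convolution wrap-around), multiplied by the kernel's
    frequency response, and cropped back.  The ramp has zero DC gain, so a
    constant row filters to zero.
    """
    frame.require_state(FrameState.LINE_INTEGRAL)
    spec = spec or FilterSpec()
    n_ang, rows, cols = frame.data.shape
    resp, pad = _ramp_response(cols, frame.geometry.pixel_size, spec)
    padded = np.zeros((n_ang, rows, pad))
    padded[:, :, :cols] = frame.data
    filt = np.real(np.fft.ifft(np.fft.fft(padded, axis=2) * resp[None, None, :], axis=2))
    return frame.advance(filt[:, :, :cols], FrameState.FILTERED)


def preprocess_frame(
    raw: ProjectionFrame,
    flat: np.ndarray,
    dark: np.ndarray,
    filter_spec: FilterSpec | None = None,
    paganin: PaganinSpec | None = None,
    floor: float = 1e-6,
) -> ProjectionFrame:
    """Full chain raw → filtered: flat/dark, Paganin or -log, ramp filter.

    Angles the streaming layer zero-filled (``raw.missing_angles``) are
    forced back to zero in the filtered output, so a backprojection from
    this frame effectively ignores them — at the price of missing-angle
    artefacts and a proportional intensity reduction when many are lost.
    """
    trans = flat_dark_correct(raw, flat, dark, floor=floor)
    if paganin is not None:
        line = paganin_filter(trans, paganin)
    else:
        line = negative_log(trans)
    filtered = ramp_filter(line, filter_spec)
    if raw.missing_angles:
        filtered.data[list(raw.missing_angles)] = 0.0
    return filtered
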
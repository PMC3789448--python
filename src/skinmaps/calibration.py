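"""Offset and flat-field correction of raw monoband camera frames.

The sensor is assumed linear: a raw frame is R = O + U * S, where O is the
per-pixel offset (dark/2 %-target level), S the per-pixel gain and U the
useful signal. The gain is estimated from a bright uniform (99 %-target)
flat-field frame F as S = (F - O) / DR with DR the camera dynamic range
(4096 for 12-bit data), and the correction inverts the model:
U = (R - O) / S. Pixels where F <= O have no usable gain and are masked,
never interpolated — downstream per-pixel inversion simply skips them.
Calibration is per band: each filter has its own exposure and dust pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DEFAULT_DR", "GainFrame", "CalibrationFrames", "gain_frame", "correct_image", "average_frames"]

DEFAULT_DR = 4096.0  # 12-bit dynamic range


@dataclass
class GainFrame:
    """Per-pixel gain with a validity mask (True where the gain is usable)."""

    values: np.ndarray
    valid: np.ndarray


@dataclass
class CalibrationFrames:
    """Per-band offset/flat-field frames (band-first stacks) and dynamic range."""

    offset: np.ndarray  # (bands, h, w)
    flatfield: np.ndarray  # (bands, h, w)
    dr: float = DEFAULT_DR

    def __post_init__(self) -> None:
        self.offset = np.asarray(self.offset, dtype=float)
        self.flatfield = np.asarray(self.flatfield, dtype=float)
        if self.offset.shape != self.flatfield.shape:
            raise ValueError("offset and flat-field stacks must share a shape")
        if self.dr <= 0:
            raise ValueError("dynamic range must be positive")

    def gain(self, band: int) -> GainFrame:
        return gain_frame(self.flatfield[band], self.offset[band], self.dr)


def gain_frame(F, O, dr: float = DEFAULT_DR) -> GainFrame:
    """Per-pixel gain S = (F - O) / DR; pixels with F <= O are flagged invalid."""
    F = np.asarray(F, dtype=float)
    O = np.asarray(O, dtype=float)
    if F.shape != O.shape:
        raise ValueError("flat-field and offset shapes differ")
    if dr <= 0:
        raise ValueError("dynamic range must be positive")
    S = (F - O) / dr
    valid = S > 0
    return GainFrame(values=np.where(valid, S, np.nan), valid=valid)


def correct_image(R, O, S: GainFrame | np.ndarray) -> np.ndarray:
    """Corrected useful signal U = (R - O) / S; invalid pixels propagate as NaN."""
    R = np.asarray(R, dtype=float)
    O = np.asarray(O, dtype=float)
    gain = S if isinstance(S, GainFrame) else gain_frame_from_values(S)
    if R.shape != O.shape or R.shape != gain.values.shape:
        raise ValueError("image, offset and gain shapes differ")
    with np.errstate(invalid="ignore"):
        U = (R - O) / gain.values
    return np.where(gain.valid, U, np.nan)


def gain_frame_from_values(S) -> GainFrame:
    S = np.asarray(S, dtype=float)
    valid = np.isfinite(S) & (S > 0)
    return GainFrame(values=np.where(valid, S, np.nan), valid=valid)


def average_frames(stack) -> np.ndarray:
    """Per-pixel arithmetic mean of >= 1 equally shaped frames."""
    frames = np.asarray(stack, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("need a non-empty stack of 2-D frames")
    return frames.mean(axis=0)
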
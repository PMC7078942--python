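"""Raw detector frame corrections: averaging, dark subtraction, calibration.

The measurement chain is: acquire many short frames at a fixed integration
time, average them to beat down shot and read noise, subtract a matching
dark frame to remove the dark-current offset, then convert counts to dose
rate with a single linear gain derived from an ionization-chamber reference.
Negative post-subtraction values are clipped to zero (and flagged) so dose
maps stay physical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SensorFrame",
    "DoseImage",
    "average_frames",
    "subtract_dark",
    "derive_gain",
    "calibrate",
]


@dataclass
class SensorFrame:
    """A raw (or corrected) detector frame in counts.

    ``saturated_mask`` marks pixels that hit the ADC ceiling;
    ``clipped_mask`` marks pixels clipped to zero by dark subtraction.
    """

    counts: np.ndarray
    integration_time_ms: float
    pixel_pitch_um: float
    saturated_mask: np.ndarray | None = None
    clipped_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2D array")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite")
        if self.saturated_mask is None:
            self.saturated_mask = np.zeros(self.counts.shape, dtype=bool)
        else:
            self.saturated_mask = np.asarray(self.saturated_mask, dtype=bool)
            if self.saturated_mask.shape != self.counts.shape:
                raise ValueError("saturated_mask shape must match counts")
        if self.pixel_pitch_um <= 0 or self.integration_time_ms <= 0:
            raise ValueError("pixel pitch and integration time must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class DoseImage:
    """A calibrated 2D dose-rate map (mGy/min)."""

    dose_rate: np.ndarray
    sample_pitch_um: float
    calibration_gain: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dose_rate = np.asarray(self.dose_rate, dtype=float)
        if self.dose_rate.ndim != 2:
            raise ValueError("dose_rate must be a 2D array")
        if self.sample_pitch_um <= 0:
            raise ValueError("sample pitch must be positive")
        if self.calibration_gain <= 0:
            raise ValueError("calibration gain must be positive")


def average_frames(frames: Sequence[SensorFrame]) -> SensorFrame:
    """Pixelwise arithmetic mean of frames sharing shape and integration time.

    The saturated mask of the result is the union of the input masks (one
    saturated draw biases the mean).
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    first = frames[0]
    for f in frames[1:]:
        if f.shape != first.shape:
            raise ValueError("frames must share a common shape")
        if f.integration_time_ms != first.integration_time_ms:
            raise ValueError("frames must share a common integration time")
        if f.pixel_pitch_um != first.pixel_pitch_um:
            raise ValueError("frames must share a common pixel pitch")
    counts = np.mean([f.counts for f in frames], axis=0)
    saturated = np.logical_or.reduce([f.saturated_mask for f in frames])
    meta = {"n_averaged": len(frames), **first.meta}
    return SensorFrame(counts, first.integration_time_ms, first.pixel_pitch_um, saturated, meta=meta)


def subtract_dark(frame: SensorFrame, dark_frame: SensorFrame) -> SensorFrame:
    """Subtract a dark frame; negative results clip to 0 and are flagged."""
    if frame.shape != dark_frame.shape:
        raise ValueError("frame and dark frame must share a shape")
    if frame.integration_time_ms != dark_frame.integration_time_ms:
        raise ValueError("frame and dark frame must share an integration time")
    diff = frame.counts - dark_frame.counts
    clipped = diff < 0
    out = SensorFrame(
        np.clip(diff, 0.0, None),
        frame.integration_time_ms,
        frame.pixel_pitch_um,
        frame.saturated_mask | dark_frame.saturated_mask,
        meta={**frame.meta, "dark_subtracted": True},
    )
    out.clipped_mask = clipped
    return out


def derive_gain(
    frame: SensorFrame,
    dark_frame: SensorFrame,
    roi: tuple[slice, slice],
    reference_dose_rate: float,
) -> float:
    """Single-point linear gain (mGy/min per count-per-frame) from a known ROI.

    The mean dark-corrected signal inside ``roi`` is pinned to
    ``reference_dose_rate``; by construction calibrating the same frame with
    the returned gain reproduces the reference over the ROI exactly.
    """
    if reference_dose_rate <= 0:
        raise ValueError("reference dose rate must be positive")
    corrected = subtract_dark(frame, dark_frame)
    region = corrected.counts[roi]
    if region.size == 0:
        raise ValueError("ROI selects no pixels")
    mean = float(region.mean())
    if mean <= 0:
        raise ValueError("mean corrected signal in ROI must be positive")
    return reference_dose_rate / mean


def calibrate(frame: SensorFrame, gain: float) -> DoseImage:
    """Convert a dark-corrected frame to a dose-rate map via a linear gain."""
    if gain <= 0:
        raise ValueError("gain must be positive")
    return DoseImage(
        dose_rate=frame.counts * gain,
        sample_pitch_um=frame.pixel_pitch_um,
        calibration_gain=gain,
        meta={**frame.meta, "calibration_gain": gain},
    )
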
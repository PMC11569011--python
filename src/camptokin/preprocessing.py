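"""Raw-signal conditioning: Savitzky-Golay smoothing and confidence masking.

Gravity-projection inclination is only meaningful when the measured
acceleration magnitude is close to 1 g; samples outside a configurable
magnitude band are flagged, never dropped, so that all downstream series
stay sample-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from camptokin.io_formats import SENSORS, AccelRecording


@dataclass(frozen=True)
class SmoothingConfig:
    """Savitzky-Golay filter settings.

    The polynomial order is 3 by default; the window is specified in
    seconds and converted to an odd sample count at the recording's rate
    (1.0 s -> 129 samples at 128 Hz).
    """

    polynomial_order: int = 3
    window_s: float = 1.0
    sample_rate: float = 128.0

    @property
    def window_samples(self) -> int:
        n = int(round(self.window_s * self.sample_rate))
        if n % 2 == 0:
            n += 1
        return n

    def __post_init__(self) -> None:
        if self.polynomial_order < 0:
            raise ValueError("polynomial_order must be non-negative")
        if self.window_s <= 0 or self.sample_rate <= 0:
            raise ValueError("window_s and sample_rate must be positive")
        if self.window_samples <= self.polynomial_order:
            raise ValueError(
                f"window of {self.window_samples} samples must exceed "
                f"polynomial order {self.polynomial_order}"
            )


def savitzky_golay(channel: np.ndarray, cfg: SmoothingConfig) -> np.ndarray:
    """Smooth one acceleration channel, preserving length.

    Edges are handled by fitting the polynomial to the truncated
    first/last window and evaluating it there (no zero padding), so a
    polynomial of degree <= the filter order passes through unchanged.
    """
    channel = np.asarray(channel, dtype=float)
    n = channel.shape[0]
    w = cfg.window_samples
    if n < w:
        raise ValueError(f"series of {n} samples is shorter than window of {w}")
    return savgol_filter(channel, w, cfg.polynomial_order, mode="interp", axis=0)


def smooth_recording(rec: AccelRecording, cfg: SmoothingConfig | None = None) -> AccelRecording:
    """Apply :func:`savitzky_golay` to every channel of every sensor."""
    if cfg is None:
        cfg = SmoothingConfig(sample_rate=rec.sample_rate)
    channels = {s: savitzky_golay(rec.channels[s], cfg) for s in rec.sensors}
    return AccelRecording(
        sample_rate=rec.sample_rate,
        channels=channels,
        start_time=rec.start_time,
        sensors=rec.sensors,
    )


def flag_low_confidence(
    rec: AccelRecording, lo: float = 0.5, hi: float = 1.5
) -> dict[str, np.ndarray]:
    """Per-sensor boolean mask, True where the sample is low-confidence.

    A sample is flagged when its acceleration vector magnitude falls
    outside the closed interval [lo, hi] g — e.g. near-free-fall or
    impact transients, where the gravity direction cannot be read off
    the accelerometer.
    """
    if not lo < hi:
        raise ValueError(f"need lo < hi, got lo={lo}, hi={hi}")
    masks = {}
    for s in rec.sensors:
        mag = np.linalg.norm(rec.channels[s], axis=1)
        masks[s] = (mag < lo) | (mag > hi)
    return masks
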
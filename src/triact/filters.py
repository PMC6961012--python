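"""Signal decomposition filters.

Raw thigh acceleration mixes three components per axis: sensor noise, body
acceleration (BA) produced by movement, and gravitational acceleration (GA)
reflecting segment orientation.  A short moving average suppresses the noise;
a Butterworth high-pass isolates BA and a Butterworth low-pass isolates GA.

Filtering is zero-phase (forward–backward) by default: the analysis is
offline, and causal filtering would delay BA relative to GA and misalign the
two branches against the window grid.  A ``zero_phase=False`` switch gives
the causal variant.  The configured order is the per-pass design order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import AccelerometerRecording


@dataclass(frozen=True)
class FilterConstants:
    """Fixed preprocessing constants.

    ma_window: moving-average span in seconds (noise removal).
    hp_cutoff: high-pass cutoff in Hz (body-acceleration branch).
    lp_cutoff: low-pass cutoff in Hz (gravity branch).
    butterworth_order: per-pass design order of both Butterworth filters.
    zero_phase: forward–backward filtering when True, causal when False.
    """

    ma_window: float = 0.12
    hp_cutoff: float = 1.0
    lp_cutoff: float = 1.25
    butterworth_order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.ma_window <= 0:
            raise ValueError("ma_window must be > 0")
        if self.hp_cutoff <= 0 or self.lp_cutoff <= 0:
            raise ValueError("filter cutoffs must be > 0")
        if self.butterworth_order < 1:
            raise ValueError("butterworth_order must be >= 1")


def moving_average_window_samples(ma_window: float, sampling_rate: float) -> int:
    """Moving-average span in samples: round to nearest, then force odd.

    An odd span keeps the filter symmetric about each sample, so the moving
    average itself introduces no phase shift.
    """
    if ma_window <= 0:
        raise ValueError("ma_window must be > 0")
    k = int(round(ma_window * sampling_rate))
    if k < 1:
        raise ValueError(
            f"ma_window {ma_window} s yields an empty window at "
            f"{sampling_rate} Hz"
        )
    if k % 2 == 0:
        k += 1
    return k


def _centered_moving_average(x: np.ndarray, k: int) -> np.ndarray:
    """Centered mean over k samples; edges shrink to the available samples."""
    n = x.shape[0]
    h = k // 2
    csum = np.vstack([np.zeros((1, x.shape[1])), np.cumsum(x, axis=0)])
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)[:, None]


def moving_average_filter(
    recording: AccelerometerRecording, ma_window: float = 0.12
) -> AccelerometerRecording:
    """Noise-removal preprocessing: per-axis centered moving average."""
    k = moving_average_window_samples(ma_window, recording.sampling_rate)
    return recording.with_samples(_centered_moving_average(recording.samples, k))


def _butterworth(
    recording: AccelerometerRecording,
    cutoff: float,
    btype: str,
    order: int,
    zero_phase: bool,
) -> AccelerometerRecording:
    nyquist = recording.sampling_rate / 2.0
    if cutoff >= nyquist:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below the Nyquist frequency "
            f"{nyquist} Hz"
        )
    sos = signal.butter(
        order, cutoff, btype=btype, fs=recording.sampling_rate, output="sos"
    )
    if zero_phase:
        out = signal.sosfiltfilt(sos, recording.samples, axis=0)
    else:
        out = signal.sosfilt(sos, recording.samples, axis=0)
    return recording.with_samples(np.asarray(out))


def extract_body_acceleration(
    recording: AccelerometerRecording,
    constants: FilterConstants = FilterConstants(),
) -> AccelerometerRecording:
    """High-pass the (noise-filtered) signal to remove gravity, leaving BA."""
    return _butterworth(
        recording,
        constants.hp_cutoff,
        "highpass",
        constants.butterworth_order,
        constants.zero_phase,
    )


def extract_gravitational_acceleration(
    recording: AccelerometerRecording,
    constants: FilterConstants = FilterConstants(),
) -> AccelerometerRecording:
    """Low-pass the (noise-filtered) signal to remove movement, leaving GA."""
    return _butterworth(
        recording,
        constants.lp_cutoff,
        "lowpass",
        constants.butterworth_order,
        constants.zero_phase,
    )
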
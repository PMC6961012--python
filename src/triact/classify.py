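"""Windowed activity classification.

The filtered signal is cut into fixed, non-overlapping windows.  Per window,
two features drive a two-level decision tree:

* **SMA** (signal magnitude area) of the body acceleration — the rectified BA
  summed over all three axes and all samples of the window, divided by the
  window length, giving counts per second (cps).  One count is one g-second
  of rectified body acceleration; this makes cps comparable across window
  sizes and sampling rates.
* **mean gravity** per axis of the GA branch; the thigh-longitudinal (X)
  component encodes posture (≈ 1 g upright, ≈ 0 g reclined).

A window is DYNAMIC when SMA ≥ the physical-activity threshold (PA Th);
otherwise STANDING when the oriented X gravity component ≥ the sensor
orientation threshold (SO Th), else SEDENTARY.  Both boundary comparisons
use ≥ by convention; the boundary is measure-zero in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .filters import (
    FilterConstants,
    extract_body_acceleration,
    extract_gravitational_acceleration,
    moving_average_filter,
)
from .io import AccelerometerRecording, ActivityLabel


@dataclass(frozen=True)
class AlgorithmParameters:
    """The three adjustable classification parameters plus fixed constants.

    Defaults are the settings optimized for healthy elderly wearing the
    sensor on the upper leg: 2 s windows, 7 cps activity threshold, 0.8 g
    orientation threshold (thigh within ≈ 36° of vertical counts as
    standing).
    """

    window_size: float = 2.0
    pa_threshold: float = 7.0
    so_threshold: float = 0.8
    orientation_sign: int = 1
    count_scale: float = 1.0
    filter_constants: FilterConstants = field(default_factory=FilterConstants)

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be > 0")
        if self.pa_threshold <= 0:
            raise ValueError("pa_threshold must be > 0")
        if not 0 < self.so_threshold <= 1:
            raise ValueError("so_threshold must lie in (0, 1]")
        if self.orientation_sign not in (1, -1):
            raise ValueError("orientation_sign must be +1 or -1")
        if self.count_scale <= 0:
            raise ValueError("count_scale must be > 0")

    def replace(self, **changes) -> "AlgorithmParameters":
        return replace(self, **changes)


#: Starting parameter set of the predecessor algorithm (chronic organ
#: failure patients, upper-leg wear); the optimization sweeps start here.
LEGACY_PARAMETERS = AlgorithmParameters(
    window_size=1.0, pa_threshold=5.0, so_threshold=0.8
)


@dataclass(frozen=True)
class WindowFeatures:
    """Per-window classifier inputs."""

    index: int
    sma_cps: float
    ga_mean: tuple[float, float, float]
    n_samples: int


@dataclass
class ClassifiedSeries:
    """Per-window labels plus the features they were derived from.

    ``window_size`` is the effective window duration ``N / sampling_rate``
    in seconds (identical to the requested size whenever the requested size
    is a whole number of samples); ``dropped_tail`` is the trailing signal
    not covered by a complete window.
    """

    labels: list[ActivityLabel]
    window_size: float
    features: list[WindowFeatures]
    dropped_tail: float = 0.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.features):
            raise ValueError("labels and features must have equal length")
        if self.dropped_tail >= self.window_size:
            raise ValueError("dropped_tail must be smaller than window_size")

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one row per window, ready for CSV export."""
        rows = []
        for label, feat in zip(self.labels, self.features):
            start = feat.index * self.window_size
            rows.append(
                {
                    "window_index": feat.index,
                    "start_s": start,
                    "end_s": start + self.window_size,
                    "sma_cps": feat.sma_cps,
                    "ga_x": feat.ga_mean[0],
                    "ga_y": feat.ga_mean[1],
                    "ga_z": feat.ga_mean[2],
                    "label": label.value,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "window_index",
                "start_s",
                "end_s",
                "sma_cps",
                "ga_x",
                "ga_y",
                "ga_z",
                "label",
            ],
        )


def window_samples(window_size: float, sampling_rate: float) -> int:
    """Window length in samples, N = round(WS × rate); must be ≥ 1."""
    n = int(round(window_size * sampling_rate))
    if n < 1:
        raise ValueError(
            f"window_size {window_size} s holds no samples at "
            f"{sampling_rate} Hz"
        )
    return n


def segment_windows(
    signal_length: int, sampling_rate: float, window_size: float
) -> list[tuple[int, int]]:
    """Non-overlapping half-open sample ranges [jN, (j+1)N).

    The trailing partial window is discarded: the window features are only
    defined over complete windows.
    """
    n = window_samples(window_size, sampling_rate)
    count = signal_length // n
    return [(j * n, (j + 1) * n) for j in range(count)]


def compute_sma_cps(
    ba_window: np.ndarray, window_size: float, count_scale: float = 1.0
) -> float:
    """Signal magnitude area of a BA window, in counts per second.

    Rectified body acceleration summed over the three axes and all samples
    of the window, divided by the window length in seconds.
    """
    ba_window = np.asarray(ba_window, dtype=float)
    if ba_window.size == 0:
        raise ValueError("empty window")
    return float(np.sum(np.abs(ba_window)) / window_size * count_scale)


def compute_mean_gravity(ga_window: np.ndarray) -> tuple[float, float, float]:
    """Per-axis arithmetic mean of a GA window."""
    ga_window = np.asarray(ga_window, dtype=float)
    if ga_window.size == 0:
        raise ValueError("empty window")
    mean = ga_window.mean(axis=0)
    return (float(mean[0]), float(mean[1]), float(mean[2]))


def classify_window(
    features: WindowFeatures, params: AlgorithmParameters
) -> ActivityLabel:
    """Two-level decision tree: activity amount, then posture."""
    if features.sma_cps >= params.pa_threshold:
        return ActivityLabel.DYNAMIC
    if params.orientation_sign * features.ga_mean[0] >= params.so_threshold:
        return ActivityLabel.STANDING
    return ActivityLabel.SEDENTARY


def prepare_branches(
    recording: AccelerometerRecording,
    constants: FilterConstants = FilterConstants(),
) -> tuple[AccelerometerRecording, AccelerometerRecording]:
    """Run the filtering front-end once: (BA branch, GA branch).

    Useful when the same recording is classified repeatedly with different
    window sizes or thresholds (parameter sweeps): the filters do not depend
    on those parameters.
    """
    smoothed = moving_average_filter(recording, constants.ma_window)
    ba = extract_body_acceleration(smoothed, constants)
    ga = extract_gravitational_acceleration(smoothed, constants)
    return ba, ga


def classify_branches(
    ba: AccelerometerRecording,
    ga: AccelerometerRecording,
    params: AlgorithmParameters,
) -> ClassifiedSeries:
    """Window, featurize and label pre-filtered BA/GA branches."""
    rate = ba.sampling_rate
    n = window_samples(params.window_size, rate)
    eff_ws = n / rate
    count = ba.n_samples // n
    ba_s, ga_s = ba.samples, ga.samples

    features: list[WindowFeatures] = []
    labels: list[ActivityLabel] = []
    for j in range(count):
        sl = slice(j * n, (j + 1) * n)
        feat = WindowFeatures(
            index=j,
            sma_cps=compute_sma_cps(ba_s[sl], eff_ws, params.count_scale),
            ga_mean=compute_mean_gravity(ga_s[sl]),
            n_samples=n,
        )
        features.append(feat)
        labels.append(classify_window(feat, params))
    return ClassifiedSeries(
        labels=labels,
        window_size=eff_ws,
        features=features,
        dropped_tail=(ba.n_samples - count * n) / rate,
        subject_id=ba.subject_id,
    )


def classify_recording(
    recording: AccelerometerRecording,
    params: AlgorithmParameters = AlgorithmParameters(),
) -> ClassifiedSeries:
    """Full pipeline: smooth, split into BA/GA, window, featurize, label."""
    ba, ga = prepare_branches(recording, params.filter_constants)
    return classify_branches(ba, ga, params)


def class_totals(series: ClassifiedSeries) -> dict[ActivityLabel, float]:
    """Total classified seconds per class (window count × window duration)."""
    totals = {label: 0.0 for label in ActivityLabel}
    for label in series.labels:
        totals[label] += series.window_size
    return totals
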
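"""Recording / annotation I/O and core domain types.

Recordings are tri-axial acceleration time series in units of g (the sensor
reports ±8 g over three orthogonal axes).  The X axis is the thigh-longitudinal
axis, positive toward the hip, so upright standing projects gravity onto +X.
Gold-standard annotations are one activity label per second, mirroring an
event sheet produced by a human observer scoring video.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Hard sensor range in g; values beyond this indicate corrupt input.
SENSOR_RANGE_G = 8.0

_AXIS_HEADERS = ({"ax", "ay", "az"}, {"x", "y", "z"})


class FormatError(ValueError):
    """Input file does not conform to the expected layout."""


class RangeError(ValueError):
    """A sample lies outside the physical sensor range."""


class ActivityLabel(enum.Enum):
    """The three behaviour classes of the decision tree."""

    DYNAMIC = "dynamic"
    STANDING = "standing"
    SEDENTARY = "sedentary"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class AccelerometerRecording:
    """Raw or filtered tri-axial acceleration samples.

    Parameters
    ----------
    samples
        Array of shape ``(n, 3)`` with columns (ax, ay, az) in g.
    sampling_rate
        Sampling frequency in Hz, > 0.
    subject_id
        Opaque participant identifier.
    start_offset
        Offset of the first sample from the protocol start, in seconds.
    x_is_longitudinal
        Axis convention flag: X is thigh-longitudinal, positive toward the hip.
    """

    samples: np.ndarray
    sampling_rate: float
    subject_id: str = ""
    start_offset: float = 0.0
    x_is_longitudinal: bool = True

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError(
                f"samples must have shape (n, 3), got {self.samples.shape}"
            )
        if self.samples.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")
        if np.any(np.abs(self.samples) > SENSOR_RANGE_G):
            raise RangeError(
                f"sample magnitude exceeds sensor range ±{SENSOR_RANGE_G} g"
            )
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def with_samples(self, samples: np.ndarray) -> "AccelerometerRecording":
        """Copy of this recording with the sample array replaced."""
        return AccelerometerRecording(
            samples=samples,
            sampling_rate=self.sampling_rate,
            subject_id=self.subject_id,
            start_offset=self.start_offset,
            x_is_longitudinal=self.x_is_longitudinal,
        )


@dataclass
class AnnotationSeries:
    """Per-second gold-standard labels, second ``t`` covering ``[t, t+1)``."""

    labels: list[ActivityLabel] = field(default_factory=list)
    observer_id: str = ""

    def __post_init__(self) -> None:
        self.labels = [ActivityLabel(l) for l in self.labels]
        if len(self.labels) < 1:
            raise ValueError("annotation series must contain at least one label")

    def __len__(self) -> int:
        return len(self.labels)


def _sampling_rate_from_header(path) -> float | None:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if body.startswith("sampling_rate_hz="):
                return float(body.split("=", 1)[1])
    return None


def read_recording_csv(
    path, sampling_rate: float | None = None, subject_id: str = ""
) -> AccelerometerRecording:
    """Read a recording CSV (columns ``ax,ay,az`` or ``x,y,z``, values in g).

    The sampling rate comes from the ``sampling_rate`` argument; if omitted, a
    ``# sampling_rate_hz=<rate>`` header comment is used.  The argument wins
    when both are present.
    """
    if sampling_rate is None:
        sampling_rate = _sampling_rate_from_header(path)
        if sampling_rate is None:
            raise FormatError(
                f"{path}: no sampling rate given and no "
                "'# sampling_rate_hz=' header comment found"
            )
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    cols = {c.strip().lower(): c for c in df.columns}
    for wanted in _AXIS_HEADERS:
        if wanted <= set(cols):
            order = sorted(wanted)  # ax,ay,az / x,y,z sort into axis order
            break
    else:
        raise FormatError(
            f"{path}: expected axis columns ax,ay,az (or x,y,z); "
            f"found {list(df.columns)}"
        )
    data = np.empty((len(df), 3), dtype=float)
    for k, name in enumerate(order):
        raw = df[cols[name]]
        numeric = pd.to_numeric(raw, errors="coerce")
        bad = numeric.isna() & raw.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: non-numeric value {raw.iloc[row]!r} in column "
                f"{cols[name]!r}, data row {row}"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise FormatError(f"{path}: empty cell in column {cols[name]!r}, data row {row}")
        data[:, k] = numeric.to_numpy()
    over = np.abs(data) > SENSOR_RANGE_G
    if over.any():
        row = int(np.flatnonzero(over.any(axis=1))[0])
        raise RangeError(
            f"{path}: value outside ±{SENSOR_RANGE_G} g at data row {row}"
        )
    return AccelerometerRecording(
        samples=data, sampling_rate=float(sampling_rate), subject_id=subject_id
    )


def write_recording_csv(recording: AccelerometerRecording, path) -> None:
    """Write a recording to CSV, lossless to double precision on round-trip."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# sampling_rate_hz={recording.sampling_rate:.17g}\n")
        fh.write("ax,ay,az\n")
        for row in recording.samples:
            fh.write(f"{row[0]:.17g},{row[1]:.17g},{row[2]:.17g}\n")


def read_annotation_csv(path, observer_id: str = "") -> AnnotationSeries:
    """Read a per-second annotation sheet (columns ``second,label``)."""
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    cols = {c.strip().lower(): c for c in df.columns}
    if not {"second", "label"} <= set(cols):
        raise FormatError(
            f"{path}: expected columns second,label; found {list(df.columns)}"
        )
    seconds = pd.to_numeric(df[cols["second"]], errors="coerce")
    if seconds.isna().any():
        row = int(np.flatnonzero(seconds.isna().to_numpy())[0])
        raise FormatError(f"{path}: non-numeric second at data row {row}")
    seconds = seconds.to_numpy()
    expected = np.arange(len(seconds))
    if not np.array_equal(seconds, expected):
        row = int(np.flatnonzero(seconds != expected)[0])
        raise FormatError(
            f"{path}: 'second' must run 0,1,2,... without gaps or duplicates; "
            f"first bad index at data row {row} (got {seconds[row]})"
        )
    labels = []
    for i, raw in enumerate(df[cols["label"]]):
        try:
            labels.append(ActivityLabel(str(raw).strip().lower()))
        except ValueError:
            raise FormatError(
                f"{path}: unknown activity label {raw!r} at data row {i}; "
                "expected dynamic, standing or sedentary"
            ) from None
    return AnnotationSeries(labels=labels, observer_id=observer_id)


def write_annotation_csv(series: AnnotationSeries, path) -> None:
    """Write an annotation series as a ``second,label`` sheet."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("second,label\n")
        for i, label in enumerate(series.labels):
            fh.write(f"{i},{label.value}\n")


def annotation_totals(series: AnnotationSeries) -> dict[ActivityLabel, int]:
    """Total annotated seconds per class; totals sum to ``len(series)``."""
    totals = {label: 0 for label in ActivityLabel}
    for label in series.labels:
        totals[label] += 1
    return totals
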
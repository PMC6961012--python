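"""Synthetic thigh-accelerometer recordings with per-second gold labels.

Each activity segment is modelled as a constant gravity vector rotated with
thigh posture (longitudinal component ``g_x = cos(thigh_angle)``; the
mediolateral axis carries no gravity by default, so the vector stays in the
X–Z plane), plus — for dynamic segments — gait-band sinusoids at the stride
frequency and its first harmonic, plus white Gaussian sensor noise.

The sinusoid amplitudes are calibrated empirically: a unit-amplitude probe
segment is pushed through the pipeline's own moving-average and high-pass
filters and its measured counts-per-second fixes the scale, so a requested
``ba_intensity`` of, say, 15 cps actually measures ≈ 15 cps after filtering.

Two protocol builders mirror validation study designs: a fixed protocol
(prescribed activity order and durations covering walking at two speeds,
overground walking, biking, standing, sitting and lying) and a simulated
free-living protocol (randomized activities of daily living with short
dynamic transfers between them).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np

from .classify import compute_sma_cps, segment_windows
from .filters import FilterConstants, extract_body_acceleration, moving_average_filter
from .io import AccelerometerRecording, ActivityLabel, AnnotationSeries

DEFAULT_SAMPLING_RATE = 25.0
#: Default white-noise SD in g; keeps static-segment activity well below
#: the smallest threshold ever swept (3 cps).
DEFAULT_NOISE_SD = 0.01


@dataclass(frozen=True)
class ActivitySegmentSpec:
    """One homogeneous activity bout.

    thigh_angle is the angle in degrees between the thigh's longitudinal
    axis and the gravity vector (0° = upright), so the longitudinal gravity
    component is cos(thigh_angle).  ba_intensity is the target body
    acceleration in cps as measured through the pipeline's own filters;
    gait_frequency is the fundamental of the movement in Hz.
    """

    label: ActivityLabel
    duration: float
    thigh_angle: float = 0.0
    ba_intensity: float = 0.0
    gait_frequency: float = 1.6
    noise_sd: float = DEFAULT_NOISE_SD
    mediolateral_angle: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if not 0 <= self.thigh_angle <= 180:
            raise ValueError("thigh_angle must lie in [0, 180] degrees")
        if self.ba_intensity < 0:
            raise ValueError("ba_intensity must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.gait_frequency <= 0:
            raise ValueError("gait_frequency must be > 0")


@dataclass(frozen=True)
class ProtocolSpec:
    """An ordered sequence of segments plus sampling configuration."""

    segments: tuple[ActivitySegmentSpec, ...]
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.segments) == 0:
            raise ValueError("protocol must contain at least one segment")

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)


# relative amplitudes of the gait waveform per axis: longitudinal and
# anteroposterior at the fundamental, vertical/harmonic content on top
_WAVE_COMPONENTS = (
    # (axis, harmonic multiple, relative amplitude)
    (0, 1, 1.0),
    (0, 2, 0.4),
    (1, 1, 0.5),
    (2, 1, 0.5),
    (2, 2, 0.3),
)


def _gait_waveform(
    n: int, sampling_rate: float, gait_frequency: float, phases: np.ndarray
) -> np.ndarray:
    t = np.arange(n) / sampling_rate
    out = np.zeros((n, 3))
    for idx, (axis, mult, amp) in enumerate(_WAVE_COMPONENTS):
        out[:, axis] += amp * np.sin(
            2.0 * np.pi * mult * gait_frequency * t + phases[idx]
        )
    return out


@functools.lru_cache(maxsize=64)
def _unit_waveform_cps(
    sampling_rate: float, gait_frequency: float, constants: FilterConstants
) -> float:
    """Measured cps of the unit-amplitude gait waveform after MA + HP.

    A 40 s probe with fixed phases is filtered exactly as the classifier
    filters real data; the mean SMA over interior 2 s windows (excluding
    2 s edge guards) gives the cps per unit amplitude.
    """
    n = int(round(40.0 * sampling_rate))
    phases = np.linspace(0.0, 2.0 * np.pi, len(_WAVE_COMPONENTS), endpoint=False)
    probe = _gait_waveform(n, sampling_rate, gait_frequency, phases)
    rec = AccelerometerRecording(samples=probe, sampling_rate=sampling_rate)
    ba = extract_body_acceleration(
        moving_average_filter(rec, constants.ma_window), constants
    )
    guard = int(round(2.0 * sampling_rate))
    core = ba.samples[guard:-guard]
    windows = segment_windows(core.shape[0], sampling_rate, 2.0)
    cps = [compute_sma_cps(core[a:b], 2.0) for a, b in windows]
    return float(np.mean(cps))


def generate_segment(
    spec: ActivitySegmentSpec,
    sampling_rate: float,
    rng: np.random.Generator,
    constants: FilterConstants = FilterConstants(),
) -> tuple[np.ndarray, list[ActivityLabel]]:
    """Generate one segment's samples and its per-second labels."""
    nyquist = sampling_rate / 2.0
    if 2.0 * spec.gait_frequency >= nyquist and spec.ba_intensity > 0:
        raise ValueError(
            f"gait frequency {spec.gait_frequency} Hz (with harmonic) must "
            f"stay below the Nyquist frequency {nyquist} Hz"
        )
    n = int(round(spec.duration * sampling_rate))
    theta = np.deg2rad(spec.thigh_angle)
    phi = np.deg2rad(spec.mediolateral_angle)
    gravity = np.array(
        [
            np.cos(theta),
            np.sin(theta) * np.sin(phi),
            np.sin(theta) * np.cos(phi),
        ]
    )
    samples = np.tile(gravity, (n, 1))
    if spec.ba_intensity > 0:
        unit_cps = _unit_waveform_cps(
            float(sampling_rate), float(spec.gait_frequency), constants
        )
        amplitude = spec.ba_intensity / unit_cps
        phases = rng.uniform(0.0, 2.0 * np.pi, size=len(_WAVE_COMPONENTS))
        samples = samples + amplitude * _gait_waveform(
            n, sampling_rate, spec.gait_frequency, phases
        )
    if spec.noise_sd > 0:
        samples = samples + rng.normal(0.0, spec.noise_sd, size=(n, 3))
    labels = [spec.label] * int(round(spec.duration))
    return samples, labels


def generate_protocol(
    protocol: ProtocolSpec, subject_id: str = ""
) -> tuple[AccelerometerRecording, AnnotationSeries]:
    """Materialize a protocol into a recording and its annotation sheet."""
    rng = np.random.default_rng(protocol.seed)
    chunks: list[np.ndarray] = []
    labels: list[ActivityLabel] = []
    for spec in protocol.segments:
        samples, seg_labels = generate_segment(spec, protocol.sampling_rate, rng)
        chunks.append(samples)
        labels.extend(seg_labels)
    recording = AccelerometerRecording(
        samples=np.vstack(chunks),
        sampling_rate=protocol.sampling_rate,
        subject_id=subject_id,
    )
    return recording, AnnotationSeries(labels=labels)


def fap_segments() -> tuple[ActivitySegmentSpec, ...]:
    """The fixed protocol: prescribed order and durations.

    Dynamic activities (two treadmill speeds, overground walking, biking),
    standing, and two sedentary postures; totals 480 s dynamic, 120 s
    standing, 300 s sedentary.
    """
    D, S, Z = ActivityLabel.DYNAMIC, ActivityLabel.STANDING, ActivityLabel.SEDENTARY
    return (
        ActivitySegmentSpec(S, 120, thigh_angle=5.0),
        ActivitySegmentSpec(D, 120, thigh_angle=12.0, ba_intensity=8.0, gait_frequency=1.4),
        ActivitySegmentSpec(D, 120, thigh_angle=12.0, ba_intensity=18.0, gait_frequency=1.9),
        ActivitySegmentSpec(D, 120, thigh_angle=12.0, ba_intensity=15.0, gait_frequency=1.7),
        ActivitySegmentSpec(D, 120, thigh_angle=60.0, ba_intensity=12.0, gait_frequency=1.3),
        ActivitySegmentSpec(Z, 180, thigh_angle=85.0),
        ActivitySegmentSpec(Z, 120, thigh_angle=90.0),
    )


def generate_fap(
    seed: int,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    segments: tuple[ActivitySegmentSpec, ...] | None = None,
) -> tuple[AccelerometerRecording, AnnotationSeries]:
    """Fixed-protocol recording; annotation totals equal the segment durations."""
    protocol = ProtocolSpec(
        segments=segments if segments is not None else fap_segments(),
        sampling_rate=sampling_rate,
        seed=seed,
    )
    return generate_protocol(protocol, subject_id=f"fap-{seed}")


def sfp_segments(
    rng: np.random.Generator,
    n_adls: int = 10,
    mixed_adl: bool = False,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> tuple[ActivitySegmentSpec, ...]:
    """Randomized free-living sequence of ADL-like bouts.

    ADL durations are uniform on 20–180 s with mixed classes; a short
    (5–15 s) dynamic transfer is inserted between consecutive non-dynamic
    bouts, emulating walking between activity stations.  With
    ``mixed_adl=True``, dynamic bouts interleave 2–5 s standing micro-pauses
    that keep the DYNAMIC gold label — the household-chore pattern (e.g.
    setting a table) that a per-ADL rater definition scores as one dynamic
    block even though the signal alternates.
    """
    if n_adls < 1:
        raise ValueError("n_adls must be >= 1")
    D, S, Z = ActivityLabel.DYNAMIC, ActivityLabel.STANDING, ActivityLabel.SEDENTARY
    segments: list[ActivitySegmentSpec] = []

    def add_dynamic(duration: float, label: ActivityLabel = D) -> None:
        spec = ActivitySegmentSpec(
            label,
            duration,
            thigh_angle=float(rng.uniform(5.0, 20.0)),
            ba_intensity=float(rng.uniform(8.0, 18.0)),
            gait_frequency=float(rng.uniform(1.3, 2.0)),
            noise_sd=noise_sd,
        )
        segments.append(spec)

    for _ in range(n_adls):
        label = [D, S, Z][int(rng.integers(0, 3))]
        duration = float(rng.integers(20, 181))
        if (
            label is not D
            and segments
            and segments[-1].label is not D
        ):
            add_dynamic(float(rng.integers(5, 16)))
        if label is D:
            if mixed_adl:
                remaining = duration
                while remaining > 0:
                    burst = min(float(rng.integers(6, 15)), remaining)
                    add_dynamic(burst)
                    remaining -= burst
                    if remaining >= 2:
                        pause = min(float(rng.integers(2, 6)), remaining)
                        segments.append(
                            ActivitySegmentSpec(
                                D,
                                pause,
                                thigh_angle=float(rng.uniform(2.0, 10.0)),
                                ba_intensity=0.0,
                                noise_sd=noise_sd,
                            )
                        )
                        remaining -= pause
            else:
                add_dynamic(duration)
        elif label is S:
            segments.append(
                ActivitySegmentSpec(
                    S,
                    duration,
                    thigh_angle=float(rng.uniform(2.0, 12.0)),
                    noise_sd=noise_sd,
                )
            )
        else:
            segments.append(
                ActivitySegmentSpec(
                    Z,
                    duration,
                    thigh_angle=float(rng.uniform(75.0, 105.0)),
                    noise_sd=noise_sd,
                )
            )
    return tuple(segments)


def generate_sfp(
    seed: int,
    n_adls: int = 10,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    mixed_adl: bool = False,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> tuple[AccelerometerRecording, AnnotationSeries]:
    """Simulated free-living recording with a seeded random ADL sequence."""
    rng = np.random.default_rng(seed)
    segments = sfp_segments(rng, n_adls=n_adls, mixed_adl=mixed_adl, noise_sd=noise_sd)
    protocol = ProtocolSpec(
        segments=segments, sampling_rate=sampling_rate, seed=int(rng.integers(2**31))
    )
    return generate_protocol(protocol, subject_id=f"sfp-{seed}")


def separation_segments(
    dynamic_cps: float = 12.0,
    noise_sd: float = 0.07,
    bout_s: float = 120.0,
) -> tuple[ActivitySegmentSpec, ...]:
    """A parameter-recovery benchmark protocol with clean class separation.

    Long alternating bouts (much longer than any candidate window) whose
    dynamic activity sits at ``dynamic_cps`` while the noise level puts
    static bouts near 2 cps, so any activity threshold between the two
    levels classifies perfectly and the optimizer should land on the
    plateau between them.
    """
    D, S, Z = ActivityLabel.DYNAMIC, ActivityLabel.STANDING, ActivityLabel.SEDENTARY
    return (
        ActivitySegmentSpec(S, bout_s, thigh_angle=5.0, noise_sd=noise_sd),
        ActivitySegmentSpec(
            D, bout_s, thigh_angle=10.0, ba_intensity=dynamic_cps,
            gait_frequency=1.4, noise_sd=noise_sd,
        ),
        ActivitySegmentSpec(Z, bout_s, thigh_angle=85.0, noise_sd=noise_sd),
        ActivitySegmentSpec(
            D, bout_s, thigh_angle=10.0, ba_intensity=dynamic_cps,
            gait_frequency=1.8, noise_sd=noise_sd,
        ),
        ActivitySegmentSpec(S, bout_s, thigh_angle=8.0, noise_sd=noise_sd),
        ActivitySegmentSpec(Z, bout_s, thigh_angle=90.0, noise_sd=noise_sd),
    )


def generate_separation_cohort(
    seed: int,
    n: int = 5,
    dynamic_cps: float = 12.0,
    noise_sd: float = 0.07,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> list[tuple[AccelerometerRecording, AnnotationSeries]]:
    """Cohort of recovery-benchmark recordings (see separation_segments)."""
    segments = separation_segments(dynamic_cps=dynamic_cps, noise_sd=noise_sd)
    out = []
    for i, s in enumerate(cohort_seeds(seed, n)):
        protocol = ProtocolSpec(segments=segments, sampling_rate=sampling_rate, seed=s)
        out.append(generate_protocol(protocol, subject_id=f"sep-{seed}-{i}"))
    return out


def cohort_seeds(seed: int, n: int) -> list[int]:
    """Derive n reproducible per-participant seeds (< 2^31) from one seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s % 2**31) for s in ss.generate_state(n, dtype=np.uint64)]


def generate_cohort(
    protocol: str,
    n: int,
    seed: int,
    **kwargs,
) -> list[tuple[AccelerometerRecording, AnnotationSeries]]:
    """Generate n participants under ``protocol`` ("fap" or "sfp")."""
    makers = {"fap": generate_fap, "sfp": generate_sfp}
    if protocol not in makers:
        raise ValueError(f"unknown protocol {protocol!r}; expected 'fap' or 'sfp'")
    return [makers[protocol](s, **kwargs) for s in cohort_seeds(seed, n)]
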
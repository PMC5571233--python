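"""Synthetic cohorts of labeled waist-accelerometer recordings.

The study population this generator emulates — able-bodied controls plus
patients recorded with two different knee-ankle-foot orthoses (a passive
stance-control brace and a microprocessor-controlled one) — was never
deposited, so downstream stages are exercised on synthetic signals with the
same hierarchical structure: activity signatures, subject-level variation,
device-level variation, and session-to-session wobble.

Signal model
------------
Each activity contributes a rotated gravity vector plus, for dynamic
activities, a sum of three harmonics of a cadence fundamental, plus white
noise:

    a(t) = R g * 1g  +  sum_k A[:, k] sin(2 pi k f t + phi_k + psi)  +  eps(t)

Subject effects scale amplitudes, shift cadence, and jitter the sensor
orientation. Device effects are parameterized by a *distortion coordinate*
c (none = 0, control brace = 0.5, novel brace = 1.0) scaled by the
``delta_device`` effect size: the coordinate drives a posture tilt, per-
activity amplitude and cadence factors (strongest on the stairs classes,
whose cadence under the novel brace drifts toward walking cadence), and a
harmonic-redistribution "pattern shift" on stairs. Setting both effect
sizes to zero makes every subject's generative parameters identical.

All randomness flows from one integer seed through named
``numpy.random.SeedSequence`` substreams keyed by (seed, stream, subject,
device, session), so adding a subject never perturbs another subject's data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io import ACTIVITIES, DEFAULT_SAMPLE_RATE_HZ, Cohort, LabelInterval, Recording, ValidationError

STATIC_ACTIVITIES = ("sit", "stand")
DYNAMIC_ACTIVITIES = ("walk", "stairs_up", "stairs_down")
STAIRS_ACTIVITIES = ("stairs_up", "stairs_down")

#: distortion coordinate per device: how far a device pushes gait away from
#: unassisted movement. The control brace sits midway because wearing any
#: KAFO already alters gait; the novel brace is furthest from no-device gait.
DEVICE_COORDINATE = {"none": 0.0, "control": 0.5, "novel": 1.0}

# log-scale device effect slopes per activity (amplitude, cadence) and the
# posture tilt in degrees, all multiplied by coordinate * delta_device
_AMP_SLOPE = {"sit": 0.0, "stand": 0.0, "walk": 0.10, "stairs_up": 0.30, "stairs_down": 0.25}
_CADENCE_SLOPE = {"sit": 0.0, "stand": 0.0, "walk": 0.04, "stairs_up": 0.32, "stairs_down": 0.20}
_TILT_DEG = 10.0
_PATTERN_SHIFT = 0.5  # stairs harmonic redistribution per unit coordinate*delta

# subject-effect scales per unit delta_subject
_SUBJ_LOG_AMP_SD = 0.25
_SUBJ_CADENCE_SD_HZ = 0.15
_SUBJ_ORIENT_JITTER_SD_DEG = 8.0
_SUBJ_DEVICE_RESPONSE_SD = 0.08  # per-(subject, device) log-factor jitter
_SESSION_WOBBLE_DEG = 3.0  # per-session orientation wobble

# named substreams
_STREAM_SUBJECT = 101
_STREAM_DEVICE = 202
_STREAM_SESSION = 303


@dataclass(frozen=True)
class ActivityModel:
    """Generative signature of one activity (before subject/device effects)."""

    activity: str
    gravity_orientation: np.ndarray  # unit 3-vector, sensor frame
    cadence_hz: float
    harmonic_amps: np.ndarray  # (3 axes, 3 harmonics), g
    noise_sd: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "gravity_orientation", _unit(np.asarray(self.gravity_orientation, float))
        )
        object.__setattr__(self, "harmonic_amps", np.asarray(self.harmonic_amps, float))
        if self.activity in STATIC_ACTIVITIES:
            if self.cadence_hz != 0:
                raise ValidationError(f"{self.activity} must have zero cadence")
        elif self.cadence_hz <= 0:
            raise ValidationError(f"{self.activity} must have positive cadence")
        if np.any(self.harmonic_amps < 0):
            raise ValidationError("harmonic amplitudes must be >= 0")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")


@dataclass(frozen=True)
class SubjectEffect:
    """Idiosyncratic movement style of one subject."""

    amp_scale: float = 1.0
    cadence_shift_hz: float = 0.0
    orientation_jitter_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.amp_scale <= 0:
            raise ValidationError("amp_scale must be > 0")
        if self.orientation_jitter_deg < 0:
            raise ValidationError("orientation_jitter_deg must be >= 0")


@dataclass(frozen=True)
class DeviceEffect:
    """How wearing a given orthosis distorts each activity's signature."""

    device: str
    amp_factor: Mapping[str, float]
    cadence_factor: Mapping[str, float]
    stairs_pattern_shift: float
    tilt_deg: float = 0.0
    tilt_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        for act in ACTIVITIES:
            if self.amp_factor[act] <= 0 or self.cadence_factor[act] <= 0:
                raise ValidationError("device factors must be > 0")
        if self.stairs_pattern_shift < 0:
            raise ValidationError("stairs_pattern_shift must be >= 0")
        if self.device == "none":
            if any(self.amp_factor[a] != 1 or self.cadence_factor[a] != 1 for a in ACTIVITIES):
                raise ValidationError("device 'none' must have unit factors")
            if self.stairs_pattern_shift != 0 or self.tilt_deg != 0:
                raise ValidationError("device 'none' must have no shift or tilt")


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults mirror the emulated protocol: 11 healthy subjects (3 sessions,
    no device) and 11 patients (3 sessions with each of two braces), each
    session a scripted sit/stand/walk/stairs sequence with stairs classes
    underrepresented relative to walking.
    """

    n_healthy: int = 11
    n_patients: int = 11
    sessions_per_condition: int = 3
    durations_s: Mapping[str, float] = field(
        default_factory=lambda: {
            "sit": 60.0,
            "stand": 60.0,
            "walk": 120.0,
            "stairs_up": 20.0,
            "stairs_down": 20.0,
        }
    )
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    seed: int = 0
    delta_subject: float = 1.0
    delta_device: float = 1.0

    def __post_init__(self) -> None:
        if self.n_healthy < 0 or self.n_patients < 0:
            raise ValidationError("subject counts must be non-negative")
        if self.sessions_per_condition < 1:
            raise ValidationError("sessions_per_condition must be >= 1")
        if self.delta_subject < 0 or self.delta_device < 0:
            raise ValidationError("effect sizes must be >= 0")
        for act in ("sit", "stand", "walk"):
            if self.durations_s[act] < 30.0:
                raise ValidationError(
                    f"protocol requires >= 30 s of {act}, got {self.durations_s[act]}"
                )
        for act in ACTIVITIES:
            if self.durations_s[act] <= 0:
                raise ValidationError(f"duration of {act} must be > 0")


def default_activity_models() -> dict[str, ActivityModel]:
    """The five activity signatures used by default.

    Sitting and standing differ only in trunk pitch (>=30 degrees apart);
    walking is a 1.8 Hz harmonic pattern, stair ascent/descent sit at 1.2
    and 1.4 Hz with distinct per-axis amplitude ratios.
    """
    deg = math.radians
    upright = np.array([0.0, 1.0, 0.0])
    return {
        "sit": ActivityModel(
            "sit",
            np.array([math.sin(deg(50)), math.cos(deg(50)), 0.0]),  # reclined trunk
            0.0,
            np.zeros((3, 3)),
            noise_sd=0.02,
        ),
        "stand": ActivityModel("stand", upright, 0.0, np.zeros((3, 3)), noise_sd=0.03),
        "walk": ActivityModel(
            "walk",
            _unit(np.array([0.08, 0.99, 0.05])),
            1.8,
            np.array(
                [
                    [0.25, 0.10, 0.04],
                    [0.35, 0.15, 0.06],
                    [0.20, 0.08, 0.03],
                ]
            ),
            noise_sd=0.08,
        ),
        "stairs_up": ActivityModel(
            "stairs_up",
            _unit(np.array([0.25, 0.95, 0.08])),  # forward lean
            1.2,
            np.array(
                [
                    [0.15, 0.12, 0.05],
                    [0.30, 0.18, 0.09],
                    [0.25, 0.06, 0.02],
                ]
            ),
            noise_sd=0.08,
        ),
        "stairs_down": ActivityModel(
            "stairs_down",
            _unit(np.array([-0.20, 0.96, 0.10])),  # slight backward lean
            1.4,
            np.array(
                [
                    [0.20, 0.05, 0.08],
                    [0.40, 0.10, 0.03],
                    [0.15, 0.12, 0.04],
                ]
            ),
            noise_sd=0.08,
        ),
    }


# ---------------------------------------------------------------------------
# effect construction


def subject_effect(seed: int, subject_index: int, delta_subject: float) -> SubjectEffect:
    """Deterministic subject idiosyncrasy, scaled by ``delta_subject``."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, _STREAM_SUBJECT, subject_index)))
    return SubjectEffect(
        amp_scale=float(np.exp(delta_subject * rng.normal(0.0, _SUBJ_LOG_AMP_SD))),
        cadence_shift_hz=float(delta_subject * rng.normal(0.0, _SUBJ_CADENCE_SD_HZ)),
        orientation_jitter_deg=float(
            delta_subject * abs(rng.normal(0.0, _SUBJ_ORIENT_JITTER_SD_DEG))
        ),
    )


def device_effect(
    device: str,
    delta_device: float,
    *,
    seed: int | None = None,
    subject_index: int | None = None,
    delta_subject: float = 0.0,
) -> DeviceEffect:
    """Device distortion at coordinate ``DEVICE_COORDINATE[device]``.

    When a subject context is given, a small per-(subject, device) response
    jitter (scaled by ``delta_subject``) is layered on top: two patients do
    not respond to the same brace identically.
    """
    c = DEVICE_COORDINATE[device] * delta_device
    jitter = {act: 0.0 for act in ACTIVITIES}
    if seed is not None and subject_index is not None and c > 0 and delta_subject > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence(
                (seed, _STREAM_DEVICE, subject_index, _device_code(device))
            )
        )
        for act in DYNAMIC_ACTIVITIES:
            jitter[act] = float(delta_subject * rng.normal(0.0, _SUBJ_DEVICE_RESPONSE_SD))
    amp = {act: math.exp(c * _AMP_SLOPE[act] + jitter[act]) for act in ACTIVITIES}
    cad = {act: math.exp(c * _CADENCE_SLOPE[act]) for act in ACTIVITIES}
    return DeviceEffect(
        device=device,
        amp_factor=amp,
        cadence_factor=cad,
        stairs_pattern_shift=c * _PATTERN_SHIFT,
        tilt_deg=c * _TILT_DEG,
        tilt_axis=np.array([0.0, 0.0, 1.0]),
    )


def effective_parameters(
    model: ActivityModel, subject: SubjectEffect, device: DeviceEffect
) -> dict:
    """Resolved per-segment generative parameters (useful for tests/inspection)."""
    cadence = 0.0
    if model.activity in DYNAMIC_ACTIVITIES:
        cadence = max(
            0.1, model.cadence_hz * device.cadence_factor[model.activity] + subject.cadence_shift_hz
        )
    amps = model.harmonic_amps * subject.amp_scale * device.amp_factor[model.activity]
    if model.activity in STAIRS_ACTIVITIES and device.stairs_pattern_shift > 0:
        r = math.tanh(device.stairs_pattern_shift)
        amps = amps.copy()
        amps[:, 0] *= 1.0 - 0.35 * r
        amps[:, 1:] *= 1.0 + 0.8 * r
    gravity = _rotate(model.gravity_orientation, device.tilt_axis, math.radians(device.tilt_deg))
    return {"cadence_hz": cadence, "harmonic_amps": amps, "gravity": gravity}


# ---------------------------------------------------------------------------
# synthesis


def synthesize_activity_segment(
    model: ActivityModel,
    subject: SubjectEffect,
    device: DeviceEffect,
    duration_s: float,
    sample_rate_hz: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Synthesize one labeled segment as an (n, 3) array of accelerations in g.

    n = round(duration * rate). Static activities are gravity + noise only.
    The subject's orientation jitter (plus a small session wobble) is applied
    as a random rotation drawn from ``rng``.
    """
    n = int(round(duration_s * sample_rate_hz))
    if n == 0:
        return np.zeros((0, 3))
    params = effective_parameters(model, subject, device)
    # per-call orientation: subject jitter magnitude about a random axis,
    # plus session wobble, both drawn from the segment's own substream
    angle = math.radians(subject.orientation_jitter_deg + abs(rng.normal(0.0, _SESSION_WOBBLE_DEG)))
    axis = _unit(rng.normal(size=3))
    gravity = _rotate(params["gravity"], axis, angle)
    t = np.arange(n) / sample_rate_hz
    acc = np.tile(gravity, (n, 1))
    if model.activity in DYNAMIC_ACTIVITIES:
        f = params["cadence_hz"]
        amps = params["harmonic_amps"]
        phase = rng.uniform(0, 2 * np.pi)
        axis_phase = np.array([0.0, np.pi / 2, np.pi / 4])  # fixed inter-axis lags
        for k in range(3):
            arg = 2 * np.pi * (k + 1) * f * t[:, None] + phase * (k + 1) + axis_phase[None, :]
            acc += amps[None, :, k] * np.sin(arg)
    acc += rng.normal(0.0, model.noise_sd, size=(n, 3))
    return acc


def sample_recording(
    spec: CohortSpec,
    models: Mapping[str, ActivityModel],
    subject_id: str,
    group: str,
    device: str,
    session_index: int,
    subject_index: int,
) -> Recording:
    """One scripted session: sit, stand, walk, stairs_up, stairs_down."""
    subj = subject_effect(spec.seed, subject_index, spec.delta_subject)
    dev = device_effect(
        device,
        spec.delta_device,
        seed=spec.seed,
        subject_index=subject_index,
        delta_subject=spec.delta_subject,
    )
    rate = spec.sample_rate_hz
    segments = []
    labels = []
    t_cursor = 0.0
    for seg_idx, act in enumerate(ACTIVITIES):
        rng = np.random.default_rng(
            np.random.SeedSequence(
                (
                    spec.seed,
                    _STREAM_SESSION,
                    subject_index,
                    _device_code(device),
                    session_index,
                    seg_idx,
                )
            )
        )
        dur = float(spec.durations_s[act])
        seg = synthesize_activity_segment(models[act], subj, dev, dur, rate, rng)
        segments.append(seg)
        labels.append(LabelInterval(t_cursor, t_cursor + len(seg) / rate, act))
        t_cursor += len(seg) / rate
    acc = np.vstack(segments)
    t = np.arange(len(acc)) / rate
    return Recording(
        subject_id=subject_id,
        group=group,
        device=device,
        session_id=f"S{session_index + 1}",
        t=t,
        acc=acc,
        labels=labels,
        sample_rate_hz=rate,
    )


def sample_cohort(spec: CohortSpec, models: Mapping[str, ActivityModel] | None = None) -> Cohort:
    """Generate the full cohort deterministically from ``spec.seed``.

    Healthy subjects (H01..) are recorded without a device; each patient
    (P01..) is recorded for ``sessions_per_condition`` sessions with the
    control brace and again with the novel brace.
    """
    models = models or default_activity_models()
    recordings: list[Recording] = []
    for h in range(spec.n_healthy):
        sid = f"H{h + 1:02d}"
        for s in range(spec.sessions_per_condition):
            recordings.append(
                sample_recording(spec, models, sid, "healthy", "none", s, subject_index=h)
            )
    for p in range(spec.n_patients):
        sid = f"P{p + 1:02d}"
        subject_index = 1000 + p  # disjoint from healthy substreams
        for device in ("control", "novel"):
            for s in range(spec.sessions_per_condition):
                recordings.append(
                    sample_recording(spec, models, sid, "patient", device, s, subject_index)
                )
    return Cohort(recordings)


# ---------------------------------------------------------------------------
# helpers


def _device_code(device: str) -> int:
    return {"none": 0, "control": 1, "novel": 2}[device]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValidationError("zero vector cannot be normalized")
    return v / n


def _rotate(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about ``axis`` by ``angle_rad``."""
    if angle_rad == 0:
        return np.asarray(v, float)
    k = _unit(np.asarray(axis, float))
    v = np.asarray(v, float)
    return (
        v * math.cos(angle_rad)
        + np.cross(k, v) * math.sin(angle_rad)
        + k * np.dot(k, v) * (1 - math.cos(angle_rad))
    )
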
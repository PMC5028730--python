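"""Synthetic Kinect-layout gait recordings with controllable structure.

The generator emulates the study geometry the pipeline was built for: a
walker traverses a ~6 m footpath toward and away from a fixed depth
camera, turning at each end, while limbs oscillate periodically at a
stride frequency with contralateral left/right phase opposition.  Each
modeled joint rides on the SpineBase translation plus a rest offset plus
a sinusoid at the stride frequency, a weaker second harmonic, and
additive Gaussian sensor noise; during turn windows the noise is
inflated tenfold, mimicking the sensor's unreliable joint estimates
while the walker rotates.  Class-dependent shifts in cadence and limb
amplitude stand in for emotion effects.

This is the minimal signal family the Fourier feature set is designed to
capture, not a biomechanical model: bone lengths are not constrained and
there is no ground-contact event structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .joints import JOINTS_25
from .skeleton_io import GaitRecord

#: Rest offsets (m) of the 14 modeled joints relative to SpineBase.
#: x lateral (positive = walker's right when facing the camera),
#: y vertical, z fore-aft.
REST_OFFSETS: dict[str, tuple[float, float, float]] = {
    "SpineBase": (0.0, 0.0, 0.0),
    "Neck": (0.0, 0.55, 0.0),
    "ShoulderL": (-0.18, 0.50, 0.0),
    "ShoulderR": (0.18, 0.50, 0.0),
    "ElbowL": (-0.22, 0.26, 0.0),
    "ElbowR": (0.22, 0.26, 0.0),
    "WristL": (-0.24, 0.02, 0.0),
    "WristR": (0.24, 0.02, 0.0),
    "HipL": (-0.09, -0.04, 0.0),
    "HipR": (0.09, -0.04, 0.0),
    "KneeL": (-0.10, -0.45, 0.0),
    "KneeR": (0.10, -0.45, 0.0),
    "AnkleL": (-0.11, -0.85, 0.0),
    "AnkleR": (0.11, -0.85, 0.0),
}

#: Oscillation amplitudes (m) per modeled joint and axis (x, y, z).
#: Distal joints swing more; the dominant motion is fore-aft (z).
DEFAULT_AMPLITUDES: dict[str, tuple[float, float, float]] = {
    "SpineBase": (0.005, 0.015, 0.005),
    "Neck": (0.005, 0.012, 0.008),
    "ShoulderL": (0.008, 0.010, 0.020),
    "ShoulderR": (0.008, 0.010, 0.020),
    "ElbowL": (0.010, 0.012, 0.050),
    "ElbowR": (0.010, 0.012, 0.050),
    "WristL": (0.015, 0.020, 0.090),
    "WristR": (0.015, 0.020, 0.090),
    "HipL": (0.008, 0.012, 0.020),
    "HipR": (0.008, 0.012, 0.020),
    "KneeL": (0.010, 0.020, 0.070),
    "KneeR": (0.010, 0.020, 0.070),
    "AnkleL": (0.010, 0.025, 0.120),
    "AnkleR": (0.010, 0.025, 0.120),
}

_ARM_JOINTS = ("ShoulderL", "ShoulderR", "ElbowL", "ElbowR", "WristL", "WristR")
_LEG_JOINTS = ("HipL", "HipR", "KneeL", "KneeR", "AnkleL", "AnkleR")

#: Joints not modeled explicitly ride rigidly with a modeled neighbor.
RIGID_ATTACHMENTS: dict[str, tuple[str, tuple[float, float, float]]] = {
    "Head": ("Neck", (0.0, 0.18, 0.0)),
    "SpineShoulder": ("Neck", (0.0, -0.06, 0.0)),
    "SpineMid": ("SpineBase", (0.0, 0.28, 0.0)),
    "HandL": ("WristL", (-0.01, -0.08, 0.02)),
    "HandR": ("WristR", (0.01, -0.08, 0.02)),
    "HandTipL": ("WristL", (-0.01, -0.14, 0.03)),
    "HandTipR": ("WristR", (0.01, -0.14, 0.03)),
    "ThumbL": ("WristL", (-0.04, -0.06, 0.02)),
    "ThumbR": ("WristR", (0.04, -0.06, 0.02)),
    "FootL": ("AnkleL", (-0.01, -0.07, 0.08)),
    "FootR": ("AnkleR", (0.01, -0.07, 0.08)),
}


@dataclass
class GaitParams:
    """Generator parameters; defaults emulate a normal adult walk.

    stride_freq in Hz (typical 0.8-1.2), speed in m/s, footpath_length
    in m, noise_sd in m (per-coordinate Gaussian sensor noise),
    turn_duration and duration in s.
    """

    stride_freq: float = 1.0
    speed: float = 1.2
    footpath_length: float = 6.0
    joint_amplitudes: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDES)
    )
    harmonic_ratio: float = 0.3
    noise_sd: float = 0.003
    turn_duration: float = 1.5
    duration: float = 60.0
    frame_rate: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        positive = {
            "stride_freq": self.stride_freq,
            "speed": self.speed,
            "footpath_length": self.footpath_length,
            "duration": self.duration,
            "frame_rate": self.frame_rate,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        if self.noise_sd < 0 or self.turn_duration < 0:
            raise ConfigError("noise_sd and turn_duration must be >= 0")
        if not self.harmonic_ratio >= 0:
            raise ConfigError("harmonic_ratio must be >= 0")
        if not self.stride_freq < self.frame_rate / 2:
            raise ConfigError("stride_freq must be below the Nyquist rate")


@dataclass
class EmotionEffect:
    """Class-dependent gait modulation standing in for an emotion.

    delta_freq shifts the stride frequency (Hz); amp_scale_arms and
    amp_scale_legs multiply arm and leg oscillation amplitudes.
    """

    label: str = "neutral"
    delta_freq: float = 0.0
    amp_scale_arms: float = 1.0
    amp_scale_legs: float = 1.0

    def validate(self, params: GaitParams) -> None:
        f = params.stride_freq + self.delta_freq
        if not 0 < f < params.frame_rate / 2:
            raise ConfigError(
                f"effective stride frequency {f} Hz outside (0, Nyquist)"
            )
        if self.amp_scale_arms <= 0 or self.amp_scale_legs <= 0:
            raise ConfigError("amplitude scales must be positive")


NEUTRAL = EmotionEffect(label="neutral")


def _footpath_track(params: GaitParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SpineBase depth z(t), heading(t) in {-1,+1}, turning mask.

    The walker starts at the near end (z = z_near) walking away from the
    camera, pauses for ``turn_duration`` at each end (z held, heading
    flips mid-turn), then walks back.
    """
    n = int(round(params.duration * params.frame_rate))
    t = np.arange(n) / params.frame_rate
    z_near = 1.0
    walk_time = params.footpath_length / params.speed
    cycle = 2 * (walk_time + params.turn_duration)
    tau = np.mod(t, cycle)

    z = np.empty(n)
    heading = np.empty(n)
    turning = np.zeros(n, dtype=bool)

    # phase 1: walk away; phase 2: turn at far end;
    # phase 3: walk toward camera; phase 4: turn at near end
    p1 = tau < walk_time
    p2 = (~p1) & (tau < walk_time + params.turn_duration)
    p3 = (~p1) & (~p2) & (tau < 2 * walk_time + params.turn_duration)
    p4 = ~(p1 | p2 | p3)

    z[p1] = z_near + params.speed * tau[p1]
    heading[p1] = 1.0
    z[p2] = z_near + params.footpath_length
    heading[p2] = 1.0
    turning[p2] = True
    z[p3] = (
        z_near
        + params.footpath_length
        - params.speed * (tau[p3] - walk_time - params.turn_duration)
    )
    heading[p3] = -1.0
    z[p4] = z_near
    heading[p4] = -1.0
    turning[p4] = True
    return z, heading, turning


def simulate_record(
    params: GaitParams,
    effect: EmotionEffect | None = None,
    subject_id: str = "S00",
    camera_id: str = "K1",
) -> GaitRecord:
    """Generate one labelled 25-joint walking recording.

    Deterministic given ``params.seed``; the record's condition label is
    ``effect.label``.
    """
    params.validate()
    effect = effect or NEUTRAL
    effect.validate(params)
    rng = np.random.default_rng(params.seed)

    n = int(round(params.duration * params.frame_rate))
    t = np.arange(n) / params.frame_rate
    freq = params.stride_freq + effect.delta_freq

    z_track, heading, turning = _footpath_track(params)
    spinebase = np.column_stack(
        [np.zeros(n), np.full(n, 0.95), z_track]
    )

    # fixed per-record phase offsets keep segments of one record coherent
    base_phase = rng.uniform(0, 2 * np.pi)
    harmonic_phase = rng.uniform(0, 2 * np.pi)

    positions: dict[str, np.ndarray] = {}
    for joint, rest in REST_OFFSETS.items():
        amp = np.array(params.joint_amplitudes.get(joint, (0.0, 0.0, 0.0)))
        if joint in _ARM_JOINTS:
            amp = amp * effect.amp_scale_arms
        elif joint in _LEG_JOINTS:
            amp = amp * effect.amp_scale_legs
        # contralateral opposition: right-side joints swing half a cycle
        # behind the left side
        side_phase = np.pi if joint.endswith("R") else 0.0
        phase = base_phase + side_phase
        osc = amp[None, :] * np.sin(
            2 * np.pi * freq * t[:, None] + phase
        ) + (params.harmonic_ratio * amp)[None, :] * np.sin(
            4 * np.pi * freq * t[:, None] + phase + harmonic_phase
        )
        rest_arr = np.tile(np.array(rest), (n, 1))
        rest_arr[:, 0] *= heading  # lateral offsets flip with facing
        positions[joint] = spinebase + rest_arr + osc

    for joint, (anchor, offset) in RIGID_ATTACHMENTS.items():
        off = np.tile(np.array(offset), (n, 1))
        off[:, 0] *= heading
        positions[joint] = positions[anchor] + off

    xyz = np.stack([positions[j] for j in JOINTS_25], axis=1)
    noise_scale = np.where(turning, 10.0, 1.0)[:, None, None]
    xyz = xyz + rng.normal(0.0, params.noise_sd, size=xyz.shape) * noise_scale

    return GaitRecord(
        subject_id=subject_id,
        condition=effect.label,
        camera_id=camera_id,
        xyz=xyz,
        frame_rate=params.frame_rate,
    )


def simulate_cohort(
    n_subjects: int,
    params_base: GaitParams | None = None,
    effects: list[EmotionEffect] | None = None,
    between_subject_sd: float = 0.05,
    seed: int = 0,
    camera_id: str = "K1",
) -> list[GaitRecord]:
    """Simulate a cohort: one record per subject per emotion effect.

    Each subject's baseline stride frequency is drawn Gaussian around
    ``params_base.stride_freq`` with sd ``between_subject_sd`` (Hz), and
    their walking speed jitters by 5%; both records of a subject share
    that baseline, as in a within-subject design.
    """
    if n_subjects < 2:
        raise ConfigError("need at least 2 subjects")
    params_base = params_base or GaitParams()
    effects = effects if effects is not None else [NEUTRAL]
    rng = np.random.default_rng(seed)
    records: list[GaitRecord] = []
    for i in range(n_subjects):
        subject = f"S{i + 1:03d}"
        stride = params_base.stride_freq + rng.normal(0, between_subject_sd)
        stride = float(np.clip(stride, 0.4, params_base.frame_rate / 2 - 0.5))
        speed = params_base.speed * float(
            np.clip(1 + rng.normal(0, 0.05), 0.7, 1.3)
        )
        for effect in effects:
            records.append(
                simulate_record(
                    replace(
                        params_base,
                        stride_freq=stride,
                        speed=speed,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    ),
                    effect=effect,
                    subject_id=subject,
                    camera_id=camera_id,
                )
            )
    return records
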
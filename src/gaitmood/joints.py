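"""Kinect-v2 skeleton joint names and the fixed analysis subset.

The Kinect v2 SDK tracks 25 skeletal joints per frame at 30 Hz.  Gait
analysis here uses a fixed, ordered 14-joint subset covering the trunk
(spine base, neck), the arms (shoulders, elbows, wrists) and the legs
(hips, knees, ankles) -- the minimal marker set that still carries the
periodic limb-swing information a walking cycle produces.
"""

from __future__ import annotations

#: All 25 Kinect-v2 joints, in the fixed column order of the skeleton CSV.
JOINTS_25: tuple[str, ...] = (
    "Head",
    "Neck",
    "SpineShoulder",
    "SpineMid",
    "SpineBase",
    "ShoulderL",
    "ShoulderR",
    "ElbowL",
    "ElbowR",
    "WristL",
    "WristR",
    "HandL",
    "HandR",
    "HandTipL",
    "HandTipR",
    "ThumbL",
    "ThumbR",
    "HipL",
    "HipR",
    "KneeL",
    "KneeR",
    "AnkleL",
    "AnkleR",
    "FootL",
    "FootR",
)

#: The ordered 14-joint analysis subset; 14 joints x 3 axes = 42 channels.
ANALYSIS_JOINTS_14: tuple[str, ...] = (
    "SpineBase",
    "Neck",
    "ShoulderL",
    "ShoulderR",
    "ElbowL",
    "ElbowR",
    "WristL",
    "WristR",
    "HipL",
    "HipR",
    "KneeL",
    "KneeR",
    "AnkleL",
    "AnkleR",
)

AXES: tuple[str, str, str] = ("x", "y", "z")

#: Column labels of the T x 42 motion matrix, e.g. "SpineBase_x".
MOTION_COLUMNS_42: tuple[str, ...] = tuple(
    f"{joint}_{axis}" for joint in ANALYSIS_JOINTS_14 for axis in AXES
)

#: Row indices of the analysis joints within the 25-joint array.
ANALYSIS_INDICES: tuple[int, ...] = tuple(
    JOINTS_25.index(j) for j in ANALYSIS_JOINTS_14
)

SPINEBASE_INDEX: int = JOINTS_25.index("SpineBase")

assert len(JOINTS_25) == 25 and len(set(JOINTS_25)) == 25
assert len(ANALYSIS_JOINTS_14) == 14 and len(MOTION_COLUMNS_42) == 42
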
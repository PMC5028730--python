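"""Read, validate and write skeleton recordings and feature tables.

Skeleton CSV dialect (wide, one row per frame):

    # subject=S01 condition=neutral camera=K1 frame_rate=30
    frame,Head_x,Head_y,Head_z,...,FootR_z
    0,0.01,1.62,3.5,...

The optional leading comment line carries record metadata; when absent,
a ``<subject>_<condition>_<camera>.csv`` filename pattern is tried.
Coordinates are meters in the camera frame (x lateral, y vertical,
z depth away from the sensor, right-handed).  Floats are written with
``repr`` so a write/read round trip is lossless.

Feature-table CSV dialect:

    instance_id,label,<feature 1>,...
    S01|neutral|K1,neutral,...

``instance_id`` is ``subject|condition|camera`` joined with ``|``.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    FormatError,
    ParseError,
    ValidationError,
)
from .joints import AXES, JOINTS_25

COORD_COLUMNS: tuple[str, ...] = tuple(
    f"{joint}_{axis}" for joint in JOINTS_25 for axis in AXES
)

_META_LINE = re.compile(r"^#\s*(.*)$")
_FILENAME_PATTERN = re.compile(r"^(?P<subject>[^_]+)_(?P<condition>[^_]+)_(?P<camera>[^_.]+)\.csv$")


@dataclass
class Frame:
    """One skeleton frame: a frame index and 25 joint positions (m)."""

    index: int
    coords: dict[str, tuple[float, float, float]]


@dataclass
class GaitRecord:
    """One uninterrupted walking recording.

    Parameters
    ----------
    xyz
        Array of shape (T, 25, 3): per-frame joint coordinates in meters,
        camera frame, joints ordered as :data:`gaitmood.joints.JOINTS_25`.
    frame_index
        Strictly increasing integer frame indices, length T.
    """

    subject_id: str
    condition: str
    camera_id: str
    xyz: np.ndarray
    frame_index: np.ndarray | None = None
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 3 or self.xyz.shape[1:] != (25, 3):
            raise ValidationError(
                f"xyz must have shape (T, 25, 3), got {self.xyz.shape}"
            )
        if self.xyz.shape[0] < 1:
            raise EmptyInputError("a GaitRecord needs at least one frame")
        if self.frame_index is None:
            self.frame_index = np.arange(self.xyz.shape[0])
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        if self.frame_index.shape != (self.xyz.shape[0],):
            raise ValidationError("frame_index length must match frame count")
        if self.frame_index.size > 1 and np.any(np.diff(self.frame_index) <= 0):
            raise ValidationError("frame indices must be strictly increasing")
        if not np.all(np.isfinite(self.xyz)):
            raise ValidationError("all joint coordinates must be finite")
        if not self.frame_rate > 0:
            raise ValidationError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    def get_frame(self, i: int) -> Frame:
        """Return frame ``i`` as a joint-name -> (x, y, z) mapping."""
        row = self.xyz[i]
        return Frame(
            index=int(self.frame_index[i]),
            coords={j: tuple(row[k]) for k, j in enumerate(JOINTS_25)},
        )

    @property
    def frames(self) -> list[Frame]:
        return [self.get_frame(i) for i in range(self.n_frames)]


@dataclass
class FeatureTable:
    """Instances x features matrix with per-instance class labels."""

    instance_ids: list[tuple[str, str, str]]
    values: np.ndarray
    feature_names: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            self.values = self.values.reshape(len(self.instance_ids), -1)
        n, d = self.values.shape
        if len(self.instance_ids) != n or len(self.labels) != n:
            raise ValidationError(
                "instance_ids, labels and value rows must have equal length"
            )
        if len(self.feature_names) != d:
            raise ValidationError("feature_names must match value columns")
        if len(set(self.feature_names)) != d:
            raise ValidationError("feature names must be unique")

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    @property
    def cameras(self) -> list[str]:
        return sorted({cam for _, _, cam in self.instance_ids})


def _fmt(x: float) -> str:
    return repr(float(x))


def read_skeleton_csv(path: str | os.PathLike) -> GaitRecord:
    """Parse a skeleton CSV into a validated :class:`GaitRecord`.

    Raises
    ------
    FormatError
        If a coordinate column is missing or unexpected columns appear.
    ParseError
        If a cell is not numeric (the message names the data row).
    EmptyInputError
        If the file has no data rows.
    """
    path = os.fspath(path)
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    meta: dict[str, str] = {}
    lines = text.splitlines()
    body_start = 0
    for line in lines:
        m = _META_LINE.match(line)
        if m is None:
            break
        body_start += 1
        for token in m.group(1).split():
            if "=" in token:
                key, _, value = token.partition("=")
                meta[key.strip()] = value.strip()
    body = "\n".join(lines[body_start:]).strip()
    if not body:
        raise EmptyInputError(f"{path}: no data")
    df = pd.read_csv(io.StringIO(body), dtype=str)
    expected = ("frame",) + COORD_COLUMNS
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in expected]
    if extra:
        raise FormatError(f"{path}: unexpected column(s) {extra}")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: header only, no frames")

    numeric = {}
    for col in expected:
        try:
            numeric[col] = df[col].astype(float).to_numpy()
        except ValueError:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ParseError(
                f"{path}: non-numeric value in column {col!r}, data row {bad}"
            ) from None

    xyz = np.column_stack([numeric[c] for c in COORD_COLUMNS]).reshape(-1, 25, 3)
    if not meta:
        m = _FILENAME_PATTERN.match(os.path.basename(path))
        if m:
            meta = {
                "subject": m.group("subject"),
                "condition": m.group("condition"),
                "camera": m.group("camera"),
            }
    return GaitRecord(
        subject_id=meta.get("subject", "unknown"),
        condition=meta.get("condition", "unknown"),
        camera_id=meta.get("camera", "unknown"),
        xyz=xyz,
        frame_index=numeric["frame"].astype(int),
        frame_rate=float(meta.get("frame_rate", 30.0)),
    )


def write_skeleton_csv(record: GaitRecord, path: str | os.PathLike) -> None:
    """Write ``record`` in the dialect :func:`read_skeleton_csv` accepts."""
    with open(os.fspath(path), "w", encoding="utf-8") as fh:
        fh.write(
            f"# subject={record.subject_id} condition={record.condition} "
            f"camera={record.camera_id} frame_rate={record.frame_rate:g}\n"
        )
        fh.write("frame," + ",".join(COORD_COLUMNS) + "\n")
        flat = record.xyz.reshape(record.n_frames, 75)
        for idx, row in zip(record.frame_index, flat):
            fh.write(str(int(idx)) + "," + ",".join(_fmt(v) for v in row) + "\n")


def write_feature_table(table: FeatureTable, path: str | os.PathLike) -> None:
    """Write a feature table as CSV (lossless round trip)."""
    with open(os.fspath(path), "w", encoding="utf-8") as fh:
        fh.write("instance_id,label," + ",".join(table.feature_names) + "\n")
        for (sub, cond, cam), label, row in zip(
            table.instance_ids, table.labels, table.values
        ):
            fh.write(
                f"{sub}|{cond}|{cam},{label},"
                + ",".join(_fmt(v) for v in row)
                + "\n"
            )


def read_feature_table(path: str | os.PathLike) -> FeatureTable:
    """Read a feature-table CSV written by :func:`write_feature_table`."""
    path = os.fspath(path)
    df = pd.read_csv(path, dtype={"instance_id": str, "label": str})
    if "instance_id" not in df.columns or "label" not in df.columns:
        raise FormatError(f"{path}: expected 'instance_id' and 'label' columns")
    feature_names = [c for c in df.columns if c not in ("instance_id", "label")]
    ids = []
    for raw in df["instance_id"]:
        parts = str(raw).split("|")
        if len(parts) != 3:
            raise ParseError(f"{path}: malformed instance_id {raw!r}")
        ids.append(tuple(parts))
    values = (
        df[feature_names].to_numpy(dtype=float)
        if len(df)
        else np.empty((0, len(feature_names)))
    )
    return FeatureTable(
        instance_ids=ids,
        values=values,
        feature_names=feature_names,
        labels=[str(x) for x in df["label"]],
    )
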
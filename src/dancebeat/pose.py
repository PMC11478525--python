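"""Joint-angle pose features.

Per-frame 2-D keypoints from an external pose estimator (OpenPose-layout
JSON, or a consolidated table) are quantified as goniometric joint angles:
for each feature (a, b, c) the interior angle at joint b between rays
b->a and b->c, in degrees within [0, 180].  Angles are invariant to
translation, rotation and uniform scaling of the keypoints, so they
compare performers across camera placements and body sizes.

The default feature set covers the limbs that matter for dance scoring —
elbows, shoulders, knees and hips on both sides (m = 8), with trunk
inclination available as an optional ninth feature.  A keypoint reported
with confidence 0 is missing, and any feature needing it is ABSENT (NaN)
for that frame; missingness is data, not an error.
"""

from __future__ import annotations

import csv
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (ConfigError, InvalidInputError, KeypointParseError,
                     MissingFrameError, UndefinedAngleError)
from .keyframes import KeyframeIndexSequence

# OpenPose output layouts: joint name -> index in people[].pose_keypoints_2d.
SKELETONS: dict[str, dict[str, int]] = {
    "coco18": {
        "nose": 0, "neck": 1,
        "r_shoulder": 2, "r_elbow": 3, "r_wrist": 4,
        "l_shoulder": 5, "l_elbow": 6, "l_wrist": 7,
        "r_hip": 8, "r_knee": 9, "r_ankle": 10,
        "l_hip": 11, "l_knee": 12, "l_ankle": 13,
        "r_eye": 14, "l_eye": 15, "r_ear": 16, "l_ear": 17,
    },
    "body25": {
        "nose": 0, "neck": 1,
        "r_shoulder": 2, "r_elbow": 3, "r_wrist": 4,
        "l_shoulder": 5, "l_elbow": 6, "l_wrist": 7,
        "mid_hip": 8,
        "r_hip": 9, "r_knee": 10, "r_ankle": 11,
        "l_hip": 12, "l_knee": 13, "l_ankle": 14,
        "r_eye": 15, "l_eye": 16, "r_ear": 17, "l_ear": 18,
        "l_big_toe": 19, "l_small_toe": 20, "l_heel": 21,
        "r_big_toe": 22, "r_small_toe": 23, "r_heel": 24,
    },
}


@dataclass(frozen=True)
class PoseFrame:
    """Detected keypoints of one video frame.

    ``keypoints`` maps joint name -> (x, y, confidence); joints with
    confidence 0 are omitted (missing).
    """

    keypoints: dict[str, tuple[float, float, float]]
    frame_index: int

    def point(self, joint: str) -> tuple[float, float] | None:
        kp = self.keypoints.get(joint)
        return None if kp is None else (kp[0], kp[1])


@dataclass(frozen=True)
class AngleFeatureDef:
    """Ordered list of (name, (a, b, c)) joint triples; angle measured at b."""

    features: tuple[tuple[str, tuple[str, str, str]], ...]
    skeleton: str = "coco18"

    def __post_init__(self):
        if self.skeleton not in SKELETONS:
            raise ConfigError(f"unknown skeleton layout {self.skeleton!r}")
        layout = SKELETONS[self.skeleton]
        names = [name for name, _ in self.features]
        if len(self.features) < 1:
            raise InvalidInputError("at least one feature required")
        if len(set(names)) != len(names):
            raise InvalidInputError("feature names must be unique")
        for name, triple in self.features:
            for joint in triple:
                if joint not in layout:
                    raise ConfigError(f"feature {name!r} uses unknown joint {joint!r}")

    @property
    def m(self) -> int:
        return len(self.features)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.features)


def default_feature_def(skeleton: str = "coco18", include_trunk: bool = False) -> AngleFeatureDef:
    """Eight standard goniometric angles: elbows, shoulders, knees, hips.

    With ``include_trunk`` a ninth feature measures trunk inclination as
    the angle at the neck between the hip line midpoint proxy and nose
    (coco18 has no mid-hip joint, so the trunk angle uses nose-neck-hip).
    """
    feats = [
        ("l_elbow_angle", ("l_shoulder", "l_elbow", "l_wrist")),
        ("r_elbow_angle", ("r_shoulder", "r_elbow", "r_wrist")),
        ("l_shoulder_angle", ("l_hip", "l_shoulder", "l_elbow")),
        ("r_shoulder_angle", ("r_hip", "r_shoulder", "r_elbow")),
        ("l_knee_angle", ("l_hip", "l_knee", "l_ankle")),
        ("r_knee_angle", ("r_hip", "r_knee", "r_ankle")),
        ("l_hip_angle", ("l_shoulder", "l_hip", "l_knee")),
        ("r_hip_angle", ("r_shoulder", "r_hip", "r_knee")),
    ]
    if include_trunk:
        hip = "mid_hip" if skeleton == "body25" else "l_hip"
        feats.append(("trunk_angle", ("nose", "neck", hip)))
    return AngleFeatureDef(tuple(feats), skeleton)


@dataclass(frozen=True)
class PoseDescriptionSequence:
    """n keyframes x m joint-angle features, in degrees; NaN marks ABSENT."""

    angles: np.ndarray       # [n, m], degrees in [0, 180] or NaN
    beat_times: np.ndarray   # seconds, length n
    feature_def: AngleFeatureDef = field(compare=False)

    def __post_init__(self):
        angles = np.asarray(self.angles, dtype=np.float64)
        object.__setattr__(self, "angles", angles)
        object.__setattr__(self, "beat_times", np.asarray(self.beat_times, dtype=np.float64))
        if angles.ndim != 2 or angles.shape[1] != self.feature_def.m:
            raise InvalidInputError("angle matrix shape does not match the feature definition")
        if angles.shape[0] != len(self.beat_times):
            raise InvalidInputError("one beat time per keyframe row required")
        present = angles[np.isfinite(angles)]
        if present.size and (present.min() < 0 or present.max() > 180):
            raise InvalidInputError("angles must lie in [0, 180] degrees")

    @property
    def n(self) -> int:
        return self.angles.shape[0]

    @property
    def m(self) -> int:
        return self.angles.shape[1]


def joint_angle(a: tuple[float, float], b: tuple[float, float],
                c: tuple[float, float]) -> float:
    """Interior angle at b between rays b->a and b->c, degrees in [0, 180]."""
    u = (a[0] - b[0], a[1] - b[1])
    v = (c[0] - b[0], c[1] - b[1])
    if (u[0] == 0.0 and u[1] == 0.0) or (v[0] == 0.0 and v[1] == 0.0):
        raise UndefinedAngleError("coincident keypoints: angle undefined")
    dot = u[0] * v[0] + u[1] * v[1]
    cross = u[0] * v[1] - u[1] * v[0]
    # atan2 form is well conditioned near 0 and 180 deg, unlike acos
    return math.degrees(math.atan2(abs(cross), dot))


def compute_feature_vector(pose: PoseFrame, fdef: AngleFeatureDef) -> np.ndarray:
    """One angle per feature; NaN where any required joint is missing."""
    row = np.full(fdef.m, np.nan)
    for j, (_, (a, b, c)) in enumerate(fdef.features):
        pa, pb, pc = pose.point(a), pose.point(b), pose.point(c)
        if pa is None or pb is None or pc is None:
            continue
        try:
            row[j] = joint_angle(pa, pb, pc)
        except UndefinedAngleError:
            pass  # degenerate detection treated as missing
    return row


# ---------------------------------------------------------------------------
# keypoint input

_FRAME_NUM_RE = re.compile(r"(\d+)\D*$")


def _frame_index_from_name(path: Path) -> int:
    m = _FRAME_NUM_RE.search(path.stem)
    if not m:
        raise KeypointParseError(f"cannot infer frame index from file name {path.name!r}")
    return int(m.group(1))


def _frame_from_triples(triples, frame_index: int, layout: dict[str, int],
                        source: str) -> PoseFrame:
    n_joints = len(layout)
    if len(triples) != 3 * n_joints:
        raise KeypointParseError(
            f"{source}: expected {3 * n_joints} keypoint values, got {len(triples)}")
    keypoints = {}
    for name, j in layout.items():
        x, y, conf = triples[3 * j], triples[3 * j + 1], triples[3 * j + 2]
        if conf > 0:
            keypoints[name] = (float(x), float(y), float(conf))
    return PoseFrame(keypoints, frame_index)


def read_keypoint_files(paths, skeleton: str = "coco18") -> list[PoseFrame]:
    """Read one OpenPose-layout JSON per frame.

    Each file holds ``{"people": [{"pose_keypoints_2d": [x, y, c, ...]}]}``;
    with several detected people the one with the highest mean keypoint
    confidence is kept (the pipeline assumes a single dancer).  The frame
    index is the trailing integer of the file name.
    """
    if skeleton not in SKELETONS:
        raise ConfigError(f"unknown skeleton layout {skeleton!r}")
    layout = SKELETONS[skeleton]
    frames = []
    for p in map(Path, paths):
        try:
            doc = json.loads(p.read_text())
            people = doc["people"]
        except (json.JSONDecodeError, KeyError, TypeError, OSError) as exc:
            raise KeypointParseError(f"malformed keypoint file {p}: {exc}") from exc
        idx = _frame_index_from_name(p)
        if not people:
            frames.append(PoseFrame({}, idx))
            continue
        best, best_conf = None, -1.0
        for person in people:
            triples = person.get("pose_keypoints_2d")
            if triples is None:
                raise KeypointParseError(f"{p}: person entry lacks pose_keypoints_2d")
            conf = float(np.mean(np.asarray(triples, dtype=float)[2::3]))
            if conf > best_conf:
                best, best_conf = triples, conf
        frames.append(_frame_from_triples(np.asarray(best, dtype=float), idx, layout, str(p)))
    return frames


def read_keypoint_table(path: str | Path, skeleton: str = "coco18") -> list[PoseFrame]:
    """Read a consolidated CSV table: frame_index, joint, x, y, confidence."""
    if skeleton not in SKELETONS:
        raise ConfigError(f"unknown skeleton layout {skeleton!r}")
    layout = SKELETONS[skeleton]
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface as a parse error naming the file
        raise KeypointParseError(f"cannot read keypoint table {path}: {exc}") from exc
    required = {"frame_index", "joint", "x", "y", "confidence"}
    if not required.issubset(df.columns):
        raise KeypointParseError(
            f"{path}: missing columns {sorted(required - set(df.columns))}")
    unknown = set(df["joint"]) - set(layout)
    if unknown:
        raise ConfigError(f"{path}: joints {sorted(unknown)} not in skeleton {skeleton!r}")
    frames = []
    for idx, group in df.groupby("frame_index", sort=True):
        keypoints = {
            str(r.joint): (float(r.x), float(r.y), float(r.confidence))
            for r in group.itertuples()
            if float(r.confidence) > 0
        }
        frames.append(PoseFrame(keypoints, int(idx)))
    return frames


def build_pose_description_sequence(frames, keyframes: KeyframeIndexSequence,
                                    fdef: AngleFeatureDef) -> PoseDescriptionSequence:
    """Assemble the n x m angle matrix for the selected keyframes.

    Alignment is by ``frame_index`` (input order is irrelevant).  The same
    operation serves the standard and the evaluated performance.
    """
    by_index = {f.frame_index: f for f in frames}
    missing = [int(i) for i in keyframes.indices if i not in by_index]
    if missing:
        raise MissingFrameError(missing)
    rows = [compute_feature_vector(by_index[int(i)], fdef) for i in keyframes.indices]
    return PoseDescriptionSequence(np.asarray(rows), keyframes.source_beat_times, fdef)


def write_pose_csv(seq: PoseDescriptionSequence, path: str | Path) -> None:
    """CSV with header ``beat_time_s, <feature names...>``; ABSENT as empty."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["beat_time_s", *seq.feature_def.names])
        for t, row in zip(seq.beat_times, seq.angles):
            writer.writerow([f"{t:.6f}",
                             *("" if not np.isfinite(v) else f"{v:.6f}" for v in row)])


def read_pose_csv(path: str | Path, skeleton: str = "coco18") -> PoseDescriptionSequence:
    """Read a matrix written by :func:`write_pose_csv`.

    The feature definition is reconstructed nominally from the header:
    names are kept; unknown names map onto placeholder triples only if
    they are not part of the default set.
    """
    df = pd.read_csv(path)
    if "beat_time_s" not in df.columns:
        raise KeypointParseError(f"{path}: missing beat_time_s column")
    names = [c for c in df.columns if c != "beat_time_s"]
    default = default_feature_def(skeleton, include_trunk=True)
    triples = dict(default.features)
    feats = tuple((name, triples.get(name, ("nose", "neck", "l_hip"))) for name in names)
    fdef = AngleFeatureDef(feats, skeleton)
    angles = df[names].to_numpy(dtype=float)
    return PoseDescriptionSequence(angles, df["beat_time_s"].to_numpy(dtype=float), fdef)
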
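"""Body-movement features from 20-joint skeletal time series.

Depth-camera skeleton tracking yields per-frame 3-D coordinates of 20 named
joints.  Tracking glitches appear as single-frame spikes, removed with a
centered running median over a one-second window.  Kinematics are then
summarized into a fixed 64-dimensional vector: mean and STD of the linear
speed of every joint (40 values), and mean and STD of the angular speed and
angular acceleration of six arm angles (left/right shoulder, elbow, wrist;
24 values).

Angles are defined at the named joint between its two adjacent skeletal
segments (shoulder: toward shoulder-center vs toward elbow; elbow: toward
shoulder vs toward wrist; wrist: toward elbow vs toward hand), so a straight
arm gives an elbow angle of pi.  Speeds are first differences divided by the
frame interval, i.e. in m/s and rad/s; features are invariant to rigid-body
motion of the whole skeleton.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "KINECT_JOINTS",
    "ANGLE_DEFINITIONS",
    "SkeletonSeries",
    "median_filter_skeleton",
    "body_angles",
    "movement_features",
    "read_skeleton_csv",
    "MOVEMENT_FEATURE_NAMES",
]

#: The 20 Kinect-v1 skeletal joints, in fixed order.
KINECT_JOINTS = (
    "HipCenter",
    "Spine",
    "ShoulderCenter",
    "Head",
    "ShoulderLeft",
    "ElbowLeft",
    "WristLeft",
    "HandLeft",
    "ShoulderRight",
    "ElbowRight",
    "WristRight",
    "HandRight",
    "HipLeft",
    "KneeLeft",
    "AnkleLeft",
    "FootLeft",
    "HipRight",
    "KneeRight",
    "AnkleRight",
    "FootRight",
)

#: angle name -> (vertex joint, neighbour joint A, neighbour joint B)
ANGLE_DEFINITIONS = (
    ("ShoulderLeftAngle", "ShoulderLeft", "ShoulderCenter", "ElbowLeft"),
    ("ElbowLeftAngle", "ElbowLeft", "ShoulderLeft", "WristLeft"),
    ("WristLeftAngle", "WristLeft", "ElbowLeft", "HandLeft"),
    ("ShoulderRightAngle", "ShoulderRight", "ShoulderCenter", "ElbowRight"),
    ("ElbowRightAngle", "ElbowRight", "ShoulderRight", "WristRight"),
    ("WristRightAngle", "WristRight", "ElbowRight", "HandRight"),
)

MOVEMENT_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{j}__linspeed_{s}" for j in KINECT_JOINTS for s in ("mean", "std")
) + tuple(
    f"{a}__angspeed_{s}" for a, *_ in ANGLE_DEFINITIONS for s in ("mean", "std")
) + tuple(
    f"{a}__angacc_{s}" for a, *_ in ANGLE_DEFINITIONS for s in ("mean", "std")
)


@dataclass
class SkeletonSeries:
    """Skeletal time series: times (s) and coords of shape (frames, 20, 3) m."""

    times: np.ndarray
    coords: np.ndarray
    joint_names: tuple[str, ...] = KINECT_JOINTS

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (20, 3):
            raise ValueError("coords must have shape (frames, 20, 3)")
        if tuple(self.joint_names) != KINECT_JOINTS and len(self.joint_names) != 20:
            raise ValueError("exactly 20 joints required")
        if self.coords.shape[0] != self.times.shape[0]:
            raise ValueError("times and coords must agree on frame count")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))


def median_filter_skeleton(s: SkeletonSeries, window_s: float = 1.0) -> SkeletonSeries:
    """Centered running median per joint coordinate (edges: window shrinks)."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    w = int(round(window_s * s.frame_rate))
    if w % 2 == 0:
        w += 1
    if w < 3:
        warnings.warn("median window shorter than 3 frames: returning input")
        return SkeletonSeries(s.times.copy(), s.coords.copy(), s.joint_names)
    flat = s.coords.reshape(s.n_frames, -1)
    filt = (
        pd.DataFrame(flat)
        .rolling(window=w, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    return SkeletonSeries(s.times.copy(), filt.reshape(s.coords.shape), s.joint_names)


def body_angles(s: SkeletonSeries) -> np.ndarray:
    """Six arm angles per frame, shape (frames, 6), radians in [0, pi].

    A frame where a segment vector degenerates to zero length keeps the
    previous frame's angle (pi at the first frame) and triggers a warning.
    """
    idx = {name: k for k, name in enumerate(s.joint_names)}
    out = np.empty((s.n_frames, len(ANGLE_DEFINITIONS)))
    flagged = False
    for j, (_, vertex, a, b) in enumerate(ANGLE_DEFINITIONS):
        v1 = s.coords[:, idx[a]] - s.coords[:, idx[vertex]]
        v2 = s.coords[:, idx[b]] - s.coords[:, idx[vertex]]
        n1 = np.linalg.norm(v1, axis=1)
        n2 = np.linalg.norm(v2, axis=1)
        ok = (n1 > 0) & (n2 > 0)
        cosang = np.full(s.n_frames, np.nan)
        dot = np.einsum("ij,ij->i", v1[ok], v2[ok])
        cosang[ok] = np.clip(dot / (n1[ok] * n2[ok]), -1.0, 1.0)
        ang = np.arccos(cosang)
        if not ok.all():
            flagged = True
            # forward-fill undefined angles; straight (pi) before first valid
            for t in range(s.n_frames):
                if not ok[t]:
                    ang[t] = ang[t - 1] if t > 0 else np.pi
        out[:, j] = ang
    if flagged:
        warnings.warn("degenerate zero-length segment; previous angle carried over")
    return out


def movement_features(
    s: SkeletonSeries, filter_window_s: float | None = 1.0
) -> tuple[np.ndarray, tuple[str, ...]]:
    """The 64-dimensional body-movement feature vector.

    Order: 20 joints x (LinSpeed mean, STD), then 6 angles x (AngSpeed mean,
    STD), then 6 angles x (AngAcc mean, STD).  STD is the population form.
    """
    if s.n_frames < 3:
        raise ValueError("need at least 3 frames (angular acceleration)")
    if filter_window_s is not None:
        s = median_filter_skeleton(s, filter_window_s)
    dt = np.diff(s.times)  # (n-1,)
    disp = np.linalg.norm(np.diff(s.coords, axis=0), axis=2)  # (n-1, 20)
    lin_speed = disp / dt[:, None]
    angles = body_angles(s)
    # speed = magnitude of the angular rate; keeps speed means non-negative
    # and time-reversal invariant (acceleration stays signed)
    ang_speed = np.abs(np.diff(angles, axis=0)) / dt[:, None]
    ang_acc = np.diff(ang_speed, axis=0) / dt[1:, None]
    values = []
    for j in range(20):
        values += [float(np.mean(lin_speed[:, j])), float(np.std(lin_speed[:, j]))]
    for a in range(6):
        values += [float(np.mean(ang_speed[:, a])), float(np.std(ang_speed[:, a]))]
    for a in range(6):
        values += [float(np.mean(ang_acc[:, a])), float(np.std(ang_acc[:, a]))]
    return np.asarray(values), MOVEMENT_FEATURE_NAMES


def read_skeleton_csv(path, frame_rate: float) -> SkeletonSeries:
    """Read a long-format skeleton CSV (frame, joint, x, y, z in metres)."""
    df = pd.read_csv(path)
    order = {name: k for k, name in enumerate(KINECT_JOINTS)}
    df = df.sort_values(["frame", "joint"], key=lambda s: s.map(order).fillna(s))
    frames = np.sort(df["frame"].unique())
    coords = np.empty((frames.size, 20, 3))
    for i, fr in enumerate(frames):
        sub = df[df["frame"] == fr].set_index("joint")
        coords[i] = sub.loc[list(KINECT_JOINTS), ["x", "y", "z"]].to_numpy()
    return SkeletonSeries(frames / frame_rate, coords)
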
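"""External representations: video clips, landmark streams, feature tables, reports.

A "video" on disk is a lossless image-sequence directory (numbered PNG frames
plus a ``clip.yaml`` with the frame rate) or a multi-page TIFF next to a YAML
of the same stem.  Landmark streams and fused feature tables are plain CSV,
one file per clip, comma-separated, UTF-8, header row, '.' decimal.  Eye and
hand landmark columns use the field's 1-based labels (``l1``..``l6`` per eye,
finger-joint labels for hands).  An absent modality is serialised as literal
zeros so every clip shares one schema and no rows are ever dropped.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml


class DecodeError(RuntimeError):
    """A clip on disk could not be decoded."""


class SchemaError(ValueError):
    """A CSV file does not carry the expected columns."""


# ---------------------------------------------------------------------------
# video clips
# ---------------------------------------------------------------------------

@dataclass
class VideoClip:
    """Ordered RGB frames with a frame rate.

    frames : (T, H, W, 3) uint8 array
    fps    : frames per second
    """

    frames: np.ndarray
    fps: float
    clip_id: str = "clip"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.uint8)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must be a (T, H, W, 3) array")
        if len(self.frames) < 1:
            raise ValueError("a clip needs at least one frame")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        return len(self.frames) / self.fps

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


def write_video(clip: VideoClip, path: str | os.PathLike) -> Path:
    """Write a clip as a directory of PNG frames plus ``clip.yaml``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(clip.frames):
        iio.imwrite(path / f"frame_{i:05d}.png", frame)
    meta = {"fps": float(clip.fps), "clip_id": clip.clip_id,
            "n_frames": int(len(clip))}
    (path / "clip.yaml").write_text(yaml.safe_dump(meta))
    return path


def read_video(path: str | os.PathLike) -> VideoClip:
    """Read a clip from an image-sequence directory or a multi-page TIFF."""
    path = Path(path)
    if not path.exists():
        raise DecodeError(f"no such clip: {path}")
    if path.is_dir():
        meta_file = path / "clip.yaml"
        frame_files = sorted(path.glob("frame_*.png"))
        if not frame_files:
            raise DecodeError(f"no frames found in clip directory {path}")
        meta = yaml.safe_load(meta_file.read_text()) if meta_file.exists() else {}
        try:
            frames = np.stack([iio.imread(f) for f in frame_files])
        except Exception as exc:  # corrupted image
            raise DecodeError(f"could not decode frames in {path}: {exc}") from exc
        return VideoClip(frames=_ensure_rgb(frames),
                         fps=float(meta.get("fps", 25.0)),
                         clip_id=str(meta.get("clip_id", path.name)))
    # single-file route (multi-page TIFF)
    try:
        frames = np.asarray(iio.imread(path))
    except Exception as exc:
        raise DecodeError(f"could not decode video file {path}: {exc}") from exc
    if frames.ndim == 3 and frames.shape[-1] == 3:
        frames = frames[None]
    if frames.ndim != 4:
        raise DecodeError(f"{path} did not decode to a frame stack")
    side = path.with_suffix(".yaml")
    meta = yaml.safe_load(side.read_text()) if side.exists() else {}
    return VideoClip(frames=_ensure_rgb(frames),
                     fps=float(meta.get("fps", 25.0)),
                     clip_id=str(meta.get("clip_id", path.stem)))


def _ensure_rgb(frames: np.ndarray) -> np.ndarray:
    if frames.ndim == 3:  # grayscale stack
        frames = np.repeat(frames[..., None], 3, axis=-1)
    return frames.astype(np.uint8)


# ---------------------------------------------------------------------------
# landmark streams
# ---------------------------------------------------------------------------

#: retained joints of one hand, in serialisation order (palm centre already
#: dropped from the 21 extracted points, leaving these 20)
HAND_JOINT_LABELS: tuple[str, ...] = (
    "w",
    "t1", "t2", "t3",
    "i1", "i2", "i3", "i4",
    "m1", "m2", "m3", "m4",
    "r1", "r2", "r3", "r4",
    "p1", "p2", "p3", "p4",
)
# thumb 3 + four fingers x 4 + wrist = 20 retained joints
assert len(HAND_JOINT_LABELS) == 20

N_HAND_JOINTS = len(HAND_JOINT_LABELS)
N_EYE_POINTS = 6
N_BROW_POINTS = 3


@dataclass
class LandmarkStream:
    """Per-frame landmark records paired with a clip.

    left_eye / right_eye : (T, 6, 2) arrays, contour points l1..l6
        (l1 outer corner, l2/l3 upper lid, l4 inner corner, l5/l6 lower lid;
        pixel coordinates, origin top-left, x right, y down)
    brows  : (T, 3, 2) eyebrow points V1..V3
    hands  : (T, 2, 20, 2) joint positions for up to two hands
    has_eyes / has_hands : modality presence flags; absent => all-zero coords
    """

    left_eye: np.ndarray
    right_eye: np.ndarray
    brows: np.ndarray
    hands: np.ndarray
    has_eyes: bool = True
    has_hands: bool = True
    clip_id: str = "clip"

    def __post_init__(self) -> None:
        self.left_eye = np.asarray(self.left_eye, dtype=float)
        self.right_eye = np.asarray(self.right_eye, dtype=float)
        self.brows = np.asarray(self.brows, dtype=float)
        self.hands = np.asarray(self.hands, dtype=float)
        T = len(self.left_eye)
        if (self.right_eye.shape != (T, N_EYE_POINTS, 2)
                or self.left_eye.shape != (T, N_EYE_POINTS, 2)
                or self.brows.shape != (T, N_BROW_POINTS, 2)
                or self.hands.shape != (T, 2, N_HAND_JOINTS, 2)):
            raise ValueError("landmark arrays disagree on frame count or shape")
        if not self.has_hands and np.any(self.hands != 0):
            raise ValueError("hands flagged absent but coordinates are nonzero")
        if not self.has_eyes and (np.any(self.left_eye != 0)
                                  or np.any(self.right_eye != 0)):
            raise ValueError("eyes flagged absent but coordinates are nonzero")

    def __len__(self) -> int:
        return len(self.left_eye)


def _landmark_columns() -> list[str]:
    cols: list[str] = []
    for eye in ("le", "re"):
        for i in range(1, N_EYE_POINTS + 1):
            cols += [f"{eye}_l{i}_x", f"{eye}_l{i}_y"]
    for i in range(1, N_BROW_POINTS + 1):
        cols += [f"V{i}_x", f"V{i}_y"]
    for hand in ("h1", "h2"):
        for lab in HAND_JOINT_LABELS:
            cols += [f"{hand}_{lab}_x", f"{hand}_{lab}_y"]
    return cols


LANDMARK_COLUMNS = _landmark_columns()


def write_landmarks(stream: LandmarkStream, path: str | os.PathLike) -> Path:
    path = Path(path)
    T = len(stream)
    data = np.hstack([
        stream.left_eye.reshape(T, -1),
        stream.right_eye.reshape(T, -1),
        stream.brows.reshape(T, -1),
        stream.hands.reshape(T, -1),
    ])
    df = pd.DataFrame(data, columns=LANDMARK_COLUMNS)
    df.insert(0, "frame", np.arange(T))
    df["has_eyes"] = int(stream.has_eyes)
    df["has_hands"] = int(stream.has_hands)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_landmarks(path: str | os.PathLike, clip_id: str | None = None) -> LandmarkStream:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path} is missing landmark columns: {missing[:6]}...")
    T = len(df)
    vals = df[LANDMARK_COLUMNS].to_numpy(float)
    off = 0

    def take(n):
        nonlocal off
        out = vals[:, off:off + n]
        off += n
        return out

    le = take(N_EYE_POINTS * 2).reshape(T, N_EYE_POINTS, 2)
    re = take(N_EYE_POINTS * 2).reshape(T, N_EYE_POINTS, 2)
    brows = take(N_BROW_POINTS * 2).reshape(T, N_BROW_POINTS, 2)
    hands = take(2 * N_HAND_JOINTS * 2).reshape(T, 2, N_HAND_JOINTS, 2)
    return LandmarkStream(
        left_eye=le, right_eye=re, brows=brows, hands=hands,
        has_eyes=bool(df.get("has_eyes", pd.Series([1])).iloc[0]),
        has_hands=bool(df.get("has_hands", pd.Series([1])).iloc[0]),
        clip_id=clip_id or path.stem,
    )


# ---------------------------------------------------------------------------
# fused feature tables
# ---------------------------------------------------------------------------

LABELS = ("TRUTH", "LIE")


@dataclass
class FeatureTable:
    """Per-keyframe fused feature rows for one clip.

    ``data`` holds one row per keyframe with stable, named columns; ``label``
    is LIE or TRUTH.  Absent-modality columns are exactly zero, never NaN.
    """

    data: pd.DataFrame
    label: str
    clip_id: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.data.isna().any().any():
            raise ValueError("feature table must not contain missing cells")

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("keyframe",)]


def write_feature_table(table: FeatureTable, path: str | os.PathLike) -> Path:
    path = Path(path)
    out = table.data.copy()
    out.insert(0, "clip_id", table.clip_id)
    out["label"] = table.label
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)
    return path


def read_feature_table(path: str | os.PathLike,
                       expected_columns: list[str] | None = None) -> FeatureTable:
    path = Path(path)
    df = pd.read_csv(path)
    for required in ("clip_id", "label"):
        if required not in df.columns:
            raise SchemaError(f"{path} is missing the '{required}' column")
    if expected_columns is not None:
        have = [c for c in df.columns if c not in ("clip_id", "label")]
        if have != list(expected_columns):
            bad = sorted(set(have).symmetric_difference(expected_columns))
            raise SchemaError(f"{path} column mismatch: {bad}")
    label = str(df["label"].iloc[0])
    clip_id = str(df["clip_id"].iloc[0])
    data = df.drop(columns=["clip_id", "label"])
    return FeatureTable(data=data, label=label, clip_id=clip_id)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_report(report: dict, path: str | os.PathLike) -> Path:
    """Serialise an evaluation report (plain dict) as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    path.write_text(json.dumps(report, indent=2, default=_default))
    return path


def read_report(path: str | os.PathLike) -> dict:
    return json.loads(Path(path).read_text())
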
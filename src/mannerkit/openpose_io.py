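"""Reading/writing Body25 per-frame JSON and stable person tracking.

Pose-estimation output arrives as one JSON file per video frame, each with
a ``people`` list holding flat 75-number ``pose_keypoints_2d`` arrays
(25 keypoints x (x, y, confidence)). The pose estimator itself has no
notion of identity: person order within ``people`` is arbitrary and changes
between frames. :func:`track` assigns stable small-integer person ids by
matching centers of mass to the nearest center in the previous frame.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .body25 import N_KEYPOINTS
from .errors import FormatError, UndefinedCenterError

_FRAME_INDEX_RE = re.compile(r"(\d{12})_keypoints\.json$")


@dataclass(frozen=True)
class Keypoint:
    """One Body25 keypoint: pixel coordinates plus detection confidence.

    Undetected keypoints are encoded as ``(0, 0, 0)``.
    """

    x: float
    y: float
    confidence: float


class PersonDetection:
    """Exactly 25 Body25 keypoints for one person in one frame.

    Internally stored as a ``(25, 3)`` float array (columns x, y,
    confidence) for speed; :attr:`keypoints` exposes the list-of-Keypoint
    view.
    """

    __slots__ = ("data",)

    def __init__(self, data: np.ndarray):
        data = np.asarray(data, dtype=float)
        if data.shape != (N_KEYPOINTS, 3):
            raise FormatError(
                f"a person detection needs shape (25, 3), got {data.shape}"
            )
        self.data = data

    @classmethod
    def from_keypoints(cls, keypoints: Sequence[Keypoint]) -> "PersonDetection":
        if len(keypoints) != N_KEYPOINTS:
            raise FormatError(f"expected 25 keypoints, got {len(keypoints)}")
        return cls(np.array([(k.x, k.y, k.confidence) for k in keypoints]))

    @classmethod
    def from_flat(cls, flat: Sequence[float]) -> "PersonDetection":
        arr = np.asarray(flat, dtype=float)
        if arr.shape != (N_KEYPOINTS * 3,):
            raise FormatError(
                f"pose_keypoints_2d must hold 75 numbers, got {arr.size}"
            )
        return cls(arr.reshape(N_KEYPOINTS, 3))

    @property
    def keypoints(self) -> list[Keypoint]:
        return [Keypoint(*row) for row in self.data]

    def to_flat(self) -> list[float]:
        return self.data.reshape(-1).tolist()

    def __eq__(self, other) -> bool:
        return isinstance(other, PersonDetection) and np.array_equal(
            self.data, other.data
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        n = int(np.count_nonzero(self.data[:, 2] > 0))
        return f"PersonDetection({n}/25 detected keypoints)"


@dataclass
class FrameRecord:
    """All detections in one frame, in file order (identity-free)."""

    frame_index: int
    detections: list[PersonDetection] = field(default_factory=list)


@dataclass
class TrackedFrame:
    """Detections of one frame keyed by stable person id.

    Ids are small integers starting at 1, unique within a frame, and never
    re-assigned to a different individual within a segment.
    """

    frame_index: int
    persons: dict[int, PersonDetection] = field(default_factory=dict)


def frame_index_from_path(path: str | Path) -> int | None:
    """Extract the 12-digit frame index from a ``*_keypoints.json`` name."""
    m = _FRAME_INDEX_RE.search(str(path))
    return int(m.group(1)) if m else None


def read_frame_json(path: str | Path, frame_index: int | None = None) -> FrameRecord:
    """Parse one per-frame JSON file into a :class:`FrameRecord`.

    The frame index is taken from ``frame_index`` if given, else from the
    12-digit counter in the filename, else 0.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot parse keypoint file {path}: {exc}") from exc
    if not isinstance(doc, dict) or "people" not in doc:
        raise FormatError(f"keypoint file {path} has no 'people' array")
    detections = []
    for i, person in enumerate(doc["people"]):
        flat = person.get("pose_keypoints_2d")
        if flat is None:
            raise FormatError(
                f"person {i} in {path} has no 'pose_keypoints_2d' array"
            )
        try:
            detections.append(PersonDetection.from_flat(flat))
        except FormatError as exc:
            raise FormatError(f"person {i} in {path}: {exc}") from exc
    if frame_index is None:
        frame_index = frame_index_from_path(path) or 0
    return FrameRecord(frame_index=frame_index, detections=detections)


def write_frame_json(record: FrameRecord, path: str | Path) -> None:
    """Write a frame in the pose estimator's JSON dialect.

    Round-trips through :func:`read_frame_json` to float precision.
    """
    doc = {
        "version": 1.3,
        "people": [
            {"person_id": [-1], "pose_keypoints_2d": det.to_flat()}
            for det in record.detections
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def frame_paths(directory: str | Path) -> list[Path]:
    """List ``*_keypoints.json`` files ordered by their 12-digit index."""
    directory = Path(directory)
    paths = [p for p in directory.glob("*_keypoints.json")
             if frame_index_from_path(p) is not None]
    return sorted(paths, key=frame_index_from_path)


def read_frame_dir(directory: str | Path) -> list[FrameRecord]:
    """Read every frame file in a directory, ordered by frame index."""
    return [read_frame_json(p) for p in frame_paths(directory)]


def center_of_mass(detection: PersonDetection) -> tuple[float, float]:
    """Unweighted mean (x, y) over keypoints with confidence > 0.

    Raises :class:`UndefinedCenterError` when no keypoint was detected;
    callers must then treat the person as absent from the frame.
    """
    mask = detection.data[:, 2] > 0
    if not mask.any():
        raise UndefinedCenterError("detection has no keypoint with confidence > 0")
    xy = detection.data[mask, :2]
    cx, cy = xy.mean(axis=0)
    return float(cx), float(cy)


def track(
    frames: Iterable[FrameRecord],
    max_jump: float = 200.0,
) -> list[TrackedFrame]:
    """Assign stable person ids across frames by nearest center of mass.

    Matching is greedy in ascending distance between current detection
    centers and the last known centers of all previously seen persons
    (ties broken by lower previous id, then file order). Pairs farther
    apart than ``max_jump`` pixels are not matched; unmatched detections
    become a new person with id ``max(ids so far) + 1``. A person missing
    from a frame keeps its id and last known center for later re-matching.

    Detections whose center of mass is undefined (all confidences zero)
    are treated as absent and skipped.
    """
    last_centers: dict[int, tuple[float, float]] = {}
    next_id = 1
    out: list[TrackedFrame] = []
    for frame in frames:
        centers: list[tuple[int, tuple[float, float]]] = []
        for j, det in enumerate(frame.detections):
            try:
                centers.append((j, center_of_mass(det)))
            except UndefinedCenterError:
                continue

        candidates = []
        for pid, (px, py) in last_centers.items():
            for j, (cx, cy) in centers:
                dist = float(np.hypot(cx - px, cy - py))
                if dist <= max_jump:
                    candidates.append((dist, pid, j))
        candidates.sort()

        assignment: dict[int, int] = {}
        used_dets: set[int] = set()
        for dist, pid, j in candidates:
            if pid in assignment or j in used_dets:
                continue
            assignment[pid] = j
            used_dets.add(j)

        persons: dict[int, PersonDetection] = {}
        for pid, j in assignment.items():
            persons[pid] = frame.detections[j]
            last_centers[pid] = dict(centers)[j]
        for j, center in centers:
            if j in used_dets:
                continue
            persons[next_id] = frame.detections[j]
            last_centers[next_id] = center
            next_id += 1
        out.append(TrackedFrame(frame_index=frame.frame_index, persons=persons))
    return out
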
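"""From tracked keypoints to the classifier's (15, 60) windows.

The preprocessing is deliberately minimal: keypoints below a confidence
threshold are discarded (encoded as zeros, no interpolation), coordinates
are normalized by the frame resolution to [0, 1] so the features are
resolution-independent, the six arm keypoints of up to five persons are
laid side by side into a 60-vector per frame, and annotated intervals are
tiled into non-overlapping 15-frame windows that inherit the interval's
[flapping, jumping] label pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .annotations import AnnotationInterval, LabelVector, MannerismType, project_labels
from .body25 import ARM_KEYPOINTS
from .errors import ValidationError
from .openpose_io import FrameRecord, PersonDetection, TrackedFrame, track

log = logging.getLogger(__name__)

CONFIDENCE_THRESHOLD = 0.6
WINDOW_LEN = 15
MAX_PERSONS = 5
N_FEATURES = MAX_PERSONS * 2 * len(ARM_KEYPOINTS)  # 5 persons x 2 coords x 6 = 60


@dataclass(eq=False)  # identity comparison: features are arrays
class Window:
    """One classifier sample: 15 frames x 60 features plus its labels.

    ``source_labels`` keeps the full mannerism set of the originating
    interval (needed for balancing rules), while ``label`` is its
    projection onto the [flapping, jumping] targets.
    """

    subject_id: str
    camera_id: str
    start_frame: int
    features: np.ndarray  # (15, 60), values in [0, 1]
    label: LabelVector
    source_labels: frozenset[MannerismType] = frozenset()
    unclear: bool = False

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (WINDOW_LEN, N_FEATURES):
            raise ValidationError(
                f"window features must have shape ({WINDOW_LEN}, {N_FEATURES}), "
                f"got {self.features.shape}"
            )


def filter_low_confidence(
    detection: PersonDetection, threshold: float = CONFIDENCE_THRESHOLD
) -> PersonDetection:
    """Replace keypoints with confidence strictly below ``threshold`` by
    the missing encoding (0, 0, 0). A keypoint at exactly the threshold is
    kept."""
    if not 0 <= threshold <= 1:
        raise ValidationError(f"threshold must lie in [0, 1], got {threshold}")
    data = detection.data.copy()
    data[data[:, 2] < threshold] = 0.0
    return PersonDetection(data)


def normalize_detection(
    detection: PersonDetection, width: float, height: float
) -> PersonDetection:
    """Scale pixel coordinates into [0, 1] by the frame resolution.

    Confidence is unchanged. Coordinates outside the frame are clamped
    into [0, 1] with a warning.
    """
    if width <= 0 or height <= 0:
        raise ValidationError("resolution must be positive")
    data = detection.data.copy()
    data[:, 0] /= width
    data[:, 1] /= height
    xy = data[:, :2]
    if (xy > 1).any() or (xy < 0).any():
        log.warning("keypoint coordinates outside the frame were clamped to [0, 1]")
        np.clip(xy, 0.0, 1.0, out=xy)
    return PersonDetection(data)


def frame_features(
    tracked: TrackedFrame,
    selection: Sequence[int] = ARM_KEYPOINTS,
    max_persons: int = MAX_PERSONS,
) -> np.ndarray:
    """Lay the selected keypoints of up to ``max_persons`` persons side by
    side into one feature vector.

    Persons occupy slots in ascending person-id order; each slot holds
    (x, y) for the six selected keypoints in fixed order. Absent persons
    and filtered keypoints contribute zeros. With more tracked persons
    than slots, the lowest ids are kept (warned).
    """
    n_sel = len(selection)
    vec = np.zeros(max_persons * 2 * n_sel)
    ids = sorted(tracked.persons)
    if len(ids) > max_persons:
        log.warning(
            "frame %d has %d tracked persons; keeping the %d lowest ids",
            tracked.frame_index, len(ids), max_persons,
        )
        ids = ids[:max_persons]
    for slot, pid in enumerate(ids):
        xy = tracked.persons[pid].data[list(selection), :2]
        vec[slot * 2 * n_sel:(slot + 1) * 2 * n_sel] = xy.reshape(-1)
    return vec


def segment_feature_matrix(
    tracked_frames: Sequence[TrackedFrame],
    width: float,
    height: float,
    threshold: float = CONFIDENCE_THRESHOLD,
    selection: Sequence[int] = ARM_KEYPOINTS,
    max_persons: int = MAX_PERSONS,
) -> np.ndarray:
    """Filter, normalize, and featurize every frame of a segment.

    Returns an ``(n_frames, 60)`` matrix aligned with frame order.
    """
    rows = []
    for tf in tracked_frames:
        persons = {
            pid: normalize_detection(filter_low_confidence(det, threshold), width, height)
            for pid, det in tf.persons.items()
        }
        rows.append(frame_features(
            TrackedFrame(tf.frame_index, persons), selection, max_persons
        ))
    return np.array(rows) if rows else np.zeros((0, max_persons * 2 * len(selection)))


def windowize(
    interval: AnnotationInterval,
    segment_features: np.ndarray,
    fps: float = 25.0,
    window_len: int = WINDOW_LEN,
    camera_id: str | None = None,
) -> list[Window]:
    """Cut an interval into consecutive non-overlapping 15-frame windows.

    ``segment_features`` is the whole segment's feature matrix (frame 0 at
    row 0); the interval selects its frame span from it. Windows start at
    the interval's first frame; a trailing remainder shorter than
    ``window_len`` is discarded, so an interval under 15 frames yields no
    window. Each window inherits the projected [flapping, jumping] label.
    """
    start_f, end_f = interval.frame_span(fps)
    end_f = min(end_f, len(segment_features))
    label = project_labels(interval.labels)
    cam = camera_id if camera_id is not None else (interval.camera_id or "cam1")
    windows = []
    for ws in range(start_f, end_f - window_len + 1, window_len):
        windows.append(Window(
            subject_id=interval.subject_id,
            camera_id=cam,
            start_frame=ws,
            features=segment_features[ws:ws + window_len],
            label=label,
            source_labels=interval.labels,
            unclear=interval.unclear,
        ))
    return windows


def featurize_segment(
    frames: Sequence[FrameRecord],
    intervals: Sequence[AnnotationInterval],
    width: float,
    height: float,
    fps: float = 25.0,
    threshold: float = CONFIDENCE_THRESHOLD,
    max_jump: float = 200.0,
    window_len: int = WINDOW_LEN,
    camera_id: str | None = None,
) -> list[Window]:
    """Track one camera's frames and windowize its annotated intervals."""
    tracked = track(frames, max_jump=max_jump)
    feats = segment_feature_matrix(tracked, width, height, threshold)
    out: list[Window] = []
    for iv in intervals:
        out.extend(windowize(iv, feats, fps, window_len, camera_id))
    return out


def windows_to_arrays(
    windows: Sequence[Window],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack windows into (X, Y, subjects) arrays for training."""
    X = np.stack([w.features for w in windows])
    Y = np.array([w.label.as_tuple() for w in windows], dtype=float)
    subjects = np.array([w.subject_id for w in windows])
    return X, Y, subjects
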
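"""Mannerism coding scheme, interval ground truth, and dataset balancing.

The coding scheme distinguishes seven mannerism categories observed in
videotaped play sessions. Only the two most frequent and most reliably
coded ones — arm flapping and jumping — are classifier targets; the model
assigns zero or more of them to each 15-frame window (multi-label), so a
window is one of "no mannerism", "flapping", "jumping", or
"flapping and jumping".
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import InsufficientNegativesError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .features import Window


class MannerismType(str, enum.Enum):
    """The seven coded mannerism categories."""

    FLAPPING = "flapping"        # flapping with arms
    CLAPPING = "clapping"        # clapping hands together or on the body
    JUMPING = "jumping"
    HAND_FINGER = "hand_finger"  # fast hand/finger movements or odd posture
    LEGS = "legs"                # movements with legs
    TIPTOEING = "tiptoeing"
    BODY = "body"                # body movements/postures incl. rocking


@dataclass(frozen=True)
class LabelVector:
    """Binary multi-label target: [flapping, jumping].

    ``(0, 0)`` means "no mannerism"; all four combinations are valid.
    """

    flapping: int
    jumping: int

    def __post_init__(self):
        if self.flapping not in (0, 1) or self.jumping not in (0, 1):
            raise ValidationError("label bits must be 0 or 1")

    @property
    def is_positive(self) -> bool:
        return bool(self.flapping or self.jumping)

    def as_tuple(self) -> tuple[int, int]:
        return (self.flapping, self.jumping)

    @property
    def powerset_class(self) -> int:
        """Stratum index 0..3 over the label powerset."""
        return self.flapping * 2 + self.jumping

    def __iter__(self):
        return iter(self.as_tuple())


@dataclass(frozen=True)
class AnnotationInterval:
    """One coded occurrence: a time span with its mannerism label set.

    An empty ``labels`` set is an explicit "no mannerism" span. Intervals
    flagged ``unclear`` (presence of the mannerism not definitive) are
    excluded from training entirely.
    """

    subject_id: str
    segment_id: str
    start_s: float
    end_s: float
    labels: frozenset[MannerismType] = frozenset()
    unclear: bool = False
    specifiers: str = ""
    camera_id: str | None = None

    def __post_init__(self):
        if not (0 <= self.start_s < self.end_s):
            raise ValidationError(
                f"interval for {self.subject_id} needs 0 <= start < end, "
                f"got [{self.start_s}, {self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def frame_span(self, fps: float) -> tuple[int, int]:
        """Half-open frame range covered by the interval at ``fps``."""
        return round(self.start_s * fps), round(self.end_s * fps)


def parse_label_field(text: str) -> frozenset[MannerismType]:
    """Parse a '+'-joined label field; '' or 'none' mean no mannerism."""
    text = (text or "").strip()
    if text in ("", "none"):
        return frozenset()
    labels = set()
    for token in text.split("+"):
        token = token.strip()
        try:
            labels.add(MannerismType(token))
        except ValueError:
            raise ValidationError(f"unknown mannerism label {token!r}") from None
    return frozenset(labels)


def format_label_field(labels: Iterable[MannerismType]) -> str:
    return "+".join(sorted(l.value for l in labels))


_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False}


def parse_annotations(path: str | Path) -> list[AnnotationInterval]:
    """Read an interval annotation CSV.

    Required columns: ``subject_id, segment_id, start_s, end_s, labels,
    unclear``; ``camera_id`` and ``specifiers`` are optional. Rows failing
    validation raise :class:`ValidationError` naming the row number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"subject_id", "segment_id", "start_s", "end_s", "labels", "unclear"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    intervals = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            unclear = _BOOL.get(str(row.unclear).strip().lower())
            if unclear is None:
                raise ValidationError(f"bad unclear flag {row.unclear!r}")
            intervals.append(AnnotationInterval(
                subject_id=row.subject_id,
                segment_id=row.segment_id,
                start_s=float(row.start_s),
                end_s=float(row.end_s),
                labels=parse_label_field(row.labels),
                unclear=unclear,
                specifiers=getattr(row, "specifiers", ""),
                camera_id=getattr(row, "camera_id", None) or None,
            ))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
    return intervals


def write_annotations(intervals: Sequence[AnnotationInterval], path: str | Path) -> None:
    """Write intervals as the annotation CSV carrier format."""
    df = pd.DataFrame({
        "subject_id": [iv.subject_id for iv in intervals],
        "segment_id": [iv.segment_id for iv in intervals],
        "camera_id": [iv.camera_id or "" for iv in intervals],
        "start_s": [iv.start_s for iv in intervals],
        "end_s": [iv.end_s for iv in intervals],
        "labels": [format_label_field(iv.labels) for iv in intervals],
        "unclear": [str(iv.unclear).lower() for iv in intervals],
        "specifiers": [iv.specifiers for iv in intervals],
    })
    df.to_csv(path, index=False)


def project_labels(labels: Iterable[MannerismType]) -> LabelVector:
    """Project a full label set onto the [flapping, jumping] targets.

    All other categories (clapping, hand/finger, legs, tiptoeing, body)
    carry no target bit of their own: clapping mostly co-occurred with
    other mannerisms and the rest were too rare or unreliably coded.
    """
    labels = set(labels)
    return LabelVector(
        flapping=int(MannerismType.FLAPPING in labels),
        jumping=int(MannerismType.JUMPING in labels),
    )


def select_and_balance(windows: Sequence["Window"], seed: int) -> list["Window"]:
    """Undersample no-mannerism windows to a 1:1 balanced dataset.

    Positives are windows whose source interval contains flapping or
    jumping (other mannerisms may co-occur). The negative pool holds
    windows from intervals with an empty label set — no mannerism of any
    coded type — from which exactly ``len(positives)`` are drawn uniformly
    without replacement across all subjects. Windows from unclear-flagged
    intervals, or from intervals carrying only non-target mannerisms, are
    excluded from both classes.
    """
    positives = [w for w in windows if not w.unclear and w.label.is_positive]
    pool = [w for w in windows if not w.unclear and not w.source_labels]
    if not positives:
        raise ValidationError("no positive (flapping/jumping) windows to balance")
    if len(pool) < len(positives):
        raise InsufficientNegativesError(
            f"need {len(positives)} no-mannerism windows, pool has {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=len(positives), replace=False)
    negatives = [pool[i] for i in sorted(idx)]
    return positives + negatives


def gap_intervals(
    intervals: Sequence[AnnotationInterval],
    duration_s: float,
    subject_id: str,
    segment_id: str,
    camera_id: str | None = None,
    min_gap_s: float = 0.6,
) -> list[AnnotationInterval]:
    """Derive explicit no-mannerism intervals from uncovered spans.

    Useful when an annotation table codes only occurrences: any stretch of
    the segment not covered by a coded interval and at least ``min_gap_s``
    long becomes an empty-label interval.
    """
    events = sorted((iv.start_s, iv.end_s) for iv in intervals)
    gaps = []
    cursor = 0.0
    for start, end in events:
        if start - cursor >= min_gap_s:
            gaps.append((cursor, start))
        cursor = max(cursor, end)
    if duration_s - cursor >= min_gap_s:
        gaps.append((cursor, duration_s))
    return [
        AnnotationInterval(subject_id=subject_id, segment_id=segment_id,
                           start_s=a, end_s=b, camera_id=camera_id)
        for a, b in gaps
    ]
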
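"""Kinematic simulator: multi-person skeletal scenes with scripted mannerisms.

The study's videos are private, so the package ships a generator that
emulates what the pose estimator would have emitted for a free-play
observation: a child plus static adults (tester, caregiver, optionally a
walker entering and leaving view), recorded by two opposite cameras at
1920x1080 / 25 fps. Arm flapping is modeled as a high-frequency sinusoidal
vertical oscillation of wrists and elbows; jumping as a slower whole-body
vertical oscillation; their combination is the sum of both. Adults never
carry mannerism kinematics. Keypoint confidence follows a high Beta mode
with a configurable dropout mixture below the 0.6 filter threshold, so
confidence filtering stays meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import body25
from .annotations import (
    AnnotationInterval,
    MannerismType,
    project_labels,
    write_annotations,
)
from .errors import ValidationError
from .openpose_io import FrameRecord, PersonDetection, write_frame_json

BEHAVIORS = ("none", "flapping", "jumping", "flapping+jumping")


@dataclass(frozen=True)
class ScheduledBehavior:
    """One scripted behavior interval for one subject."""

    behavior: str
    start_s: float
    end_s: float

    def __post_init__(self):
        if self.behavior not in BEHAVIORS:
            raise ValidationError(f"unknown behavior {self.behavior!r}")
        if not (0 <= self.start_s < self.end_s):
            raise ValidationError(
                f"behavior interval needs 0 <= start < end, "
                f"got [{self.start_s}, {self.end_s})"
            )


@dataclass
class SimConfig:
    """Study-condition parameters of the simulator.

    Defaults mirror the recording setup being emulated: two Full HD
    (1920x1080) cameras at 25 fps, a child with up to two adults present.
    Kinematic defaults place flapping well above the per-keypoint jitter
    (sigma 2 px): 4 Hz / 40 px at the wrists and elbows, and jumping at
    2 Hz / 60 px body-wide.
    """

    n_subjects: int
    segment_duration_s: float
    behavior_schedule: dict[str, list[ScheduledBehavior]]
    fps: float = 25.0
    resolution: tuple[int, int] = (1920, 1080)
    n_cameras: int = 2
    max_adults: int = 2
    flap_freq_hz: float = 4.0
    flap_amp_px: float = 40.0
    jump_freq_hz: float = 2.0
    jump_amp_px: float = 60.0
    jitter_px: float = 2.0
    dropout_prob: float = 0.05
    walker_presence: dict[str, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.fps <= 0:
            raise ValidationError("fps must be positive")
        if self.n_cameras < 1 or self.max_adults < 0:
            raise ValidationError("n_cameras >= 1 and max_adults >= 0 required")
        if not 0 <= self.dropout_prob < 1:
            raise ValidationError("dropout_prob must lie in [0, 1)")
        if self.flap_amp_px <= self.jitter_px or self.jump_amp_px <= self.jitter_px:
            raise ValidationError(
                "mannerism amplitudes must exceed the jitter standard deviation"
            )
        if self.flap_freq_hz <= 0 or self.jump_freq_hz <= 0:
            raise ValidationError("mannerism frequencies must be positive")
        for subject, schedule in self.behavior_schedule.items():
            prev_end = {}
            for sb in sorted(schedule, key=lambda s: s.start_s):
                if sb.end_s > self.segment_duration_s + 1e-9:
                    raise ValidationError(
                        f"{subject}: interval [{sb.start_s}, {sb.end_s}) exceeds "
                        f"the {self.segment_duration_s} s segment"
                    )
                if prev_end and sb.start_s < prev_end["end"] - 1e-9:
                    raise ValidationError(
                        f"{subject}: overlapping behavior intervals"
                    )
                prev_end["end"] = sb.end_s

    @property
    def n_frames(self) -> int:
        return int(round(self.segment_duration_s * self.fps))

    def subject_ids(self) -> list[str]:
        return sorted(self.behavior_schedule)

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "segment_duration_s": self.segment_duration_s,
            "fps": self.fps,
            "resolution": list(self.resolution),
            "n_cameras": self.n_cameras,
            "max_adults": self.max_adults,
            "flap_freq_hz": self.flap_freq_hz,
            "flap_amp_px": self.flap_amp_px,
            "jump_freq_hz": self.jump_freq_hz,
            "jump_amp_px": self.jump_amp_px,
            "jitter_px": self.jitter_px,
            "dropout_prob": self.dropout_prob,
            "seed": self.seed,
            "walker_presence": {k: list(v) for k, v in self.walker_presence.items()},
            "behavior_schedule": {
                s: [[sb.behavior, sb.start_s, sb.end_s] for sb in sched]
                for s, sched in self.behavior_schedule.items()
            },
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SimConfig":
        doc = dict(doc)
        doc["resolution"] = tuple(doc.get("resolution", (1920, 1080)))
        doc["walker_presence"] = {
            k: tuple(v) for k, v in doc.get("walker_presence", {}).items()
        }
        doc["behavior_schedule"] = {
            s: [ScheduledBehavior(*row) for row in sched]
            for s, sched in doc["behavior_schedule"].items()
        }
        return cls(**doc)


@dataclass
class SimOutput:
    """Everything one simulated cohort produced, in memory.

    ``frames[(subject_id, camera_id)]`` holds the ordered frame records;
    ``annotations`` the ground-truth intervals (one copy per camera, as
    each camera's stream is windowized independently); ``truth`` a
    per-interval table with the expected window counts and label bits.
    """

    config: SimConfig
    frames: dict[tuple[str, str], list[FrameRecord]]
    annotations: list[AnnotationInterval]
    truth: pd.DataFrame


def flapping_offset(t: float, freq: float, amp: float):
    """Vertical arm-flapping displacement ``amp * sin(2 pi freq t)`` in px,
    applied to the wrist and elbow keypoints of both arms."""
    if freq <= 0:
        raise ValidationError("freq must be positive")
    if amp < 0:
        raise ValidationError("amp must be non-negative")
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValidationError("t must be finite")
    out = amp * np.sin(2 * math.pi * freq * t)
    return float(out) if out.ndim == 0 else out


def jumping_offset(t: float, freq: float, amp: float):
    """Vertical whole-body jumping displacement, same closed form as
    :func:`flapping_offset` but applied to all 25 keypoints. During
    combined flapping+jumping the two offsets add at the arm keypoints."""
    return flapping_offset(t, freq, amp)


# Person layout: (role, height as fraction of frame height, body-midline x
# as fraction of width, head-top y as fraction of height). Fractional so the
# same scene renders consistently at any resolution.
_CHILD = ("child", 0.213, 0.50, 0.519)
_ADULTS = (
    ("tester", 0.361, 0.22, 0.389),
    ("caregiver", 0.361, 0.78, 0.398),
)
_WALKER = ("walker", 0.343, 0.63, 0.394)

_BEHAVIOR_LABELS = {
    "none": frozenset(),
    "flapping": frozenset({MannerismType.FLAPPING}),
    "jumping": frozenset({MannerismType.JUMPING}),
    "flapping+jumping": frozenset({MannerismType.FLAPPING, MannerismType.JUMPING}),
}


def _full_schedule(config: SimConfig, subject: str) -> list[ScheduledBehavior]:
    """Scheduled intervals plus explicit none-fills for uncovered time."""
    sched = sorted(config.behavior_schedule[subject], key=lambda s: s.start_s)
    full = []
    cursor = 0.0
    for sb in sched:
        if sb.start_s - cursor > 1e-9:
            full.append(ScheduledBehavior("none", cursor, sb.start_s))
        full.append(sb)
        cursor = sb.end_s
    if config.segment_duration_s - cursor > 1e-9:
        full.append(ScheduledBehavior("none", cursor, config.segment_duration_s))
    return full


def _confidences(rng: np.random.Generator, shape, dropout_prob: float) -> np.ndarray:
    """High Beta(8, 2) mode rescaled into [0.6, 1], mixed with a
    ``dropout_prob`` mass of Uniform(0, 0.6) below the filter threshold."""
    high = 0.6 + 0.4 * rng.beta(8.0, 2.0, size=shape)
    low = rng.uniform(0.0, 0.6, size=shape)
    drop = rng.random(size=shape) < dropout_prob
    return np.where(drop, low, high)


def _simulate_subject(
    config: SimConfig, subject: str, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Emit per-person coordinate/confidence arrays for one subject's segment.

    Returns ``{"coords": (P, F, 25, 2), "conf": (P, F, 25),
    "present": (P, F) bool}`` with the child always person 0.
    """
    width, height = config.resolution
    n = config.n_frames
    t = np.arange(n) / config.fps

    roles = [_CHILD] + list(_ADULTS[: config.max_adults])
    walker_span = config.walker_presence.get(subject)
    if walker_span is not None:
        roles.append(_WALKER)

    coords = np.empty((len(roles), n, body25.N_KEYPOINTS, 2))
    present = np.ones((len(roles), n), dtype=bool)
    for p, (role, h_frac, x_frac, head_frac) in enumerate(roles):
        base = body25.skeleton_template(
            h_frac * height, x_frac * width, head_frac * height
        )
        coords[p] = base[None, :, :] + rng.normal(
            0.0, config.jitter_px, size=(n, body25.N_KEYPOINTS, 2)
        )
        if role == "walker":
            a, b = walker_span
            inside = (t >= a) & (t < b)
            present[p] = inside

    # Mannerism kinematics on the child only (person 0): upward (negative y)
    # sinusoidal displacement.
    for sb in config.behavior_schedule[subject]:
        active = (t >= sb.start_s) & (t < sb.end_s)
        if sb.behavior in ("jumping", "flapping+jumping"):
            off = jumping_offset(t[active], config.jump_freq_hz, config.jump_amp_px)
            coords[0, active, :, 1] -= off[:, None]
        if sb.behavior in ("flapping", "flapping+jumping"):
            off = flapping_offset(t[active], config.flap_freq_hz, config.flap_amp_px)
            ai = np.where(active)[0]
            sel = np.ix_(ai, list(body25.FLAPPING_KEYPOINTS), [1])
            coords[0][sel] -= off[:, None, None]

    conf = _confidences(rng, (len(roles), n, body25.N_KEYPOINTS), config.dropout_prob)
    return {"coords": coords, "conf": conf, "present": present}


def simulate_cohort(config: SimConfig, out_dir: str | Path | None = None) -> SimOutput:
    """Run the simulator for every subject and camera.

    Deterministic given ``config`` (including its seed). Camera 2 is the
    x-mirrored view of camera 1 (``x' = width - x``), exercising the
    both-cameras-as-augmentation path without 3D projection. When
    ``out_dir`` is given, per-frame JSON files, the annotation CSV, and a
    YAML copy of the config are written beneath it.
    """
    width, _ = config.resolution
    rng = np.random.default_rng(config.seed)
    frames: dict[tuple[str, str], list[FrameRecord]] = {}
    annotations: list[AnnotationInterval] = []
    truth_rows = []
    cameras = [f"cam{i + 1}" for i in range(config.n_cameras)]

    for subject in config.subject_ids():
        arrays = _simulate_subject(config, subject, rng)
        coords, conf, present = arrays["coords"], arrays["conf"], arrays["present"]
        n_persons, n_frames = present.shape
        for ci, cam in enumerate(cameras):
            cam_coords = coords.copy()
            if ci % 2 == 1:
                cam_coords[..., 0] = width - cam_coords[..., 0]
            recs = []
            for f in range(n_frames):
                dets = []
                for p in range(n_persons):
                    if not present[p, f]:
                        continue
                    data = np.concatenate(
                        [cam_coords[p, f], conf[p, f, :, None]], axis=1
                    )
                    dets.append(PersonDetection(data))
                recs.append(FrameRecord(frame_index=f, detections=dets))
            frames[(subject, cam)] = recs

        for sb in _full_schedule(config, subject):
            labels = _BEHAVIOR_LABELS[sb.behavior]
            for cam in cameras:
                iv = AnnotationInterval(
                    subject_id=subject, segment_id="seg1",
                    start_s=sb.start_s, end_s=sb.end_s,
                    labels=labels, camera_id=cam,
                )
                annotations.append(iv)
                start_f, end_f = iv.frame_span(config.fps)
                lv = project_labels(labels)
                truth_rows.append({
                    "subject_id": subject, "camera_id": cam,
                    "start_s": sb.start_s, "end_s": sb.end_s,
                    "n_windows": max(0, (end_f - start_f) // 15),
                    "flapping": lv.flapping, "jumping": lv.jumping,
                })

    truth = pd.DataFrame(truth_rows)
    out = SimOutput(config=config, frames=frames, annotations=annotations, truth=truth)
    if out_dir is not None:
        write_sim_output(out, out_dir)
    return out


def write_sim_output(out: SimOutput, out_dir: str | Path) -> Path:
    """Write frame files, the annotation CSV, and the config YAML.

    Layout: ``frames/<subject>/<camera>/<subject>_<camera>_%012d_keypoints.json``
    plus ``annotations.csv``, ``truth.csv`` and ``sim_config.yaml``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    for (subject, cam), recs in out.frames.items():
        d = out_dir / "frames" / subject / cam
        d.mkdir(parents=True, exist_ok=True)
        for rec in recs:
            write_frame_json(
                rec, d / f"{subject}_{cam}_{rec.frame_index:012d}_keypoints.json"
            )
    write_annotations(out.annotations, out_dir / "annotations.csv")
    out.truth.to_csv(out_dir / "truth.csv", index=False)
    with open(out_dir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(out.config.to_dict(), fh, sort_keys=True)
    return out_dir


def default_cohort(
    n_subjects: int = 20,
    segment_duration_s: float = 24.0,
    seed: int = 0,
    dropout_prob: float = 0.05,
    **overrides,
) -> SimConfig:
    """A cohort whose schedule covers all four behavior classes.

    Each subject performs two 4-second mannerism intervals (at 4-8 s and
    14-18 s) drawn from a per-subject pattern cycling through
    flapping/jumping, both/flapping, and jumping/both, leaving 16 s of
    no-mannerism time per segment so the negative pool exceeds the
    positive count. Every fifth subject has a walker crossing the scene
    mid-segment to exercise new-person id assignment.
    """
    patterns = [
        ("flapping", "jumping"),
        ("flapping+jumping", "flapping"),
        ("jumping", "flapping+jumping"),
    ]
    schedule = {}
    walkers = {}
    d = segment_duration_s
    marks = [round(f * d, 3) for f in (0, 1 / 6, 1 / 3, 7 / 12, 3 / 4, 1)]
    for i in range(n_subjects):
        subject = f"s{i + 1:02d}"
        a, b = patterns[i % len(patterns)]
        schedule[subject] = [
            ScheduledBehavior("none", marks[0], marks[1]),
            ScheduledBehavior(a, marks[1], marks[2]),
            ScheduledBehavior("none", marks[2], marks[3]),
            ScheduledBehavior(b, marks[3], marks[4]),
            ScheduledBehavior("none", marks[4], marks[5]),
        ]
        if i % 5 == 0:
            walkers[subject] = (round(3 / 8 * d, 3), round(13 / 24 * d, 3))
    return SimConfig(
        n_subjects=n_subjects,
        segment_duration_s=segment_duration_s,
        behavior_schedule=schedule,
        walker_presence=walkers,
        dropout_prob=dropout_prob,
        seed=seed,
        **overrides,
    )
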
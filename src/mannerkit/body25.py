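"""Body25 keypoint convention: index constants and a stick-figure template.

The Body25 output format encodes each detected person as 25 keypoints in a
fixed order, each an ``(x, y, confidence)`` triple flattened into a
75-number array. Coordinates are 0-based pixels with the origin at the
top-left corner and y increasing downward.
"""

from __future__ import annotations

import numpy as np

N_KEYPOINTS = 25

NOSE = 0
NECK = 1
R_SHOULDER = 2
R_ELBOW = 3
R_WRIST = 4
L_SHOULDER = 5
L_ELBOW = 6
L_WRIST = 7
MID_HIP = 8
R_HIP = 9
R_KNEE = 10
R_ANKLE = 11
L_HIP = 12
L_KNEE = 13
L_ANKLE = 14
R_EYE = 15
L_EYE = 16
R_EAR = 17
L_EAR = 18
L_BIG_TOE = 19
L_SMALL_TOE = 20
L_HEEL = 21
R_BIG_TOE = 22
R_SMALL_TOE = 23
R_HEEL = 24

KEYPOINT_NAMES = (
    "nose", "neck",
    "r_shoulder", "r_elbow", "r_wrist",
    "l_shoulder", "l_elbow", "l_wrist",
    "mid_hip", "r_hip", "r_knee", "r_ankle",
    "l_hip", "l_knee", "l_ankle",
    "r_eye", "l_eye", "r_ear", "l_ear",
    "l_big_toe", "l_small_toe", "l_heel",
    "r_big_toe", "r_small_toe", "r_heel",
)

#: The six upper-limb keypoints used as classifier features, in fixed order:
#: right shoulder, right elbow, right wrist, left shoulder, left elbow,
#: left wrist.
ARM_KEYPOINTS = (R_SHOULDER, R_ELBOW, R_WRIST, L_SHOULDER, L_ELBOW, L_WRIST)

#: Keypoints displaced by the arm-flapping kinematic (wrists and elbows of
#: both arms).
FLAPPING_KEYPOINTS = (R_ELBOW, R_WRIST, L_ELBOW, L_WRIST)

# Upright stick-figure template: per keypoint (x offset, y offset) in units
# of person height, y measured downward from the top of the head. Scaled by
# height in pixels and anchored at a base position to place a person.
_TEMPLATE = np.array([
    (0.00, 0.06),   # nose
    (0.00, 0.18),   # neck
    (-0.10, 0.18),  # r_shoulder
    (-0.14, 0.33),  # r_elbow
    (-0.16, 0.47),  # r_wrist
    (0.10, 0.18),   # l_shoulder
    (0.14, 0.33),   # l_elbow
    (0.16, 0.47),   # l_wrist
    (0.00, 0.52),   # mid_hip
    (-0.06, 0.52),  # r_hip
    (-0.07, 0.74),  # r_knee
    (-0.07, 0.95),  # r_ankle
    (0.06, 0.52),   # l_hip
    (0.07, 0.74),   # l_knee
    (0.07, 0.95),   # l_ankle
    (-0.02, 0.04),  # r_eye
    (0.02, 0.04),   # l_eye
    (-0.05, 0.05),  # r_ear
    (0.05, 0.05),   # l_ear
    (0.09, 0.99),   # l_big_toe
    (0.11, 0.98),   # l_small_toe
    (0.06, 1.00),   # l_heel
    (-0.09, 0.99),  # r_big_toe
    (-0.11, 0.98),  # r_small_toe
    (-0.06, 1.00),  # r_heel
], dtype=float)


def skeleton_template(height_px: float, base_x: float, head_top_y: float) -> np.ndarray:
    """Return a (25, 2) array of pixel coordinates for an upright person.

    ``height_px`` scales the template, ``base_x`` places the body midline,
    and ``head_top_y`` is the y pixel of the top of the head.
    """
    pts = _TEMPLATE * height_px
    pts = pts + np.array([base_x, head_top_y])
    return pts
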
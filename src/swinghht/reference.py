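"""Reference values from a published golf-swing inertial-capture study.

These small tables are study *inputs* for worked examples and consistency
checks; the package never emits them as results. All captures were recorded
at 120 Hz and trimmed per trajectory group after synchronizing the six
swings of each group to a common impact point.

``CAPTURE_LOG`` rows: per trajectory group, the printed swing time (s),
frame count, and 0-based impact-frame position after trimming.

``NECK_FREQUENCY_STATS`` rows: per IMF index (1 = fastest), the printed
mean +/- SD (Hz) and coefficient of variation of the instantaneous
frequency of the neck joint, straight-trajectory swings, averaged over six
swings, for five subjects.
"""

from __future__ import annotations

CAPTURE_FRAME_RATE = 120.0

# (group, time_s, frames, impact_frame)
CAPTURE_LOG = (
    ("straight", 1.93, 231, 144),
    ("slice_head_up", 1.90, 228, 132),
    ("slice_opening", 1.89, 227, 130),
)

# subject -> {imf_index: (mean_hz, sd_hz, cv)}
NECK_FREQUENCY_STATS = {
    "average_golfer": {
        1: (31.57, 12.45, 0.39),
        2: (22.48, 3.64, 0.16),
        3: (11.58, 3.29, 0.28),
        4: (6.73, 2.37, 0.35),
        5: (3.65, 0.92, 0.25),
        6: (2.35, 0.57, 0.24),
        7: (1.30, 0.55, 0.42),
    },
    "single_handicapper": {
        1: (26.88, 10.93, 0.41),
        2: (21.02, 4.71, 0.22),
        3: (10.23, 4.72, 0.46),
        4: (5.20, 2.50, 0.48),
        5: (3.50, 1.58, 0.45),
        6: (2.16, 0.52, 0.24),
        7: (0.94, 0.82, 0.87),
    },
    "beginner_1": {
        1: (36.53, 13.31, 0.36),
        2: (24.56, 3.61, 0.15),
        3: (14.23, 2.30, 0.16),
        4: (7.48, 1.45, 0.19),
        5: (4.16, 1.41, 0.34),
        6: (2.06, 0.58, 0.28),
        7: (1.22, 0.95, 0.78),
    },
    "beginner_2": {
        1: (27.70, 11.10, 0.40),
        2: (20.15, 3.16, 0.16),
        3: (12.16, 1.63, 0.13),
        4: (6.15, 1.58, 0.26),
        5: (3.04, 1.04, 0.34),
        6: (1.96, 0.69, 0.35),
        7: (0.62, 0.30, 0.48),
    },
    "beginner_3": {
        1: (34.52, 9.28, 0.27),
        2: (22.59, 3.23, 0.14),
        3: (12.73, 2.28, 0.18),
        4: (6.63, 1.15, 0.17),
        5: (4.06, 1.39, 0.34),
        6: (1.45, 0.59, 0.41),
        7: (1.28, 1.14, 0.89),
    },
}

#: joints most implicated in slice-producing movement: the head (neck) and
#: the left half of the body (lead side for a right-handed golfer)
IMPORTANT_JOINTS = ("Neck", "LeftArm", "LeftUpLeg", "LeftLeg")
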
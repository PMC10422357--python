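"""Seeded generator of motion-like multichannel signals and swing datasets.

Real golf-swing captures are ~1.9 s of 120 Hz Euler angles per joint: a slow
posture trend spanning address -> backswing -> follow-through, a handful of
AM/FM oscillatory components spread over roughly 1-35 Hz, and a sharp
high-frequency burst centered on the impact. The generator emulates exactly
that structure so every pipeline stage is testable end to end:

* per joint, a smooth trend plus amplitude-modulated tones at 3, 8 and
  24 Hz (straddling the per-mode frequency bands observed in swing data)
  and a 24 Hz impact-centered burst;
* optional planted faults as extra pre-impact bursts in the 5-10 Hz band,
  0.15 s wide: ``head_up`` into the Neck channels, ``opening`` into
  LeftUpLeg + LeftLeg (the movements that open the club face and slice the
  ball);
* small Gaussian sensor noise.

Everything is deterministic under a fixed seed, and the exact per-component
series are returned alongside the rendered clip for oracle checks.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .bvh import Joint, MotionClip, Skeleton, write_bvh

__all__ = [
    "Component",
    "SwingRecipe",
    "render",
    "default_recipe",
    "make_dataset",
    "DEFAULT_SKELETON_JOINTS",
    "FAULT_JOINTS",
]

#: joints of the compact synthetic skeleton (root first)
DEFAULT_SKELETON_JOINTS = (
    "Hips",
    "Spine",
    "Neck",
    "LeftArm",
    "RightArm",
    "LeftUpLeg",
    "LeftLeg",
    "RightUpLeg",
    "RightLeg",
)

#: which joints receive the planted pre-impact burst, per fault kind
FAULT_JOINTS = {
    "none": (),
    "head_up": ("Neck",),
    "opening": ("LeftUpLeg", "LeftLeg"),
}

#: study-like jitter bounds: trimmed captures ran 227-231 frames with the
#: impact landing between frames 130 and 144
FRAME_BOUNDS = (227, 231)
IMPACT_BOUNDS = (130, 144)

#: planted-fault burst: a 5-10 Hz band movement, 0.15 s wide, peaking 0.15 s
#: before impact. 12 degrees per channel puts the aggregated (Euclidean)
#: amplitude near 16 degrees — clearly above the >10 degree scale of the
#: movements these spectra resolve, and distinct from the quiet pre-impact
#: background of a clean swing.
FAULT_FREQ_HZ = 7.0
FAULT_WIDTH_S = 0.15
FAULT_LEAD_S = 0.15
FAULT_AMPLITUDE_DEG = 12.0


@dataclass(frozen=True)
class Component:
    """One additive signal component of a joint's Euler channels.

    kind: tone | chirp | am_burst | trend. ``freq`` is the tone frequency
    (Hz); for a chirp, the start frequency with ``freq_end`` the final one.
    ``center``/``width`` (s) place the Gaussian envelope of an am_burst;
    tones and chirps use a broad raised-cosine envelope over the whole clip.
    ``weights`` split the amplitude across (theta_x, theta_y, theta_z).
    """

    kind: str
    amplitude: float
    freq: float = 0.0
    freq_end: float | None = None
    center: float | None = None
    width: float | None = None
    weights: tuple[float, float, float] = (1.0, 0.8, 0.6)
    phase: float = 0.0

    def __post_init__(self):
        if self.kind not in ("tone", "chirp", "am_burst", "trend"):
            raise ValueError(f"unknown component kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class SwingRecipe:
    """Full description of one synthetic swing."""

    duration: float = 1.9
    frame_rate: float = 120.0
    impact_time: float = 1.1
    joints: tuple[str, ...] = DEFAULT_SKELETON_JOINTS
    components: dict[str, tuple[Component, ...]] = field(default_factory=dict)
    noise_deg: float = 0.3
    planted_fault: str = "none"
    fault_amplitude: float = FAULT_AMPLITUDE_DEG
    label: str = "straight"
    seed: int = 0

    def __post_init__(self):
        if self.duration * self.frame_rate < 64:
            raise ValueError("recipe must span at least 64 frames")
        if not 0 < self.impact_time < self.duration:
            raise ValueError("impact_time must lie inside the clip")
        if self.planted_fault not in FAULT_JOINTS:
            raise ValueError(f"planted_fault must be one of {sorted(FAULT_JOINTS)}")
        if self.fault_amplitude < 0 or self.noise_deg < 0:
            raise ValueError("amplitudes must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    @property
    def impact_frame(self) -> int:
        return int(round(self.impact_time * self.frame_rate))


def _default_components(rng: np.random.Generator) -> tuple[Component, ...]:
    """Posture trend, slow sway, and impact-centered 3/8/24 Hz bursts.

    A clean swing is pendulum-like: its oscillatory energy concentrates
    around the hit, and the quarter-second before impact is comparatively
    quiet — which is precisely why an extra pre-impact burst (a fault) is
    diagnostic. Phases and channel weights are randomised per joint so
    swings differ realistically while sharing this structure.
    """
    ph = rng.uniform(0, 2 * np.pi, size=4)
    # channel weights distribute motion across the Euler axes: a random
    # direction of fixed overall magnitude (mild +/-7% jitter), so swings
    # differ in axis mix and phase but carry comparable per-joint energy
    raw = rng.uniform(0.4, 1.0, size=3)
    w = tuple(raw / np.linalg.norm(raw) * 1.2 * rng.uniform(0.93, 1.07))
    mk = lambda freq, amp, width, phase: Component(
        kind="am_burst",
        freq=freq,
        amplitude=amp,
        center=-1.0,  # resolved to impact_time at render
        width=width,
        weights=w,
        phase=phase,
    )
    return (
        Component(kind="trend", amplitude=25.0, weights=w),
        # slow postural sway over the whole clip
        Component(kind="tone", freq=2.0, amplitude=1.5, weights=w, phase=ph[0]),
        # the swing itself: impact-centered energy across the 3-24 Hz bands
        mk(3.0, 5.0, 0.5, ph[1]),
        mk(8.0, 3.0, 0.3, ph[2]),
        mk(24.0, 6.0, 0.1, ph[3]),
    )


def default_recipe(
    label: str = "straight",
    planted_fault: str | None = None,
    seed: int = 0,
    **overrides,
) -> SwingRecipe:
    """Study-condition recipe: 1.9 s at 120 Hz, impact just past mid-swing."""
    if planted_fault is None:
        planted_fault = {
            "straight": "none",
            "slice_head_up": "head_up",
            "slice_opening": "opening",
        }.get(label, "none")
    return SwingRecipe(label=label, planted_fault=planted_fault, seed=seed, **overrides)


def _component_series(
    comp: Component, t: np.ndarray, duration: float, impact_time: float
) -> np.ndarray:
    """Scalar time series of one component (before channel weighting)."""
    if comp.kind == "trend":
        # smooth unimodal posture excursion: address -> top -> follow-through
        return comp.amplitude * np.sin(np.pi * t / duration) ** 2
    if comp.kind == "tone":
        env = 0.5 * (1 - np.cos(2 * np.pi * t / duration))  # raised cosine
        return comp.amplitude * env * np.sin(2 * np.pi * comp.freq * t + comp.phase)
    if comp.kind == "chirp":
        f1 = comp.freq_end if comp.freq_end is not None else comp.freq
        phase = 2 * np.pi * (comp.freq * t + (f1 - comp.freq) * t**2 / (2 * duration))
        return comp.amplitude * np.sin(phase + comp.phase)
    # am_burst: Gaussian-envelope tone; center -1 means "at impact"
    center = impact_time if (comp.center is None or comp.center < 0) else comp.center
    width = comp.width if comp.width else 0.1
    env = np.exp(-0.5 * ((t - center) / (width / 2)) ** 2)
    return comp.amplitude * env * np.sin(2 * np.pi * comp.freq * t + comp.phase)


def _fault_component(recipe: SwingRecipe) -> Component:
    return Component(
        kind="am_burst",
        freq=FAULT_FREQ_HZ,
        amplitude=recipe.fault_amplitude,
        center=recipe.impact_time - FAULT_LEAD_S,
        width=FAULT_WIDTH_S,
        weights=(1.0, 0.7, 0.5),
    )


def _build_skeleton(joint_names: tuple[str, ...]) -> Skeleton:
    rot = ("Zrotation", "Xrotation", "Yrotation")
    joints = [
        Joint(
            name=joint_names[0],
            parent=None,
            offset=(0.0, 0.0, 0.0),
            channels=("Xposition", "Yposition", "Zposition") + rot,
        )
    ]
    for name in joint_names[1:]:
        joints.append(
            Joint(name=name, parent=joint_names[0], offset=(0.0, 10.0, 0.0), channels=rot)
        )
    return Skeleton(tuple(joints))


def render(recipe: SwingRecipe) -> tuple[MotionClip, dict]:
    """Render a recipe to a MotionClip plus its exact ground truth.

    The ground-truth record maps each joint to its list of noiseless
    per-component (T, 3) arrays, and records which joints carry the planted
    fault. Identical recipe (same seed) -> identical output.
    """
    rng = np.random.default_rng(recipe.seed)
    n = recipe.n_frames
    t = np.arange(n) / recipe.frame_rate

    euler: dict[str, np.ndarray] = {}
    truth: dict = {"components": {}, "fault_joints": [], "recipe": recipe}
    fault_joints = FAULT_JOINTS[recipe.planted_fault] if recipe.fault_amplitude > 0 else ()
    for joint in recipe.joints:
        comps = list(recipe.components.get(joint) or _default_components(rng))
        if joint in fault_joints:
            comps.append(_fault_component(recipe))
            truth["fault_joints"].append(joint)
        series = np.zeros((n, 3))
        comp_series = []
        for comp in comps:
            base = _component_series(comp, t, recipe.duration, recipe.impact_time)
            contrib = base[:, None] * np.asarray(comp.weights)[None, :]
            comp_series.append(contrib)
            series += contrib
        if recipe.noise_deg > 0:
            series = series + rng.normal(0.0, recipe.noise_deg, size=series.shape)
        euler[joint] = series
        truth["components"][joint] = comp_series

    clip = MotionClip(
        skeleton=_build_skeleton(recipe.joints),
        frame_rate=recipe.frame_rate,
        euler=euler,
        positions={recipe.joints[0]: np.zeros((n, 3))},
        impact_frame=recipe.impact_frame,
        label=recipe.label,
    )
    return clip, truth


def make_dataset(
    out_dir,
    n_per_group: int = 6,
    groups: tuple[str, ...] = ("straight", "slice_head_up", "slice_opening"),
    seed: int = 0,
    fault_amplitude: float = FAULT_AMPLITUDE_DEG,
    noise_deg: float = 0.3,
    frame_bounds: tuple[int, int] = FRAME_BOUNDS,
    impact_bounds: tuple[int, int] = IMPACT_BOUNDS,
) -> "Path":
    """Write a labelled BVH dataset plus a swings.csv metadata sidecar.

    Swing lengths and impact frames jitter uniformly inside the study-like
    bounds (frames 227-231, impact 130-144). Returns the metadata path;
    the CSV columns are (path, impact_frame, label).
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    for g in groups:
        if g not in ("straight", "slice_head_up", "slice_opening"):
            raise ValueError(
                f"unknown group {g!r}; valid: straight, slice_head_up, slice_opening"
            )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for g in groups:
        for k in range(n_per_group):
            frames = int(rng.integers(frame_bounds[0], frame_bounds[1] + 1))
            lo = max(impact_bounds[0], 1)
            hi = min(impact_bounds[1], frames - 2)
            impact = int(rng.integers(lo, hi + 1))
            fr = 120.0
            recipe = default_recipe(
                label=g,
                seed=int(rng.integers(0, 2**31 - 1)),
                duration=frames / fr,
                impact_time=impact / fr,
                fault_amplitude=fault_amplitude,
                noise_deg=noise_deg,
            )
            # round-trip of duration/impact through the recipe must re-land
            # on the drawn integers; guaranteed since both are frame-exact
            clip, _ = render(recipe)
            name = f"{g}_{k:02d}.bvh"
            (out / name).write_text(write_bvh(clip))
            rows.append({"path": name, "impact_frame": impact, "label": g})
    meta = out / "swings.csv"
    with open(meta, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["path", "impact_frame", "label"])
        writer.writeheader()
        writer.writerows(rows)
    return meta
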
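"""Biovision Hierarchy (BVH) motion-capture I/O.

A BVH document has two sections: HIERARCHY, a nested tree of JOINT blocks
each declaring an OFFSET and a CHANNELS list, and MOTION, a frame count, a
frame time, and one whitespace-separated row of channel values per frame.

Rotation channels are stored internally on labelled axes (theta_x, theta_y,
theta_z) in degrees regardless of the on-disk channel order; the declared
order is kept on the skeleton so a clip re-exports in its native dialect.
Root position channels are parsed and preserved but play no part in the
angle analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BVHParseError",
    "Joint",
    "Skeleton",
    "MotionClip",
    "parse_bvh",
    "write_bvh",
    "read_bvh_file",
    "select_joints",
    "LABELS",
]

LABELS = ("straight", "slice_head_up", "slice_opening", "unlabeled")

_ROTATION_AXIS = {"Xrotation": 0, "Yrotation": 1, "Zrotation": 2}
_POSITION_CHANNELS = {"Xposition", "Yposition", "Zposition"}


class BVHParseError(ValueError):
    """Malformed BVH document; the message names the offending line."""

    def __init__(self, message: str, line_no: int | None = None):
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)
        self.line_no = line_no


@dataclass(frozen=True)
class Joint:
    name: str
    parent: str | None
    offset: tuple[float, float, float]
    channels: tuple[str, ...]  # declared on-disk order, e.g. Zrotation Xrotation Yrotation
    end_site: tuple[float, float, float] | None = None


@dataclass(frozen=True)
class Skeleton:
    """Joint hierarchy in declaration order (parents precede children)."""

    joints: tuple[Joint, ...]

    def __post_init__(self):
        roots = [j for j in self.joints if j.parent is None]
        if len(roots) != 1:
            raise ValueError(f"skeleton must have exactly one root, found {len(roots)}")
        seen: set[str] = set()
        for j in self.joints:
            if j.name in seen:
                raise ValueError(f"duplicate joint name {j.name!r}")
            if j.parent is not None and j.parent not in seen:
                raise ValueError(f"joint {j.name!r}: parent {j.parent!r} does not precede it")
            rot = [c for c in j.channels if c in _ROTATION_AXIS]
            if rot and len(set(rot)) != 3:
                raise ValueError(f"joint {j.name!r}: needs three distinct rotation axes, got {rot}")
            seen.add(j.name)

    @property
    def joint_names(self) -> list[str]:
        return [j.name for j in self.joints]

    def __getitem__(self, name: str) -> Joint:
        for j in self.joints:
            if j.name == name:
                return j
        raise KeyError(name)

    @property
    def total_channels(self) -> int:
        return sum(len(j.channels) for j in self.joints)


@dataclass
class MotionClip:
    """A captured motion: skeleton plus per-joint Euler-angle series.

    ``euler[name]`` is a ``(frames, 3)`` float array holding
    (theta_x, theta_y, theta_z) in degrees. ``positions`` keeps any
    translation channels, keyed by joint, as ``(frames, 3)`` (x, y, z).
    """

    skeleton: Skeleton
    frame_rate: float
    euler: dict[str, np.ndarray]
    positions: dict[str, np.ndarray] = field(default_factory=dict)
    impact_frame: int | None = None
    label: str = "unlabeled"

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be positive, got {self.frame_rate}")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        counts = {a.shape[0] for a in self.euler.values()}
        if len(counts) > 1:
            raise ValueError(f"joint series have unequal lengths: {sorted(counts)}")
        for name, a in self.euler.items():
            if a.ndim != 2 or a.shape[1] != 3:
                raise ValueError(f"euler[{name!r}] must be (frames, 3), got {a.shape}")
            if not np.all(np.isfinite(a)):
                raise ValueError(f"euler[{name!r}] contains non-finite angles")
        if self.impact_frame is not None:
            if not 0 <= self.impact_frame < self.frames:
                raise ValueError(
                    f"impact_frame {self.impact_frame} outside [0, {self.frames})"
                )

    @property
    def frames(self) -> int:
        if not self.euler:
            return 0
        return next(iter(self.euler.values())).shape[0]

    @property
    def duration(self) -> float:
        return self.frames / self.frame_rate

    @property
    def joint_names(self) -> list[str]:
        return self.skeleton.joint_names


def _tokenize(text: str) -> list[tuple[int, str]]:
    out = []
    for i, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line:
            out.append((i, line))
    return out


def parse_bvh(
    text: str, impact_frame: int | None = None, label: str = "unlabeled"
) -> MotionClip:
    """Parse a BVH document into a :class:`MotionClip`.

    The file's declared channel order is honoured when mapping values into
    labelled (theta_x, theta_y, theta_z) storage, so ``Zrotation Xrotation
    Yrotation`` files and ``Xrotation Yrotation Zrotation`` files carrying
    the same rotations parse identically.
    """
    lines = _tokenize(text)
    if not lines:
        raise BVHParseError("empty document")
    pos = 0

    def peek() -> tuple[int, str]:
        if pos >= len(lines):
            raise BVHParseError("unexpected end of document", lines[-1][0])
        return lines[pos]

    def advance() -> tuple[int, str]:
        nonlocal pos
        ln = peek()
        pos += 1
        return ln

    no, line = advance()
    if line != "HIERARCHY":
        raise BVHParseError(f"expected HIERARCHY, got {line!r}", no)

    joints: list[Joint] = []

    def parse_joint(parent: str | None):
        no, line = advance()
        words = line.split()
        if words[0] not in ("ROOT", "JOINT") or len(words) < 2:
            raise BVHParseError(f"expected ROOT/JOINT declaration, got {line!r}", no)
        name = " ".join(words[1:])
        no, line = advance()
        if line != "{":
            raise BVHParseError(f"expected '{{' after joint {name!r}", no)
        no, line = advance()
        if not line.startswith("OFFSET"):
            raise BVHParseError(f"expected OFFSET in joint {name!r}", no)
        try:
            offset = tuple(float(v) for v in line.split()[1:])
        except ValueError:
            raise BVHParseError(f"non-numeric OFFSET: {line!r}", no) from None
        if len(offset) != 3:
            raise BVHParseError(f"OFFSET needs 3 values: {line!r}", no)
        no, line = advance()
        if not line.startswith("CHANNELS"):
            raise BVHParseError(f"expected CHANNELS in joint {name!r}", no)
        words = line.split()
        try:
            n_ch = int(words[1])
        except (IndexError, ValueError):
            raise BVHParseError(f"bad CHANNELS count: {line!r}", no) from None
        channels = tuple(words[2:])
        if len(channels) != n_ch:
            raise BVHParseError(
                f"CHANNELS declares {n_ch} but lists {len(channels)}: {line!r}", no
            )
        for c in channels:
            if c not in _ROTATION_AXIS and c not in _POSITION_CHANNELS:
                raise BVHParseError(f"unknown channel {c!r} in joint {name!r}", no)
        end_site = None
        # children / end site / closing brace
        idx = len(joints)
        joints.append(Joint(name, parent, offset, channels))  # placeholder, fixed below
        while True:
            no, line = peek()
            if line == "}":
                advance()
                break
            if line.startswith(("JOINT", "ROOT")):
                parse_joint(name)
            elif line.startswith("End Site"):
                advance()
                no2, l2 = advance()
                if l2 != "{":
                    raise BVHParseError("expected '{' after End Site", no2)
                no2, l2 = advance()
                if not l2.startswith("OFFSET"):
                    raise BVHParseError("expected OFFSET in End Site", no2)
                try:
                    end_site = tuple(float(v) for v in l2.split()[1:])
                except ValueError:
                    raise BVHParseError(f"non-numeric OFFSET: {l2!r}", no2) from None
                no2, l2 = advance()
                if l2 != "}":
                    raise BVHParseError("expected '}' closing End Site", no2)
            else:
                raise BVHParseError(f"unexpected line in joint {name!r}: {line!r}", no)
        if end_site is not None:
            joints[idx] = replace(joints[idx], end_site=end_site)

    parse_joint(None)
    try:
        skeleton = Skeleton(tuple(joints))
    except ValueError as e:
        raise BVHParseError(f"malformed hierarchy: {e}") from None

    no, line = advance()
    if line != "MOTION":
        raise BVHParseError(f"expected MOTION, got {line!r}", no)
    no, line = advance()
    if not line.startswith("Frames:"):
        raise BVHParseError(f"expected 'Frames:', got {line!r}", no)
    try:
        n_frames = int(line.split(":", 1)[1])
    except ValueError:
        raise BVHParseError(f"non-numeric frame count: {line!r}", no) from None
    no, line = advance()
    if not line.startswith("Frame Time:"):
        raise BVHParseError(f"expected 'Frame Time:', got {line!r}", no)
    try:
        frame_time = float(line.split(":", 1)[1])
    except ValueError:
        raise BVHParseError(f"non-numeric Frame Time: {line!r}", no) from None
    if frame_time <= 0:
        raise BVHParseError(f"Frame Time must be positive: {line!r}", no)

    total = skeleton.total_channels
    rows = np.empty((n_frames, total))
    for f in range(n_frames):
        no, line = advance()
        vals = line.split()
        if len(vals) != total:
            raise BVHParseError(
                f"frame {f}: {len(vals)} values but hierarchy declares {total} channels",
                no,
            )
        try:
            rows[f] = [float(v) for v in vals]
        except ValueError:
            raise BVHParseError(f"non-numeric frame value in frame {f}: {line!r}", no) from None

    euler: dict[str, np.ndarray] = {}
    positions: dict[str, np.ndarray] = {}
    col = 0
    for j in skeleton.joints:
        ang = np.zeros((n_frames, 3))
        pos3 = None
        has_rot = False
        for c in j.channels:
            if c in _ROTATION_AXIS:
                ang[:, _ROTATION_AXIS[c]] = rows[:, col]
                has_rot = True
            else:
                if pos3 is None:
                    pos3 = np.zeros((n_frames, 3))
                pos3[:, "XYZ".index(c[0])] = rows[:, col]
            col += 1
        if has_rot:
            euler[j.name] = ang
        if pos3 is not None:
            positions[j.name] = pos3

    return MotionClip(
        skeleton=skeleton,
        frame_rate=1.0 / frame_time,
        euler=euler,
        positions=positions,
        impact_frame=impact_frame,
        label=label,
    )


def read_bvh_file(
    path, impact_frame: int | None = None, label: str = "unlabeled"
) -> MotionClip:
    with open(path) as fh:
        return parse_bvh(fh.read(), impact_frame=impact_frame, label=label)


def write_bvh(clip: MotionClip, angle_decimals: int = 6) -> str:
    """Serialize a clip back to BVH text.

    Channel values are printed in each joint's declared on-disk order, so
    ``parse_bvh(write_bvh(clip))`` reproduces hierarchy, frame rate and
    angles to print precision (<= 1e-4 degrees by default).
    """
    if clip.frames == 0:
        raise ValueError("cannot serialize a clip with zero frames")
    sk = clip.skeleton
    children: dict[str | None, list[Joint]] = {}
    for j in sk.joints:
        children.setdefault(j.parent, []).append(j)

    out: list[str] = ["HIERARCHY"]

    def emit(j: Joint, depth: int):
        ind = "  " * depth
        kw = "ROOT" if j.parent is None else "JOINT"
        out.append(f"{ind}{kw} {j.name}")
        out.append(f"{ind}{{")
        out.append(f"{ind}  OFFSET {j.offset[0]:.6f} {j.offset[1]:.6f} {j.offset[2]:.6f}")
        out.append(f"{ind}  CHANNELS {len(j.channels)} " + " ".join(j.channels))
        kids = children.get(j.name, [])
        for k in kids:
            emit(k, depth + 1)
        if not kids:
            es = j.end_site or (0.0, 0.0, 0.0)
            out.append(f"{ind}  End Site")
            out.append(f"{ind}  {{")
            out.append(f"{ind}    OFFSET {es[0]:.6f} {es[1]:.6f} {es[2]:.6f}")
            out.append(f"{ind}  }}")
        out.append(f"{ind}}}")

    emit(children[None][0], 0)
    out.append("MOTION")
    out.append(f"Frames: {clip.frames}")
    out.append(f"Frame Time: {1.0 / clip.frame_rate:.7f}")

    fmt = f"{{:.{angle_decimals}f}}"
    for f in range(clip.frames):
        vals: list[str] = []
        for j in sk.joints:
            for c in j.channels:
                if c in _ROTATION_AXIS:
                    v = clip.euler[j.name][f, _ROTATION_AXIS[c]]
                else:
                    v = clip.positions.get(j.name, np.zeros((clip.frames, 3)))[
                        f, "XYZ".index(c[0])
                    ]
                vals.append(fmt.format(v))
        out.append(" ".join(vals))
    return "\n".join(out) + "\n"


def select_joints(clip: MotionClip, names: list[str]) -> MotionClip:
    """Restrict a clip to the requested joints, in request order.

    The returned skeleton is flattened (every kept joint re-parented to the
    first requested joint) since the analysis consumes angle channels only.
    """
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate joint names requested: {dupes}")
    available = [n for n in clip.skeleton.joint_names if n in clip.euler]
    missing = [n for n in names if n not in available]
    if missing:
        raise KeyError(
            f"unknown joint(s) {missing}; available rotation joints: {available}"
        )
    if names == clip.skeleton.joint_names:
        return clip
    root, *rest = names
    src = {j.name: j for j in clip.skeleton.joints}
    joints = [replace(src[root], parent=None, channels=_rotation_only(src[root].channels))]
    joints += [
        replace(src[n], parent=root, channels=_rotation_only(src[n].channels)) for n in rest
    ]
    return MotionClip(
        skeleton=Skeleton(tuple(joints)),
        frame_rate=clip.frame_rate,
        euler={n: clip.euler[n].copy() for n in names},
        positions={},
        impact_frame=clip.impact_frame,
        label=clip.label,
    )


def _rotation_only(channels: tuple[str, ...]) -> tuple[str, ...]:
    rot = tuple(c for c in channels if c in _ROTATION_AXIS)
    return rot if rot else ("Zrotation", "Xrotation", "Yrotation")
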
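"""Reading, writing and geometric normalization of 3D skeleton sequences.

The canonical on-disk format is a long-form CSV with columns
``frame,joint,x,y,z`` (0-based contiguous frame and joint indices,
coordinates in meters, right-handed camera frame).  Adapters for the
per-frame text layouts used by two popular Kinect datasets (15-joint
CAD-60-style and 20-joint MSR-style files) normalize into the same
in-memory container, :class:`SkeletonSequence`.

The module also implements handedness mirroring: reflecting every joint
of a sequence across a body-symmetry plane, used to map a left-handed
subject's activities onto the right-handed majority before training.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import GeometryError, ParseError, StructureError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SkeletonSequence",
    "JointRoleMap",
    "read_skeleton_csv",
    "write_skeleton_csv",
    "read_cad60_skeleton",
    "read_msr_skeleton",
    "mirror_sequence",
]


@dataclass
class SkeletonSequence:
    """One labeled video of per-frame 3D joint coordinates.

    Attributes
    ----------
    coords:
        ``(T, J, 3)`` float array; ``coords[t, j]`` is the (x, y, z)
        position of joint ``j`` in frame ``t``, in meters.
    activity_label:
        Activity class of the video (non-empty string).
    subject_id:
        Identifier of the person performing the activity (non-empty).
    frame_rate_hz:
        Acquisition rate; metadata only, never used in computation.
    joint_names:
        ``J`` identifiers; defaults to ``joint_00 .. joint_{J-1}``.
    """

    coords: np.ndarray
    activity_label: str
    subject_id: str
    frame_rate_hz: float = 30.0
    joint_names: Sequence[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError(
                f"coords must have shape (T, J, 3), got {self.coords.shape}"
            )
        t, j, _ = self.coords.shape
        if t < 1 or j < 2:
            raise ValidationError(f"need T >= 1 and J >= 2, got T={t}, J={j}")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coords contain non-finite values")
        if not self.activity_label or not self.subject_id:
            raise ValidationError("activity_label and subject_id must be non-empty")
        if self.frame_rate_hz <= 0:
            raise ValidationError("frame_rate_hz must be positive")
        if self.joint_names is None:
            self.joint_names = [f"joint_{k:02d}" for k in range(j)]
        elif len(self.joint_names) != j:
            raise ValidationError(
                f"joint_names has {len(self.joint_names)} entries for J={j}"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_joints(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class JointRoleMap:
    """Indices of the four joints that anchor the body-symmetry planes."""

    left_arm: int
    right_arm: int
    left_hip: int
    right_hip: int

    def __post_init__(self) -> None:
        idx = (self.left_arm, self.right_arm, self.left_hip, self.right_hip)
        if len(set(idx)) != 4 or any(i < 0 for i in idx):
            raise ValidationError(f"role joints must be 4 distinct indices, got {idx}")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.left_arm, self.right_arm, self.left_hip, self.right_hip)


# ---------------------------------------------------------------------------
# canonical CSV
# ---------------------------------------------------------------------------

def read_skeleton_csv(
    path: str | Path,
    activity_label: str = "unknown",
    subject_id: str = "unknown",
    frame_rate_hz: float = 30.0,
) -> SkeletonSequence:
    """Read a long-form ``frame,joint,x,y,z`` CSV into a sequence.

    Rows may appear in any order; a header row is optional.  Frame and
    joint indices must be 0-based and contiguous, and every
    ``(frame, joint)`` cell must be present exactly once.
    """
    path = Path(path)
    cells: dict[tuple[int, int], tuple[float, float, float]] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            tokens = [tok.strip() for tok in row]
            if lineno == 1 and not _is_number(tokens[0]):
                continue  # header
            if len(tokens) != 5:
                raise ParseError(
                    f"{path}:{lineno}: expected 5 fields (frame,joint,x,y,z), "
                    f"got {len(tokens)}"
                )
            try:
                t, j = int(tokens[0]), int(tokens[1])
                xyz = (float(tokens[2]), float(tokens[3]), float(tokens[4]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed row: {exc}") from None
            if not all(np.isfinite(v) for v in xyz):
                raise ValidationError(f"{path}:{lineno}: non-finite coordinate")
            if (t, j) in cells:
                raise StructureError(f"{path}:{lineno}: duplicate cell (frame={t}, joint={j})")
            cells[(t, j)] = xyz
    if not cells:
        raise ParseError(f"{path}: no data rows")

    frames = sorted({t for t, _ in cells})
    joints = sorted({j for _, j in cells})
    if frames != list(range(len(frames))) or joints != list(range(len(joints))):
        raise StructureError(
            f"{path}: frame/joint indices must be 0-based contiguous; "
            f"got frames {frames[:5]}..{frames[-1]}, joints {joints[:5]}..{joints[-1]}"
        )
    t_n, j_n = len(frames), len(joints)
    if len(cells) != t_n * j_n:
        missing = [(t, j) for t in range(t_n) for j in range(j_n) if (t, j) not in cells]
        raise StructureError(f"{path}: missing cells, e.g. {missing[:5]}")
    coords = np.empty((t_n, j_n, 3))
    for (t, j), xyz in cells.items():
        coords[t, j] = xyz
    return SkeletonSequence(coords, activity_label, subject_id, frame_rate_hz)


def write_skeleton_csv(seq: SkeletonSequence, path: str | Path) -> None:
    """Write the canonical CSV.  ``repr``-based float formatting makes
    ``read(write(seq))`` reproduce ``seq.coords`` bit-exactly."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "joint", "x", "y", "z"])
        for t in range(seq.n_frames):
            for j in range(seq.n_joints):
                x, y, z = seq.coords[t, j]
                writer.writerow([t, j, repr(float(x)), repr(float(y)), repr(float(z))])


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# dataset dialect adapters
# ---------------------------------------------------------------------------

#: tokens per joint in the CAD-60-style layout:
#: 9 orientation entries + 1 orientation confidence + 3 position entries
#: + 1 position confidence for the first 11 joints; 3 + 1 for the last 4.
_CAD60_FULL_JOINTS = 11
_CAD60_POS_JOINTS = 4
_CAD60_TOKENS = 1 + _CAD60_FULL_JOINTS * 14 + _CAD60_POS_JOINTS * 4


def read_cad60_skeleton(
    path: str | Path,
    activity_label: str = "unknown",
    subject_id: str = "unknown",
) -> SkeletonSequence:
    """Read a CAD-60-style 15-joint skeleton text file.

    Assumed layout (documented here because dataset exports vary): one
    comma-separated line per frame starting with the frame number,
    followed by 11 joints with ``9 orientation + 1 conf + 3 position
    (mm) + 1 conf`` fields each, then 4 joints with ``3 position (mm)
    + 1 conf`` fields; an optional trailing comma and a final line
    containing only ``END``.  Orientations and confidences are parsed
    and discarded; positions are converted from millimeters to meters.
    Frames in which any joint is reported at the exact origin (tracker
    dropout) are dropped with a logged warning.
    """
    path = Path(path)
    frames: list[np.ndarray] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.rstrip(",").upper() == "END":
                break
            tokens = [tok for tok in line.split(",") if tok.strip()]
            if len(tokens) != _CAD60_TOKENS:
                raise ParseError(
                    f"{path}:{lineno}: expected {_CAD60_TOKENS} fields in "
                    f"CAD-60-style line, got {len(tokens)}"
                )
            try:
                values = np.array([float(tok) for tok in tokens[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed number: {exc}") from None
            pos = np.empty((15, 3))
            cursor = 0
            for j in range(_CAD60_FULL_JOINTS):
                pos[j] = values[cursor + 10 : cursor + 13]
                cursor += 14
            for j in range(_CAD60_POS_JOINTS):
                pos[_CAD60_FULL_JOINTS + j] = values[cursor : cursor + 3]
                cursor += 4
            if np.any(np.all(pos == 0.0, axis=1)):
                dropped += 1
                continue
            frames.append(pos / 1000.0)  # mm -> m
    if dropped:
        logger.warning("%s: dropped %d frame(s) with all-zero joints", path, dropped)
    if not frames:
        raise ParseError(f"{path}: no usable frames")
    return SkeletonSequence(np.stack(frames), activity_label, subject_id, 30.0)


def read_msr_skeleton(
    path: str | Path,
    activity_label: str = "unknown",
    subject_id: str = "unknown",
    n_joints: int = 20,
) -> SkeletonSequence:
    """Read an MSR-style 20-joint real-world skeleton text file.

    Assumed layout: an optional first line with two integers (frame and
    row counts), then one whitespace-separated ``x y z confidence`` line
    per joint, ``n_joints`` consecutive lines per frame, coordinates in
    meters.  The confidence column is parsed and discarded.  A frame in
    which every coordinate of some joint is exactly zero (tracker
    dropout) is dropped with a logged warning; a trailing incomplete
    frame is a parse error.
    """
    path = Path(path)
    rows: list[tuple[float, float, float]] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    start = 0
    if lines:
        head = lines[0].split()
        if len(head) == 2 and all(tok.lstrip("-").isdigit() for tok in head):
            start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        tokens = line.split()
        if len(tokens) != 4:
            raise ParseError(
                f"{path}:{lineno}: expected 4 fields (x y z conf), got {len(tokens)}"
            )
        try:
            x, y, z = float(tokens[0]), float(tokens[1]), float(tokens[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: malformed number: {exc}") from None
        rows.append((x, y, z))
    if not rows or len(rows) % n_joints != 0:
        raise ParseError(
            f"{path}: {len(rows)} joint rows is not a multiple of {n_joints} "
            "(truncated frame?)"
        )
    coords = np.array(rows).reshape(-1, n_joints, 3)
    keep = ~np.any(np.all(coords == 0.0, axis=2), axis=1)
    dropped = int(np.sum(~keep))
    if dropped:
        logger.warning("%s: dropped %d frame(s) with all-zero joints", path, dropped)
    coords = coords[keep]
    if coords.shape[0] == 0:
        raise ParseError(f"{path}: no usable frames")
    return SkeletonSequence(coords, activity_label, subject_id, 16.0)


# ---------------------------------------------------------------------------
# handedness mirroring
# ---------------------------------------------------------------------------

def _fit_plane_normal(points: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Total-least-squares plane through 4 points: the unit normal is the
    right singular vector of the centered point matrix with the smallest
    singular value."""
    centered = points - points.mean(axis=0)
    _, svals, vt = np.linalg.svd(centered, full_matrices=True)
    # rank-deficient fit (collinear points): the two smallest singular
    # values coincide at ~0 and the normal direction is not unique.
    if svals[1] <= tol * max(svals[0], 1.0):
        raise GeometryError("role joints are collinear; plane fit is rank-deficient")
    return vt[2]


def mirror_frame(frame: np.ndarray, roles: JointRoleMap) -> np.ndarray:
    """Reflect one ``(J, 3)`` frame across its body-symmetry plane.

    The plane P1 is fitted (total least squares) through the four role
    joints; the mirror plane P2 contains the line from the arm midpoint
    ``m_a`` to the hip midpoint ``m_h`` and is perpendicular to P1, i.e.
    its normal is ``n2 = normalize(n1 x (m_h - m_a))``.
    """
    la, ra, lh, rh = roles.as_tuple()
    j = frame.shape[0]
    if max(la, ra, lh, rh) >= j:
        raise ValidationError(f"role joint index out of range for J={j}")
    anchor = frame[[la, ra, lh, rh]]
    n1 = _fit_plane_normal(anchor)
    m_a = 0.5 * (frame[la] + frame[ra])
    m_h = 0.5 * (frame[lh] + frame[rh])
    axis = m_h - m_a
    norm = np.linalg.norm(axis)
    if norm <= 1e-12:
        raise GeometryError("arm and hip midpoints coincide; mirror axis undefined")
    n2 = np.cross(n1, axis / norm)
    n2_norm = np.linalg.norm(n2)
    if n2_norm <= 1e-12:
        raise GeometryError("mirror-plane normal degenerate (axis parallel to n1)")
    n2 = n2 / n2_norm
    return frame - 2.0 * np.outer((frame - m_a) @ n2, n2)


def mirror_sequence(seq: SkeletonSequence, roles: JointRoleMap) -> SkeletonSequence:
    """Reflect every frame of *seq* across its per-frame symmetry plane.

    Reflection is an isometry (pairwise inter-joint distances are
    preserved) and an involution (mirroring twice restores the input up
    to floating-point round-off).  Planes are recomputed per frame so a
    subject who turns during the video stays consistently mirrored.
    """
    mirrored = np.stack([mirror_frame(f, roles) for f in seq.coords])
    return replace(seq, coords=mirrored)
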
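"""Space-time-joint volumes and dense temporal sub-volume sampling.

A video of T frames with J joints becomes a ``3 x J x T`` volume after
per-frame centering (each coordinate column of a frame has its mean
over joints subtracted, removing global camera/body placement).  Dense
sampling slides a window of ``r3`` consecutive frames along the time
axis (stride 1 keeps all possible windows), and each ``3 x J x r3``
window is permuted so frames and coordinates swap axes, then flattened
with the frame index varying fastest.  The resulting columns form the
sample matrix fed to dictionary learning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ValidationError
from .skeleton_io import SkeletonSequence

__all__ = [
    "CenteredVolume",
    "SampleMatrix",
    "center_frame",
    "build_volume",
    "permute_and_vectorize",
    "devectorize",
    "sample_subvolumes",
]


@dataclass
class CenteredVolume:
    """Per-frame-centered joint volume with axes (xyz, joint, frame)."""

    values: np.ndarray  # (3, J, T)
    source: Optional[SkeletonSequence] = None

    @property
    def n_frames(self) -> int:
        return self.values.shape[2]

    @property
    def n_joints(self) -> int:
        return self.values.shape[1]


@dataclass
class SampleMatrix:
    """Vectorized sub-volume samples as columns of a ``p x N`` matrix."""

    columns: np.ndarray  # (p, N)
    starts: np.ndarray  # (N,) start frame of each window
    r3: int
    activity_label: Optional[str] = None
    subject_id: Optional[str] = None

    @property
    def n_samples(self) -> int:
        return self.columns.shape[1]

    @property
    def sample_dim(self) -> int:
        return self.columns.shape[0]


def center_frame(frame: np.ndarray) -> np.ndarray:
    """Subtract the per-coordinate mean over joints from a ``(J, 3)`` frame."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2 or frame.shape[1] != 3:
        raise ValidationError(f"frame must have shape (J, 3), got {frame.shape}")
    if not np.all(np.isfinite(frame)):
        raise ValidationError("frame contains non-finite values")
    return frame - frame.mean(axis=0, keepdims=True)


def build_volume(seq: SkeletonSequence) -> CenteredVolume:
    """Center every frame and stack into a ``(3, J, T)`` volume.

    ``values[c, j, t]`` is coordinate ``c`` of joint ``j`` in frame ``t``
    after centering, so a global translation of the skeleton leaves the
    volume unchanged.
    """
    centered = seq.coords - seq.coords.mean(axis=1, keepdims=True)
    return CenteredVolume(values=np.transpose(centered, (2, 1, 0)).copy(), source=seq)


def permute_and_vectorize(window: np.ndarray) -> np.ndarray:
    """Flatten a ``(3, J, r3)`` window into a length ``3*J*r3`` vector.

    The xyz axis is swapped with the frame axis (the joint axis stays in
    the middle), giving shape ``(r3, J, 3)`` in which each column holds
    one coordinate of one joint across the window's frames.  The vector
    enumerates entries with the frame index fastest, then joint, then
    coordinate: ``vec[t + r3*j + r3*J*c] = window[c, j, t]``.
    """
    window = np.asarray(window, dtype=np.float64)
    if window.ndim != 3 or window.shape[0] != 3:
        raise ValidationError(f"window must have shape (3, J, r3), got {window.shape}")
    return window.transpose(2, 1, 0).reshape(-1, order="F")


def devectorize(vector: np.ndarray, n_joints: int, r3: int) -> np.ndarray:
    """Inverse of :func:`permute_and_vectorize` (exact bijection)."""
    vector = np.asarray(vector, dtype=np.float64)
    if vector.size != 3 * n_joints * r3:
        raise ValidationError(
            f"vector length {vector.size} != 3*{n_joints}*{r3}"
        )
    return vector.reshape(r3, n_joints, 3, order="F").transpose(2, 1, 0)


def sample_subvolumes(vol: CenteredVolume, r3: int, stride: int = 1) -> SampleMatrix:
    """Densely sample temporal windows of ``r3`` frames from a volume.

    Windows start at frames ``0, stride, 2*stride, ...``; with the
    default stride 1 all ``N = T - r3 + 1`` windows are taken.  The full
    spatial extent (all 3 coordinates, all J joints) is kept in every
    window.
    """
    if r3 < 1 or stride < 1:
        raise ValidationError("r3 and stride must be positive")
    t_n = vol.n_frames
    if r3 > t_n:
        raise ValidationError(
            f"sequence too short: T={t_n} frames but the window needs r3={r3}"
        )
    windows = np.lib.stride_tricks.sliding_window_view(vol.values, r3, axis=2)
    # windows: (3, J, T-r3+1, r3) -> stride selection on the start axis
    windows = windows[:, :, ::stride, :]
    starts = np.arange(0, t_n - r3 + 1, stride)
    # (c, j, start, t) -> rows ordered frame-fastest, then joint, then coord
    n = windows.shape[2]
    columns = np.ascontiguousarray(windows.transpose(0, 1, 3, 2)).reshape(-1, n)
    src = vol.source
    return SampleMatrix(
        columns=columns,
        starts=starts,
        r3=r3,
        activity_label=src.activity_label if src is not None else None,
        subject_id=src.subject_id if src is not None else None,
    )
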
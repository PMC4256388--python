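"""Synthetic multi-class skeleton datasets for testing the pipeline.

Each activity class is a set of smooth joint trajectories: every joint
follows the rest pose plus a sum of two sinusoids whose frequencies,
phases and amplitudes are drawn once per class, so all subjects share
the class's motion signature.  Subjects differ by a random global
placement offset (removed by centering), a small amplitude jitter, and
per-repetition sensor noise — mirroring the structure that a
leave-one-subject-out protocol must generalize across.  A planted
orthonormal-dictionary generator provides ground truth for dictionary
recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ValidationError
from .skeleton_io import JointRoleMap, SkeletonSequence, mirror_sequence

__all__ = [
    "SynthConfig",
    "generate_dataset",
    "generate_planted_dictionary_data",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study-design knobs of the synthetic skeleton generator.

    Defaults emulate a small indoor activity corpus: 6 activities, 4
    subjects, 2 repetitions, 4-second clips at 30 Hz with 15 tracked
    joints; gesture amplitudes around 0.25 m, ~1 cm sensor noise, and
    ~0.5 m camera-placement offsets.
    """

    n_classes: int = 6
    n_subjects: int = 4
    reps_per_subject: int = 2
    n_frames: int = 120
    n_joints: int = 15
    frame_rate_hz: float = 30.0
    amplitude: float = 0.25  # meters
    noise_sd: float = 0.01  # meters
    offset_scale: float = 0.5  # meters
    seed: int = 0
    #: mirror all sequences of the last subject across the body plane
    #: (emulates one left-handed subject); requires ``roles``.
    mirror_last_subject: bool = False
    roles: Optional[JointRoleMap] = None

    def __post_init__(self) -> None:
        counts = (
            self.n_classes,
            self.n_subjects,
            self.reps_per_subject,
            self.n_frames,
            self.n_joints,
        )
        if any(c < 1 for c in counts):
            raise ValidationError("all counts in SynthConfig must be positive")
        if self.noise_sd < 0 or self.amplitude < 0 or self.offset_scale < 0:
            raise ValidationError("scales must be non-negative")
        if self.mirror_last_subject and self.roles is None:
            raise ValidationError("mirror_last_subject requires a JointRoleMap")


def generate_dataset(cfg: SynthConfig) -> list[SkeletonSequence]:
    """Generate ``A * S * R`` labeled sequences from a seeded generator.

    Class motifs (two sinusoids per joint per coordinate, frequencies
    uniform in 0.5–3 Hz) are drawn first, then per-subject offsets and
    amplitude jitters, then per-repetition noise, all from one seeded
    stream, so identical configs give bit-identical datasets.
    """
    rng = np.random.default_rng(cfg.seed)
    a_n, s_n, r_n = cfg.n_classes, cfg.n_subjects, cfg.reps_per_subject
    t_n, j_n = cfg.n_frames, cfg.n_joints
    rest = rng.normal(scale=0.3, size=(j_n, 3))
    freqs = rng.uniform(0.5, 3.0, size=(a_n, 2, j_n, 3))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(a_n, 2, j_n, 3))
    amps = cfg.amplitude * rng.uniform(0.5, 1.5, size=(a_n, 2, j_n, 3))
    offsets = rng.normal(scale=cfg.offset_scale, size=(s_n, 3))
    jitters = rng.uniform(0.9, 1.1, size=(s_n,))
    times = np.arange(t_n) / cfg.frame_rate_hz  # (T,)

    sequences: list[SkeletonSequence] = []
    for a in range(a_n):
        # (2, J, 3, T) sinusoids summed over the harmonic axis
        waves = amps[a][..., None] * np.sin(
            2.0 * np.pi * freqs[a][..., None] * times + phases[a][..., None]
        )
        motion = waves.sum(axis=0)  # (J, 3, T)
        for s in range(s_n):
            placed = jitters[s] * motion + rest[:, :, None] + offsets[s][None, :, None]
            for r in range(r_n):
                noise = rng.normal(scale=cfg.noise_sd, size=(j_n, 3, t_n))
                coords = np.transpose(placed + noise, (2, 0, 1))  # (T, J, 3)
                seq = SkeletonSequence(
                    coords=coords,
                    activity_label=f"activity_{a}",
                    subject_id=f"subject_{s}",
                    frame_rate_hz=cfg.frame_rate_hz,
                )
                if cfg.mirror_last_subject and s == s_n - 1:
                    seq = mirror_sequence(seq, cfg.roles)
                sequences.append(seq)
    return sequences


def generate_planted_dictionary_data(
    n_atoms: int,
    dim: int,
    n_samples: int,
    sparsity: int = 1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Samples that are sparse non-negative combinations of orthonormal atoms.

    Returns ``(X, atoms)`` with ``X`` of shape ``(dim, n_samples)`` and
    ``atoms`` of shape ``(n_atoms, dim)`` (orthonormal rows).  Each
    sample activates ``sparsity`` distinct atoms with coefficients
    uniform in [0.5, 1.5], plus isotropic Gaussian noise.
    """
    if dim < n_atoms:
        raise ValidationError(
            f"cannot draw {n_atoms} orthonormal atoms in dimension {dim}"
        )
    if not 1 <= sparsity <= n_atoms:
        raise ValidationError("sparsity must be in [1, n_atoms]")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((dim, n_atoms)))
    atoms = q.T  # (n_atoms, dim), orthonormal rows
    coeffs = np.zeros((n_atoms, n_samples))
    for i in range(n_samples):
        active = rng.choice(n_atoms, size=sparsity, replace=False)
        coeffs[active, i] = rng.uniform(0.5, 1.5, size=sparsity)
    x = atoms.T @ coeffs
    if noise_sd > 0:
        x = x + rng.normal(scale=noise_sd, size=x.shape)
    return x, atoms
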
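"""Rigid-body least-squares superposition of conformers.

Provides the classic Kabsch fit (rotation + translation minimizing the
sum of squared distances between matched atoms, reflections rejected)
and an iterative outlier-rejecting variant in the spirit of the
"best-fit" algorithms of interactive structure viewers: alternate a
Kabsch fit on the current core set with removal of poorly fitting pairs
until a fixed point is reached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

_ORTHO_TOL = 1e-8


@dataclass
class RigidTransform:
    """Proper rotation followed by translation: ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("improper rotation (reflection) rejected")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class FitResult:
    transform: RigidTransform
    rmsd: float
    core_residues: set
    n_iterations: int

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")


def _check_input(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("moving and fixed must be equal-length (n, 3) arrays")
    if len(moving) < 3:
        raise ValueError("superposition needs at least 3 paired atoms")
    for name, arr in (("moving", moving), ("fixed", fixed)):
        centered = arr - arr.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
            raise ValueError(f"{name} coordinates are degenerate (collinear)")
    return moving, fixed


def kabsch_fit(
    moving: np.ndarray,
    fixed: np.ndarray,
    residue_numbers: list[int] | None = None,
) -> FitResult:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Returns the proper rotation and translation minimizing the sum of
    squared distances between matched points, with
    ``rmsd = sqrt(mean squared residual distance)``.
    """
    moving, fixed = _check_input(moving, fixed)
    mov_mean = moving.mean(axis=0)
    fix_mean = fixed.mean(axis=0)
    rot, _ = Rotation.align_vectors(fixed - fix_mean, moving - mov_mean)
    R = rot.as_matrix()
    transform = RigidTransform(R, fix_mean - R @ mov_mean)
    residuals = np.linalg.norm(transform.apply(moving) - fixed, axis=1)
    rmsd = float(np.sqrt(np.mean(residuals**2)))
    if residue_numbers is None:
        residue_numbers = list(range(len(moving)))
    return FitResult(
        transform=transform,
        rmsd=rmsd,
        core_residues=set(residue_numbers),
        n_iterations=1,
    )


def iterative_fit(
    moving: np.ndarray,
    fixed: np.ndarray,
    reject_multiplier: float = 2.0,
    max_iter: int = 10,
    residue_numbers: list[int] | None = None,
) -> FitResult:
    """Outlier-rejecting superposition.

    Alternates a Kabsch fit on the current core set with removal of
    pairs whose residual exceeds ``reject_multiplier`` times the current
    rmsd, stopping at a fixed point or after ``max_iter`` rounds.  The
    final transform and rmsd refer to the surviving core set.
    """
    moving, fixed = _check_input(moving, fixed)
    if residue_numbers is None:
        residue_numbers = list(range(len(moving)))
    residue_numbers = np.asarray(residue_numbers)
    core = np.ones(len(moving), dtype=bool)
    fit = kabsch_fit(moving, fixed)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        fit = kabsch_fit(moving[core], fixed[core])
        residuals = np.linalg.norm(fit.transform.apply(moving) - fixed, axis=1)
        # small absolute floor so numerically exact fits are a fixed point
        keep = core & (residuals <= reject_multiplier * fit.rmsd + 1e-9)
        if keep.sum() == core.sum():
            break
        if keep.sum() < 3:
            raise ValueError(
                "iterative fit rejected too many pairs (core below 3)"
            )
        core = keep
    return FitResult(
        transform=fit.transform,
        rmsd=fit.rmsd,
        core_residues=set(int(n) for n in residue_numbers[core]),
        n_iterations=n_iter,
    )


def fit(
    moving: np.ndarray,
    fixed: np.ndarray,
    mode: str = "kabsch",
    residue_numbers: list[int] | None = None,
    **kwargs,
) -> FitResult:
    """Dispatch to :func:`kabsch_fit` or :func:`iterative_fit` by name."""
    if mode == "kabsch":
        return kabsch_fit(moving, fixed, residue_numbers=residue_numbers)
    if mode == "iterative":
        return iterative_fit(moving, fixed, residue_numbers=residue_numbers, **kwargs)
    raise ValueError(f"unknown fit mode: {mode!r}")
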
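"""Orientation frames and orthographic projection.

The default view of a structure aligns the principal axes of its atomic
coordinate distribution with the canvas: largest variance along x,
second along y, smallest along the view axis z — the behavior of the
``orient`` command in molecular viewers. A :class:`RotationFrame` can
also come from a family alignment or be loaded from a plain-text matrix
file; every frame is validated to be a proper rotation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "RotationFrame",
    "ProjectedPoint",
    "InvalidMatrixError",
    "compute_inertia_frame",
    "validate_frame",
    "load_matrix_file",
    "save_matrix_file",
    "apply_frame",
    "orthographic_project",
    "ORTHO_TOL",
]

#: Orthonormality / determinant tolerance for accepting a rotation.
ORTHO_TOL = 1e-6


class InvalidMatrixError(ValueError):
    """A user-supplied matrix is not a proper rotation (or is malformed).

    Callers log a warning and fall back to the inertia frame.
    """


@dataclass(frozen=True)
class RotationFrame:
    """A rigid transform ``p' = R @ (p + t)``.

    ``rotation`` rows are the canvas axes expressed in input
    coordinates; ``translation`` is applied before rotating (for the
    inertia frame it is minus the centroid, so the view is centered).
    """

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    source: str = "user_file"  # 'inertia' | 'family_alignment' | 'user_file'

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise InvalidMatrixError(f"bad shape: rotation {R.shape}, translation {t.shape}")
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise InvalidMatrixError("non-finite entries")
        if np.abs(R.T @ R - np.eye(3)).max() > ORTHO_TOL:
            raise InvalidMatrixError("matrix is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > ORTHO_TOL:
            raise InvalidMatrixError("matrix determinant is not +1 (improper rotation)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def compose(self, outer: "RotationFrame", source: str | None = None) -> "RotationFrame":
        """The frame applying ``self`` first, then ``outer``.

        ``outer(self(p)) = (R_o R_s) (p + t_s + R_sᵀ t_o)``.
        """
        R = outer.rotation @ self.rotation
        t = self.translation + self.rotation.T @ outer.translation
        return RotationFrame(R, t, source or self.source)

    def inverse(self) -> "RotationFrame":
        R = self.rotation.T
        return RotationFrame(R, -(self.rotation @ self.translation), self.source)


@dataclass(frozen=True)
class ProjectedPoint:
    x: float
    y: float
    depth: float


def compute_inertia_frame(coords: Sequence[Sequence[float]] | np.ndarray) -> RotationFrame:
    """Principal-axis frame of a point cloud.

    Rows of the returned rotation are the covariance eigenvectors sorted
    by descending eigenvalue, so rotated coordinates have
    var(x) >= var(y) >= var(z). Signs are fixed deterministically: each
    of the first two axes is flipped so the point projecting farthest
    along it lands on the non-negative side (exactly symmetric clouds
    fall back to a positive dominant axis component); the third axis is
    the cross product of the first two (right-handed). Degenerate clouds
    (single point, collinear, coplanar) get a deterministically
    completed basis with a warning.
    """
    X = np.asarray(coords, dtype=float).reshape(-1, 3)
    if X.shape[0] == 0:
        raise ValueError("cannot orient an empty point set")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite coordinates")
    centroid = X.mean(axis=0)
    Xc = X - centroid
    cov = (Xc.T @ Xc) / max(1, X.shape[0] - 1) if X.shape[0] > 1 else np.zeros((3, 3))
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    axes = evecs[:, order].T  # rows = principal axes, descending variance

    rank = int(np.sum(evals > 1e-12 * max(evals.max(), 1.0)))
    if rank < 3:
        warnings.warn(
            f"rank-deficient coordinate covariance (rank {rank}); "
            "completing the basis deterministically")
        axes = _complete_basis(axes, rank)

    # deterministic signs: the farthest-projecting point lands non-negatively;
    # symmetric clouds (tie) fall back to a positive dominant component
    for i in range(2):
        s = Xc @ axes[i]
        smax, smin = float(s.max()), float(s.min())
        if smax + smin < -1e-12:
            axes[i] = -axes[i]
        elif abs(smax + smin) <= 1e-12 and axes[i][np.argmax(np.abs(axes[i]))] < 0:
            axes[i] = -axes[i]
    axes[2] = np.cross(axes[0], axes[1])
    return RotationFrame(axes, -centroid, source="inertia")


def _complete_basis(axes: np.ndarray, rank: int) -> np.ndarray:
    """Fill the null-space axes of a degenerate cloud with fixed choices."""
    basis = list(axes[:rank]) if rank > 0 else []
    for cand in (np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0])):
        if len(basis) == 3:
            break
        v = cand.copy()
        for b in basis:
            v -= (v @ b) * b
        n = np.linalg.norm(v)
        if n > 1e-9:
            basis.append(v / n)
    return np.array(basis)


def validate_frame(values: Sequence[Sequence[float]] | np.ndarray,
                   source: str = "user_file") -> RotationFrame:
    """Validate 3 (rotation) or 4 (rotation + translation) rows of 3 numbers.

    Raises :class:`InvalidMatrixError` for a wrong shape, non-numeric
    input, a non-orthonormal matrix, or a reflection; the caller is
    expected to warn and fall back to the inertia orientation.
    """
    try:
        M = np.asarray(values, dtype=float)
    except (TypeError, ValueError) as exc:
        raise InvalidMatrixError(f"non-numeric matrix: {exc}") from exc
    if M.shape == (3, 3):
        return RotationFrame(M, np.zeros(3), source)
    if M.shape == (4, 3):
        return RotationFrame(M[:3], M[3], source)
    raise InvalidMatrixError(f"expected 3x3 or 4x3 numbers, got shape {M.shape}")


def load_matrix_file(path: str | Path) -> RotationFrame:
    """Read the plain-text matrix dialect: whitespace-separated numbers,
    3 or 4 rows of 3 columns, ``#`` comments allowed."""
    rows: list[list[float]] = []
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise InvalidMatrixError(f"cannot read matrix file {path}: {exc}") from exc
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            rows.append([float(tok) for tok in line.split()])
        except ValueError as exc:
            raise InvalidMatrixError(f"non-numeric line {line!r} in {path}") from exc
    return validate_frame(rows)


def save_matrix_file(frame: RotationFrame, path: str | Path) -> None:
    """Write a frame in the same dialect ``load_matrix_file`` reads."""
    lines = ["# rotation (3 rows) then translation (1 row)"]
    for row in frame.rotation:
        lines.append(" ".join(f"{v: .10f}" for v in row))
    lines.append(" ".join(f"{v: .10f}" for v in frame.translation))
    Path(path).write_text("\n".join(lines) + "\n")


def apply_frame(coords: np.ndarray, frame: RotationFrame) -> np.ndarray:
    """Apply ``p' = R (p + t)`` to an (n, 3) array. An isometry."""
    X = np.asarray(coords, dtype=float).reshape(-1, 3)
    return (X + frame.translation) @ frame.rotation.T


def orthographic_project(coords: np.ndarray, frame: RotationFrame) -> list[ProjectedPoint]:
    """Project points onto the canvas plane: x, y kept, z becomes depth.

    No perspective scaling; +z points toward the viewer.
    """
    P = apply_frame(coords, frame)
    return [ProjectedPoint(float(x), float(y), float(z)) for x, y, z in P]
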
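"""Core geometry: RMSD and least-squares (Kabsch) rigid superposition.

The RMSD here is the plain unweighted root-mean-square deviation over matched
atoms, sqrt((1/N) * sum_i d_i^2), with no fitting performed inside the
measure itself.  Superposition is a separate, explicit step: the analysis
convention of this package is NO fitting by default (trajectories produced
with a fixed positional reference, such as a restrained heme group, are
already in a common frame), with an opt-in Kabsch fit for inputs that are
not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import CorrespondenceError, DegenerateGeometryError, EmptySelectionError
from .structures_io import Selection, Trajectory, apply_selection


def _as_coords(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise CorrespondenceError(f"{name} must be an (N, 3) array, got {arr.shape}")
    return arr


def rmsd(coords_a, coords_b) -> float:
    """Root-mean-square deviation between two matched coordinate sets (Å).

    Correspondence must already be established (same atom at the same row);
    no fitting is performed.
    """
    a = _as_coords(coords_a, "coords_a")
    b = _as_coords(coords_b, "coords_b")
    if a.shape[0] != b.shape[0]:
        raise CorrespondenceError(f"coordinate sets differ in length: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[0] == 0:
        raise EmptySelectionError("RMSD over zero atoms is undefined")
    delta = a - b
    return float(np.sqrt(np.mean(np.einsum("ij,ij->i", delta, delta))))


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation plus translation, x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("reflections are not rigid transforms of a molecule")

    def apply(self, coords) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def as_matrix(self) -> np.ndarray:
        """The transform as a homogeneous 4x4 matrix."""
        mat = np.eye(4)
        mat[:3, :3] = self.rotation
        mat[:3, 3] = self.translation
        return mat

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def kabsch_fit(mobile, reference) -> RigidTransform:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns the proper-rotation + translation transform minimising the RMSD
    of the transformed mobile set against the reference.  Requires at least
    three non-collinear points; reflections are never returned.
    """
    mob = _as_coords(mobile, "mobile")
    ref = _as_coords(reference, "reference")
    if mob.shape[0] != ref.shape[0]:
        raise CorrespondenceError(f"coordinate sets differ in length: {mob.shape[0]} vs {ref.shape[0]}")
    if mob.shape[0] < 3:
        raise DegenerateGeometryError("rigid fit needs at least 3 atoms")
    mob_center = mob.mean(axis=0)
    ref_center = ref.mean(axis=0)
    mob_c = mob - mob_center
    ref_c = ref - ref_center
    # rank of the cross-covariance decides whether the rotation is determined
    singular = np.linalg.svd(mob_c.T @ mob_c, compute_uv=False)
    if singular[1] <= 1e-10 * max(singular[0], 1.0):
        raise DegenerateGeometryError("points are collinear; rotation is not determined")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    matrix = rot.as_matrix()
    return RigidTransform(matrix, ref_center - matrix @ mob_center)


def fitted_rmsd(mobile, reference) -> float:
    """RMSD after an optimal Kabsch fit of ``mobile`` onto ``reference``."""
    transform = kabsch_fit(mobile, reference)
    return rmsd(transform.apply(mobile), reference)


def superpose_trajectory(traj: Trajectory, reference, fit_selection: Selection | None = None,
                         fit_indices=None) -> Trajectory:
    """Rigid-fit every frame onto ``reference`` coordinates.

    The fit is computed on the ``fit_selection`` atoms (or explicit
    ``fit_indices``) and the resulting transform moves the whole frame.
    ``reference`` must hold one coordinate triple per fit atom.
    """
    if fit_indices is None:
        fit_indices = (
            apply_selection(traj.topology, fit_selection)
            if fit_selection is not None
            else np.arange(len(traj.topology))
        )
    fit_indices = np.asarray(fit_indices, dtype=int)
    if fit_indices.size < 3:
        raise DegenerateGeometryError("fit selection must yield at least 3 atoms")
    ref = _as_coords(reference, "reference")
    if ref.shape[0] != fit_indices.size:
        raise CorrespondenceError(
            f"reference has {ref.shape[0]} atoms, fit selection {fit_indices.size}"
        )
    out = np.empty_like(traj.coords)
    for t in range(traj.n_frames):
        transform = kabsch_fit(traj.coords[t, fit_indices], ref)
        out[t] = transform.apply(traj.coords[t])
    return Trajectory(traj.topology, out, traj.frame_interval)
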
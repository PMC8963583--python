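"""Per-system trajectory statistics.

The central quantity is the movement RMSD M: the per-frame RMSD of a
trajectory against its own time-average structure.  Because the time average
minimises the total squared deviation, M is the intrinsic mobility of a
system, independent of any external reference.  RMSD against a fixed
external reference (a crystal structure) and per-residue RMSF complete the
picture; a minimum-distance series between a ligand reference and a protein
group tracks binding-site approach.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import CorrespondenceError, EmptySelectionError
from .structures_io import AtomMap, Selection, Structure, Trajectory, apply_selection, match_atoms
from .superposition import fitted_rmsd


def _selected_indices(traj: Trajectory, selection: Selection | None) -> np.ndarray:
    idx = (
        apply_selection(traj.topology, selection)
        if selection is not None
        else np.arange(len(traj.topology))
    )
    if idx.size == 0:
        raise EmptySelectionError("selection matched no atoms of the trajectory topology")
    return idx


def per_frame_rmsd(frames: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Vectorised per-frame RMSD of (T, n, 3) frames against one (n, 3) reference."""
    delta = frames - reference[None, :, :]
    return np.sqrt(np.einsum("tij,tij->t", delta, delta) / frames.shape[1])


@dataclass(frozen=True)
class RmsdSeries:
    """Per-frame RMSD values against a stated reference, with summaries."""

    values: np.ndarray
    reference_label: str = ""
    selection_label: str = ""
    mean: float = field(init=False)
    sd: float = field(init=False)
    min: float = field(init=False)
    max: float = field(init=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mean", float(values.mean()))
        object.__setattr__(self, "sd", float(values.std(ddof=0)))
        object.__setattr__(self, "min", float(values.min()))
        object.__setattr__(self, "max", float(values.max()))

    @property
    def rms(self) -> float:
        """Root-mean-square of the series (the scale on which the
        time-average reference is exactly optimal)."""
        return float(np.sqrt(np.mean(self.values**2)))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FluctuationProfile:
    """Per-residue RMSF values (Å), ordered along the chain."""

    residues: tuple[tuple[str, int], ...]
    rmsf: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rmsf", np.asarray(self.rmsf, dtype=float))
        if len(self.residues) != len(self.rmsf):
            raise CorrespondenceError("one RMSF value per residue required")


@dataclass(frozen=True)
class DistanceSeries:
    """Per-frame minimum distances (Å) between two atom groups."""

    values: np.ndarray
    group_a_label: str = ""
    group_b_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def average_structure(traj: Trajectory, selection: Selection | None = None) -> np.ndarray:
    """Per-atom arithmetic mean of the coordinates over all frames."""
    idx = _selected_indices(traj, selection)
    return traj.coords[:, idx].mean(axis=0)


def movement_rmsd(traj: Trajectory, selection: Selection | None = None) -> RmsdSeries:
    """Movement RMSD M: per-frame RMSD against the trajectory's own time average.

    The series mean is the scalar M reported per system.
    """
    if traj.n_frames < 2:
        raise ValueError("movement RMSD needs at least 2 frames")
    idx = _selected_indices(traj, selection)
    frames = traj.coords[:, idx]
    avg = frames.mean(axis=0)
    values = per_frame_rmsd(frames, avg)
    return RmsdSeries(values, reference_label="own-average",
                      selection_label=selection.describe() if selection else "all")


def reference_rmsd(traj: Trajectory, reference: Structure,
                   atom_map: AtomMap | None = None,
                   selection: Selection | None = None,
                   fit: bool = False) -> RmsdSeries:
    """Per-frame RMSD against a fixed external reference structure.

    The atom correspondence comes from ``atom_map`` (trajectory topology ->
    reference) or is built with :func:`match_atoms` on ``selection``.  No
    fitting is applied unless ``fit`` is set, in which case each frame is
    Kabsch-fitted onto the reference atoms before measuring.
    """
    if atom_map is None:
        atom_map = match_atoms(traj.topology, reference, selection)
    frames = traj.coords[:, atom_map.idx_a]
    ref = reference.coords[atom_map.idx_b]
    if fit:
        values = np.array([fitted_rmsd(frame, ref) for frame in frames])
    else:
        values = per_frame_rmsd(frames, ref)
    return RmsdSeries(values, reference_label=reference.id or "reference",
                      selection_label=selection.describe() if selection else "mapped")


def atomic_rmsf(traj: Trajectory, selection: Selection | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom RMSF about each atom's own time-average position.

    Returns (selected indices, per-atom RMSF values in Å).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    idx = _selected_indices(traj, selection)
    frames = traj.coords[:, idx]
    delta = frames - frames.mean(axis=0)[None, :, :]
    values = np.sqrt(np.einsum("tij,tij->i", delta, delta) / frames.shape[0])
    return idx, values


def rmsf_profile(traj: Trajectory, selection: Selection | None = None,
                 per_residue_reduce: str = "mean_over_atoms") -> FluctuationProfile:
    """Per-residue RMSF profile.

    ``per_residue_reduce``: ``mean_over_atoms`` averages the selected atoms
    of each residue; ``ca_only`` uses only the Cα atom.
    """
    if per_residue_reduce not in ("mean_over_atoms", "ca_only"):
        raise ValueError(f"unknown reduction {per_residue_reduce!r}")
    idx, values = atomic_rmsf(traj, selection)
    residues: list[tuple[str, int]] = []
    grouped: dict[tuple[str, int], list[float]] = {}
    for i, value in zip(idx, values):
        atom = traj.topology.atoms[i]
        if per_residue_reduce == "ca_only" and atom.name != "CA":
            continue
        key = (atom.chain, atom.resnum)
        if key not in grouped:
            grouped[key] = []
            residues.append(key)
        grouped[key].append(float(value))
    if not residues:
        raise EmptySelectionError("no residues left after RMSF reduction")
    profile = np.array([np.mean(grouped[key]) for key in residues])
    return FluctuationProfile(tuple(residues), profile)


def min_distance_series(traj: Trajectory, group_a, group_b_coords,
                        group_a_label: str = "", group_b_label: str = "") -> DistanceSeries:
    """Per-frame minimum distance between trajectory atoms and a reference group.

    ``group_a`` are atom indices into the trajectory topology; ``group_b_coords``
    is a fixed (m, 3) coordinate set (e.g. the crystal pose of a ligand) or a
    per-frame (T, m, 3) stack.
    """
    group_a = np.asarray(group_a, dtype=int)
    if group_a.size == 0:
        raise EmptySelectionError("group_a is empty")
    group_b_coords = np.asarray(group_b_coords, dtype=float)
    if group_b_coords.size == 0:
        raise EmptySelectionError("group_b is empty")
    per_frame_b = group_b_coords.ndim == 3
    if per_frame_b and group_b_coords.shape[0] != traj.n_frames:
        raise CorrespondenceError("per-frame group_b must have one coordinate set per frame")
    values = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        b = group_b_coords[t] if per_frame_b else group_b_coords
        values[t] = cdist(traj.coords[t, group_a], b).min()
    return DistanceSeries(values, group_a_label, group_b_label)
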
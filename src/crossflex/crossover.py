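"""Pairwise trajectory comparison and the 2x2 cross-over study.

The bias problem: two trajectories can sit in different regions of
conformational space yet have similar *intrinsic* mobility, or sit in the
same region with very different mobility.  Comparing each system against
the *joint* average structure of both systems mixes those effects.  The
similarity score used here removes the intrinsic part:

    S = (A1 - M1) + (A2 - M2)

where M_k is the mean per-frame RMSD of system k against its own time
average (its movement), and A_k the mean per-frame RMSD of system k against
the joint average of both systems' pooled frames.  If the two systems
occupy the same region, the joint average nearly coincides with each own
average and S ≈ 0; the further apart the sampled regions, the larger S.
The higher the score, the more structural difference between the two
systems beyond their own movements.

The cross-over design pairs two start structures (apo and holo crystals of
the same enzyme) with two ligand states (ligand present/absent), giving
four systems and six pairwise scores.  Each system's verdict on induced
fit follows from which crystal its trajectory resembles more: a liganded
system ending near the holo crystal (or an unliganded one near the apo
crystal) is evidence of induced fit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import CorrespondenceError, DesignError
from .structures_io import AtomMap, Selection, Structure, Trajectory, match_atoms
from .superposition import fitted_rmsd, rmsd
from .trajectory_metrics import RmsdSeries, movement_rmsd, per_frame_rmsd, reference_rmsd


@dataclass(eq=False)
class SystemRecord:
    """One simulated system of a cross-over study."""

    label: str
    trajectory: Trajectory
    liganded: bool
    origin_structure: str


@dataclass(frozen=True)
class PairScore:
    """The quadruple (M1, M2, A1, A2) and the score S = (A1-M1)+(A2-M2), in Å.

    ``score`` is kept at full precision; display rounding happens only at
    render time (rounding M/A first and then combining does not, in general,
    give the rounded score).
    """

    system1: str
    system2: str
    M1: float
    M2: float
    A1: float
    A2: float

    @property
    def score(self) -> float:
        return (self.A1 - self.M1) + (self.A2 - self.M2)

    def rounded(self, ndigits: int = 1) -> float:
        return round(self.score, ndigits)

    @classmethod
    def from_values(cls, M1: float, M2: float, A1: float, A2: float,
                    system1: str = "system1", system2: str = "system2") -> "PairScore":
        return cls(system1, system2, float(M1), float(M2), float(A1), float(A2))


@dataclass(frozen=True)
class InterpretationRow:
    """Which crystal a system's trajectory resembles, and the verdict."""

    system_label: str
    reference_crystal: str
    similarity: float
    verdict: str  # induced_fit | no_induced_fit | indeterminate


@dataclass(frozen=True)
class CrystalRecord:
    """A crystal reference structure and its ligand state."""

    label: str
    structure: Structure
    liganded: bool


def _mapped_frames(traj1: Trajectory, traj2: Trajectory,
                   atom_map: AtomMap | None, selection: Selection | None):
    if atom_map is None:
        atom_map = match_atoms(traj1.topology, traj2.topology, selection)
    frames1 = traj1.coords[:, atom_map.idx_a]
    frames2 = traj2.coords[:, atom_map.idx_b]
    if frames1.shape[1] != frames2.shape[1]:
        raise CorrespondenceError("mapped atom counts differ between the two systems")
    return frames1, frames2


def joint_average_rmsd(traj1: Trajectory, traj2: Trajectory,
                       atom_map: AtomMap | None = None,
                       selection: Selection | None = None,
                       weighting: str = "frame") -> tuple[float, float]:
    """Mean per-frame RMSD of each system against the joint average structure.

    The joint average is taken over the pooled frames of both systems on the
    mapped atoms.  ``weighting="frame"`` weighs every pooled frame equally
    (systems with more frames contribute more); ``weighting="system"``
    averages the two per-system averages instead.
    """
    if weighting not in ("frame", "system"):
        raise ValueError(f"unknown weighting {weighting!r}")
    frames1, frames2 = _mapped_frames(traj1, traj2, atom_map, selection)
    if weighting == "frame":
        total = frames1.sum(axis=0) + frames2.sum(axis=0)
        joint = total / (frames1.shape[0] + frames2.shape[0])
    else:
        joint = 0.5 * (frames1.mean(axis=0) + frames2.mean(axis=0))
    a1 = float(per_frame_rmsd(frames1, joint).mean())
    a2 = float(per_frame_rmsd(frames2, joint).mean())
    return a1, a2


def pair_score(traj1: Trajectory, traj2: Trajectory,
               atom_map: AtomMap | None = None,
               selection: Selection | None = None,
               weighting: str = "frame",
               label1: str = "system1", label2: str = "system2") -> PairScore:
    """Bias-corrected similarity score for a pair of systems.

    M_k is computed on the *mapped* atoms so the movement and joint terms
    describe the same atom set; the score is symmetric in the two systems.
    """
    if traj1.n_frames < 2 or traj2.n_frames < 2:
        raise ValueError("pair score needs at least 2 frames per system")
    frames1, frames2 = _mapped_frames(traj1, traj2, atom_map, selection)
    m1 = float(per_frame_rmsd(frames1, frames1.mean(axis=0)).mean())
    m2 = float(per_frame_rmsd(frames2, frames2.mean(axis=0)).mean())
    if weighting == "frame":
        total = frames1.sum(axis=0) + frames2.sum(axis=0)
        joint = total / (frames1.shape[0] + frames2.shape[0])
    else:
        joint = 0.5 * (frames1.mean(axis=0) + frames2.mean(axis=0))
    a1 = float(per_frame_rmsd(frames1, joint).mean())
    a2 = float(per_frame_rmsd(frames2, joint).mean())
    return PairScore(label1, label2, m1, m2, a1, a2)


def crystal_rmsd(a: Structure, b: Structure, selection: Selection | None = None,
                 fit: bool = True) -> float:
    """RMSD between two crystal structures on their matched atoms.

    Two crystals share no coordinate frame, so a Kabsch fit on the compared
    selection is applied by default.
    """
    atom_map = match_atoms(a, b, selection)
    coords_a = a.coords[atom_map.idx_a]
    coords_b = b.coords[atom_map.idx_b]
    return fitted_rmsd(coords_a, coords_b) if fit else rmsd(coords_a, coords_b)


def interpret_similarity(system: SystemRecord,
                         reference_means: Mapping[str, float],
                         crystal_liganded: Mapping[str, bool],
                         tol: float = 1e-9) -> InterpretationRow:
    """Verdict for one system from its mean RMSD against the two crystals.

    The system "resembles" the crystal with the lower mean reference RMSD.
    A liganded system resembling the liganded-origin crystal (or an
    unliganded system resembling the unliganded-origin crystal) is induced
    fit; the opposite pairing is not; a tie is indeterminate.
    """
    if len(reference_means) != 2:
        raise DesignError("interpretation needs RMSD against exactly two crystals")
    (label_x, mean_x), (label_y, mean_y) = sorted(reference_means.items())
    if abs(mean_x - mean_y) <= tol:
        return InterpretationRow(system.label, label_x, float(mean_x), "indeterminate")
    closer = label_x if mean_x < mean_y else label_y
    similarity = min(mean_x, mean_y)
    verdict = (
        "induced_fit"
        if crystal_liganded[closer] == system.liganded
        else "no_induced_fit"
    )
    return InterpretationRow(system.label, closer, float(similarity), verdict)


@dataclass(eq=False)
class StudyReport:
    """Full cross-over study output.

    ``reference_series`` maps (system label, crystal label) to the RMSD
    series against that crystal; ``movement`` maps system label to its
    movement-RMSD series; ``pair_scores`` holds all six unordered pairs in
    ascending score order; ``interpretations`` the per-system verdicts.
    """

    system_labels: tuple[str, ...]
    crystal_labels: tuple[str, ...]
    selection_label: str
    reference_series: dict
    movement: dict
    pair_scores: list
    interpretations: list
    fit: bool = False


def _check_design(systems: Sequence[SystemRecord], crystals: Sequence[CrystalRecord]) -> None:
    if len(systems) != 4:
        raise DesignError(f"a cross-over study needs exactly 4 systems, got {len(systems)}")
    labels = [s.label for s in systems]
    if len(set(labels)) != 4:
        raise DesignError("system labels must be unique")
    cells = {(s.origin_structure, s.liganded) for s in systems}
    origins = {s.origin_structure for s in systems}
    if len(origins) != 2 or len(cells) != 4:
        raise DesignError(
            "systems must form the 2x2 design: two origin structures, each liganded and unliganded"
        )
    if len(crystals) != 2:
        raise DesignError(f"a cross-over study needs exactly 2 crystals, got {len(crystals)}")
    if {c.liganded for c in crystals} != {True, False}:
        raise DesignError("one crystal must be liganded and one unliganded")


def crossover_study(systems: Sequence[SystemRecord], crystals: Sequence[CrystalRecord],
                    selection: Selection | None = None, fit: bool = False,
                    weighting: str = "frame") -> StudyReport:
    """Run the full 2x2 cross-over analysis.

    Emits, for the four systems: mean RMSD against both crystals, movement
    RMSD summaries, the six pairwise bias-corrected scores (ascending, ties
    broken by labels so the ranking is deterministic), and per-system
    induced-fit verdicts.
    """
    _check_design(systems, crystals)
    crystal_liganded = {c.label: c.liganded for c in crystals}

    reference_series: dict[tuple[str, str], RmsdSeries] = {}
    for system in systems:
        for crystal in crystals:
            reference_series[(system.label, crystal.label)] = reference_rmsd(
                system.trajectory, crystal.structure, selection=selection, fit=fit
            )

    movement = {
        system.label: movement_rmsd(system.trajectory, selection)
        for system in systems
    }

    scores = [
        pair_score(s1.trajectory, s2.trajectory, selection=selection,
                   weighting=weighting, label1=s1.label, label2=s2.label)
        for s1, s2 in itertools.combinations(systems, 2)
    ]
    scores.sort(key=lambda p: (p.score, p.system1, p.system2))

    interpretations = [
        interpret_similarity(
            system,
            {c.label: reference_series[(system.label, c.label)].mean for c in crystals},
            crystal_liganded,
        )
        for system in systems
    ]

    return StudyReport(
        system_labels=tuple(s.label for s in systems),
        crystal_labels=tuple(c.label for c in crystals),
        selection_label=selection.describe() if selection else "all",
        reference_series=reference_series,
        movement=movement,
        pair_scores=scores,
        interpretations=interpretations,
        fit=fit,
    )
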
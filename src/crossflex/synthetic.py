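"""Synthetic structures and trajectories with known ground truth.

The generator emulates the statistical structure the cross-over analysis
assumes: a fixed atom set fluctuating around a reference conformation with
per-atom Gaussian amplitudes (optionally AR(1)-correlated in time), and
optional drift between two conformers to mimic a loop relocation between
apo-like and holo-like states.  "Liganded" regimes are stiff (small sigma),
"unliganded" regimes floppy (large sigma) — the qualitative contrast seen
between ligand-bound and free enzyme simulations.

For a fluctuation trajectory with per-coordinate standard deviation sigma,
each atom's displacement from its mean is chi-distributed with 3 degrees of
freedom, so its RMSF is sigma*sqrt(3) and, for many atoms, the per-frame
movement RMSD concentrates around sigma*sqrt(3) ≈ 0.866 Å at sigma = 0.5 Å.
These closed forms make every downstream statistic testable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .crossover import CrystalRecord, SystemRecord
from .errors import CorrespondenceError, SpecError
from .structures_io import Atom, Structure, Trajectory

# idealised backbone offsets (Å) relative to each residue's CA position
_BACKBONE_OFFSETS = {
    "N": np.array([-1.46, 0.0, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.52, 0.0, 0.0]),
    "O": np.array([1.52, 1.23, 0.0]),
}
_CA_SPACING = 3.8  # Å between consecutive CA atoms


def make_toy_protein(n_residues: int, geometry: str = "extended",
                     chain: str = "A", structure_id: str = "TOY") -> Structure:
    """Deterministic toy backbone: N, CA, C, O per residue, 3.8 Å CA spacing.

    ``extended`` lays the chain along x; ``helix_like`` winds it on a coarse
    helix (same CA-CA spacing along the arc's chord is approximate).
    """
    if n_residues < 1:
        raise SpecError("n_residues must be >= 1")
    if geometry not in ("extended", "helix_like"):
        raise SpecError(f"unknown geometry {geometry!r}")
    atoms: list[Atom] = []
    serial = 1
    for res in range(1, n_residues + 1):
        if geometry == "extended":
            ca = np.array([(res - 1) * _CA_SPACING, 0.0, 0.0])
        else:
            # coarse helix: 100 deg turn and 1.5 Å rise per residue
            angle = np.deg2rad(100.0 * (res - 1))
            ca = np.array([5.0 * np.cos(angle), 5.0 * np.sin(angle), 1.5 * (res - 1)])
        for name in ("N", "CA", "C", "O"):
            atoms.append(Atom(
                serial=serial, name=name, element=name[0], resname="ALA",
                resnum=res, chain=chain, coords=ca + _BACKBONE_OFFSETS[name],
            ))
            serial += 1
    return Structure(atoms, id=structure_id)


def make_toy_ligand(center, n_atoms: int = 5, resname: str = "RIT",
                    chain: str = "A", resnum: int = 900,
                    first_serial: int = 100000) -> list[Atom]:
    """A small rigid dummy ligand (heavy atoms only) centred at ``center``."""
    center = np.asarray(center, dtype=float)
    offsets = np.array([
        [0.0, 0.0, 0.0],
        [1.4, 0.0, 0.0],
        [-1.4, 0.0, 0.0],
        [0.0, 1.4, 0.0],
        [0.0, 0.0, 1.4],
    ])[:n_atoms]
    return [
        Atom(serial=first_serial + k, name=f"C{k + 1}", element="C", resname=resname,
             resnum=resnum, chain=chain, coords=center + off, het=True)
        for k, off in enumerate(offsets)
    ]


@dataclass(frozen=True)
class FluctuationSpec:
    """Gaussian fluctuation around a base structure.

    ``sigma`` is the stationary per-atom per-coordinate standard deviation
    in Å (scalar or per-atom array); ``autocorr`` the AR(1) coefficient of
    the noise process in [0, 1).
    """

    base: Structure
    sigma: float | np.ndarray
    n_frames: int
    seed: int
    autocorr: float = 0.0
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise SpecError("n_frames must be >= 2")
        if not (0.0 <= self.autocorr < 1.0):
            raise SpecError("autocorr must lie in [0, 1)")
        if np.any(np.asarray(self.sigma) < 0):
            raise SpecError("sigma must be >= 0")


@dataclass(frozen=True)
class TwoStateSpec:
    """Drift between two matched conformers plus Gaussian fluctuation.

    ``schedule`` is either an integer switch frame (occupancy of conformer B
    jumps from 0 to 1 at that frame) or a per-frame array of blend weights
    in [0, 1].
    """

    conformer_a: np.ndarray
    conformer_b: np.ndarray
    sigma: float | np.ndarray
    n_frames: int
    seed: int
    schedule: int | np.ndarray | None = None
    autocorr: float = 0.0
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        a = np.asarray(self.conformer_a, dtype=float)
        b = np.asarray(self.conformer_b, dtype=float)
        object.__setattr__(self, "conformer_a", a)
        object.__setattr__(self, "conformer_b", b)
        if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
            raise CorrespondenceError(
                f"conformers must be matched (n, 3) arrays, got {a.shape} and {b.shape}"
            )
        if self.n_frames < 2:
            raise SpecError("n_frames must be >= 2")
        if not (0.0 <= self.autocorr < 1.0):
            raise SpecError("autocorr must lie in [0, 1)")
        if np.any(np.asarray(self.sigma) < 0):
            raise SpecError("sigma must be >= 0")
        if isinstance(self.schedule, (int, np.integer)):
            if not (0 <= int(self.schedule) <= self.n_frames):
                raise SpecError("switch frame must lie in [0, n_frames]")

    def weights(self) -> np.ndarray:
        """Per-frame occupancy of conformer B."""
        if self.schedule is None:
            return np.zeros(self.n_frames)
        if isinstance(self.schedule, (int, np.integer)):
            w = np.zeros(self.n_frames)
            w[int(self.schedule):] = 1.0
            return w
        w = np.asarray(self.schedule, dtype=float)
        if w.shape != (self.n_frames,):
            raise SpecError("blend schedule must have one weight per frame")
        if np.any((w < 0) | (w > 1)):
            raise SpecError("blend weights must lie in [0, 1]")
        return w


def _sigma_per_atom(sigma, n_atoms: int) -> np.ndarray:
    arr = np.asarray(sigma, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n_atoms, float(arr))
    if arr.shape != (n_atoms,):
        raise SpecError(f"sigma must be scalar or length {n_atoms}, got {arr.shape}")
    return arr[:, None]


def _ar1_noise(rng: np.random.Generator, sigma: np.ndarray, phi: float,
               n_frames: int, n_atoms: int) -> np.ndarray:
    """AR(1) per-coordinate noise with stationary SD ``sigma``."""
    if phi == 0.0:
        return sigma[None, :, :] * rng.standard_normal((n_frames, n_atoms, 3))
    noise = np.empty((n_frames, n_atoms, 3))
    e = sigma * rng.standard_normal((n_atoms, 3))  # stationary start
    noise[0] = e
    innovation_scale = np.sqrt(1.0 - phi * phi) * sigma
    for t in range(1, n_frames):
        e = phi * e + innovation_scale * rng.standard_normal((n_atoms, 3))
        noise[t] = e
    return noise


def simulate_fluctuation(spec: FluctuationSpec) -> Trajectory:
    """Simulate Gaussian fluctuation around the base structure.

    Fully reproducible from the seed; the stationary per-coordinate SD of
    each atom equals its sigma.
    """
    n_atoms = len(spec.base)
    sigma = _sigma_per_atom(spec.sigma, n_atoms)
    rng = np.random.default_rng(spec.seed)
    noise = _ar1_noise(rng, sigma, spec.autocorr, spec.n_frames, n_atoms)
    coords = spec.base.coords[None, :, :] + noise
    return Trajectory(spec.base, coords, spec.frame_interval)


def simulate_two_state(spec: TwoStateSpec, topology: Structure | None = None) -> Trajectory:
    """Simulate drift between two conformers with fluctuation noise.

    Frame t's base is conformer_a + w_t * (conformer_b - conformer_a), with
    AR(1) Gaussian noise added as in :func:`simulate_fluctuation`.  If no
    topology is given, a bare CA pseudo-topology is synthesised.
    """
    n_atoms = spec.conformer_a.shape[0]
    if topology is None:
        topology = Structure(
            [Atom(i + 1, "CA", "C", "GLY", i + 1, "A", spec.conformer_a[i])
             for i in range(n_atoms)],
            id="two-state",
        )
    if len(topology) != n_atoms:
        raise CorrespondenceError("topology atom count does not match conformers")
    weights = spec.weights()
    base = spec.conformer_a[None, :, :] + weights[:, None, None] * (
        spec.conformer_b - spec.conformer_a
    )[None, :, :]
    sigma = _sigma_per_atom(spec.sigma, n_atoms)
    rng = np.random.default_rng(spec.seed)
    noise = _ar1_noise(rng, sigma, spec.autocorr, spec.n_frames, n_atoms)
    return Trajectory(topology, base + noise, spec.frame_interval)


@dataclass(eq=False)
class CrossoverFixture:
    """Four synthetic systems plus the two crystal-like references."""

    systems: list[SystemRecord]
    crystals: list[CrystalRecord]
    loop_range: tuple[int, int]


def make_crossover_fixture(stiff_sigma: float = 0.2, floppy_sigma: float = 0.7,
                           loop_range: tuple[int, int] = (20, 30),
                           n_frames: int = 2000, seed: int = 0,
                           n_residues: int = 60,
                           dwell_fraction: float = 0.05) -> CrossoverFixture:
    """Build a full synthetic 2x2 cross-over study.

    Two crystal-like conformers of a toy protein differ only in the loop
    residues ``loop_range`` (relocated by a fixed 4 Å shift); the holo
    crystal carries a rigid dummy ligand near the loop.  Liganded systems
    fluctuate tightly (sigma ``stiff_sigma``) about the holo conformer — the
    system started from the apo crystal adopts it after a brief initial
    dwell (``dwell_fraction`` of the frames) in its start conformation.
    Unliganded systems fluctuate broadly (sigma ``floppy_sigma``) and settle
    into the apo conformer the same way.  Deterministic given the seed.
    """
    if not stiff_sigma < floppy_sigma:
        raise SpecError("stiff_sigma must be smaller than floppy_sigma")
    lo, hi = loop_range
    if not (1 <= lo <= hi <= n_residues):
        raise SpecError(f"loop_range {loop_range} outside 1..{n_residues}")

    apo_protein = make_toy_protein(n_residues, structure_id="APO")
    loop_mask = np.array([lo <= a.resnum <= hi for a in apo_protein.atoms])
    holo_coords = apo_protein.coords.copy()
    holo_coords[loop_mask] += np.array([0.0, 4.0, 0.0])  # loop relocation
    holo_protein = apo_protein.with_coords(holo_coords, id="HOLO")

    loop_center = holo_coords[loop_mask].mean(axis=0)
    ligand_atoms = make_toy_ligand(loop_center + np.array([0.0, 3.0, 0.0]))
    holo_crystal = Structure(holo_protein.atoms + ligand_atoms, id="HOLO")
    liganded_topology = Structure(holo_protein.atoms + ligand_atoms, id="HOLO+lig")
    ligand_coords = np.array([a.coords for a in ligand_atoms])
    n_lig = len(ligand_atoms)

    seeds = [int(s.generate_state(1)[0] % (2**31))
             for s in np.random.SeedSequence(seed).spawn(4)]
    switch = max(1, int(round(dwell_fraction * n_frames)))

    def liganded_system(label: str, origin: str, start_coords: np.ndarray,
                        sys_seed: int) -> SystemRecord:
        # protein drifts start -> holo, dummy ligand held fixed (sigma 0)
        conf_a = np.vstack([start_coords, ligand_coords])
        conf_b = np.vstack([holo_coords, ligand_coords])
        sigma = np.full(conf_a.shape[0], stiff_sigma)
        sigma[-n_lig:] = 0.0
        spec = TwoStateSpec(conf_a, conf_b, sigma, n_frames, sys_seed, schedule=switch)
        traj = simulate_two_state(spec, topology=liganded_topology)
        return SystemRecord(label, traj, liganded=True, origin_structure=origin)

    def unliganded_system(label: str, origin: str, start_coords: np.ndarray,
                          sys_seed: int) -> SystemRecord:
        spec = TwoStateSpec(start_coords, apo_protein.coords,
                            floppy_sigma, n_frames, sys_seed, schedule=switch)
        traj = simulate_two_state(spec, topology=apo_protein)
        return SystemRecord(label, traj, liganded=False, origin_structure=origin)

    systems = [
        liganded_system("HOLO+LIG", "HOLO", holo_coords, seeds[0]),
        unliganded_system("APO-LIG", "APO", apo_protein.coords, seeds[1]),
        liganded_system("APO+LIG", "APO", apo_protein.coords, seeds[2]),
        unliganded_system("HOLO-LIG", "HOLO", holo_coords, seeds[3]),
    ]
    crystals = [
        CrystalRecord("HOLO", holo_crystal, liganded=True),
        CrystalRecord("APO", apo_protein, liganded=False),
    ]
    return CrossoverFixture(systems, crystals, loop_range)
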
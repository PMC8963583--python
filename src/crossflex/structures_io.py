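"""Structures, trajectories, selections and atom matching.

Coordinates are in Angstrom throughout.  PDB files are read and written with
biotite; DCD trajectories with mdtraj's low-level reader (both formats store
Angstrom natively, no unit conversion is performed).  Residue numbers are the
author numbering from the PDB file, never renumbered, so literature residue
ranges (e.g. the CYP3A4 active-site segments) can be used verbatim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from mdtraj.formats import DCDTrajectoryFile

from .errors import (
    CorrespondenceError,
    EmptyStructureError,
    FormatError,
    NoCommonAtomsError,
    TopologyError,
)

logger = logging.getLogger(__name__)

MAIN_CHAIN_NAMES = ("N", "CA", "C", "O")

#: Literature-known CYP3A4 active-site segments (author numbering):
#: H54-F60, S100-E122, T207-P218, I238-E244, V296-S311, F367-R375.
ACTIVE_SITE_CYP3A4_RANGES = (
    (54, 60),
    (100, 122),
    (207, 218),
    (238, 244),
    (296, 311),
    (367, 375),
)


@dataclass(eq=False)
class Atom:
    """One atom of a structure, with PDB-style identity fields."""

    serial: int
    name: str
    element: str
    resname: str
    resnum: int
    chain: str
    coords: np.ndarray
    altloc: str = ""
    het: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name} has invalid coordinates {self.coords}")

    @property
    def is_hydrogen(self) -> bool:
        """Hydrogen by element column, atom-name heuristic if element is blank."""
        el = self.element.strip()
        if el:
            return el.upper() in ("H", "D")
        stripped = self.name.strip().lstrip("0123456789")
        return stripped[:1].upper() == "H"

    def key(self) -> tuple[str, int, str]:
        """Identity key used for cross-structure matching."""
        return (self.chain, self.resnum, self.name)


@dataclass(eq=False)
class Structure:
    """An ordered, fixed set of atoms.

    Atom order is stable and defines the coordinate-array order for all
    downstream math.
    """

    atoms: list[Atom]
    id: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in file order."""
        cached = getattr(self, "_coords", None)
        if cached is None or len(cached) != len(self.atoms):
            cached = np.array([a.coords for a in self.atoms], dtype=float)
            self._coords = cached
        return cached

    def with_coords(self, coords: np.ndarray, id: str | None = None) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise CorrespondenceError(
                f"coordinate array {coords.shape} does not match {len(self.atoms)} atoms"
            )
        atoms = [
            Atom(a.serial, a.name, a.element, a.resname, a.resnum, a.chain,
                 c, a.altloc, a.het)
            for a, c in zip(self.atoms, coords)
        ]
        return Structure(atoms, id=self.id if id is None else id)


@dataclass(eq=False)
class Trajectory:
    """An ordered stack of coordinate frames over one topology.

    ``coords`` has shape (n_frames, n_atoms, 3); ``frame_interval`` is the
    time per frame in ps and is metadata only.
    """

    topology: Structure
    coords: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TopologyError(f"trajectory coordinates must be (T, n, 3), got {self.coords.shape}")
        if self.coords.shape[1] != len(self.topology):
            raise TopologyError(
                f"frames have {self.coords.shape[1]} atoms, topology has {len(self.topology)}"
            )
        if self.coords.shape[0] < 1:
            raise TopologyError("a trajectory needs at least one frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_frames


@dataclass(frozen=True)
class Selection:
    """Declarative atom filter.

    ``atom_class`` is one of ``main_chain`` (N, CA, C, O), ``heavy``
    (everything but hydrogen), ``all``, or ``named`` with ``atom_names``.
    Protein selections (``main_chain``/``heavy``/``named``) exclude HETATM
    records (ligand, heme, waters) unless ``resnames`` asks for them
    explicitly; ``all`` keeps every atom.
    """

    chains: frozenset[str] | None = None
    residue_ranges: tuple[tuple[int, int], ...] | None = None
    atom_class: str = "all"
    atom_names: tuple[str, ...] | None = None
    resnames: frozenset[str] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.atom_class not in ("main_chain", "heavy", "all", "named"):
            raise ValueError(f"unknown atom_class {self.atom_class!r}")
        if self.atom_class == "named" and not self.atom_names:
            raise ValueError("atom_class 'named' requires atom_names")
        if self.residue_ranges is not None:
            for start, end in self.residue_ranges:
                if start > end:
                    raise ValueError(f"residue range {start}-{end} has start > end")

    def describe(self) -> str:
        if self.label:
            return self.label
        parts = [self.atom_class]
        if self.chains:
            parts.append("chains=" + ",".join(sorted(self.chains)))
        if self.residue_ranges:
            parts.append(",".join(f"{a}-{b}" for a, b in self.residue_ranges))
        return " ".join(parts)


def active_site_cyp3a4(atom_class: str = "main_chain") -> Selection:
    """The CYP3A4 active-site preset over the six literature segments."""
    return Selection(
        residue_ranges=ACTIVE_SITE_CYP3A4_RANGES,
        atom_class=atom_class,
        label=f"active-site-cyp3a4/{atom_class}",
    )


def parse_selection(text: str, atom_class: str = "main_chain") -> Selection:
    """Parse a range expression like ``"A:54-60,A:100-122"`` or a preset name.

    Chain prefixes are optional (``"54-60,100-122"`` selects from any chain).
    The preset ``active-site-cyp3a4`` expands to the six CYP3A4 segments.
    """
    text = text.strip()
    if text in ("", "all"):
        return Selection(atom_class=atom_class)
    if text == "active-site-cyp3a4":
        return active_site_cyp3a4(atom_class)
    chains: set[str] = set()
    ranges: list[tuple[int, int]] = []
    for token in text.split(","):
        token = token.strip()
        if not token:
            continue
        if ":" in token:
            chain, span = token.split(":", 1)
            chains.add(chain.strip())
        else:
            span = token
        try:
            if "-" in span:
                lo, hi = span.split("-", 1)
                ranges.append((int(lo), int(hi)))
            else:
                ranges.append((int(span), int(span)))
        except ValueError as exc:
            raise ValueError(f"cannot parse selection token {token!r}") from exc
    return Selection(
        chains=frozenset(chains) or None,
        residue_ranges=tuple(ranges) or None,
        atom_class=atom_class,
        label=text + "/" + atom_class,
    )


@dataclass(frozen=True)
class AtomMap:
    """Ordered index pairs between two structures, (index_in_a, index_in_b)."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise NoCommonAtomsError("atom map is empty")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def idx_a(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=int)

    @property
    def idx_b(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=int)

    @classmethod
    def identity(cls, n: int) -> "AtomMap":
        return cls(tuple((i, i) for i in range(n)))


# ---------------------------------------------------------------------------
# Selection / matching
# ---------------------------------------------------------------------------

def apply_selection(structure: Structure, selection: Selection) -> np.ndarray:
    """Return indices of atoms matching ``selection``, in topology order.

    Deterministic; an empty result is legal output (the caller decides
    whether that is an error).
    """
    indices = []
    ranges = selection.residue_ranges
    for i, atom in enumerate(structure.atoms):
        if selection.resnames is not None:
            if atom.resname not in selection.resnames:
                continue
        elif atom.het and selection.atom_class != "all":
            continue
        if selection.chains is not None and atom.chain not in selection.chains:
            continue
        if ranges is not None and not any(lo <= atom.resnum <= hi for lo, hi in ranges):
            continue
        if selection.atom_class == "main_chain":
            if atom.name not in MAIN_CHAIN_NAMES:
                continue
        elif selection.atom_class == "heavy":
            if atom.is_hydrogen:
                continue
        elif selection.atom_class == "named":
            if atom.name not in selection.atom_names:
                continue
        indices.append(i)
    return np.array(indices, dtype=int)


def match_atoms(a: Structure, b: Structure, selection: Selection | None = None) -> AtomMap:
    """Pair atoms of two structures by (chain, resnum, atom name).

    Only the intersection is kept, ordered as in ``a``; atoms unresolved in
    either structure (e.g. a crystal's missing loop residues) are silently
    dropped and reported via a log message.
    """
    if not len(a) or not len(b):
        raise EmptyStructureError("cannot match atoms of an empty structure")
    selection = selection or Selection()
    idx_a = apply_selection(a, selection)
    idx_b = apply_selection(b, selection)
    lookup_b = {}
    for j in idx_b:
        key = b.atoms[j].key()
        lookup_b.setdefault(key, int(j))
    pairs = []
    for i in idx_a:
        j = lookup_b.get(a.atoms[i].key())
        if j is not None:
            pairs.append((int(i), j))
    if not pairs:
        raise NoCommonAtomsError(
            f"no common atoms between {a.id or 'A'} and {b.id or 'B'} for {selection.describe()}"
        )
    dropped_a = len(idx_a) - len(pairs)
    dropped_b = len(idx_b) - len(pairs)
    if dropped_a or dropped_b:
        logger.info(
            "match_atoms %s/%s (%s): %d pairs, dropped %d from %s, %d from %s",
            a.id, b.id, selection.describe(), len(pairs),
            dropped_a, a.id or "A", dropped_b, b.id or "B",
        )
    return AtomMap(tuple(pairs))


# ---------------------------------------------------------------------------
# PDB / DCD I/O
# ---------------------------------------------------------------------------

def _diagnose_pdb(path: Path, cause: Exception) -> str:
    """Best-effort line-level diagnosis of a malformed fixed-column PDB file."""
    try:
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                if line.startswith(("ATOM", "HETATM")):
                    try:
                        float(line[30:38])
                        float(line[38:46])
                        float(line[46:54])
                        int(line[22:26])
                    except (ValueError, IndexError):
                        return f"{path}: malformed record at line {lineno}: {line.rstrip()!r}"
    except OSError:
        pass
    return f"{path}: {cause}"


def _structure_from_atom_array(arr, structure_id: str) -> Structure:
    n = arr.array_length()
    serials = (
        arr.get_annotation("atom_id")
        if "atom_id" in arr.get_annotation_categories()
        else np.arange(1, n + 1)
    )
    altlocs = (
        arr.get_annotation("altloc_id")
        if "altloc_id" in arr.get_annotation_categories()
        else [""] * n
    )
    atoms = [
        Atom(
            serial=int(serials[i]),
            name=str(arr.atom_name[i]),
            element=str(arr.element[i]),
            resname=str(arr.res_name[i]),
            resnum=int(arr.res_id[i]),
            chain=str(arr.chain_id[i]),
            coords=np.asarray(arr.coord[i], dtype=float),
            altloc=str(altlocs[i]).strip().replace(".", ""),
            het=bool(arr.hetero[i]),
        )
        for i in range(n)
    ]
    return Structure(atoms, id=structure_id)


def _atom_array_from_structure(structure: Structure):
    n = len(structure)
    arr = struc.AtomArray(n)
    arr.coord = structure.coords.astype(np.float32)
    arr.chain_id = np.array([a.chain or "A" for a in structure.atoms])
    arr.res_id = np.array([a.resnum for a in structure.atoms])
    arr.res_name = np.array([a.resname for a in structure.atoms])
    arr.atom_name = np.array([a.name for a in structure.atoms])
    arr.element = np.array([a.element for a in structure.atoms])
    arr.hetero = np.array([a.het for a in structure.atoms])
    return arr


def read_pdb(path, altloc_policy: str = "first", model: int = 1,
             structure_id: str | None = None) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    ``altloc_policy``: ``"first"`` keeps the first alternate location per
    atom (the blank/"A" convention), ``"occupancy"`` keeps the highest
    occupancy, and a single letter keeps blank locations plus that letter.
    Occupancy is otherwise ignored.
    """
    path = Path(path)
    if structure_id is None:
        structure_id = path.stem
    try:
        pdb_file = PDBFile.read(str(path))
        if not any(line.startswith(("ATOM", "HETATM")) for line in pdb_file.lines):
            raise EmptyStructureError(f"{path}: no atoms found")
        if altloc_policy in ("first", "occupancy"):
            arr = pdb_file.get_structure(
                model=model, altloc=altloc_policy, extra_fields=["atom_id"]
            )
        else:
            arr = pdb_file.get_structure(
                model=model, altloc="all", extra_fields=["atom_id"]
            )
            altloc_ids = np.char.strip(arr.get_annotation("altloc_id").astype(str))
            arr = arr[(altloc_ids == "") | (altloc_ids == ".") | (altloc_ids == altloc_policy)]
    except (FileNotFoundError, EmptyStructureError):
        raise
    except Exception as exc:  # biotite raises assorted parse errors
        raise FormatError(_diagnose_pdb(path, exc)) from exc
    if arr.array_length() == 0:
        raise EmptyStructureError(f"{path}: no atoms found")
    return _structure_from_atom_array(arr, structure_id)


def write_pdb(structure: Structure, path) -> None:
    """Write a single-model PDB file."""
    pdb_file = PDBFile()
    pdb_file.set_structure(_atom_array_from_structure(structure))
    pdb_file.write(str(path))


def _check_frame_identity(arr, topology: Structure, frame: int) -> None:
    if arr.array_length() != len(topology):
        raise TopologyError(
            f"frame {frame}: {arr.array_length()} atoms, topology has {len(topology)}"
        )
    names = np.array([a.name for a in topology.atoms])
    resnums = np.array([a.resnum for a in topology.atoms])
    if not (np.all(arr.atom_name == names) and np.all(arr.res_id == resnums)):
        bad = int(np.flatnonzero((arr.atom_name != names) | (arr.res_id != resnums))[0])
        raise TopologyError(
            f"frame {frame}: atom {bad} is {arr.atom_name[bad]}/{int(arr.res_id[bad])}, "
            f"topology expects {names[bad]}/{int(resnums[bad])}"
        )


def read_trajectory(path, topology: Structure, format: str | None = None,
                    frame_interval: float = 1.0) -> Trajectory:
    """Read a multi-model PDB or DCD trajectory over a known topology.

    Frames are returned in file order; no superposition is applied on read.
    Multi-model PDB frames are checked atom-by-atom (name and residue
    number) against the topology; DCD carries no identities, only the atom
    count is checked.
    """
    path = Path(path)
    if format is None:
        format = "dcd" if path.suffix.lower() == ".dcd" else "multi_model_pdb"
    if format == "dcd":
        try:
            with DCDTrajectoryFile(str(path)) as handle:
                xyz, _, _ = handle.read()
        except Exception as exc:
            raise FormatError(f"{path}: not a readable DCD file ({exc})") from exc
        if xyz.shape[1] != len(topology):
            raise TopologyError(
                f"DCD frames have {xyz.shape[1]} atoms, topology has {len(topology)}"
            )
        return Trajectory(topology, np.asarray(xyz, dtype=float), frame_interval)
    if format != "multi_model_pdb":
        raise ValueError(f"unknown trajectory format {format!r}")
    try:
        pdb_file = PDBFile.read(str(path))
        n_models = pdb_file.get_model_count()
    except Exception as exc:
        raise FormatError(_diagnose_pdb(path, exc)) from exc
    try:
        stack = pdb_file.get_structure(model=None, altloc="first")
        _check_frame_identity(stack[0], topology, 0)
        coords = np.asarray(stack.coord, dtype=float)
    except TopologyError:
        raise
    except Exception:
        # inconsistent models: re-read one by one to name the offending frame
        coords_list = []
        for m in range(1, n_models + 1):
            try:
                arr = pdb_file.get_structure(model=m, altloc="first")
            except Exception as exc:
                raise TopologyError(f"frame {m - 1}: {exc}") from exc
            _check_frame_identity(arr, topology, m - 1)
            coords_list.append(np.asarray(arr.coord, dtype=float))
        coords = np.stack(coords_list)
    return Trajectory(topology, coords, frame_interval)


def write_trajectory(traj: Trajectory, path, format: str | None = None) -> None:
    """Write a trajectory as multi-model PDB or DCD (CHARMM/NAMD float32)."""
    path = Path(path)
    if format is None:
        format = "dcd" if path.suffix.lower() == ".dcd" else "multi_model_pdb"
    if format == "dcd":
        with DCDTrajectoryFile(str(path), "w") as handle:
            handle.write(traj.coords.astype(np.float32))
        return
    if format != "multi_model_pdb":
        raise ValueError(f"unknown trajectory format {format!r}")
    template = _atom_array_from_structure(traj.topology)
    stack = struc.from_template(template, traj.coords.astype(np.float32))
    pdb_file = PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))
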
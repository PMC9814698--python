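"""Structure/trajectory data model, PDB readers/writers and atom selection.

The in-memory model is deliberately small: a :class:`Topology` (ordered
atoms with author residue numbering preserved), :class:`Frame` (one
coordinate snapshot in angstroms) and :class:`Trajectory` (ordered frames
at a fixed write interval, 20 ps by default).  Multi-model PDB is the
baseline interchange format, read and written through biotite; DCD/XTC
with a PDB topology are supported through mdtraj behind the same reader
contract.

Author residue numbers (``residue_seq``; e.g. 29-43 for the 15-mer
substrate peptides, K36 = residue 36) are authoritative everywhere;
0-based positional indices are internal only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Topology",
    "Frame",
    "Trajectory",
    "Selection",
    "ParseError",
    "SelectionError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "select",
]


class ParseError(ValueError):
    """Malformed or empty structure file."""


class SelectionError(ValueError):
    """Unresolvable or syntactically invalid atom selection."""


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    residue_seq: int
    chain_id: str

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class Topology:
    atoms: list[Atom]

    def __post_init__(self):
        seen = set()
        for atom in self.atoms:
            key = (atom.chain_id, atom.residue_seq, atom.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in topology")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def residues(self) -> list[tuple[str, int, str]]:
        out: list[tuple[str, int, str]] = []
        for atom in self.atoms:
            key = (atom.chain_id, atom.residue_seq, atom.residue_name)
            if not out or out[-1] != key:
                out.append(key)
        return out

    def index_of(self, residue_seq: int, name: str, chain_id: str | None = None) -> int:
        for i, atom in enumerate(self.atoms):
            if atom.residue_seq == residue_seq and atom.name == name:
                if chain_id is None or atom.chain_id == chain_id:
                    return i
        raise SelectionError(
            f"no atom {name!r} in residue {residue_seq}"
            + (f" chain {chain_id!r}" if chain_id else "")
        )


@dataclass
class Frame:
    coordinates: np.ndarray
    frame_index: int = 0
    time_ps: float = 0.0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("frame coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("frame coordinates must be finite")


@dataclass
class Trajectory:
    topology: Topology
    frames: list[Frame]
    frame_interval_ps: float = 20.0
    condition_label: str = ""
    replicate_id: int = 0

    def __post_init__(self):
        n = len(self.topology)
        for frame in self.frames:
            if frame.coordinates.shape[0] != n:
                raise ValueError(
                    f"frame has {frame.coordinates.shape[0]} atoms, topology has {n}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinate_stack(self, indices=None) -> np.ndarray:
        """(n_frames, n_atoms, 3) array, optionally restricted to indices."""
        stack = np.stack([f.coordinates for f in self.frames])
        if indices is not None:
            stack = stack[:, np.asarray(indices, dtype=int), :]
        return stack


@dataclass(frozen=True)
class Selection:
    """Tiny conjunctive selection language over topology fields.

    Clauses joined by ``and``; each clause is one of

    - ``name CA`` / ``name CA,NZ`` — atom name(s)
    - ``residue_seq 36`` / ``residue_seq 29-43`` / ``residue_seq 29,43``
    - ``residue_name ALA`` — 3-letter code(s)
    - ``chain A`` — chain id(s)
    - ``element N`` — element symbol(s)
    - ``heavy`` — non-hydrogen atoms
    """

    expression: str


_FIELDS = {"name", "residue_seq", "residue_name", "chain", "element"}


def _clause_predicate(clause: str):
    tokens = clause.split()
    if not tokens:
        raise SelectionError("empty selection clause")
    if tokens[0] == "heavy":
        if len(tokens) != 1:
            raise SelectionError(f"bad clause {clause!r}")
        return lambda atom: atom.is_heavy
    if tokens[0] not in _FIELDS:
        raise SelectionError(f"unknown selection field {tokens[0]!r}")
    if len(tokens) != 2:
        raise SelectionError(f"bad clause {clause!r}")
    fieldname, value = tokens
    if fieldname == "residue_seq":
        allowed: set[int] = set()
        for part in value.split(","):
            if "-" in part[1:]:
                lo, hi = part.split("-", 1)
                allowed.update(range(int(lo), int(hi) + 1))
            else:
                allowed.add(int(part))
        return lambda atom: atom.residue_seq in allowed
    values = set(value.split(","))
    attr = {"name": "name", "residue_name": "residue_name",
            "chain": "chain_id", "element": "element"}[fieldname]
    return lambda atom: getattr(atom, attr) in values


def select(topology: Topology, selection: Selection | str) -> list[int]:
    """Resolve a selection to an ordered, duplicate-free index list."""
    expr = selection.expression if isinstance(selection, Selection) else selection
    predicates = [_clause_predicate(c.strip()) for c in expr.split(" and ")]
    return [
        i for i, atom in enumerate(topology.atoms)
        if all(p(atom) for p in predicates)
    ]


# --- biotite interconversion -------------------------------------------------

def _to_atom_array(topology: Topology, coordinates: np.ndarray) -> struc.AtomArray:
    n = len(topology)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coordinates, dtype=np.float32)
    arr.chain_id = np.array([a.chain_id for a in topology.atoms])
    arr.res_id = np.array([a.residue_seq for a in topology.atoms])
    arr.res_name = np.array([a.residue_name for a in topology.atoms])
    arr.atom_name = np.array([a.name for a in topology.atoms])
    arr.element = np.array([a.element for a in topology.atoms])
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def _from_atom_array(arr: struc.AtomArray) -> Topology:
    if "altloc_id" in arr.get_annotation_categories():
        keep = np.isin(arr.altloc_id, ("", ".", "A", " "))
        if not np.all(keep):
            logger.warning("dropping %d alternate-location atoms", np.sum(~keep))
            arr = arr[keep]
    atoms = []
    res_index = -1
    last = None
    for i in range(arr.array_length()):
        key = (str(arr.chain_id[i]), int(arr.res_id[i]), str(arr.res_name[i]))
        if key != last:
            res_index += 1
            last = key
        atoms.append(
            Atom(
                serial=i + 1,
                name=str(arr.atom_name[i]),
                element=str(arr.element[i]).upper() or "X",
                residue_index=res_index,
                residue_name=str(arr.res_name[i]),
                residue_seq=int(arr.res_id[i]),
                chain_id=str(arr.chain_id[i]),
            )
        )
    return Topology(atoms=atoms)


def _load_pdb(path) -> tuple[Topology, np.ndarray]:
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stack = pdb.get_structure(altloc="first")
    except Exception as exc:  # biotite raises assorted parse errors
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    if stack.array_length() == 0:
        raise ParseError(f"no atoms in {path}")
    topology = _from_atom_array(stack[0])
    return topology, np.asarray(stack.coord, dtype=float)


def read_structure(path) -> tuple[Topology, Frame]:
    """Read a single-model PDB file into (Topology, Frame)."""
    topology, coords = _load_pdb(path)
    return topology, Frame(coordinates=coords[0], frame_index=0, time_ps=0.0)


def write_structure(path, topology: Topology, frame: Frame) -> None:
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(topology, frame.coordinates))
    pdb.write(str(path))


def read_trajectory(
    path,
    topology: Topology | None = None,
    frame_interval_ps: float = 20.0,
    condition_label: str = "",
    replicate_id: int = 0,
) -> Trajectory:
    """Read a multi-model PDB (or DCD/XTC with a known topology).

    For binary formats ``topology`` must come from a matching PDB file.
    Frame times are ``frame_index * frame_interval_ps``.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".dcd", ".xtc"):
        if topology is None:
            raise ValueError("binary trajectories need an explicit topology")
        coords = _load_binary_coords(path, topology)
    else:
        file_topology, coords = _load_pdb(path)
        if topology is None:
            topology = file_topology
        elif len(topology) != coords.shape[1]:
            raise ValueError(
                f"atom count mismatch: topology {len(topology)}, file {coords.shape[1]}"
            )
    if topology is not None and coords.shape[1] != len(topology):
        raise ValueError(
            f"atom count mismatch: topology {len(topology)}, file {coords.shape[1]}"
        )
    frames = [
        Frame(coordinates=coords[i], frame_index=i, time_ps=i * frame_interval_ps)
        for i in range(coords.shape[0])
    ]
    return Trajectory(
        topology=topology,
        frames=frames,
        frame_interval_ps=frame_interval_ps,
        condition_label=condition_label,
        replicate_id=replicate_id,
    )


def _load_binary_coords(path: Path, topology: Topology) -> np.ndarray:
    import tempfile

    import mdtraj

    with tempfile.NamedTemporaryFile(suffix=".pdb", delete=False) as handle:
        tmp = handle.name
    try:
        write_structure(tmp, topology, Frame(np.zeros((len(topology), 3))))
        traj = mdtraj.load(str(path), top=tmp)
    finally:
        Path(tmp).unlink(missing_ok=True)
    return np.asarray(traj.xyz, dtype=float) * 10.0  # nm -> angstrom


def write_trajectory(path, trajectory: Trajectory) -> None:
    """Write a multi-model PDB."""
    arrays = [
        _to_atom_array(trajectory.topology, frame.coordinates)
        for frame in trajectory.frames
    ]
    pdb = PDBFile()
    pdb.set_structure(struc.stack(arrays))
    pdb.write(str(path))
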
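"""Trajectory containers and text-format I/O.

The in-memory model is deliberately small: a :class:`Trajectory` is an atom
template (names, residues, chains — read once from the first model of a file)
plus an ordered list of :class:`Frame` coordinate snapshots.  Coordinates are
always in Angstrom, times always in picoseconds; atom indices are 0-based
internally while residue ids stay 1-based as written in PDB files.

Multi-model PDB is the native on-disk format (MODEL/ENDMDL blocks, one model
per frame); plain XYZ is supported as a lighter alternative.  Binary MD
formats are out of scope — convert externally to multi-model PDB first.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError, FormatError, SelectionError

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_xyz",
    "write_xyz",
    "select_atoms",
    "window_subsample",
]


@dataclass(frozen=True)
class AtomRecord:
    """One template atom: identity metadata plus its reference coordinates."""

    serial: int
    name: str
    element: str
    resname: str
    resid: int
    chain: str
    coords: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)
        if not self.name:
            raise ValueError(f"atom {self.serial}: empty atom name")


@dataclass
class Frame:
    """One snapshot: a timestamp (ps) and an N x 3 coordinate array (A)."""

    time: float
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("frame coords must have shape (N, 3)")
        if self.time < 0:
            raise ValueError("frame time must be non-negative")


class Trajectory:
    """Ordered frames over a fixed atom template.

    Parameters
    ----------
    atoms
        Template atoms (identity only; per-frame coordinates live in frames).
    frames
        Snapshots with strictly increasing times and a constant atom count
        equal to ``len(atoms)``.
    replicate_label
        Free-form tag identifying the replicate simulation (e.g. ``"conf3"``).
    """

    def __init__(self, atoms, frames, replicate_label: str = ""):
        self.atoms = list(atoms)
        self.frames = list(frames)
        self.replicate_label = replicate_label
        n = len(self.atoms)
        prev_t = -math.inf
        for i, fr in enumerate(self.frames):
            if fr.coords.shape[0] != n:
                raise ValueError(
                    f"frame {i} has {fr.coords.shape[0]} atoms, template has {n}"
                )
            if fr.time <= prev_t:
                raise ValueError("frame times must be strictly increasing")
            prev_t = fr.time
        self._universe = None  # lazy MDAnalysis selection backend

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)

    def coords_array(self) -> np.ndarray:
        """All coordinates as one (n_frames, n_atoms, 3) array."""
        return np.stack([f.coords for f in self.frames])

    def select(self, expression: str) -> np.ndarray:
        return select_atoms(self, expression)

    def __repr__(self):
        return (
            f"Trajectory(n_atoms={self.n_atoms}, n_frames={self.n_frames}, "
            f"replicate_label={self.replicate_label!r})"
        )


def _stack_to_trajectory(stack, default_dt, replicate_label) -> Trajectory:
    import biotite.structure as struc

    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    atoms = []
    for i in range(stack.array_length()):
        atoms.append(
            AtomRecord(
                serial=i,
                name=str(stack.atom_name[i]),
                element=str(stack.element[i]),
                resname=str(stack.res_name[i]),
                resid=int(stack.res_id[i]),
                chain=str(stack.chain_id[i]),
                coords=stack.coord[0, i],
            )
        )
    frames = [
        Frame(time=m * default_dt, coords=stack.coord[m])
        for m in range(stack.stack_depth())
    ]
    return Trajectory(atoms, frames, replicate_label=replicate_label)


def read_multimodel_pdb(
    path, default_dt: float = 10.0, replicate_label: str = ""
) -> Trajectory:
    """Read a multi-model PDB file as a trajectory.

    The first MODEL defines the atom template; a file without MODEL records is
    treated as a single frame.  PDB carries no time axis, so frame times are
    filled as ``model_index * default_dt`` (ps).

    Raises
    ------
    FormatError
        If models disagree in atom count or an ATOM line cannot be parsed.
    """
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except FileNotFoundError:
        raise
    except Exception as exc:  # biotite raises several parse-error types
        raise FormatError(f"cannot parse multi-model PDB {path}: {exc}") from exc
    return _stack_to_trajectory(stack, default_dt, replicate_label)


def write_multimodel_pdb(traj: Trajectory, path) -> None:
    """Write a trajectory as MODEL/ENDMDL blocks with fixed-width columns.

    Coordinates are written to 3 decimals (the PDB field width); values with
    magnitude >= 10000 A overflow the 8-column field and raise FormatError.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if traj.n_frames == 0:
        raise FormatError("cannot write a trajectory with no frames")
    coords = traj.coords_array()
    if np.max(np.abs(coords)) >= 10000.0:
        raise FormatError("coordinate magnitude >= 10000 A overflows PDB fields")
    n = traj.n_atoms
    template = struc.AtomArray(n)
    template.coord = coords[0]
    template.atom_name = np.array([a.name for a in traj.atoms], dtype="U6")
    template.res_name = np.array([a.resname for a in traj.atoms], dtype="U5")
    template.res_id = np.array([a.resid for a in traj.atoms], dtype=int)
    template.chain_id = np.array([a.chain for a in traj.atoms], dtype="U4")
    template.element = np.array([a.element for a in traj.atoms], dtype="U2")
    stack = struc.stack([template] * traj.n_frames)
    stack.coord = coords
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_xyz(path, default_dt: float = 10.0, replicate_label: str = "") -> Trajectory:
    """Read a concatenated plain-XYZ file (count line, comment, atom lines)."""
    frames_coords = []
    names = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(f"{path}: expected atom count at line {i + 1}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise FormatError(f"{path}: truncated frame starting at line {i + 1}")
        frame_names, coords = [], []
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise FormatError(f"{path}: bad XYZ atom line {i + 3 + j}")
            frame_names.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        if names is None:
            names = frame_names
        elif frame_names != names:
            raise FormatError(f"{path}: atom names differ between frames")
        frames_coords.append(np.array(coords))
        i += 2 + n
    if names is None:
        raise FormatError(f"{path}: empty XYZ file")
    atoms = [
        AtomRecord(
            serial=k, name=nm, element=nm[:1], resname="UNK", resid=1, chain="A",
            coords=frames_coords[0][k],
        )
        for k, nm in enumerate(names)
    ]
    frames = [Frame(m * default_dt, c) for m, c in enumerate(frames_coords)]
    return Trajectory(atoms, frames, replicate_label=replicate_label)


def write_xyz(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        for fr in traj.frames:
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"t= {fr.time:.3f} ps {traj.replicate_label}\n")
            for a, xyz in zip(traj.atoms, fr.coords):
                fh.write(
                    f"{a.name:<4s} {xyz[0]:12.6f} {xyz[1]:12.6f} {xyz[2]:12.6f}\n"
                )


def _build_universe(traj: Trajectory):
    import MDAnalysis as mda

    resid_chain = []
    atom_resindex = []
    for a in traj.atoms:
        key = (a.chain, a.resid, a.resname)
        if not resid_chain or resid_chain[-1] != key:
            resid_chain.append(key)
        atom_resindex.append(len(resid_chain) - 1)
    u = mda.Universe.empty(
        traj.n_atoms,
        n_residues=len(resid_chain),
        atom_resindex=np.array(atom_resindex),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [a.name for a in traj.atoms])
    u.add_TopologyAttr("elements", [a.element for a in traj.atoms])
    u.add_TopologyAttr("chainIDs", [a.chain for a in traj.atoms])
    u.add_TopologyAttr("resids", [k[1] for k in resid_chain])
    u.add_TopologyAttr("resnames", [k[2] for k in resid_chain])
    u.atoms.positions = np.stack([a.coords for a in traj.atoms])
    return u


def select_atoms(traj: Trajectory, expression: str) -> np.ndarray:
    """Resolve a selection expression to sorted 0-based atom indices.

    The grammar is the MDAnalysis selection language restricted to identity
    attributes (``name``, ``resid``, ``resname``, ``chainID``, ``element``,
    boolean operators, index ranges).

    Raises
    ------
    SelectionError
        If the expression is malformed or selects no atoms.
    """
    if traj._universe is None:
        traj._universe = _build_universe(traj)
    try:
        group = traj._universe.select_atoms(expression)
    except Exception as exc:
        raise SelectionError(f"bad selection expression {expression!r}: {exc}") from exc
    idx = np.sort(np.asarray(group.ix, dtype=int))
    if idx.size == 0:
        raise SelectionError(f"selection {expression!r} matches no atoms")
    return idx


def window_subsample(
    traj: Trajectory, start: float, end: float, interval: float
) -> Trajectory:
    """Frames with time in the half-open window ``(start, end]`` on a stride grid.

    A frame at time t is kept when ``start < t <= end`` and ``t - start`` is an
    integer multiple of ``interval`` (within 1e-6 ps).  When the source stride
    divides ``interval`` the output has exactly ``floor((end - start)/interval)``
    frames; an interval coarser than the source stride keeps every k-th frame.
    """
    if not start < end:
        raise ValueError("window start must be < end")
    if interval <= 0:
        raise ValueError("interval must be positive")
    kept = []
    for fr in traj.frames:
        if start < fr.time <= end + 1e-9:
            k = (fr.time - start) / interval
            if abs(k - round(k)) < 1e-6:
                kept.append(Frame(fr.time, fr.coords))
    if not kept:
        span = (
            f"[{traj.frames[0].time}, {traj.frames[-1].time}] ps"
            if traj.frames
            else "no frames"
        )
        raise AnalysisError(
            f"window ({start}, {end}] ps at {interval} ps matches no frames "
            f"(trajectory spans {span})"
        )
    return Trajectory(traj.atoms, kept, replicate_label=traj.replicate_label)
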
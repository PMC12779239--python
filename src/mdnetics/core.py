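"""Domain types, structure/trajectory I/O, and atom selection.

The central objects are :class:`Topology` (ordered atoms with residue and
chain structure plus per-atom physical parameters), :class:`Frame`
(coordinates of one snapshot, nm), and :class:`TrajectoryEnsemble` (one or
more replicas of time-stamped frames sharing a topology, carrying the
discard-equilibration convention used by every time-averaged analysis).

PDB files (single and multi-model) are parsed and written through biotite;
a lightweight ``.npz`` array format and an explicit array constructor
(:func:`ensemble_from_arrays`) serve as the adapter contract for plugging
in standard binary trajectory readers (XTC/DCD via MDAnalysis or mdtraj):
any reader that can produce ``coords`` (n_frames, n_atoms, 3) in nm and
``times`` in ps feeds the same entry point.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import ANGSTROM_PER_NM, ATOMIC_MASSES

__all__ = [
    "AtomRecord", "Residue", "Topology", "Frame", "Replica",
    "TrajectoryEnsemble", "Selection", "FormatError", "SelectionError",
    "ParameterError", "read_structure", "write_structure",
    "read_atom_parameters", "write_atom_parameters", "load_trajectory",
    "ensemble_from_arrays", "select",
]

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HID", "HIE", "HIP", "CYX", "MSE",
}


class FormatError(ValueError):
    """Raised when an input file cannot be parsed."""


class SelectionError(ValueError):
    """Raised on selection-grammar syntax errors."""


class ParameterError(ValueError):
    """Raised when a parameter table does not cover the topology."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, residue membership, and physical parameters.

    Units: ``mass`` amu, ``charge`` elementary charges, ``lj_sigma`` nm,
    ``lj_epsilon`` kJ/mol.
    """

    index: int
    name: str
    element: str
    mass: float
    residue_index: int
    residue_name: str
    chain_id: str
    charge: float = 0.0
    lj_sigma: float = 0.0
    lj_epsilon: float = 0.0

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    def __post_init__(self):
        if not self.mass > 0:
            raise ValueError(f"atom {self.index} ({self.name}): mass must be > 0, got {self.mass}")
        if self.lj_sigma < 0 or self.lj_epsilon < 0:
            raise ValueError(f"atom {self.index} ({self.name}): LJ parameters must be >= 0")


@dataclass(frozen=True)
class Residue:
    """Residue bookkeeping: internal 0-based index plus the original
    author numbering (with insertion code) retained as a reporting label."""

    index: int
    name: str
    chain_id: str
    atom_indices: tuple
    author_seq_id: int = None
    insertion_code: str = ""

    @property
    def label(self) -> str:
        seq = self.author_seq_id if self.author_seq_id is not None else self.index
        return f"{self.chain_id}:{self.name}{seq}{self.insertion_code}"


class Topology:
    """Ordered atoms with residue/chain structure and named group selections.

    Atom indices are contiguous from 0 and every atom belongs to exactly one
    residue. Residue indices are internally 0-based contiguous; original PDB
    author numbering is kept on :class:`Residue` for reporting.
    """

    def __init__(self, atoms, groups=None):
        atoms = list(atoms)
        if not atoms:
            raise ValueError("empty topology: no atoms")
        for i, a in enumerate(atoms):
            if a.index != i:
                raise ValueError(f"atom indices must be contiguous from 0; atom {i} has index {a.index}")
        self.atoms = atoms
        self.residues = self._build_residues(atoms)
        self.groups: dict[str, np.ndarray] = {}
        self.parameters_assigned = False
        self.group_charges: dict[str, float] = {}
        if groups:
            for name, idx in groups.items():
                self.set_group(name, idx)
        # cached arrays for vectorised numerics
        self._refresh_arrays()

    @staticmethod
    def _build_residues(atoms):
        residues = []
        current_key, current_atoms = None, []
        for a in atoms:
            key = a.residue_index
            if key != current_key:
                if current_atoms:
                    first = current_atoms[0]
                    residues.append(Residue(
                        index=first.residue_index, name=first.residue_name,
                        chain_id=first.chain_id,
                        atom_indices=tuple(x.index for x in current_atoms),
                        author_seq_id=getattr(first, "_author_seq", None),
                    ))
                current_key, current_atoms = key, []
            current_atoms.append(a)
        if current_atoms:
            first = current_atoms[0]
            residues.append(Residue(
                index=first.residue_index, name=first.residue_name,
                chain_id=first.chain_id,
                atom_indices=tuple(x.index for x in current_atoms),
                author_seq_id=getattr(first, "_author_seq", None),
            ))
        expected = list(range(len(residues)))
        got = [r.index for r in residues]
        if got != expected:
            raise ValueError(f"residue indices must be 0-based contiguous, got {got[:10]}...")
        return residues

    def _refresh_arrays(self):
        self.masses = np.array([a.mass for a in self.atoms])
        self.charges = np.array([a.charge for a in self.atoms])
        self.lj_sigmas = np.array([a.lj_sigma for a in self.atoms])
        self.lj_epsilons = np.array([a.lj_epsilon for a in self.atoms])
        self.residue_indices = np.array([a.residue_index for a in self.atoms])
        self.heavy_mask = np.array([a.is_heavy for a in self.atoms])

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def set_group(self, name: str, atom_indices) -> None:
        idx = np.asarray(atom_indices, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= len(self.atoms)):
            raise ValueError(f"group {name!r}: atom index out of range")
        if len(np.unique(idx)) != len(idx):
            raise ValueError(f"group {name!r}: duplicate atom indices")
        self.groups[name] = np.sort(idx)

    def residue_label(self, residue_index: int) -> str:
        return self.residues[residue_index].label

    def with_parameters(self, masses=None, charges=None, sigmas=None, epsilons=None) -> "Topology":
        """Return a copy with per-atom parameters replaced."""
        new_atoms = []
        for a in self.atoms:
            new_atoms.append(replace(
                a,
                mass=float(masses[a.index]) if masses is not None else a.mass,
                charge=float(charges[a.index]) if charges is not None else a.charge,
                lj_sigma=float(sigmas[a.index]) if sigmas is not None else a.lj_sigma,
                lj_epsilon=float(epsilons[a.index]) if epsilons is not None else a.lj_epsilon,
            ))
        out = Topology(new_atoms, groups={k: v.copy() for k, v in self.groups.items()})
        out.parameters_assigned = True
        out.group_charges = {
            name: float(out.charges[idx].sum()) for name, idx in out.groups.items()
        }
        # carry author numbering labels through
        out.residues = [replace(r, author_seq_id=s.author_seq_id, insertion_code=s.insertion_code)
                        for r, s in zip(out.residues, self.residues)]
        return out


@dataclass
class Frame:
    """One snapshot: per-atom coordinates (nm), time (ps), optional box (nm)."""

    coordinates: np.ndarray
    time: float = 0.0
    box: np.ndarray = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Replica:
    """One contiguous trajectory: stacked coordinates and strictly
    increasing times."""

    coords: np.ndarray          # (n_frames, n_atoms, 3) nm
    times: np.ndarray           # (n_frames,) ps
    box: np.ndarray = None      # optional (3,) nm

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("replica coords must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("times length must match number of frames")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Frame:
        return Frame(self.coords[i], time=self.times[i], box=self.box)


class TrajectoryEnsemble:
    """Replicas of time-stamped frames tied to one topology.

    ``discard_ps`` is the initial time window (measured from each replica's
    first frame, inclusive threshold) excluded from every time-averaged
    analysis; analysis frames are those with ``t - t0 >= discard_ps``.
    """

    def __init__(self, topology: Topology, replicas, discard_ps: float = 0.0):
        replicas = list(replicas)
        if not replicas:
            raise ValueError("ensemble needs at least one replica")
        for r in replicas:
            if r.coords.shape[1] != topology.n_atoms:
                raise ValueError(
                    f"replica has {r.coords.shape[1]} atoms but topology has {topology.n_atoms}")
        self.topology = topology
        self.replicas = replicas
        self.discard_ps = float(discard_ps)

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    @property
    def total_frames(self) -> int:
        return sum(r.n_frames for r in self.replicas)

    def analysis_mask(self, replica: Replica) -> np.ndarray:
        return (replica.times - replica.times[0]) >= self.discard_ps

    def analysis_coords(self, replica_index: int = None):
        """Post-discard coordinate stacks, per replica or for one replica."""
        if replica_index is not None:
            r = self.replicas[replica_index]
            return r.coords[self.analysis_mask(r)]
        return [r.coords[self.analysis_mask(r)] for r in self.replicas]

    @property
    def n_analysis_frames(self) -> list:
        return [int(self.analysis_mask(r).sum()) for r in self.replicas]

    def restricted(self, atom_indices) -> "TrajectoryEnsemble":
        """Ensemble restricted to a subset of atoms (single-trajectory
        convention for component energetics)."""
        idx = np.asarray(atom_indices, dtype=int)
        sub_atoms = []
        old_res = None
        new_res = -1
        for new_i, old_i in enumerate(idx):
            a = self.topology.atoms[old_i]
            if a.residue_index != old_res:
                old_res = a.residue_index
                new_res += 1
            sub_atoms.append(replace(a, index=new_i, residue_index=new_res))
        sub_top = Topology(sub_atoms)
        sub_top.parameters_assigned = self.topology.parameters_assigned
        reps = [Replica(r.coords[:, idx], r.times, r.box) for r in self.replicas]
        return TrajectoryEnsemble(sub_top, reps, discard_ps=self.discard_ps)


@dataclass(frozen=True)
class Selection:
    """Ordered, duplicate-free atom index list bound to a topology size."""

    atom_indices: tuple

    def __post_init__(self):
        idx = tuple(int(i) for i in self.atom_indices)
        if len(set(idx)) != len(idx):
            raise ValueError("selection contains duplicate indices")
        object.__setattr__(self, "atom_indices", idx)

    def __len__(self):
        return len(self.atom_indices)

    @property
    def indices(self) -> np.ndarray:
        return np.asarray(self.atom_indices, dtype=int)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _infer_element(atom_name: str, element_field: str, residue_name: str) -> str:
    """Element from the PDB element column, falling back to the atom name.

    Ambiguous two-letter names in standard amino acids (CA, CB, ...) are
    carbon by residue context.
    """
    e = element_field.strip().upper()
    if e and e in ATOMIC_MASSES:
        return "H" if e == "H" else e.capitalize().upper() if len(e) == 2 else e
    name = atom_name.strip()
    if residue_name.strip().upper() in STANDARD_AMINO_ACIDS:
        lead = re.sub(r"^[0-9]+", "", name)[:1].upper()
        return lead if lead else "C"
    stripped = re.sub(r"^[0-9]+", "", name).upper()
    if stripped[:2] in ("CL", "NA", "MG", "ZN", "FE", "MN", "SE"):
        return stripped[:2]
    return stripped[:1] if stripped else "C"


def _validate_pdb_lines(path):
    n_atoms = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                n_atoms += 1
                for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                    fieldtxt = line[lo:hi].strip()
                    try:
                        float(fieldtxt)
                    except ValueError:
                        raise FormatError(
                            f"{path}: line {lineno}: non-numeric {what} coordinate "
                            f"{fieldtxt!r}") from None
    if n_atoms == 0:
        raise FormatError(f"{path}: no ATOM/HETATM records")


def _structure_from_file(path):
    from biotite.structure.io.pdb import PDBFile
    _validate_pdb_lines(path)
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(altloc="occupancy")
    except Exception as exc:  # pragma: no cover - biotite internal failures
        raise FormatError(f"{path}: could not parse PDB: {exc}") from exc
    return stack


def _topology_from_atom_array(arr):
    atoms = []
    res_counter = -1
    prev_key = None
    author_seq = {}
    for i in range(arr.array_length()):
        key = (arr.chain_id[i], int(arr.res_id[i]), str(arr.ins_code[i]) if hasattr(arr, "ins_code") else "")
        if key != prev_key:
            res_counter += 1
            prev_key = key
        elem = _infer_element(arr.atom_name[i], str(arr.element[i]), arr.res_name[i])
        rec = AtomRecord(
            index=i, name=str(arr.atom_name[i]), element=elem,
            mass=ATOMIC_MASSES.get(elem, 12.011),
            residue_index=res_counter, residue_name=str(arr.res_name[i]),
            chain_id=str(arr.chain_id[i]),
        )
        object.__setattr__(rec, "_author_seq", int(arr.res_id[i]))
        atoms.append(rec)
        author_seq[res_counter] = (int(arr.res_id[i]),
                                   str(arr.ins_code[i]).strip() if hasattr(arr, "ins_code") else "")
    top = Topology(atoms)
    top.residues = [
        replace(r, author_seq_id=author_seq[r.index][0], insertion_code=author_seq[r.index][1])
        for r in top.residues
    ]
    return top


def read_structure(path):
    """Read a PDB file into ``(Topology, Frame)``.

    Coordinates are converted Angstrom -> nm. Atom order follows the file;
    the highest-occupancy alternate conformer is kept; elements come from
    the element column with atom-name fallback.
    """
    stack = _structure_from_file(path)
    arr = stack[0] if stack.stack_depth() >= 1 else stack
    top = _topology_from_atom_array(arr)
    coords = np.asarray(arr.coord, dtype=float) / ANGSTROM_PER_NM
    return top, Frame(coords, time=0.0)


def write_structure(path, topology: Topology, frames) -> None:
    """Write a single- or multi-model PDB preserving names, author residue
    numbering and chain ids; nm -> Angstrom at the boundary."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if isinstance(frames, Frame):
        frames = [frames]
    n = topology.n_atoms
    arrays = []
    for fr in frames:
        arr = struc.AtomArray(n)
        arr.coord = np.asarray(fr.coordinates, dtype=np.float32) * ANGSTROM_PER_NM
        arr.chain_id = np.array([a.chain_id for a in topology.atoms], dtype="U4")
        arr.res_id = np.array(
            [topology.residues[a.residue_index].author_seq_id
             if topology.residues[a.residue_index].author_seq_id is not None
             else a.residue_index + 1
             for a in topology.atoms], dtype=int)
        arr.res_name = np.array([a.residue_name for a in topology.atoms], dtype="U5")
        arr.atom_name = np.array([a.name for a in topology.atoms], dtype="U6")
        arr.element = np.array([a.element for a in topology.atoms], dtype="U2")
        arr.hetero = np.zeros(n, dtype=bool)
        arrays.append(arr)
    stack = struc.stack(arrays) if len(arrays) > 1 else arrays[0]
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Parameter tables
# ---------------------------------------------------------------------------

PARAM_COLUMNS = ["chain", "residue_index", "atom_name", "mass", "charge", "sigma", "epsilon"]


def read_atom_parameters(path, topology: Topology) -> Topology:
    """Attach per-atom mass/charge/LJ parameters from a delimited table.

    The table must have a header with columns ``chain residue_index
    atom_name mass charge sigma epsilon`` (whitespace or comma delimited;
    residue_index in the file's author numbering) and cover every topology
    atom exactly once. Returns a new Topology with ``group_charges``
    populated per named group.
    """
    import pandas as pd
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing_cols = [c for c in PARAM_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParameterError(f"parameter table missing columns: {missing_cols}")
    keyed = {}
    for row in df.itertuples(index=False):
        key = (str(row.chain), int(row.residue_index), str(row.atom_name))
        if key in keyed:
            raise ParameterError(
                f"duplicate parameter row for chain={key[0]} residue={key[1]} atom={key[2]}")
        keyed[key] = row

    masses = np.empty(topology.n_atoms)
    charges = np.empty(topology.n_atoms)
    sigmas = np.empty(topology.n_atoms)
    epsilons = np.empty(topology.n_atoms)
    for a in topology.atoms:
        res = topology.residues[a.residue_index]
        seq = res.author_seq_id if res.author_seq_id is not None else a.residue_index
        key = (a.chain_id, seq, a.name)
        if key not in keyed:
            raise ParameterError(
                f"no parameters for atom chain={a.chain_id} residue={seq} "
                f"({a.residue_name}) atom={a.name}")
        row = keyed[key]
        masses[a.index] = row.mass
        charges[a.index] = row.charge
        sigmas[a.index] = row.sigma
        epsilons[a.index] = row.epsilon
    return topology.with_parameters(masses, charges, sigmas, epsilons)


def write_atom_parameters(path, topology: Topology) -> None:
    import pandas as pd
    rows = []
    for a in topology.atoms:
        res = topology.residues[a.residue_index]
        seq = res.author_seq_id if res.author_seq_id is not None else a.residue_index
        rows.append((a.chain_id, seq, a.name, a.mass, a.charge, a.lj_sigma, a.lj_epsilon))
    pd.DataFrame(rows, columns=PARAM_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Trajectory loading
# ---------------------------------------------------------------------------

def load_trajectory(paths, topology: Topology, discard_ns: float = 200.0,
                    dt_ps: float = 1000.0) -> TrajectoryEnsemble:
    """Load one or more replicas into a :class:`TrajectoryEnsemble`.

    Each path may be a multi-model PDB (times assigned at ``dt_ps``
    spacing) or an ``.npz`` with keys ``coords`` (n_frames, n_atoms, 3, nm),
    ``times`` (ps) and optionally ``box``. ``discard_ns`` is stored on the
    ensemble; frames inside the window stay on disk and in memory but are
    excluded from every averaged analysis.
    """
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]
    replicas = []
    for path in paths:
        spath = str(path)
        if spath.endswith(".npz"):
            data = np.load(spath)
            coords = data["coords"]
            times = data["times"] if "times" in data else np.arange(len(coords)) * dt_ps
            box = data["box"] if "box" in data else None
        else:
            stack = _structure_from_file(spath)
            coords = np.asarray(stack.coord, dtype=float) / ANGSTROM_PER_NM
            if coords.ndim == 2:
                coords = coords[None]
            times = np.arange(coords.shape[0]) * dt_ps
            box = None
        if coords.shape[1] != topology.n_atoms:
            raise ValueError(
                f"{spath}: trajectory has {coords.shape[1]} atoms but topology has "
                f"{topology.n_atoms}")
        replicas.append(Replica(coords, times, box))
    return TrajectoryEnsemble(topology, replicas, discard_ps=discard_ns * 1000.0)


def ensemble_from_arrays(topology: Topology, coords_per_replica, times_per_replica=None,
                         box=None, discard_ns: float = 0.0) -> TrajectoryEnsemble:
    """Adapter entry point: build an ensemble from in-memory arrays.

    ``coords_per_replica``: list of (n_frames, n_atoms, 3) arrays in nm.
    Any external trajectory reader (MDAnalysis, mdtraj, ...) can plug in
    through this function without changes downstream.
    """
    reps = []
    for i, coords in enumerate(coords_per_replica):
        coords = np.asarray(coords, dtype=float)
        times = (np.asarray(times_per_replica[i], dtype=float)
                 if times_per_replica is not None else np.arange(coords.shape[0], dtype=float))
        reps.append(Replica(coords, times, None if box is None else np.asarray(box, float)))
    return TrajectoryEnsemble(topology, reps, discard_ps=discard_ns * 1000.0)


# ---------------------------------------------------------------------------
# Selection grammar
# ---------------------------------------------------------------------------
#
#   expr     := term ('or' term)*
#   term     := factor ('and' factor)*
#   factor   := 'not' factor | '(' expr ')' | primitive
#   primitive:= 'chain' ID | 'resid' RANGE(,RANGE)* | 'name' ID(,ID)*
#               | 'heavy' | 'group' ID | 'all'
#
# resid matches the author (PDB) numbering when present, else the internal
# 0-based index. Ranges are inclusive, e.g. "resid 3-5".

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(expression):
    tokens = []
    for m in _TOKEN_RE.finditer(expression):
        tokens.append((m.group(0), m.start()))
    return tokens


class _SelParser:
    def __init__(self, topology: Topology, expression: str):
        self.top = topology
        self.expr = expression
        self.tokens = _tokenize(expression)
        self.pos = 0

    def _peek(self):
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def _next(self):
        if self.pos >= len(self.tokens):
            raise SelectionError(f"unexpected end of selection {self.expr!r}")
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self._expr()
        if self.pos != len(self.tokens):
            tok, at = self.tokens[self.pos]
            raise SelectionError(f"unexpected token {tok!r} at position {at} in {self.expr!r}")
        return mask

    def _expr(self):
        mask = self._term()
        while self._peek() == "or":
            self._next()
            mask = mask | self._term()
        return mask

    def _term(self):
        mask = self._factor()
        while self._peek() == "and":
            self._next()
            mask = mask & self._factor()
        return mask

    def _factor(self):
        tok = self._peek()
        if tok == "not":
            self._next()
            return ~self._factor()
        if tok == "(":
            self._next()
            mask = self._expr()
            closing, at = self._next()
            if closing != ")":
                raise SelectionError(f"expected ')' at position {at} in {self.expr!r}")
            return mask
        return self._primitive()

    def _primitive(self):
        tok, at = self._next()
        top = self.top
        n = top.n_atoms
        if tok == "all":
            return np.ones(n, dtype=bool)
        if tok == "heavy":
            return top.heavy_mask.copy()
        if tok == "chain":
            val, _ = self._next()
            return np.array([a.chain_id == val for a in top.atoms])
        if tok == "name":
            val, _ = self._next()
            names = set(val.split(","))
            return np.array([a.name in names for a in top.atoms])
        if tok == "group":
            val, vat = self._next()
            if val not in top.groups:
                raise SelectionError(f"unknown group {val!r} at position {vat} in {self.expr!r}")
            mask = np.zeros(n, dtype=bool)
            mask[top.groups[val]] = True
            return mask
        if tok == "resid":
            val, vat = self._next()
            wanted = set()
            for part in val.split(","):
                if "-" in part[1:]:  # allow negative single ids
                    lo_s, hi_s = part.rsplit("-", 1) if not part.startswith("-") else (part, None)
                    try:
                        lo, hi = int(lo_s), int(hi_s)
                    except (TypeError, ValueError):
                        raise SelectionError(
                            f"bad resid range {part!r} at position {vat} in {self.expr!r}") from None
                    if hi < lo:
                        raise SelectionError(
                            f"reversed resid range {part!r} at position {vat} in {self.expr!r}")
                    wanted.update(range(lo, hi + 1))
                else:
                    try:
                        wanted.add(int(part))
                    except ValueError:
                        raise SelectionError(
                            f"bad resid {part!r} at position {vat} in {self.expr!r}") from None
            mask = np.zeros(n, dtype=bool)
            for a in top.atoms:
                res = top.residues[a.residue_index]
                seq = res.author_seq_id if res.author_seq_id is not None else res.index
                if seq in wanted:
                    mask[a.index] = True
            return mask
        raise SelectionError(f"unknown selection keyword {tok!r} at position {at} in {self.expr!r}")


def select(topology: Topology, expression: str) -> Selection:
    """Evaluate a selection expression to a deterministic ordered Selection.

    Grammar: ``chain X``, ``resid 3-7`` (author numbering, inclusive),
    ``name CA``, ``heavy``, ``group NAME``, ``all``, combined with
    ``and``/``or``/``not`` and parentheses. An empty result warns but is
    not an error.
    """
    mask = _SelParser(topology, expression).parse()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        warnings.warn(f"selection {expression!r} matched no atoms", stacklevel=2)
    return Selection(tuple(int(i) for i in idx))
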
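"""Topology/trajectory readers and COLVAR time-series I/O.

Internal unit conventions, applied at the I/O boundary only:

* coordinates in Å (GRO/XTC sources, natively nm, are converted on read),
* times in ps,
* energies in kcal/mol,
* angles in radians.

Periodic boxes are orthorhombic; all distance helpers apply the minimum-image
convention when a box is present. Atom and residue indices are 0-based
internally; 1-based serials appear only in emitted PDB/PLUMED text.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Topology",
    "Frame",
    "Trajectory",
    "TimeSeries",
    "FormatError",
    "TopologyError",
    "read_topology",
    "read_trajectory",
    "read_colvar",
    "write_colvar",
    "write_pdb",
    "write_xtc",
    "minimum_image",
    "pair_distance",
]

WATER_RESNAMES = frozenset({"HOH", "SOL", "WAT", "TIP3", "TIP3P", "SPC", "T3P"})

PROTEIN_RESNAMES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS HIE HID HIP ILE LEU LYS MET PHE PRO "
    "SER THR TRP TYR VAL NLE ACE NME NMA CYX ASH GLH LYN".split()
)

ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}


class FormatError(ValueError):
    """Raised when an input file is structurally malformed."""


class TopologyError(ValueError):
    """Raised when coordinates and topology disagree."""


def _element_from_name(name: str) -> str:
    """Infer the element from an atom name (PDB/GRO naming heuristics)."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    # Two-letter pattern only when unambiguous (e.g. CL, NA are not present
    # in peptide fixtures; treat the leading letter as the element).
    return stripped[0].upper()


@dataclass(frozen=True)
class Topology:
    """Static atom metadata for one molecular system.

    All arrays are indexed by 0-based atom index; residue indices are 0-based
    and contiguous. ``is_protein`` and ``is_water`` are disjoint by
    construction (water residue names never enter the protein set).
    """

    names: np.ndarray          # (n,) str
    elements: np.ndarray       # (n,) str
    resindices: np.ndarray     # (n,) int
    resnames: np.ndarray       # (n,) str
    chain_ids: np.ndarray      # (n,) str
    masses: np.ndarray         # (n,) float, amu
    is_protein: np.ndarray     # (n,) bool
    is_water: np.ndarray       # (n,) bool

    def __post_init__(self) -> None:
        n = len(self.names)
        for attr in ("elements", "resindices", "resnames", "chain_ids",
                     "masses", "is_protein", "is_water"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"topology field {attr!r} length mismatch")
        if np.any(self.is_protein & self.is_water):
            raise ValueError("atoms flagged both protein and water")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_residues(self) -> int:
        return int(self.resindices.max()) + 1 if self.n_atoms else 0

    @property
    def is_heavy(self) -> np.ndarray:
        return self.elements != "H"

    def residue_atoms(self, resindex: int) -> np.ndarray:
        """Atom indices belonging to one residue."""
        return np.flatnonzero(self.resindices == resindex)

    def select(self, names: set[str] | None = None, *, protein: bool | None = None,
               water: bool | None = None, heavy: bool | None = None) -> np.ndarray:
        mask = np.ones(self.n_atoms, dtype=bool)
        if names is not None:
            mask &= np.isin(self.names, list(names))
        if protein is not None:
            mask &= self.is_protein == protein
        if water is not None:
            mask &= self.is_water == water
        if heavy is not None:
            mask &= self.is_heavy == heavy
        return np.flatnonzero(mask)


@dataclass
class Frame:
    """One configuration: coordinates in Å plus an optional orthorhombic box."""

    coords: np.ndarray                 # (n, 3) float, Å
    box: np.ndarray | None = None      # (3,) float, Å, or None (vacuum)
    time: float = 0.0                  # ps

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be 3 strictly positive lengths")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class Trajectory:
    """Time-ordered frames over a fixed topology."""

    topology: Topology
    frames: list[Frame]

    def __post_init__(self) -> None:
        for fr in self.frames:
            if fr.n_atoms != self.topology.n_atoms:
                raise TopologyError(
                    f"frame has {fr.n_atoms} atoms, topology has "
                    f"{self.topology.n_atoms}")
        times = [fr.time for fr in self.frames]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    @property
    def stride(self) -> float:
        """Median inter-frame spacing in ps (0 for single-frame input)."""
        t = self.times
        return float(np.median(np.diff(t))) if len(t) > 1 else 0.0

    def coordinate_array(self) -> np.ndarray:
        """Stacked (n_frames, n_atoms, 3) coordinates for vectorised kernels."""
        return np.stack([fr.coords for fr in self.frames])


@dataclass
class TimeSeries:
    """Named columns of per-frame real values; first column is time in ps."""

    names: list[str]
    data: np.ndarray  # (n_rows, n_cols)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[1] != len(self.names):
            raise ValueError("column count does not match names")
        if "time" in self.names:
            t = self.column("time")
            if len(t) > 1 and np.any(np.diff(t) <= 0):
                raise ValueError("time column must be strictly increasing")

    def column(self, name: str) -> np.ndarray:
        try:
            return self.data[:, self.names.index(name)]
        except ValueError as exc:
            raise KeyError(f"no column {name!r}") from exc

    def __len__(self) -> int:
        return self.data.shape[0]


# ---------------------------------------------------------------------------
# periodic-distance helpers shared by every featurizer
# ---------------------------------------------------------------------------

def minimum_image(vectors: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image cell (orthorhombic)."""
    if box is None:
        return vectors
    return vectors - box * np.round(vectors / box)


def pair_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Minimum-image distance between broadcastable coordinate arrays (Å)."""
    d = minimum_image(np.asarray(a) - np.asarray(b), box)
    return np.linalg.norm(d, axis=-1)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _universe(path: str):
    import MDAnalysis as mda
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(path)


def read_topology(path: str | os.PathLike) -> Topology:
    """Read a PDB or GRO file into a :class:`Topology`.

    Protein/water flags come from residue names (waters: HOH/SOL/WAT/TIP3...);
    hydrogens are retained. Elements and masses are assigned from atom names.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    try:
        u = _universe(path)
    except Exception as exc:  # MDAnalysis raises assorted parse errors
        raise FormatError(f"could not parse topology {path!r}: {exc}") from exc
    if len(u.atoms) == 0:
        raise FormatError(f"{path!r} contains no atoms")

    names = np.array([a.name for a in u.atoms])
    elements = np.array([_element_from_name(n) for n in names])
    resnames = np.array([a.resname.strip().upper() for a in u.atoms])
    # renumber residues 0-based and contiguous in file order
    _, resindices = np.unique(u.atoms.resindices, return_inverse=True)
    try:
        chain_ids = np.array([str(a.segid).strip() or "A" for a in u.atoms])
    except Exception:
        chain_ids = np.full(len(names), "A")
    masses = np.array([ATOMIC_MASSES.get(e, 12.011) for e in elements])
    is_water = np.isin(resnames, list(WATER_RESNAMES))
    is_protein = np.isin(resnames, list(PROTEIN_RESNAMES)) & ~is_water
    return Topology(names=names, elements=elements, resindices=resindices,
                    resnames=resnames, chain_ids=chain_ids, masses=masses,
                    is_protein=is_protein, is_water=is_water)


def _box_from_dimensions(dims) -> np.ndarray | None:
    if dims is None:
        return None
    dims = np.asarray(dims, dtype=float)
    if np.all(dims[:3] <= 0):
        return None
    if not np.allclose(dims[3:6], 90.0):
        raise FormatError("only orthorhombic boxes are supported")
    return dims[:3].copy()


def read_trajectory(path: str | os.PathLike, top: Topology) -> Trajectory:
    """Read an XTC/DCD/multi-frame-PDB/GRO trajectory against ``top``.

    Coordinates are returned in Å regardless of the source format's native
    unit (MDAnalysis converts nm-based formats on read).
    """
    import MDAnalysis as mda

    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    ext = os.path.splitext(path)[1].lower()
    frames: list[Frame] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if ext == ".xtc":
            reader = mda.coordinates.XTC.XTCReader(path)
        elif ext == ".dcd":
            reader = mda.coordinates.DCD.DCDReader(path)
        else:  # multi-frame PDB / GRO
            reader = _universe(path).trajectory
        if reader.n_atoms != top.n_atoms:
            raise TopologyError(
                f"trajectory has {reader.n_atoms} atoms, topology has "
                f"{top.n_atoms}")
        for ts in reader:
            frames.append(Frame(coords=np.array(ts.positions, dtype=float),
                                box=_box_from_dimensions(ts.dimensions),
                                time=float(ts.time)))
    # Some writers stamp every frame with time 0; fall back to frame index.
    times = [fr.time for fr in frames]
    if len(frames) > 1 and any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
        for i, fr in enumerate(frames):
            fr.time = float(i)
    return Trajectory(topology=top, frames=frames)


# ---------------------------------------------------------------------------
# COLVAR (PLUMED time-series dialect)
# ---------------------------------------------------------------------------

def read_colvar(path: str | os.PathLike | io.TextIOBase) -> TimeSeries:
    """Read a PLUMED COLVAR file (``#! FIELDS time ...`` header)."""
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#! FIELDS"):
        raise FormatError("COLVAR file must start with a '#! FIELDS' header")
    names = lines[0].split()[2:]
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        values = line.split()
        if len(values) != len(names):
            raise FormatError(
                f"line {lineno}: expected {len(names)} columns, got {len(values)}")
        rows.append([float(v) for v in values])
    return TimeSeries(names=names, data=np.array(rows, dtype=float).reshape(-1, len(names)))


def write_colvar(ts: TimeSeries, path: str | os.PathLike | io.TextIOBase) -> None:
    """Write a :class:`TimeSeries` as a PLUMED COLVAR file (6+ sig. digits)."""
    own = not hasattr(path, "write")
    fh = open(path, "w") if own else path
    try:
        fh.write("#! FIELDS " + " ".join(ts.names) + "\n")
        for row in ts.data:
            fh.write(" ".join(f"{v:.9g}" for v in row) + "\n")
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# writers used by the fixture generator (text PDB, binary XTC)
# ---------------------------------------------------------------------------

def write_pdb(top: Topology, frames: Frame | list[Frame],
              path: str | os.PathLike) -> None:
    """Write one or more frames as a (multi-)MODEL PDB with 1-based serials."""
    if isinstance(frames, Frame):
        frames = [frames]
    multi = len(frames) > 1
    with open(path, "w") as fh:
        for imodel, fr in enumerate(frames, start=1):
            if fr.box is not None:
                fh.write(f"CRYST1{fr.box[0]:9.3f}{fr.box[1]:9.3f}"
                         f"{fr.box[2]:9.3f}  90.00  90.00  90.00 P 1           1\n")
            if multi:
                fh.write(f"MODEL     {imodel:4d}\n")
            for i in range(top.n_atoms):
                name = top.names[i]
                # PDB alignment rule: 1-3 char names start in column 14
                pname = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
                x, y, z = fr.coords[i]
                fh.write(
                    f"ATOM  {i + 1:5d} {pname}{'':1s}{top.resnames[i]:<4s}"
                    f"{top.chain_ids[i][:1] or 'A'}{top.resindices[i] + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                    f"{top.elements[i]:>2s}\n")
            fh.write("ENDMDL\n" if multi else "END\n")


def write_xtc(traj: Trajectory, path: str | os.PathLike) -> None:
    """Write a trajectory as XTC (MDAnalysis converts Å → nm on write)."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.coordinates.XTC.XTCWriter(os.fspath(path),
                                           traj.topology.n_atoms) as w:
            u = mda.Universe.empty(traj.topology.n_atoms, trajectory=True)
            for i, fr in enumerate(traj.frames):
                u.atoms.positions = fr.coords
                if fr.box is not None:
                    u.dimensions = [*fr.box, 90.0, 90.0, 90.0]
                u.trajectory.ts.time = fr.time
                u.trajectory.ts.frame = i
                w.write(u.atoms)
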
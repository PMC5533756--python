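"""Molecular system model, trajectory I/O, atom selection and periodic-box
utilities.

A :class:`SystemModel` is an immutable atom table (pandas DataFrame) carrying
the per-atom nonbonded parameters (mass, charge, LJ ε and r_min/2) and a
disjoint group label per atom: the two protein protomers, the three lipid
species (DOPC/DOPE/DOPS), water and ions.  Coordinates live in
:class:`Frame`/:class:`Trajectory` objects, read and written in a simple
columnar text format; structures are read from PDB via MDAnalysis with
nonbonded parameters supplied by a sidecar TSV table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("protein_A", "protein_B", "DOPC", "DOPE", "DOPS", "water", "ion")
PROTEIN_GROUPS = ("protein_A", "protein_B")
LIPID_GROUPS = ("DOPC", "DOPE", "DOPS")

WATER_RESNAMES = {"TIP3", "HOH", "SOL", "WAT", "TIP"}
ION_RESNAMES = {"SOD", "CLA", "POT", "NA", "CL", "K", "MG", "CAL"}

# residue-level formal charges at neutral pH (His neutral by default)
FORMAL_CHARGES = {"LYS": +1, "ARG": +1, "ASP": -1, "GLU": -1, "HIS": 0}

_TWO_LETTER_ELEMENTS = {"CL", "NA", "MG", "ZN", "FE", "BR", "CA"}
_ION_ELEMENTS = {"SOD": "Na", "CLA": "Cl", "POT": "K", "CAL": "Ca"}


class SystemError_(ValueError):
    """Raised for unresolvable or inconsistent system definitions."""


class TrajectoryFormatError(ValueError):
    """Raised on malformed native-format trajectory files."""


def element_from_name(name: str, residue_name: str = "") -> str:
    """Infer the chemical element from a PDB atom name.

    Ion residues use an explicit lookup; otherwise digits are stripped and
    the leading one- or two-letter symbol taken.
    """
    if residue_name in _ION_ELEMENTS:
        return _ION_ELEMENTS[residue_name]
    stripped = "".join(c for c in name if c.isalpha()).upper()
    if not stripped:
        raise SystemError_(f"cannot infer element from atom name {name!r}")
    if stripped[:2] in _TWO_LETTER_ELEMENTS and residue_name in ION_RESNAMES:
        return stripped[:2].capitalize()
    return stripped[0]


def assign_group(residue_name: str, segment: str,
                 protein_segments: dict[str, str] | None = None) -> str:
    """Map (residue name, segment id) to one of the seven atom groups."""
    if protein_segments is None:
        protein_segments = {"A": "protein_A", "B": "protein_B"}
    if residue_name in ("DOPC", "DOPE", "DOPS"):
        return residue_name
    if residue_name in WATER_RESNAMES:
        return "water"
    if residue_name in ION_RESNAMES:
        return "ion"
    seg = segment.strip()
    if seg in protein_segments:
        return protein_segments[seg]
    raise SystemError_(
        f"cannot assign group for residue {residue_name!r} in segment {seg!r}; "
        f"known protein segments: {sorted(protein_segments)}")


@dataclass(frozen=True)
class SelectionSpec:
    """Declarative atom selection over the atom table.

    All criteria are conjunctive; ``None`` means "no constraint".  Empty
    selections are legal and yield an all-False mask.
    """

    groups: tuple[str, ...] | None = None
    residue_ids: tuple[int, int] | frozenset[int] | None = None
    names: frozenset[str] | None = None
    heavy_only: bool = False

    def mask(self, system: "SystemModel") -> np.ndarray:
        atoms = system.atoms
        m = np.ones(len(atoms), dtype=bool)
        if self.groups is not None:
            m &= atoms["group"].isin(self.groups).to_numpy()
        if self.residue_ids is not None:
            rid = atoms["residue_id"].to_numpy()
            if isinstance(self.residue_ids, tuple):
                lo, hi = self.residue_ids
                m &= (rid >= lo) & (rid <= hi)
            else:
                m &= atoms["residue_id"].isin(self.residue_ids).to_numpy()
        if self.names is not None:
            m &= atoms["name"].isin(self.names).to_numpy()
        if self.heavy_only:
            m &= system.heavy_mask
        return m

    def indices(self, system: "SystemModel") -> np.ndarray:
        return np.flatnonzero(self.mask(system))


def sel(groups: Iterable[str] | str | None = None, *,
        residue_ids=None, names: Iterable[str] | None = None,
        heavy_only: bool = False) -> SelectionSpec:
    """Convenience constructor for :class:`SelectionSpec`."""
    if isinstance(groups, str):
        groups = (groups,)
    return SelectionSpec(
        groups=tuple(groups) if groups is not None else None,
        residue_ids=(tuple(residue_ids) if isinstance(residue_ids, (tuple, list))
                     and len(residue_ids) == 2 and not isinstance(residue_ids[0], (list, tuple))
                     else (frozenset(residue_ids) if residue_ids is not None else None)),
        names=frozenset(names) if names is not None else None,
        heavy_only=heavy_only)


PROTEIN_SEL = SelectionSpec(groups=PROTEIN_GROUPS)
PROTEIN_HEAVY = SelectionSpec(groups=PROTEIN_GROUPS, heavy_only=True)
LIPID_SEL = SelectionSpec(groups=LIPID_GROUPS)
LIPID_HEAVY = SelectionSpec(groups=LIPID_GROUPS, heavy_only=True)


class SystemModel:
    """Atom table with nonbonded parameters and disjoint group labels."""

    REQUIRED_COLUMNS = ("atom_id", "name", "element", "residue_name",
                        "residue_id", "segment", "mass", "charge",
                        "lj_epsilon", "lj_rmin_half", "group")

    def __init__(self, atoms: pd.DataFrame):
        missing = [c for c in self.REQUIRED_COLUMNS if c not in atoms.columns]
        if missing:
            raise SystemError_(f"atom table missing columns {missing}")
        atoms = atoms.reset_index(drop=True)
        if atoms["atom_id"].duplicated().any():
            dup = atoms.loc[atoms["atom_id"].duplicated(), "atom_id"].tolist()
            raise SystemError_(f"duplicate atom_id values: {dup[:10]}")
        if (atoms["mass"] <= 0).any():
            raise SystemError_("all atom masses must be positive")
        if (atoms["lj_epsilon"] < 0).any() or (atoms["lj_rmin_half"] < 0).any():
            raise SystemError_("LJ parameters must be non-negative")
        bad = set(atoms["group"]) - set(GROUPS)
        if bad:
            raise SystemError_(f"unknown groups {sorted(bad)}")
        self.atoms = atoms
        self.masses = atoms["mass"].to_numpy(float)
        self.charges = atoms["charge"].to_numpy(float)
        self.lj_epsilon = atoms["lj_epsilon"].to_numpy(float)
        self.lj_rmin_half = atoms["lj_rmin_half"].to_numpy(float)
        self.heavy_mask = (atoms["element"].str.upper() != "H").to_numpy()
        self.groups = atoms["group"].to_numpy()

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def group_counts(self) -> dict[str, int]:
        return self.atoms.groupby("group", observed=True).size().to_dict()

    def residue_counts(self, groups: Iterable[str] | None = None) -> dict[str, int]:
        """Number of residues per residue type, optionally restricted to groups."""
        a = self.atoms
        if groups is not None:
            a = a[a["group"].isin(tuple(groups))]
        residues = a.drop_duplicates(["segment", "residue_id"])
        return residues.groupby("residue_name").size().to_dict()

    def select(self, spec: SelectionSpec) -> np.ndarray:
        return spec.indices(self)


def net_formal_charge(residue_counts: dict[str, int]) -> int:
    """Net formal charge (units of e) from a residue-type composition.

    Lys/Arg carry +1, Asp/Glu −1, His and all others 0 (neutral pH,
    termini not counted).
    """
    return sum(FORMAL_CHARGES.get(res.upper(), 0) * int(n)
               for res, n in residue_counts.items())


@dataclass
class Frame:
    """One trajectory frame: N×3 coordinates (Å), orthorhombic box, time (ns)."""

    coordinates: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be N×3")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be 3 positive lengths")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


class Trajectory:
    """Time-ordered frames over a fixed :class:`SystemModel`."""

    def __init__(self, system: SystemModel, frames: Sequence[Frame]):
        frames = list(frames)
        if not frames:
            raise ValueError("trajectory must contain at least one frame")
        n = system.n_atoms
        for i, f in enumerate(frames):
            if f.n_atoms != n:
                raise ValueError(
                    f"frame {i} has {f.n_atoms} atoms, system has {n}")
        times = np.array([f.time for f in frames])
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        self.system = system
        self.frames = frames

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i) -> Frame:
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


# ----------------------------------------------------------------------
# periodic boundary utilities
# ----------------------------------------------------------------------

def minimum_image_displacement(p: np.ndarray, q: np.ndarray,
                               box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement q − p in an orthorhombic box.

    Each component lies in (−L/2, L/2].  Broadcasts over leading axes.
    """
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box lengths must be positive")
    d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
    d = d - box * np.round(d / box)
    # round() ties-to-even can land on −L/2; fold to +L/2
    half = box / 2.0
    d = np.where(np.isclose(d, -half), half, d)
    return d


def minimum_image_distance(p, q, box) -> np.ndarray:
    d = minimum_image_displacement(p, q, box)
    return np.linalg.norm(d, axis=-1)


def wrap_coordinates(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into [0, L) per axis."""
    box = np.asarray(box, dtype=float)
    return np.mod(coords, box)


# ----------------------------------------------------------------------
# structure + parameter-table loading
# ----------------------------------------------------------------------

def load_parameter_table(path: str | Path) -> pd.DataFrame:
    """Read a sidecar nonbonded parameter table.

    TSV columns: residue_name, atom_name, mass, charge, epsilon, rmin_half.
    """
    table = pd.read_csv(path, sep="\t", comment="#")
    required = {"residue_name", "atom_name", "mass", "charge",
                "epsilon", "rmin_half"}
    missing = required - set(table.columns)
    if missing:
        raise SystemError_(
            f"parameter table {path} missing columns {sorted(missing)}")
    return table


def load_system(structure_path: str | Path,
                parameter_table_path: str | Path,
                protein_segments: dict[str, str] | None = None) -> SystemModel:
    """Build a :class:`SystemModel` from a PDB file and a parameter table.

    Every atom must resolve to a (residue_name, atom_name) row of the table;
    unresolved atoms are a hard error listing the offending pairs.
    """
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(structure_path))
    except Exception as exc:  # noqa: BLE001 - wrap parser failures
        raise SystemError_(
            f"failed to parse PDB {structure_path}: {exc}") from exc

    names = [a.name for a in u.atoms]
    resnames = [a.resname for a in u.atoms]
    resids = [int(a.resid) for a in u.atoms]
    segids = [getattr(a, "segid", "") or getattr(a, "chainID", "")
              for a in u.atoms]

    table = load_parameter_table(parameter_table_path)
    params = {(r, a): (m, q, e, rm) for r, a, m, q, e, rm in zip(
        table["residue_name"], table["atom_name"], table["mass"],
        table["charge"], table["epsilon"], table["rmin_half"])}

    rows, unresolved = [], []
    for i, (nm, rn, rid, seg) in enumerate(zip(names, resnames, resids, segids)):
        key = (rn, nm)
        if key not in params:
            unresolved.append(key)
            continue
        m, q, e, rm = params[key]
        rows.append((i + 1, nm, element_from_name(nm, rn), rn, rid, seg,
                     float(m), float(q), float(e), float(rm),
                     assign_group(rn, seg, protein_segments)))
    if unresolved:
        uniq = sorted(set(unresolved))
        raise SystemError_(
            f"{len(unresolved)} atoms unresolved in parameter table; "
            f"(residue, atom) pairs: {uniq[:20]}")

    atoms = pd.DataFrame(rows, columns=SystemModel.REQUIRED_COLUMNS)
    logger.info("loaded system: %d atoms, groups %s", len(atoms),
                atoms.groupby("group").size().to_dict())
    return SystemModel(atoms)


def pdb_frame(structure_path: str | Path,
              box: Sequence[float] | None = None, time: float = 0.0) -> Frame:
    """Read coordinates (and CRYST1 box if present) from a PDB as a Frame."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(structure_path))
    if box is None:
        dims = u.dimensions
        if dims is None or not np.all(dims[:3] > 0):
            raise SystemError_(f"PDB {structure_path} has no box; pass box=")
        box = dims[:3]
    return Frame(u.atoms.positions.astype(float), np.asarray(box, float), time)


def write_pdb(system: SystemModel, frame: Frame, path: str | Path) -> None:
    """Write a SystemModel + Frame as a PDB with CRYST1 record.

    Segments are written as single-character chain identifiers, so segment
    labels should be one character for a lossless round trip.
    """
    import MDAnalysis as mda

    a = system.atoms
    n = system.n_atoms
    # consecutive (segment, residue_id) runs define residues
    res_key = list(zip(a["segment"], a["residue_id"]))
    atom_resindex = np.zeros(n, dtype=int)
    res_rows = [0]
    for i in range(1, n):
        if res_key[i] != res_key[i - 1]:
            res_rows.append(i)
        atom_resindex[i] = len(res_rows) - 1
    n_res = len(res_rows)
    res_seg = [a["segment"].iloc[i] for i in res_rows]
    seg_ids = sorted(set(res_seg))
    seg_index = {s: k for k, s in enumerate(seg_ids)}
    residue_segindex = np.array([seg_index[s] for s in res_seg])

    u = mda.Universe.empty(n, n_residues=n_res, atom_resindex=atom_resindex,
                           n_segments=len(seg_ids),
                           residue_segindex=residue_segindex,
                           trajectory=True)
    u.add_TopologyAttr("name", a["name"].tolist())
    u.add_TopologyAttr("resname", [a["residue_name"].iloc[i] for i in res_rows])
    u.add_TopologyAttr("resid", [int(a["residue_id"].iloc[i]) for i in res_rows])
    u.add_TopologyAttr("segid", seg_ids)
    u.add_TopologyAttr("chainID", a["segment"].astype(str).str[:1].tolist())
    u.add_TopologyAttr("elements", a["element"].tolist())
    u.atoms.positions = frame.coordinates
    u.dimensions = [*frame.box, 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=n) as w:
            w.write(u.atoms)


# ----------------------------------------------------------------------
# native trajectory format
# ----------------------------------------------------------------------
# Per frame:
#   #atoms N box Lx Ly Lz time t_ns
#   atom_id x y z          (N lines)

_COORD_FMT = "{:d} {:.6f} {:.6f} {:.6f}\n"
_HEADER_FMT = "#atoms {:d} box {:.6f} {:.6f} {:.6f} time {:.6f}\n"


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write the native columnar frame format (bit-stable round trip)."""
    ids = trajectory.system.atoms["atom_id"].to_numpy()
    with open(path, "w") as fh:
        for frame in trajectory:
            fh.write(_HEADER_FMT.format(frame.n_atoms, *frame.box, frame.time))
            for aid, (x, y, z) in zip(ids, frame.coordinates):
                fh.write(_COORD_FMT.format(int(aid), x, y, z))


def load_trajectory(path: str | Path, system: SystemModel) -> Trajectory:
    """Read the native frame format; errors carry 1-based line numbers."""
    frames: list[Frame] = []
    id_order = system.atoms["atom_id"].to_numpy()
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        parts = line.split()
        if parts[0] != "#atoms" or len(parts) != 8 or parts[2] != "box" \
                or parts[6] != "time":
            raise TrajectoryFormatError(
                f"{path}:{i + 1}: expected frame header, got {line!r}")
        n = int(parts[1])
        if n != system.n_atoms:
            raise TrajectoryFormatError(
                f"{path}:{i + 1}: frame has {n} atoms, system has "
                f"{system.n_atoms}")
        box = np.array(parts[3:6], dtype=float)
        t = float(parts[7])
        if i + 1 + n > len(lines):
            raise TrajectoryFormatError(
                f"{path}:{i + 1}: frame declares {n} atoms but file ends at "
                f"line {len(lines)}")
        coords = np.empty((n, 3))
        for j in range(n):
            row = lines[i + 1 + j].split()
            if len(row) != 4:
                raise TrajectoryFormatError(
                    f"{path}:{i + 2 + j}: expected 'atom_id x y z'")
            if int(row[0]) != int(id_order[j]):
                raise TrajectoryFormatError(
                    f"{path}:{i + 2 + j}: atom_id {row[0]} out of order "
                    f"(expected {id_order[j]})")
            coords[j] = [float(row[1]), float(row[2]), float(row[3])]
        frames.append(Frame(coords, box, t))
        i += 1 + n
    if not frames:
        raise TrajectoryFormatError(f"{path}: no frames found")
    return Trajectory(system, frames)
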
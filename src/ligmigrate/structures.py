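"""Structure container, PDB I/O, protonation assignment and system assembly.

Coordinates are in Å, masses in atomic mass units, charges in elementary
charge units.  A :class:`Structure` stores its atoms as parallel numpy
arrays for fast energy evaluation; :class:`AtomRecord` is the per-atom
record view used for construction and round-tripping.

PDB files carry no partial-charge column with useful precision, so charges
travel in a sidecar CSV (``<file>.charges.csv``, columns ``serial,charge``)
which :func:`read_pdb` picks up automatically when present.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.info as struc_info
import biotite.structure.io.pdb as pdbio
from scipy.spatial.transform import Rotation

from .errors import DomainError, FormatError

__all__ = [
    "AtomRecord",
    "Structure",
    "ProtonationState",
    "PROTONATION_CHARGES",
    "CompetitiveSystem",
    "read_pdb",
    "write_pdb",
    "center_of_mass",
    "assign_protonation",
    "assemble_system",
    "superpose",
]

# Fallback masses for pseudo-atom elements biotite does not know.
_EXTRA_MASSES = {"X": 72.0}


def _element_mass(element: str) -> float:
    element = element.strip()
    if element in _EXTRA_MASSES:
        return _EXTRA_MASSES[element]
    try:
        m = struc_info.mass(element)
    except KeyError:
        m = None
    if m is None or m <= 0:
        raise DomainError(f"no mass known for element {element!r}")
    return float(m)


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, position, mass and partial charge."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: np.ndarray
    mass: float
    charge: float = 0.0

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise DomainError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if self.mass <= 0:
            raise DomainError(f"atom {self.serial}: mass must be positive")
        if not self.element:
            raise DomainError(f"atom {self.serial}: element must be nonempty")
        if self.serial <= 0:
            raise DomainError("atom serial must be a positive integer")


class Structure:
    """Ordered collection of atoms for one receptor or ligand.

    Atom fields are stored as parallel arrays (``coords`` is (N, 3));
    ``atoms`` materialises :class:`AtomRecord` views in file order.
    """

    def __init__(self, atoms: Iterable[AtomRecord], label: str = ""):
        atoms = list(atoms)
        if not atoms:
            raise DomainError("a Structure needs at least one atom")
        self.label = label
        self.serials = np.array([a.serial for a in atoms], dtype=int)
        self.names = np.array([a.name for a in atoms], dtype=object)
        self.elements = np.array([a.element for a in atoms], dtype=object)
        self.residue_names = np.array([a.residue_name for a in atoms], dtype=object)
        self.residue_seqs = np.array([a.residue_seq for a in atoms], dtype=int)
        self.chain_ids = np.array([a.chain_id for a in atoms], dtype=object)
        self.coords = np.array([a.position for a in atoms], dtype=float)
        self.masses = np.array([a.mass for a in atoms], dtype=float)
        self.charges = np.array([a.charge for a in atoms], dtype=float)

    def __len__(self) -> int:
        return len(self.serials)

    @property
    def atoms(self) -> list[AtomRecord]:
        return [
            AtomRecord(
                serial=int(self.serials[i]),
                name=str(self.names[i]),
                element=str(self.elements[i]),
                residue_name=str(self.residue_names[i]),
                residue_seq=int(self.residue_seqs[i]),
                chain_id=str(self.chain_ids[i]),
                position=self.coords[i].copy(),
                mass=float(self.masses[i]),
                charge=float(self.charges[i]),
            )
            for i in range(len(self))
        ]

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    def copy(self) -> "Structure":
        new = Structure.__new__(Structure)
        new.label = self.label
        for attr in (
            "serials",
            "names",
            "elements",
            "residue_names",
            "residue_seqs",
            "chain_ids",
            "coords",
            "masses",
            "charges",
        ):
            setattr(new, attr, getattr(self, attr).copy())
        return new

    def translated(self, shift: np.ndarray) -> "Structure":
        new = self.copy()
        new.coords = new.coords + np.asarray(shift, dtype=float)
        return new

    def heavy_mask(self) -> np.ndarray:
        return np.array([e.strip().upper() != "H" for e in self.elements], dtype=bool)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Structure {self.label!r}: {len(self)} atoms, net charge {self.net_charge:+.2f}>"


# --- protonation -----------------------------------------------------------

#: Net ligand charge per protonation state.  Protonation is cumulative:
#: ``imidazole_protonated`` means the amine terminus is protonated too,
#: hence net +2.  The ligand must designate its amine-terminus site by an
#: atom name starting with "NT" and its imidazole nitrogen by "NI".
PROTONATION_CHARGES = {
    "deprotonated": 0.0,
    "amine_protonated": 1.0,
    "imidazole_protonated": 2.0,
}


@dataclass(frozen=True)
class ProtonationState:
    """Ligand hydrogen-ion occupancy, mapped to a fixed net charge."""

    token: str

    def __post_init__(self):
        if self.token not in PROTONATION_CHARGES:
            raise DomainError(
                f"unknown protonation state {self.token!r}; "
                f"expected one of {sorted(PROTONATION_CHARGES)}"
            )

    @property
    def net_ligand_charge(self) -> float:
        return PROTONATION_CHARGES[self.token]


def assign_protonation(ligand: Structure, state: ProtonationState | str) -> Structure:
    """Return a copy of *ligand* with charges set for *state*.

    Geometry is untouched.  The amine-terminus bead (name ``NT*``) takes +1
    for the amine-protonated state; the imidazole nitrogen (name ``NI*``)
    takes an additional +1 for the imidazole-protonated state (cumulative,
    net +2).  Deprotonated zeroes both sites.
    """
    if isinstance(state, str):
        state = ProtonationState(state)
    names = [str(n).upper() for n in ligand.names]
    amine = [i for i, n in enumerate(names) if n.startswith("NT")]
    imid = [i for i, n in enumerate(names) if n.startswith("NI")]
    if not amine:
        raise DomainError("ligand has no designated amine-terminus site (atom name NT*)")
    if not imid:
        raise DomainError("ligand has no designated imidazole-nitrogen site (atom name NI*)")
    new = ligand.copy()
    new.charges = np.zeros_like(new.charges)
    if state.token in ("amine_protonated", "imidazole_protonated"):
        new.charges[amine[0]] += 1.0
    if state.token == "imidazole_protonated":
        new.charges[imid[0]] += 1.0
    assert abs(new.net_charge - state.net_ligand_charge) < 1e-12
    return new


# --- geometry --------------------------------------------------------------


def center_of_mass(structure: Structure, heavy_only: bool = True) -> np.ndarray:
    """Mass-weighted mean position in Å.

    Hydrogens are excluded by default: the distances this package compares
    against were produced by a visualization-tool workflow whose weighting
    convention is unstated, and heavy-atom weighting is the conservative
    reading (a ±0.5 Å tolerance is applied wherever such distances are
    compared).
    """
    mask = structure.heavy_mask() if heavy_only else np.ones(len(structure), bool)
    if not mask.any():
        raise DomainError("no atoms left after heavy-atom filtering")
    m = structure.masses[mask]
    return (structure.coords[mask] * m[:, None]).sum(axis=0) / m.sum()


def superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of *mobile* onto *reference*.

    Points are paired by index.  Returns ``(rotation, translation, rmsd)``
    such that ``mobile @ rotation.T + translation`` best fits *reference*;
    the rotation is proper (no reflection) and the RMSD is post-fit.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise DomainError("superpose needs two equally-shaped (N, 3) coordinate sets")
    n = mobile.shape[0]
    if n < 3:
        raise DomainError("superpose needs at least 3 paired points")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    rot, rssd = Rotation.align_vectors(reference - rc, mobile - mc)
    R = rot.as_matrix()
    t = rc - mc @ R.T
    rmsd = float(rssd / np.sqrt(n))
    return R, t, rmsd


# --- competitive system ----------------------------------------------------


@dataclass
class LigandPose:
    """A ligand structure with its current coordinates in the assembly frame."""

    structure: Structure
    coords: np.ndarray
    bound: bool = False

    def com(self) -> np.ndarray:
        mask = self.structure.heavy_mask()
        m = self.structure.masses[mask]
        return (self.coords[mask] * m[:, None]).sum(axis=0) / m.sum()


@dataclass
class CompetitiveSystem:
    """Two receptors plus ligand poses with the assembly geometry metadata.

    ``receptor_b`` may be ``None`` for individual-binding runs.
    """

    receptor_a: Structure
    receptor_b: Structure | None
    ligands: list[LigandPose]
    separation: float = 67.0
    ligand_offset: float = 42.0
    metadata: dict = field(default_factory=dict)

    def com_a(self) -> np.ndarray:
        return center_of_mass(self.receptor_a)

    def com_b(self) -> np.ndarray:
        if self.receptor_b is None:
            raise DomainError("system has no receptor_b")
        return center_of_mass(self.receptor_b)


def assemble_system(
    receptor_a: Structure,
    receptor_b: Structure,
    ligands: Sequence[Structure],
    separation: float = 67.0,
    ligand_offset: float = 42.0,
    seed: int = 0,
) -> CompetitiveSystem:
    """Build the two-receptor competitive assembly.

    ``receptor_b`` is rigidly translated so the two receptor COMs are
    *separation* Å apart along +x.  Each ligand COM goes on the
    perpendicular-bisector plane of the COM-COM segment, at *ligand_offset*
    Å from both COMs; the in-plane placement angle is drawn from *seed*
    (the protocol specifies only the distances, not the direction).
    """
    if separation <= 0:
        raise DomainError("separation must be positive")
    if ligand_offset < separation / 2:
        raise DomainError(
            f"ligand_offset ({ligand_offset} Å) must be at least half the "
            f"separation ({separation / 2} Å) for equidistant placement"
        )
    com_a = center_of_mass(receptor_a)
    com_b_now = center_of_mass(receptor_b)
    target_b = com_a + np.array([separation, 0.0, 0.0])
    receptor_b = receptor_b.translated(target_b - com_b_now)

    midpoint = com_a + np.array([separation / 2, 0.0, 0.0])
    rho = np.sqrt(max(ligand_offset**2 - (separation / 2) ** 2, 0.0))
    rng = np.random.default_rng(seed)
    poses = []
    for lig in ligands:
        theta = rng.uniform(0.0, 2 * np.pi)
        target = midpoint + rho * np.array([0.0, np.cos(theta), np.sin(theta)])
        lig_com = center_of_mass(lig)
        poses.append(LigandPose(structure=lig, coords=lig.coords + (target - lig_com)))
    return CompetitiveSystem(
        receptor_a=receptor_a,
        receptor_b=receptor_b,
        ligands=poses,
        separation=separation,
        ligand_offset=ligand_offset,
        metadata={"seed": seed},
    )


# --- PDB I/O ---------------------------------------------------------------


def _charges_sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".charges.csv")


def _structure_to_atomarray(structure: Structure, coords: np.ndarray) -> struc.AtomArray:
    n = len(structure)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = np.array([str(c)[:1] or "A" for c in structure.chain_ids])
    arr.res_id = structure.residue_seqs.astype(int)
    arr.res_name = np.array([str(r)[:3] for r in structure.residue_names])
    arr.atom_name = np.array([str(a)[:4] for a in structure.names])
    arr.element = np.array([str(e) for e in structure.elements])
    arr.hetero = np.array([str(r) not in _STANDARD_RES for r in structure.residue_names])
    return arr


_STANDARD_RES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def write_pdb(
    structure: Structure,
    path: str | Path,
    models: Sequence[np.ndarray] | None = None,
    write_charges: bool = True,
) -> None:
    """Write *structure* as a fixed-column PDB file.

    *models*, if given, is a sequence of (N, 3) coordinate sets written as
    MODEL/ENDMDL blocks (trajectory output); otherwise the structure's own
    coordinates are written as a single model.  Nonzero partial charges go
    to a ``<file>.charges.csv`` sidecar since the PDB format cannot hold
    them at useful precision.
    """
    path = Path(path)
    if models is None:
        model_coords = [structure.coords]
    else:
        model_coords = [np.asarray(m, dtype=float) for m in models]
        if not model_coords:
            raise DomainError("models must contain at least one coordinate set")
    pdb_file = pdbio.PDBFile()
    if len(model_coords) == 1:
        pdb_file.set_structure(_structure_to_atomarray(structure, model_coords[0]))
    else:
        stack = struc.stack(
            [_structure_to_atomarray(structure, c) for c in model_coords]
        )
        pdb_file.set_structure(stack)
    pdb_file.write(str(path))
    if write_charges and np.any(structure.charges != 0):
        with open(_charges_sidecar(path), "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["serial", "charge"])
            for s, q in zip(structure.serials, structure.charges):
                w.writerow([int(s), repr(float(q))])


def read_pdb(path: str | Path, label: str | None = None) -> Structure:
    """Read the first model of a PDB file into a :class:`Structure`.

    Masses come from the element; unknown elements are inferred from the
    atom name per PDB v3 columns (biotite's behaviour).  A
    ``<file>.charges.csv`` sidecar, when present, supplies partial charges
    keyed by atom serial.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such PDB file: {path}")
    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        arr = pdb_file.get_structure(model=1)
    except Exception as exc:
        _raise_naming_bad_line(path, exc)
        raise  # pragma: no cover
    # altloc handling: biotite's default filters to one location already.
    if arr.array_length() == 0:
        raise FormatError(f"{path}: no parsable ATOM/HETATM records")
    charges = np.zeros(arr.array_length())
    sidecar = _charges_sidecar(path)
    serial_to_index = {}
    atoms = []
    for i in range(arr.array_length()):
        element = str(arr.element[i]) or "C"
        atoms.append(
            AtomRecord(
                serial=i + 1,
                name=str(arr.atom_name[i]),
                element=element,
                residue_name=str(arr.res_name[i]),
                residue_seq=int(arr.res_id[i]),
                chain_id=str(arr.chain_id[i]) or "A",
                position=np.asarray(arr.coord[i], dtype=float),
                mass=_element_mass(element),
                charge=0.0,
            )
        )
        serial_to_index[i + 1] = i
    st = Structure(atoms, label=label if label is not None else path.stem)
    if sidecar.exists():
        with open(sidecar, newline="") as fh:
            for row in csv.DictReader(fh):
                idx = serial_to_index.get(int(row["serial"]))
                if idx is not None:
                    charges[idx] = float(row["charge"])
        st.charges = charges
    return st


def _raise_naming_bad_line(path: Path, exc: Exception) -> None:
    """Turn a parser failure into a FormatError naming the offending line."""
    try:
        lines = path.read_text().splitlines()
    except OSError:
        raise FormatError(f"{path}: unreadable ({exc})") from exc
    for lineno, line in enumerate(lines, start=1):
        if line.startswith(("ATOM", "HETATM")):
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fieldtxt = line[lo:hi].strip()
                try:
                    float(fieldtxt) if fieldtxt else None
                except ValueError:
                    raise FormatError(
                        f"{path}: malformed coordinate field {fieldtxt!r} on line {lineno}"
                    ) from exc
    raise FormatError(f"{path}: could not parse PDB ({exc})") from exc
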
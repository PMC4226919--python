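"""Simplified nonbonded energy model and the receptor-ligand decomposition.

The model is a Lennard-Jones 12-6 term with Lorentz-Berthelot combining
rules plus a Coulomb term screened by a distance-dependent dielectric
eps(r) = 4r (a common implicit-solvent proxy), truncated at a cutoff with
an energy shift so the potential is continuous there.  It deliberately
trades force-field realism for the one property the competitive-binding
protocol depends on: the electrostatic asymmetry between an acidic and a
neutral receptor surface.  Absolute energies are therefore on the model's
own scale, not a physical one.

The interaction energy of a complex is decomposed as

    E = E_AB - (E_A + E_B)

i.e. complex energy minus the isolated-unit energies; for rigid bodies
this equals the sum of receptor-atom x ligand-atom pair energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .structures import AtomRecord, CompetitiveSystem, Structure

__all__ = [
    "COULOMB_CONSTANT",
    "DEFAULT_ATOM_CLASSES",
    "ForceFieldParams",
    "EnergyBreakdown",
    "pair_energy",
    "structure_energy",
    "interaction_energy",
    "system_energy",
    "cross_energy",
]

#: Coulomb constant in kcal*Å/(mol*e^2).
COULOMB_CONSTANT = 332.06

#: Built-in per-class LJ parameters (epsilon kcal/mol, sigma Å).
#: OPLS-flavoured values for the elements plus an "X" coarse bead class.
DEFAULT_ATOM_CLASSES: dict[str, tuple[float, float]] = {
    "C": (0.105, 3.75),
    "N": (0.170, 3.25),
    "O": (0.210, 2.96),
    "S": (0.250, 3.55),
    "H": (0.015, 2.42),
    "X": (0.150, 4.00),
}


@dataclass
class ForceFieldParams:
    """Tunables of the simplified nonbonded model."""

    atom_classes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ATOM_CLASSES)
    )
    dielectric_model: str = "distance_dependent"
    dielectric_scale: float = 4.0
    nonbonded_cutoff: float = 12.0
    coulomb_constant: float = COULOMB_CONSTANT

    def __post_init__(self):
        if self.dielectric_model not in ("constant", "distance_dependent"):
            raise DomainError(f"unknown dielectric model {self.dielectric_model!r}")
        for cls, (eps, sig) in self.atom_classes.items():
            if eps < 0 or sig <= 0:
                raise DomainError(f"atom class {cls!r}: need epsilon >= 0, sigma > 0")
        max_sigma = max(s for _, s in self.atom_classes.values())
        if self.nonbonded_cutoff <= max_sigma:
            raise DomainError("nonbonded cutoff must exceed the largest sigma")

    def lj_params(self, element: str) -> tuple[float, float]:
        key = element.strip().upper()[:1] if element.strip().upper() not in self.atom_classes else element.strip().upper()
        try:
            return self.atom_classes[key]
        except KeyError:
            return self.atom_classes["C"]

    def epsilon_r(self, r: np.ndarray) -> np.ndarray:
        """Dielectric screening factor at separation r."""
        if self.dielectric_model == "constant":
            return np.full_like(np.asarray(r, dtype=float), self.dielectric_scale)
        return self.dielectric_scale * np.asarray(r, dtype=float)


@dataclass(frozen=True)
class EnergyBreakdown:
    """E = E_AB - (E_A + E_B), all in kcal/mol."""

    e_complex: float
    e_receptor: float
    e_ligand: float

    @property
    def e_interaction(self) -> float:
        return self.e_complex - (self.e_receptor + self.e_ligand)


def _pair_terms(
    r: np.ndarray,
    qq: np.ndarray,
    eps_ij: np.ndarray,
    sig_ij: np.ndarray,
    params: ForceFieldParams,
) -> np.ndarray:
    """Shifted LJ + screened Coulomb for arrays of pairs; 0 beyond cutoff."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise DomainError("pair energy undefined at zero separation")
    rc = params.nonbonded_cutoff

    def raw(rr):
        sr6 = (sig_ij / rr) ** 6
        lj = 4.0 * eps_ij * (sr6**2 - sr6)
        coul = params.coulomb_constant * qq / (params.epsilon_r(rr) * rr)
        return lj + coul

    e = raw(r) - raw(np.full_like(r, rc))
    return np.where(r < rc, e, 0.0)


def pair_energy(
    atom_i: AtomRecord, atom_j: AtomRecord, params: ForceFieldParams | None = None
) -> float:
    """Nonbonded energy of one atom pair in kcal/mol."""
    params = params or ForceFieldParams()
    r = float(np.linalg.norm(atom_i.position - atom_j.position))
    if r == 0.0:
        raise DomainError("pair energy undefined at zero separation")
    ei, si = params.lj_params(atom_i.element)
    ej, sj = params.lj_params(atom_j.element)
    # Lorentz-Berthelot combining
    eps_ij = np.sqrt(ei * ej)
    sig_ij = 0.5 * (si + sj)
    return float(
        _pair_terms(
            np.array([r]),
            np.array([atom_i.charge * atom_j.charge]),
            np.array([eps_ij]),
            np.array([sig_ij]),
            params,
        )[0]
    )


def _lj_arrays(structure: Structure, params: ForceFieldParams):
    eps = np.empty(len(structure))
    sig = np.empty(len(structure))
    for i, el in enumerate(structure.elements):
        eps[i], sig[i] = params.lj_params(str(el))
    return eps, sig


def cross_energy(
    coords_a: np.ndarray,
    charges_a: np.ndarray,
    eps_a: np.ndarray,
    sig_a: np.ndarray,
    coords_b: np.ndarray,
    charges_b: np.ndarray,
    eps_b: np.ndarray,
    sig_b: np.ndarray,
    params: ForceFieldParams,
) -> float:
    """Sum of pair energies across two rigid atom groups (vectorised)."""
    diff = coords_a[:, None, :] - coords_b[None, :, :]
    r = np.sqrt((diff**2).sum(axis=-1))
    if np.any(r == 0.0):
        raise DomainError("overlapping atoms at zero separation")
    mask = r < params.nonbonded_cutoff
    if not mask.any():
        return 0.0
    qq = charges_a[:, None] * charges_b[None, :]
    eps_ij = np.sqrt(eps_a[:, None] * eps_b[None, :])
    sig_ij = 0.5 * (sig_a[:, None] + sig_b[None, :])
    e = _pair_terms(r[mask], qq[mask], eps_ij[mask], sig_ij[mask], params)
    return float(e.sum())


def _residue_keys(structure: Structure) -> np.ndarray:
    return np.array(
        [f"{c}|{s}" for c, s in zip(structure.chain_ids, structure.residue_seqs)],
        dtype=object,
    )


def structure_energy(
    structure: Structure,
    params: ForceFieldParams | None = None,
    coords: np.ndarray | None = None,
    _residue_tags: np.ndarray | None = None,
) -> float:
    """Intra-structure nonbonded energy in kcal/mol.

    Pairs within the same residue (same chain id and residue number) are
    excluded, standing in for bonded-topology exclusions.
    """
    params = params or ForceFieldParams()
    n = len(structure)
    if n < 2:
        return 0.0
    xyz = structure.coords if coords is None else np.asarray(coords, dtype=float)
    res = _residue_keys(structure) if _residue_tags is None else _residue_tags
    eps, sig = _lj_arrays(structure, params)
    iu, ju = np.triu_indices(n, k=1)
    keep = res[iu] != res[ju]
    iu, ju = iu[keep], ju[keep]
    if iu.size == 0:
        return 0.0
    r = np.linalg.norm(xyz[iu] - xyz[ju], axis=1)
    if np.any(r == 0.0):
        raise DomainError("overlapping atoms at zero separation")
    within = r < params.nonbonded_cutoff
    if not within.any():
        return 0.0
    qq = structure.charges[iu] * structure.charges[ju]
    eps_ij = np.sqrt(eps[iu] * eps[ju])
    sig_ij = 0.5 * (sig[iu] + sig[ju])
    e = _pair_terms(r[within], qq[within], eps_ij[within], sig_ij[within], params)
    return float(e.sum())


def interaction_energy(
    receptor: Structure,
    ligand: Structure,
    params: ForceFieldParams | None = None,
    receptor_coords: np.ndarray | None = None,
    ligand_coords: np.ndarray | None = None,
) -> EnergyBreakdown:
    """Receptor-ligand interaction energy via the decomposition identity.

    ``e_complex`` is evaluated on the union of both atom sets (residues
    are disambiguated per structure, so cross pairs are never excluded);
    the returned breakdown satisfies
    ``e_interaction == e_complex - (e_receptor + e_ligand)`` exactly.
    """
    params = params or ForceFieldParams()
    rxyz = receptor.coords if receptor_coords is None else np.asarray(receptor_coords)
    lxyz = ligand.coords if ligand_coords is None else np.asarray(ligand_coords)
    e_receptor = structure_energy(receptor, params, coords=rxyz)
    e_ligand = structure_energy(ligand, params, coords=lxyz)
    eps_r, sig_r = _lj_arrays(receptor, params)
    eps_l, sig_l = _lj_arrays(ligand, params)
    e_cross = cross_energy(
        rxyz, receptor.charges, eps_r, sig_r,
        lxyz, ligand.charges, eps_l, sig_l,
        params,
    )
    return EnergyBreakdown(
        e_complex=e_receptor + e_ligand + e_cross,
        e_receptor=e_receptor,
        e_ligand=e_ligand,
    )


def system_energy(
    system: CompetitiveSystem,
    ligand_index: int,
    params: ForceFieldParams | None = None,
) -> tuple[float, float]:
    """Interaction energy of one ligand to each receptor, in kcal/mol.

    Other ligands flagged ``bound`` count as part of the receptor nearer
    to them.  For an individual-binding system (no receptor_b) the second
    value is 0.  The ligand's total interaction energy is the sum of the
    two values.
    """
    params = params or ForceFieldParams()
    if not (0 <= ligand_index < len(system.ligands)):
        raise DomainError(f"ligand index {ligand_index} out of range")
    lig = system.ligands[ligand_index]
    eps_l, sig_l = _lj_arrays(lig.structure, params)

    groups = {"a": [system.receptor_a], "b": []}
    if system.receptor_b is not None:
        groups["b"].append(system.receptor_b)
    for j, other in enumerate(system.ligands):
        if j == ligand_index or not other.bound:
            continue
        com = other.com()
        da = np.linalg.norm(com - system.com_a())
        db = (
            np.linalg.norm(com - system.com_b())
            if system.receptor_b is not None
            else np.inf
        )
        groups["a" if da <= db else "b"].append(other)

    energies = {}
    for key, members in groups.items():
        total = 0.0
        for member in members:
            if isinstance(member, Structure):
                st, xyz = member, member.coords
            else:
                st, xyz = member.structure, member.coords
            eps_m, sig_m = _lj_arrays(st, params)
            total += cross_energy(
                xyz, st.charges, eps_m, sig_m,
                lig.coords, lig.structure.charges, eps_l, sig_l,
                params,
            )
        energies[key] = total
    return energies["a"], energies["b"]
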
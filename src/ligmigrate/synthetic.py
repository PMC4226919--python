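"""Coarse-grained receptor and ligand fixture generator.

The fixtures reduce the competitive-binding problem to the two features
the protocol's conclusions rest on — cavity geometry and surface charge:

* ``acidic_barrel`` — a β-barrel-like open cylinder of pseudo-atom beads
  whose open-mouth rim carries ``n_rim_charges`` beads of ``rim_charge``
  (default −1 e), emulating the Asp-rich hairpin loops of a histamine-
  binding lipocalin; ``has_second_site`` adds a buried −1 pocket bead at
  the closed mouth (the two-site barrel that sequesters two ligands).
* ``neutral_barrel`` — bitwise-identical coordinates for the same seed,
  all charges zero: the matched electrostatic control, so any preference
  difference between the two is attributable to charge alone.
* ``pocket_receptor`` — a hemispherical cavity with one buried −1 e site,
  playing the role of a native receptor's single binding pocket.
* ``small_globule`` — a compact neutral bead cluster (false-positive
  control role).

The ligand is a 4-bead rigid histamine analog (two ring beads, linker,
amine terminus) whose net charge follows the protonation state:
0 / +1 / +2 for deprotonated / amine-protonated / imidazole-protonated
(cumulative protonation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .structures import (
    AtomRecord,
    CompetitiveSystem,
    ProtonationState,
    Structure,
    assemble_system,
    assign_protonation,
)

__all__ = [
    "FixtureSpec",
    "make_receptor",
    "make_ligand",
    "make_competition_fixture",
    "SCALED_GEOMETRY",
    "DEFAULT_GEOMETRY",
]

ARCHETYPES = ("acidic_barrel", "neutral_barrel", "pocket_receptor", "small_globule")

#: Full-scale assembly geometry (separation, ligand offset) in Å.
DEFAULT_GEOMETRY = (67.0, 42.0)
#: Scaled-down desk geometry for fast migration runs.
SCALED_GEOMETRY = (30.0, 18.0)

_BEAD_ELEMENT = "X"
_BEAD_MASS = 72.0


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic receptor."""

    archetype: str
    n_rim_charges: int = 6
    rim_charge: float = -1.0
    barrel_radius: float = 6.0
    barrel_length: float = 12.0
    has_second_site: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.archetype not in ARCHETYPES:
            raise DomainError(
                f"unknown archetype {self.archetype!r}; expected one of {ARCHETYPES}"
            )
        if self.barrel_radius <= 0 or self.barrel_length <= 0:
            raise DomainError("barrel radius and length must be positive")
        if not np.isfinite(self.rim_charge):
            raise DomainError("rim charge must be finite")


def _bead(serial, name, pos, charge=0.0, res=None, resname="BEA"):
    return AtomRecord(
        serial=serial,
        name=name,
        element=_BEAD_ELEMENT,
        residue_name=resname,
        residue_seq=res if res is not None else serial,
        chain_id="A",
        position=np.asarray(pos, dtype=float),
        mass=_BEAD_MASS,
        charge=charge,
    )


def _barrel_coords(spec: FixtureSpec, rng: np.random.Generator):
    """Rings of beads forming an open-ended cylinder along z, jittered."""
    n_per_ring = max(8, int(round(2 * np.pi * spec.barrel_radius / 4.0)))
    n_rings = max(3, int(round(spec.barrel_length / 3.0)) + 1)
    zs = np.linspace(-spec.barrel_length / 2, spec.barrel_length / 2, n_rings)
    coords = []
    for ring, z in enumerate(zs):
        phase = np.pi / n_per_ring * (ring % 2)  # stagger alternate rings
        for k in range(n_per_ring):
            ang = 2 * np.pi * k / n_per_ring + phase
            coords.append(
                [spec.barrel_radius * np.cos(ang), spec.barrel_radius * np.sin(ang), z]
            )
    coords = np.array(coords)
    coords += rng.normal(scale=0.15, size=coords.shape)  # mild surface roughness
    return coords, n_per_ring


def make_receptor(spec: FixtureSpec) -> Structure:
    """Build one pseudo-atom receptor; deterministic for a given spec + seed.

    The acidic and neutral barrels share coordinates bitwise for the same
    seed (the charge pattern is the only difference), so preference
    differences between them isolate electrostatics.
    """
    rng = np.random.default_rng(spec.seed)
    atoms = []
    if spec.archetype in ("acidic_barrel", "neutral_barrel"):
        coords, n_per_ring = _barrel_coords(spec, rng)
        acidic = spec.archetype == "acidic_barrel"
        # open mouth = +z rim ring; charges spread evenly around that rim
        rim_start = len(coords) - n_per_ring
        charged = set()
        if acidic and spec.n_rim_charges > 0:
            picks = np.linspace(0, n_per_ring, spec.n_rim_charges, endpoint=False)
            charged = {rim_start + int(round(p)) % n_per_ring for p in picks}
        for i, pos in enumerate(coords):
            q = spec.rim_charge if i in charged else 0.0
            name = "RIM" if i in charged else "BB"
            atoms.append(_bead(i + 1, name, pos, q, resname="ACB" if acidic else "NEB"))
        if spec.has_second_site:
            # buried pocket site just inside the closed (-z) mouth
            pos = np.array([0.0, 0.0, -spec.barrel_length / 2 + 1.5])
            q = spec.rim_charge if acidic else 0.0
            atoms.append(_bead(len(atoms) + 1, "POC", pos, q, resname="SIT"))
        label = spec.archetype
    elif spec.archetype == "pocket_receptor":
        # hemispherical cavity opening toward +z, one buried charge at bottom
        radius = spec.barrel_radius
        coords = []
        n_lat = 4
        for i in range(n_lat):
            theta = np.pi / 2 * (i + 1) / n_lat  # polar angle from -z pole
            n_ring = max(6, int(round(10 * np.sin(theta))))
            for k in range(n_ring):
                phi = 2 * np.pi * k / n_ring
                coords.append(
                    [
                        radius * np.sin(theta) * np.cos(phi),
                        radius * np.sin(theta) * np.sin(phi),
                        -radius * np.cos(theta),
                    ]
                )
        coords = np.array(coords)
        coords += rng.normal(scale=0.15, size=coords.shape)
        for i, pos in enumerate(coords):
            atoms.append(_bead(i + 1, "BB", pos, 0.0, resname="POK"))
        atoms.append(
            _bead(len(atoms) + 1, "SIT", [0.0, 0.0, -radius + 1.0], -1.0, resname="SIT")
        )
        label = "pocket_receptor"
    else:  # small_globule
        n = 20
        pts = rng.normal(size=(n, 3))
        pts = pts / np.linalg.norm(pts, axis=1, keepdims=True) * spec.barrel_radius * 0.6
        pts += rng.normal(scale=0.15, size=pts.shape)
        for i, pos in enumerate(pts):
            atoms.append(_bead(i + 1, "BB", pos, 0.0, resname="GLO"))
        label = "small_globule"
    return Structure(atoms, label=label)


def make_ligand(state: ProtonationState | str = "deprotonated", seed: int = 0) -> Structure:
    """4-bead rigid histamine analog with charges per protonation state.

    Beads: NI (imidazole nitrogen) and CR (ring carbon) 1.4 Å apart, a CL
    linker bead, and the NT amine-terminus bead.  Charge placement:
    deprotonated 0; amine-protonated +1 on NT; imidazole-protonated +1 on
    NT and +1 on NI (net +2).
    """
    if isinstance(state, str):
        state = ProtonationState(state)
    geom = {
        "NI": [0.0, 0.0, 0.0],
        "CR": [1.4, 0.0, 0.0],
        "CL": [2.4, 1.1, 0.0],
        "NT": [3.8, 1.3, 0.3],
    }
    elements = {"NI": "N", "CR": "C", "CL": "C", "NT": "N"}
    atoms = [
        AtomRecord(
            serial=i + 1,
            name=name,
            element=elements[name],
            residue_name="HSM",
            residue_seq=1,
            chain_id="L",
            position=np.array(pos),
            mass=14.007 if elements[name] == "N" else 12.011,
            charge=0.0,
        )
        for i, (name, pos) in enumerate(geom.items())
    ]
    ligand = Structure(atoms, label=f"histamine_{state.token}")
    return assign_protonation(ligand, state)


def make_competition_fixture(
    spec_a: FixtureSpec,
    spec_b: FixtureSpec,
    state: ProtonationState | str = "amine_protonated",
    seed: int = 0,
    n_ligands: int = 1,
    scaled_down: bool = False,
) -> CompetitiveSystem:
    """Assemble a two-receptor competitive system with unbound ligand(s).

    Uses the standard assembly geometry (67 Å separation, 42 Å ligand
    offset) by default; ``scaled_down`` switches to the fast desk
    geometry (30 Å / 18 Å), recorded in the system metadata.
    """
    separation, offset = SCALED_GEOMETRY if scaled_down else DEFAULT_GEOMETRY
    receptor_a = make_receptor(spec_a)
    receptor_b = make_receptor(spec_b)
    ligands = [make_ligand(state, seed=seed + i) for i in range(n_ligands)]
    system = assemble_system(
        receptor_a, receptor_b, ligands, separation=separation,
        ligand_offset=offset, seed=seed,
    )
    system.metadata.update(
        {
            "fixture_a": spec_a.archetype,
            "fixture_b": spec_b.archetype,
            "protonation": state if isinstance(state, str) else state.token,
            "scaled_down": scaled_down,
            "geometry": (separation, offset),
        }
    )
    return system
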
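"""Assemble the two-receptor competitive system and probe its energetics.

Places the two receptors 67 Å apart (COM to COM) with the ligand
equidistant at 42 Å — the standard competitive-assembly geometry — then
evaluates the interaction-energy decomposition E = E_AB - (E_A + E_B)
for a pose at the acidic rim vs the identical pose at the neutral rim.
"""

import numpy as np

from ligmigrate import (
    FixtureSpec,
    interaction_energy,
    make_competition_fixture,
    make_ligand,
    make_receptor,
)

system = make_competition_fixture(
    FixtureSpec("acidic_barrel", has_second_site=True, seed=1),
    FixtureSpec("pocket_receptor", seed=1),
    "amine_protonated",
    seed=1,
)
d_ab = np.linalg.norm(system.com_a() - system.com_b())
lig_com = system.ligands[0].com()
print(f"inter-receptor COM distance : {d_ab:.6f} Å  (target 67)")
print(f"ligand COM to receptor a    : {np.linalg.norm(lig_com - system.com_a()):.6f} Å")
print(f"ligand COM to receptor b    : {np.linalg.norm(lig_com - system.com_b()):.6f} Å  (both 42)")

acidic = make_receptor(FixtureSpec("acidic_barrel", seed=9))
neutral = make_receptor(FixtureSpec("neutral_barrel", seed=9))
lig = make_ligand("amine_protonated")
pose = lig.coords - lig.coords.mean(0) + np.array([0.0, 0.0, 9.5])  # above the rim

for rec in (acidic, neutral):
    br = interaction_energy(rec, lig, ligand_coords=pose)
    print(
        f"\n{rec.label}: E_AB={br.e_complex:+.3f}  E_A={br.e_receptor:+.3f}  "
        f"E_B={br.e_ligand:+.3f}  ->  E={br.e_interaction:+.3f} kcal/mol"
    )
print(
    "\nThe +1 ligand sees a strictly lower interaction energy at the acidic"
    "\nrim than at the geometry-identical neutral rim: the electrostatic"
    "\nasymmetry the competitive protocol is built on."
)
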
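"""Protonation series: receptor preference vs ligand net charge.

Runs the competitive fixture for the three protonation states (net
charge 0, +1, +2) with identical seeds and prints the acidic-barrel
preference for each.  The preference grows with charge — the engine's
desk-scale mirror of the published protonation-dependent preference
trend.  Shortened to 600 steps per state to stay quick; the acceptance
suite runs the full 2000-step version.
"""

from ligmigrate import (
    FilterSpec,
    FixtureSpec,
    MCConfig,
    RunSpec,
    assign_clusters,
    cluster_frames,
    filter_frames,
    make_competition_fixture,
    preference,
    run_experiment,
)

print(f"{'state':<24}{'net q':>6}{'frames':>8}{'pref(acidic)':>14}")
for state, q in (
    ("deprotonated", 0),
    ("amine_protonated", 1),
    ("imidazole_protonated", 2),
):
    system = make_competition_fixture(
        FixtureSpec("acidic_barrel", has_second_site=True, seed=1),
        FixtureSpec("pocket_receptor", seed=1),
        state,
        seed=1,
        scaled_down=True,
    )
    spec = RunSpec(
        mode="competitive", system=system, mc=MCConfig(steps=600, n_chains=8, seed=11)
    )
    filtered = filter_frames(run_experiment(spec), FilterSpec())
    clusters = assign_clusters(cluster_frames(filtered.all_frames()), system)
    pref = 100 - preference(clusters).preference_b_percent
    print(f"{state:<24}{q:>+6d}{len(filtered.all_frames()):>8}{pref:>13}%")

print(
    "\nMore protonated ligands spend more of their clustered frames around"
    "\nthe acidic barrel: electrostatics, not geometry, drives the shift."
)
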
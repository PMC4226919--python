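# ligmigrate

Metropolis Monte Carlo ligand-migration simulations with a competitive
two-receptor preference analysis, at coarse-grained desk scale.

## The problem

Some blood-feeding parasites secrete small β-barrel proteins (lipocalins)
whose acidic cavities out-compete host receptors for inflammatory amines
such as histamine.  A standard way to study this computationally is a
ligand-migration simulation: place two receptors in one box, let a ligand
explore by Metropolis Monte Carlo, and measure which receptor's
neighbourhood the ligand's poses cluster around.  The readout is a
*preference statistic* — the percentage of clustered trajectories on one
receptor's side — and the scientific question is how that preference
shifts with the ligand's protonation state (net charge 0, +1, +2).

`ligmigrate` implements that whole protocol end to end:

* **engine** — a three-step Monte Carlo propagator: rigid-body ligand
  perturbation (translations within `tra_r`, rotations within
  `rot_r·π`), optional side-chain resampling near the ligand, rigid-body
  pose minimization, then the Metropolis test
  `accept if E_new ≤ E_ref, else with probability exp(−ΔE/kT)` against
  the previous accepted state;
* **energy model** — Lennard-Jones 12-6 with Lorentz–Berthelot combining
  plus Coulomb screened by a distance-dependent dielectric ε(r) = 4r,
  shifted to zero at a 12 Å cutoff; the receptor–ligand interaction
  energy is the decomposition `E = E_AB − (E_A + E_B)`;
* **protocols** — individual binding (one receptor, with *spawning*:
  once the ligand COM comes within 10 Å of the receptor COM the chain is
  confined to an 8 Å sphere around it), unconstrained competitive
  binding, induced-fit refinement around an already-bound ligand, and
  sequential multi-ligand binding;
* **analysis** — frame filters (burn-in, 100 Å distance ceiling,
  negative energies only), greedy quality-threshold clustering of ligand
  COM positions (every 10th frame, 5 Å cutoff, up to 10 clusters),
  cluster→receptor assignment by nearest COM, the preference statistic,
  COM-distance traces, RMSD, CSV export;
* **synthetic fixtures** — coarse bead-resolution receptors (an acidic
  β-barrel with a charged rim, its coordinate-identical neutral control,
  a single-pocket receptor, a small globule) and a 4-bead histamine
  analog whose net charge tracks its protonation state.

Everything runs from synthetic fixtures; no downloads are needed.

## Worked example

Assembly geometry and the electrostatic discrimination the protocol is
built on (`python examples/02_assemble_and_energy.py`):

```
inter-receptor COM distance : 67.000000 Å  (target 67)
ligand COM to receptor a    : 42.000000 Å
ligand COM to receptor b    : 42.000000 Å  (both 42)

acidic_barrel: E_AB=+87.457  E_A=+95.557  E_B=+0.000  ->  E=-8.100 kcal/mol
neutral_barrel: E_AB=+77.784  E_A=+78.516  E_B=+0.000  ->  E=-0.733 kcal/mol
```

The receptors sit exactly 67 Å apart (COM to COM) with the ligand
equidistant at 42 Å, and a +1 ligand posed at the acidic rim is ~7
kcal/mol more favourable than the identical pose at the charge-free but
geometry-identical control — charge, not shape, drives the asymmetry.

Preference arithmetic from per-cluster trajectory counts
(`python examples/06_table_preference_arithmetic.py`):

```
run                     native  barrel  total  pref
deprotonated               207    360     567   64%
protonated amine           351    775    1126   69%
protonated imidazole       162    785     947   83%
second ligand              274    812    1086   75%
```

`pref` is the barrel's share of clustered trajectories, rounded up; the
four rows reproduce the published 64/69/83/75 series from its published
per-cluster counts.

A full migration run with clustering and preference is in
`examples/03_competitive_migration.py`, the protonation series in
`examples/04_protonation_trend.py`, spawning and induced-fit refinement
in `examples/05_individual_and_induced_fit.py`.

There is also a thin CLI for shell use:

```bash
ligmigrate fixture  --config run.yaml --out-dir out   # write fixture PDBs
ligmigrate simulate --config run.yaml --out-dir out   # frames.csv, poses.pdb, run_record.json
ligmigrate analyze  --frames out/frames.csv --config run.yaml --out-dir out
```

Seeds are mandatory in the config; every run is reproducible from its
run record.

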
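# Competitive-migration run configuration for the ligmigrate CLI.
# Seeds are mandatory: every run must be reproducible from its record.
mode: competitive            # individual | competitive | induced_fit
protonation: amine_protonated
scaled_down: true            # 30/18 Å desk geometry (false -> 67/42 Å)
stride: 10                   # clustering stride for `analyze`

mc:
  steps: 400                 # 2000 for production-style runs
  n_chains: 4
  seed: 11
  tra_r: 12.0
  rot_r: 0.2
  sprad: 6.0
  spawn_radius: 8.0
  spawn_trigger: 10.0
  temperature_kT: 1.0

filters:
  burn_in: 50
  max_com_distance: 100.0
  max_energy: 0.0

fixtures:
  receptor_a:
    archetype: acidic_barrel
    n_rim_charges: 6
    has_second_site: true
    seed: 1
  receptor_b:
    archetype: pocket_receptor
    seed: 1
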
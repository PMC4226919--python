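"""Receptor-preference arithmetic from per-cluster trajectory counts.

The preference statistic is the tick-barrel share of clustered
trajectories: sum the per-cluster counts on each side, divide, round up.
Feeding in the published per-cluster counts for the four competitive
runs reproduces the published 64 / 69 / 83 / 75 percentages.
"""

from ligmigrate import preference_from_counts

RUNS = {
    "deprotonated": ([63, 40, 37, 35, 32], [210, 44, 41, 35, 30]),
    "protonated amine": ([105, 101, 74, 71], [210, 181, 131, 117, 68, 68]),
    "protonated imidazole": ([58, 53, 51], [163, 153, 126, 125, 91, 74, 53]),
    "second ligand": ([126, 77, 71], [170, 144, 140, 132, 78, 74, 74]),
}

print(f"{'run':<22}{'native':>8}{'barrel':>8}{'total':>7}{'pref':>6}")
for run, (native, barrel) in RUNS.items():
    r = preference_from_counts(native, barrel)
    print(f"{run:<22}{r.counts_a:>8}{r.counts_b:>7}{r.total:>8}{r.preference_b_percent:>5}%")
print("\n'pref' is the percentage of clustered trajectories on the acidic-barrel side.")
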
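"""Fixed-temperature ensemble: clustering, SASA ratios, basin populations.

A trajectory at the transition temperature is decorrelated into an ensemble,
clustered with a target radius, and characterised against the native state.
Run:  python examples/04_ensemble_analysis.py   (about a minute)
"""

import numpy as np

from gofold import (
    EngineParams,
    MacrostateDefinition,
    build_ensemble,
    build_pair_tables,
    cluster_kmeans,
    initialize_state,
    macrostate_populations,
    make_minifold,
    run_dmd,
    sasa_ratio_profile,
)

m = make_minifold(12, seed=1).model
tables = build_pair_tables(m.atoms, m.bonds, m.contacts)
T = 1.45  # near the melting temperature
state = initialize_state(tables, m.positions, T, seed=3)
traj = run_dmd(state, 300_000, EngineParams(temperature=T, thermostat_rate=0.2, seed=4),
               tables, sample_every=5_000, native_positions=m.positions,
               collect_frames=True)
ens = build_ensemble([traj], stride=1, temperature=T)
print(f"ensemble: {len(ens)} frames; mean E = {np.mean(traj.energy):.1f}, "
      f"mean Rg = {np.mean(traj.rg):.1f} Å, mean RMSD = {np.mean(traj.rmsd):.1f} Å")

clusters = cluster_kmeans(ens, target_radius=3.0, seed=5)
print(f"clusters at 3 Å radius: {clusters.k} "
      f"(largest holds {np.bincount(clusters.labels).max()} frames)")

basins = MacrostateDefinition({"folded/collapsed": (-42.0, -3.0), "coil": (-3.0, 1.0)})
pops = macrostate_populations(np.array(traj.energy), basins)
print("populations:", {k: round(v, 3) for k, v in pops.items()})

profile = sasa_ratio_profile(ens, m.positions, m.atoms)
worst = max((r for r in profile if not profile[r]["undefined"]),
            key=lambda r: profile[r]["ratio"])
print(f"largest per-residue SASA ratio vs native: residue {worst} "
      f"({profile[worst]['ratio']:.2f}x)")
# ratios above 1 flag residues that become solvent exposed when the fold
# opens — the melting ensemble exposes what the native core buries
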
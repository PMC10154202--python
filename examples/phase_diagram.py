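"""Survival/extinction phase diagram over medium volume and seeding density.

For each (volume, density) condition, eight replicate simulations are
labeled always-extinct, always-survives or both-possible, and the phase
boundary (the 50% extinction density) is bisected per volume.  Because
the factor concentration scales as N/V, the threshold density rises
roughly in proportion to the volume.
"""

from macroqs.stochastic_quorum import QSParams, phase_diagram

VOLUMES_ML = [2, 5, 10, 18, 20, 30, 40, 60]
DENSITIES = [172, 431, 862, 1724, 3448, 6034, 12069, 15517]

pd_res = phase_diagram(QSParams(), VOLUMES_ML, DENSITIES, n_reps=8, seed=3)

print("phase boundary (threshold density vs volume):")
for _, row in pd_res.boundary.iterrows():
    print(f"  V = {row.V_ml:>4.0f} ml   threshold = {row.threshold_density:7.0f} cells/cm^2")

print("\ncondition labels (rows: density, columns: volume):")
table = pd_res.conditions.pivot(index="density_cells_per_cm2",
                                columns="V_ml", values="label")
short = table.replace({"always_survives": "S", "always_extinct": "E",
                       "both_possible": "?"})
print(short.to_string())
print("\nS = all 8 replicates expand, E = all go extinct, ? = mixed outcomes.")
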
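"""How far can a secreted survival factor carry a signal?

Estimates the Stokes-Einstein diffusion length of a ~22-kDa factor that
is stable for three days, then evaluates the concentric-ring colony sum:
the factor concentration at a colony's center rises with colony size but
saturates once the colony radius reaches the order of the diffusion
length, so sub-millimeter colonies cannot reach a high survival
threshold on their own.
"""

from macroqs.diffusion_geometry import (
    ColonyGeometry,
    MoleculeSpec,
    center_concentration,
    colony_survival_criterion,
    diffusion_coefficient,
    diffusion_length,
    saturation_radius,
)

mol = MoleculeSpec(mass_kda=22.0, half_life_h=72.0)
lam_mm = diffusion_length(mol)
print(f"22-kDa factor, 72-h half-life, 37 C water:")
print(f"  D      = {diffusion_coefficient(mol):.3g} m^2/s")
print(f"  lambda = {lam_mm:.2f} mm  (communication range; >= 5 mm)\n")

R_UM = 5.0                  # cell radius
lam_um = lam_mm * 1000.0
c_inf = center_concentration(ColonyGeometry(R_UM, lam_um, n_rings=None))
print(f"center concentration of an unbounded colony: c_tot/c_R = {c_inf:.3g}")
print(f"5% saturation radius: {saturation_radius(R_UM, lam_um, 0.05)/1000:.1f} mm\n")

print("colony radius ->  c_tot/c_R   survives alone at c_thres = 0.9 c_tot(inf)?")
for radius_um in (17.5, 100.0, 1000.0, 10000.0, 5 * lam_um):
    geom = ColonyGeometry(R_UM, lam_um, colony_radius_um=radius_um)
    c = center_concentration(geom)
    ok = colony_survival_criterion(geom, 0.9 * c_inf)
    print(f"  {radius_um/1000:7.2f} mm   {c:10.3g}   {'yes' if ok else 'no'}")

print("\nOnly colonies whose radius rivals the diffusion length clear a high")
print("threshold alone - microcolonies must rely on dish-wide quorum sensing.")
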
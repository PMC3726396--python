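"""Linker structural-integrity metrics: backbone RMSD and helix bend.

Generates an ideal 18-residue α-helix numbered like the VSD–CD linker
(240–257), perturbs and kinks it, and measures backbone RMSD after optimal
superposition plus the bend angle at the pivot residue 245.
"""
import numpy as np

from vsplink import helix_bend_angle, kabsch_superpose, region_rmsd, synth_helix

LINKER = range(240, 258)

reference = synth_helix(18, start_residue=240)
perturbed = synth_helix(18, start_residue=240, noise_sd_A=0.8, seed=7)
kinked = synth_helix(18, start_residue=240, kink_deg=40.0, kink_at=6)  # pivot = 245

rmsd_noisy = region_rmsd(reference, perturbed, LINKER, atom_class="backbone")
rmsd_kinked = region_rmsd(reference, kinked, LINKER)
rmsd_no_superpose = region_rmsd(reference, perturbed, LINKER, superpose=False)

print(f"backbone RMSD, σ=0.8 Å perturbed copy (superposed) : {rmsd_noisy:.2f} Å")
print(f"backbone RMSD, same copy without superposition     : {rmsd_no_superpose:.2f} Å")
print(f"backbone RMSD, 40° kinked helix                    : {rmsd_kinked:.2f} Å")

bend_straight = helix_bend_angle(reference, LINKER, pivot=245)
bend_kinked = helix_bend_angle(kinked, LINKER, pivot=245)
print(f"bend at residue 245, straight helix                : {bend_straight:.1f}°")
print(f"bend at residue 245, 40° kinked helix              : {bend_kinked:.1f}°")
print()
print(
    "RMSD values in the 2–4 Å range signal noticeable rearrangement of the\n"
    "linker backbone; the bend angle isolates a hinge at one pivot residue\n"
    "from overall displacement (it is invariant under rigid motion)."
)

# the Superposition object also exposes the optimal rotation itself
sup = kabsch_superpose(kinked.coordinates(), reference.coordinates())
print(f"optimal whole-structure superposition RMSD         : {sup.rmsd:.2f} Å "
      f"(det R = {np.linalg.det(sup.rotation):+.0f})")
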
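"""RMSD panels and active-site opening distances on a synthetic opening run.

Builds the toy NBD dimer, plants a 20-degree outward rotation of the
apo monomer's core subdomain over 500 frames (with 0.2 Å coordinate noise),
and contrasts the dimer-wide RMSD with the per-subdomain RMSD: the dimer
rearranges while each subdomain stays internally rigid. The two composite
active-site distances show that exactly one site (the empty one) opens.
"""

import numpy as np

import nbdtraj as nt

scheme = nt.ResidueScheme()
dimer = nt.build_toy_dimer()
traj, truth = nt.generate_opening_trajectory(
    dimer, theta_max=20.0, n_frames=500, noise_sigma=0.2, seed=1)

sel_all = nt.select_dimer_calpha(dimer, scheme)
dimer_rmsd = nt.rmsd_series(traj, sel_all, sel_all, dimer)
smoothed = nt.moving_average(dimer_rmsd, 20)

print("dimer-wide CA RMSD:  first frame %.2f Å, last frame %.2f Å"
      % (dimer_rmsd[0], dimer_rmsd[-1]))
print("moving average (period 20) at end: %.2f Å" % smoothed[-1])

for chain in scheme.chains:
    core = nt.select_calpha(dimer, chain, scheme.core)
    helical = nt.select_calpha(dimer, chain, scheme.helical_rmsd)
    core_r = nt.rmsd_series(traj, core, core, dimer)
    hel_r = nt.rmsd_series(traj, helical, helical, dimer)
    print("monomer %s: core RMSD stays at %.2f Å, helical at %.2f Å "
          "(self-fit; subdomains are internally rigid)"
          % (chain, core_r[-1], hel_r[-1]))

opening = nt.opening_distance_series(traj, scheme)
print("\nactive-site opening (Walker A to trans C-motif centroids):")
print("  nucleotide-bound site: %.2f -> %.2f Å (closed throughout)"
      % (opening["site_nuc"].values[0], opening["site_nuc"].values[-1]))
print("  empty (apo) site:      %.2f -> %.2f Å (opens by %.1f Å)"
      % (opening["site_apo"].values[0], opening["site_apo"].values[-1],
         opening["site_apo"].values[-1] - opening["site_apo"].values[0]))
print("  planted analytic opening at the last frame: %.2f Å"
      % truth.expected_opening[-1])
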
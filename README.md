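# ibarlab

Trajectory analysis for I-BAR domain / membrane binding simulations.

The inverse-BAR (I-BAR) domain is a zeppelin-shaped protein dimer that
binds lipid bilayers through a basic surface and bends them outward.
Understanding how it does so from all-atom MD output takes a specific
stack of analyses, and `ibarlab` implements that stack end to end for
anyone studying BAR-family proteins on membranes:

- **Binding geometry** — center-of-mass separation D_Z along the membrane
  normal and its offset ΔD_Z from the bound state, the orientation angle
  θ = arccos|a₂·ẑ| between the protein's second principal axis of inertia
  and the normal, Z-gap, minimum heavy-atom pair distance, first-contact
  time and residues.
- **Interface census** — residue–lipid contacts (any heavy-atom pair
  ≤ 5 Å) and salt bridges (basic N to acidic O ≤ 3.2 Å, deduplicated per
  group pair), hydrogen bonds, and windowed mean ± SD tallies by
  amino-acid and lipid type for a DOPC/DOPE/DOPS (4:4:1) bilayer.
- **Membrane shape and dynamics** — leaflet assignment, headgroup-COM
  height profile h(X), signed curvature C(X) = h″/(1+h′²)^{3/2} in nm⁻¹
  (positive toward the protein) with footprint averages C_ave/C_max and
  the diameter conversion d = 2/C, local lipid density N_lipid(X), and
  lateral mean-square displacement ⟨Δr²(t)⟩.
- **Energetics** — CHARMM-form nonbonded energies
  E = 332.0636·q_iq_j/r + ε_ij[(r_min/r)¹² − 2(r_min/r)⁶] with a switched
  cutoff, per-lipid XY interaction-energy maps, and the bound-minus-unbound
  decomposition ΔE_int by partner (lipids/water/ions).
- **Free energy** — umbrella-sampling profiles ΔG_B(ΔD_Z) via a
  self-consistent MBAR solver (Newton-accelerated, fixed-point and WHAM
  cross-checks), 0.5 Å bins anchored at the global minimum, and
  2/4/6/8/10-ns block convergence diagnostics.
- **Thermodynamic cycle** — ΔG_B = ΔE − TΔS + ΔΔμ with
  S = S_trans (Sackur–Tetrode) + S_rot (rigid rotor) + S_internal
  (quasi-harmonic: quantum oscillator entropy at effective frequencies
  ω_i = √(k_BT/λ_i) from the mass-weighted covariance spectrum).
- **Synthetic data** — seeded generators with analytic ground truth for
  every stage (bilayer point clouds on known surfaces, planted
  interfaces, Brownian lipids, Gaussian ensembles, Metropolis umbrella
  windows, a scripted end-to-end binding scene).

## Worked example

```python
import numpy as np
from ibarlab import geometry, interactions, membrane, synthetic, thermo
from ibarlab.system_model import PROTEIN_SEL, LIPID_SEL

# thermodynamic cycle from measured components (kcal/mol)
cc = thermo.assemble_cycle(226.0, 81.7, -316.3)
print(f"cycle: dG_B = {cc.delta_g[0]:.1f} kcal/mol")
print(f"diameter at C_max: {membrane.curvature_to_diameter(9.2e-2):.1f} nm")

# census on an interface with planted ground truth
system, frame, truth = synthetic.gen_planted_interface(7, 5, seed=1)
bridges = interactions.find_salt_bridges(frame, system)
contacts = interactions.find_contacts(frame, system, PROTEIN_SEL, LIPID_SEL)
print(f"planted 7 bridges -> found {len(bridges)}; "
      f"contact pairs: {len(contacts)} (bridges are contacts too)")

# scripted binding scene: approach, contact, membrane deformation
cfg = synthetic.GeneratorConfig(seed=5, jitter=0.0, noise_sd=0.0)
sysb, traj, script = synthetic.gen_binding_trajectory(cfg, n_frames=24,
                                                      bump_width=60.0)
t_fc, residues = geometry.first_contact_time(traj, PROTEIN_SEL, LIPID_SEL, 5.0)
print(f"first contact at {t_fc:.1f} ns via {residues[0][1]}{residues[0][0]} "
      f"(scripted: {script.first_contact_time:.1f} ns)")
surf = membrane.surface_profile([traj[-1]], sysb, n_bins=30)
curv = membrane.curvature_profile(surf, smoothing_window=1)
print(f"final C_max = {curv.c_max*100:.2f}e-2 nm^-1 "
      f"(scripted {script.final_apex_curvature_nm*100:.2f}e-2)")
```

Output:

```
cycle: dG_B = -8.6 kcal/mol
diameter at C_max: 21.7 nm
planted 7 bridges -> found 7; contact pairs: 12 (bridges are contacts too)
first contact at 11.0 ns via LYS295 (scripted: 11.0 ns)
final C_max = 1.35e-2 nm^-1 (scripted 1.39e-2)
```

The cycle sums its three components exactly (−8.6 kcal/mol); the census
recovers every planted salt bridge, and each bridge also satisfies the
5 Å contact criterion, so 7 + 5 = 12 contact pairs; the end-to-end scene
recovers the scripted contact time and residue exactly and the final apex
curvature to within the 30-bin discretisation error.

## Command line

```bash
ibarlab synth binding --seed 1 --out scene/       # generate a dataset
ibarlab geometry  --structure scene/system.pdb --parameters scene/params.tsv \
                  --traj scene/traj.txt --out orientation.tsv
ibarlab membrane  ... --out profiles.tsv          # h, C, N_lipid per X bin
ibarlab pmf       --windows windows/ --out pmf.tsv
ibarlab cycle     --components components.tsv --out cycle.tsv
ibarlab run       --config run.yaml               # full pipeline + summary.json
```

All outputs are TSV/JSON; re-running with the same inputs and config is
byte-identical.

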
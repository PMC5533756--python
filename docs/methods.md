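# Methods

`ibarlab` analyses molecular-dynamics trajectories of an I-BAR domain dimer
binding a mixed DOPC/DOPE/DOPS bilayer: where the protein sits and how it is
oriented, which residues and lipids form the interface, how the membrane
deforms underneath, how the interaction energy decomposes by partner, what
the binding free-energy profile along the membrane normal looks like, and
how the protein's conformational entropy changes on binding.  Every stage
is exercised on seeded synthetic inputs with known ground truth; this note
records the models, the defaults, and what the recovery tests do and do not
demonstrate.

## System model and units

Atoms carry mass, partial charge, Lennard-Jones ε and r_min/2, and exactly
one group label (protein protomer A/B, DOPC, DOPE, DOPS, water, ion).
Nonbonded parameters come from a sidecar TSV rather than force-field
topology files: only those four per-atom quantities are ever consumed, so
full CHARMM parsing would add surface without substance.  Coordinates are
in Å, energies in kcal/mol, times in ns; curvature is converted to nm⁻¹
(×10) only at the reporting boundary.  Boxes are orthorhombic, matching
the simulated systems (e.g. 470 × 90 × 150 Å³), and all distances use the
minimum-image convention.  Hydrogens are kept in the model but excluded
from "heavy-atom" analyses by a selection flag.

The native trajectory format is deliberately plain text — a header
`#atoms N box Lx Ly Lz time t` followed by one `atom_id x y z` line per
atom — and round-trips bit-identically.  PDB I/O goes through MDAnalysis.

## Binding geometry

θ is the angle between the protein's second principal axis of inertia and
the membrane normal (Z), folded into [0°, 90°].  Axes are eigenvectors of
the mass-weighted inertia tensor in ascending eigenvalue order; each axis
sign is fixed to a non-negative Z component (then X, then Y) so θ is
deterministic for symmetric shapes.  Strictly collinear point sets are
rejected as degenerate even though the smallest-inertia axis would still
be defined: a near-rod behaves continuously, an exact rod has no unique
axis pair.

D_Z is the |Z| distance between protein and membrane centers of mass
(whole membrane by default; the proximal leaflet is selectable), and
ΔD_Z = D_Z − reference, with the reference supplied by configuration —
anchored at the free-energy global minimum, or at a late-trajectory
average.  Two separation measures are reported side by side because both
appear in practice: the 3D minimum heavy-atom pair distance, and the
Z-projected gap (zero when the Z extents interpenetrate).  First contact
is the earliest frame whose minimum heavy-atom pair distance falls below
the 5 Å contact cutoff, together with the residues achieving it.

## Interface census

A residue contacts a lipid when any heavy-atom pair is within 5 Å.  A
salt bridge forms when any basic nitrogen is within 3.2 Å of any acidic
oxygen; records are deduplicated per (basic group, acidic group) pair so a
bidentate arginine–phosphate interaction counts once — at atom-pair level
the ~30-bridge interface would double-count.  Default groups: Lys NZ and
Arg NE/NH1/NH2 (basic); Asp OD1/OD2 and Glu OE1/OE2 (acidic); lipid
phosphate O1P–O4P plus the DOPS serine carboxylate (acidic); and the lipid
amine/choline nitrogen (basic).  The quaternary choline N of DOPC counts
as basic deliberately: zwitterionic PC lipids do form bridges to protein
acidic oxygens, and excluding it would zero out an observed interaction
class.  Histidine and chain termini are excluded by default (protonation
is an input, never predicted); both are configurable.

The hydrogen-bond criterion (d(D···A) ≤ 3.5 Å, ∠D–H···A ≥ 130°) is a
package default — a standard geometric definition, configurable — since no
criterion is fixed by the analysis itself.  Windowed tallies report
mean ± sample SD (ddof = 1) of per-frame counts keyed by amino-acid type
and by lipid type.

## Membrane profiles

Lipids are represented by the center of mass of their headgroup
(phosphate + amine moiety; atom sets configurable).  Leaflets are split at
the median headgroup Z (ties go to the upper leaflet).  The upper,
protein-facing leaflet's height field h(X) is the mean headgroup Z per X
bin within a Y slab of half-width 48.3 Å, averaged over frames; empty bins
are filled by periodic linear interpolation and flagged.

Curvature is the 1D profile curvature C(X) = h″/(1 + h′²)^{3/2} from
periodic central differences after an odd-width moving average (default 5
bins), signed positive when the membrane bends toward the protein.  This
is a reconstruction: the original study's curvature method is not
specified in the available text, but it plots C against X and averages
over Y, which is exactly what a height-field profile provides.  C_ave
averages C(X) over the protein's heavy-atom X-footprint; C_max is the
footprint maximum; d = 2/C converts to tubule diameter.  The smoothing
window is a noise-suppression device with a known apex bias of order
h⁗·w²Δx²; recovery tests on noiseless analytic surfaces therefore run
with the window set to 1, and the criterion "apex curvature within 2% at
64 bins" holds in that configuration.  With the default window and
realistic headgroup noise the apex bias for a 40–60 Å-wide deformation can
reach tens of percent — smoothing choices must be reported alongside any
curvature number.

Local density is the time-averaged headgroup count per X bin in the same
slab.  Lateral MSD unwraps headgroup trajectories across periodic images,
removes leaflet center drift, and averages squared XY displacements over
lipids and multiple time origins (configurable stride); the per-X-bin
variant assigns each lipid by its origin-frame bin.

## Interaction energies

Pair energies use the CHARMM functional form
E = 332.0636·q_iq_j/r + ε_ij[(r_min,ij/r)¹² − 2(r_min,ij/r)⁶] with
ε_ij = √(ε_iε_j), r_min,ij = r_min,i/2 + r_min,j/2, dielectric 1.  Group
energies sum inter-group pairs under a C¹ switched cutoff (switching from
10 Å, cutoff 12 Å; ∞ supported).  This is an analysis-level decomposition,
not a production electrostatics scheme: no Ewald summation is attempted,
because the decomposition is a proxy used for interpreting binding, and a
plain documented cutoff keeps it well-defined and configurable.  The
XY energy map assigns each lipid's whole protein-interaction energy to its
headgroup-COM bin, time-averaged; the X profile is the exact row sum.
ΔE_int components (lipid/water/ion) are bound-window minus unbound-window
means, and the total is their sum by construction.

## Free-energy profile (umbrella sampling + MBAR)

Windows impose harmonic biases 0.5·k(x − x₀)² with k = 50 kcal/mol/Å² on
ΔD_Z, centers −4.0…30.5 Å every 0.5 Å plus 3.6…3.9 Å every 0.1 Å.  Window
free energies solve the self-consistent MBAR equations, anchored f₀ = 0,
iterated to max|Δf| < 1e-8 kcal/mol with a 100 000-iteration cap.  The
default solver takes damped Newton–Raphson steps on the MBAR gradient
(K×K Hessian, quadratic convergence), falling back to a fixed-point step
whenever a Newton step fails to reduce the gradient norm; a pure
fixed-point route is retained, and the two are asserted to agree to 1e-6
as a dual-algorithm cross-check.  A binned WHAM solver provides a second,
independent estimator: note WHAM evaluates the bias at bin centers, so its
bins must be fine relative to the bias variation (0.05 Å at k = 50),
whereas the MBAR PMF may be binned at the reporting resolution directly.

The PMF is −k_BT ln of the MBAR-weighted histogram
(k_B = 0.0019872041 kcal/mol/K), bins 0.5 Å wide aligned to the window
grid, global minimum anchored at 0; empty bins are flagged NaN, never
silently zero.  Uncertainties come from a seeded block bootstrap over each
window's time series (off by default; 200 resamples when requested —
none are quoted for the headline numbers).  Convergence is monitored by
recomputing the profile on cumulative 2/4/6/8/10-ns blocks on a shared bin
grid and tabulating pairwise maximum deviations; stationary synthetic data
keep the 6-vs-10-ns deviation within the same 0.3 kcal/mol bound used for
barrier recovery.  Decorrelation is the caller's responsibility; the
synthetic sampler thins its Metropolis chains (default 10 steps per
retained sample) because MBAR's finite-sample bias under the thin overlap
of this schedule (window σ ≈ 0.11 Å vs 0.5 Å spacing) is what limits
accuracy, and autocorrelation multiplies it.

## Entropy and the thermodynamic cycle

S_protein = S_trans + S_rot + S_internal.  Translational entropy is
Sackur–Tetrode at a 1 M standard state (1660.5 Å³/molecule, configurable
— the original convention is unstated); rotational entropy is the
classical rigid rotor with symmetry number 1 on the inertia moments of the
mean structure.  Internal entropy is quasi-harmonic: after mass-weighted
rigid-body superposition (Kabsch), the mass-weighted displacement
covariance is diagonalised with the six rigid-body modes projected out;
eigenvalues below 1e-8 Å²·amu are dropped as numerical rank deficiency;
each retained mode contributes the quantum harmonic-oscillator entropy at
its effective frequency ω_i = √(k_BT/λ_i) (classical form available as a
flag; the quantum form is standard quasi-harmonic practice).  The
reconstruction of the entropy terms as Sackur–Tetrode + rigid rotor +
quantum HO is documented as such — the source's exact formulas live in
supplementary references that are not part of the available text.

The cycle ΔG_B = ΔE_protein − TΔS_protein + ΔΔμ is an identity by
construction once its three components are supplied; ΔΔμ (solvation) is
never computed here — the package accepts it and can report its Pearson
correlation with the total interaction-energy change, which is the proxy
relationship the decomposition relies on.  With the printed components
(226.0, 81.7, −316.3 kcal/mol) the assembly returns −8.6 kcal/mol.

## Synthetic data: what it does and does not emulate

Generators are deterministic under a fixed seed and target statistical
structure only — no force-field dynamics:

- **Bilayer surfaces**: 640/640/160 DOPC/DOPE/DOPS (4:4:1) split evenly
  across leaflets on a jittered lattice (≈59 Å²/lipid in the 470 × 90 Å
  box), headgroup COM exactly on an analytic flat/sinusoid/Gaussian-bump
  surface plus Gaussian Z noise (default 0.3 Å); the analytic curvature
  function is returned as ground truth.  Surfaces too steep for a height
  field are rejected.
- **Planted interfaces**: exact numbers of basic-N/acidic-O pairs at
  2.8–3.1 Å and contact-only residue–lipid pairs at 4.0–4.9 Å on a ≥16 Å
  grid, so no unintended pair is detectable.
- **Brownian lipids**: independent 2D Gaussian increments of variance
  2D·dt per axis (closed form ⟨Δr²⟩ = 4Dt).
- **Gaussian ensembles**: frames with a prescribed mass-weighted
  covariance spectrum in a random orthonormal mode basis orthogonal to
  the rigid-body subspace; closed-form entropy as truth.
- **Umbrella windows**: vectorised Metropolis chains per window over an
  analytic potential, step size tuned to 30–60% acceptance during
  burn-in, thinned 10×.  The default double well emulates the study's
  profile: global minimum 8.6 kcal/mol below the unbound plateau at
  ΔD_Z = 0 and a second minimum at 3.5 Å.
- **Binding scene**: a rigid plate protein (second inertia axis along its
  width, vertical when bound) descending with θ relaxing linearly to 0,
  first contact through a designated lysine NZ computed arithmetically
  from the scripted approach, and a Gaussian membrane bump growing after
  contact — ground truth for the full pipeline.

Passing recovery tests on these inputs demonstrates that the estimators
are correct and converge at the stated rates; it does not demonstrate
robustness to features real trajectories have and the generators lack —
anharmonic protein dynamics, correlated lipid motion, undulation spectra,
protonation changes, or force-field error.

## Problem sizes and numerical choices

Recovery suites run at the sizes their error analyses require: 10⁴
samples/window × 74 windows for the PMF (barrier within 0.3 kcal/mol of
analytic; the long plateau arm carries a residual MBAR small-overlap bias
of a few percent of the depth), 10⁴ frames for entropy (within 2%), 500
lipids × 10⁴ steps for MSD (within 3 SE), 64 bins/1536 lipids for
curvature (within 2% at the apex).  Unit tests use smaller versions of the
same constructions.  Ties and degeneracies are fixed deterministically
(axis signs, leaflet ties, bin edges aligned to the window grid); empty
bins and rank-deficient covariances are flagged rather than silently
patched.

## Known limitations

- Curvature is a 1D profile along X, averaged over Y; no 2D mean/Gaussian
  curvature tensor, no tubule/vesicle topology.
- Analysis energies use a switched cutoff, not Ewald sums; absolute
  electrostatic magnitudes differ from production values.
- ΔE_protein's bonded part is accepted as externally supplied per-frame
  energies; only the nonbonded part is computable in-package.
- The WHAM cross-check is binned and therefore biased at coarse bins;
  use it only with bins fine relative to the bias curvature.
- MBAR free energies across the full 70-window schedule accumulate a
  small-overlap bias that decays as 1/n per window; depth-type quantities
  converge more slowly than barrier-type ones.
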
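"""Physical constants and package-wide default parameters.

Energies are in kcal/mol, lengths in Å, masses in amu, times in ns
(except mode frequencies, rad/ps) unless stated otherwise.  Curvature is
reported in nm^-1 at the reporting boundary (conversion x10 from Å^-1).
"""

from __future__ import annotations

import scipy.constants as _sc

# Boltzmann constant, kcal/mol/K
KB_KCAL: float = 0.0019872041

# Coulomb prefactor in CHARMM convention, kcal*Å/(mol*e^2)
COULOMB_KCAL: float = 332.0636

# hbar in kcal*ps/mol  (J*s -> kcal/mol * ps)
HBAR_KCAL_PS: float = _sc.hbar * _sc.Avogadro / 4184.0 * 1e12

# 1 kcal/mol expressed in amu*Å^2/ps^2 (4184 J/mol, 1 amu*Å^2/ps^2 = 10 J/mol)
KCAL_TO_AMU_A2_PS2: float = 4184.0 / (_sc.atomic_mass * _sc.Avogadro * 1e4)

# Standard-state volume per molecule at 1 M, Å^3
STANDARD_VOLUME_A3: float = 1e27 / (_sc.Avogadro * 1e-3)

# Å^-1 -> nm^-1
CURVATURE_A_TO_NM: float = 10.0

# --- analysis defaults -------------------------------------------------
CONTACT_CUTOFF: float = 5.0        # Å, heavy-atom residue-lipid contact
SALT_BRIDGE_CUTOFF: float = 3.2    # Å, basic N ... acidic O
HBOND_DIST_CUTOFF: float = 3.5     # Å, donor...acceptor
HBOND_ANGLE_CUTOFF: float = 130.0  # degrees, D-H...A
Y_HALF_WIDTH: float = 48.3         # Å, membrane profile Y slab half-width
TEMPERATURE: float = 300.0         # K
UMBRELLA_K: float = 50.0           # kcal/mol/Å^2, harmonic bias
NB_CUTOFF: float = 12.0            # Å, nonbonded cutoff
NB_SWITCH_ON: float = 10.0         # Å, switching starts
MODE_EIGENVALUE_FLOOR: float = 1e-8  # Å^2*amu, rank-deficiency threshold
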
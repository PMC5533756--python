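"""Protein entropy and the binding thermodynamic cycle.

The binding free energy is decomposed as

    ΔG_B = ΔE_protein − TΔS_protein + ΔΔμ,

where ΔE and ΔS compare the protein's conformational ensembles generated
in the bound and unbound states, and ΔΔμ is the solvation term (supplied,
never computed here; its consistency with the total interaction-energy
change can be reported as a correlation).  S_protein is the sum of a
Sackur–Tetrode translational term, a classical rigid-rotor rotational term
(symmetry number 1), and the internal quasi-harmonic term: a quantum
harmonic-oscillator entropy per principal mode, with effective frequencies
ω_i = √(k_B T / λ_i) from the eigenvalues λ_i of the mass-weighted
displacement covariance after rigid-body superposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.constants as sc
from scipy.spatial.transform import Rotation

from . import constants as C

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# superposition
# ----------------------------------------------------------------------

def superpose(frames: np.ndarray, reference: np.ndarray,
              masses: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mass-weighted least-squares rigid-body superposition (Kabsch).

    ``frames``: (F, N, 3); ``reference``: (N, 3).  Returns (aligned frames,
    per-frame mass-weighted RMSD).
    """
    frames = np.asarray(frames, dtype=float)
    reference = np.asarray(reference, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if frames.ndim != 3 or frames.shape[1:] != reference.shape:
        raise ValueError("frames must be (F, N, 3) matching reference")
    n = reference.shape[0]
    if n < 3 or np.linalg.matrix_rank(
            reference - reference.mean(axis=0), tol=1e-10) < 2:
        raise ValueError("degenerate reference geometry")
    wtot = masses.sum()
    ref_com = (masses[:, None] * reference).sum(axis=0) / wtot
    ref_c = reference - ref_com
    aligned = np.empty_like(frames)
    rmsd = np.empty(len(frames))
    for i, fr in enumerate(frames):
        com = (masses[:, None] * fr).sum(axis=0) / wtot
        mob = fr - com
        rot, _ = Rotation.align_vectors(ref_c, mob, weights=masses)
        out = rot.apply(mob) + ref_com
        aligned[i] = out
        rmsd[i] = np.sqrt((masses * ((out - reference) ** 2).sum(axis=1)).sum()
                          / wtot)
    return aligned, rmsd


# ----------------------------------------------------------------------
# quasi-harmonic analysis
# ----------------------------------------------------------------------

@dataclass
class ModeSpectrum:
    """Principal-mode spectrum of the mass-weighted covariance."""

    eigenvalues: np.ndarray   # Å²·amu, descending, rigid-body removed
    frequencies: np.ndarray   # rad/ps, ω_i = sqrt(k_B T / λ_i)
    temperature: float        # K
    n_dropped: int            # modes below the eigenvalue floor


def _rigid_body_basis(reference: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted translation+rotation basis, (3N, 6)."""
    n = reference.shape[0]
    com = (masses[:, None] * reference).sum(axis=0) / masses.sum()
    r = reference - com
    sqm = np.sqrt(masses)
    basis = np.zeros((3 * n, 6))
    for a in range(3):
        basis[a::3, a] = sqm
    for a, axis in enumerate(np.eye(3)):
        rot = np.cross(np.broadcast_to(axis, r.shape), r) * sqm[:, None]
        basis[:, 3 + a] = rot.reshape(-1)
    q, _ = np.linalg.qr(basis)
    return q


def covariance_pca(aligned: np.ndarray, masses: np.ndarray,
                   temperature: float = C.TEMPERATURE,
                   remove_rigid_body: bool = True,
                   eigenvalue_floor: float = C.MODE_EIGENVALUE_FLOOR) -> ModeSpectrum:
    """Eigen-decompose the mass-weighted displacement covariance.

    Rigid-body modes are projected out; eigenvalues below the floor are
    dropped (counted in ``n_dropped``).  Fewer frames than modes is legal
    but flagged as rank-deficient.
    """
    aligned = np.asarray(aligned, dtype=float)
    if aligned.ndim != 3 or len(aligned) == 0:
        raise ValueError("need (F, N, 3) aligned frames")
    n_frames, n_atoms, _ = aligned.shape
    mean = aligned.mean(axis=0)
    sqm = np.sqrt(np.asarray(masses, dtype=float))
    disp = ((aligned - mean) * sqm[None, :, None]).reshape(n_frames, -1)
    if remove_rigid_body:
        basis = _rigid_body_basis(mean, np.asarray(masses, float))
        disp = disp - (disp @ basis) @ basis.T
    if n_frames < disp.shape[1]:
        logger.warning("covariance is rank-deficient: %d frames < %d modes",
                       n_frames, disp.shape[1])
    # eigenvalues of disp^T disp / F via SVD (economical either way)
    s = np.linalg.svd(disp / np.sqrt(n_frames), compute_uv=False)
    lam = np.sort(s ** 2)[::-1]
    n_dropped = int((lam < eigenvalue_floor).sum())
    lam = lam[lam >= eigenvalue_floor]
    kt_amu = C.KB_KCAL * temperature * C.KCAL_TO_AMU_A2_PS2
    freq = np.sqrt(kt_amu / lam) if lam.size else np.empty(0)
    return ModeSpectrum(lam, freq, temperature, n_dropped)


def internal_entropy(spectrum: ModeSpectrum, temperature: float | None = None,
                     classical: bool = False) -> float:
    """Quasi-harmonic internal-motion entropy, kcal/mol/K.

    Quantum harmonic oscillator per mode (default):
        S = k_B Σ_i [ x_i/(e^{x_i}−1) − ln(1 − e^{−x_i}) ],  x_i = ħω_i/k_BT.
    The classical variant S = k_B Σ_i [1 − ln x_i] is available as a flag.
    """
    t = spectrum.temperature if temperature is None else temperature
    if t <= 0:
        raise ValueError("temperature must be positive")
    if spectrum.frequencies.size == 0:
        return 0.0
    x = C.HBAR_KCAL_PS * spectrum.frequencies / (C.KB_KCAL * t)
    if classical:
        per_mode = 1.0 - np.log(x)
    else:
        per_mode = x / np.expm1(x) - np.log1p(-np.exp(-x))
    return float(C.KB_KCAL * per_mode.sum())


# ----------------------------------------------------------------------
# translational and rotational entropy
# ----------------------------------------------------------------------

def trans_rot_entropy(total_mass_amu: float, inertia_moments_amu_A2: np.ndarray,
                      temperature: float = C.TEMPERATURE,
                      volume_A3: float = C.STANDARD_VOLUME_A3) -> tuple[float, float]:
    """Sackur–Tetrode translational and classical rigid-rotor rotational
    entropy (symmetry number 1), both kcal/mol/K.

    The standard-state volume defaults to 1 M (1660.5 Å³ per molecule).
    """
    moments = np.asarray(inertia_moments_amu_A2, dtype=float)
    if total_mass_amu <= 0 or np.any(moments <= 0) or volume_A3 <= 0 \
            or temperature <= 0:
        raise ValueError("mass, moments, volume and temperature must be > 0")
    m = total_mass_amu * sc.atomic_mass
    kt = sc.k * temperature
    lam = sc.h / np.sqrt(2 * np.pi * m * kt)           # thermal wavelength, m
    v = volume_A3 * 1e-30
    s_trans = sc.R * (np.log(v / lam ** 3) + 2.5)
    inertia = moments * sc.atomic_mass * 1e-20          # kg m^2
    theta = sc.hbar ** 2 / (2 * inertia * sc.k)         # rotational temps, K
    s_rot = sc.R * (1.5 + np.log(np.sqrt(np.pi)
                                 * np.sqrt(np.prod(temperature / theta))))
    return float(s_trans / 4184.0), float(s_rot / 4184.0)


@dataclass
class EntropyReport:
    """Total protein entropy and its components, kcal/mol/K."""

    s_trans: float
    s_rot: float
    s_internal: float
    temperature: float
    volume_A3: float

    @property
    def s_total(self) -> float:
        return self.s_trans + self.s_rot + self.s_internal


def protein_entropy(coords: np.ndarray, masses: np.ndarray,
                    temperature: float = C.TEMPERATURE,
                    volume_A3: float = C.STANDARD_VOLUME_A3,
                    classical: bool = False) -> EntropyReport:
    """Full entropy of a conformational ensemble: superpose on the first
    frame, quasi-harmonic internal term, plus translational/rotational terms
    from the mean structure's mass and inertia moments."""
    coords = np.asarray(coords, dtype=float)
    aligned, _ = superpose(coords, coords[0], masses)
    spectrum = covariance_pca(aligned, masses, temperature)
    s_int = internal_entropy(spectrum, classical=classical)
    mean = aligned.mean(axis=0)
    com = (masses[:, None] * mean).sum(axis=0) / masses.sum()
    r = mean - com
    r2 = (r * r).sum(axis=1)
    tensor = (masses[:, None, None] * (r2[:, None, None] * np.eye(3)
                                       - r[:, :, None] * r[:, None, :])).sum(axis=0)
    moments = np.linalg.eigvalsh(tensor)
    s_tr, s_rot = trans_rot_entropy(float(masses.sum()), moments,
                                    temperature, volume_A3)
    return EntropyReport(s_tr, s_rot, s_int, temperature, volume_A3)


# ----------------------------------------------------------------------
# thermodynamic cycle
# ----------------------------------------------------------------------

@dataclass
class CycleComponents:
    """ΔG_B = ΔE_protein + (−TΔS_protein) + ΔΔμ, kcal/mol (scalars or
    per-ΔD_Z series on a shared grid)."""

    delta_e: np.ndarray
    minus_t_delta_s: np.ndarray
    delta_delta_mu: np.ndarray
    delta_g: np.ndarray
    d_z: np.ndarray | None = None
    mu_eint_correlation: float | None = None


def assemble_cycle(delta_e, minus_t_delta_s, delta_delta_mu,
                   d_z=None, delta_e_int=None) -> CycleComponents:
    """Assemble the thermodynamic cycle; ΔG_B is the component sum by
    construction.  If the total interaction-energy change ΔE_int is given as
    a series alongside series components, its Pearson correlation with ΔΔμ
    is reported (the solvation proxy consistency check)."""
    de = np.atleast_1d(np.asarray(delta_e, dtype=float))
    ts = np.atleast_1d(np.asarray(minus_t_delta_s, dtype=float))
    mu = np.atleast_1d(np.asarray(delta_delta_mu, dtype=float))
    if not (de.shape == ts.shape == mu.shape):
        raise ValueError("component series have mismatched grids")
    if d_z is not None:
        d_z = np.asarray(d_z, dtype=float)
        if d_z.shape != de.shape:
            raise ValueError("ΔD_Z grid does not match components")
    corr = None
    if delta_e_int is not None:
        ei = np.asarray(delta_e_int, dtype=float)
        if ei.shape != mu.shape or mu.size < 2:
            raise ValueError("ΔE_int series must match ΔΔμ series (length ≥2)")
        corr = float(np.corrcoef(ei, mu)[0, 1])
    dg = de + ts + mu
    if dg.size == 1:
        logger.info("cycle: ΔE=%.1f, −TΔS=%.1f, ΔΔμ=%.1f → ΔG_B=%.1f kcal/mol",
                    de[0], ts[0], mu[0], dg[0])
    return CycleComponents(de, ts, mu, dg, d_z, corr)
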
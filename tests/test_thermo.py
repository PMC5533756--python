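"""Superposition, quasi-harmonic entropy, translational/rotational entropy
and the thermodynamic cycle."""

import math

import numpy as np
import pytest
import scipy.constants as sc

from ibarlab import constants as C
from ibarlab import synthetic, thermo


def _random_structure(rng, n=20):
    return rng.normal(0, 4, (n, 3)) + 30.0


def test_superpose_recovers_rigid_transform():
    rng = np.random.default_rng(0)
    ref = _random_structure(rng)
    masses = rng.uniform(1, 15, len(ref))
    from scipy.spatial.transform import Rotation
    rot = Rotation.random(rng=np.random.default_rng(1))
    moved = rot.apply(ref - ref.mean(0)) + ref.mean(0) + [5.0, -3.0, 2.0]
    aligned, rmsd = thermo.superpose(moved[None], ref, masses)
    assert rmsd[0] < 1e-10
    np.testing.assert_allclose(aligned[0], ref, atol=1e-9)
    # identity on already-aligned frames
    aligned2, rmsd2 = thermo.superpose(ref[None], ref, masses)
    assert rmsd2[0] < 1e-12


def test_superpose_degenerate_reference_rejected():
    line = np.column_stack([np.zeros(5), np.zeros(5), np.arange(5.0)])
    with pytest.raises(ValueError, match="degenerate"):
        thermo.superpose(line[None], line, np.ones(5))


def test_covariance_pca_recovers_isotropic_variance():
    rng = np.random.default_rng(2)
    n_atoms, sigma2 = 8, 0.25
    ref = _random_structure(rng, n_atoms)
    masses = np.full(n_atoms, 12.0)
    n_frames = 6000
    disp = rng.normal(0, np.sqrt(sigma2), (n_frames, 3 * n_atoms))
    coords = ref[None] + (disp / np.sqrt(12.0)).reshape(n_frames, n_atoms, 3)
    spec = thermo.covariance_pca(coords, masses, remove_rigid_body=False)
    se = sigma2 * np.sqrt(2.0 / n_frames)
    assert np.all(np.abs(spec.eigenvalues - sigma2) < 5 * se * np.sqrt(n_atoms))


def test_covariance_pca_matches_brute_force_eigenvalues():
    rng = np.random.default_rng(3)
    n_atoms, n_frames = 5, 300
    ref = _random_structure(rng, n_atoms)
    masses = rng.uniform(2, 16, n_atoms)
    coords = ref[None] + rng.normal(0, 0.5, (n_frames, n_atoms, 3))
    spec = thermo.covariance_pca(coords, masses, remove_rigid_body=False,
                                 eigenvalue_floor=0.0)
    disp = ((coords - coords.mean(0)) * np.sqrt(masses)[None, :, None]
            ).reshape(n_frames, -1)
    brute = np.sort(np.linalg.eigvalsh(disp.T @ disp / n_frames))[::-1]
    np.testing.assert_allclose(spec.eigenvalues, brute[:len(spec.eigenvalues)],
                               rtol=1e-8)


def test_rigid_ensemble_has_empty_spectrum():
    rng = np.random.default_rng(4)
    ref = _random_structure(rng, 6)
    coords = np.repeat(ref[None], 50, axis=0)
    spec = thermo.covariance_pca(coords, np.full(6, 12.0))
    assert spec.eigenvalues.size == 0
    assert thermo.internal_entropy(spec) == 0.0


def test_internal_entropy_closed_form_single_mode():
    # βħω = 1: S/k_B = 1/(e−1) − ln(1 − e⁻¹)
    t = 300.0
    omega = C.KB_KCAL * t / C.HBAR_KCAL_PS  # makes βħω = 1
    lam = C.KB_KCAL * t * C.KCAL_TO_AMU_A2_PS2 / omega ** 2
    spec = thermo.ModeSpectrum(np.array([lam]), np.array([omega]), t, 0)
    expected = C.KB_KCAL * (1 / (math.e - 1) - math.log(1 - 1 / math.e))
    assert thermo.internal_entropy(spec) == pytest.approx(expected,
                                                          rel=1e-10)
    assert expected / C.KB_KCAL == pytest.approx(1.04065, abs=2e-5)


def test_internal_entropy_classical_limit():
    # βħω → 0: quantum S per mode → k_B (1 − ln βħω)
    t = 300.0
    x = 1e-4
    omega = x * C.KB_KCAL * t / C.HBAR_KCAL_PS
    spec = thermo.ModeSpectrum(np.array([1.0]), np.array([omega]), t, 0)
    sq = thermo.internal_entropy(spec)
    scl = thermo.internal_entropy(spec, classical=True)
    assert sq == pytest.approx(scl, rel=1e-4)


def test_internal_entropy_monotone_in_eigenvalue():
    t = 300.0
    kt_amu = C.KB_KCAL * t * C.KCAL_TO_AMU_A2_PS2

    def s_of(lam):
        spec = thermo.ModeSpectrum(np.array([lam]),
                                   np.sqrt(kt_amu / np.array([lam])), t, 0)
        return thermo.internal_entropy(spec)

    lams = [0.01, 0.1, 1.0, 10.0]
    vals = [s_of(l) for l in lams]
    assert vals == sorted(vals)


def test_sackur_tetrode_argon():
    # argon at 298.15 K in the 1-atm ideal-gas volume: S ≈ 36.98 cal/mol/K
    v = sc.k * 298.15 / 101325.0 * 1e30  # Å^3 per molecule
    s_trans, _ = thermo.trans_rot_entropy(39.948, np.array([1.0, 1.0, 1.0]),
                                          298.15, v)
    assert s_trans * 1000 == pytest.approx(36.98, abs=0.02)


def test_translational_entropy_mass_scaling():
    s1, _ = thermo.trans_rot_entropy(10.0, np.ones(3), 300.0, 1660.5)
    s2, _ = thermo.trans_rot_entropy(20.0, np.ones(3), 300.0, 1660.5)
    assert s2 - s1 == pytest.approx(1.5 * sc.R / 4184.0 * np.log(2),
                                    rel=1e-10)


def test_rotational_entropy_matches_closed_form():
    moments = np.array([1e4, 2e4, 3e4])  # amu Å^2
    t = 300.0
    _, s_rot = thermo.trans_rot_entropy(100.0, moments, t, 1660.5)
    inertia = moments * sc.atomic_mass * 1e-20
    theta = sc.hbar ** 2 / (2 * inertia * sc.k)
    expected = sc.R * (1.5 + np.log(np.sqrt(np.pi * t ** 3
                                            / np.prod(theta)))) / 4184.0
    assert s_rot == pytest.approx(expected, rel=1e-12)


def test_gaussian_ensemble_entropy_recovery():
    spectrum = np.geomspace(5.0, 0.2, 15)
    system, traj, truth = synthetic.gen_gaussian_ensemble(
        spectrum, 12.0, 4000, seed=6)
    coords = np.array([f.coordinates for f in traj])
    aligned, _ = thermo.superpose(coords, coords[0], system.masses)
    spec = thermo.covariance_pca(aligned, system.masses)
    s = thermo.internal_entropy(spec)
    assert abs(s - truth["entropy_kcal_mol_K"]) / truth["entropy_kcal_mol_K"] \
        < 0.05


def test_internal_entropy_invariant_under_rigid_motion_of_ensemble():
    spectrum = np.geomspace(2.0, 0.3, 9)
    system, traj, truth = synthetic.gen_gaussian_ensemble(
        spectrum, 12.0, 2000, seed=8)
    coords = np.array([f.coordinates for f in traj])
    from scipy.spatial.transform import Rotation
    rot = Rotation.random(rng=np.random.default_rng(9))
    moved = rot.apply(coords.reshape(-1, 3)).reshape(coords.shape) + 40.0

    def entropy_of(ens):
        aligned, _ = thermo.superpose(ens, ens[0], system.masses)
        return thermo.internal_entropy(
            thermo.covariance_pca(aligned, system.masses))

    assert entropy_of(moved) == pytest.approx(entropy_of(coords), rel=1e-6)


def test_cycle_reproduces_reported_binding_free_energy():
    cc = thermo.assemble_cycle(226.0, 81.7, -316.3)
    assert cc.delta_g[0] == pytest.approx(-8.6, abs=1e-12)
    zero = thermo.assemble_cycle(0.0, 0.0, 0.0)
    assert zero.delta_g[0] == 0.0
    # raising −TΔS at fixed other terms raises ΔG_B
    up = thermo.assemble_cycle(226.0, 90.0, -316.3)
    assert up.delta_g[0] > cc.delta_g[0]


def test_cycle_series_and_correlation():
    d_z = np.array([0.0, 10.0, 20.0, 30.5])
    de = np.array([226.0, 100.0, 30.0, 0.0])
    ts = np.array([81.7, 40.0, 10.0, 0.0])
    mu = np.array([-316.3, -150.0, -45.0, 0.0])
    eint = 1.1 * mu + 5.0
    cc = thermo.assemble_cycle(de, ts, mu, d_z=d_z, delta_e_int=eint)
    np.testing.assert_allclose(cc.delta_g, de + ts + mu)
    assert cc.mu_eint_correlation == pytest.approx(1.0)
    with pytest.raises(ValueError, match="grid"):
        thermo.assemble_cycle(de, ts[:2], mu)
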
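"""Binding-geometry observables: COM, principal axes, θ, ΔD_Z, gap."""

import numpy as np
import pandas as pd
import pytest

from ibarlab import geometry as G
from ibarlab.system_model import (Frame, SelectionSpec, SystemModel,
                                  PROTEIN_SEL, LIPID_SEL)


def _point_system(coords, masses, group="protein_A"):
    n = len(coords)
    atoms = pd.DataFrame({
        "atom_id": np.arange(1, n + 1), "name": "CA", "element": "C",
        "residue_name": "GLY", "residue_id": np.arange(1, n + 1),
        "segment": "A", "mass": masses, "charge": 0.0,
        "lj_epsilon": 0.07, "lj_rmin_half": 2.0, "group": group})
    system = SystemModel(atoms)
    frame = Frame(np.asarray(coords, float), [200.0, 200.0, 200.0])
    return system, frame


ALL = SelectionSpec()


def test_center_of_mass_weighting():
    system, frame = _point_system([[0, 0, 0], [2, 0, 0]], [1.0, 1.0])
    np.testing.assert_allclose(G.center_of_mass(frame, system, ALL),
                               [1, 0, 0])
    system, frame = _point_system([[0, 0, 0], [0, 0, 4]], [1.0, 3.0])
    assert G.center_of_mass(frame, system, ALL)[2] == pytest.approx(3.0)


def test_center_of_mass_matches_brute_force():
    rng = np.random.default_rng(3)
    coords = rng.uniform(0, 50, (40, 3))
    masses = rng.uniform(1, 20, 40)
    system, frame = _point_system(coords, masses)
    expect = (masses[:, None] * coords).sum(0) / masses.sum()
    np.testing.assert_allclose(G.center_of_mass(frame, system, ALL), expect)


def test_principal_axes_of_near_rod_and_plane():
    # thin rod along Z (slightly thickened to avoid the collinear error)
    z = np.linspace(-10, 10, 9)
    coords = np.column_stack([np.r_[np.full(9, 0.01), np.full(9, -0.01)],
                              np.zeros(18), np.r_[z, z]])
    system, frame = _point_system(coords, np.ones(18))
    axes = G.principal_axes(frame, system, ALL)
    assert abs(axes[0] @ [0, 0, 1]) == pytest.approx(1.0, abs=1e-6)
    # planar square in XY: largest-inertia axis is Z
    sq = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]], float)
    system, frame = _point_system(sq, np.ones(4))
    axes = G.principal_axes(frame, system, ALL)
    assert abs(axes[2] @ [0, 0, 1]) == pytest.approx(1.0)


def test_principal_axes_collinear_raises():
    coords = np.column_stack([np.zeros(5), np.zeros(5), np.arange(5.0)])
    system, frame = _point_system(coords, np.ones(5))
    with pytest.raises(ValueError, match="collinear"):
        G.principal_axes(frame, system, ALL)


def test_principal_axes_diagonalize_inertia_tensor():
    rng = np.random.default_rng(11)
    coords = rng.normal(0, 5, (60, 3)) * [3.0, 2.0, 1.0]
    masses = rng.uniform(1, 15, 60)
    system, frame = _point_system(coords, masses)
    axes = G.principal_axes(frame, system, ALL)
    tensor = G.inertia_tensor(coords, masses)
    rotated = axes @ tensor @ axes.T
    off = rotated - np.diag(np.diag(rotated))
    assert np.abs(off).max() < 1e-8 * np.abs(np.diag(rotated)).max()
    assert np.all(np.diff(np.diag(rotated)) >= -1e-9)  # ascending


def _plate(nx=11, nz=5):
    """Plate with distinct inertia moments; second axis along Z."""
    pts = [(i * 5.0 - 25.0, jy, k * 5.0 - 10.0)
           for i in range(nx) for jy in (-2.0, 2.0) for k in range(nz)]
    return np.array(pts)


def test_theta_zero_ninety_and_known_rotation():
    plate = _plate()
    system, frame = _point_system(plate + 50.0, np.ones(len(plate)))
    assert G.theta_angle(frame, system, ALL) == pytest.approx(0.0, abs=1e-9)
    # rotate 30° about the first (long, X) axis: θ = 30°
    th = np.radians(30.0)
    rot = np.array([[1, 0, 0], [0, np.cos(th), -np.sin(th)],
                    [0, np.sin(th), np.cos(th)]])
    system, frame = _point_system(plate @ rot.T + 50.0, np.ones(len(plate)))
    assert G.theta_angle(frame, system, ALL) == pytest.approx(30.0, abs=1e-8)
    # second axis rotated into the XY plane: θ = 90°
    rot90 = np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]], float)
    system, frame = _point_system(plate @ rot90.T + 50.0,
                                  np.ones(len(plate)))
    assert G.theta_angle(frame, system, ALL) == pytest.approx(90.0, abs=1e-8)


def test_theta_invariant_under_z_rotation_and_translation():
    plate = _plate()
    rng = np.random.default_rng(5)
    th = np.radians(23.0)
    tilt = np.array([[1, 0, 0], [0, np.cos(th), -np.sin(th)],
                     [0, np.sin(th), np.cos(th)]])
    base = plate @ tilt.T
    system, frame = _point_system(base + 60.0, np.ones(len(plate)))
    ref = G.theta_angle(frame, system, ALL)
    phi = rng.uniform(0, 2 * np.pi)
    zrot = np.array([[np.cos(phi), -np.sin(phi), 0],
                     [np.sin(phi), np.cos(phi), 0], [0, 0, 1]])
    moved = base @ zrot.T + rng.uniform(-10, 10, 3) + 60.0
    system2, frame2 = _point_system(moved, np.ones(len(plate)))
    assert G.theta_angle(frame2, system2, ALL) == pytest.approx(ref,
                                                                abs=1e-8)


def test_binding_coordinates_and_gap(two_group_system):
    system, frame = two_group_system
    state = G.binding_coordinates(frame, system, PROTEIN_SEL, LIPID_SEL,
                                  reference_d_z=5.0)
    com_p = G.center_of_mass(frame, system, PROTEIN_SEL)
    com_m = G.center_of_mass(frame, system, LIPID_SEL)
    assert state.d_z == pytest.approx(abs(com_p[2] - com_m[2]))
    assert state.delta_d_z == pytest.approx(state.d_z - 5.0)
    assert state.gap_z >= 0
    assert state.gap_z <= state.min_pair_distance


def test_min_pair_distance_matches_brute_force(random_interface_system):
    system, frame = random_interface_system
    heavy_p = SelectionSpec(groups=("protein_A",), heavy_only=True)
    heavy_l = SelectionSpec(groups=("DOPC", "DOPE", "DOPS"), heavy_only=True)
    d = G.min_pair_distance(frame, system, heavy_p, heavy_l)
    from ibarlab.system_model import minimum_image_distance
    ip = heavy_p.indices(system)
    il = heavy_l.indices(system)
    brute = min(minimum_image_distance(frame.coordinates[i],
                                       frame.coordinates[j], frame.box)
                for i in ip for j in il)
    assert d == pytest.approx(brute, abs=1e-9)


def test_first_contact_time_planted_and_never():
    # protein residue descending 1 Å per ns toward a lipid
    from ibarlab.synthetic import _Builder
    frames = []
    system = None
    for t in range(20):
        b = _Builder()
        b.place("DOPC", 1, "M", "DOPC", np.array([20.0, 20.0, 10.0]))
        b.place("LYS", 2, "A", "protein_A",
                np.array([20.0, 20.0, 30.0 - 1.0 * t]))
        s, f = b.build(np.array([60.0, 60.0, 60.0]), time=float(t))
        system = system or s
        frames.append(f)
    from ibarlab.system_model import Trajectory
    traj = Trajectory(system, frames)
    result = G.first_contact_time(traj, PROTEIN_SEL, LIPID_SEL, cutoff=5.0)
    assert result is not None
    t_hit, residues = result
    # verify against per-frame brute-force minimum distance
    heavy_p = SelectionSpec(groups=("protein_A",), heavy_only=True)
    heavy_l = SelectionSpec(groups=("DOPC",), heavy_only=True)
    expected = next(f.time for f in frames if G.min_pair_distance(
        f, system, heavy_p, heavy_l) <= 5.0)
    assert t_hit == expected
    assert (2, "LYS") in residues
    # contact in frame 0
    assert G.first_contact_time(
        Trajectory(system, frames[::-1][:1]), PROTEIN_SEL, LIPID_SEL,
        cutoff=5.0)[0] == frames[-1].time
    # never within cutoff
    assert G.first_contact_time(
        Trajectory(system, frames[:3]), PROTEIN_SEL, LIPID_SEL,
        cutoff=2.0) is None
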
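"""Contact, salt-bridge and hydrogen-bond census."""

import numpy as np
import pytest

from ibarlab import interactions as I
from ibarlab import synthetic
from ibarlab.system_model import (LIPID_SEL, PROTEIN_SEL, SelectionSpec,
                                  Trajectory, minimum_image_distance)


def _pair_at(distance, protein="LYS", lipid="DOPC", patom="NZ", latom="O1P"):
    """Protein residue above a lipid with a chosen atom pair distance."""
    b = synthetic._Builder()
    anchor = np.array([20.0, 20.0, 20.0])
    loff = np.array([t[6:9] for t in synthetic._RECENTRED[lipid]
                     if t[0] == latom][0])
    poff = np.array([t[6:9] for t in synthetic._RECENTRED[protein]
                     if t[0] == patom][0])
    b.place(lipid, 1, "M", lipid, anchor - loff)
    b.place(protein, 2, "A", "protein_A",
            anchor + np.array([0, 0, distance]) - poff)
    return b.build(np.array([60.0, 60.0, 60.0]))


@pytest.mark.parametrize("d,expected", [(4.9, 1), (5.1, 0)])
def test_contact_cutoff_boundary(d, expected):
    system, frame = _pair_at(d, protein="SER", patom="OG")
    contacts = I.find_contacts(frame, system, PROTEIN_SEL, LIPID_SEL)
    assert len(contacts) == expected


@pytest.mark.parametrize("d,expected", [(3.1, 1), (3.3, 0)])
def test_salt_bridge_cutoff_boundary(d, expected):
    system, frame = _pair_at(d)
    bridges = I.find_salt_bridges(frame, system)
    assert len(bridges) == expected


def test_lys_to_glu_bridge_and_bidentate_dedup():
    # Lys NZ at 3.1 Å from Glu OE1: one intra-protein bridge even though
    # OE2 may also fall inside the cutoff (group-pair dedup)
    b = synthetic._Builder()
    anchor = np.array([20.0, 20.0, 20.0])
    oe1 = np.array([t[6:9] for t in synthetic._RECENTRED["GLU"]
                    if t[0] == "OE1"][0])
    nz = np.array([t[6:9] for t in synthetic._RECENTRED["LYS"]
                   if t[0] == "NZ"][0])
    b.place("GLU", 1, "A", "protein_A", anchor - oe1)
    b.place("LYS", 2, "A", "protein_A",
            anchor + np.array([0, 0, 3.1]) - nz)
    system, frame = b.build(np.array([60.0, 60.0, 60.0]))
    bridges = I.find_salt_bridges(frame, system)
    assert len(bridges) == 1
    assert bool(bridges["intra_protein"].iloc[0]) is True


def test_planted_interface_counts_exact():
    for k in (0, 7):
        system, frame, truth = synthetic.gen_planted_interface(k, 5, seed=3)
        bridges = I.find_salt_bridges(frame, system)
        contacts = I.find_contacts(frame, system, PROTEIN_SEL, LIPID_SEL)
        assert len(bridges) == k
        assert len(contacts) == truth["n_contact_pairs_total"]


def test_planted_interface_survives_wrapping():
    system, frame, truth = synthetic.gen_planted_interface(6, 4, seed=9)
    shifted = frame.coordinates + np.array([frame.box[0] * 0.7, 5.0, -8.0])
    wrapped = np.mod(shifted, frame.box)
    from ibarlab.system_model import Frame
    frame2 = Frame(wrapped, frame.box)
    assert len(I.find_salt_bridges(frame2, system)) == 6
    assert len(I.find_contacts(frame2, system, PROTEIN_SEL,
                               LIPID_SEL)) == 10


def test_contacts_match_brute_force(random_interface_system):
    system, frame = random_interface_system
    contacts = I.find_contacts(frame, system, PROTEIN_SEL, LIPID_SEL, 5.0)
    found = {(r.segment, r.residue_id, r.lipid_id)
             for r in contacts.itertuples()}
    a = system.atoms
    brute = set()
    heavy = system.heavy_mask
    prot = np.isin(system.groups, ("protein_A", "protein_B")) & heavy
    lip = np.isin(system.groups, ("DOPC", "DOPE", "DOPS")) & heavy
    for i in np.flatnonzero(prot):
        for j in np.flatnonzero(lip):
            d = minimum_image_distance(frame.coordinates[i],
                                       frame.coordinates[j], frame.box)
            if d <= 5.0:
                brute.add((a["segment"].iloc[i], a["residue_id"].iloc[i],
                           a["residue_id"].iloc[j]))
    assert found == brute


def test_every_salt_bridge_is_a_contact(random_interface_system):
    system, frame = random_interface_system
    bridges = I.find_salt_bridges(frame, system)
    contacts = I.find_contacts(frame, system, PROTEIN_SEL, LIPID_SEL)
    cpairs = {(r.residue_id, r.lipid_id) for r in contacts.itertuples()}
    for r in bridges.itertuples():
        if r.intra_protein:
            continue
        pair = ((r.basic_id, r.acidic_id)
                if r.basic_group.startswith("protein")
                else (r.acidic_id, r.basic_id))
        assert pair in cpairs


def test_bridge_count_monotone_in_cutoff(random_interface_system):
    system, frame = random_interface_system
    counts = [len(I.find_salt_bridges(frame, system, cutoff=c))
              for c in (2.0, 3.2, 5.0, 8.0)]
    assert counts == sorted(counts)


def test_census_invariant_under_rigid_motion_and_reordering():
    system, frame, _ = synthetic.gen_planted_interface(5, 3, seed=1)
    ref_b = len(I.find_salt_bridges(frame, system))
    ref_c = len(I.find_contacts(frame, system, PROTEIN_SEL, LIPID_SEL))
    phi = 0.7
    rot = np.array([[np.cos(phi), -np.sin(phi), 0],
                    [np.sin(phi), np.cos(phi), 0], [0, 0, 1]])
    center = frame.box / 2
    moved = (frame.coordinates - center) @ rot.T + center + [3.0, -2.0, 1.0]
    from ibarlab.system_model import Frame
    frame2 = Frame(np.mod(moved, frame.box), frame.box)
    assert len(I.find_salt_bridges(frame2, system)) == ref_b
    assert len(I.find_contacts(frame2, system, PROTEIN_SEL,
                               LIPID_SEL)) == ref_c


def test_hydrogen_bond_geometry():
    # linear D-H...A at d(D...A)=2.9 detected; 90° rejected
    import pandas as pd
    from ibarlab.system_model import Frame, SystemModel

    def hb_system(acceptor_pos):
        atoms = pd.DataFrame({
            "atom_id": [1, 2, 3], "name": ["OG", "HG", "OE1"],
            "element": ["O", "H", "O"],
            "residue_name": ["SER", "SER", "GLU"],
            "residue_id": [1, 1, 2], "segment": ["A", "A", "A"],
            "mass": [15.999, 1.008, 15.999], "charge": 0.0,
            "lj_epsilon": 0.1, "lj_rmin_half": 1.7,
            "group": ["protein_A"] * 3})
        coords = np.array([[10.0, 10, 10], [11.0, 10, 10], acceptor_pos])
        return SystemModel(atoms), Frame(coords, [30.0, 30.0, 30.0])

    donors = [("SER", "OG", "HG")]
    acceptors = [("GLU", "OE1")]
    system, frame = hb_system([12.9, 10.0, 10.0])    # linear
    assert len(I.find_hydrogen_bonds(frame, system, donors, acceptors)) == 1
    system, frame = hb_system([11.0, 12.0, 10.0])    # 90° at H
    assert len(I.find_hydrogen_bonds(frame, system, donors, acceptors)) == 0


def test_tally_constant_interface_has_zero_sd():
    system, frame, truth = synthetic.gen_planted_interface(4, 2, seed=5)
    frames = [type(frame)(frame.coordinates.copy(), frame.box, time=float(t))
              for t in range(10)]
    traj = Trajectory(system, frames)
    tally = I.tally_interface(traj, PROTEIN_SEL, LIPID_SEL)
    totals = tally.totals.set_index("quantity")
    assert totals.loc["protein_lipid_bridges", "mean"] == 4.0
    assert totals.loc["protein_lipid_bridges", "sd"] == 0.0
    assert totals.loc["contacts", "mean"] == 6.0
    lys = tally.by_residue_type.set_index("residue_name")
    assert lys.loc["LYS", "bridges_mean"] == 4.0


def test_tally_empty_interface_is_all_zero():
    system, frame, _ = synthetic.gen_planted_interface(0, 0, seed=2)
    frames = [type(frame)(frame.coordinates.copy(), frame.box, time=float(t))
              for t in range(3)]
    tally = I.tally_interface(Trajectory(system, frames), PROTEIN_SEL,
                              LIPID_SEL)
    totals = tally.totals.set_index("quantity")
    assert totals.loc["contacts", "mean"] == 0.0
    assert totals.loc["protein_lipid_bridges", "mean"] == 0.0
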
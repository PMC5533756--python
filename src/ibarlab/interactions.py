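"""Protein–lipid interface census: contacts, salt bridges, hydrogen bonds,
and windowed per-type tallies.

Criteria: a residue contacts a lipid when any heavy-atom pair is within
5 Å; a salt bridge forms when any basic nitrogen is within 3.2 Å of any
acidic oxygen.  Salt bridges are deduplicated at the group-pair level, so
a bidentate arginine–phosphate interaction counts once.  The quaternary
choline nitrogen of DOPC counts as a basic nitrogen (a zwitterionic lipid
can therefore bridge to protein acidic oxygens).  All distances use the
minimum-image convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import constants as C
from .system_model import (Frame, LIPID_GROUPS, PROTEIN_GROUPS, SelectionSpec,
                           SystemModel, Trajectory, minimum_image_distance,
                           wrap_coordinates)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupDefinitions:
    """Basic-nitrogen and acidic-oxygen atom names per residue/lipid type.

    Histidine and chain termini are excluded by default; protonation is an
    input, not predicted.
    """

    basic: dict = field(default_factory=lambda: {
        "LYS": ("NZ",),
        "ARG": ("NE", "NH1", "NH2"),
        "DOPC": ("N",),   # quaternary choline N
        "DOPE": ("N",),   # ammonium N
        "DOPS": ("N",),   # ammonium N
    })
    acidic: dict = field(default_factory=lambda: {
        "ASP": ("OD1", "OD2"),
        "GLU": ("OE1", "OE2"),
        "DOPC": ("O1P", "O2P", "O3P", "O4P"),
        "DOPE": ("O1P", "O2P", "O3P", "O4P"),
        "DOPS": ("O1P", "O2P", "O3P", "O4P", "OC1", "OC2"),
    })


DEFAULT_GROUP_DEFS = GroupDefinitions()


def _wrapped(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    w = wrap_coordinates(coords, box)
    return np.where(w >= box, 0.0, w)


def _cross_pairs(frame: Frame, idx_a: np.ndarray, idx_b: np.ndarray,
                 cutoff: float):
    """All (i, j, distance) with i in idx_a, j in idx_b within cutoff
    (minimum image)."""
    if idx_a.size == 0 or idx_b.size == 0:
        return np.empty(0, int), np.empty(0, int), np.empty(0)
    box = frame.box
    pa = _wrapped(frame.coordinates[idx_a], box)
    pb = _wrapped(frame.coordinates[idx_b], box)
    tree_a = cKDTree(pa, boxsize=box)
    tree_b = cKDTree(pb, boxsize=box)
    hits = tree_a.query_ball_tree(tree_b, r=cutoff)
    ii, jj = [], []
    for i, lst in enumerate(hits):
        ii.extend([i] * len(lst))
        jj.extend(lst)
    if not ii:
        return np.empty(0, int), np.empty(0, int), np.empty(0)
    ii = np.asarray(ii)
    jj = np.asarray(jj)
    d = minimum_image_distance(frame.coordinates[idx_a[ii]],
                               frame.coordinates[idx_b[jj]], box)
    keep = d <= cutoff
    return idx_a[ii[keep]], idx_b[jj[keep]], d[keep]


def find_contacts(frame: Frame, system: SystemModel,
                  protein_sel: SelectionSpec, lipid_sel: SelectionSpec,
                  cutoff: float = C.CONTACT_CUTOFF) -> pd.DataFrame:
    """Residue–lipid contact records for one frame.

    One row per (protein residue, lipid) pair with any heavy-atom pair
    distance ≤ cutoff; the row carries the minimum distance.
    """
    heavy_p = SelectionSpec(protein_sel.groups, protein_sel.residue_ids,
                            protein_sel.names, heavy_only=True)
    heavy_l = SelectionSpec(lipid_sel.groups, lipid_sel.residue_ids,
                            lipid_sel.names, heavy_only=True)
    ip, il, d = _cross_pairs(frame, heavy_p.indices(system),
                             heavy_l.indices(system), cutoff)
    cols = ["residue_id", "residue_name", "segment", "lipid_id", "lipid_type",
            "distance", "time"]
    if ip.size == 0:
        return pd.DataFrame(columns=cols)
    a = system.atoms
    df = pd.DataFrame({
        "residue_id": a["residue_id"].to_numpy()[ip],
        "residue_name": a["residue_name"].to_numpy()[ip],
        "segment": a["segment"].to_numpy()[ip],
        "lipid_id": a["residue_id"].to_numpy()[il],
        "lipid_type": a["residue_name"].to_numpy()[il],
        "distance": d,
    })
    out = (df.groupby(["segment", "residue_id", "residue_name",
                       "lipid_id", "lipid_type"], as_index=False)["distance"]
           .min())
    out["time"] = frame.time
    return out[cols]


def _typed_atoms(system: SystemModel, type_map: dict) -> np.ndarray:
    """Indices of atoms whose (residue_name, name) appear in type_map."""
    a = system.atoms
    keep = np.zeros(len(a), dtype=bool)
    seen_types = set(a["residue_name"].unique())
    for resname, names in type_map.items():
        if resname not in seen_types:
            logger.warning("group definition for unknown residue type %s "
                           "skipped", resname)
            continue
        keep |= ((a["residue_name"] == resname)
                 & a["name"].isin(names)).to_numpy()
    return np.flatnonzero(keep)


def find_salt_bridges(frame: Frame, system: SystemModel,
                      group_definitions: GroupDefinitions = DEFAULT_GROUP_DEFS,
                      cutoff: float = C.SALT_BRIDGE_CUTOFF) -> pd.DataFrame:
    """Salt-bridge records for one frame, deduplicated per group pair.

    A group is a residue or lipid instance keyed by (segment, residue_id);
    same-residue N/O pairs (intramolecular zwitterions) are excluded.
    """
    ib = _typed_atoms(system, group_definitions.basic)
    ia = _typed_atoms(system, group_definitions.acidic)
    bi, ai, d = _cross_pairs(frame, ib, ia, cutoff)
    cols = ["basic_segment", "basic_id", "basic_name", "acidic_segment",
            "acidic_id", "acidic_name", "distance", "intra_protein", "time"]
    if bi.size == 0:
        return pd.DataFrame(columns=cols)
    a = system.atoms
    df = pd.DataFrame({
        "basic_segment": a["segment"].to_numpy()[bi],
        "basic_id": a["residue_id"].to_numpy()[bi],
        "basic_name": a["residue_name"].to_numpy()[bi],
        "basic_group": a["group"].to_numpy()[bi],
        "acidic_segment": a["segment"].to_numpy()[ai],
        "acidic_id": a["residue_id"].to_numpy()[ai],
        "acidic_name": a["residue_name"].to_numpy()[ai],
        "acidic_group": a["group"].to_numpy()[ai],
        "distance": d,
    })
    same = ((df["basic_segment"] == df["acidic_segment"])
            & (df["basic_id"] == df["acidic_id"]))
    df = df[~same]
    if df.empty:
        return pd.DataFrame(columns=cols)
    out = (df.groupby(["basic_segment", "basic_id", "basic_name",
                       "basic_group", "acidic_segment", "acidic_id",
                       "acidic_name", "acidic_group"],
                      as_index=False)["distance"].min())
    out["intra_protein"] = (out["basic_group"].isin(PROTEIN_GROUPS)
                            & out["acidic_group"].isin(PROTEIN_GROUPS))
    out["time"] = frame.time
    return out[cols + ["basic_group", "acidic_group"]]


def find_hydrogen_bonds(frame: Frame, system: SystemModel,
                        donors: list[tuple[str, str, str]],
                        acceptors: list[tuple[str, str]],
                        d_cut: float = C.HBOND_DIST_CUTOFF,
                        angle_cut: float = C.HBOND_ANGLE_CUTOFF) -> pd.DataFrame:
    """Geometric hydrogen bonds: d(D···A) ≤ d_cut and ∠D–H···A ≥ angle_cut.

    ``donors`` lists (residue_name, donor_atom, hydrogen_atom) triples;
    ``acceptors`` lists (residue_name, acceptor_atom) pairs.  Donors whose
    hydrogen is missing in a residue are skipped with a warning.
    """
    a = system.atoms
    # map (segment, resid, name) -> atom row index
    key_index = {(s, r, n): i for i, (s, r, n) in enumerate(
        zip(a["segment"], a["residue_id"], a["name"]))}
    donor_rows = []  # (D index, H index)
    for resname, dname, hname in donors:
        rows = a.index[(a["residue_name"] == resname) & (a["name"] == dname)]
        for i in rows:
            hkey = (a["segment"].iloc[i], a["residue_id"].iloc[i], hname)
            if hkey not in key_index:
                logger.warning("donor %s %s/%d lacks hydrogen %s; skipped",
                               resname, dname, a["residue_id"].iloc[i], hname)
                continue
            donor_rows.append((i, key_index[hkey]))
    acc_idx = _typed_atoms(system, {rn: tuple(n for r, n in acceptors
                                              if r == rn)
                                    for rn, _ in acceptors})
    cols = ["donor_segment", "donor_id", "donor_name", "donor_atom",
            "hydrogen_atom", "acceptor_segment", "acceptor_id",
            "acceptor_name", "acceptor_atom", "distance", "angle", "time"]
    if not donor_rows or acc_idx.size == 0:
        return pd.DataFrame(columns=cols)
    di = np.array([d for d, _ in donor_rows])
    hi = np.array([h for _, h in donor_rows])
    pi, ai_, d = _cross_pairs(frame, di, acc_idx, d_cut)
    if pi.size == 0:
        return pd.DataFrame(columns=cols)
    h_of = dict(zip(di, hi))
    rows = []
    box = frame.box
    from .system_model import minimum_image_displacement
    for dd, aa, dist in zip(pi, ai_, d):
        if (a["segment"].iloc[dd] == a["segment"].iloc[aa]
                and a["residue_id"].iloc[dd] == a["residue_id"].iloc[aa]):
            continue
        hh = h_of[dd]
        # D-H...A angle at the hydrogen, minimum-image H->A vector
        hd = frame.coordinates[dd] - frame.coordinates[hh]
        ha = minimum_image_displacement(frame.coordinates[hh],
                                        frame.coordinates[aa], box)
        cos_dha = np.dot(hd, ha) / (np.linalg.norm(hd) * np.linalg.norm(ha))
        angle = float(np.degrees(np.arccos(np.clip(cos_dha, -1, 1))))
        if angle < angle_cut:
            continue
        rows.append((a["segment"].iloc[dd], int(a["residue_id"].iloc[dd]),
                     a["residue_name"].iloc[dd], a["name"].iloc[dd],
                     a["name"].iloc[hh], a["segment"].iloc[aa],
                     int(a["residue_id"].iloc[aa]), a["residue_name"].iloc[aa],
                     a["name"].iloc[aa], float(dist), angle, frame.time))
    return pd.DataFrame(rows, columns=cols)


@dataclass
class InterfaceTally:
    """Windowed mean ± sd interface composition."""

    by_residue_type: pd.DataFrame  # residue_name, contacts_mean/sd, bridges_mean/sd
    by_lipid_type: pd.DataFrame    # lipid_type, residues_mean/sd, bridges_mean/sd
    totals: pd.DataFrame           # quantity, mean, sd
    n_frames: int


def tally_interface(trajectory: Trajectory, protein_sel: SelectionSpec,
                    lipid_sel: SelectionSpec,
                    group_definitions: GroupDefinitions = DEFAULT_GROUP_DEFS,
                    contact_cutoff: float = C.CONTACT_CUTOFF,
                    bridge_cutoff: float = C.SALT_BRIDGE_CUTOFF,
                    window: tuple[float, float] | None = None) -> InterfaceTally:
    """Aggregate per-frame contact and protein–lipid salt-bridge counts over a
    frame window into mean ± sample sd, keyed by amino-acid and lipid type."""
    frames = [f for f in trajectory
              if window is None or window[0] <= f.time <= window[1]]
    if len(frames) < 2:
        raise ValueError("tally window must contain at least 2 frames")
    system = trajectory.system
    res_counts, lip_counts, res_bridges, lip_bridges, totals = [], [], [], [], []
    for f in frames:
        contacts = find_contacts(f, system, protein_sel, lipid_sel,
                                 contact_cutoff)
        bridges = find_salt_bridges(f, system, group_definitions,
                                    bridge_cutoff)
        pl = bridges[~bridges["intra_protein"]] if len(bridges) else bridges
        # drop lipid-lipid bridges: keep rows touching a protein group
        if len(pl):
            pl = pl[(pl["basic_group"].isin(PROTEIN_GROUPS))
                    | (pl["acidic_group"].isin(PROTEIN_GROUPS))]
        res_counts.append(contacts.groupby("residue_name").size()
                          if len(contacts) else pd.Series(dtype=int))
        lip_counts.append(
            contacts.groupby("lipid_type")
            .apply(lambda g: g[["segment", "residue_id"]]
                   .drop_duplicates().shape[0], include_groups=False)
            if len(contacts) else pd.Series(dtype=int))
        if len(pl):
            prot_res = np.where(pl["basic_group"].isin(PROTEIN_GROUPS),
                                pl["basic_name"], pl["acidic_name"])
            lip_res = np.where(pl["basic_group"].isin(LIPID_GROUPS),
                               pl["basic_name"], pl["acidic_name"])
            res_bridges.append(pd.Series(prot_res).value_counts())
            lip_bridges.append(pd.Series(lip_res).value_counts())
        else:
            res_bridges.append(pd.Series(dtype=int))
            lip_bridges.append(pd.Series(dtype=int))
        totals.append({"contacts": float(len(contacts)),
                       "protein_lipid_bridges": float(len(pl)),
                       "intra_protein_bridges":
                           float(bridges["intra_protein"].sum())
                           if len(bridges) else 0.0})

    def _stats(series_list):
        df = pd.DataFrame(series_list).astype(float).fillna(0.0)
        if df.empty:
            return pd.DataFrame(columns=["mean", "sd"], dtype=float)
        return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})

    res = _stats(res_counts).rename(
        columns={"mean": "contacts_mean", "sd": "contacts_sd"})
    resb = _stats(res_bridges).rename(
        columns={"mean": "bridges_mean", "sd": "bridges_sd"})
    by_res = res.join(resb, how="outer").fillna(0.0)
    by_res.index.name = "residue_name"

    lip = _stats(lip_counts).rename(
        columns={"mean": "residues_mean", "sd": "residues_sd"})
    lipb = _stats(lip_bridges).rename(
        columns={"mean": "bridges_mean", "sd": "bridges_sd"})
    by_lip = lip.join(lipb, how="outer").fillna(0.0)
    by_lip.index.name = "lipid_type"

    tot = pd.DataFrame(totals)
    totals_df = pd.DataFrame({"mean": tot.mean(), "sd": tot.std(ddof=1)})
    totals_df.index.name = "quantity"
    return InterfaceTally(by_res.reset_index(), by_lip.reset_index(),
                          totals_df.reset_index(), len(frames))
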
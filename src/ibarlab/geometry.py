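"""Binding-geometry observables.

Describes how the protein approaches and sits on the bilayer: mass-weighted
centers, principal axes of inertia, the orientation angle θ between the
second principal axis and the membrane normal (Z), the center-of-mass
separation D_Z and its offset ΔD_Z from a bound-state reference, the
Z-projected gap, the 3D minimum heavy-atom pair distance, and the first
membrane-contact time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .system_model import (Frame, SelectionSpec, SystemModel, Trajectory,
                           wrap_coordinates)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrientationState:
    """Binding geometry of one frame."""

    time: float          # ns
    theta: float         # degrees, [0, 90]
    d_z: float           # Å
    delta_d_z: float     # Å
    gap_z: float         # Å, >= 0
    min_pair_distance: float  # Å


def center_of_mass(frame: Frame, system: SystemModel,
                   selection: SelectionSpec) -> np.ndarray:
    """Mass-weighted mean position of the selected atoms (Å)."""
    idx = selection.indices(system)
    if idx.size == 0:
        raise ValueError("empty selection in center_of_mass")
    m = system.masses[idx]
    return (m[:, None] * frame.coordinates[idx]).sum(axis=0) / m.sum()


def inertia_tensor(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Inertia tensor about the center of mass."""
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    r = coords - com
    r2 = (r * r).sum(axis=1)
    eye = np.eye(3)
    tensor = (masses[:, None, None] *
              (r2[:, None, None] * eye - r[:, :, None] * r[:, None, :])).sum(axis=0)
    return tensor


def principal_axes(frame: Frame, system: SystemModel,
                   selection: SelectionSpec) -> np.ndarray:
    """Principal axes of inertia, rows ordered by ascending eigenvalue.

    Sign convention: each axis is flipped so its Z component is positive;
    if Z is (numerically) zero, the X then Y component decides.  Collinear
    point sets (vanishing smallest eigenvalue gap to a doubly degenerate
    pair with a zero) raise a ValueError.
    """
    idx = selection.indices(system)
    if idx.size < 3:
        raise ValueError("principal_axes needs at least 3 atoms")
    coords = frame.coordinates[idx]
    masses = system.masses[idx]
    tensor = inertia_tensor(coords, masses)
    evals, evecs = np.linalg.eigh(tensor)  # ascending
    # collinearity: all points on a line => smallest eigenvalue ~ 0 AND the
    # two largest are equal; detect via rank of centered coordinates
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    if np.linalg.matrix_rank(coords - com, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    axes = evecs.T.copy()
    for i in range(3):
        a = axes[i]
        for comp in (2, 0, 1):  # Z, then X, then Y decide the sign
            if abs(a[comp]) > 1e-12:
                if a[comp] < 0:
                    axes[i] = -a
                break
    return axes


def theta_angle(frame: Frame, system: SystemModel,
                protein_selection: SelectionSpec) -> float:
    """Angle θ (degrees, folded into [0, 90]) between the second principal
    axis of inertia of the selection and the Z axis."""
    axes = principal_axes(frame, system, protein_selection)
    cosv = abs(float(np.clip(axes[1] @ np.array([0.0, 0.0, 1.0]), -1, 1)))
    return float(np.degrees(np.arccos(cosv)))


def min_pair_distance(frame: Frame, system: SystemModel,
                      sel_a: SelectionSpec, sel_b: SelectionSpec,
                      return_pair: bool = False):
    """Minimum-image 3D minimum distance between two heavy-atom selections.

    Uses a periodic k-d tree; O((NA+NB) log NB).
    """
    ia = sel_a.indices(system)
    ib = sel_b.indices(system)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("empty selection in min_pair_distance")
    box = frame.box
    pa = wrap_coordinates(frame.coordinates[ia], box)
    pb = wrap_coordinates(frame.coordinates[ib], box)
    # guard against points landing exactly on the box edge after wrapping
    pa = np.where(pa >= box, 0.0, pa)
    pb = np.where(pb >= box, 0.0, pb)
    tree = cKDTree(pb, boxsize=box)
    dists, nearest = tree.query(pa, k=1)
    j = int(np.argmin(dists))
    if return_pair:
        return float(dists[j]), int(ia[j]), int(ib[nearest[j]])
    return float(dists[j])


def gap_z(frame: Frame, system: SystemModel,
          sel_a: SelectionSpec, sel_b: SelectionSpec) -> float:
    """Minimum heavy-atom pair separation projected on Z.

    Zero when the Z extents of the two selections interpenetrate.
    """
    ia = sel_a.indices(system)
    ib = sel_b.indices(system)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("empty selection in gap_z")
    za = frame.coordinates[ia, 2]
    zb = frame.coordinates[ib, 2]
    sep = max(za.min() - zb.max(), zb.min() - za.max())
    return float(max(0.0, sep))


def binding_coordinates(frame: Frame, system: SystemModel,
                        protein_sel: SelectionSpec,
                        membrane_sel: SelectionSpec,
                        reference_d_z: float = 0.0) -> OrientationState:
    """Full orientation state of one frame.

    ``d_z`` is the |Z| distance between the protein and membrane centers of
    mass; ``delta_d_z = d_z − reference_d_z`` with the reference anchored by
    configuration (free-energy global minimum, or a late-window average).
    """
    com_p = center_of_mass(frame, system, protein_sel)
    com_m = center_of_mass(frame, system, membrane_sel)
    d_z = abs(float(com_p[2] - com_m[2]))
    heavy_p = SelectionSpec(protein_sel.groups, protein_sel.residue_ids,
                            protein_sel.names, heavy_only=True)
    heavy_m = SelectionSpec(membrane_sel.groups, membrane_sel.residue_ids,
                            membrane_sel.names, heavy_only=True)
    return OrientationState(
        time=frame.time,
        theta=theta_angle(frame, system, protein_sel),
        d_z=d_z,
        delta_d_z=d_z - reference_d_z,
        gap_z=gap_z(frame, system, heavy_p, heavy_m),
        min_pair_distance=min_pair_distance(frame, system, heavy_p, heavy_m))


def orientation_series(trajectory: Trajectory, protein_sel: SelectionSpec,
                       membrane_sel: SelectionSpec,
                       reference_d_z: float = 0.0) -> pd.DataFrame:
    """Per-frame :func:`binding_coordinates` as a tidy DataFrame."""
    rows = [binding_coordinates(f, trajectory.system, protein_sel,
                                membrane_sel, reference_d_z)
            for f in trajectory]
    return pd.DataFrame([vars(r) for r in rows])


def first_contact_time(trajectory: Trajectory, protein_sel: SelectionSpec,
                       lipid_sel: SelectionSpec, cutoff: float = 5.0):
    """Earliest frame time at which any heavy-atom pair distance between the
    protein and the lipids is ≤ cutoff, with the contacting residue(s).

    Returns ``(time_ns, [(residue_id, residue_name), ...])`` or ``None`` if
    contact never occurs.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    system = trajectory.system
    heavy_p = SelectionSpec(protein_sel.groups, protein_sel.residue_ids,
                            protein_sel.names, heavy_only=True)
    heavy_l = SelectionSpec(lipid_sel.groups, lipid_sel.residue_ids,
                            lipid_sel.names, heavy_only=True)
    ip = heavy_p.indices(system)
    for frame in trajectory:
        d, ai, _ = min_pair_distance(frame, system, heavy_p, heavy_l,
                                     return_pair=True)
        if d <= cutoff:
            # all protein residues with an atom within cutoff at this frame
            box = frame.box
            pl = wrap_coordinates(frame.coordinates[heavy_l.indices(system)],
                                  box)
            pl = np.where(pl >= box, 0.0, pl)
            pp = wrap_coordinates(frame.coordinates[ip], box)
            pp = np.where(pp >= box, 0.0, pp)
            tree = cKDTree(pl, boxsize=box)
            dmin, _ = tree.query(pp, k=1)
            hit = ip[dmin <= cutoff]
            res = (system.atoms.iloc[hit][["residue_id", "residue_name"]]
                   .drop_duplicates())
            residues = [(int(r), str(n)) for r, n in
                        zip(res["residue_id"], res["residue_name"])]
            logger.info("first contact at t=%.3f ns via %s", frame.time,
                        residues)
            return frame.time, residues
    return None
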
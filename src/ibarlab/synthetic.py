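"""Seeded generators producing inputs with known ground truth for every
analysis stage.

These generators target statistical structure, not force-field physics: a
three-species bilayer leaflet point cloud (DOPC:DOPE:DOPS 4:4:1, 640/640/160
lipids by default) on flat or analytically curved surfaces, planted
contact/salt-bridge interfaces, 2D Brownian lipid motion, Gaussian
conformational ensembles with a prescribed mass-weighted covariance
spectrum, Metropolis-sampled umbrella windows over an analytic potential,
and a scripted end-to-end binding scene.  Identical configuration and seed
give bit-identical output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import constants as C
from .free_energy import UmbrellaWindow, paper_schedule
from .system_model import (Frame, SystemModel, Trajectory, write_pdb,
                           write_trajectory)

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# residue templates: name -> list of
#   (atom, element, mass, charge, eps, rmin_half, dx, dy, dz)
# Headgroup-atom offsets are recentred so the headgroup COM sits exactly
# at the placement point.
# ----------------------------------------------------------------------

_BACKBONE = [
    ("N", "N", 14.007, -0.30, 0.20, 1.85, -0.7, 0.6, 0.9),
    ("CA", "C", 12.011, 0.10, 0.07, 2.00, 0.0, 0.0, 0.8),
    ("C", "C", 12.011, 0.30, 0.07, 2.00, 0.7, -0.5, 0.9),
    ("O", "O", 15.999, -0.10, 0.12, 1.70, 1.2, 0.4, 1.4),
]

PROTEIN_TEMPLATES = {
    "GLY": _BACKBONE,
    "ALA": _BACKBONE + [("CB", "C", 12.011, 0.0, 0.07, 2.0, 0.0, 0.8, -0.2)],
    "SER": _BACKBONE + [("CB", "C", 12.011, 0.0, 0.07, 2.0, 0.0, 0.8, -0.2),
                        ("OG", "O", 15.999, 0.0, 0.12, 1.7, 0.0, 0.2, -1.5)],
    "LYS": _BACKBONE + [("CB", "C", 12.011, 0.0, 0.07, 2.0, 0.0, 0.8, -0.2),
                        ("NZ", "N", 14.007, 1.0, 0.20, 1.85, 0.0, 0.0, -1.5)],
    "ARG": _BACKBONE + [("CB", "C", 12.011, 0.0, 0.07, 2.0, 0.0, 0.8, -0.2),
                        ("NE", "N", 14.007, 0.30, 0.2, 1.85, -0.6, 0.1, -1.3),
                        ("NH1", "N", 14.007, 0.35, 0.2, 1.85, 0.6, 0.5, -1.5),
                        ("NH2", "N", 14.007, 0.35, 0.2, 1.85, 0.4, -0.6, -1.5)],
    "GLU": _BACKBONE + [("CB", "C", 12.011, 0.0, 0.07, 2.0, 0.0, 0.8, -0.2),
                        ("OE1", "O", 15.999, -0.5, 0.12, 1.7, -0.5, 0.3, -1.4),
                        ("OE2", "O", 15.999, -0.5, 0.12, 1.7, 0.5, -0.3, -1.5)],
    "ASP": _BACKBONE + [("CB", "C", 12.011, 0.0, 0.07, 2.0, 0.0, 0.8, -0.2),
                        ("OD1", "O", 15.999, -0.5, 0.12, 1.7, -0.5, 0.3, -1.4),
                        ("OD2", "O", 15.999, -0.5, 0.12, 1.7, 0.5, -0.3, -1.5)],
}

_PHOSPHATE = [
    ("P", "P", 30.974, 1.20, 0.585, 2.15, -0.4, -0.2, 0.1),
    ("O1P", "O", 15.999, -0.55, 0.12, 1.70, -1.2, 0.6, 0.4),
    ("O2P", "O", 15.999, -0.55, 0.12, 1.70, 0.3, -1.0, -0.2),
    ("O3P", "O", 15.999, -0.55, 0.12, 1.70, -0.3, 0.9, -0.7),
    ("O4P", "O", 15.999, -0.55, 0.12, 1.70, 0.9, -0.6, -0.5),
]
_LIPID_TAIL = [
    ("C1", "C", 12.011, 0.0, 0.07, 2.0, 0.5, 0.3, -2.0),
    ("CT1", "C", 12.011, 0.0, 0.07, 2.0, 0.2, 0.0, -4.0),
    ("CT2", "C", 12.011, 0.0, 0.07, 2.0, -0.2, 0.4, -6.0),
]

LIPID_TEMPLATES = {
    "DOPC": [("N", "N", 14.007, 1.0, 0.2, 1.85, 0.8, 0.5, 0.6)]
            + _PHOSPHATE + _LIPID_TAIL,
    "DOPE": [("N", "N", 14.007, 1.0, 0.2, 1.85, 0.8, 0.5, 0.6)]
            + _PHOSPHATE + _LIPID_TAIL,
    "DOPS": [("N", "N", 14.007, 1.0, 0.2, 1.85, 0.8, 0.5, 0.6)]
            + _PHOSPHATE
            + [("OC1", "O", 15.999, -0.5, 0.12, 1.7, 1.5, 0.8, 1.0),
               ("OC2", "O", 15.999, -0.5, 0.12, 1.7, 1.8, -0.4, 0.8)]
            + _LIPID_TAIL,
}

SOLVENT_TEMPLATES = {
    "TIP3": [("OH2", "O", 15.999, -0.834, 0.1521, 1.7682, 0.0, 0.0, 0.0),
             ("H1", "H", 1.008, 0.417, 0.046, 0.2245, 0.76, 0.0, 0.59),
             ("H2", "H", 1.008, 0.417, 0.046, 0.2245, -0.76, 0.0, 0.59)],
    "SOD": [("SOD", "Na", 22.990, 1.0, 0.0469, 1.41075, 0.0, 0.0, 0.0)],
    "CLA": [("CLA", "Cl", 35.453, -1.0, 0.150, 2.27, 0.0, 0.0, 0.0)],
}

TEMPLATES = {**PROTEIN_TEMPLATES, **LIPID_TEMPLATES, **SOLVENT_TEMPLATES}

_HEADGROUP_SETS = {
    "DOPC": ("N", "P", "O1P", "O2P", "O3P", "O4P"),
    "DOPE": ("N", "P", "O1P", "O2P", "O3P", "O4P"),
    "DOPS": ("N", "P", "O1P", "O2P", "O3P", "O4P", "OC1", "OC2"),
}


def _recentred_template(resname: str) -> list:
    """Template with offsets shifted so the headgroup COM (lipids) or the
    full-residue COM (everything else) is at the origin."""
    tpl = TEMPLATES[resname]
    anchor = _HEADGROUP_SETS.get(resname)
    rows = [t for t in tpl if anchor is None or t[0] in anchor]
    m = np.array([t[2] for t in rows])
    xyz = np.array([t[6:9] for t in rows])
    com = (m[:, None] * xyz).sum(axis=0) / m.sum()
    return [(n, e, ms, q, ep, rm, dx - com[0], dy - com[1], dz - com[2])
            for n, e, ms, q, ep, rm, dx, dy, dz in tpl]


_RECENTRED = {r: _recentred_template(r) for r in TEMPLATES}


def parameter_table(resnames=None) -> pd.DataFrame:
    """Sidecar nonbonded parameter table covering the template residues."""
    if resnames is None:
        resnames = sorted(TEMPLATES)
    rows = []
    for rn in resnames:
        for n, e, m, q, ep, rm, *_ in TEMPLATES[rn]:
            rows.append((rn, n, m, q, ep, rm))
    return pd.DataFrame(rows, columns=["residue_name", "atom_name", "mass",
                                       "charge", "epsilon", "rmin_half"])


@dataclass
class _Builder:
    """Accumulates placed residues into an atom table + coordinates."""

    rows: list = field(default_factory=list)
    coords: list = field(default_factory=list)
    next_atom_id: int = 1

    def place(self, resname: str, residue_id: int, segment: str, group: str,
              center: np.ndarray, z_rotation: float = 0.0,
              flip_z: bool = False) -> None:
        cz, sz = np.cos(z_rotation), np.sin(z_rotation)
        for n, e, m, q, ep, rm, dx, dy, dz in _RECENTRED[resname]:
            if flip_z:
                dz = -dz
            rx = cz * dx - sz * dy
            ry = sz * dx + cz * dy
            self.rows.append((self.next_atom_id, n, e, resname, residue_id,
                              segment, m, q, ep, rm, group))
            self.coords.append(center + np.array([rx, ry, dz]))
            self.next_atom_id += 1

    def build(self, box, time: float = 0.0) -> tuple[SystemModel, Frame]:
        atoms = pd.DataFrame(self.rows, columns=SystemModel.REQUIRED_COLUMNS)
        return SystemModel(atoms), Frame(np.array(self.coords), box, time)


@dataclass
class GeneratorConfig:
    """Shared generator configuration; defaults mirror the simulated study
    conditions (lipid composition, box, temperature, umbrella schedule)."""

    seed: int = 0
    box: tuple = (470.0, 90.0, 150.0)
    n_dopc: int = 640
    n_dope: int = 640
    n_dops: int = 160
    noise_sd: float = 0.3          # Å, headgroup Z roughness
    jitter: float = 1.5            # Å, lateral displacement off the lattice
    amplitude: float = 5.0         # Å, surface deformation
    wavelength: float | None = None  # Å, default = box X
    bump_width: float = 40.0       # Å, gaussian bump sigma
    bilayer_thickness: float = 38.0  # Å, headgroup-to-headgroup
    temperature: float = C.TEMPERATURE
    n_frames: int = 5


# ----------------------------------------------------------------------
# membrane surfaces
# ----------------------------------------------------------------------

def _surface_functions(shape: str, cfg: GeneratorConfig, box):
    a = cfg.amplitude
    lx = box[0]
    lam = cfg.wavelength or lx
    xc = lx / 2.0
    w = cfg.bump_width
    if shape == "flat":
        h = lambda x: np.zeros_like(np.asarray(x, float))
        hp = lambda x: np.zeros_like(np.asarray(x, float))
        hpp = lambda x: np.zeros_like(np.asarray(x, float))
    elif shape == "sinusoid":
        k = 2 * np.pi / lam
        h = lambda x: a * np.sin(k * np.asarray(x, float))
        hp = lambda x: a * k * np.cos(k * np.asarray(x, float))
        hpp = lambda x: -a * k * k * np.sin(k * np.asarray(x, float))
    elif shape == "gaussian_bump":
        h = lambda x: a * np.exp(-(np.asarray(x, float) - xc) ** 2 / (2 * w * w))
        hp = lambda x: h(x) * (-(np.asarray(x, float) - xc) / (w * w))
        hpp = lambda x: h(x) * (((np.asarray(x, float) - xc) ** 2 - w * w)
                                / w ** 4)
    else:
        raise ValueError(f"unknown surface shape {shape!r}")
    return h, hp, hpp


def gen_membrane_surface(shape: str = "flat",
                         config: GeneratorConfig | None = None):
    """Bilayer point cloud on an analytic surface with Gaussian Z noise.

    Both leaflets are generated (deformation on the upper, protein-facing
    leaflet; the lower is flat).  Returns ``(system, trajectory,
    curvature_fn, ground_truth)`` where ``curvature_fn(x)`` is the analytic
    signed curvature in nm⁻¹ (positive toward the protein above) and
    ground_truth records lipid counts and the apex curvature.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    box = np.array(cfg.box, float)
    h, hp, hpp = _surface_functions(shape, cfg, box)
    xs = np.linspace(0, box[0], 2048)
    if np.max(np.abs(hp(xs))) > 0.8:
        raise ValueError("surface slope too steep for a height field")

    def curvature_fn(x):
        return -hpp(x) / (1 + hp(x) ** 2) ** 1.5 * C.CURVATURE_A_TO_NM

    n_total = cfg.n_dopc + cfg.n_dope + cfg.n_dops
    if n_total % 2:
        raise ValueError("lipid counts must split evenly across leaflets")
    per_leaflet = n_total // 2
    types = (["DOPC"] * (cfg.n_dopc // 2) + ["DOPE"] * (cfg.n_dope // 2)
             + ["DOPS"] * (cfg.n_dops // 2))
    if len(types) != per_leaflet:
        raise ValueError("per-leaflet composition must be integral")

    # jittered lattice covering the box
    aspect = box[0] / box[1]
    ny = max(int(round(np.sqrt(per_leaflet / aspect))), 1)
    nx = int(np.ceil(per_leaflet / ny))
    gx = (np.arange(nx) + 0.5) * box[0] / nx
    gy = (np.arange(ny) + 0.5) * box[1] / ny
    sites = np.array([(x, y) for x in gx for y in gy])[:per_leaflet]

    z_mid = box[2] / 2.0
    z_up = z_mid + cfg.bilayer_thickness / 2.0
    z_lo = z_mid - cfg.bilayer_thickness / 2.0

    # fixed per-lipid identities/orientations; only thermal noise varies
    # between frames
    leaflet_state = {}
    for leaflet in ("upper", "lower"):
        leaflet_state[leaflet] = (rng.permutation(per_leaflet),
                                  rng.uniform(0, 2 * np.pi, per_leaflet))
    frames = []
    system = None
    for t in range(cfg.n_frames):
        b = _Builder()
        rid = 1
        for leaflet, zbase in (("upper", z_up), ("lower", z_lo)):
            order, rot = leaflet_state[leaflet]
            jitter = rng.uniform(-cfg.jitter, cfg.jitter,
                                 size=(per_leaflet, 2)) \
                if cfg.jitter else np.zeros((per_leaflet, 2))
            znoise = rng.normal(0.0, cfg.noise_sd, size=per_leaflet) \
                if cfg.noise_sd else np.zeros(per_leaflet)
            for i in range(per_leaflet):
                x, y = sites[i] + jitter[i]
                x = np.mod(x, box[0])
                y = np.mod(y, box[1])
                z = zbase + (h(x) if leaflet == "upper" else 0.0) + znoise[i]
                b.place(types[order[i]], rid, "M", types[order[i]],
                        np.array([x, y, z]), z_rotation=rot[i],
                        flip_z=(leaflet == "lower"))
                rid += 1
        sys_t, frame = b.build(box, time=float(t))
        if system is None:
            system = sys_t
        frames.append(frame)
    truth = {"n_dopc": cfg.n_dopc, "n_dope": cfg.n_dope, "n_dops": cfg.n_dops,
             "per_leaflet": per_leaflet, "shape": shape,
             "amplitude": cfg.amplitude,
             "apex_curvature_nm": float(np.max(curvature_fn(xs)))}
    return system, Trajectory(system, frames), curvature_fn, truth


# ----------------------------------------------------------------------
# planted interface
# ----------------------------------------------------------------------

def gen_planted_interface(n_bridges: int, n_contacts: int, seed: int = 0):
    """Interface with exactly ``n_bridges`` basic-N/acidic-O pairs at
    2.8–3.1 Å and ``n_contacts`` additional residue–lipid pairs at
    4.0–4.9 Å; distinct planted pairs are separated by >10 Å so no other
    residue–lipid pair is detectable.

    Bridges pair a LYS NZ with a lipid phosphate O1P; contact-only pairs
    use SER (no basic/acidic atoms) above a lipid.  Returns
    ``(system, frame, ground_truth)``.
    """
    rng = np.random.default_rng(seed)
    n_sites = n_bridges + n_contacts
    spacing = 16.0
    nx = max(int(np.ceil(np.sqrt(max(n_sites, 1)))), 2)
    ny = max(int(np.ceil(n_sites / nx)), 2)
    box = np.array([nx * spacing + spacing, ny * spacing + spacing, 60.0])
    b = _Builder()
    site = 0
    rid = 1
    lipid_cycle = ["DOPC", "DOPE", "DOPS"]
    z_lip = 20.0
    if n_sites == 0:
        # keep the system non-empty: one residue-lipid pair far apart
        b.place("DOPC", 1, "M", "DOPC", np.array([spacing, spacing, z_lip]))
        b.place("SER", 2, "A", "protein_A",
                np.array([spacing, spacing, z_lip + 15.0]))
        rid = 3
    for kind, count, dlo, dhi in (("bridge", n_bridges, 2.8, 3.1),
                                  ("contact", n_contacts, 4.0, 4.9)):
        for _ in range(count):
            cx = spacing * (site % nx) + spacing
            cy = spacing * (site // nx) + spacing
            d = rng.uniform(dlo, dhi)
            lipid = lipid_cycle[site % 3]
            # lipid placed so its O1P sits at the site anchor
            o1p = np.array([t[6:9] for t in _RECENTRED[lipid]
                            if t[0] == "O1P"][0])
            anchor = np.array([cx, cy, z_lip])
            b.place(lipid, rid, "M", lipid, anchor - o1p)
            rid_lipid = rid
            rid += 1
            resname = "LYS" if kind == "bridge" else "SER"
            target = "NZ" if kind == "bridge" else "OG"
            off = np.array([t[6:9] for t in _RECENTRED[resname]
                            if t[0] == target][0])
            b.place(resname, rid, "A", "protein_A",
                    anchor + np.array([0, 0, d]) - off)
            rid += 1
            site += 1
    if box[0] * box[1] < n_sites * spacing ** 2:
        raise ValueError("infeasible packing for requested counts")
    system, frame = b.build(box)
    truth = {"n_bridges": n_bridges, "n_contacts": n_contacts,
             "n_contact_pairs_total": n_bridges + n_contacts}
    return system, frame, truth


# ----------------------------------------------------------------------
# Brownian lipids
# ----------------------------------------------------------------------

def gen_brownian_lipids(diffusion: float, dt: float, n_steps: int,
                        n_lipids: int, box=(200.0, 200.0, 60.0),
                        seed: int = 0):
    """Independent 2D Brownian motion of single-point lipids.

    Increments are Gaussian with variance 2·D·dt per axis; Z is fixed.
    Returns ``(system, trajectory, ground_truth)`` with the closed-form
    ⟨Δr²(t)⟩ = 4·D·t as truth.  Diffusion in Å²/ns, dt in ns.
    """
    if diffusion < 0:
        raise ValueError("diffusion coefficient must be non-negative")
    rng = np.random.default_rng(seed)
    box = np.array(box, float)
    b = _Builder()
    start = rng.uniform([0, 0], box[:2], size=(n_lipids, 2))
    z0 = box[2] / 2.0
    for i in range(n_lipids):
        b.rows.append((i + 1, "P", "P", "DOPC", i + 1, "M",
                       30.974, 0.0, 0.585, 2.15, "DOPC"))
        b.coords.append(np.array([start[i, 0], start[i, 1], z0]))
    system, first = b.build(box, time=0.0)
    steps = rng.normal(0.0, np.sqrt(2 * diffusion * dt),
                       size=(n_steps, n_lipids, 2))
    pos = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    wrapped = np.mod(pos, box[:2])
    frames = []
    for t in range(n_steps + 1):
        coords = np.column_stack([wrapped[t], np.full(n_lipids, z0)])
        frames.append(Frame(coords, box, time=t * dt))
    truth = {"diffusion": diffusion, "dt": dt,
             "msd_slope": 4.0 * diffusion}
    return system, Trajectory(system, frames), truth


# ----------------------------------------------------------------------
# Gaussian conformational ensembles
# ----------------------------------------------------------------------

def gen_gaussian_ensemble(spectrum, masses, n_frames: int, seed: int = 0,
                          temperature: float = C.TEMPERATURE):
    """Frames from a multivariate Gaussian with prescribed mass-weighted
    covariance spectrum, rigid-body modes excluded by construction.

    Returns ``(system, trajectory, ground_truth)``; truth carries the input
    eigenvalues (Å²·amu) and the closed-form quasi-harmonic entropy.
    """
    from .thermo import ModeSpectrum, internal_entropy, _rigid_body_basis

    spectrum = np.asarray(spectrum, dtype=float)
    if np.any(spectrum <= 0):
        raise ValueError("covariance spectrum must be positive definite")
    n_modes = spectrum.size
    n_atoms = int(np.ceil((n_modes + 6) / 3))
    masses = np.broadcast_to(np.asarray(masses, dtype=float), (n_atoms,)).copy()
    rng = np.random.default_rng(seed)
    reference = rng.normal(0.0, 5.0, size=(n_atoms, 3)) + 100.0

    rigid = _rigid_body_basis(reference, masses)           # (3N, 6)
    rand = rng.normal(size=(3 * n_atoms, 3 * n_atoms - 6))
    full, _ = np.linalg.qr(np.hstack([rigid, rand]))
    modes = full[:, 6:6 + n_modes]                          # orthonormal

    z = rng.normal(size=(n_frames, n_modes)) * np.sqrt(spectrum)
    disp_mw = z @ modes.T                                   # mass-weighted
    disp = disp_mw.reshape(n_frames, n_atoms, 3) / np.sqrt(masses)[None, :, None]
    coords = reference[None] + disp
    if n_frames == 1:
        logger.warning("single-frame ensemble is degenerate for PCA")

    b = _Builder()
    for i in range(n_atoms):
        b.rows.append((i + 1, "CA", "C", "GLY", i + 1, "A", masses[i],
                       0.0, 0.07, 2.0, "protein_A"))
        b.coords.append(reference[i])
    box = np.array([200.0, 200.0, 200.0])
    system, _ = b.build(box)
    frames = [Frame(coords[t], box, time=t * 1e-3) for t in range(n_frames)]
    kt_amu = C.KB_KCAL * temperature * C.KCAL_TO_AMU_A2_PS2
    true_spec = ModeSpectrum(np.sort(spectrum)[::-1],
                             np.sqrt(kt_amu / np.sort(spectrum)[::-1]),
                             temperature, 0)
    truth = {"spectrum": spectrum.tolist(),
             "entropy_kcal_mol_K": internal_entropy(true_spec),
             "temperature": temperature}
    return system, Trajectory(system, frames), truth


# ----------------------------------------------------------------------
# umbrella-window sampling
# ----------------------------------------------------------------------

def double_well_pmf(x, depth_global: float = 8.6, depth_second: float = 6.0,
                    pos_second: float = 3.5, width_global: float = 1.2,
                    width_second: float = 0.8):
    """Analytic double-well binding profile (kcal/mol): a deep minimum at
    x = 0, a second minimum near ``pos_second``, and a flat unbound plateau
    at large x.  Defaults emulate the reported profile (global minimum
    −8.6 kcal/mol relative to the plateau; second minimum at 3.5 Å)."""
    x = np.asarray(x, dtype=float)
    return (-depth_global * np.exp(-x ** 2 / (2 * width_global ** 2))
            - depth_second * np.exp(-(x - pos_second) ** 2
                                    / (2 * width_second ** 2)))


def gen_umbrella_samples(analytic_pmf, schedule: pd.DataFrame | None = None,
                         n_per_window: int = 10000, seed: int = 0,
                         burn_in: int = 1000, span_ns: float = 10.0,
                         thin: int = 10,
                         temperature: float = C.TEMPERATURE):
    """Metropolis samples from exp(−β(U(x) + bias_k(x))) per window.

    Step sizes are tuned during burn-in to 30–60% acceptance (error if the
    final rates fall outside); the chain is thinned by ``thin`` steps per
    retained sample to suppress autocorrelation; timestamps span
    ``span_ns`` per window.
    """
    if schedule is None:
        schedule = paper_schedule(temperature=temperature)
    rng = np.random.default_rng(seed)
    centers = schedule["center"].to_numpy(float)
    ks = schedule["k"].to_numpy(float)
    kt = C.KB_KCAL * temperature
    n_win = len(centers)

    def total_u(x):
        return analytic_pmf(x) + 0.5 * ks * (x - centers) ** 2

    x = centers.copy()
    step = np.sqrt(kt / ks) * 2.0
    u_cur = total_u(x)
    acc_count = np.zeros(n_win)
    window_count = 0
    for it in range(burn_in):
        prop = x + rng.normal(size=n_win) * step
        u_prop = total_u(prop)
        accept = rng.random(n_win) < np.exp(np.minimum(0, -(u_prop - u_cur) / kt))
        x = np.where(accept, prop, x)
        u_cur = np.where(accept, u_prop, u_cur)
        acc_count += accept
        window_count += 1
        if (it + 1) % 100 == 0:
            rate = acc_count / window_count
            step = step * np.where(rate > 0.6, 1.3,
                                   np.where(rate < 0.3, 0.7, 1.0))
            acc_count[:] = 0.0
            window_count = 0

    samples = np.empty((n_per_window, n_win))
    acc = np.zeros(n_win)
    n_steps = n_per_window * max(thin, 1)
    for it in range(n_steps):
        prop = x + rng.normal(size=n_win) * step
        u_prop = total_u(prop)
        accept = rng.random(n_win) < np.exp(np.minimum(0, -(u_prop - u_cur) / kt))
        x = np.where(accept, prop, x)
        u_cur = np.where(accept, u_prop, u_cur)
        acc += accept
        if (it + 1) % max(thin, 1) == 0:
            samples[(it + 1) // max(thin, 1) - 1] = x
    rates = acc / n_steps
    if np.any(rates < 0.2) or np.any(rates > 0.7):
        raise RuntimeError(
            f"Metropolis acceptance outside bounds after tuning: "
            f"min {rates.min():.2f}, max {rates.max():.2f}")
    times = np.linspace(0.0, span_ns, n_per_window)
    return [UmbrellaWindow(centers[i], samples[:, i], ks[i], temperature,
                           times.copy())
            for i in range(n_win)]


# ----------------------------------------------------------------------
# scripted end-to-end binding trajectory
# ----------------------------------------------------------------------

@dataclass
class BindingScript:
    """Scripted ground truth of the composite binding scene."""

    theta: np.ndarray          # degrees per frame
    com_z: np.ndarray          # protein COM Z per frame, Å
    first_contact_frame: int
    first_contact_time: float  # ns
    contact_residue: tuple     # (residue_id, residue_name)
    final_apex_curvature_nm: float
    bump_amplitude: np.ndarray  # Å per frame


def gen_binding_trajectory(config: GeneratorConfig | None = None,
                           n_frames: int = 40, theta0: float = 30.0,
                           contact_cutoff: float = 5.0,
                           final_bump: float = 5.0, bump_width: float = 40.0,
                           membrane_noise: float = 0.0):
    """Composite scene: a rigid plate protein descending along Z with θ
    relaxing to 0, making first contact through a designated lysine, while
    the membrane develops a Gaussian bump under it.

    All observables (ΔD_Z(t), θ(t), contact onset, final curvature) are
    scripted and returned as ground truth.
    """
    cfg = config or GeneratorConfig(noise_sd=membrane_noise)
    cfg.noise_sd = membrane_noise
    cfg.amplitude = 0.0
    rng = np.random.default_rng(cfg.seed)
    box = np.array(cfg.box, float)
    xc, yc = box[0] / 2.0, box[1] / 2.0
    z_mid = box[2] / 2.0
    z_up = z_mid + cfg.bilayer_thickness / 2.0

    # --- static membrane sites (bump grows after contact) ---------------
    n_total = cfg.n_dopc + cfg.n_dope + cfg.n_dops
    per_leaflet = n_total // 2
    types = (["DOPC"] * (cfg.n_dopc // 2) + ["DOPE"] * (cfg.n_dope // 2)
             + ["DOPS"] * (cfg.n_dops // 2))
    aspect = box[0] / box[1]
    ny = max(int(round(np.sqrt(per_leaflet / aspect))), 1)
    nx = int(np.ceil(per_leaflet / ny))
    gx = (np.arange(nx) + 0.5) * box[0] / nx
    gy = (np.arange(ny) + 0.5) * box[1] / ny
    sites = np.array([(x, y) for x in gx for y in gy])[:per_leaflet]
    jitter = rng.uniform(-cfg.jitter, cfg.jitter, size=(per_leaflet, 2)) \
        if cfg.jitter else np.zeros((per_leaflet, 2))
    xy = np.mod(sites + jitter, box[:2])
    order = rng.permutation(per_leaflet)
    rot = rng.uniform(0, 2 * np.pi, per_leaflet)
    # contact lipid: nearest site to the scene center, pinned exactly there
    contact_lipid = int(np.argmin(((xy - [xc, yc]) ** 2).sum(axis=1)))
    xy[contact_lipid] = (xc, yc)
    rot[contact_lipid] = 0.0

    # --- protein plate: length along X, width along Z, thin along Y, so
    # the second principal axis (middle inertia eigenvalue) is the width
    # axis and points along Z in the bound state ------------------------
    length_p, width_p, thick_p = 100.0, 30.0, 6.0
    spacing = 5.0
    pnx = int(length_p / spacing) + 1
    pnz = int(width_p / spacing) + 1
    local = []
    res_info = []
    rid = 1
    for i in range(pnx):
        for jy in (-thick_p / 2, thick_p / 2):
            for kz in range(pnz):
                pos = np.array([i * spacing - length_p / 2, jy,
                                kz * spacing - width_p / 2])
                local.append(pos)
                seg = "A" if i < pnx // 2 else "B"
                res_info.append((rid, "ALA", seg))
                rid += 1
    local = np.array(local)
    # designated contact residue: LYS with NZ 3 Å below the plate's lower
    # edge, on the symmetry axis (keeps the inertia tensor diagonal)
    contact_rid = rid
    lys_nz_local = np.array([0.0, 0.0, -width_p / 2 - 3.0])

    # --- scripts ---------------------------------------------------------
    times = np.arange(n_frames, dtype=float)         # 1 ns per frame
    t_relax = 0.6 * (n_frames - 1)
    theta_t = theta0 * np.clip(1 - times / t_relax, 0.0, 1.0)
    z_contact = z_up + contact_cutoff - 0.6          # NZ height at contact+
    z_start = z_up + 25.0
    t_desc = 0.5 * (n_frames - 1)
    nz_z_t = np.maximum(z_contact,
                        z_start + (z_contact - z_start) * times / t_desc)
    # exact first-contact frame: NZ sits at (xc, yc); nearest membrane atom
    # is one of the pinned contact lipid's atoms at anchor + offset
    contact_type = types[order[contact_lipid]]
    offs = np.array([t[6:9] for t in _RECENTRED[contact_type]])
    d2 = (offs[:, 0] ** 2 + offs[:, 1] ** 2
          + (nz_z_t[:, None] - z_up - offs[:, 2]) ** 2)
    dist_t = np.sqrt(d2.min(axis=1))
    if not np.any(dist_t <= contact_cutoff):
        raise RuntimeError("scripted approach never reaches the cutoff")
    fc_frame = int(np.argmax(dist_t <= contact_cutoff))
    bump_t = final_bump * np.clip((times - fc_frame) / (0.3 * n_frames),
                                  0.0, 1.0)

    def bump(x, amp):
        return amp * np.exp(-(np.asarray(x, float) - xc) ** 2
                            / (2 * bump_width ** 2))

    apex_c = final_bump / bump_width ** 2 * C.CURVATURE_A_TO_NM

    frames = []
    system = None
    for f in range(n_frames):
        b = _Builder()
        rrid = 1
        amp = bump_t[f]
        znoise = rng.normal(0, cfg.noise_sd, per_leaflet) if cfg.noise_sd \
            else np.zeros(per_leaflet)
        for leaflet, zbase in (("upper", z_up),
                               ("lower", z_mid - cfg.bilayer_thickness / 2)):
            for i in range(per_leaflet):
                z = zbase + (bump(xy[i, 0], amp) if leaflet == "upper" else 0.0)
                if not (leaflet == "upper" and i == contact_lipid):
                    z += znoise[i]
                b.place(types[order[i]], rrid, "M", types[order[i]],
                        np.array([xy[i, 0], xy[i, 1], z]),
                        z_rotation=rot[i], flip_z=(leaflet == "lower"))
                rrid += 1
        # protein: rotate about X through COM by theta, then set NZ height
        th = np.radians(theta_t[f])
        rot_x = np.array([[1, 0, 0],
                          [0, np.cos(th), -np.sin(th)],
                          [0, np.sin(th), np.cos(th)]])
        pts = local @ rot_x.T
        nz = lys_nz_local @ rot_x.T
        # place so the LYS NZ sits at (xc, yc, nz_z) above the contact lipid
        nz_target = np.array([xc, yc, nz_z_t[f] + bump(xc, amp)])
        shift = nz_target - nz
        for (rid_i, rn, seg), p in zip(res_info, pts):
            pos = p + shift
            b.rows.append((b.next_atom_id, "CA", "C", rn, rid_i, seg,
                           12.011, 0.0, 0.07, 2.0,
                           "protein_A" if seg == "A" else "protein_B"))
            b.coords.append(pos)
            b.next_atom_id += 1
        b.rows.append((b.next_atom_id, "NZ", "N", "LYS", contact_rid, "A",
                       14.007, 1.0, 0.2, 1.85, "protein_A"))
        b.coords.append(nz_target)
        b.next_atom_id += 1
        sys_f, frame = b.build(box, time=times[f])
        if system is None:
            system = sys_f
        frames.append(frame)

    prot = np.isin(system.groups, ("protein_A", "protein_B"))
    pm = system.masses[prot]
    com_z = np.array([(pm * fr.coordinates[prot, 2]).sum() / pm.sum()
                      for fr in frames])
    script = BindingScript(theta_t, com_z, fc_frame, float(times[fc_frame]),
                           (contact_rid, "LYS"), float(apex_c), bump_t)
    return system, Trajectory(system, frames), script


# ----------------------------------------------------------------------
# bundle output (PDB + native frames + parameters + ground truth)
# ----------------------------------------------------------------------

def write_bundle(outdir: str | Path, system: SystemModel,
                 trajectory: Trajectory, ground_truth: dict) -> None:
    """Write system.pdb, params.tsv, traj.txt and ground_truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_pdb(system, trajectory[0], outdir / "system.pdb")
    resnames = sorted(set(system.atoms["residue_name"]))
    parameter_table([r for r in resnames if r in TEMPLATES]).to_csv(
        outdir / "params.tsv", sep="\t", index=False)
    write_trajectory(trajectory, outdir / "traj.txt")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(ground_truth, fh, indent=2, default=float)
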
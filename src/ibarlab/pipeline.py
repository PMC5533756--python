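"""Configuration-driven orchestration of the full analysis: binding
geometry, interface census, membrane profiles, energy decomposition and
(optionally) PMF and entropy, emitting deterministic TSV tables and a JSON
summary with provenance (config echo + hash, seeds, package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import constants as C
from . import energetics, free_energy, geometry, interactions, membrane
from .system_model import (LIPID_GROUPS, PROTEIN_GROUPS, SelectionSpec,
                           load_system, load_trajectory)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "structure": None,            # PDB path
    "parameters": None,           # TSV path
    "trajectory": None,           # native frame format path
    "windows": None,              # umbrella window directory (optional)
    "out": "ibarlab_out",
    "reference_d_z": 0.0,
    "contact_cutoff": C.CONTACT_CUTOFF,
    "salt_bridge_cutoff": C.SALT_BRIDGE_CUTOFF,
    "membrane_bins": 64,
    "y_half_width": C.Y_HALF_WIDTH,
    "smoothing_window": 5,
    "temperature": C.TEMPERATURE,
    "nb_cutoff": C.NB_CUTOFF,
    "nb_switch_on": C.NB_SWITCH_ON,
    "tally_window": None,         # [t0, t1] ns
    "msd_lag": None,              # ns (optional)
    "seed": 0,
}

_FLOAT_FMT = "%.6f"


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = {**DEFAULT_CONFIG, **user}
    return cfg


def _config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: dict) -> dict:
    """Run every applicable stage; returns the summary dict.

    Deterministic for fixed config and inputs; any stage failure aborts
    with the stage name and cause.
    """
    cfg = {**DEFAULT_CONFIG, **config}
    out = Path(cfg["out"])
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "config_hash": _config_hash(cfg),
                     "seed": cfg["seed"], "stages": []}

    def stage(name):
        logger.info("pipeline stage: %s", name)
        summary["stages"].append(name)

    try:
        stage("load")
        for key in ("structure", "parameters", "trajectory"):
            if cfg[key] is None or not Path(cfg[key]).exists():
                raise FileNotFoundError(
                    f"required input {key!r} missing: {cfg[key]}")
        system = load_system(cfg["structure"], cfg["parameters"])
        traj = load_trajectory(cfg["trajectory"], system)
    except Exception as exc:
        raise RuntimeError(f"stage 'load' failed: {exc}") from exc

    protein = SelectionSpec(groups=PROTEIN_GROUPS)
    lipids = SelectionSpec(groups=LIPID_GROUPS)
    has_protein = protein.indices(system).size > 0

    if has_protein:
        try:
            stage("geometry")
            orient = geometry.orientation_series(
                traj, protein, lipids, cfg["reference_d_z"])
            _write_tsv(orient, out / "orientation.tsv")
        except Exception as exc:
            raise RuntimeError(f"stage 'geometry' failed: {exc}") from exc

        try:
            stage("interface")
            window = tuple(cfg["tally_window"]) if cfg["tally_window"] else None
            tally = interactions.tally_interface(
                traj, protein, lipids,
                contact_cutoff=cfg["contact_cutoff"],
                bridge_cutoff=cfg["salt_bridge_cutoff"], window=window)
            _write_tsv(tally.by_residue_type, out / "tally_residue.tsv")
            _write_tsv(tally.by_lipid_type, out / "tally_lipid.tsv")
            _write_tsv(tally.totals, out / "tally_totals.tsv")
            bridges = pd.concat(
                [interactions.find_salt_bridges(
                    f, system, cutoff=cfg["salt_bridge_cutoff"])
                 for f in traj], ignore_index=True)
            _write_tsv(bridges[["time", "basic_segment", "basic_id",
                                "acidic_segment", "acidic_id", "distance",
                                "intra_protein"]], out / "bridges.tsv")
            tot = tally.totals.set_index("quantity")
            summary["salt_bridges_mean"] = float(
                tot.loc["protein_lipid_bridges", "mean"])
            summary["salt_bridges_sd"] = float(
                tot.loc["protein_lipid_bridges", "sd"])
            summary["contacts_mean"] = float(tot.loc["contacts", "mean"])
        except Exception as exc:
            raise RuntimeError(f"stage 'interface' failed: {exc}") from exc

    try:
        stage("membrane")
        frames = list(traj)
        surf = membrane.surface_profile(
            frames, system, n_bins=cfg["membrane_bins"],
            y_half_width=cfg["y_half_width"])
        foot = (membrane.protein_footprint(frames[-1], system, protein)
                if has_protein else None)
        curv = membrane.curvature_profile(
            surf, smoothing_window=cfg["smoothing_window"], footprint=foot)
        dens = membrane.local_density(
            frames, system, n_bins=cfg["membrane_bins"],
            y_half_width=cfg["y_half_width"])
        prof = pd.DataFrame({"x": surf.x_centers, "h": surf.height,
                             "curvature": curv.curvature,
                             "n_lipid": dens.n_lipid})
        if cfg["msd_lag"]:
            msd = membrane.lateral_msd(frames, system,
                                       lags=[cfg["msd_lag"]])
            summary["msd_at_lag"] = float(msd.msd[-1])
        _write_tsv(prof, out / "profiles.tsv")
        summary["c_ave_nm"] = curv.c_ave
        summary["c_max_nm"] = curv.c_max
        summary["diameter_from_c_max_nm"] = (
            membrane.curvature_to_diameter(curv.c_max)
            if curv.c_max != 0 else None)
        summary["diameter_from_c_ave_nm"] = (
            membrane.curvature_to_diameter(curv.c_ave)
            if curv.c_ave != 0 else None)
    except Exception as exc:
        raise RuntimeError(f"stage 'membrane' failed: {exc}") from exc

    if has_protein:
        try:
            stage("energy")
            emap = energetics.interaction_map(
                list(traj), system, protein,
                cutoff=cfg["nb_cutoff"], switch_on=cfg["nb_switch_on"])
            grid = pd.DataFrame(emap.grid)
            grid.to_csv(out / "energy_map.tsv", sep="\t", index=False,
                        float_format=_FLOAT_FMT)
            _write_tsv(pd.DataFrame({
                "x": 0.5 * (emap.x_edges[:-1] + emap.x_edges[1:]),
                "energy": emap.profile_x}), out / "energy_profile_x.tsv")
            summary["protein_lipid_energy_total"] = float(emap.grid.sum())
        except Exception as exc:
            raise RuntimeError(f"stage 'energy' failed: {exc}") from exc

    if cfg["windows"]:
        try:
            stage("pmf")
            windows = free_energy.read_windows(cfg["windows"])
            profile = free_energy.compute_pmf(windows)
            _write_tsv(pd.DataFrame({
                "delta_d_z": profile.bin_centers,
                "delta_g": profile.delta_g,
                "empty": profile.empty_bins}), out / "pmf.tsv")
            summary["pmf_minimum_position"] = profile.minimum_position
        except Exception as exc:
            raise RuntimeError(f"stage 'pmf' failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    logger.info("pipeline complete: %s", out / "summary.json")
    return summary
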
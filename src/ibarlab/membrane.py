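"""Membrane shape and dynamics from lipid headgroup positions.

The bilayer is described through the centers of mass of the lipid
headgroups (phosphate plus choline/ethanolamine/serine moiety).  The
protein-facing (upper) leaflet's height field h(X) — averaged over a Y
slab of configurable half-width — yields a 1D curvature profile
C(X) = h''/(1+h'^2)^{3/2}, reported in nm⁻¹ with the sign positive when
the membrane bends toward the protein.  Local lipid density N_lipid(X)
and the lateral (XY) mean-square displacement complete the Fig-level
observables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import constants as C
from .system_model import Frame, SystemModel

logger = logging.getLogger(__name__)

# default headgroup atom names per lipid type (phosphate + amine moiety)
DEFAULT_HEADGROUP_ATOMS = {
    "DOPC": ("N", "P", "O1P", "O2P", "O3P", "O4P"),
    "DOPE": ("N", "P", "O1P", "O2P", "O3P", "O4P"),
    "DOPS": ("N", "P", "O1P", "O2P", "O3P", "O4P", "OC1", "OC2"),
}


@dataclass
class SurfaceProfile:
    """Leaflet height field h(X) averaged over frames and a Y slab."""

    x_centers: np.ndarray   # Å
    height: np.ndarray      # Å, mean headgroup-COM Z per bin
    counts: np.ndarray      # samples per bin (all frames)
    interpolated: np.ndarray  # bool, bins filled from neighbours
    y_half_width: float     # Å
    box_x: float            # Å


@dataclass
class CurvatureProfile:
    """Signed curvature profile and footprint statistics, nm⁻¹."""

    x_centers: np.ndarray
    curvature: np.ndarray       # nm⁻¹, positive toward the protein
    c_ave: float                # nm⁻¹ over the binding footprint
    c_max: float                # nm⁻¹ over the binding footprint
    footprint: tuple[float, float]  # Å


@dataclass
class DensityProfile:
    x_centers: np.ndarray
    n_lipid: np.ndarray     # time-averaged count per bin


@dataclass
class MSDResult:
    lags: np.ndarray        # ns
    msd: np.ndarray         # Å²
    per_bin: pd.DataFrame | None = None  # lag x X-bin table


def headgroup_centers(frame: Frame, system: SystemModel,
                      headgroup_atoms: dict = DEFAULT_HEADGROUP_ATOMS,
                      lipid_ids: np.ndarray | None = None) -> pd.DataFrame:
    """Per-lipid headgroup center of mass.

    Returns a DataFrame with lipid_id, lipid_type, x, y, z (Å).
    """
    a = system.atoms
    keep = np.zeros(len(a), dtype=bool)
    for resname, names in headgroup_atoms.items():
        keep |= ((a["residue_name"] == resname)
                 & a["name"].isin(names)).to_numpy()
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError("no headgroup atoms found")
    sub = a.iloc[idx]
    m = system.masses[idx]
    xyz = frame.coordinates[idx]
    df = pd.DataFrame({"lipid_id": sub["residue_id"].to_numpy(),
                       "lipid_type": sub["residue_name"].to_numpy(),
                       "m": m, "mx": m * xyz[:, 0], "my": m * xyz[:, 1],
                       "mz": m * xyz[:, 2]})
    g = df.groupby(["lipid_id", "lipid_type"], as_index=False).sum()
    g["x"] = g["mx"] / g["m"]
    g["y"] = g["my"] / g["m"]
    g["z"] = g["mz"] / g["m"]
    out = g[["lipid_id", "lipid_type", "x", "y", "z"]]
    if lipid_ids is not None:
        out = out[out["lipid_id"].isin(lipid_ids)]
    return out.reset_index(drop=True)


def assign_leaflets(frame: Frame, system: SystemModel,
                    headgroup_atoms: dict = DEFAULT_HEADGROUP_ATOMS) -> pd.DataFrame:
    """Label each lipid upper/lower by headgroup-COM Z about the midplane.

    Midplane = median of all headgroup Z; ties (z == midplane) go upper.
    """
    hg = headgroup_centers(frame, system, headgroup_atoms)
    if len(hg) < 2:
        raise ValueError("need at least 2 lipids to assign leaflets")
    midplane = float(np.median(hg["z"]))
    hg = hg.copy()
    hg["leaflet"] = np.where(hg["z"] >= midplane, "upper", "lower")
    return hg


def surface_profile(frames: list[Frame], system: SystemModel,
                    leaflet: str = "upper", n_bins: int = 64,
                    y_half_width: float = C.Y_HALF_WIDTH,
                    headgroup_atoms: dict = DEFAULT_HEADGROUP_ATOMS,
                    y_center: float | None = None) -> SurfaceProfile:
    """Mean headgroup height h(X) of one leaflet over frames.

    Lipids outside the Y slab |y − y_center| ≤ y_half_width are ignored.
    Empty bins are filled by linear interpolation from neighbours and
    flagged.
    """
    if not frames:
        raise ValueError("need at least one frame")
    if n_bins < 8:
        raise ValueError("need at least 8 bins")
    box = frames[0].box
    yc = box[1] / 2.0 if y_center is None else y_center
    edges = np.linspace(0.0, box[0], n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    zsum = np.zeros(n_bins)
    count = np.zeros(n_bins, dtype=int)
    for frame in frames:
        lab = assign_leaflets(frame, system, headgroup_atoms)
        lab = lab[lab["leaflet"] == leaflet]
        dy = np.abs(lab["y"].to_numpy() - yc)
        dy = np.minimum(dy, box[1] - dy)
        lab = lab[dy <= y_half_width]
        x = np.mod(lab["x"].to_numpy(), box[0])
        which = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
        np.add.at(zsum, which, lab["z"].to_numpy())
        np.add.at(count, which, 1)
    if count.sum() == 0:
        raise ValueError("all bins empty")
    h = np.full(n_bins, np.nan)
    h[count > 0] = zsum[count > 0] / count[count > 0]
    interpolated = count == 0
    if interpolated.any():
        good = np.flatnonzero(~interpolated)
        # periodic linear interpolation across the box
        h = np.interp(centers, centers[good], h[good],
                      period=box[0])
        logger.info("interpolated %d empty surface bins",
                    int(interpolated.sum()))
    return SurfaceProfile(centers, h, count, interpolated, y_half_width,
                          float(box[0]))


def _periodic_moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.copy()
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    k = window // 2
    ext = np.concatenate([y[-k:], y, y[:k]])
    kernel = np.ones(window) / window
    return np.convolve(ext, kernel, mode="valid")


def curvature_profile(surface: SurfaceProfile, smoothing_window: int = 5,
                      footprint: tuple[float, float] | None = None,
                      protein_above: bool = True) -> CurvatureProfile:
    """Signed 1D curvature of the leaflet height field.

    h(X) is smoothed by an odd-width periodic moving average; derivatives
    are periodic central differences; C = h''/(1+h'^2)^{3/2} converted to
    nm⁻¹ and signed positive when the membrane bends toward the protein
    (above the leaflet by default).  C_ave / C_max are taken over the
    binding footprint (whole box if None).
    """
    n = len(surface.x_centers)
    if n - int(surface.interpolated.sum()) < 5:
        raise ValueError("need at least 5 usable bins")
    dx = surface.box_x / n
    h = _periodic_moving_average(surface.height, smoothing_window)
    hp = (np.roll(h, -1) - np.roll(h, 1)) / (2 * dx)
    hpp = (np.roll(h, -1) - 2 * h + np.roll(h, 1)) / dx**2
    curv = hpp / (1 + hp**2) ** 1.5
    sign = -1.0 if protein_above else 1.0
    curv = sign * curv * C.CURVATURE_A_TO_NM
    if footprint is None:
        footprint = (0.0, surface.box_x)
    if footprint[0] < -dx or footprint[1] > surface.box_x + dx:
        raise ValueError("footprint outside box")
    inside = ((surface.x_centers >= footprint[0])
              & (surface.x_centers <= footprint[1]))
    if not inside.any():
        raise ValueError("footprint contains no bins")
    return CurvatureProfile(surface.x_centers, curv,
                            float(curv[inside].mean()),
                            float(curv[inside].max()),
                            (float(footprint[0]), float(footprint[1])))


def curvature_to_diameter(curvature_nm: float) -> float:
    """Tubule diameter (nm) corresponding to a curvature (nm⁻¹): d = 2/C."""
    if curvature_nm == 0:
        raise ValueError("curvature of 0 has no finite diameter")
    return 2.0 / abs(curvature_nm)


def protein_footprint(frame: Frame, system: SystemModel,
                      protein_sel) -> tuple[float, float]:
    """X-range of the protein's heavy-atom projection (binding footprint)."""
    from .system_model import SelectionSpec
    heavy = SelectionSpec(protein_sel.groups, protein_sel.residue_ids,
                          protein_sel.names, heavy_only=True)
    idx = heavy.indices(system)
    if idx.size == 0:
        raise ValueError("empty protein selection")
    x = np.mod(frame.coordinates[idx, 0], frame.box[0])
    return float(x.min()), float(x.max())


def local_density(frames: list[Frame], system: SystemModel,
                  leaflet: str = "upper", n_bins: int = 64,
                  y_half_width: float = C.Y_HALF_WIDTH,
                  headgroup_atoms: dict = DEFAULT_HEADGROUP_ATOMS,
                  y_center: float | None = None) -> DensityProfile:
    """Time-averaged headgroup count per X bin within the Y slab."""
    if not frames:
        raise ValueError("need at least one frame")
    box = frames[0].box
    yc = box[1] / 2.0 if y_center is None else y_center
    edges = np.linspace(0.0, box[0], n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros(n_bins)
    for frame in frames:
        lab = assign_leaflets(frame, system, headgroup_atoms)
        lab = lab[lab["leaflet"] == leaflet]
        dy = np.abs(lab["y"].to_numpy() - yc)
        dy = np.minimum(dy, box[1] - dy)
        lab = lab[dy <= y_half_width]
        x = np.mod(lab["x"].to_numpy(), box[0])
        which = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
        np.add.at(counts, which, 1.0)
    return DensityProfile(centers, counts / len(frames))


def _unwrap(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Unwrap an (F, L, 2|3) lateral position series across periodic images."""
    steps = np.diff(positions, axis=0)
    steps -= box * np.round(steps / box)
    out = np.empty_like(positions)
    out[0] = positions[0]
    out[1:] = positions[0] + np.cumsum(steps, axis=0)
    return out


def lateral_msd(frames: list[Frame], system: SystemModel,
                lags: np.ndarray | list[float] | None = None,
                leaflet: str | None = "upper",
                headgroup_atoms: dict = DEFAULT_HEADGROUP_ATOMS,
                origin_stride: int = 1, n_x_bins: int | None = None,
                remove_drift: bool = True) -> MSDResult:
    """Lateral (XY) mean-square displacement of lipid headgroup centers.

    Coordinates are unwrapped across periodic images, the leaflet
    center-of-geometry drift removed, and displacements averaged over
    lipids and multiple time origins (stride ≥ 1 frame).  The per-X-bin
    variant assigns each lipid by its origin-frame bin.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames for MSD")
    box = frames[0].box
    times = np.array([f.time for f in frames])
    dt = times[1] - times[0]
    if not np.allclose(np.diff(times), dt):
        raise ValueError("MSD requires evenly spaced frames")

    first = assign_leaflets(frames[0], system, headgroup_atoms)
    if leaflet is not None:
        first = first[first["leaflet"] == leaflet]
    ids = first["lipid_id"].to_numpy()
    pos = np.empty((len(frames), len(ids), 2))
    for t, frame in enumerate(frames):
        hg = headgroup_centers(frame, system, headgroup_atoms, lipid_ids=ids)
        hg = hg.set_index("lipid_id").loc[ids]
        pos[t, :, 0] = hg["x"].to_numpy()
        pos[t, :, 1] = hg["y"].to_numpy()
    pos = _unwrap(pos, box[:2])
    if remove_drift:
        pos = pos - pos.mean(axis=1, keepdims=True)

    if lags is None:
        max_lag = (len(frames) - 1) // 2
        lag_frames = np.arange(0, max(max_lag, 1) + 1)
    else:
        lag_frames = np.array([int(round(l / dt)) for l in np.atleast_1d(lags)])
        if np.any(lag_frames > len(frames) - 1):
            raise ValueError("lag exceeds trajectory span")
    msd = np.zeros(len(lag_frames))
    per_bin = None
    if n_x_bins:
        edges = np.linspace(0, box[0], n_x_bins + 1)
        bin_of = np.clip(np.digitize(np.mod(pos[0, :, 0], box[0]), edges) - 1,
                         0, n_x_bins - 1)
        per_bin_arr = np.zeros((len(lag_frames), n_x_bins))
    for k, lf in enumerate(lag_frames):
        if lf == 0:
            continue
        origins = np.arange(0, len(frames) - lf, origin_stride)
        disp = pos[origins + lf] - pos[origins]     # (O, L, 2)
        sq = (disp ** 2).sum(axis=-1)
        msd[k] = sq.mean()
        if n_x_bins:
            for b in range(n_x_bins):
                sel_b = bin_of == b
                per_bin_arr[k, b] = sq[:, sel_b].mean() if sel_b.any() else np.nan
    if n_x_bins:
        per_bin = pd.DataFrame(per_bin_arr, index=lag_frames * dt,
                               columns=0.5 * (edges[:-1] + edges[1:]))
    return MSDResult(lag_frames * dt, msd, per_bin)
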
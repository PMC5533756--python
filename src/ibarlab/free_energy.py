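"""Umbrella-sampling free-energy profiles along ΔD_Z.

Windows carry harmonic biases 0.5·k·(x − x₀)² (default k = 50 kcal/mol/Å²,
centers −4.0…30.5 Å every 0.5 Å plus 3.6…3.9 Å every 0.1 Å).  Window free
energies f_k are obtained from the self-consistent multistate Bennett
acceptance ratio (MBAR) equations,

    f_k = −ln Σ_n exp(−u_k(x_n)) / Σ_l N_l exp(f_l − u_l(x_n)),

solved either by direct fixed-point iteration or (default) by damped
Newton–Raphson on the MBAR gradient, iterated to max|Δf| < 1e-8 kcal/mol.  The unbiased PMF is recovered by weighted
histogramming of the MBAR weights, anchored so the global minimum is zero.
A binned WHAM solver is provided as an internal cross-check, and blockwise
profiles (2/4/6/8/10 ns) serve as the convergence diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import constants as C

logger = logging.getLogger(__name__)


@dataclass
class UmbrellaWindow:
    """Samples of the reaction coordinate under one harmonic bias."""

    center: float                      # x0, Å
    samples: np.ndarray                # Å, retained samples
    k: float = C.UMBRELLA_K            # kcal/mol/Å^2
    temperature: float = C.TEMPERATURE  # K
    times: np.ndarray | None = None    # ns, per-sample timestamps
    equilibration_discard: float = 0.0  # ns already removed

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.k <= 0:
            raise ValueError("force constant must be positive")
        if self.samples.size < 1:
            raise ValueError("window must retain at least one sample")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != self.samples.shape:
                raise ValueError("times must match samples")


def bias_energy(window: UmbrellaWindow, x) -> np.ndarray:
    """Harmonic umbrella potential 0.5·k·(x − x₀)², kcal/mol."""
    x = np.asarray(x, dtype=float)
    return 0.5 * window.k * (x - window.center) ** 2


def paper_schedule(k: float = C.UMBRELLA_K,
                   temperature: float = C.TEMPERATURE) -> pd.DataFrame:
    """The umbrella window schedule: centers −4.0…30.5 Å every 0.5 Å plus
    3.6…3.9 Å every 0.1 Å, all with the same force constant."""
    centers = np.concatenate([np.arange(-4.0, 30.5 + 1e-9, 0.5),
                              np.array([3.6, 3.7, 3.8, 3.9])])
    centers = np.unique(np.round(centers, 6))
    return pd.DataFrame({"center": centers, "k": k,
                         "temperature": temperature})


@dataclass
class MBARResult:
    f: np.ndarray                     # window free energies, kcal/mol, f[0]=0
    n_iterations: int
    max_residual: float               # max |Δf| at exit, kcal/mol
    overlap_ok: bool
    disconnected_pairs: list = field(default_factory=list)


def _reduced_bias_matrix(windows: list[UmbrellaWindow]) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    temps = {w.temperature for w in windows}
    if len(temps) != 1:
        raise ValueError("all windows must share one temperature")
    kt = C.KB_KCAL * windows[0].temperature
    x = np.concatenate([w.samples for w in windows])
    n_k = np.array([w.samples.size for w in windows])
    centers = np.array([w.center for w in windows])
    ks = np.array([w.k for w in windows])
    u = 0.5 * ks[:, None] * (x[None, :] - centers[:, None]) ** 2 / kt
    return u, n_k, x, kt


def _check_overlap(windows: list[UmbrellaWindow]) -> list:
    """Adjacent windows (by center) whose sampled ranges do not overlap."""
    order = np.argsort([w.center for w in windows])
    bad = []
    for a, b in zip(order[:-1], order[1:]):
        if windows[a].samples.max() < windows[b].samples.min() or \
                windows[b].samples.max() < windows[a].samples.min():
            bad.append((float(windows[a].center), float(windows[b].center)))
    return bad


def mbar_solve(windows: list[UmbrellaWindow], tol: float = 1e-8,
               max_iter: int = 100000,
               method: str = "newton") -> MBARResult:
    """Solve the self-consistent MBAR equations for the window free
    energies f_k (kcal/mol, anchored f₀ = 0).

    ``method="self-consistent"`` runs pure fixed-point iteration;
    ``"newton"`` (default) takes damped Newton–Raphson steps on the MBAR
    gradient (K×K Hessian), falling back to fixed-point whenever a step does
    not reduce the gradient norm.  The two routes solve the same equations
    by different algorithms and serve as mutual cross-checks.
    """
    if len(windows) < 2:
        raise ValueError("need at least 2 windows")
    if method not in ("newton", "self-consistent"):
        raise ValueError(f"unknown method {method!r}")
    u, n_k, _, kt = _reduced_bias_matrix(windows)
    log_n = np.log(n_k)
    disconnected = _check_overlap(windows)
    if disconnected:
        logger.warning("non-overlapping adjacent windows: %s; free energies "
                       "will carry large uncertainty", disconnected)

    def log_denominator(f):
        return logsumexp(log_n[:, None] + f[:, None] - u, axis=0)

    def sc_from_denom(f, denom):
        f_new = -logsumexp(-u - denom[None, :], axis=1)
        return f_new - f_new[0]

    def grad_norm(f):
        denom = log_denominator(f)
        w = np.exp(log_n[:, None] + f[:, None] - u - denom[None, :])
        return float(np.linalg.norm(w.sum(axis=1) - n_k))

    f = np.zeros(len(windows))
    residual = np.inf
    converged = False
    for n_iter in range(1, max_iter + 1):
        denom = log_denominator(f)
        f_sc = sc_from_denom(f, denom)
        residual = float(np.max(np.abs((f_sc - f) * kt)))
        if residual < tol:
            f = f_sc
            converged = True
            break
        if method == "self-consistent":
            f = f_sc
            continue
        w = np.exp(log_n[:, None] + f[:, None] - u - denom[None, :])
        g = w.sum(axis=1) - n_k
        hess = np.diag(w.sum(axis=1)) - w @ w.T
        try:
            step = np.linalg.solve(hess[1:, 1:], -g[1:])
            f_newton = f + np.concatenate([[0.0], step])
            if np.all(np.isfinite(f_newton)) and \
                    grad_norm(f_newton) < np.linalg.norm(g):
                f = f_newton
                continue
        except np.linalg.LinAlgError:
            pass
        f = f_sc
    if not converged:
        raise RuntimeError(
            f"MBAR did not converge: residual {residual:.3e} kcal/mol after "
            f"{max_iter} iterations")
    if not np.all(np.isfinite(f)):
        raise RuntimeError("MBAR diverged to non-finite free energies")
    return MBARResult(f * kt, n_iter, residual, not disconnected,
                      disconnected)


@dataclass
class FreeEnergyProfile:
    """Unbiased free-energy profile ΔG_B(ΔD_Z), global minimum anchored 0."""

    bin_centers: np.ndarray
    delta_g: np.ndarray          # kcal/mol, NaN where empty
    empty_bins: np.ndarray       # bool mask
    window_f: np.ndarray         # kcal/mol
    temperature: float
    uncertainty: np.ndarray | None = None

    @property
    def minimum_position(self) -> float:
        return float(self.bin_centers[np.nanargmin(self.delta_g)])

    def value_at(self, x: float) -> float:
        """ΔG at the bin nearest x (kcal/mol)."""
        i = int(np.argmin(np.abs(self.bin_centers - x)))
        return float(self.delta_g[i])


def _mbar_log_weights(windows, f_kcal):
    u, n_k, x, kt = _reduced_bias_matrix(windows)
    f = f_kcal / kt
    denom = logsumexp(np.log(n_k)[:, None] + f[:, None] - u, axis=0)
    return x, -denom, kt


def pmf(windows: list[UmbrellaWindow], f_kcal: np.ndarray,
        bin_edges: np.ndarray, n_bootstrap: int = 0,
        seed: int | None = None) -> FreeEnergyProfile:
    """Unbiased PMF via MBAR weights, −k_BT ln p per bin, min anchored 0.

    Empty bins are flagged (NaN), never silently zero.  Optional block
    bootstrap over each window's time series gives per-bin uncertainties.
    """
    x, logw, kt = _mbar_log_weights(windows, f_kcal)
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])

    def profile_from(xv, lw):
        which = np.digitize(xv, bin_edges) - 1
        g = np.full(len(centers), np.nan)
        for i in range(len(centers)):
            m = which == i
            if m.any():
                g[i] = -kt * logsumexp(lw[m])
        g -= np.nanmin(g)
        return g

    g = profile_from(x, logw)
    unc = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_bootstrap):
            bw = []
            for w in windows:
                n = w.samples.size
                blk = max(n // 10, 1)
                starts = rng.integers(0, max(n - blk, 1) + 1,
                                      size=int(np.ceil(n / blk)))
                idx = np.concatenate([np.arange(s, s + blk) for s in starts])[:n]
                bw.append(UmbrellaWindow(w.center, w.samples[idx], w.k,
                                         w.temperature))
            fr = mbar_solve(bw, tol=1e-6)
            xb, lwb, _ = _mbar_log_weights(bw, fr.f)
            boots.append(profile_from(xb, lwb))
        unc = np.nanstd(np.array(boots), axis=0, ddof=1)
    return FreeEnergyProfile(centers, g, np.isnan(g),
                             np.asarray(f_kcal, float),
                             windows[0].temperature, unc)


def compute_pmf(windows: list[UmbrellaWindow],
                bin_width: float = 0.5, tol: float = 1e-8,
                method: str = "newton", n_bootstrap: int = 0,
                seed: int | None = None) -> FreeEnergyProfile:
    """Convenience wrapper: MBAR solve + PMF on a bin grid spanning the
    sampled range (default width 0.5 Å, matching the window spacing)."""
    result = mbar_solve(windows, tol=tol, method=method)
    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    # align bin centers with the window-center grid (multiples of bin_width)
    first = np.round(lo / bin_width) * bin_width
    if first - bin_width / 2 > lo:
        first -= bin_width
    edges = np.arange(first - bin_width / 2, hi + bin_width, bin_width)
    return pmf(windows, result.f, edges, n_bootstrap=n_bootstrap, seed=seed)


def wham(windows: list[UmbrellaWindow], bin_edges: np.ndarray,
         tol: float = 1e-10, max_iter: int = 200000) -> FreeEnergyProfile:
    """Binned WHAM solution on the same input; internal cross-check oracle
    for the MBAR route."""
    u, n_k, x, kt = _reduced_bias_matrix(windows)
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    hist = np.zeros((len(windows), len(centers)))
    for i, w in enumerate(windows):
        h, _ = np.histogram(w.samples, bins=bin_edges)
        hist[i] = h
    h_tot = hist.sum(axis=0)
    u_bias = 0.5 * np.array([w.k for w in windows])[:, None] * \
        (centers[None, :] - np.array([w.center for w in windows])[:, None]) ** 2 / kt
    f = np.zeros(len(windows))
    for it in range(max_iter):
        with np.errstate(divide="ignore", invalid="ignore"):
            log_denom = logsumexp(np.log(n_k)[:, None] + f[:, None] - u_bias,
                                  axis=0)
            log_p = np.where(h_tot > 0, np.log(h_tot) - log_denom, -np.inf)
        f_new = -logsumexp(log_p[None, :] - u_bias, axis=1)
        f_new -= f_new[0]
        if np.max(np.abs((f_new - f) * kt)) < tol:
            f = f_new
            break
        f = f_new
    g = np.where(h_tot > 0, -kt * log_p, np.nan)
    g -= np.nanmin(g)
    return FreeEnergyProfile(centers, g, np.isnan(g), f * kt,
                             windows[0].temperature)


def convergence_blocks(windows: list[UmbrellaWindow],
                       block_lengths: list[float] = (2.0, 4.0, 6.0, 8.0, 10.0),
                       bin_width: float = 0.5,
                       tol: float = 1e-8) -> tuple[dict, pd.DataFrame]:
    """PMFs from cumulative time blocks (default 2/4/6/8/10 ns) and the
    pairwise maximum-deviation table over commonly occupied bins."""
    for w in windows:
        if w.times is None:
            raise ValueError("convergence blocks need per-sample timestamps")
    spans = [w.times.max() - w.times.min() for w in windows]
    if max(block_lengths) > max(spans) + 1e-9:
        raise ValueError("block longer than available data")
    # shared bin grid from the full data so block profiles are comparable
    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    first = np.round(lo / bin_width) * bin_width
    if first - bin_width / 2 > lo:
        first -= bin_width
    edges = np.arange(first - bin_width / 2, hi + bin_width, bin_width)
    profiles = {}
    for L in block_lengths:
        sub = []
        for w in windows:
            m = w.times <= w.times.min() + L
            if not m.any():
                raise ValueError(f"window at {w.center} empty for block {L}")
            sub.append(UmbrellaWindow(w.center, w.samples[m], w.k,
                                      w.temperature, w.times[m]))
        result = mbar_solve(sub, tol=tol)
        profiles[L] = pmf(sub, result.f, edges)
    keys = list(profiles)
    dev = np.zeros((len(keys), len(keys)))
    for i, a in enumerate(keys):
        for j, b in enumerate(keys):
            ga, gb = profiles[a].delta_g, profiles[b].delta_g
            common = ~np.isnan(ga) & ~np.isnan(gb)
            dev[i, j] = float(np.max(np.abs(ga[common] - gb[common])))
    table = pd.DataFrame(dev, index=keys, columns=keys)
    return profiles, table


# ----------------------------------------------------------------------
# window TSV I/O (one file per window + a schedule file)
# ----------------------------------------------------------------------

def write_windows(windows: list[UmbrellaWindow], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sched = pd.DataFrame({
        "window": range(len(windows)),
        "center": [w.center for w in windows],
        "k": [w.k for w in windows],
        "temperature": [w.temperature for w in windows]})
    sched.to_csv(directory / "schedule.tsv", sep="\t", index=False)
    for i, w in enumerate(windows):
        t = w.times if w.times is not None else np.arange(w.samples.size,
                                                          dtype=float)
        pd.DataFrame({"time_ns": t, "x": w.samples}).to_csv(
            directory / f"window_{i:03d}.tsv", sep="\t", index=False)


def read_windows(directory: str | Path) -> list[UmbrellaWindow]:
    directory = Path(directory)
    sched = pd.read_csv(directory / "schedule.tsv", sep="\t")
    windows = []
    for _, row in sched.iterrows():
        df = pd.read_csv(directory / f"window_{int(row['window']):03d}.tsv",
                         sep="\t")
        windows.append(UmbrellaWindow(float(row["center"]),
                                      df["x"].to_numpy(),
                                      float(row["k"]),
                                      float(row["temperature"]),
                                      df["time_ns"].to_numpy()))
    return windows
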
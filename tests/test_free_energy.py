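"""MBAR solver, PMF reconstruction, WHAM cross-check, convergence blocks."""

import numpy as np
import pytest
from scipy.integrate import quad

from ibarlab import constants as C
from ibarlab import free_energy as FE
from ibarlab import synthetic

KT = C.KB_KCAL * 300.0


def test_bias_energy_values():
    w = FE.UmbrellaWindow(2.0, np.array([2.0]), k=50.0)
    assert FE.bias_energy(w, 3.0) == pytest.approx(25.0)
    assert FE.bias_energy(w, 2.0) == 0.0
    assert FE.bias_energy(w, 2.5) == pytest.approx(6.25)


def test_paper_schedule_window_count_and_spacing():
    sched = FE.paper_schedule()
    centers = sched["center"].to_numpy()
    assert centers.min() == -4.0 and centers.max() == 30.5
    assert {3.6, 3.7, 3.8, 3.9} <= set(np.round(centers, 6))
    assert (sched["k"] == 50.0).all()


def test_identical_windows_give_zero_free_energies():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 0.3, 400)
    ws = [FE.UmbrellaWindow(0.0, x), FE.UmbrellaWindow(0.0, x.copy())]
    r = FE.mbar_solve(ws)
    np.testing.assert_allclose(r.f, 0.0, atol=1e-10)


def test_two_gaussian_windows_match_analytic_normalization():
    # exact draws from the biased Gaussians of a flat landscape:
    # f_2 - f_1 = 0 analytically; agreement within 3 standard errors
    rng = np.random.default_rng(1)
    k, c1, c2, n = 50.0, 0.0, 0.3, 8000
    s = np.sqrt(KT / k)
    ws = [FE.UmbrellaWindow(c1, rng.normal(c1, s, n), k),
          FE.UmbrellaWindow(c2, rng.normal(c2, s, n), k)]
    r = FE.mbar_solve(ws)
    # overlap fraction sets the effective sample size
    n_eff = n * 2 * 0.1
    assert abs(r.f[1]) < 3 * KT / np.sqrt(n_eff)


def test_solver_routes_agree_to_1e6():
    rng = np.random.default_rng(2)
    k = 50.0
    s = np.sqrt(KT / k)
    ws = [FE.UmbrellaWindow(c, rng.normal(c, 1.5 * s, 2000), k)
          for c in (0.0, 0.25, 0.5, 0.75)]
    fa = FE.mbar_solve(ws, method="newton").f
    fb = FE.mbar_solve(ws, method="self-consistent").f
    np.testing.assert_allclose(fa, fb, atol=1e-6)


def test_window_free_energies_match_quadrature():
    # harmonic windows over a known potential: f_k from MBAR agree with
    # direct quadrature of the biased partition functions
    def u_fn(x):
        return 2.0 * (np.asarray(x) - 1.0) ** 2

    rng = np.random.default_rng(3)
    import pandas as pd
    sched = pd.DataFrame({"center": [0.0, 0.5, 1.0, 1.5, 2.0], "k": 20.0,
                          "temperature": 300.0})
    ws = synthetic.gen_umbrella_samples(u_fn, sched, n_per_window=4000,
                                        seed=3, thin=10)
    r = FE.mbar_solve(ws)
    fa = []
    for c in sched["center"]:
        val, _ = quad(lambda x: np.exp(-(u_fn(x) + 10.0 * (x - c) ** 2)
                                       / KT), c - 4, c + 4, limit=200)
        fa.append(-KT * np.log(val))
    fa = np.array(fa) - fa[0]
    np.testing.assert_allclose(r.f, fa, atol=0.1)


def test_pmf_recovers_quadratic_potential_from_unbiased_samples():
    # Boltzmann samples of U = 2(x-1)^2 via two zero-bias windows:
    # PMF ≈ U + const, deviation < 0.2 kcal/mol where well sampled
    rng = np.random.default_rng(4)
    sigma = np.sqrt(KT / 4.0)
    x = rng.normal(1.0, sigma, 50000)
    ws = [FE.UmbrellaWindow(1.0, x[:25000], k=1e-9),
          FE.UmbrellaWindow(1.0, x[25000:], k=1e-9)]
    r = FE.mbar_solve(ws)
    edges = np.linspace(1 - 2.5 * sigma, 1 + 2.5 * sigma, 25)
    prof = FE.pmf(ws, r.f, edges)
    u_ref = 2.0 * (prof.bin_centers - 1.0) ** 2
    u_ref -= u_ref.min()
    good = ~prof.empty_bins
    assert np.abs(prof.delta_g[good] - u_ref[good]).max() < 0.2


def test_pmf_minimum_anchored_at_zero_and_empty_bins_flagged():
    rng = np.random.default_rng(5)
    ws = [FE.UmbrellaWindow(0.0, rng.normal(0, 0.1, 1000)),
          FE.UmbrellaWindow(0.5, rng.normal(0.5, 0.1, 1000))]
    r = FE.mbar_solve(ws)
    edges = np.arange(-1.0, 2.1, 0.25)
    prof = FE.pmf(ws, r.f, edges)
    assert np.nanmin(prof.delta_g) == 0.0
    assert prof.empty_bins.any()
    assert np.isnan(prof.delta_g[prof.empty_bins]).all()


def test_translation_invariance_of_free_energies():
    # shifting all centers and samples together changes nothing
    rng = np.random.default_rng(6)
    s = np.sqrt(KT / 50.0)
    xs = [rng.normal(c, 1.5 * s, 1500) for c in (0.0, 0.3, 0.6)]
    ws = [FE.UmbrellaWindow(c, x) for c, x in zip((0.0, 0.3, 0.6), xs)]
    shifted = [FE.UmbrellaWindow(c + 7.0, x + 7.0)
               for c, x in zip((0.0, 0.3, 0.6), xs)]
    np.testing.assert_allclose(FE.mbar_solve(ws).f,
                               FE.mbar_solve(shifted).f, atol=1e-9)


def test_wham_agrees_with_mbar_within_statistical_error():
    ws = synthetic.gen_umbrella_samples(
        lambda x: 0.5 * np.asarray(x) ** 2,
        FE.paper_schedule().iloc[:12], n_per_window=3000, seed=7, thin=5)
    # WHAM evaluates the bias at bin centers, so its bins must be fine
    # relative to the bias variation (k = 50: 0.05 Å)
    edges = np.arange(-4.3, 1.85, 0.05)
    result = FE.mbar_solve(ws)
    prof = FE.pmf(ws, result.f, edges)
    whp = FE.wham(ws, edges)
    assert np.abs(whp.window_f - result.f).max() < 0.15
    common = ~np.isnan(prof.delta_g) & ~np.isnan(whp.delta_g)
    assert np.abs(prof.delta_g[common] - whp.delta_g[common]).max() < 0.3


def test_non_overlapping_windows_warn():
    rng = np.random.default_rng(8)
    ws = [FE.UmbrellaWindow(0.0, rng.normal(0, 0.05, 500)),
          FE.UmbrellaWindow(5.0, rng.normal(5, 0.05, 500))]
    r = FE.mbar_solve(ws)
    assert not r.overlap_ok
    assert r.disconnected_pairs == [(0.0, 5.0)]


def test_convergence_blocks_stationary_and_trend():
    def u_fn(x):
        return 0.5 * np.asarray(x) ** 2

    import pandas as pd
    sched = pd.DataFrame({"center": np.arange(0.0, 2.1, 0.5), "k": 50.0,
                          "temperature": 300.0})
    ws = synthetic.gen_umbrella_samples(u_fn, sched, n_per_window=4000,
                                        seed=9, thin=5)
    profiles, table = FE.convergence_blocks(ws, block_lengths=(2, 4, 6, 8, 10))
    # single block equal to the full span reproduces compute_pmf
    full = FE.compute_pmf(ws)
    np.testing.assert_allclose(profiles[10].delta_g, full.delta_g,
                               atol=1e-9, equal_nan=True)
    # stationary data: 6-ns and 10-ns blocks agree within the same
    # 0.3 kcal/mol bound used for barrier convergence
    assert table.loc[6, 10] < 0.3
    # planted trend: shift the first 2 ns of every window upward
    ws_bad = []
    for w in ws:
        x = w.samples.copy()
        x[w.times <= 2.0] += 0.35
        ws_bad.append(FE.UmbrellaWindow(w.center, x, w.k, w.temperature,
                                        w.times))
    _, table_bad = FE.convergence_blocks(ws_bad,
                                         block_lengths=(2, 4, 6, 8, 10))
    assert table_bad.loc[2, 10] > 3 * table.loc[2, 10]


def test_block_longer_than_data_raises():
    w = FE.UmbrellaWindow(0.0, np.random.default_rng(0).normal(0, 0.1, 100),
                          times=np.linspace(0, 1, 100))
    with pytest.raises(ValueError, match="block"):
        FE.convergence_blocks([w, w], block_lengths=(5.0,))


def test_window_tsv_roundtrip(tmp_path):
    ws = synthetic.gen_umbrella_samples(
        lambda x: np.zeros_like(np.asarray(x, float)),
        FE.paper_schedule().iloc[:3], n_per_window=50, seed=0, thin=1)
    FE.write_windows(ws, tmp_path)
    back = FE.read_windows(tmp_path)
    assert len(back) == 3
    np.testing.assert_allclose(back[1].samples, ws[1].samples)
    assert back[1].center == ws[1].center
    assert back[1].k == ws[1].k
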
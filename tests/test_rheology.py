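"""Green-Kubo relaxation modulus, Maxwell-mode fits, viscosity."""

import numpy as np
import pytest

from cgllps import rheology as rh
from cgllps.constants import BAR_PS_TO_MPA_S, KB, PRESSURE_KJ_NM3_TO_BAR
from cgllps.synthetic import synthetic_stress_series


def direct_autocorrelation(x, max_lag):
    n = len(x)
    return np.array(
        [np.dot(x[: n - k], x[k:]) / (n - k) for k in range(max_lag + 1)]
    )


def test_fft_autocorrelation_matches_direct_sum():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(257)  # odd length exercises the padding
    got = rh.autocorrelation(x, 40)
    ref = direct_autocorrelation(x, 40)
    assert np.allclose(got, ref, rtol=1e-10, atol=1e-12)


def make_series(times, comps, volume=1000.0, T=300.0):
    return rh.StressSeries(times, *comps, volume, T)


def test_stress_series_requires_uniform_times():
    t = np.array([0.0, 1.0, 2.5])
    z = np.zeros(3)
    with pytest.raises(rh.RheologyError):
        make_series(t, [z] * 6)


def test_constant_stress_gives_flat_modulus():
    # a constant shear stress has a constant (non-decaying) raw ACF
    t = np.arange(200.0)
    c = np.full(200, 2.0)
    z = np.zeros(200)
    series = make_series(t, [c, z, z, z, z, z])
    G = rh.relaxation_modulus(series, max_lag=20.0)
    pref = 1000.0 / (5 * KB * 300.0) / PRESSURE_KJ_NM3_TO_BAR
    assert np.allclose(G.G, pref * 4.0, rtol=1e-12)


def test_relaxation_modulus_isotropic_weighting():
    # equal independent white components: the normal differences contribute
    # (1/6) * 3 * 2 = 1 extra variance unit versus 3 from the off-diagonals
    rng = np.random.default_rng(1)
    comps = [rng.standard_normal(200000) for _ in range(6)]
    series = make_series(np.arange(200000.0), comps)
    G = rh.relaxation_modulus(series, max_lag=5.0)
    pref = 1000.0 / (5 * KB * 300.0) / PRESSURE_KJ_NM3_TO_BAR
    # lag-zero value: 3 * var + (1/6) * 3 * 2 var = 4 var
    assert G.G[0] == pytest.approx(pref * 4.0, rel=0.02)
    # later lags decorrelate to ~0
    assert abs(G.G[3]) < 0.02 * G.G[0]


def test_max_lag_must_fit_in_series():
    t = np.arange(10.0)
    z = np.zeros(10)
    series = make_series(t, [z] * 6)
    with pytest.raises(rh.RheologyError):
        rh.relaxation_modulus(series, max_lag=9.0)


def test_choose_t0_zero_for_monotone_modulus():
    t = np.linspace(0, 50, 501)
    G = rh.RelaxationModulus(t, 10.0 * np.exp(-t / 5.0))
    assert rh.choose_t0(G, smooth=1) == 0.0


def test_choose_t0_skips_negative_head():
    t = np.linspace(0, 50, 501)
    g = 10.0 * np.exp(-t / 5.0)
    g[:3] = -1.0  # corrupted head
    G = rh.RelaxationModulus(t, g)
    t0 = rh.choose_t0(G, smooth=1)
    assert t0 >= t[3]


def test_choose_t0_raises_when_never_monotone():
    rng = np.random.default_rng(0)
    t = np.linspace(0, 50, 501)
    G = rh.RelaxationModulus(t, rng.standard_normal(501))
    with pytest.raises(rh.RheologyError):
        rh.choose_t0(G, smooth=1)


def test_maxwell_grid_log_equidistant():
    taus = rh.maxwell_tau_grid(1.0, 1000.0, 7)
    ratios = taus[1:] / taus[:-1]
    assert np.allclose(ratios, ratios[0])
    assert taus[0] == 1.0 and taus[-1] == 1000.0


def test_default_mode_count_four_per_decade():
    assert rh.default_mode_count(1.0, 1000.0) == 12
    assert rh.default_mode_count(1.0, 10.0) == 4


def test_nnls_recovers_single_mode_on_grid():
    # tau = 10 lies exactly on the grid {1, 10, 100}: recovery is exact
    t = np.linspace(0, 100, 1001)
    G0, tau = 7.5, 10.0
    G = rh.RelaxationModulus(t, G0 * np.exp(-t / tau))
    taus = rh.maxwell_tau_grid(1.0, 100.0, 3)
    assert tau in taus
    spec = rh.fit_maxwell_modes(G, t0=1.0, M=3)
    k = np.argmin(np.abs(spec.tau_modes - tau))
    assert spec.G_modes[k] == pytest.approx(G0, rel=1e-8)
    others = np.delete(spec.G_modes, k)
    assert np.all(others < 1e-8 * G0)


def test_viscosity_equals_sum_G_tau_for_pure_maxwell_spectrum():
    # eta = G0 * tau exactly when the whole integral comes from the modes
    t = np.linspace(0, 300, 3001)
    G0, tau = 7.5, 10.0
    G = rh.RelaxationModulus(t, G0 * np.exp(-t / tau))
    spec = rh.MaxwellSpectrum(t0=0.0, G_modes=np.array([G0]), tau_modes=np.array([tau]))
    eta = rh.viscosity(G, spec)
    assert eta == pytest.approx(G0 * tau * BAR_PS_TO_MPA_S, rel=1e-14)


def test_hybrid_viscosity_matches_numeric_integral_within_percent():
    # multi-mode analytic modulus sampled densely over many decades
    t = np.arange(0.0, 2000.0, 0.05)
    modes = [(40.0, 2.0), (15.0, 20.0), (5.0, 120.0)]
    g = sum(G0 * np.exp(-t / tau) for G0, tau in modes)
    G = rh.RelaxationModulus(t, g)
    exact = sum(G0 * tau for G0, tau in modes) * BAR_PS_TO_MPA_S
    numeric = rh.numeric_viscosity(G)
    t0 = rh.choose_t0(G, smooth=1)
    spec = rh.fit_maxwell_modes(G, t0)
    hybrid = rh.viscosity(G, spec)
    assert numeric == pytest.approx(exact, rel=0.01)
    assert hybrid == pytest.approx(numeric, rel=0.01)
    assert hybrid == pytest.approx(exact, rel=0.01)


def test_ou_synthetic_viscosity_recovered_within_ten_percent():
    series, truth = synthetic_stress_series(
        [50.0, 20.0], [5.0, 50.0], dt=0.5, n_samples=2**18, seed=11
    )
    G = rh.relaxation_modulus(series, max_lag=400.0)
    t0 = rh.choose_t0(G)
    spec = rh.fit_maxwell_modes(G, t0)
    eta = rh.viscosity(G, spec)
    exact = truth["viscosity_bar_ps"] * BAR_PS_TO_MPA_S
    assert eta == pytest.approx(exact, rel=0.10)


def test_ou_modulus_matches_analytic_form():
    series, truth = synthetic_stress_series(
        [30.0], [10.0], dt=0.5, n_samples=2**18, seed=3
    )
    G = rh.relaxation_modulus(series, max_lag=30.0)
    analytic = 30.0 * np.exp(-G.times / 10.0)
    # statistical estimate: agree within a few percent of G(0)
    assert np.max(np.abs(G.G - analytic)) < 0.05 * 30.0


def test_viscosity_negative_raises():
    t = np.linspace(0, 10, 101)
    G = rh.RelaxationModulus(t, -np.ones(101))
    spec = rh.MaxwellSpectrum(t0=10.0, G_modes=np.array([0.0]), tau_modes=np.array([1.0]))
    with pytest.raises(rh.RheologyError):
        rh.viscosity(G, spec)


def test_stress_series_round_trip_frame():
    t = np.arange(5.0)
    comps = [np.arange(5.0) + i for i in range(6)]
    series = make_series(t, comps)
    df = series.to_frame()
    assert list(df.columns) == ["t_ps", "sxy", "sxz", "syz", "sxx", "syy", "szz"]
    assert np.allclose(df["syz"], comps[2])
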
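"""Green-Kubo viscosity from equilibrium stress fluctuations.

The shear-stress relaxation modulus G(t) is estimated from the
autocorrelation of the three off-diagonal pressure-tensor components plus,
for isotropic systems, the three normal-stress differences weighted by 1/6:

    G(t) = V / (5 kB T) [ <sxy(t) sxy(0)> + <sxz sxz> + <syz syz>
                          + (1/6)(<Nxy Nxy> + <Nxz Nxz> + <Nyz Nyz>) ]

with N_ab = s_aa - s_bb.  The zero-shear viscosity is the time integral of
G(t).  Because the long-time tail is noisy, the integral is split at a time
t0: below t0 it is evaluated by trapezoidal quadrature of the raw estimate,
above t0 G(t) is fitted by Maxwell modes G_i exp(-t/tau_i) with relaxation
times equidistant in logarithmic time and integrated analytically, giving

    eta = eta(t0) + sum_i G_i tau_i.

Stress components are carried in bar, times in ps; viscosities are reported
in mPa s (1 bar ps = 1e-4 mPa s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .constants import BAR_PS_TO_MPA_S, KB, PRESSURE_KJ_NM3_TO_BAR


class RheologyError(ValueError):
    pass


@dataclass
class StressSeries:
    """Six pressure-tensor components over time (bar), with box volume and T."""

    times: np.ndarray  # ps, uniformly spaced
    sxy: np.ndarray
    sxz: np.ndarray
    syz: np.ndarray
    sxx: np.ndarray
    syy: np.ndarray
    szz: np.ndarray
    volume: float  # nm^3
    temperature: float  # K

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        for name in ("sxy", "sxz", "syz", "sxx", "syy", "szz"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.volume <= 0 or self.temperature <= 0:
            raise RheologyError("volume and temperature must be positive")
        dt = np.diff(self.times)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
            raise RheologyError("stress series must be uniformly spaced in time")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_ps": self.times,
                "sxy": self.sxy,
                "sxz": self.sxz,
                "syz": self.syz,
                "sxx": self.sxx,
                "syy": self.syy,
                "szz": self.szz,
            }
        )

    @classmethod
    def from_csv(cls, path, volume: float, temperature: float) -> "StressSeries":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            df["t_ps"].to_numpy(),
            df["sxy"].to_numpy(),
            df["sxz"].to_numpy(),
            df["syz"].to_numpy(),
            df["sxx"].to_numpy(),
            df["syy"].to_numpy(),
            df["szz"].to_numpy(),
            volume,
            temperature,
        )


@dataclass
class RelaxationModulus:
    times: np.ndarray  # lag times, ps
    G: np.ndarray  # bar


@dataclass
class MaxwellSpectrum:
    t0: float  # ps
    G_modes: np.ndarray  # bar
    tau_modes: np.ndarray  # ps, strictly increasing, log-equidistant
    residual: float = 0.0
    condition: float = field(default=0.0)

    @property
    def n_modes(self) -> int:
        return len(self.G_modes)


def autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """FFT-based autocorrelation <x(t0) x(t0+t)> averaged over all origins."""
    n = len(x)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1]
    return acf / (n - np.arange(max_lag + 1))


def relaxation_modulus(stress: StressSeries, max_lag: float) -> RelaxationModulus:
    """Multi-component Green-Kubo estimate of G(t) up to lag ``max_lag`` (ps)."""
    span = stress.times[-1] - stress.times[0]
    if max_lag >= span:
        raise RheologyError(f"max_lag {max_lag} ps >= series span {span} ps")
    nlag = int(round(max_lag / stress.dt))
    acc = np.zeros(nlag + 1)
    for comp in (stress.sxy, stress.sxz, stress.syz):
        acc += autocorrelation(comp, nlag)
    for a, b in ((stress.sxx, stress.syy), (stress.sxx, stress.szz), (stress.syy, stress.szz)):
        n_ab = a - b
        acc += autocorrelation(n_ab, nlag) / 6.0
    # convert bar^2 -> internal, apply V/(5 kB T), convert back to bar
    prefactor = stress.volume / (5.0 * KB * stress.temperature) / PRESSURE_KJ_NM3_TO_BAR
    lags = np.arange(nlag + 1) * stress.dt
    return RelaxationModulus(lags, prefactor * acc)


def choose_t0(
    G: RelaxationModulus,
    window_decades: float = 1.0,
    smooth: int = 5,
    noise_tolerance: float = 0.05,
) -> float:
    """Earliest lag after which the smoothed modulus is strictly positive and
    decays monotonically over a sliding window of one decade in time.

    ``noise_tolerance`` allows upward fluctuations of that relative size in
    the smoothed signal so estimator noise does not defeat the criterion.
    """
    g = G.G
    if smooth > 1:
        kernel = np.ones(smooth)
        norm = np.convolve(np.ones_like(g), kernel, mode="same")
        g = np.convolve(g, kernel, mode="same") / norm
    n = len(g)
    t = G.times
    for k in range(n):
        if t[k] <= 0:
            hi = min(n, k + smooth + 1)
        else:
            t_end = t[k] * 10.0**window_decades
            hi = min(max(int(np.searchsorted(t, t_end, side="right")), k + 2), n)
        seg = g[k:hi]
        if len(seg) < 2:
            continue
        rises = np.diff(seg) - noise_tolerance * np.abs(seg[:-1])
        if np.all(seg > 0) and np.all(rises <= 1e-12 * max(abs(seg[0]), 1e-300)):
            return float(t[k])
    raise RheologyError(
        "no lag found after which G(t) is positive and monotonically decaying; "
        "a longer stress series is needed"
    )


def maxwell_tau_grid(t0: float, t_max: float, M: int) -> np.ndarray:
    """M relaxation times equidistant in log time spanning [t0, t_max]."""
    if M == 1:
        return np.array([np.sqrt(t0 * t_max)])
    return np.geomspace(t0, t_max, M)


def default_mode_count(t0: float, t_max: float, per_decade: float = 4.0) -> int:
    decades = max(np.log10(t_max / t0), 0.25)
    return max(int(np.ceil(per_decade * decades)), 1)


def fit_maxwell_modes(
    G: RelaxationModulus, t0: float, M: int | None = None
) -> MaxwellSpectrum:
    """Non-negative least-squares fit of Maxwell modes to G(t >= t0)."""
    if M is not None and M < 1:
        raise RheologyError("at least one Maxwell mode is required")
    t = G.times
    if t0 < t[0] or t0 > t[-1]:
        raise RheologyError(f"t0 = {t0} ps outside the lag range [{t[0]}, {t[-1]}]")
    sel = t >= t0
    ts, gs = t[sel], G.G[sel]
    eff_t0 = max(t0, ts[0], G.times[1])  # avoid a zero lower edge on the log grid
    if M is None:
        M = default_mode_count(eff_t0, ts[-1])
    taus = maxwell_tau_grid(eff_t0, ts[-1], M)
    design = np.exp(-ts[:, None] / taus[None, :])
    cond = np.linalg.cond(design)
    if cond > 1e12:
        warnings.warn(f"ill-conditioned Maxwell fit (cond ~ {cond:.2e})", stacklevel=2)
    coeffs, rnorm = nnls(design, gs)
    return MaxwellSpectrum(float(t0), coeffs, taus, residual=float(rnorm), condition=float(cond))


def numeric_viscosity(G: RelaxationModulus) -> float:
    """Plain trapezoidal Green-Kubo integral of G(t) over the full lag range (mPa s)."""
    return float(np.trapezoid(G.G, G.times)) * BAR_PS_TO_MPA_S


def viscosity(G: RelaxationModulus, spectrum: MaxwellSpectrum) -> float:
    """Hybrid viscosity: numeric integral on [0, t0] plus sum G_i tau_i (mPa s)."""
    sel = G.times <= spectrum.t0
    short = np.trapezoid(G.G[sel], G.times[sel]) if sel.sum() > 1 else 0.0
    long = float(np.dot(spectrum.G_modes, spectrum.tau_modes))
    eta = (short + long) * BAR_PS_TO_MPA_S
    if eta < 0:
        raise RheologyError(f"negative viscosity {eta}; the Maxwell fit is unreliable")
    return float(eta)
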
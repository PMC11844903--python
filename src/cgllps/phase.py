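"""Density profiles, coexistence densities, and critical-point extraction.

Direct-coexistence trajectories are reduced to mass-density profiles along
the long (z) axis.  Each frame is recentred on the dense slab before
averaging so slab drift does not smear the plateaus; recentring uses the
mass-weighted circular mean of the periodic z coordinate.  Coexistence
densities come from a two-interface hyperbolic-tangent fit of the averaged
profile.  The critical point is obtained from the law of critical exponents
and rectilinear diameters,

    (rho_l - rho_v)^alpha = s1 (1 - T/Tc),        alpha = 3.06
    (rho_l + rho_v)/2     = rho_c + s2 (Tc - T),

fitted jointly by nonlinear least squares with alpha held fixed.  The
printed exponent sits on the density difference itself (alpha ~ 1/beta with
beta ~ 0.327 of the 3D Ising class); the conventional form
rho_l - rho_v ~ (1 - T/Tc)^beta is equivalent and not silently substituted.
The Tc uncertainty is the spread of refits restricted to the last two,
three, and four temperatures below the critical point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .constants import MASS_DENSITY_TO_G_CM3
from .forcefield import ModelDefinition
from .system import Trajectory

ISING_ALPHA = 3.06


class PhaseAnalysisError(ValueError):
    pass


@dataclass
class DensityProfile:
    z: np.ndarray  # bin centres, nm
    density: np.ndarray  # g/cm^3
    n_frames: int
    box: np.ndarray  # nm

    @property
    def bin_width(self) -> float:
        return float(self.z[1] - self.z[0])

    def total_mass(self) -> float:
        """Integrated mass (g/mol), i.e. bin integral x cross-section."""
        cross = self.box[0] * self.box[1]
        return float(self.density.sum() * self.bin_width * cross / MASS_DENSITY_TO_G_CM3)


@dataclass
class CoexistencePoint:
    T: float  # K
    rho_l: float  # g/cm^3
    rho_v: float
    rho_l_err: float = 0.0
    rho_v_err: float = 0.0

    def __post_init__(self):
        if not self.rho_l > self.rho_v >= 0:
            raise PhaseAnalysisError(
                f"need rho_l > rho_v >= 0, got ({self.rho_l}, {self.rho_v})"
            )


@dataclass
class CoexistenceFit:
    """Result of the interface fit; ``single_phase`` signals a flat profile."""

    single_phase: bool
    rho_l: float | None = None
    rho_v: float | None = None
    rho_l_err: float = 0.0
    rho_v_err: float = 0.0
    interface_width: float = 0.0


@dataclass
class CriticalPoint:
    Tc: float  # K
    rho_c: float  # g/cm^3
    s1: float
    s2: float
    alpha: float = ISING_ALPHA
    Tc_err: float = 0.0


def _recentre_offsets(z: np.ndarray, weights: np.ndarray, Lz: float) -> float:
    """Mass-weighted circular mean of periodic z; the dense slab dominates."""
    theta = 2.0 * np.pi * z / Lz
    s = np.average(np.sin(theta), weights=weights)
    c = np.average(np.cos(theta), weights=weights)
    return (np.arctan2(s, c) % (2.0 * np.pi)) * Lz / (2.0 * np.pi)


def density_profile(
    trajectory: Trajectory,
    model: ModelDefinition,
    n_bins: int = 100,
    recentre: bool = True,
) -> DensityProfile:
    """Mass-density profile along z, averaged over recentred frames."""
    if len(trajectory) < 1:
        raise PhaseAnalysisError("trajectory holds no frames")
    if n_bins < 4:
        raise PhaseAnalysisError("need at least 4 bins")
    box = trajectory.frames[0].box
    Lz = float(box[2])
    edges = np.linspace(0.0, Lz, n_bins + 1)
    bin_volume = (edges[1] - edges[0]) * box[0] * box[1]
    acc = np.zeros(n_bins)
    masses = trajectory.frames[0].masses(model.residue_masses)
    for frame in trajectory:
        z = frame.positions[:, 2] % Lz
        if recentre:
            centre = _recentre_offsets(z, masses, Lz)
            z = (z - centre + 0.5 * Lz) % Lz
        hist, _ = np.histogram(z, bins=edges, weights=masses)
        acc += hist
    acc /= len(trajectory)
    density = acc / bin_volume * MASS_DENSITY_TO_G_CM3
    centres = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(centres, density, len(trajectory), np.asarray(box, float))


def _two_interface_tanh(z, rho_v, drho, z_lo, z_hi, width):
    return rho_v + 0.5 * drho * (
        np.tanh((z - z_lo) / width) - np.tanh((z - z_hi) / width)
    )


def coexistence_densities(
    profile: DensityProfile,
    contrast_threshold: float = 0.2,
) -> CoexistenceFit:
    """Plateau densities from a two-interface tanh fit of the profile.

    A profile whose high/low contrast is below ``contrast_threshold``
    (relative to its mean) is reported as single phase rather than forced
    through the interface fit.
    """
    z, rho = profile.z, profile.density
    lo = np.percentile(rho, 10)
    hi = np.percentile(rho, 90)
    mean = rho.mean()
    if mean <= 0 or (hi - lo) < contrast_threshold * mean:
        return CoexistenceFit(single_phase=True)
    Lz = profile.box[2]
    # initial guesses: dense slab centred after recentring
    dense = rho > 0.5 * (hi + lo)
    if dense.sum() < 2:
        return CoexistenceFit(single_phase=True)
    z_lo0 = z[dense][0]
    z_hi0 = z[dense][-1]
    p0 = [max(lo, 1e-12), hi - lo, z_lo0, z_hi0, max(2.0 * profile.bin_width, 0.5)]
    try:
        popt, pcov = curve_fit(
            _two_interface_tanh,
            z,
            rho,
            p0=p0,
            maxfev=20000,
            bounds=(
                [0.0, 0.0, 0.0, 0.0, 1e-6],
                [np.inf, np.inf, Lz, Lz, Lz],
            ),
        )
    except RuntimeError:
        return CoexistenceFit(single_phase=True)
    rho_v, drho, _, _, width = popt
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    rho_l = rho_v + drho
    if drho <= 0 or rho_l <= rho_v:
        return CoexistenceFit(single_phase=True)
    return CoexistenceFit(
        single_phase=False,
        rho_l=float(rho_l),
        rho_v=float(rho_v),
        rho_l_err=float(np.hypot(perr[0], perr[1])),
        rho_v_err=float(perr[0]),
        interface_width=float(width),
    )


def _critical_residuals(params, T, rho_l, rho_v, alpha):
    Tc, rho_c, s1, s2 = params
    r1 = (rho_l - rho_v) ** alpha - s1 * (1.0 - T / Tc)
    r2 = 0.5 * (rho_l + rho_v) - rho_c - s2 * (Tc - T)
    return np.concatenate([r1, r2])


def _fit_once(T, rho_l, rho_v, alpha):
    drho_a = (rho_l - rho_v) ** alpha
    # linear pre-fits give robust starting values
    A = np.vstack([np.ones_like(T), T]).T
    c1, m1 = np.linalg.lstsq(A, drho_a, rcond=None)[0]
    Tc0 = -c1 / m1 if m1 < 0 else T.max() * 1.05
    if not np.isfinite(Tc0) or Tc0 <= T.max():
        Tc0 = T.max() * 1.05
    s1_0 = max(drho_a.max(), 1e-6) / max(1.0 - T.min() / Tc0, 1e-6)
    mid = 0.5 * (rho_l + rho_v)
    c2, m2 = np.linalg.lstsq(A, mid, rcond=None)[0]
    s2_0 = -m2
    rho_c0 = c2 + m2 * Tc0
    res = least_squares(
        _critical_residuals,
        x0=[Tc0, max(rho_c0, 1e-6), s1_0, s2_0],
        args=(T, rho_l, rho_v, alpha),
        method="lm" if len(T) >= 2 else "trf",
        max_nfev=20000,
    )
    return res.x


def fit_critical_point(
    points: list[CoexistencePoint], alpha: float = ISING_ALPHA
) -> CriticalPoint:
    """Joint fit of the critical-exponent and rectilinear-diameter laws.

    Requires at least three subcritical coexistence points for the main fit;
    the Tc uncertainty is the spread of refits on the last two, three, and
    four temperatures (the points closest to the critical point).
    """
    if len(points) < 2:
        raise PhaseAnalysisError("at least two coexistence points are required")
    pts = sorted(points, key=lambda p: p.T)
    T = np.array([p.T for p in pts])
    rho_l = np.array([p.rho_l for p in pts])
    rho_v = np.array([p.rho_v for p in pts])
    if np.any(np.diff(rho_l - rho_v) > 0):
        import warnings

        warnings.warn("rho_l - rho_v is not monotonically decreasing with T", stacklevel=2)
    Tc, rho_c, s1, s2 = _fit_once(T, rho_l, rho_v, alpha)
    subset_Tcs = []
    for k in (2, 3, 4):
        if len(T) >= k:
            sol = _fit_once(T[-k:], rho_l[-k:], rho_v[-k:], alpha)
            subset_Tcs.append(sol[0])
    Tc_err = float(max(abs(t - Tc) for t in subset_Tcs)) if subset_Tcs else 0.0
    return CriticalPoint(float(Tc), float(rho_c), float(s1), float(s2), alpha, Tc_err)
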
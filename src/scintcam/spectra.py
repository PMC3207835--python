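"""Emission models for the three radioembolization-relevant isotopes.

99mTc is a pure gamma emitter for imaging purposes (140.5 keV, 89%).
90Y is a pure beta emitter (E_max = 2.28 MeV); its only imageable emission
is the continuous Bremsstrahlung spectrum created as the betas slow down in
tissue.  166Ho is a combined beta-gamma emitter (betas up to 1.85 MeV,
gamma lines at 80.6, 1379.4 and 1581.0 keV).

Beta spectra use the allowed-transition shape with a nonrelativistic Fermi
screening correction.  The Bremsstrahlung continuum is a thick-target model:
each beta slows down completely in the surrounding medium, radiating a total
energy Y(T)*T (radiation yield from the embedded stopping-power tables)
distributed over photon energies with the Kramers thick-target shape
dN/dk ~ (T - k)/k.  A single dimensionless normalization fixes the absolute
photon number scale against the accepted thick-target yield of 90Y in water
(about 0.020 photons per decay above 50 keV); the corresponding 166Ho yield
is then a prediction of the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import materials
from .materials import collision_stopping_power, radiation_yield

ALPHA_FS = 1.0 / 137.036
MEC2_MEV = 0.511

ISOTOPES = ("Tc99m", "Y90", "Ho166")

#: gamma lines: (energy keV, photons per decay)
_GAMMA_LINES = {
    "Tc99m": [(140.5, 0.89)],
    "Y90": [],
    "Ho166": [(80.6, 0.067), (1379.4, 0.009), (1581.0, 0.002)],
}

#: beta branches: (E_max MeV, branch fraction per decay)
_BETA_BRANCHES = {
    "Tc99m": [],
    "Y90": [(2.28, 0.999)],
    "Ho166": [(1.77, 0.487), (1.85, 0.500)],
}

#: Z of the daughter nucleus, used in the Fermi correction
_DAUGHTER_Z = {"Y90": 40, "Ho166": 68}

#: photopeak energy windows (lo, hi) keV per isotope; 90Y has two in use
ENERGY_WINDOWS = {
    "Tc99m": [(130.0, 151.0)],
    "Y90": [(120.0, 250.0), (50.0, 250.0)],
    "Ho166": [(74.6, 86.6)],
}

# Thick-target photon-number normalization of the Kramers shape, fixed once
# against the 90Y-in-water yield of 0.020 photons/decay above 50 keV.
BREMS_NORM = 1.0  # calibrated below at import time


def _check_isotope(isotope: str, allowed=ISOTOPES) -> None:
    if isotope not in allowed:
        raise ValueError(f"unknown isotope {isotope!r}; valid identifiers: {list(allowed)}")


@dataclass(frozen=True)
class EmissionLines:
    """Discrete gamma lines: list of (energy keV, photons per decay)."""

    entries: tuple

    def __post_init__(self):
        for e, a in self.entries:
            if e <= 0 or not (0 < a <= 1):
                raise ValueError("energies must be > 0 and abundances in (0, 1]")

    @property
    def total_abundance(self) -> float:
        return sum(a for _, a in self.entries)


@dataclass(frozen=True)
class BetaSpectrum:
    """Continuous beta spectrum: branches plus the summed normalized density.

    `energy_mev` / `density` tabulate the branch-weighted probability density
    of the emitted electron kinetic energy (normalized to 1 over (0, E_max]).
    """

    branches: tuple
    energy_mev: np.ndarray
    density: np.ndarray

    @property
    def emax(self) -> float:
        return max(q for q, _ in self.branches)

    def mean_energy(self) -> float:
        return float(np.trapezoid(self.energy_mev * self.density, self.energy_mev))


@dataclass(frozen=True)
class EmissionSpectrum:
    """Gamma lines plus continuous Bremsstrahlung density per decay.

    continuum density units: photons / decay / keV on `continuum_kev`.
    """

    isotope: str
    lines: EmissionLines
    continuum_kev: np.ndarray
    continuum_density: np.ndarray
    yield_above_50kev: float

    @property
    def photons_per_decay_above(self) -> float:
        """Total imageable photons per decay (lines + continuum > 50 keV)."""
        return self.lines.total_abundance + self.yield_above_50kev


def gamma_lines(isotope: str) -> EmissionLines:
    """Discrete gamma emissions of `isotope` (empty for the pure beta 90Y)."""
    _check_isotope(isotope)
    return EmissionLines(tuple(_GAMMA_LINES[isotope]))


def allowed_beta_density(z_daughter: int, q_mev: float, t_mev: np.ndarray) -> np.ndarray:
    """Unnormalized allowed-transition beta shape p*E*(Q-T)^2*F(Z,T).

    F is the nonrelativistic Fermi function 2*pi*eta/(1-exp(-2*pi*eta)) with
    eta = alpha*Z/beta for electron emission.
    """
    t = np.asarray(t_mev, dtype=float)
    e_tot = t + MEC2_MEV
    p = np.sqrt(np.maximum(t * (t + 2.0 * MEC2_MEV), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(p > 0, p / e_tot, 1e-12)
        eta = ALPHA_FS * z_daughter / beta
        fermi = 2.0 * np.pi * eta / (1.0 - np.exp(-2.0 * np.pi * eta))
    shape = p * e_tot * np.maximum(q_mev - t, 0.0) ** 2 * fermi
    shape[t <= 0] = 0.0
    shape[t >= q_mev] = 0.0
    return shape


def beta_spectrum(isotope: str, n_grid: int = 2000) -> BetaSpectrum:
    """Branch-weighted beta kinetic-energy density for 90Y or 166Ho."""
    _check_isotope(isotope)
    branches = _BETA_BRANCHES[isotope]
    if not branches:
        raise ValueError(f"{isotope} has no beta branch modelled")
    z = _DAUGHTER_Z[isotope]
    emax = max(q for q, _ in branches)
    t = np.linspace(0.0, emax, n_grid)
    total_frac = sum(f for _, f in branches)
    dens = np.zeros_like(t)
    for q, frac in branches:
        shape = allowed_beta_density(z, q, t)
        norm = np.trapezoid(shape, t)
        dens += (frac / total_frac) * shape / norm
    return BetaSpectrum(tuple(branches), t, dens)


def sample_beta(isotope: str, n: int, seed: int) -> np.ndarray:
    """Draw `n` beta kinetic energies [MeV] by inverse-CDF sampling."""
    _check_isotope(isotope, allowed=("Y90", "Ho166"))
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = beta_spectrum(isotope)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (spec.density[1:] + spec.density[:-1])
                                           * np.diff(spec.energy_mev))])
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    return np.interp(u, cdf, spec.energy_mev)


def _brems_continuum(isotope: str, medium: str, grid_kev: np.ndarray) -> np.ndarray:
    """Photon number density [photons/decay/keV] of the thick-target model."""
    spec = beta_spectrum(isotope)
    total_beta_per_decay = sum(f for _, f in spec.branches)
    t_grid = spec.energy_mev
    keep = t_grid > 0.012  # below the stopping-power table nothing radiates above 10 keV
    t_grid = t_grid[keep]
    phi = spec.density[keep] * total_beta_per_decay  # electrons/decay/MeV
    y = radiation_yield(medium, t_grid)
    amp = 2.0 * y / t_grid  # Kramers amplitude A(T): dN/dk = A*(T-k)/k  [1/MeV]
    k_mev = grid_kev / 1000.0
    dens = np.zeros_like(k_mev)
    for j, k in enumerate(k_mev):
        mask = t_grid > k
        if not np.any(mask):
            continue
        integrand = phi[mask] * amp[mask] * (t_grid[mask] - k) / k
        dens[j] = np.trapezoid(integrand, t_grid[mask])
    return BREMS_NORM * dens / 1000.0  # 1/MeV -> 1/keV


def brems_spectrum(isotope: str, medium: str = "water",
                   grid_kev: np.ndarray | None = None) -> EmissionSpectrum:
    """Thick-target Bremsstrahlung continuum plus gamma lines for `isotope`.

    `medium` must have tabulated stopping powers (water or PMMA).  The
    returned continuum is zero above the maximum beta energy, and
    `yield_above_50kev` is its integral above 50 keV.
    """
    _check_isotope(isotope)
    if medium not in ("water", "pmma"):
        # surface the stopping-power coverage error with the energy range
        collision_stopping_power(medium, 1.0)
    lines = gamma_lines(isotope)
    if not _BETA_BRANCHES[isotope]:
        grid = np.array([10.0, 2500.0])
        return EmissionSpectrum(isotope, lines, grid, np.zeros(2), 0.0)
    emax_kev = 1000.0 * max(q for q, _ in _BETA_BRANCHES[isotope])
    if grid_kev is None:
        grid_kev = np.arange(10.0, emax_kev + 2.0, 2.0)
    dens = _brems_continuum(isotope, medium, grid_kev)
    dens[grid_kev >= emax_kev] = 0.0
    above = grid_kev >= 50.0
    yield50 = float(np.trapezoid(dens[above], grid_kev[above]))
    return EmissionSpectrum(isotope, lines, grid_kev, dens, yield50)


def _calibrate_brems_norm() -> float:
    """Fix the Kramers normalization on the 90Y-in-water 2.0% yield."""
    global BREMS_NORM
    BREMS_NORM = 1.0
    raw = brems_spectrum("Y90", "water").yield_above_50kev
    return 0.020 / raw


BREMS_NORM = _calibrate_brems_norm()


# ---------------------------------------------------------------------------
# Emission sampling tables for the transport kernel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmissionSampler:
    """Inverse-CDF tables for drawing photon energies above `e_min_kev`.

    `photons_per_decay` converts simulated photon counts back to decays.
    """

    isotope: str
    line_energies: np.ndarray
    line_cum_prob: np.ndarray   # cumulative, ends at p_lines (fraction of photons)
    continuum_icdf: np.ndarray  # 4096-point inverse CDF of the continuum [keV]
    photons_per_decay: float


def emission_sampler(isotope: str, medium: str = "water",
                     e_min_kev: float = 50.0) -> EmissionSampler:
    """Build photon-energy sampling tables for one isotope.

    Photons below `e_min_kev` are not simulated: every photopeak window in
    use starts at or above 50 keV and upward energy blur over tens of keV
    does not occur.
    """
    spec = brems_spectrum(isotope, medium)
    line_e = np.array([e for e, _ in spec.lines.entries])
    line_a = np.array([a for _, a in spec.lines.entries])
    cont_yield = spec.yield_above_50kev if e_min_kev <= 50.0 else float(
        np.trapezoid(spec.continuum_density[spec.continuum_kev >= e_min_kev],
                     spec.continuum_kev[spec.continuum_kev >= e_min_kev]))
    total = line_a.sum() + cont_yield
    if total <= 0:
        raise ValueError(f"{isotope} emits no photons above {e_min_kev} keV")
    if line_e.size:
        line_cum = np.cumsum(line_a) / total
    else:
        line_cum = np.zeros(0)
    if cont_yield > 0:
        # restrict the grid exactly at the cutoff so the sampled density and
        # the stored density share the same normalization convention
        sel = spec.continuum_kev >= e_min_kev
        k = spec.continuum_kev[sel]
        d = spec.continuum_density[sel]
        if k[0] > e_min_kev:
            d = np.concatenate([[np.interp(e_min_kev, spec.continuum_kev,
                                           spec.continuum_density)], d])
            k = np.concatenate([[e_min_kev], k])
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (d[1:] + d[:-1]) * np.diff(k))])
        cdf /= cdf[-1]
        u = np.linspace(0.0, 1.0, 4096)
        icdf = np.interp(u, cdf, k)
    else:
        icdf = np.full(4096, line_e[0] if line_e.size else e_min_kev)
    return EmissionSampler(isotope, line_e, line_cum, icdf, float(total))
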
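"""Photon cross sections and electron stopping powers for the camera materials.

Embedded static data covering 10--2600 keV for the materials that appear in
the simulated scenes: water, PMMA, lead, NaI(Tl), crown glass, aluminum and
air.  The dominant channel in the phantom materials (incoherent scattering)
is computed analytically from the Klein--Nishina cross section with the
free-electron approximation; photoelectric absorption, coherent scattering
and pair production are semi-empirical piecewise power laws anchored to
published mass-attenuation values (e.g. lead 5.549 cm^2/g at 100 keV,
2.014 at 150 keV; water 0.171 at 100 keV), with K-edge jumps for iodine
(33.17 keV) and lead (88.0 keV).

Collision stopping powers for water and PMMA are tabulated on a log grid;
radiative stopping powers use the Koch--Motz-style rule
S_rad/S_col = Z_eff * T[MeV] / 800, which carries the energy dependence of
the radiative yield (its absolute scale is absorbed into the thick-target
normalization in :mod:`scintcam.spectra`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ELECTRON_REST_KEV = 511.0
N_AVOGADRO = 6.02214076e23
R_E_CM = 2.8179403262e-13  # classical electron radius [cm]

# ---------------------------------------------------------------------------
# Elements
# ---------------------------------------------------------------------------

#: symbol -> (Z, atomic mass A [g/mol])
ELEMENTS: dict[str, tuple[int, float]] = {
    "H": (1, 1.008),
    "C": (6, 12.011),
    "N": (7, 14.007),
    "O": (8, 15.999),
    "Na": (11, 22.990),
    "Al": (13, 26.982),
    "Si": (14, 28.085),
    "Ca": (20, 40.078),
    "I": (53, 126.904),
    "Pb": (82, 207.2),
}

# Photoelectric mass attenuation anchor at 100 keV [cm^2/g] for each element.
# Light elements follow a Z^4.4/A scaling calibrated on oxygen (water photo
# component ~0.0026 cm^2/g at 100 keV); iodine and lead are anchored
# independently on their published totals.
_TAU100 = {
    "H": 4.0e-6,
    "C": 1.13e-3,
    "N": 1.91e-3,
    "O": 3.00e-3,
    "Na": 8.5e-3,
    "Al": 1.51e-2,
    "Si": 2.00e-2,
    "Ca": 6.75e-2,
    "I": 1.66,   # above the K edge
    "Pb": 5.20,  # above the K edge
}

# K edges [keV] and edge jump ratios (tau just above / just below).
_K_EDGE = {"I": 33.17, "Pb": 88.0}
_K_JUMP = {"I": 5.6, "Pb": 4.9}

# Power-law exponents: (low-E exponent, break energy keV, high-E exponent).
_TAU_EXP = {
    "default": (3.05, 300.0, 1.9),
    "I": (2.85, 500.0, 1.8),
    "Pb": (2.75, 500.0, 1.8),
}
# Exponent used below the K edge (L-shell continuation).
_TAU_EXP_BELOW_K = {"I": 2.9, "Pb": 3.0}

_COH_CONST = 1.985e-4  # Z^2.9/A scaling; reproduces water 0.0046, Pb ~0.34,
                       # iodine ~0.16, graphite ~0.003 cm^2/g at 100 keV
_PAIR_CONST = 2.57e-4  # calibrated: lead pair ~0.008 cm^2/g at 2 MeV


def _tau_element(symbol: str, e_kev: np.ndarray) -> np.ndarray:
    """Photoelectric mass attenuation [cm^2/g] for one element."""
    e = np.asarray(e_kev, dtype=float)
    p_lo, brk, p_hi = _TAU_EXP.get(symbol, _TAU_EXP["default"])
    tau100 = _TAU100[symbol]
    # piecewise power law continuous at the break
    tau = np.where(
        e <= brk,
        tau100 * (100.0 / e) ** p_lo,
        tau100 * (100.0 / brk) ** p_lo * (brk / e) ** p_hi,
    )
    if symbol in _K_EDGE:
        ek = _K_EDGE[symbol]
        below = e < ek
        if np.any(below):
            # value just above the edge, reduced by the jump ratio, continued
            # downwards with the L-shell exponent
            tau_edge_above = tau100 * (100.0 / ek) ** p_lo
            tau_below_edge = tau_edge_above / _K_JUMP[symbol]
            p_below = _TAU_EXP_BELOW_K[symbol]
            tau = np.where(below, tau_below_edge * (ek / e) ** p_below, tau)
    return tau


def klein_nishina_total(e_kev: np.ndarray) -> np.ndarray:
    """Total Klein--Nishina cross section per electron [cm^2]."""
    k = np.asarray(e_kev, dtype=float) / ELECTRON_REST_KEV
    term1 = (1.0 + k) / k**2 * (2.0 * (1.0 + k) / (1.0 + 2.0 * k) - np.log(1.0 + 2.0 * k) / k)
    term2 = np.log(1.0 + 2.0 * k) / (2.0 * k)
    term3 = -(1.0 + 3.0 * k) / (1.0 + 2.0 * k) ** 2
    return 2.0 * np.pi * R_E_CM**2 * (term1 + term2 + term3)


def _incoh_element(symbol: str, e_kev: np.ndarray) -> np.ndarray:
    z, a = ELEMENTS[symbol]
    return N_AVOGADRO * z / a * klein_nishina_total(e_kev)


def _coh_element(symbol: str, e_kev: np.ndarray) -> np.ndarray:
    z, a = ELEMENTS[symbol]
    e = np.maximum(np.asarray(e_kev, dtype=float), 30.0)
    return _COH_CONST * z**2.9 / a * (100.0 / e) ** 1.9


def _pair_element(symbol: str, e_kev: np.ndarray) -> np.ndarray:
    z, a = ELEMENTS[symbol]
    e = np.asarray(e_kev, dtype=float)
    return _PAIR_CONST * z**2 / a * np.maximum(0.0, (e - 2.0 * ELECTRON_REST_KEV) / 1000.0)


# ---------------------------------------------------------------------------
# Materials
# ---------------------------------------------------------------------------

E_GRID_KEV = np.geomspace(10.0, 2600.0, 200)

# channel indices used throughout the transport kernel
CH_PHOTO, CH_INCOH, CH_COH, CH_PAIR = 0, 1, 2, 3
CHANNEL_NAMES = ("photoelectric", "incoherent", "coherent", "pair")


@dataclass(frozen=True)
class Material:
    """A homogeneous material with tabulated linear attenuation coefficients.

    Attributes
    ----------
    name : str
    composition : dict
        Element symbol -> mass fraction (normalized).
    density : float
        g/cm^3.
    coherent_enabled : bool
        Coherent scattering is switched off in the detector crystal, where
        every interaction counts as detection and a forward deflection of
        the already-converging photon is irrelevant.
    """

    name: str
    composition: dict
    density: float
    coherent_enabled: bool = True
    #: linear attenuation per channel [1/mm], shape (4, len(E_GRID_KEV))
    mu_table: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        total = sum(self.composition.values())
        comp = {k: v / total for k, v in self.composition.items()}
        object.__setattr__(self, "composition", comp)
        tab = np.zeros((4, E_GRID_KEV.size))
        for sym, w in comp.items():
            tab[CH_PHOTO] += w * _tau_element(sym, E_GRID_KEV)
            tab[CH_INCOH] += w * _incoh_element(sym, E_GRID_KEV)
            if self.coherent_enabled:
                tab[CH_COH] += w * _coh_element(sym, E_GRID_KEV)
            tab[CH_PAIR] += w * _pair_element(sym, E_GRID_KEV)
        tab *= self.density / 10.0  # cm^2/g * g/cm^3 = 1/cm -> 1/mm
        object.__setattr__(self, "mu_table", tab)

    @property
    def electrons_per_gram(self) -> float:
        return sum(
            w * N_AVOGADRO * ELEMENTS[s][0] / ELEMENTS[s][1]
            for s, w in self.composition.items()
        )

    @property
    def z_eff(self) -> float:
        """Bremsstrahlung-weighted effective atomic number (Z^2-weighted)."""
        num = sum(w * ELEMENTS[s][0] ** 2 / ELEMENTS[s][1] for s, w in self.composition.items())
        den = sum(w * ELEMENTS[s][0] / ELEMENTS[s][1] for s, w in self.composition.items())
        return num / den

    def mu(self, e_kev, channel: int | None = None) -> np.ndarray:
        """Linear attenuation coefficient [1/mm] at energy `e_kev`.

        `channel=None` returns the total; otherwise one of CH_PHOTO,
        CH_INCOH, CH_COH, CH_PAIR.  Raises for energies outside the table.
        """
        e = np.asarray(e_kev, dtype=float)
        if np.any(e < E_GRID_KEV[0]) or np.any(e > E_GRID_KEV[-1]):
            raise ValueError(
                f"energy outside tabulated range "
                f"[{E_GRID_KEV[0]:.0f}, {E_GRID_KEV[-1]:.0f}] keV"
            )
        loge = np.log(E_GRID_KEV)
        if channel is None:
            tot = self.mu_table.sum(axis=0)
            return np.exp(np.interp(np.log(e), loge, np.log(np.maximum(tot, 1e-300))))
        row = self.mu_table[channel]
        # channels may be exactly zero (pair below threshold): interp linearly
        return np.interp(np.log(e), loge, row)


WATER = Material("water", {"H": 0.1119, "O": 0.8881}, 1.000)
PMMA = Material("pmma", {"H": 0.0805, "C": 0.5998, "O": 0.3196}, 1.190)
LEAD = Material("lead", {"Pb": 1.0}, 11.35)
NAI = Material("nai", {"Na": 0.1534, "I": 0.8466}, 3.667, coherent_enabled=False)
CROWN_GLASS = Material(
    "crown_glass",
    {"Si": 0.3412, "O": 0.4898, "Na": 0.1039, "Ca": 0.0643, "Al": 0.0008},
    2.52,
)
ALUMINUM = Material("aluminum", {"Al": 1.0}, 2.699)
AIR = Material("air", {"N": 0.755, "O": 0.232, "C": 0.013}, 1.205e-3)

MATERIALS: dict[str, Material] = {
    m.name: m
    for m in (WATER, PMMA, LEAD, NAI, CROWN_GLASS, ALUMINUM, AIR)
}

# integer ids for the transport kernel; 0 is vacuum
MATERIAL_IDS = {"vacuum": 0}
MATERIAL_IDS.update({name: i + 1 for i, name in enumerate(MATERIALS)})


def mu_kernel_tables() -> tuple[np.ndarray, np.ndarray]:
    """(log-energy grid, mu array [n_mats+1, 4, nE]) for the numba kernel."""
    n = len(MATERIALS) + 1
    tab = np.zeros((n, 4, E_GRID_KEV.size))
    for name, mat in MATERIALS.items():
        tab[MATERIAL_IDS[name]] = mat.mu_table
    return np.log(E_GRID_KEV), tab


def binding_tables() -> tuple[np.ndarray, np.ndarray]:
    """Per-material-id incoherent (q0) and coherent (fb) shape parameters.

    q0 parameterizes the incoherent scattering-function suppression of
    small-angle Compton scattering (S/Z reaches 1/2 at x = q0, ~0.6 1/A for
    water), fb the dipole form factor of coherent scattering (F/Z = 1/2 at
    x = fb); both scale as Z_eff^(1/3) relative to water.  The NaI
    crystal keeps the free-electron response (q0 = 0) so that every crystal
    interaction counts as detection.
    """
    n = len(MATERIALS) + 1
    q0 = np.zeros(n)
    fb = np.zeros(n)
    for name, mat in MATERIALS.items():
        scale = (mat.z_eff / WATER.z_eff) ** (1.0 / 3.0)
        idx = MATERIAL_IDS[name]
        q0[idx] = 0.0 if name == "nai" else 0.6 * scale
        fb[idx] = 0.42 * scale if mat.coherent_enabled else 0.0
    return q0, fb


# ---------------------------------------------------------------------------
# Electron stopping powers (collision), water  [kinetic energy MeV, MeV cm^2/g]
# ---------------------------------------------------------------------------

_SP_T_MEV = np.array(
    [0.010, 0.015, 0.020, 0.030, 0.040, 0.050, 0.060, 0.080, 0.100,
     0.150, 0.200, 0.300, 0.400, 0.500, 0.600, 0.800, 1.000, 1.250,
     1.500, 2.000, 2.500]
)
_SP_WATER_COL = np.array(
    [22.56, 16.47, 13.17, 9.653, 7.777, 6.603, 5.797, 4.757, 4.115,
     3.238, 2.793, 2.355, 2.148, 2.034, 1.963, 1.886, 1.849, 1.829,
     1.822, 1.824, 1.834]
)
# PMMA collision stopping power scales with electron density (per gram it is
# ~3% below water across this range).
_SP_PMMA_COL = 0.968 * _SP_WATER_COL

_STOPPING = {"water": _SP_WATER_COL, "pmma": _SP_PMMA_COL}


def collision_stopping_power(material: str, t_mev) -> np.ndarray:
    """Collision mass stopping power [MeV cm^2/g] for water or PMMA."""
    if material not in _STOPPING:
        raise ValueError(
            f"no stopping-power table for {material!r} over "
            f"{_SP_T_MEV[0]}-{_SP_T_MEV[-1]} MeV; have {sorted(_STOPPING)}"
        )
    t = np.asarray(t_mev, dtype=float)
    if np.any(t < _SP_T_MEV[0]) or np.any(t > _SP_T_MEV[-1]):
        raise ValueError(
            f"kinetic energy outside tabulated range "
            f"[{_SP_T_MEV[0]} MeV, {_SP_T_MEV[-1]} MeV]"
        )
    return np.exp(np.interp(np.log(t), np.log(_SP_T_MEV), np.log(_STOPPING[material])))


def radiative_stopping_power(material: str, t_mev) -> np.ndarray:
    """Radiative mass stopping power [MeV cm^2/g] via S_rad/S_col = Z_eff*T/800."""
    z_eff = MATERIALS[material].z_eff
    t = np.asarray(t_mev, dtype=float)
    return collision_stopping_power(material, t) * z_eff * t / 800.0


def radiation_yield(material: str, t_mev) -> np.ndarray:
    """Fraction of an electron's kinetic energy radiated while slowing down.

    Y(T) = (1/T) * integral_0^T  S_rad / (S_col + S_rad)  dT'
    evaluated by trapezoidal quadrature on a fine log grid.  Below the
    stopping-power table (10 keV) the integrand is extrapolated linearly in
    T, an entirely negligible contribution.
    """
    t = np.atleast_1d(np.asarray(t_mev, dtype=float))
    out = np.empty_like(t)
    for i, ti in enumerate(t):
        grid = np.linspace(_SP_T_MEV[0], ti, 400)
        s_col = collision_stopping_power(material, grid)
        s_rad = radiative_stopping_power(material, grid)
        frac = s_rad / (s_col + s_rad)
        integral = np.trapezoid(frac, grid) + frac[0] * _SP_T_MEV[0] / 2.0
        out[i] = integral / ti
    return out if np.ndim(t_mev) else out[0]
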
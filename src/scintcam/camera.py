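"""Camera head parameterization: collimator, crystal, blur models, windows.

The modelled head follows a dual-headed Anger camera with 3/8 inch (9.525 mm)
NaI(Tl) crystals and exchangeable parallel-hole collimators with hexagonal
holes.  Intrinsic spatial resolution and energy resolution are not part of
the collimator data sheet; they are calibration knobs held in the config
(defaults: 3.5 mm FWHM and 9.5% FWHM at 140 keV, typical for 3/8" NaI,
scaling as 1/sqrt(E) and sqrt(E) respectively).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


@dataclass(frozen=True)
class CollimatorSpec:
    """Parallel-hole collimator with a hexagonal hole lattice.

    hole_size is the hexagon flat-to-flat distance; the lattice pitch is
    hole_size + septal_thickness.  All dimensions in mm, material is lead.
    """

    name: str
    hole_size: float
    septal_thickness: float
    length: float
    material: str = "lead"

    def __post_init__(self):
        if min(self.hole_size, self.septal_thickness, self.length) <= 0:
            raise ValueError("all collimator dimensions must be > 0")

    @property
    def pitch(self) -> float:
        return self.hole_size + self.septal_thickness


#: hole size / septal thickness / length (mm)
COLLIMATORS = {
    "VXGP": CollimatorSpec("VXGP", 1.78, 0.152, 42.0),
    "MEGP": CollimatorSpec("MEGP", 2.95, 1.143, 48.0),
    "HEGP": CollimatorSpec("HEGP", 3.81, 1.727, 60.0),
}


@dataclass(frozen=True)
class EnergyWindow:
    """Closed acceptance interval [lo, hi] on measured energy, keV."""

    lo: float
    hi: float

    def __post_init__(self):
        if not (0 < self.lo < self.hi):
            raise ValueError("energy window requires 0 < lo < hi")

    def __str__(self):
        return f"{self.lo:g}-{self.hi:g}keV"


#: an energy window covering the complete usable range of the camera,
#: used for the dead-time (intrinsic count-rate) measurements
FULL_ENERGY_WINDOW = EnergyWindow(20.0, 2500.0)


@dataclass(frozen=True)
class CameraConfig:
    """Full camera-head parameterization used by the transport code."""

    collimator: CollimatorSpec
    window: EnergyWindow
    crystal_thickness: float = 9.525          # mm, 3/8 inch NaI(Tl)
    intrinsic_resolution_fwhm: float = 3.5    # mm FWHM at 140 keV
    energy_resolution_fraction: float = 0.095  # FWHM/E at 140 keV
    backscatter_thickness: float = 50.0       # mm crown glass
    al_window_thickness: float = 1.0          # mm crystal-housing entrance
    crystal_gap: float = 3.0                  # mm air between housing and NaI
    pixel_size: float = 2.332                 # mm, planar 256x256 matrix
    detector_half_width: float = 298.5        # mm (256 * 2.332 / 2)
    detector_half_height: float = 298.5
    low_threshold: float = 20.0               # keV detection threshold

    def energy_fwhm(self, e_kev: float) -> float:
        """Energy resolution FWHM [keV] at energy E (Poisson light scaling)."""
        return self.energy_resolution_fraction * 140.0 * np.sqrt(np.asarray(e_kev) / 140.0)

    def position_fwhm(self, e_kev: float) -> float:
        """Intrinsic spatial FWHM [mm] at energy E, scaling as 1/sqrt(E)."""
        return self.intrinsic_resolution_fwhm * np.sqrt(140.0 / np.asarray(e_kev))

    def with_window(self, window: EnergyWindow) -> "CameraConfig":
        return replace(self, window=window)


def make_camera(collimator_id: str, window: EnergyWindow, **overrides) -> CameraConfig:
    """Camera config for one of the mounted collimators (VXGP, MEGP, HEGP)."""
    if collimator_id not in COLLIMATORS:
        raise ValueError(
            f"unknown collimator {collimator_id!r}; valid ids: {sorted(COLLIMATORS)}"
        )
    return CameraConfig(collimator=COLLIMATORS[collimator_id], window=window, **overrides)


def blur_energy(e_true, camera: CameraConfig, rng: np.random.Generator):
    """Gaussian energy blur, truncated at zero.

    FWHM(E) = energy_resolution_fraction * 140 * sqrt(E/140) keV.
    """
    e = np.asarray(e_true, dtype=float)
    if np.any(e <= 0):
        raise ValueError("true energy must be > 0")
    sigma = camera.energy_fwhm(e) * FWHM_TO_SIGMA
    out = e + sigma * rng.standard_normal(e.shape if e.shape else None)
    return np.maximum(out, 0.0)


def blur_position(xy, e_kev, camera: CameraConfig, rng: np.random.Generator):
    """Intrinsic lateral position blur of the detected centroid."""
    xy = np.asarray(xy, dtype=float)
    sigma = camera.position_fwhm(e_kev) * FWHM_TO_SIGMA
    return xy + np.asarray(sigma)[..., None] * rng.standard_normal(xy.shape)


def in_window(e_measured, window: EnergyWindow):
    """True iff lo <= E <= hi (closed interval on both bounds)."""
    e = np.asarray(e_measured)
    return (e >= window.lo) & (e <= window.hi)
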
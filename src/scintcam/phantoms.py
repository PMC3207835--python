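"""The four measurement geometries as transportable or projectable scenes.

* line source in PMMA slab stacks (spatial resolution, photon-class
  fractions) -- five measured configurations S01D02 ... S10D11;
* Petri dish with a thin activity layer (planar sensitivity);
* cylindrical vial at large standoff (intrinsic count rate; only its
  analytic photon flux is used -- dead time is modelled, not transported);
* NEMA IEC torso image-quality phantom with six hot spheres and a cold
  lung insert (contrast recovery, handled by the hybrid projector).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .transport import Scene

#: (scatter_total_cm, distance_cm) -> geometry code of the measured set-up
LINE_CONFIGS = {
    (2, 2): "S01D02",
    (2, 6): "S01D06",
    (2, 11): "S01D11",
    (10, 11): "S05D11",
    (20, 11): "S10D11",
}
GEOMETRY_CODES = {v: k for k, v in LINE_CONFIGS.items()}

LINE_SOURCE_HALF_LENGTH = 140.0  # mm (28 cm line)
SLAB_HALF_EXTENT = 200.0         # mm (40 x 40 cm slabs)


def line_source_scene(scatter_total_cm: int, distance_cm: int, isotope: str) -> Scene:
    """Line source centered in symmetric PMMA, one of the measured set-ups.

    `scatter_total_cm` is the full PMMA stack thickness (the source is
    centered, so half of it sits between source and camera); `distance_cm`
    is the source to collimator-face distance.
    """
    key = (int(scatter_total_cm), int(distance_cm))
    if key not in LINE_CONFIGS:
        raise ValueError(
            f"unmeasured configuration {key}; measured (scatter_cm, distance_cm) "
            f"combinations: {sorted(LINE_CONFIGS)}"
        )
    return _line_scene(scatter_total_cm * 10.0 / 2.0, distance_cm * 10.0, isotope)


def _line_scene(half_stack_mm: float, distance_mm: float, isotope: str) -> Scene:
    """Line source with `half_stack_mm` of PMMA above and below the source.

    Unrestricted variant used for point-spread-function calibration runs at
    arbitrary distances.
    """
    d = float(distance_mm)
    volumes = (
        (-d - half_stack_mm, -d, "pmma"),   # below/behind the source
        (-d, -d + half_stack_mm, "pmma"),   # between source and camera
    )
    return Scene(
        isotope=isotope,
        volumes=volumes,
        source={"kind": "line", "half_length": LINE_SOURCE_HALF_LENGTH},
        distance_mm=d,
        lateral_half_mm=SLAB_HALF_EXTENT,
    )


def petri_scene(distance_cm: int, isotope: str, dish_radius_mm: float = 50.0) -> Scene:
    """Thin-layer Petri dish sensitivity geometry.

    For the beta emitters, 1 cm PMMA slabs sit below and on top of the dish
    (they stop the electrons and create the Bremsstrahlung photons); the
    99mTc dish is measured bare.  The slabs travel with the dish when the
    standoff changes.
    """
    if distance_cm not in (10, 40):
        raise ValueError("measured Petri distances are 10 and 40 cm")
    d = distance_cm * 10.0
    if isotope in ("Y90", "Ho166"):
        volumes = ((-d - 10.0, -d, "pmma"), (-d, -d + 10.0, "pmma"))
    else:
        volumes = ()
    return Scene(
        isotope=isotope,
        volumes=volumes,
        source={"kind": "disk", "radius": dish_radius_mm},
        distance_mm=d,
        lateral_half_mm=SLAB_HALF_EXTENT,
    )


@dataclass(frozen=True)
class VialSpec:
    """Count-rate vial: 11 ml solution, 2.4 cm inner diameter, 66.5 cm away.

    Only the analytic flux of this geometry enters the dead-time analysis;
    the paralyzable model is fitted to intrinsic rates, not transported.
    """

    volume_ml: float = 11.0
    inner_diameter_mm: float = 24.0
    distance_mm: float = 665.0


@dataclass(frozen=True)
class IQPhantomSpec:
    """NEMA IEC torso phantom: body, six coplanar spheres, cold lung insert.

    The body cross-section is the standard two half-circles joined by
    straights; dimensions chosen so the body volume is 9700 ml at the
    default 180 mm interior length.
    """

    body_volume_ml: float = 9700.0
    sphere_diameters_mm: tuple = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
    sphere_ring_radius_mm: float = 57.2
    lung_diameter_mm: float = 50.0
    lung_relative_density: float = 0.30
    body_half_height_mm: float = 105.0   # half-circle radius r
    body_straight_mm: float = 45.84      # half-length w of the straight section
    axial_length_mm: float = 180.0
    background_kbq_ml: float = 137.0
    ratio: float = 9.0

    def __post_init__(self):
        if len(self.sphere_diameters_mm) != 6:
            raise ValueError("the IQ phantom has six spheres")
        if self.ratio <= 1:
            raise ValueError(
                "sphere-to-background ratio must exceed 1 (contrast recovery "
                "is undefined at R = 1)"
            )

    @property
    def cross_section_area_mm2(self) -> float:
        r, w = self.body_half_height_mm, self.body_straight_mm
        return np.pi * r * r + 4.0 * r * w

    @property
    def sphere_centers(self) -> np.ndarray:
        """(6, 2) in-plane sphere centers on the placement ring [mm]."""
        angles = np.deg2rad(30.0 + 60.0 * np.arange(6))
        return self.sphere_ring_radius_mm * np.stack(
            [np.cos(angles), np.sin(angles)], axis=1
        )

    def body_mask(self, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
        """Boolean mask of the body cross-section on coordinate grids [mm]."""
        r, w = self.body_half_height_mm, self.body_straight_mm
        inside = (np.abs(yy) <= r) & (np.abs(xx) <= w)
        left = (xx + w) ** 2 + yy**2 <= r * r
        right = (xx - w) ** 2 + yy**2 <= r * r
        return inside | (left & (xx < -w)) | (right & (xx > w))

    def total_activity_mbq(self) -> float:
        """Total phantom activity [MBq] = concentration x volume (the hot
        spheres add (R-1) x background over their volume)."""
        sphere_ml = sum(
            4.0 / 3.0 * np.pi * (d / 2.0) ** 3 for d in self.sphere_diameters_mm
        ) / 1000.0
        lung_ml = (
            np.pi * (self.lung_diameter_mm / 2.0) ** 2 * self.axial_length_mm / 1000.0
        )
        bg_ml = self.body_volume_ml - lung_ml - sphere_ml
        total_kbq = self.background_kbq_ml * (bg_ml + self.ratio * sphere_ml)
        return total_kbq / 1000.0


def iq_phantom_scene(isotope: str, background_kbq_ml: float, ratio: float,
                     **overrides) -> Scene:
    """Image-quality phantom scene for the hybrid SPECT projector."""
    spec = IQPhantomSpec(background_kbq_ml=background_kbq_ml, ratio=ratio, **overrides)
    return Scene(
        isotope=isotope,
        volumes=(),
        source={"kind": "iq"},
        distance_mm=200.0,  # orbit radius from the phantom axis
        kind="iq",
        payload={"spec": spec},
    )
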
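"""NEMA-style analysis of simulated acquisitions.

Line-spread-function extraction and FWHM/FWTM, planar sensitivity, the
paralyzable (Sorensen) dead-time model with system count-rate composition,
and the maximum linear-range activity.

Width measurement follows the NEMA procedure: the peak is located by a
parabolic fit through the maximum bin and its two neighbours, and each
crossing of fraction*peak is found by linear interpolation between the
adjacent bins; the width is the distance between the two crossings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .camera import EnergyWindow
from .transport import EventList

PIXEL_MM = 2.332
GRID = 256
LSF_BAND_MM = 50.0  # central +-5 cm of rows are summed (10 cm total)


@dataclass(frozen=True)
class LSFProfile:
    """Binned line-spread function: bin centers [mm] and weighted counts."""

    centers: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        if np.any(self.counts < 0):
            raise ValueError("LSF counts must be non-negative")


@dataclass(frozen=True)
class ResolutionResult:
    fwhm: float
    fwtm: float
    peak_method: str = "parabolic"

    def __post_init__(self):
        if not (self.fwtm >= self.fwhm > 0):
            raise ValueError("resolution requires FWTM >= FWHM > 0")


@dataclass(frozen=True)
class CountRateModel:
    """Paralyzable camera: tau plus full-window / photopeak sensitivities.

    tau : s
        Paralyzable dead time; each photon hitting the crystal extends the
        dead period, so losses are driven by the full-energy-window rate.
    s_full, s_peak : cps/MBq
        System sensitivities in the full energy window and in the isotope's
        photopeak window.
    """

    tau: float
    s_full: float
    s_peak: float

    def __post_init__(self):
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if not (0 < self.s_peak <= self.s_full):
            raise ValueError("need 0 < s_peak <= s_full")


def binned_image(events: EventList, window: EnergyWindow | None = None,
                 grid: int = GRID, pixel_mm: float = PIXEL_MM):
    """(image, edges) on the planar acquisition matrix, weighted counts."""
    mask = np.ones(len(events), dtype=bool)
    if window is not None:
        mask = events.in_window(window)
    half = grid * pixel_mm / 2.0
    edges = np.linspace(-half, half, grid + 1)
    img, _, _ = np.histogram2d(
        events.x[mask], events.y[mask], bins=(edges, edges), weights=events.weight[mask]
    )
    return img, edges


def extract_lsf(events: EventList, axis: str = "x",
                window: EnergyWindow | None = None,
                band_mm: float = LSF_BAND_MM) -> LSFProfile:
    """Sum the central 10 cm of lines perpendicular to the source axis.

    The line source runs along y; the LSF is the profile across x after
    summing the rows with |y| < 5 cm (and vice versa for axis='y').
    """
    img, edges = binned_image(events, window=window)
    if img.sum() <= 0:
        raise ValueError("empty detector image")
    centers = 0.5 * (edges[:-1] + edges[1:])
    band = np.abs(centers) < band_mm
    if axis == "x":
        profile = img[:, band].sum(axis=1)
    elif axis == "y":
        profile = img[band, :].sum(axis=0)
    else:
        raise ValueError("axis must be 'x' or 'y'")
    return LSFProfile(centers, profile)


def _parabolic_peak(y: np.ndarray, i: int) -> tuple[float, float]:
    """(position offset in bins, peak value) from a 3-point parabola."""
    if i == 0 or i == y.size - 1:
        return 0.0, y[i]
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom >= 0:  # degenerate / flat: fall back to the max bin
        return 0.0, y[i]
    d = 0.5 * (y[i - 1] - y[i + 1]) / denom
    peak = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * d
    return d, peak


def width_at_fraction(profile: LSFProfile, fraction: float) -> float:
    """Full width of the profile at `fraction` of its (parabolic) peak [mm].

    Raises if the profile does not drop below fraction*peak on both sides
    (truncated tail).
    """
    y = np.asarray(profile.counts, dtype=float)
    x = np.asarray(profile.centers, dtype=float)
    i = int(np.argmax(y))
    if y[i] <= 0:
        raise ValueError("profile peak must be strictly positive")
    _, peak = _parabolic_peak(y, i)
    level = fraction * peak
    # left crossing
    j = i
    while j > 0 and y[j] > level:
        j -= 1
    if y[j] > level:
        raise ValueError(
            f"profile never drops below {fraction:g} x peak on the left "
            "(truncated tail)"
        )
    xl = x[j] + (x[j + 1] - x[j]) * (level - y[j]) / (y[j + 1] - y[j])
    # right crossing
    j = i
    while j < y.size - 1 and y[j] > level:
        j += 1
    if y[j] > level:
        raise ValueError(
            f"profile never drops below {fraction:g} x peak on the right "
            "(truncated tail)"
        )
    xr = x[j - 1] + (x[j] - x[j - 1]) * (level - y[j - 1]) / (y[j] - y[j - 1])
    return xr - xl


def resolution(profile: LSFProfile) -> ResolutionResult:
    """FWHM and FWTM of a line-spread function, NEMA interpolation rules."""
    return ResolutionResult(
        fwhm=width_at_fraction(profile, 0.5),
        fwtm=width_at_fraction(profile, 0.1),
    )


def sensitivity(counts: float, duration_s: float, activity_mbq: float) -> float:
    """Planar sensitivity [cps/MBq] = counts / (time x activity)."""
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    if activity_mbq <= 0:
        raise ValueError("activity must be > 0")
    return counts / (duration_s * activity_mbq)


def simulated_sensitivity(events: EventList, window: EnergyWindow) -> float:
    """System sensitivity [cps/MBq] from a traced Petri-dish acquisition.

    weighted in-window counts per simulated decay x 1e6 decays/s per MBq.
    """
    w = events.weight[events.in_window(window)].sum()
    return w / events.n_decays * 1.0e6


def fit_paralyzable(ideal_rates, observed_rates) -> float:
    """Least-squares dead time tau [s] of R_obs = R_ideal*exp(-R_ideal*tau).

    Needs at least 3 positive-rate points; raises on non-convergence with
    the residual report.
    """
    r_i = np.asarray(ideal_rates, dtype=float)
    r_o = np.asarray(observed_rates, dtype=float)
    if r_i.size < 3:
        raise ValueError("need at least 3 count-rate points")
    if np.any(r_i <= 0) or np.any(r_o <= 0):
        raise ValueError("rates must be positive")

    def model(r, tau):
        return r * np.exp(-r * tau)

    with np.errstate(invalid="ignore"):
        tau0 = float(np.mean(np.log(np.maximum(r_i / r_o, 1e-12)) / r_i))
    tau0 = max(tau0, 0.0)
    try:
        popt, _ = curve_fit(model, r_i, r_o, p0=[tau0], maxfev=10000)
    except RuntimeError as err:
        resid = model(r_i, tau0) - r_o
        raise RuntimeError(
            f"paralyzable fit did not converge (residuals at tau0={tau0:g}: "
            f"{resid})"
        ) from err
    return float(popt[0])


def system_curve(model: CountRateModel, activities_mbq) -> np.ndarray:
    """Observed photopeak system rate [cps] on an activity grid [MBq].

    R_sys(A) = S_peak*A*exp(-S_full*A*tau): the loss factor uses the
    full-window rate because dead time is driven by every photon that hits
    the crystal, while the recorded rate is the photopeak-window one.
    """
    a = np.asarray(activities_mbq, dtype=float)
    return model.s_peak * a * np.exp(-model.s_full * a * model.tau)


def linmax(model: CountRateModel) -> tuple[float, float]:
    """(A_linmax [MBq], R_linmax [cps]): the 2%-loss point of the curve.

    A_linmax = -ln(0.98)/(S_full*tau) is the highest activity with less
    than 2% count-rate loss; R_linmax = 0.98*S_peak*A_linmax.
    """
    if model.tau <= 0:
        raise ValueError("tau = 0 gives an unbounded linear range")
    a_lin = -np.log(0.98) / (model.s_full * model.tau)
    return a_lin, 0.98 * model.s_peak * a_lin
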
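"""Hyperspectral reflectance processing: distance correction, illumination
class selection and water-related vegetation indices.

The imaging system calibrates reflectance against a white reference tile
at a fixed 1.2 m distance; plants taller or shorter than that sit at a
different distance and show a systematically shifted reflectance level.
A broadband distance-response curve ``h(d)`` (``h(1.2 m) = 1``) fitted on
plants imaged at several lift heights converts a spectrum measured at
distance ``d`` to the level it would have had at the reference height,
``rho_adj = rho / h(d)`` -- an exactly invertible scalar correction
applied per pixel before illumination classification and averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Spectrum:
    """One reflectance spectrum on a strictly increasing wavelength grid."""

    wavelengths: np.ndarray
    reflectance: np.ndarray
    distance: float = 1.2
    pixel_count: int | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.ndim != 1 or np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be 1-D and strictly increasing")
        if self.reflectance.shape != self.wavelengths.shape:
            raise ValueError("reflectance and wavelengths shapes differ")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance must be finite")
        if self.distance <= 0:
            raise ValueError("distance must be positive")


@dataclass
class DistanceResponse:
    """Broadband distance-response curve h(d), normalised to 1 at the
    white-reference distance."""

    coefficients: np.ndarray  # polynomial in d, highest power first
    reference_distance: float = 1.2
    calibrated_range: tuple = (1.0, 3.2)
    calibration_points: pd.DataFrame | None = None

    def __call__(self, distance):
        d = np.asarray(distance, dtype=float)
        if np.any(d <= 0):
            raise ValueError("distance must be positive")
        h = np.polyval(self.coefficients, d) / np.polyval(
            self.coefficients, self.reference_distance
        )
        return float(h) if h.ndim == 0 else h


def fit_distance_response(
    calibration: pd.DataFrame,
    degree: int = 2,
    reference_distance: float = 1.2,
) -> DistanceResponse:
    """Fit the distance response from plants imaged at multiple lift heights.

    ``calibration`` has columns ``plant_id``, ``distance`` and
    ``mean_reflectance`` (broadband average plant reflectance).  Each
    plant's series is scaled by its own maximum -- removing biological
    level differences between plants while preserving the multiplicative
    shape -- the scaled values are pooled, a polynomial (quadratic by
    default) is fitted, and the curve is renormalised to 1 at the
    reference distance.
    """
    groups = list(calibration.groupby("plant_id"))
    if calibration["distance"].nunique() < 3:
        raise ValueError("need calibration spectra at >= 3 distances")
    lo = max(g["distance"].min() for _, g in groups)
    hi = min(g["distance"].max() for _, g in groups)
    if lo >= hi:
        raise ValueError("per-plant distance ranges do not overlap")
    scaled = []
    for _, g in groups:
        m = g["mean_reflectance"].to_numpy(dtype=float)
        if np.any(m <= 0):
            raise ValueError("mean reflectance must be positive")
        scaled.append(pd.DataFrame({"distance": g["distance"], "scaled": m / m.max()}))
    pooled = pd.concat(scaled, ignore_index=True)
    coeffs = np.polyfit(pooled["distance"], pooled["scaled"], deg=degree)
    rng = (float(calibration["distance"].min()), float(calibration["distance"].max()))
    response = DistanceResponse(
        coefficients=coeffs,
        reference_distance=reference_distance,
        calibrated_range=rng,
        calibration_points=pooled,
    )
    grid = np.linspace(rng[0], rng[1], 50)
    if np.any(response(grid) <= 0):
        raise ValueError("fitted distance response is not positive over the calibrated range")
    return response


def correct_reflectance(spectrum: Spectrum, response: DistanceResponse) -> Spectrum:
    """Adjust a spectrum to the white-reference distance: rho / h(d)."""
    lo, hi = response.calibrated_range
    if not lo <= spectrum.distance <= hi:
        warnings.warn(
            f"distance {spectrum.distance} m outside calibrated range [{lo}, {hi}]; extrapolating",
            stacklevel=2,
        )
    h = response(spectrum.distance)
    if h <= 0:
        raise ValueError("distance response is non-positive at this distance")
    return Spectrum(
        wavelengths=spectrum.wavelengths,
        reflectance=spectrum.reflectance / h,
        distance=response.reference_distance,
        pixel_count=spectrum.pixel_count,
    )


def select_intermediate_class(
    pixel_spectra: np.ndarray,
    wavelengths: np.ndarray,
    lower: float = 0.25,
    upper: float = 0.75,
    vnir_max: float = 1000.0,
):
    """Average the intermediate-illumination pixels of one plant.

    Pixels are ranked by broadband VNIR brightness (mean reflectance below
    ``vnir_max`` nm) and only the central order-statistics band
    [floor(n * lower), ceil(n * upper)) is retained, discarding shaded and
    saturated pixels.  Returns the class-mean :class:`Spectrum` with
    ``pixel_count`` set to the retained count.
    """
    pixel_spectra = np.asarray(pixel_spectra, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    n = pixel_spectra.shape[0]
    if n < 10:
        raise ValueError("need >= 10 plant pixels for illumination classification")
    vnir = wavelengths <= vnir_max
    brightness = pixel_spectra[:, vnir].mean(axis=1)
    order = np.argsort(brightness, kind="stable")
    keep = order[int(np.floor(n * lower)) : int(np.ceil(n * upper))]
    if keep.size == 0:
        raise ValueError("illumination quantile band retained no pixels")
    mean = pixel_spectra[keep].mean(axis=0)
    return Spectrum(wavelengths=wavelengths, reflectance=mean, pixel_count=int(keep.size))


# ---------------------------------------------------------------------------
# indices


def nearest_band(wavelengths: np.ndarray, target: float) -> int:
    """Index of the sensor band closest to a named wavelength."""
    return int(np.argmin(np.abs(np.asarray(wavelengths, dtype=float) - target)))


def _ratio(num, den):
    return num / den if den != 0 else np.nan


def _nd(a, b):
    return (a - b) / (a + b) if (a + b) != 0 else np.nan


def compute_hyperspectral_indices(spectrum: Spectrum) -> dict:
    """Water-related reflectance indices (nearest-band lookup).

    The first-derivative ratio uses central differences (``numpy.gradient``)
    on the native wavelength grid.  Zero denominators yield NaN.
    """
    wl = spectrum.wavelengths
    r = spectrum.reflectance

    def b(target):
        return r[nearest_band(wl, target)]

    deriv = np.gradient(r, wl)

    def db(target):
        return deriv[nearest_band(wl, target)]

    return {
        "dSR_660_1040": _ratio(db(660.0), db(1040.0)) if db(1040.0) != 0 else np.nan,
        "ND_1425_2145": _nd(b(1425.0), b(2145.0)),
        "WBI": _ratio(b(900.0), b(970.0)),
        "SR_1440_1460": _ratio(b(1440.0), b(1460.0)),
        "NDWI": _nd(b(857.0), b(1241.0)),
        "RMP_1483_1430": _ratio(b(1483.0), b(1430.0)),
        "WCI": _ratio(b(686.0) - b(955.0), b(955.0) - b(548.0)),
        "WPI2": _ratio(b(665.0) + b(1457.0), b(715.0) + b(1457.0)),
        "R_953_492": _ratio(b(953.0), b(492.0)),
        "NDI_1407_1862": _nd(b(1407.0), b(1862.0)),
    }


def compute_index_table(spectra: dict, extra: pd.DataFrame | None = None) -> pd.DataFrame:
    """Index table for many plants: ``spectra`` maps key -> Spectrum."""
    rows = []
    for key, spectrum in spectra.items():
        row = {"key": key}
        row.update(compute_hyperspectral_indices(spectrum))
        rows.append(row)
    out = pd.DataFrame(rows)
    if extra is not None:
        out = out.merge(extra, on="key", how="left")
    return out
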
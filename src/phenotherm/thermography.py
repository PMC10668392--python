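"""Raw thermal frame processing for top-view plant thermography.

Converts 16-bit raw digital numbers (DN) of an uncooled LWIR camera to
object temperature with the standard thermographic signal decomposition
(Planck-type camera calibration curve, emissivity, reflected-temperature,
atmospheric and protective-window corrections), corrects slow camera drift
against a thermocouple-equipped black reference plate, aligns RGB-derived
plant masks into the thermal frame, and extracts the per-plant median
temperature ``T_p`` together with the imaged dry-reference temperature
``T_dry``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from skimage.morphology import erosion as _gray_erosion, footprint_rectangle
from skimage.transform import ProjectiveTransform, warp

ZERO_C = 273.15

#: FLIR atmospheric transmittance model constants (alpha/beta pairs weight
#: two exponential attenuation terms in sqrt(path length) and sqrt(water
#: vapour content); X mixes them).
ATM_X = 1.9
ATM_ALPHA1 = 0.006569
ATM_ALPHA2 = 0.01262
ATM_BETA1 = -0.002276
ATM_BETA2 = -0.00667


@dataclass
class ThermalCalibration:
    """Camera calibration constants for DN <-> temperature conversion.

    The Planck constants are camera-specific factory values; the defaults
    are those of the FLIR SC645 used on the platform.  ``reflected_T`` is
    measured from crumpled aluminium foil in the scene.
    """

    PlanckR1: float = 16963.094
    PlanckB: float = 1435.3
    PlanckF: float = 1.0
    PlanckO: float = -4328.0
    PlanckR2: float = 0.014514672
    emissivity: float = 0.96
    reflected_T: float = 23.0
    distance: float = 3.5
    window_T: float = 20.0
    window_transmission: float = 1.0

    def __post_init__(self) -> None:
        if self.PlanckB <= 0:
            raise ValueError("PlanckB must be positive")
        if not 0 < self.emissivity <= 1:
            raise ValueError("emissivity must be in (0, 1]")
        if not 0 < self.window_transmission <= 1:
            raise ValueError("window_transmission must be in (0, 1]")


Rect = tuple[int, int, int, int]  # (row0, row1, col0, col1), half-open


@dataclass
class ThermalFrame:
    """One raw thermal acquisition plus everything needed to process it.

    ``env`` is any object exposing ``T_a`` and ``RH`` attributes for the
    in-cabin monitoring position.  Reference regions are half-open pixel
    rectangles ``(row0, row1, col0, col1)``.
    """

    raw: np.ndarray
    calibration: ThermalCalibration
    env: object
    plate_region: Rect
    foil_region: Rect
    plate_thermocouple_T: float | None = None
    timestamp: object = None
    plant_id: str | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw)
        if np.any(self.raw < 0):
            raise ValueError("raw DN must be non-negative")
        nrow, ncol = self.raw.shape
        for name, (r0, r1, c0, c1) in (
            ("plate_region", self.plate_region),
            ("foil_region", self.foil_region),
        ):
            if not (0 <= r0 < r1 <= nrow and 0 <= c0 < c1 <= ncol):
                raise ValueError(f"{name} outside frame bounds")


def planck_signal(T, calibration: ThermalCalibration | None = None):
    """Camera signal (DN scale) emitted by a blackbody at temperature ``T`` degC.

    ``S = R1 / (R2 (exp(B / T_K) - F)) - O``; strictly increasing in T.
    """
    cal = calibration or ThermalCalibration()
    T_k = np.asarray(T, dtype=float) + ZERO_C
    if np.any(T_k <= 0):
        raise ValueError("temperature must exceed absolute zero")
    return cal.PlanckR1 / (cal.PlanckR2 * (np.exp(cal.PlanckB / T_k) - cal.PlanckF)) - cal.PlanckO


def inverse_planck_signal(S, calibration: ThermalCalibration | None = None):
    """Invert :func:`planck_signal`.  Invalid signals map to NaN."""
    cal = calibration or ThermalCalibration()
    S = np.asarray(S, dtype=float)
    shifted = S + cal.PlanckO
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = cal.PlanckR1 / (cal.PlanckR2 * shifted) + cal.PlanckF
        out = np.where(
            (shifted > 0) & (arg > 1.0),
            cal.PlanckB / np.log(np.where(arg > 1.0, arg, 2.0)) - ZERO_C,
            np.nan,
        )
    return float(out) if out.ndim == 0 else out


def water_vapour_content(T_a: float, RH: float) -> float:
    """Water vapour content of air (g m-3 scale) in the FLIR polynomial."""
    return (RH / 100.0) * np.exp(
        1.5587 + 0.06939 * T_a - 0.00027816 * T_a**2 + 0.00000068455 * T_a**3
    )


def atmospheric_transmittance(distance: float, T_a: float, RH: float) -> float:
    """Atmospheric transmittance over ``distance`` m of humid air.

    Standard two-term exponential attenuation model; at the few metres of
    an indoor imaging cabin tau is very close to 1.
    """
    omega = water_vapour_content(T_a, RH)
    sq_d = np.sqrt(distance)
    sq_w = np.sqrt(omega)
    return ATM_X * np.exp(-sq_d * (ATM_ALPHA1 + ATM_BETA1 * sq_w)) + (1.0 - ATM_X) * np.exp(
        -sq_d * (ATM_ALPHA2 + ATM_BETA2 * sq_w)
    )


def _path_terms(cal: ThermalCalibration, T_a: float, RH: float):
    tau = atmospheric_transmittance(cal.distance, T_a, RH)
    tau_w = cal.window_transmission
    eps = cal.emissivity
    s_refl = planck_signal(cal.reflected_T, cal)
    s_atm = planck_signal(T_a, cal)
    s_win = planck_signal(cal.window_T, cal)
    return tau, tau_w, eps, s_refl, s_atm, s_win


def raw_to_temperature(frame: ThermalFrame):
    """Convert a raw frame to object temperature.

    Removes reflected, atmospheric and window radiance from the measured
    signal before inverting the camera calibration curve:

    ``S_obj = raw/(eps tau tau_w) - S(T_refl)(1-eps)/eps
      - S(T_a)(1-tau)/(eps tau) - S(T_win)(1-tau_w)/(eps tau tau_w)``

    Returns
    -------
    T : ndarray
        Object temperature grid in degC; invalid pixels (signal outside
        the invertible domain) are NaN.
    """
    cal = frame.calibration
    T_a, RH = float(frame.env.T_a), float(frame.env.RH)
    tau, tau_w, eps, s_refl, s_atm, s_win = _path_terms(cal, T_a, RH)
    raw = frame.raw.astype(float)
    s_obj = (
        raw / (eps * tau * tau_w)
        - s_refl * (1.0 - eps) / eps
        - s_atm * (1.0 - tau) / (eps * tau)
        - s_win * (1.0 - tau_w) / (eps * tau * tau_w)
    )
    T = inverse_planck_signal(s_obj, cal)
    n_bad = int(np.sum(~np.isfinite(T)))
    if n_bad:
        warnings.warn(f"{n_bad} pixels outside the invertible signal domain", stacklevel=2)
    return T


def temperature_to_raw(T, calibration: ThermalCalibration, T_a: float, RH: float, round_dn: bool = False):
    """Exact forward model of :func:`raw_to_temperature`.

    Used by the scene generator to render frames.  ``round_dn`` rounds to
    integer DN (the final rendering step only).
    """
    cal = calibration
    tau, tau_w, eps, s_refl, s_atm, s_win = _path_terms(cal, T_a, RH)
    raw = (
        eps * tau * tau_w * planck_signal(T, cal)
        + tau * tau_w * (1.0 - eps) * s_refl
        + tau_w * (1.0 - tau) * s_atm
        + (1.0 - tau_w) * s_win
    )
    if round_dn:
        raw = np.rint(raw)
    return raw


# ---------------------------------------------------------------------------
# drift correction


def correct_drift(
    frames: Sequence[ThermalFrame],
    temperatures: Sequence[np.ndarray] | None = None,
    window: int = 20,
    threshold: float = 1.0,
):
    """Correct slow camera drift against the black-plate thermocouple.

    For each frame ``d`` is the imaged plate median minus the thermocouple
    reading.  A frame is adjusted (window-median ``d`` subtracted from all
    pixels) only when the rolling-window median of ``|d|`` exceeds
    ``threshold`` degC, i.e. the discrepancy is consistent and not a
    single-frame glitch.  Frames without a thermocouple value pass through
    unadjusted and flagged.

    Returns
    -------
    corrected : list of ndarray
        Temperature grids after adjustment.
    report : DataFrame
        Per-frame columns ``d``, ``applied_offset``, ``adjusted``,
        ``missing_thermocouple``.
    """
    if temperatures is None:
        temperatures = [raw_to_temperature(f) for f in frames]
    d = np.full(len(frames), np.nan)
    missing = np.zeros(len(frames), dtype=bool)
    for i, (frame, T) in enumerate(zip(frames, temperatures)):
        if frame.plate_thermocouple_T is None:
            missing[i] = True
            continue
        r0, r1, c0, c1 = frame.plate_region
        d[i] = np.nanmedian(T[r0:r1, c0:c1]) - frame.plate_thermocouple_T
    ds = pd.Series(d)
    roll = ds.rolling(window, center=True, min_periods=1)
    med_abs = ds.abs().rolling(window, center=True, min_periods=1).median()
    med_d = roll.median()
    adjusted = (med_abs > threshold).to_numpy() & ~missing & np.isfinite(d)
    offsets = np.where(adjusted, -med_d.to_numpy(), 0.0)
    corrected = [T + off for T, off in zip(temperatures, offsets)]
    report = pd.DataFrame(
        {
            "d": d,
            "applied_offset": offsets,
            "adjusted": adjusted,
            "missing_thermocouple": missing,
        }
    )
    return corrected, report


# ---------------------------------------------------------------------------
# mask alignment


def align_mask(
    rgb_mask: np.ndarray,
    K_rgb: np.ndarray,
    K_tir: np.ndarray,
    translation: Callable[[float], np.ndarray] | np.ndarray,
    plant_height: float,
    camera_height: float,
    out_shape: tuple[int, int] = (480, 640),
    erosion_radius: int = 1,
):
    """Reproject an RGB-frame plant mask into the thermal frame.

    Mask pixels are back-projected at a single depth -- the distance from
    the camera to 2/3 of the plant height -- translated by the
    depth-dependent extrinsic translation, and re-projected with the
    thermal intrinsics.  A morphological erosion (square footprint of side
    ``2 r + 1``) then strips mixed border pixels.

    Parameters
    ----------
    translation : callable or array
        Either a length-3 translation vector (metres) or a function of
        depth returning one.
    plant_height, camera_height : float
        Metres; depth used is ``camera_height - 2/3 * plant_height``.

    Returns
    -------
    mask : ndarray of bool
        Thermal-frame mask.
    empty : bool
        True when nothing survives the erosion.
    """
    depth = camera_height - 2.0 / 3.0 * plant_height
    if depth <= 0:
        raise ValueError("plant reaches above the camera; invalid depth")
    t = translation(depth) if callable(translation) else np.asarray(translation, dtype=float)
    t = np.asarray(t, dtype=float).reshape(3)
    K_rgb = np.asarray(K_rgb, dtype=float)
    K_tir = np.asarray(K_tir, dtype=float)
    A = np.zeros((3, 3))
    A[:, 2] = t / depth
    H = K_tir @ (np.linalg.inv(K_rgb) + A)
    # skimage transforms act on (x, y) = (col, row) coordinates; the
    # pinhole matrices here are built the same way.
    tform = ProjectiveTransform(matrix=H)
    out = warp(
        rgb_mask.astype(float),
        tform.inverse,
        output_shape=out_shape,
        order=0,
        preserve_range=True,
    )
    mask = out > 0.5
    if erosion_radius > 0:
        side = 2 * erosion_radius + 1
        mask = _gray_erosion(mask, footprint_rectangle((side, side))).astype(bool)
    return mask, not bool(mask.any())


# ---------------------------------------------------------------------------
# extraction


def extract_plant_temperature(T: np.ndarray, mask: np.ndarray, plate_region: Rect):
    """Median plant temperature and imaged dry-reference temperature.

    Returns
    -------
    result : dict
        ``T_p``, ``T_dry``, ``n_valid`` and ``reason`` (None when valid;
        otherwise why ``T_p`` is missing).  Invalid (NaN) pixels are
        excluded from both medians.
    """
    mask = np.asarray(mask, dtype=bool)
    r0, r1, c0, c1 = plate_region
    plate = T[r0:r1, c0:c1]
    t_dry = float(np.nanmedian(plate)) if np.any(np.isfinite(plate)) else np.nan
    if not mask.any():
        return {"T_p": np.nan, "T_dry": t_dry, "n_valid": 0, "reason": "empty mask"}
    vals = T[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return {"T_p": np.nan, "T_dry": t_dry, "n_valid": 0, "reason": "no valid pixels"}
    return {"T_p": float(np.median(vals)), "T_dry": t_dry, "n_valid": int(vals.size), "reason": None}


def process_frames(
    frames: Sequence[ThermalFrame],
    masks: Sequence[np.ndarray],
    drift_window: int = 20,
    drift_threshold: float = 1.0,
) -> pd.DataFrame:
    """Run the frame pipeline: convert, drift-correct, extract T_p / T_dry."""
    corrected, report = correct_drift(frames, window=drift_window, threshold=drift_threshold)
    rows = []
    for frame, T, mask, (_, rep) in zip(frames, corrected, masks, report.iterrows()):
        res = extract_plant_temperature(T, mask, frame.plate_region)
        rows.append(
            {
                "plant_id": frame.plant_id,
                "timestamp": frame.timestamp,
                "T_p": res["T_p"],
                "T_dry": res["T_dry"],
                "n_valid_pixels": res["n_valid"],
                "drift_applied": rep["applied_offset"],
            }
        )
    return pd.DataFrame(rows)
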
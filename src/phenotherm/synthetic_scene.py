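"""Synthetic phenotyping-platform experiments with known ground truth.

Emulates an indoor maize drought experiment on an automated imaging
platform: a diurnal greenhouse environment (air temperature rising from
22 degC at night to 28 degC in the afternoon, VPD from 1.5 to 3 kPa, a
daytime PAR plateau near 280 umol m-2 s-1) monitored at three positions
(growth zone ``gz``, inside ``in`` and outside ``out`` the imaging cabin),
well-watered and water-deficit treatments defined by gravimetric soil
water content, genotype-specific stomatal behaviour, raw 16-bit thermal
frames containing a black dry-reference plate and an aluminium-foil
reflected-temperature reference, and VNIR+SWIR reflectance spectra whose
water-absorption troughs track leaf water status and whose overall level
declines with camera-plant distance.

Every quantity the downstream modules estimate (T_p, T_dry, E, g_s, psi)
is available as ground truth, so the processing chain can be validated by
parameter recovery rather than against withheld data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .energy_balance import EBParams, forward_leaf_temperature, transpiration_from_conductance
from .thermography import Rect, ThermalCalibration, ThermalFrame, temperature_to_raw

#: Tetens saturation vapour pressure constants (kPa, degC)
TETENS_A = 0.61078
TETENS_B = 17.27
TETENS_C = 237.3

POSITIONS = ("gz", "in", "out")

#: gravimetric soil water content (g H2O / g dry soil) -> soil water
#: potential (MPa); anchors follow the treatment definitions of the study
#: system (2.4 g/g ~ -10 kPa well-watered down to 0.8 g/g below the
#: wilting point).
_SOIL_PSI_POINTS = (
    (0.8, -2.0),
    (1.0, -1.6),
    (1.4, -0.35),
    (1.6, -0.15),
    (1.8, -0.08),
    (2.4, -0.01),
)
_soil_psi_interp = PchipInterpolator(
    [s for s, _ in _SOIL_PSI_POINTS], [np.log(-p) for _, p in _SOIL_PSI_POINTS]
)


def saturation_vapor_pressure(T_a):
    """Tetens saturation vapour pressure e_s(T_a), kPa."""
    T_a = np.asarray(T_a, dtype=float)
    return TETENS_A * np.exp(TETENS_B * T_a / (T_a + TETENS_C))


def vpd_from_t_rh(T_a, RH):
    """Vapour pressure deficit (kPa) from air temperature and RH.

    ``VPD = e_s(T_a) * (1 - RH/100)`` with the Tetens formula for e_s.
    """
    T_a = np.asarray(T_a, dtype=float)
    RH = np.asarray(RH, dtype=float)
    if np.any(T_a <= -40) or np.any(T_a >= 60):
        raise ValueError("T_a outside the (-40, 60) degC domain")
    if np.any(RH < 0) or np.any(RH > 100):
        raise ValueError("RH must lie in [0, 100]")
    out = saturation_vapor_pressure(T_a) * (1.0 - RH / 100.0)
    return float(out) if out.ndim == 0 else out


def rh_from_t_vpd(T_a, VPD):
    """Relative humidity realising a target VPD at a given T_a (clipped to [0, 100])."""
    es = saturation_vapor_pressure(T_a)
    rh = 100.0 * (1.0 - np.asarray(VPD, dtype=float) / es)
    out = np.clip(rh, 0.0, 100.0)
    return float(out) if out.ndim == 0 else out


def soil_water_potential(soil_water):
    """Soil water potential (MPa) from gravimetric soil water content (g/g)."""
    s = np.clip(np.asarray(soil_water, dtype=float), 0.8, 2.4)
    out = -np.exp(_soil_psi_interp(s))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# configuration


@dataclass
class EnvConfig:
    """Diurnal environment waveform and monitoring-position offsets.

    The temperature and VPD cycles are clipped sinusoids: flat at the
    night level outside the warm phase, a half-sine between ``warm_start``
    and ``warm_end`` peaking mid-afternoon.  Position offsets are constant
    daytime biases matching the reported position means (out > in > gz).
    """

    t_night: float = 22.0
    t_day: float = 28.0
    vpd_night: float = 1.5
    vpd_day: float = 3.0
    warm_start: float = 9.0
    warm_end: float = 21.0
    lights_on: float = 6.0
    lights_off: float = 22.0
    par_day: float = 280.0
    t_a_offsets: dict = field(default_factory=lambda: {"gz": 0.0, "in": 0.53, "out": 2.0})
    vpd_offsets: dict = field(default_factory=lambda: {"gz": 0.0, "in": 0.1, "out": 0.4})
    tbs_day_offset: float = 1.5
    t_noise_sd: float = 0.2
    vpd_noise_sd: float = 0.05
    par_noise_sd: float = 5.0
    sample_minutes: int = 60


@dataclass
class GenotypeParams:
    """Stomatal response parameters of one genotype.

    ``g_s = g_night + (g_max * f_sw * f_vpd - g_night) * f_par`` with a
    saturating soil-water response (normalised to 1 at the well-watered
    content 2.4 g/g), a hyperbolic VPD decline and a rectangular-hyperbola
    light response that switches off to the nocturnal floor in the dark.
    """

    name: str = "B104"
    g_max: float = 0.35
    sw_midpoint: float = 1.5
    sw_steepness: float = 3.5
    vpd_half: float = 3.0
    par_half: float = 150.0
    g_night: float = 0.02
    g_max_cv: float = 0.08
    hydraulic_resistance: float = 0.05

    def __post_init__(self) -> None:
        vals = [self.g_max, self.sw_midpoint, self.sw_steepness, self.vpd_half, self.par_half]
        if not all(np.isfinite(vals)):
            raise ValueError("genotype parameters must be finite")
        if self.g_max <= 0 or self.g_night < 0:
            raise ValueError("conductance parameters must be non-negative (g_max > 0)")


@dataclass
class SceneConfig:
    """Full description of a synthetic platform experiment."""

    random_seed: int = 0
    n_plants: int = 10
    n_days: int = 20
    genotypes: list = field(default_factory=lambda: [GenotypeParams("B104")])
    treatments: dict = field(default_factory=lambda: {"WW": 2.4, "WD": 1.4})
    wd_ramp_days: int = 8
    env: EnvConfig = field(default_factory=EnvConfig)
    eb: EBParams = field(default_factory=lambda: EBParams(wind_speed=1.0))
    calibration: ThermalCalibration = field(default_factory=ThermalCalibration)
    # frame geometry
    frame_shape: tuple = (480, 640)
    plate_region: Rect = (20, 60, 20, 100)
    foil_region: Rect = (20, 60, 540, 620)
    plant_radius_px: int = 60
    # noise levels
    thermal_dn_sd: float = 2.0
    texture_sd: float = 0.1
    tp_noise_sd: float = 0.15
    reflectance_sd: float = 0.002
    drift_offset: float = 0.0
    # radiative load and boundary-layer variability
    rad_base: float = 10.0
    rad_par_coeff: float = 0.07
    rad_noise_sd: float = 5.0
    wind_jitter_sd: float = 0.15
    # hyperspectral distance response h(d) = 1 + a (d - ref) + b (d - ref)^2
    reference_distance: float = 1.2
    distance_coeff_lin: float = -0.07
    distance_coeff_quad: float = -0.0074
    # growth / biomass
    silking_day: int = 30
    ww_fresh_weight_silking: float = 615.3
    wd_fresh_weight_ratio: float = 375.3 / 615.3
    fresh_weight_cv: float = 0.115
    attrition_end_n: int | None = None
    start_date: datetime = field(default_factory=lambda: datetime(2021, 6, 1))

    def __post_init__(self) -> None:
        for sd in (self.thermal_dn_sd, self.texture_sd, self.reflectance_sd, self.tp_noise_sd):
            if sd < 0:
                raise ValueError("noise standard deviations must be >= 0")
        for name, sw in self.treatments.items():
            if not 0.8 <= sw <= 2.4:
                raise ValueError(f"treatment {name!r} soil water {sw} outside [0.8, 2.4]")
        p = self.plate_region
        f = self.foil_region
        if not (p[1] <= f[0] or f[1] <= p[0] or p[3] <= f[2] or f[3] <= p[2]):
            raise ValueError("plate and foil reference regions overlap")


@dataclass
class PlantTruth:
    """Ground truth for one plant at one timepoint."""

    plant_id: str
    genotype: str
    treatment: str
    soil_water: float
    day_after_V5: int
    g_s_true: float
    E_true: float
    psi_true: float
    T_p_true: float
    T_dry_true: float
    leaf_water_fraction: float
    fresh_weight: float
    plant_height: float


# ---------------------------------------------------------------------------
# environment


def _warm_fraction(cfg: EnvConfig, hour):
    """Clipped half-sine in [0, 1]; 0 at night, 1 at the afternoon peak."""
    hour = np.asarray(hour, dtype=float) % 24.0
    span = cfg.warm_end - cfg.warm_start
    frac = np.sin(np.pi * (hour - cfg.warm_start) / span)
    return np.clip(np.where((hour >= cfg.warm_start) & (hour <= cfg.warm_end), frac, 0.0), 0.0, 1.0)


def _daylight(cfg: EnvConfig, hour):
    hour = np.asarray(hour, dtype=float) % 24.0
    return (hour >= cfg.lights_on) & (hour < cfg.lights_off)


def environment_at(config: SceneConfig, hour, position: str, rng: np.random.Generator | None = None):
    """Environment state at a clock hour for one monitoring position.

    Noise-free when ``rng`` is None.  RH is always derived from the final
    (T_a, VPD) pair so the Tetens consistency invariant holds exactly.
    """
    if position not in POSITIONS:
        raise ValueError(f"unknown position {position!r}")
    cfg = config.env
    w = _warm_fraction(cfg, hour)
    day = _daylight(cfg, hour)
    t_a = cfg.t_night + (cfg.t_day - cfg.t_night) * w + cfg.t_a_offsets[position] * day
    vpd = cfg.vpd_night + (cfg.vpd_day - cfg.vpd_night) * w + cfg.vpd_offsets[position] * day
    if rng is not None:
        t_a = t_a + rng.normal(0.0, cfg.t_noise_sd, size=np.shape(t_a))
        vpd = vpd + rng.normal(0.0, cfg.vpd_noise_sd, size=np.shape(vpd))
    vpd = np.maximum(vpd, 0.0)
    rh = rh_from_t_vpd(t_a, vpd)
    vpd = vpd_from_t_rh(t_a, rh)  # exact consistency after clipping
    out = {"T_a": t_a, "RH": rh, "VPD": vpd, "PAR": np.nan, "T_BS": np.nan}
    if position == "gz":
        par = np.where(day, cfg.par_day, 0.0)
        if rng is not None:
            par = np.maximum(par + rng.normal(0.0, cfg.par_noise_sd, size=np.shape(par)) * day, 0.0)
        out["PAR"] = par
        out["T_BS"] = t_a + cfg.tbs_day_offset * np.asarray(par) / cfg.par_day
    return out


def generate_environment(config: SceneConfig, n_days: int, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate the environment record series for all three positions.

    Returns a tidy frame with columns ``timestamp, position, T_a, RH, VPD,
    PAR, T_BS`` (PAR and T_BS only for the growth zone).  Reproducible for
    a fixed ``config.random_seed``.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.random_seed)
    step = config.env.sample_minutes
    n_per_day = (24 * 60) // step
    hours = np.arange(n_days * n_per_day) * step / 60.0
    timestamps = [config.start_date + timedelta(minutes=int(h * 60)) for h in hours]
    frames = []
    for position in POSITIONS:
        state = environment_at(config, hours, position, rng=rng)
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": timestamps,
                    "position": position,
                    "T_a": state["T_a"],
                    "RH": state["RH"],
                    "VPD": state["VPD"],
                    "PAR": state["PAR"],
                    "T_BS": state["T_BS"],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# plant physiology


def soil_water_response(params: GenotypeParams, soil_water):
    """Saturating soil-water factor, exactly 1 at 2.4 g/g and < 0.5 at 1.4."""
    s = np.asarray(soil_water, dtype=float)
    logistic = lambda x: 1.0 / (1.0 + np.exp(-params.sw_steepness * (x - params.sw_midpoint)))
    out = logistic(s) / logistic(2.4)
    return float(out) if out.ndim == 0 else out


def stomatal_conductance(params: GenotypeParams, soil_water, VPD, PAR, g_max: float | None = None):
    """Stomatal conductance (mol H2O m-2 s-1) of the phenomenological model."""
    g_max = params.g_max if g_max is None else g_max
    f_sw = soil_water_response(params, soil_water)
    f_vpd = 1.0 / (1.0 + np.asarray(VPD, dtype=float) / params.vpd_half)
    par = np.asarray(PAR, dtype=float)
    f_par = par / (par + params.par_half)
    out = params.g_night + (g_max * f_sw * f_vpd - params.g_night) * f_par
    out = np.maximum(out, 0.0)
    return float(out) if np.ndim(out) == 0 else out


def _fresh_weight(config: SceneConfig, treatment: str, day: int) -> float:
    t_mid, tau = 0.6 * config.silking_day, 0.2 * config.silking_day
    ww = config.ww_fresh_weight_silking * (1.0 + np.exp(-(config.silking_day - t_mid) / tau))
    fw = ww / (1.0 + np.exp(-(day - t_mid) / tau))
    if treatment == "WD":
        frac = min(max(day, 0) / config.silking_day, 1.0)
        fw *= 1.0 - (1.0 - config.wd_fresh_weight_ratio) * frac
    return fw


def soil_water_trajectory(config: SceneConfig, treatment: str, day: int) -> float:
    """Soil water content on a given day after V5 (drought onset at day 0).

    WW plants stay at the well-watered content; WD plants dry down
    linearly from it over ``wd_ramp_days`` (water withheld) and are then
    held at the treatment target.
    """
    target = config.treatments[treatment]
    ww = max(config.treatments.values())
    if treatment == "WW" or day <= 0:
        return ww if treatment == "WW" else ww
    frac = min(day / config.wd_ramp_days, 1.0)
    return ww + (target - ww) * frac


def simulate_plant_day(
    genotype: GenotypeParams,
    soil_water: float,
    env_day: dict,
    config: SceneConfig | None = None,
    *,
    eb_params: EBParams | None = None,
    net_radiation: float | None = None,
    g_max: float | None = None,
    plant_id: str = "P0",
    treatment: str = "WW",
    day_after_V5: int = 0,
) -> PlantTruth:
    """Simulate one plant at one imaging timepoint.

    ``env_day`` maps position -> environment dict (as produced by
    :func:`environment_at`); stomata respond to growth-zone PAR and VPD,
    while the leaf temperature forms under the in-cabin air during
    imaging.
    """
    config = config or SceneConfig()
    if not 0.5 <= soil_water <= 3.0:
        raise ValueError("soil_water outside the supported [0.5, 3.0] g/g range")
    eb = eb_params or config.eb
    gz, cabin = env_day["gz"], env_day["in"]
    g_s = stomatal_conductance(genotype, soil_water, gz["VPD"], gz["PAR"], g_max=g_max)
    e_true = transpiration_from_conductance(g_s, cabin["VPD"], eb)
    rn = net_radiation
    if rn is None:
        rn = config.rad_base + config.rad_par_coeff * float(np.nan_to_num(gz["PAR"]))
    t_p, t_dry = forward_leaf_temperature(cabin["T_a"], params=eb, E=e_true, net_radiation=rn)
    r_h = genotype.hydraulic_resistance * (2.4 / soil_water) ** 2
    psi = soil_water_potential(soil_water) - e_true * r_h
    lwf = float(np.clip(0.92 + 0.12 * psi, 0.3, 0.98))
    fw = _fresh_weight(config, treatment, day_after_V5)
    height = float(np.clip(0.25 + 1.3 * max(day_after_V5, 0) / config.silking_day, 0.2, 1.8))
    return PlantTruth(
        plant_id=plant_id,
        genotype=genotype.name,
        treatment=treatment,
        soil_water=float(soil_water),
        day_after_V5=int(day_after_V5),
        g_s_true=float(g_s),
        E_true=float(e_true),
        psi_true=float(psi),
        T_p_true=float(t_p),
        T_dry_true=float(t_dry),
        leaf_water_fraction=lwf,
        fresh_weight=float(fw),
        plant_height=height,
    )


# ---------------------------------------------------------------------------
# thermal frame rendering


def render_thermal_frame(
    T_p_true: float,
    T_dry_true: float,
    env_in,
    config: SceneConfig,
    rng: np.random.Generator | None = None,
    drift_offset: float | None = None,
    timestamp=None,
    plant_id: str | None = None,
):
    """Render a raw 16-bit thermal frame plus its ground-truth plant mask.

    Background and foil sit at the reflected temperature, the black plate
    at the dry-reference temperature and the plant silhouette (a centred
    disk) at ``T_p_true`` plus optional within-plant texture.  The
    temperature field is pushed through the exact forward model of
    :func:`phenotherm.thermography.raw_to_temperature`, an optional camera
    drift offset is added in temperature space, and DN noise is applied
    before integer rounding.
    """
    cal = config.calibration
    nrow, ncol = config.frame_shape
    drift = config.drift_offset if drift_offset is None else drift_offset
    rr, cc = np.mgrid[0:nrow, 0:ncol]
    mask = (rr - nrow / 2.0) ** 2 + (cc - ncol / 2.0) ** 2 <= config.plant_radius_px**2
    temp = np.full((nrow, ncol), float(cal.reflected_T))
    plant = np.full(int(mask.sum()), float(T_p_true))
    if rng is not None and config.texture_sd > 0:
        plant = plant + rng.normal(0.0, config.texture_sd, size=plant.shape)
    temp[mask] = plant
    r0, r1, c0, c1 = config.plate_region
    temp[r0:r1, c0:c1] = T_dry_true
    r0, r1, c0, c1 = config.foil_region
    temp[r0:r1, c0:c1] = cal.reflected_T
    if mask[config.plate_region[0]:config.plate_region[1], config.plate_region[2]:config.plate_region[3]].any():
        raise ValueError("plant silhouette overlaps the plate reference region")
    env_t_a = float(env_in["T_a"] if isinstance(env_in, dict) else env_in.T_a)
    env_rh = float(env_in["RH"] if isinstance(env_in, dict) else env_in.RH)
    raw = temperature_to_raw(temp + drift, cal, env_t_a, env_rh)
    if rng is not None and config.thermal_dn_sd > 0:
        raw = raw + rng.normal(0.0, config.thermal_dn_sd, size=raw.shape)
    raw = np.clip(np.rint(raw), 0, 65535).astype(np.uint16)

    class _Env:
        T_a = env_t_a
        RH = env_rh

    frame = ThermalFrame(
        raw=raw,
        calibration=cal,
        env=_Env(),
        plate_region=config.plate_region,
        foil_region=config.foil_region,
        plate_thermocouple_T=float(T_dry_true),
        timestamp=timestamp,
        plant_id=plant_id,
    )
    return frame, mask


# ---------------------------------------------------------------------------
# spectra


def default_wavelength_grid():
    """Combined VNIR (400-1000 nm at 3 nm) + SWIR (970-2500 nm at 6.3 nm) grid.

    VNIR bands above the SWIR start are dropped so the merged grid is
    strictly increasing.
    """
    vnir = np.arange(400.0, 1000.0 + 1e-9, 3.0)
    swir = np.arange(970.0, 2500.0 + 1e-9, 6.3)
    return np.concatenate([vnir[vnir < swir[0]], swir])


def _gauss(wl, center, sigma):
    return np.exp(-((wl - center) ** 2) / (2.0 * sigma**2))


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def vegetation_reflectance(wavelengths, leaf_water_fraction: float, pigment_level: float = 1.0):
    """Noise-free leaf reflectance: smooth baseline plus Gaussian features.

    Water-absorption troughs near 970, 1200, 1450 and 1940 nm deepen with
    ``leaf_water_fraction``; a broad NIR scattering term also declines
    with hydration, so the 900/970 nm ratio falls as water status rises.
    Green reflectance and the red absorption dip scale with
    ``pigment_level``.
    """
    wl = np.asarray(wavelengths, dtype=float)
    lwf = float(leaf_water_fraction)
    r = 0.06 + 0.42 * _logistic((wl - 710.0) / 15.0)
    r = r + 0.05 * pigment_level * _gauss(wl, 550.0, 25.0)
    r = r - 0.02 * pigment_level * _gauss(wl, 670.0, 30.0)
    r = r - 0.20 * _logistic((wl - 1350.0) / 150.0)
    r = r - lwf * (
        0.04 * _gauss(wl, 970.0, 30.0)
        + 0.05 * _gauss(wl, 1200.0, 35.0)
        + 0.32 * _gauss(wl, 1450.0, 45.0)
        + 0.26 * _gauss(wl, 1940.0, 60.0)
        + 0.10 * _gauss(wl, 880.0, 60.0)  # structural NIR scattering term
    )
    return np.maximum(r, 0.005)


def distance_factor(distance_m, config: SceneConfig | None = None):
    """Monotone decreasing broadband distance response h(d) with h(1.2 m) = 1."""
    config = config or SceneConfig()
    d = np.asarray(distance_m, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distance must be positive")
    x = d - config.reference_distance
    out = 1.0 + config.distance_coeff_lin * x + config.distance_coeff_quad * x**2
    return float(out) if out.ndim == 0 else out


def render_spectrum(
    leaf_water_fraction: float,
    pigment_level: float,
    distance_m: float,
    config: SceneConfig | None = None,
    rng: np.random.Generator | None = None,
    wavelengths: np.ndarray | None = None,
):
    """Render one plant-average reflectance spectrum at a camera distance.

    Returns ``(wavelengths, reflectance)``.  Deterministic when ``rng`` is
    None; otherwise adds Gaussian noise of sd ``config.reflectance_sd``.
    """
    config = config or SceneConfig()
    wl = default_wavelength_grid() if wavelengths is None else np.asarray(wavelengths, dtype=float)
    r = vegetation_reflectance(wl, leaf_water_fraction, pigment_level)
    r = r * distance_factor(distance_m, config)
    if rng is not None and config.reflectance_sd > 0:
        r = r + rng.normal(0.0, config.reflectance_sd, size=r.shape)
    return wl, np.maximum(r, 0.0)


def render_pixel_spectra(
    leaf_water_fraction: float,
    pigment_level: float,
    distance_m: float,
    n_pixels: int,
    config: SceneConfig | None = None,
    rng: np.random.Generator | None = None,
    brightness_sd: float = 0.15,
):
    """Per-pixel spectra with lognormal illumination variation across pixels."""
    config = config or SceneConfig()
    rng = rng or np.random.default_rng(config.random_seed)
    wl, base = render_spectrum(leaf_water_fraction, pigment_level, distance_m, config)
    scale = np.exp(rng.normal(0.0, brightness_sd, size=n_pixels))
    spectra = base[None, :] * scale[:, None]
    if config.reflectance_sd > 0:
        spectra = spectra + rng.normal(0.0, config.reflectance_sd, size=spectra.shape)
    return wl, np.maximum(spectra, 0.0)


# ---------------------------------------------------------------------------
# full experiment


def _plants_on_day(config: SceneConfig, day: int) -> int:
    if config.attrition_end_n is None:
        return config.n_plants
    frac = day / max(config.n_days - 1, 1)
    return int(round(config.n_plants + (config.attrition_end_n - config.n_plants) * frac))


def simulate_experiment(config: SceneConfig) -> dict:
    """Simulate a full experiment; returns ``{"truth": DataFrame, "env": DataFrame}``.

    One observation per plant per day at a random imaging hour between
    7:30 and 14:00.  The truth table carries both ground-truth physiology
    and the "measured" T_p / T_dry (truth plus thermal measurement noise),
    the per-observation environment at every monitoring position, the
    realised radiative load and boundary-layer wind, and the plant's
    spectrum-level water status -- everything the downstream stages need
    without rendering full frames.
    """
    rng = np.random.default_rng(config.random_seed)
    env = generate_environment(config, config.n_days, rng=np.random.default_rng(config.random_seed + 1))
    rows = []
    for genotype in config.genotypes:
        for treatment in config.treatments:
            g_max_i = genotype.g_max * np.exp(
                rng.normal(0.0, genotype.g_max_cv, size=config.n_plants)
            )
            for p in range(config.n_plants):
                plant_id = f"{genotype.name}_{treatment}_{p:02d}"
                for day in range(config.n_days):
                    if p >= _plants_on_day(config, day):
                        continue
                    hour = rng.uniform(7.5, 14.0)
                    env_day = {
                        pos: environment_at(config, hour, pos, rng=rng) for pos in POSITIONS
                    }
                    sw = soil_water_trajectory(config, treatment, day)
                    rn = (
                        config.rad_base
                        + config.rad_par_coeff * float(env_day["gz"]["PAR"])
                        + rng.normal(0.0, config.rad_noise_sd)
                    )
                    wind = config.eb.wind_speed * np.exp(rng.normal(0.0, config.wind_jitter_sd))
                    eb_i = replace(config.eb, wind_speed=wind)
                    truth = simulate_plant_day(
                        genotype,
                        sw,
                        env_day,
                        config,
                        eb_params=eb_i,
                        net_radiation=rn,
                        g_max=float(g_max_i[p]),
                        plant_id=plant_id,
                        treatment=treatment,
                        day_after_V5=day,
                    )
                    row = dataclasses.asdict(truth)
                    row["timestamp"] = config.start_date + timedelta(days=day, hours=hour)
                    row["hour"] = hour
                    row["net_radiation"] = rn
                    row["wind_speed"] = wind
                    row["T_p"] = truth.T_p_true + rng.normal(0.0, config.tp_noise_sd)
                    row["T_dry"] = truth.T_dry_true + rng.normal(0.0, config.tp_noise_sd / 2.0)
                    for pos in POSITIONS:
                        for key in ("T_a", "RH", "VPD"):
                            row[f"{key}_{pos}"] = float(env_day[pos][key])
                    row["PAR_gz"] = float(env_day["gz"]["PAR"])
                    row["T_BS_gz"] = float(env_day["gz"]["T_BS"])
                    rows.append(row)
    truth = pd.DataFrame(rows)
    return {"truth": truth, "env": env}
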
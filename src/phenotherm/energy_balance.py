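"""Simplified leaf energy balance with a dry reference surface.

Transpiration (latent heat) cools a leaf below the temperature of a
non-transpiring reference that absorbs the same radiative load and shares
the same boundary layer.  Under the isothermal net-radiation linearisation
the latent heat flux is proportional to the temperature depression of the
leaf relative to the dry reference,

    lambda * E = rho_a * c_p * (T_dry - T_p) / r_HR

where ``r_HR`` is the parallel combination of the boundary-layer resistance
to heat and the radiative "resistance".  The same balance run forward gives
the leaf and dry-reference temperatures for a prescribed transpiration rate
and is what the synthetic scene generator uses, so the inverse estimator can
be validated against known ground truth.

All temperatures are in degrees Celsius, E in mmol H2O m-2 s-1, resistances
in s m-1 and fluxes in W m-2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Stefan-Boltzmann constant, W m-2 K-4
SIGMA_SB = 5.670374419e-8

ZERO_C = 273.15


@dataclass
class EBParams:
    """Physical constants and geometry for the leaf energy balance.

    Attributes
    ----------
    air_density : float
        Density of air, kg m-3.
    specific_heat : float
        Specific heat capacity of air at constant pressure, J kg-1 K-1.
    latent_heat_molar : float
        Molar latent heat of vaporisation of water, J mol-1.
    leaf_dimension : float
        Characteristic dimension of the leaf (maize leaf width), m.
    wind_speed : float
        Air speed over the leaf, m s-1.  Indoors this is near free
        convection.
    emissivity : float
        Longwave emissivity of the leaf surface.
    pressure : float
        Atmospheric pressure, kPa.  Used in the diffusion approximation
        E = g_s * VPD / P.
    exchange_sides : int
        Number of leaf faces exchanging sensible heat (2 for a thin
        amphistomatous leaf).
    kinematic_viscosity, thermal_diffusivity, prandtl : float
        Properties of air near 25 degC used in the flat-plate forced
        convection correlation.
    net_radiation : float
        Isothermal net radiation absorbed by leaf and reference, W m-2.
        Only the forward model uses it; the dry-reference inverse cancels
        it by construction.
    """

    air_density: float = 1.184
    specific_heat: float = 1007.0
    latent_heat_molar: float = 44000.0
    leaf_dimension: float = 0.08
    wind_speed: float = 0.1
    emissivity: float = 0.96
    pressure: float = 101.325
    exchange_sides: int = 2
    kinematic_viscosity: float = 15.5e-6
    thermal_diffusivity: float = 21.5e-6
    prandtl: float = 0.71
    net_radiation: float = 30.0

    def __post_init__(self) -> None:
        for name in (
            "air_density",
            "specific_heat",
            "latent_heat_molar",
            "leaf_dimension",
            "pressure",
            "kinematic_viscosity",
            "thermal_diffusivity",
            "prandtl",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"EBParams.{name} must be strictly positive")
        if self.wind_speed < 0:
            raise ValueError("EBParams.wind_speed must be non-negative")
        if not 0 < self.emissivity <= 1:
            raise ValueError("EBParams.emissivity must be in (0, 1]")


@dataclass
class Resistances:
    """Boundary-layer, radiative and combined resistances (s m-1)."""

    r_aH: float
    r_R: float
    r_HR: float


def resistances(params: EBParams, T_a: float) -> Resistances:
    """Compute the heat-transfer resistances of the leaf-air interface.

    The radiative resistance linearises longwave exchange at air
    temperature, ``r_R = rho_a c_p / (4 sigma eps T_aK^3)``.  The
    boundary-layer resistance uses the laminar flat-plate correlation
    ``Nu = 0.664 Re^1/2 Pr^1/3`` divided over ``exchange_sides`` faces;
    the Nusselt number is floored at 1 so the still-air limit stays
    finite (pure conduction).
    """
    T_k = float(T_a) + ZERO_C
    r_R = params.air_density * params.specific_heat / (
        4.0 * SIGMA_SB * params.emissivity * T_k**3
    )
    d = params.leaf_dimension
    re = params.wind_speed * d / params.kinematic_viscosity
    nu = max(0.664 * np.sqrt(re) * params.prandtl ** (1.0 / 3.0), 1.0)
    r_aH = d / (params.thermal_diffusivity * nu) / params.exchange_sides
    r_HR = 1.0 / (1.0 / r_aH + 1.0 / r_R)
    return Resistances(r_aH=r_aH, r_R=r_R, r_HR=r_HR)


def estimate_E(T_p, T_dry, T_a, params: EBParams | None = None):
    """Estimate transpiration rate from the dry-reference depression.

    Parameters
    ----------
    T_p, T_dry, T_a : float or array-like
        Plant, dry-reference and air temperature in degC.
    params : EBParams, optional
        Physical constants; defaults are for indoor conditions.

    Returns
    -------
    E : float or ndarray
        Transpiration rate in mmol H2O m-2 s-1.  Negative when the plant
        is warmer than the dry reference (flagged upstream, not clipped).
    """
    params = params or EBParams()
    T_p = np.asarray(T_p, dtype=float)
    T_dry = np.asarray(T_dry, dtype=float)
    T_a = np.asarray(T_a, dtype=float)
    if not (np.all(np.isfinite(T_p)) and np.all(np.isfinite(T_dry)) and np.all(np.isfinite(T_a))):
        raise ValueError("non-finite temperature passed to estimate_E")
    scalar = T_p.ndim == 0 and T_dry.ndim == 0 and T_a.ndim == 0
    T_a_b = np.broadcast_arrays(T_p, T_dry, T_a)[2]
    r_hr = np.vectorize(lambda t: resistances(params, t).r_HR)(T_a_b)
    latent = params.air_density * params.specific_heat * (T_dry - T_p) / r_hr
    e_mmol = latent / params.latent_heat_molar * 1000.0
    return float(e_mmol) if scalar else e_mmol


def transpiration_from_conductance(g_s, VPD, params: EBParams | None = None):
    """Diffusion approximation E = g_s * VPD / P, returned in mmol m-2 s-1."""
    params = params or EBParams()
    return 1000.0 * np.asarray(g_s, dtype=float) * np.asarray(VPD, dtype=float) / params.pressure


def forward_leaf_temperature(
    T_a,
    VPD=None,
    params: EBParams | None = None,
    *,
    g_s=None,
    E=None,
    net_radiation=None,
):
    """Solve the energy balance forward for leaf and dry-reference temperature.

    Exactly one of ``g_s`` (mol m-2 s-1) or ``E`` (mmol m-2 s-1) must be
    given; with ``g_s`` the transpiration rate follows the diffusion
    approximation ``E = g_s * VPD / P``.  The dry reference solves the same
    balance with zero latent flux, so ``estimate_E`` applied to the returned
    temperatures recovers ``E`` by construction.

    Returns
    -------
    T_p, T_dry : float or ndarray
        Leaf and dry-reference temperature, degC.
    """
    params = params or EBParams()
    if (g_s is None) == (E is None):
        raise ValueError("provide exactly one of g_s or E")
    if g_s is not None:
        if VPD is None:
            raise ValueError("VPD is required when transpiration is given as g_s")
        E = transpiration_from_conductance(g_s, VPD, params)
    E = np.asarray(E, dtype=float)
    T_a = np.asarray(T_a, dtype=float)
    rn = params.net_radiation if net_radiation is None else net_radiation
    rn = np.asarray(rn, dtype=float)
    scalar = E.ndim == 0 and T_a.ndim == 0 and rn.ndim == 0
    T_a_b = np.broadcast_arrays(E, T_a, rn)[1]
    r_hr = np.vectorize(lambda t: resistances(params, t).r_HR)(T_a_b)
    rho_cp = params.air_density * params.specific_heat
    latent = E / 1000.0 * params.latent_heat_molar
    T_dry = T_a + r_hr * rn / rho_cp
    T_p = T_a + r_hr * (rn - latent) / rho_cp
    if scalar:
        return float(T_p), float(T_dry)
    return T_p, T_dry


def balance_residual(T_p, T_dry, T_a, E, params: EBParams | None = None):
    """Residual of the dry-reference balance (W m-2); ~0 at a solution."""
    params = params or EBParams()
    r = resistances(params, float(np.mean(np.asarray(T_a, dtype=float))))
    rho_cp = params.air_density * params.specific_heat
    latent = np.asarray(E, dtype=float) / 1000.0 * params.latent_heat_molar
    return rho_cp * (np.asarray(T_dry) - np.asarray(T_p)) / r.r_HR - latent
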
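"""Thermal infrared water-stress indices and non-water-stressed baselines.

Implements the canonical index set used to normalise median plant
temperature ``T_p`` against the ambient environment:

- ``CTD = T_p - T_a`` (canopy temperature depression)
- ``CSI = (T_p - T_a) / VPD`` (canopy stress index)
- ``TRI = T_p / T_a`` (temperature ratio index; temperatures in degC)
- ``T_dry - T_p`` (simplified stomatal conductance index)
- ``T_BS - T_p`` (black-sphere variant)
- ``ICWSI = (T_p - T_min) / (T_max - T_min)`` with the fully-transpiring
  anchor ``T_min`` predicted by a T_p ~ VPD baseline fitted on
  well-watered plants and the non-transpiring anchor ``T_max = T_a + 3``
- ``CWSI = (CTD - CTD_max) / (CTD_min - CTD_max)`` with ``CTD_min`` from
  a CTD ~ VPD baseline (per development stage, or with T_a and the
  VPD x T_a interaction as extra predictors) and ``CTD_max = 3`` degC.

The CWSI is computed exactly as printed, which puts a fully transpiring
plant at 1 and a non-transpiring plant at 0; the conventional orientation
(1 = stressed) is available through the ``orientation`` switch and is
never applied silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

#: non-transpiring anchor: maximum canopy temperature is T_a + 3 degC
T_MAX_OFFSET = 3.0

BASELINE_MODES = ("tp_vpd", "ctd_vpd_dev", "ctd_vpd_ta")


class DegenerateFitError(ValueError):
    """Raised when a baseline predictor has no variation."""


@dataclass
class BaselineModel:
    """Fitted non-water-stressed baseline.

    ``coefficients`` maps term names (``intercept``, ``VPD``, ``T_a``,
    ``VPD:T_a``) to OLS estimates.
    """

    mode: str
    genotype: str | None
    dev_stage: str
    coefficients: dict
    n_obs: int
    adj_r2: float

    def predict(self, VPD, T_a=None):
        """Predicted fully-transpiring T_p (tp_vpd mode) or CTD (ctd modes)."""
        c = self.coefficients
        vpd = np.asarray(VPD, dtype=float)
        out = c["intercept"] + c["VPD"] * vpd
        if self.mode == "ctd_vpd_ta":
            if T_a is None:
                raise ValueError("ctd_vpd_ta baseline requires T_a")
            t_a = np.asarray(T_a, dtype=float)
            out = out + c["T_a"] * t_a + c["VPD:T_a"] * vpd * t_a
        return float(out) if np.ndim(out) == 0 else out


def compute_basic_indices(T_p, T_a, VPD, T_dry=None, T_BS=None) -> dict:
    """Baseline-free thermal indices for one or many observations.

    CSI is missing where VPD <= 0 and TRI where T_a = 0 (the ratio is
    taken with temperatures in degC).
    """
    T_p = np.asarray(T_p, dtype=float)
    T_a = np.asarray(T_a, dtype=float)
    VPD = np.asarray(VPD, dtype=float)
    ctd = T_p - T_a
    with np.errstate(divide="ignore", invalid="ignore"):
        csi = np.where(VPD > 0, ctd / np.where(VPD > 0, VPD, 1.0), np.nan)
        tri = np.where(T_a != 0, T_p / np.where(T_a != 0, T_a, 1.0), np.nan)
    out = {"CTD": ctd, "CSI": csi, "TRI": tri}
    out["Tdry_minus_Tp"] = (np.asarray(T_dry, dtype=float) - T_p) if T_dry is not None else None
    out["TBS_minus_Tp"] = (np.asarray(T_BS, dtype=float) - T_p) if T_BS is not None else None
    if T_p.ndim == 0:
        out = {k: (float(v) if v is not None else None) for k, v in out.items()}
    return out


def fit_baseline(
    observations: pd.DataFrame,
    mode: str,
    genotype: str | None = None,
    dev_stage: str = "all",
    min_obs_warn: int = 30,
) -> BaselineModel:
    """Fit one non-water-stressed baseline on well-watered observations.

    ``observations`` must provide ``T_p``, ``T_a`` and ``VPD`` columns.
    Modes: ``tp_vpd`` regresses T_p on VPD; ``ctd_vpd_dev`` regresses CTD
    on VPD (callers fit young and mature plants separately);
    ``ctd_vpd_ta`` regresses CTD on VPD, T_a and their interaction.
    """
    if mode not in BASELINE_MODES:
        raise ValueError(f"unknown baseline mode {mode!r}")
    df = observations.copy()
    needed = 5 if mode == "ctd_vpd_ta" else 3
    if len(df) < needed:
        raise ValueError(f"baseline mode {mode!r} needs >= {needed} observations, got {len(df)}")
    if len(df) < min_obs_warn:
        warnings.warn(
            f"baseline fitted on only {len(df)} observations; coefficients may be unstable",
            stacklevel=2,
        )
    predictors = ["VPD"] if mode != "ctd_vpd_ta" else ["VPD", "T_a"]
    for name in predictors:
        if np.ptp(df[name].to_numpy(dtype=float)) == 0:
            raise DegenerateFitError(f"predictor {name!r} is constant; baseline is rank deficient")
    df["CTD"] = df["T_p"] - df["T_a"]
    if mode == "tp_vpd":
        formula = "T_p ~ VPD"
    elif mode == "ctd_vpd_dev":
        formula = "CTD ~ VPD"
    else:
        formula = "CTD ~ VPD * T_a"
    fit = smf.ols(formula, data=df).fit()
    names = {"Intercept": "intercept", "VPD": "VPD", "T_a": "T_a", "VPD:T_a": "VPD:T_a"}
    coefficients = {names.get(k, k): float(v) for k, v in fit.params.items()}
    return BaselineModel(
        mode=mode,
        genotype=genotype,
        dev_stage=dev_stage,
        coefficients=coefficients,
        n_obs=int(fit.nobs),
        adj_r2=float(fit.rsquared_adj),
    )


def fit_baselines(
    ww_observations: pd.DataFrame,
    mode: str,
    dev_stage_threshold: int | None = None,
) -> dict:
    """Fit baselines per genotype (and per development stage for dev modes).

    ``dev_stage_threshold`` splits days-after-V5 into young (<= threshold)
    and mature plants for the development-corrected modes; ``None`` uses a
    single ``all`` stage.  Returns ``{(genotype, dev_stage): BaselineModel}``.
    """
    out = {}
    for genotype, gdf in ww_observations.groupby("genotype"):
        if mode in ("tp_vpd", "ctd_vpd_dev") and dev_stage_threshold is not None:
            young = gdf[gdf["day_after_V5"] <= dev_stage_threshold]
            mature = gdf[gdf["day_after_V5"] > dev_stage_threshold]
            for stage, sdf in (("young", young), ("mature", mature)):
                if len(sdf) >= 3:
                    out[(genotype, stage)] = fit_baseline(sdf, mode, genotype, stage)
        else:
            out[(genotype, "all")] = fit_baseline(gdf, mode, genotype, "all")
    return out


def compute_icwsi(T_p, T_a, VPD, baseline: BaselineModel):
    """Idso's crop water stress index with a T_p ~ VPD baseline.

    0 at the fully-transpiring baseline, 1 at T_a + 3 degC; values are not
    clipped to [0, 1].
    """
    if baseline.mode != "tp_vpd":
        raise ValueError("ICWSI requires a tp_vpd baseline")
    T_p = np.asarray(T_p, dtype=float)
    T_a = np.asarray(T_a, dtype=float)
    t_min = baseline.predict(VPD)
    t_max = T_a + T_MAX_OFFSET
    denom = t_max - t_min
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, (T_p - t_min) / np.where(denom != 0, denom, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def compute_cwsi(T_p, T_a, VPD, baseline: BaselineModel, orientation: str = "as_printed"):
    """Crop water stress index normalising CTD between its anchors.

    ``as_printed`` follows the published formula
    ``(CTD - CTD_max) / (CTD_min - CTD_max)`` (1 = fully transpiring);
    ``conventional`` flips it so 1 means non-transpiring.
    """
    if baseline.mode not in ("ctd_vpd_dev", "ctd_vpd_ta"):
        raise ValueError("CWSI requires a ctd_vpd_dev or ctd_vpd_ta baseline")
    if orientation not in ("as_printed", "conventional"):
        raise ValueError("orientation must be 'as_printed' or 'conventional'")
    T_p = np.asarray(T_p, dtype=float)
    T_a = np.asarray(T_a, dtype=float)
    ctd = T_p - T_a
    ctd_min = baseline.predict(VPD, T_a=T_a if baseline.mode == "ctd_vpd_ta" else None)
    ctd_max = T_MAX_OFFSET
    denom = ctd_min - ctd_max
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, (ctd - ctd_max) / np.where(denom != 0, denom, 1.0), np.nan)
    if orientation == "conventional":
        out = 1.0 - out
    return float(out) if out.ndim == 0 else out


def compute_index_table(
    plants: pd.DataFrame,
    baselines: dict | None = None,
    positions: tuple = ("in", "out", "gz"),
    orientation: str = "as_printed",
    dev_stage_threshold: int | None = None,
) -> pd.DataFrame:
    """Compute all indices for every observation at every monitoring position.

    ``plants`` is a wide per-observation table carrying ``T_p``, ``T_dry``,
    optional ``T_BS_gz``, and ``T_a_<pos>`` / ``VPD_<pos>`` columns.
    ``baselines`` maps mode -> {(genotype, stage): BaselineModel}; missing
    modes leave the corresponding index columns absent.  Every index
    column name records the position whose environment it used
    (``CTD_in``, ``CSI_out``, ...), so recomputation with the same
    position is bit-identical.
    """
    out = plants.copy()
    if "T_dry" in out:
        out["Tdry_minus_Tp"] = out["T_dry"] - out["T_p"]
    if "T_BS_gz" in out:
        out["TBS_minus_Tp"] = out["T_BS_gz"] - out["T_p"]

    def _stage(day):
        if dev_stage_threshold is None:
            return "all"
        return "young" if day <= dev_stage_threshold else "mature"

    for pos in positions:
        t_a = out[f"T_a_{pos}"]
        vpd = out[f"VPD_{pos}"]
        basic = compute_basic_indices(out["T_p"], t_a, vpd)
        out[f"CTD_{pos}"] = basic["CTD"]
        out[f"CSI_{pos}"] = basic["CSI"]
        out[f"TRI_{pos}"] = basic["TRI"]
        if baselines:
            for mode, label in (
                ("tp_vpd", "ICWSI"),
                ("ctd_vpd_dev", "CWSI_dev"),
                ("ctd_vpd_ta", "CWSI_Ta"),
            ):
                models = baselines.get((mode, pos)) or baselines.get(mode)
                if not models:
                    continue
                vals = np.full(len(out), np.nan)
                for i, (_, row) in enumerate(out.iterrows()):
                    key = (row.get("genotype"), _stage(row.get("day_after_V5", 0)))
                    model = models.get(key) or models.get((row.get("genotype"), "all"))
                    if model is None:
                        continue
                    if mode == "tp_vpd":
                        vals[i] = compute_icwsi(row["T_p"], row[f"T_a_{pos}"], row[f"VPD_{pos}"], model)
                    else:
                        vals[i] = compute_cwsi(
                            row["T_p"], row[f"T_a_{pos}"], row[f"VPD_{pos}"], model, orientation
                        )
                out[f"{label}_{pos}"] = vals
    return out
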
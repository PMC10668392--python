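"""End-to-end pipeline: simulate -> process -> indices -> hyper -> detect ->
model -> energy balance, with a reproducible run manifest.

The pipeline mirrors the platform's processing order.  Stage outputs are
plain CSV files with a fixed float format so reruns with the same
configuration and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import replace
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import drought_detection, e_prediction, energy_balance, hyperspectral, tir_indices
from .synthetic_scene import (
    POSITIONS,
    EnvConfig,
    GenotypeParams,
    SceneConfig,
    distance_factor,
    render_spectrum,
    render_thermal_frame,
    simulate_experiment,
)
from .thermography import extract_plant_temperature, raw_to_temperature

STAGES = ("simulate", "process", "indices", "hyper", "detect", "emodel", "eb")

FLOAT_FORMAT = "%.10g"

INDEX_TRAITS = ["CTD_in", "CSI_in", "TRI_in", "Tdry_minus_Tp", "ICWSI_in", "CWSI_dev_in", "CWSI_Ta_in", "TBS_minus_Tp"]
PHYS_TRAITS = ["E_meas", "g_s_true", "psi_true"]


class PipelineError(RuntimeError):
    pass


def _require(results: dict, key: str, stage: str, needed_by: str):
    if key not in results:
        raise PipelineError(
            f"stage {needed_by!r} needs output {key!r}; run stage {stage!r} first"
        )
    return results[key]


def config_from_dict(d: dict) -> SceneConfig:
    """Build a SceneConfig from a plain (YAML-loadable) mapping."""
    d = dict(d)
    if "env" in d:
        d["env"] = EnvConfig(**d["env"])
    if "eb" in d:
        d["eb"] = energy_balance.EBParams(**d["eb"])
    if "calibration" in d:
        from .thermography import ThermalCalibration

        d["calibration"] = ThermalCalibration(**d["calibration"])
    if "genotypes" in d:
        d["genotypes"] = [GenotypeParams(**g) if isinstance(g, dict) else g for g in d["genotypes"]]
    for key in ("frame_shape", "plate_region", "foil_region"):
        if key in d:
            d[key] = tuple(d[key])
    if "start_date" in d and isinstance(d["start_date"], str):
        d["start_date"] = datetime.fromisoformat(d["start_date"])
    return SceneConfig(**d)


def load_config(path) -> SceneConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def config_hash(config: SceneConfig) -> str:
    def default(o):
        if isinstance(o, datetime):
            return o.isoformat()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def fit_position_baselines(truth: pd.DataFrame, dev_stage_threshold: int | None = None) -> dict:
    """Fit all three baseline variants per monitoring position on WW rows."""
    ww = truth[truth["treatment"] == "WW"]
    baselines = {}
    for pos in POSITIONS:
        sub = ww.rename(columns={f"T_a_{pos}": "T_a", f"VPD_{pos}": "VPD"})[
            ["T_p", "T_a", "VPD", "genotype", "day_after_V5"]
        ]
        for mode in tir_indices.BASELINE_MODES:
            thr = dev_stage_threshold if mode in ("tp_vpd", "ctd_vpd_dev") else None
            baselines[(mode, pos)] = tir_indices.fit_baselines(sub, mode, dev_stage_threshold=thr)
    return baselines


def hyperspectral_features(truth: pd.DataFrame, config: SceneConfig, seed: int) -> pd.DataFrame:
    """Render, distance-correct and index one spectrum per observation."""
    rng = np.random.default_rng(seed)
    # distance-response calibration: three plants lifted through the range
    cal_rows = []
    for pid, lwf in enumerate((0.75, 0.85, 0.92)):
        for d in np.linspace(1.2, 3.0, 7):
            wl, r = render_spectrum(lwf, 1.0, d, config, rng=None)
            cal_rows.append({"plant_id": f"cal{pid}", "distance": d, "mean_reflectance": r.mean()})
    response = hyperspectral.fit_distance_response(pd.DataFrame(cal_rows))
    rows = []
    for i, row in truth.iterrows():
        distance = float(np.clip(2.8 - 2.0 / 3.0 * row["plant_height"], 1.0, 3.0))
        wl, r = render_spectrum(row["leaf_water_fraction"], 1.0, distance, config, rng=rng)
        spec = hyperspectral.Spectrum(wl, r, distance=distance)
        adj = hyperspectral.correct_reflectance(spec, response)
        rec = hyperspectral.compute_hyperspectral_indices(adj)
        rec["_row"] = i
        rows.append(rec)
    return pd.DataFrame(rows).set_index("_row")


DEMO_CONFIG = SceneConfig(
    n_plants=10,
    n_days=20,
    genotypes=[
        GenotypeParams("B104"),
        GenotypeParams("H99", g_max=0.30, sw_steepness=2.5),
    ],
)


def run_experiment(
    config: SceneConfig | None = None,
    outdir: str | Path = "out",
    stages=STAGES,
    seed: int | None = None,
    n_boot: int = 25,
    n_rendered_frames: int = 8,
) -> dict:
    """Run the pipeline end to end and write stage outputs plus a manifest.

    ``stages`` selects a subset (later stages require their upstreams).
    The ``process`` stage renders a handful of full thermal frames and
    runs the frame-processing chain on them as an internal consistency
    check; the per-observation table otherwise carries the measured T_p
    directly.  Returns the in-memory stage results keyed by name.
    """
    config = config if config is not None else DEMO_CONFIG
    if seed is not None:
        config = replace(config, random_seed=seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = tuple(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    results: dict = {}
    manifest = {
        "config_hash": config_hash(config),
        "seed": config.random_seed,
        "stages": list(stages),
        "outputs": {},
        "row_counts": {},
        "warnings": [],
    }

    def _write(name: str, df: pd.DataFrame):
        path = outdir / name
        df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
        manifest["outputs"][name] = str(path)
        manifest["row_counts"][name] = len(df)

    if "simulate" in stages:
        sim = simulate_experiment(config)
        results["truth"] = sim["truth"]
        results["env"] = sim["env"]
        results["truth"]["E_meas"] = results["truth"]["E_true"] * (
            1.0
            + np.random.default_rng(config.random_seed + 7).normal(
                0.0, 0.04, size=len(results["truth"])
            )
        )
        _write("truth.csv", results["truth"])
        _write("env.csv", results["env"])

    if "process" in stages:
        truth = _require(results, "truth", "simulate", "process")
        rng = np.random.default_rng(config.random_seed + 3)
        rows = []
        for _, row in truth.head(n_rendered_frames).iterrows():
            frame, mask = render_thermal_frame(
                row["T_p_true"],
                row["T_dry_true"],
                {"T_a": row["T_a_in"], "RH": row["RH_in"]},
                config,
                rng=rng,
                plant_id=row["plant_id"],
                timestamp=row["timestamp"],
            )
            T = raw_to_temperature(frame)
            res = extract_plant_temperature(T, mask, config.plate_region)
            rows.append(
                {
                    "plant_id": row["plant_id"],
                    "timestamp": row["timestamp"],
                    "T_p": res["T_p"],
                    "T_dry": res["T_dry"],
                    "n_valid_pixels": res["n_valid"],
                    "T_p_true": row["T_p_true"],
                }
            )
        results["plants"] = pd.DataFrame(rows)
        _write("plants.csv", results["plants"])

    if "indices" in stages:
        truth = _require(results, "truth", "simulate", "indices")
        baselines = fit_position_baselines(truth)
        results["baselines"] = baselines
        indices = tir_indices.compute_index_table(truth, baselines, positions=POSITIONS)
        results["indices"] = indices
        _write("indices.csv", indices)
        serial = {
            f"{mode}|{pos}|{geno}|{stage}": m.coefficients | {"adj_r2": m.adj_r2, "n_obs": m.n_obs}
            for (mode, pos), models in baselines.items()
            for (geno, stage), m in models.items()
        }
        (outdir / "baselines.json").write_text(json.dumps(serial, indent=1, sort_keys=True))
        manifest["outputs"]["baselines.json"] = str(outdir / "baselines.json")

    if "hyper" in stages:
        indices = _require(results, "indices", "indices", "hyper")
        hyp = hyperspectral_features(indices, config, config.random_seed + 5)
        features = indices.join(hyp)
        results["features"] = features
        _write("features.csv", features)

    if "detect" in stages:
        indices = _require(results, "indices", "indices", "detect")
        index_traits = [t for t in INDEX_TRAITS if t in indices.columns]
        detection = drought_detection.run_detection(indices, index_traits, kind="index")
        phys = drought_detection.run_detection(
            indices, [t for t in PHYS_TRAITS if t in indices.columns], kind="physiology"
        )
        detection = pd.concat([detection, phys], ignore_index=True)
        results["detection"] = detection
        results["detection_summary"] = drought_detection.summarize_detection(detection)
        _write("detection.csv", detection)
        _write("detection_summary.csv", results["detection_summary"])

    if "emodel" in stages:
        features = _require(results, "features", "hyper", "emodel")
        train = features[features["genotype"] == features["genotype"].iloc[0]]
        multi_cols = [
            c
            for c in features.columns
            if any(
                c.startswith(p)
                for p in ("CTD_", "CSI_", "TRI_", "ICWSI_", "CWSI_", "Tdry_", "TBS_")
            )
        ] + ["T_a_out", "VPD_out", "PAR_gz", "T_BS_gz"]
        specs = {
            "linear_ctd_out": e_prediction.ModelSpec("linear_index", ["CTD_out"]),
            "rf_index_env": e_prediction.ModelSpec("rf", multi_cols),
            "lasso_index_env": e_prediction.ModelSpec("lasso", multi_cols),
        }
        evals = {}
        per_boot = []
        for label, spec in specs.items():
            ev = e_prediction.bootstrap_evaluate(
                spec, train, n_boot=n_boot, seed=config.random_seed, response="E_meas", label=label
            )
            evals[label] = ev
            pb = ev.per_boot.copy()
            pb["model"] = label
            per_boot.append(pb)
        results["evaluations"] = evals
        _write("evaluation.csv", pd.concat(per_boot, ignore_index=True))
        summary = {k: v.medians | {"selected": v.selected_variables} for k, v in evals.items()}
        (outdir / "model_summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        manifest["outputs"]["model_summary.json"] = str(outdir / "model_summary.json")
        transfer = e_prediction.evaluate_transfer(
            evals["rf_index_env"].final_model, features, response="E_meas"
        )
        results["transfer"] = transfer
        _write("transfer.csv", transfer)

    if "eb" in stages:
        truth = _require(results, "truth", "simulate", "eb")
        e_eb = energy_balance.estimate_E(
            truth["T_p"].to_numpy(), truth["T_dry"].to_numpy(), truth["T_a_in"].to_numpy(), config.eb
        )
        eb_df = truth[["plant_id", "timestamp", "E_true", "E_meas"]].copy()
        eb_df["E_energy_balance"] = e_eb
        results["e_eb"] = eb_df
        _write("e_eb.csv", eb_df)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    results["manifest"] = manifest
    return results
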
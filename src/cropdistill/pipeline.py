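"""End-to-end orchestration: synthesize → simulate → build → train → explain.

A single flat YAML config drives all stages; every stochastic stage has
its own explicit seed.  Each run writes its artifacts plus a manifest with
content hashes, so a rerun of the same config can be checked for
bit-identical results.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import cultivar, dataset, distiller, saliency, simriw, weather


class ConfigError(ValueError):
    pass


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def default_config() -> dict[str, Any]:
    return {
        "weather": {
            "n_grids": 10,
            "n_years": 5,
            "lat_min": 31.0,
            "lat_max": 42.0,
            "noise_sd": 1.5,
            "co2_ppm": 350.0,
            "scenario_weights": dict(weather.DEFAULT_SCENARIO_WEIGHTS),
            "seed": 11,
        },
        "cultivar": {"params": "default"},
        "dataset": {
            "noise_amplitude": 0.001,
            "train_fraction": 0.75,
            "seed": 21,
        },
        "train": {
            "lr": 1.0e-3,
            "batch_size": 64,
            "max_epochs": 60,
            "patience": 10,
            "hidden": 64,
            "conv1_maps": 32,
            "conv2_maps": 64,
            "seed": 31,
        },
        "saliency": {
            "n_maps": 500,
            "percentile": 10.0,
            "bin_width": 0.05,
            "cases": list(saliency.CASE_NAMES),
            "seed": 41,
        },
    }


def load_config(path: str | Path) -> dict[str, Any]:
    try:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"unparsable config: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ConfigError("config must be a mapping of stage sections")
    return merge_config(raw)


def merge_config(overrides: Mapping[str, Any]) -> dict[str, Any]:
    """Defaults overlaid with ``overrides``; unknown keys are errors."""
    config = default_config()
    for section, values in overrides.items():
        if section not in config:
            raise ConfigError(f"unknown config section {section!r}")
        if not isinstance(values, Mapping):
            raise ConfigError(f"section {section!r} must be a mapping")
        for key, val in values.items():
            if key not in config[section]:
                raise ConfigError(f"unknown key {section}.{key}")
            config[section][key] = val
    return config


def _hash_bytes(*chunks: bytes) -> str:
    h = hashlib.sha256()
    for c in chunks:
        h.update(c)
    return h.hexdigest()


def _hash_arrays(arrays: Mapping[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    for k in sorted(arrays):
        h.update(k.encode())
        h.update(np.ascontiguousarray(arrays[k]).tobytes())
    return h.hexdigest()


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Execute all stages in order and write ``manifest.json``.

    Content hashes in the manifest cover the generated data itself, so two
    runs of one config produce identical manifests.  Any stage failure is
    re-raised as :class:`PipelineError` naming the stage.
    """
    config = merge_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": config,
        "config_hash": _hash_bytes(
            json.dumps(config, sort_keys=True).encode()),
        "stages": {},
    }

    # --- synth ---
    wc = config["weather"]
    try:
        series = weather.synth_grid(
            n_grids=int(wc["n_grids"]), n_years=int(wc["n_years"]),
            lat_range=(float(wc["lat_min"]), float(wc["lat_max"])),
            scenario_weights=wc["scenario_weights"],
            seed=int(wc["seed"]), noise_sd=float(wc["noise_sd"]),
            co2_ppm=float(wc["co2_ppm"]),
        )
    except Exception as exc:
        raise PipelineError("synth", str(exc)) from exc
    weather_dir = out_dir / "weather"
    weather.write_weather_dir(series, weather_dir)
    manifest["stages"]["synth"] = {
        "seed": wc["seed"],
        "n_series": len(series),
        "artifact": str(weather_dir),
        "hash": _hash_arrays({
            f"{s.grid_id}/{s.year_index}": np.concatenate(
                [s.tmean, s.tmax, s.s_incident, s.day_len, s.co2])
            for s in series
        }),
    }

    # --- simulate ---
    try:
        if config["cultivar"]["params"] == "default":
            params = cultivar.default_params()
        else:
            params = cultivar.load_params(config["cultivar"]["params"])
        results = simriw.simulate_batch(series, params)
        scalars_csv, traj_csv = simriw.write_results(results, out_dir / "simulated")
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc
    n_excluded = sum(r.excluded for r in results)
    manifest["stages"]["simulate"] = {
        "artifacts": [str(scalars_csv), str(traj_csv)],
        "n_results": len(results),
        "n_excluded": n_excluded,
        "hash": _hash_bytes(scalars_csv.read_bytes(), traj_csv.read_bytes()),
    }

    # --- build ---
    dc = config["dataset"]
    try:
        corpus = dataset.build_corpus(
            series, results,
            noise_amplitude=float(dc["noise_amplitude"]),
            train_fraction=float(dc["train_fraction"]),
            seed=int(dc["seed"]),
        )
    except Exception as exc:
        raise PipelineError("build", str(exc)) from exc
    corpus_path = out_dir / "corpus.npz"
    dataset.save_corpus(corpus, corpus_path)
    manifest["stages"]["build"] = {
        "seed": dc["seed"],
        "artifact": str(corpus_path),
        "n_train": corpus.n_train,
        "n_val": corpus.n_val,
        "hash": _hash_arrays({
            "x_train": corpus.x_train, "y_train": corpus.y_train,
            "x_val": corpus.x_val, "y_val": corpus.y_val,
        }),
    }

    # --- train ---
    tc = config["train"]
    try:
        spec = distiller.SurrogateSpec(
            conv1_maps=int(tc["conv1_maps"]),
            conv2_maps=int(tc["conv2_maps"]),
            hidden=int(tc["hidden"]),
        )
        tconf = distiller.TrainConfig(
            lr=float(tc["lr"]), batch_size=int(tc["batch_size"]),
            max_epochs=int(tc["max_epochs"]), patience=int(tc["patience"]),
            seed=int(tc["seed"]),
        )
        model = distiller.build_surrogate(spec, seed=int(tc["seed"]))
        model, history = distiller.train(
            model, (corpus.x_train, corpus.y_train),
            (corpus.x_val, corpus.y_val), tconf)
    except Exception as exc:
        raise PipelineError("train", str(exc)) from exc
    model_path = out_dir / "surrogate.npz"
    distiller.save_model(model, model_path, history=history)
    val_pred = distiller.predict(model, corpus.x_val)
    val_r2 = distiller.r_squared(corpus.y_val, val_pred)
    history_csv = out_dir / "history.csv"
    with open(history_csv, "w", encoding="utf-8") as fh:
        fh.write("epoch,train_mse,val_mse\n")
        for e, (tl, vl) in enumerate(zip(history.train_loss, history.val_loss)):
            fh.write(f"{e},{tl!r},{vl!r}\n")
    manifest["stages"]["train"] = {
        "seed": tc["seed"],
        "artifacts": [str(model_path), str(history_csv)],
        "best_epoch": history.best_epoch,
        "n_epochs": history.n_epochs,
        "val_mse": history.val_loss[history.best_epoch],
        "val_r2": val_r2,
        "hash": _hash_arrays(model.params),
    }

    # --- explain ---
    sc = config["saliency"]
    try:
        cases = [saliency.CaseSpec(name, float(sc["percentile"]))
                 for name in sc["cases"]]
        profiles = saliency.case_profiles(
            model, corpus, cases=cases, n_maps=int(sc["n_maps"]),
            bin_width=float(sc["bin_width"]), seed=int(sc["seed"]))
    except Exception as exc:
        raise PipelineError("explain", str(exc)) from exc
    profiles_csv = out_dir / "saliency_profiles.csv"
    saliency.write_profiles(profiles, profiles_csv)
    manifest["stages"]["explain"] = {
        "seed": sc["seed"],
        "artifact": str(profiles_csv),
        "n_maps": sc["n_maps"],
        "cases": list(sc["cases"]),
        "hash": _hash_bytes(profiles_csv.read_bytes()),
    }

    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8")
    return manifest
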
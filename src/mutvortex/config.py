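"""YAML configuration and JSON run manifests.

Configs are flat key-value YAML mirroring :class:`ModelParams` /
:class:`SimConfig`; manifests record everything needed to re-run: the
package version, full parameter echo, seed, and runtime.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import yaml

from . import __version__
from .analytic_model import ModelParams
from .dfe import dfe_from_config, dfe_to_config
from .genome_sim import GenomeArchitecture, SimConfig

__all__ = [
    "model_params_to_dict",
    "model_params_from_dict",
    "sim_config_to_dict",
    "sim_config_from_dict",
    "load_sim_config",
    "save_sim_config",
    "write_manifest",
]


def model_params_to_dict(params: ModelParams) -> dict:
    return {
        "ud": params.ud,
        "ub": params.ub,
        "deleterious_dfe": dfe_to_config(params.deleterious_dfe),
        "beneficial_dfe": dfe_to_config(params.beneficial_dfe),
        "delta_env": params.delta_env,
    }


def model_params_from_dict(d: dict) -> ModelParams:
    return ModelParams(
        ud=float(d["ud"]),
        ub=float(d["ub"]),
        deleterious_dfe=dfe_from_config(d["deleterious_dfe"]),
        beneficial_dfe=dfe_from_config(d["beneficial_dfe"]),
        delta_env=float(d.get("delta_env", 0.0)),
    )


def sim_config_to_dict(cfg: SimConfig) -> dict:
    return {
        "n": cfg.n,
        "params": model_params_to_dict(cfg.params),
        "architecture": {
            "n_chromosomes": cfg.architecture.n_chromosomes,
            "blocks_per_chromosome": cfg.architecture.blocks_per_chromosome,
            "crossovers_per_chromosome": cfg.architecture.crossovers_per_chromosome,
        },
        "run_generations": cfg.run_generations,
        "burn_in_window": cfg.burn_in_window,
        "burn_in_slope_factor": cfg.burn_in_slope_factor,
        "post_threshold_wait": cfg.post_threshold_wait,
        "seed": cfg.seed,
        "focal_chromosome": cfg.focal_chromosome,
        "focal_block": cfg.focal_block,
    }


def sim_config_from_dict(d: dict) -> SimConfig:
    arch = d.get("architecture", {})
    return SimConfig(
        n=int(d["n"]),
        params=model_params_from_dict(d["params"]),
        architecture=GenomeArchitecture(
            n_chromosomes=int(arch.get("n_chromosomes", 23)),
            blocks_per_chromosome=int(arch.get("blocks_per_chromosome", 100)),
            crossovers_per_chromosome=int(arch.get("crossovers_per_chromosome", 2)),
        ),
        run_generations=d.get("run_generations"),
        burn_in_window=int(d.get("burn_in_window", 200)),
        burn_in_slope_factor=float(d.get("burn_in_slope_factor", 0.07)),
        post_threshold_wait=int(d.get("post_threshold_wait", 100)),
        seed=int(d.get("seed", 0)),
        focal_chromosome=d.get("focal_chromosome"),
        focal_block=d.get("focal_block"),
    )


def load_sim_config(path) -> SimConfig:
    with open(path) as fh:
        return sim_config_from_dict(yaml.safe_load(fh))


def save_sim_config(cfg: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(sim_config_to_dict(cfg), fh, sort_keys=False)


def write_manifest(out_dir, name: str, seed=None, parameters: dict | None = None, **extra):
    """Write <out_dir>/manifest.json and return its contents."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "name": name,
        "package": "mutvortex",
        "version": __version__,
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "parameters": parameters or {},
        **extra,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
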
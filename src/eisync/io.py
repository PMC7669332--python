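"""Configuration loading, result serialization and format round-tripping.

Formats: YAML (primary) or JSON configs; CSV spike/count/strength/sweep
tables (comma-separated, header row, UTF-8, times in ms with 3 decimals);
JSON efficiency reports; PNG and plain-text PGM rate images.  Every output
directory gets a run manifest (config digest, seeds, package version) from
which the run can be regenerated bit-identically.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import __version__
from .experiments import ExperimentConfig, PairedRunResult, SweepResult
from .network import CountVector, SpikeRecord
from .stimulus import (
    STREAM_BACKGROUND,
    STREAM_CONNECTIVITY,
    STREAM_INIT_ISOLATED,
    STREAM_INIT_NETWORK,
    STREAM_STIMULUS,
    child_seed,
)

__all__ = [
    "load_config",
    "save_config",
    "load_reference_config",
    "REFERENCE_CONFIGS",
    "RunManifest",
    "config_digest",
    "save_outputs",
    "write_spikes_csv",
    "read_spikes_csv",
    "write_strengths_csv",
    "read_strengths_csv",
    "write_pgm",
]

REFERENCE_CONFIGS = ("fully_connected_baseline", "random_heterogeneous")

_CONFIG_FIELDS = {f.name: f for f in dataclasses.fields(ExperimentConfig)}


def _parse_mapping(path: Path) -> dict:
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data


def config_from_dict(data: dict, require_complete: bool = False) -> ExperimentConfig:
    """Build a validated config from a plain mapping, rejecting unknown keys
    (typo safety) and, for config files, listing every missing key at once."""
    unknown = sorted(set(data) - set(_CONFIG_FIELDS))
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    if require_complete:
        missing = sorted(set(_CONFIG_FIELDS) - set(data))
        if missing:
            raise ValueError(f"missing config keys: {', '.join(missing)}")
    cfg = ExperimentConfig(**data)
    # surface invalid physical parameters at load time
    cfg.e_neuron_params()
    cfg.i_neuron_params()
    cfg.synapse_params()
    cfg.grid()
    cfg.stimulus_config()
    cfg.background_config()
    if not 0.0 <= cfg.rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    if cfg.bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    return cfg


def load_config(path) -> ExperimentConfig:
    """Load an experiment configuration from YAML or JSON.  Config files
    must be complete: a missing key is more likely a typo than an intended
    default, and the error lists every absent key."""
    return config_from_dict(_parse_mapping(Path(path)), require_complete=True)


def save_config(cfg: ExperimentConfig, path) -> Path:
    """Write a config so that load_config(save_config(cfg)) == cfg."""
    path = Path(path)
    data = cfg.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")
    return path


def load_reference_config(name: str) -> ExperimentConfig:
    """One of the shipped reference configurations:

    - ``fully_connected_baseline``: all-to-all 450E/150I network with
      homogeneous background (the noise condition; set sigma_n_s=0 for the
      noise-free variant).
    - ``random_heterogeneous``: 70% random connectivity, heterogeneous noisy
      background, distinct excitatory/inhibitory decay constants.
    """
    if name not in REFERENCE_CONFIGS:
        raise ValueError(f"unknown reference config {name!r}; choose from {REFERENCE_CONFIGS}")
    ref = resources.files("eisync.configs").joinpath(f"{name}.yaml")
    with resources.as_file(ref) as p:
        return load_config(p)


def config_digest(cfg: ExperimentConfig) -> str:
    """SHA-256 of the canonical (key-sorted) JSON form of the config."""
    canonical = json.dumps(cfg.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


@dataclass(frozen=True)
class RunManifest:
    """Provenance of one run: enough to regenerate its outputs exactly."""

    digest: str
    master_seed: int
    child_seeds: dict
    version: str
    timestamp: str

    @classmethod
    def for_run(cls, cfg: ExperimentConfig, master_seed: int) -> "RunManifest":
        return cls(
            digest=config_digest(cfg),
            master_seed=master_seed,
            child_seeds={
                "stimulus": child_seed(master_seed, STREAM_STIMULUS),
                "background": child_seed(master_seed, STREAM_BACKGROUND),
                "connectivity": child_seed(master_seed, STREAM_CONNECTIVITY),
                "init_network": child_seed(master_seed, STREAM_INIT_NETWORK),
                "init_isolated": child_seed(master_seed, STREAM_INIT_ISOLATED),
            },
            version=__version__,
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---- tables -----------------------------------------------------------------

def write_spikes_csv(rec: SpikeRecord, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "neuron_id": rec.neuron_ids,
            "population": np.where(rec.neuron_ids < rec.n_e, "E", "I"),
            "spike_time_ms": np.round(rec.times, 3),
        }
    ).sort_values(["neuron_id", "spike_time_ms"], kind="stable")
    df.to_csv(path, index=False, float_format="%.3f")
    return path


def read_spikes_csv(path, n_e: int, n_i: int, duration: float) -> SpikeRecord:
    df = pd.read_csv(path)
    return SpikeRecord(
        neuron_ids=df["neuron_id"].to_numpy(),
        times=df["spike_time_ms"].to_numpy(dtype=float),
        n_e=n_e, n_i=n_i, duration=duration,
    )


def write_strengths_csv(strengths, path) -> Path:
    """Single-column CSV so printed stimulus tables can be injected verbatim."""
    path = Path(path)
    pd.DataFrame({"strength": np.asarray(strengths, dtype=float)}).to_csv(
        path, index=False
    )
    return path


def read_strengths_csv(path) -> np.ndarray:
    return pd.read_csv(path)["strength"].to_numpy(dtype=float)


# ---- images -----------------------------------------------------------------

def write_pgm(img: np.ndarray, path) -> Path:
    """Plain-text (P2) PGM writer for 8-bit gray images."""
    img = np.asarray(img, dtype=np.uint8)
    path = Path(path)
    lines = [f"P2", f"{img.shape[1]} {img.shape[0]}", "255"]
    lines += [" ".join(str(v) for v in row) for row in img]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_png(img: np.ndarray, path, upscale: int = 12) -> Path:
    """PNG rate map, nearest-neighbour upscaled for visibility."""
    path = Path(path)
    arr = np.asarray(img, dtype=np.uint8)
    if upscale > 1:
        arr = np.kron(arr, np.ones((upscale, upscale), dtype=np.uint8))
    Image.fromarray(arr, mode="L").save(path)
    return path


# ---- bundled outputs --------------------------------------------------------

def save_outputs(result: PairedRunResult, out_dir) -> dict[str, Path]:
    """Write the standard artifact set of one paired run."""
    from .experiments import rate_image  # local import avoids cycle at module load

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    files["config"] = save_config(result.config, out / "config.yaml")
    files["manifest"] = out / "manifest.json"
    files["manifest"].write_text(
        json.dumps(RunManifest.for_run(result.config, result.seed).to_dict(), indent=2),
        encoding="utf-8",
    )
    files["spikes_network"] = write_spikes_csv(result.network_record, out / "spikes_network.csv")
    files["spikes_isolated"] = write_spikes_csv(result.isolated_record, out / "spikes_isolated.csv")
    files["strengths"] = write_strengths_csv(result.stim.strengths, out / "strengths.csv")
    counts = pd.DataFrame(
        {
            "neuron_id": np.arange(result.network_counts.n_neurons),
            "count_network": result.network_counts.counts,
            "count_isolated": result.isolated_counts.counts,
        }
    )
    files["counts"] = out / "counts.csv"
    counts.to_csv(files["counts"], index=False)
    files["efficiency"] = out / "efficiency.json"
    files["efficiency"].write_text(
        json.dumps(result.efficiency.to_dict(), indent=2), encoding="utf-8"
    )
    n_cells = 400 if result.network_counts.n_neurons >= 400 else None
    if n_cells:
        for label, cv in (("network", result.network_counts), ("isolated", result.isolated_counts)):
            img = rate_image(1000.0 * cv.counts / cv.window)
            files[f"rate_map_{label}_png"] = write_png(img, out / f"rate_map_{label}.png")
            files[f"rate_map_{label}_pgm"] = write_pgm(img, out / f"rate_map_{label}.pgm")
    return files


def save_sweep(result: SweepResult, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "parameter": result.parameter,
            "value": result.values,
            "ic_mean": result.mean,
            "ic_sd": result.sd,
        }
    )
    df.to_csv(path, index=False)
    return path
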
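"""Run configuration, packaged parameter bundles and output management.

Units are fixed package-wide and never configurable: energies and
frequencies in cm^-1, coordinates in Angstrom, dipoles in Debye,
temperatures in K, times in fs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .pipeline import ParameterBundle, SpectrumResult

__all__ = [
    "RunConfig",
    "load_bundle",
    "packaged_bundles",
    "write_outputs",
    "read_spectrum",
    "ConfigError",
    "InputDataError",
]


class ConfigError(ValueError):
    """Malformed or inconsistent run configuration (CLI exit code 2)."""


class InputDataError(ValueError):
    """Unreadable or inconsistent input data (CLI exit code 3)."""


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one pipeline run."""

    bundle: str = "LH2purp"
    seed: int = 0
    global_shift: float = 0.0
    temperature: float = 300.0
    n_frames: int = 50
    sigma_static: Mapping[str, float] = field(default_factory=dict)
    sigma_add: Mapping[str, float] = field(default_factory=dict)
    sigma_coupling: float = 0.0
    omega_min: float = 11200.0
    omega_max: float = 14900.0
    omega_step: float = 2.0
    outdir: str = "out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except (OSError, yaml.YAMLError) as err:
            raise ConfigError(f"cannot read config {path}: {err}") from err
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def omega_grid(self) -> np.ndarray:
        if self.omega_step <= 0 or self.omega_max <= self.omega_min:
            raise ConfigError("invalid omega grid in config")
        return np.arange(self.omega_min, self.omega_max, self.omega_step)


def packaged_bundles() -> list[str]:
    """Names of the parameter bundles shipped with the package."""
    pkg = resources.files("lh2exciton") / "data"
    return sorted(p.name[: -len(".yaml")] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_bundle(name_or_path: str) -> ParameterBundle:
    """Load a packaged bundle by name ('LH2purp', 'LH2acid') or any YAML
    bundle file by path."""
    path = Path(name_or_path)
    if path.suffix in (".yaml", ".yml") and path.exists():
        text = path.read_text()
    else:
        res = resources.files("lh2exciton") / "data" / f"{name_or_path}.yaml"
        if not res.is_file():
            raise InputDataError(
                f"unknown bundle {name_or_path!r}; packaged bundles: {packaged_bundles()}"
            )
        text = res.read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as err:
        raise InputDataError(f"malformed bundle {name_or_path!r}: {err}") from err
    try:
        return ParameterBundle(
            name=raw["name"],
            site_energies=raw["site_energies"],
            couplings=raw["couplings"],
            n_units=raw["n_units"],
            ct=raw.get("ct"),
            provenance=raw.get("provenance", {}),
        )
    except (KeyError, ValueError, TypeError) as err:
        raise InputDataError(f"invalid bundle {name_or_path!r}: {err}") from err


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_outputs(
    result: SpectrumResult,
    outdir,
    config: RunConfig | dict | None = None,
    prefix: str = "spectrum",
) -> Path:
    """Write spectra and a manifest; returns the manifest path.

    File names are deterministic; rerunning with the same configuration and
    seed reproduces the files bitwise.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as err:
        raise InputDataError(f"cannot create output directory {outdir}: {err}") from err

    spec_path = outdir / f"{prefix}.tsv"
    with open(spec_path, "w") as fh:
        fh.write("energy_cm1\tabsorption\tcd\n")
        for w, a, c in zip(result.omega, result.absorption, result.cd):
            fh.write(f"{w:.6f}\t{a:.8e}\t{c:.8e}\n")

    if isinstance(config, RunConfig):
        config = {k: getattr(config, k) for k in config.__dataclass_fields__}
    manifest = {
        "global_shift_cm1": result.global_shift,
        "peaks": result.peaks,
        "provenance": dict(result.provenance),
        "config": config,
        "config_hash": _config_hash(config or {}),
        "files": [spec_path.name],
    }
    manifest_path = outdir / f"{prefix}_manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest_path


def read_spectrum(path) -> dict[str, np.ndarray]:
    """Parse a spectrum TSV back into arrays."""
    data = np.loadtxt(path, skiprows=1)
    return {
        "energy_cm1": data[:, 0],
        "absorption": data[:, 1],
        "cd": data[:, 2],
    }
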
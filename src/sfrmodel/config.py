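"""Configuration loading, result writers, and run manifests.

Configs are YAML or JSON mappings with a small validated schema; defaults
follow the reference probe (NA 0.22, indices 1.35/1.45/1.00) and the
calibrated model constants.  Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from .diffuse import ProbeConfig
from .forward import ModelConstants

__all__ = ["RunManifest", "load_config", "load_constants", "write_results",
           "EXIT_OK", "EXIT_CONFIG_ERROR", "EXIT_NUMERICAL_ERROR"]

EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_NUMERICAL_ERROR = 3

_KNOWN_KEYS = {
    "na", "d_um", "n_sample", "n_fiber", "n_external", "A",
    "musp_per_cm", "mus_per_cm", "n_photons", "seed",
    "termination_distance_cm", "launch",
}


@dataclass(frozen=True)
class RunManifest:
    """Provenance record written next to every CLI output."""

    command: str
    config_path: str | None
    seed: int | None
    output_dir: str
    package_version: str
    timestamp: str

    @classmethod
    def create(cls, command: str, output_dir, config_path=None, seed=None):
        from . import __version__

        return cls(command=command,
                   config_path=str(config_path) if config_path else None,
                   seed=seed, output_dir=str(output_dir),
                   package_version=__version__,
                   timestamp=datetime.datetime.now().isoformat(timespec="seconds"))

    def write(self) -> Path:
        path = Path(self.output_dir) / "manifest.json"
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return path


@dataclass(frozen=True)
class LoadedConfig:
    """Validated configuration: probe geometry plus optional MC settings."""

    probe: ProbeConfig
    musp_per_cm: float | None = None
    mus_per_cm: float | None = None
    n_photons: int | None = None
    seed: int | None = None
    termination_distance_cm: float | None = None
    launch: str = "uniform-polar"

    def to_dict(self) -> dict:
        d = {
            "na": self.probe.na, "d_um": self.probe.d * 1e4,
            "n_sample": self.probe.n_sample, "n_fiber": self.probe.n_fiber,
            "n_external": self.probe.n_external, "A": self.probe.A,
            "launch": self.launch,
        }
        for k in ("musp_per_cm", "mus_per_cm", "n_photons", "seed",
                  "termination_distance_cm"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return d

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _parse_mapping(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return data


def load_config(path) -> LoadedConfig:
    """Load and validate a YAML/JSON config, injecting defaults.

    Minimal config: ``{na: 0.22, d_um: 100}``.  Unknown keys are rejected
    with their paths; geometric invariants (e.g. ``NA < n_sample``) are
    enforced by :class:`ProbeConfig`.
    """
    data = _parse_mapping(path)
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)} "
                         f"(known: {sorted(_KNOWN_KEYS)})")
    if "d_um" not in data:
        raise ValueError("config must set d_um (fiber diameter in microns)")
    probe = ProbeConfig(
        d=float(data["d_um"]) * 1e-4,
        na=float(data.get("na", 0.22)),
        n_sample=float(data.get("n_sample", 1.35)),
        n_fiber=float(data.get("n_fiber", 1.45)),
        n_external=float(data.get("n_external", 1.00)),
        A=float(data["A"]) if "A" in data else None,
    )
    return LoadedConfig(
        probe=probe,
        musp_per_cm=(float(data["musp_per_cm"]) if "musp_per_cm" in data else None),
        mus_per_cm=(float(data["mus_per_cm"]) if "mus_per_cm" in data else None),
        n_photons=(int(float(data["n_photons"])) if "n_photons" in data else None),
        seed=(int(data["seed"]) if "seed" in data else None),
        termination_distance_cm=(float(data["termination_distance_cm"])
                                 if "termination_distance_cm" in data else None),
        launch=str(data.get("launch", "uniform-polar")),
    )


def load_constants(path) -> ModelConstants:
    """Read model constants from a YAML/JSON file keyed by NA.

    Format: ``{a1: 1.11, na: {0.22: {a2: 3046, a3: 0.748}, ...}}``.
    """
    data = _parse_mapping(path)
    a2a3 = {float(na): (float(v["a2"]), float(v["a3"]))
            for na, v in data.get("na", {}).items()}
    return ModelConstants(a1=float(data.get("a1", 1.11)), a2a3=a2a3)


def write_results(table: pd.DataFrame, path, fmt: str | None = None) -> Path:
    """Write a result table as CSV, JSON or HDF5 (lossless numerics).

    ``fmt`` defaults to the file extension.  CSV uses full ``repr``
    precision; JSON uses pandas' table orientation; HDF5 stores the table
    under the ``table`` key.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty results table")
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".")
    if fmt == "csv":
        table.to_csv(path, index=False, float_format=None)
    elif fmt == "json":
        path.write_text(table.to_json(orient="table", indent=2, index=False))
    elif fmt in ("h5", "hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            grp = f.create_group("table")
            for col in table.columns:
                vals = table[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                grp.create_dataset(col, data=vals)
    else:
        raise ValueError(f"unsupported format {fmt!r} (csv, json, hdf5)")
    return path


def read_results(path, fmt: str | None = None) -> pd.DataFrame:
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".")
    if fmt == "csv":
        return pd.read_csv(path)
    if fmt == "json":
        return pd.read_json(path, orient="table")
    if fmt in ("h5", "hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            grp = f["table"]
            data = {}
            for col in grp:
                vals = grp[col][()]
                if vals.dtype.kind == "S":
                    vals = vals.astype(str)
                data[col] = vals
        return pd.DataFrame(data)
    raise ValueError(f"unsupported format {fmt!r}")
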
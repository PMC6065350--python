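"""Serialization: matrices and topologies as headered CSV, configs as YAML,
results as CSV/JSON, plus a run manifest for bit-identical re-runs.

CSV dialect is fixed: comma-separated, period decimal, UTF-8, mandatory
header row, species ids ``S1..Sn`` as header and first column.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .community import BinaryTopology, MODULAR
from .experiment import ExperimentConfig, PersistenceTable
from .geometry import GammaEstimate
from .lv import InteractionMatrix

__all__ = [
    "FormatError",
    "RunManifest",
    "read_interaction_matrix",
    "write_interaction_matrix",
    "read_topology",
    "write_topology",
    "load_experiment_config",
    "load_environment_spec",
    "write_results",
]


class FormatError(ValueError):
    """Malformed input file (non-square table, bad ids, schema violation)."""


@dataclass
class RunManifest:
    """Record of one run: config hash, master seed, and emitted artifacts.

    The recorded seed plus the config hash suffice to re-run the pipeline
    bit-identically; every listed artifact path was written by this run.
    """

    config_hash: str = ""
    seed: int | None = None
    artifacts: list[str] = field(default_factory=list)
    sub_seeds: dict = field(default_factory=dict)

    @staticmethod
    def hash_config(config) -> str:
        if dataclasses.is_dataclass(config) and not isinstance(config, type):
            payload = dataclasses.asdict(config)
        else:
            payload = config
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def add(self, path) -> None:
        self.artifacts.append(str(path))

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "sub_seeds": self.sub_seeds,
                    "artifacts": self.artifacts,
                },
                indent=2,
            )
            + "\n"
        )


def _read_square_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if df.shape[0] != df.shape[1]:
        raise FormatError(
            f"{path}: table is {df.shape[0]} rows x {df.shape[1]} columns, not square"
        )
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicated row id {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicated column id {dup!r}")
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row ids and column ids differ")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric entry ({exc})") from None
    return df


def read_interaction_matrix(path) -> InteractionMatrix:
    """Read an interaction matrix from headered CSV (ids in header + first
    column); validates squareness, numeric entries, and unique ids."""
    df = _read_square_table(path)
    return InteractionMatrix(A=df.to_numpy(), species_ids=[str(c) for c in df.columns])


def write_interaction_matrix(mat: InteractionMatrix, path) -> None:
    df = pd.DataFrame(mat.A, index=mat.species_ids, columns=mat.species_ids)
    df.to_csv(path, float_format="%.17g")


def write_topology(topology: BinaryTopology, path, sidecar: dict | None = None) -> None:
    """Write adjacency CSV plus a sidecar JSON with structure metadata."""
    ids = [f"S{i + 1}" for i in range(topology.n)]
    pd.DataFrame(topology.adjacency, index=ids, columns=ids).to_csv(path)
    meta = {
        "structure_label": topology.structure_label,
        "n": topology.n,
        "n_links": topology.n_links(),
    }
    if topology.module_partition is not None:
        meta["module_partition"] = topology.module_partition.tolist()
    if sidecar:
        meta.update(sidecar)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2) + "\n")


def read_topology(path) -> BinaryTopology:
    df = _read_square_table(path)
    meta_path = Path(str(path) + ".json")
    label, partition = "random", None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        label = meta.get("structure_label", "random")
        if "module_partition" in meta:
            partition = np.asarray(meta["module_partition"], dtype=int)
    return BinaryTopology(
        adjacency=df.to_numpy().astype(int),
        structure_label=label,
        module_partition=partition if label == MODULAR else None,
    )


_CONFIG_KEYS = {f.name for f in dataclasses.fields(ExperimentConfig)}


def load_experiment_config(path=None, overrides: dict | None = None) -> ExperimentConfig:
    """Load a YAML experiment config; defaults filled, unknown keys rejected.

    An empty or missing file yields the full defaults (21 species, 5,000
    replicates, scenarios a-f).  ``overrides`` are applied on top.
    """
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise FormatError(f"{path}: config must be a mapping")
        data.update(raw)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    unknown = sorted(set(data) - _CONFIG_KEYS)
    if unknown:
        raise FormatError(f"unknown config keys: {', '.join(unknown)}")
    for key in ("structures", "scenarios"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    try:
        return ExperimentConfig(**data)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"invalid config: {exc}") from None


def load_environment_spec(path):
    """Load an environment distribution Ξ from YAML.

    Schema: ``kind`` (gaussian | uniform_box | point_mass) plus the family
    parameters: mean + cov (or a scalar variance) for gaussian, low + high
    for uniform_box, location for point_mass.
    """
    from .geometry import EnvironmentDistribution

    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "kind" not in raw:
        raise FormatError(f"{path}: environment spec must be a mapping with a 'kind'")
    kind = raw["kind"]
    try:
        if kind == "gaussian":
            mean = np.asarray(raw["mean"], dtype=float)
            cov = raw["cov"]
            cov = (
                float(cov) * np.eye(mean.shape[0])
                if np.isscalar(cov)
                else np.asarray(cov, dtype=float)
            )
            return EnvironmentDistribution.gaussian(mean, cov)
        if kind == "uniform_box":
            return EnvironmentDistribution.uniform_box(raw["low"], raw["high"])
        if kind == "point_mass":
            return EnvironmentDistribution.point_mass(raw["location"])
    except KeyError as exc:
        raise FormatError(f"{path}: missing key {exc} for kind {kind!r}") from None
    raise FormatError(f"{path}: unknown environment kind {kind!r}")


def write_results(result, path, manifest: RunManifest | None = None):
    """Write a PersistenceTable as CSV or a GammaEstimate as JSON.

    Column order is stable and output is byte-identical across re-runs
    with the same seed.  Returns the manifest entry (the path written).
    """
    path = Path(path)
    if isinstance(result, PersistenceTable):
        result.to_frame().to_csv(path, index=False)
    elif isinstance(result, GammaEstimate):
        payload = {
            "gamma": result.gamma,
            "se": result.se,
            "n_samples": result.n_samples,
            "seed": result.seed,
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")
    if manifest is not None:
        manifest.add(path)
    return str(path)
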
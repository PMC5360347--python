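"""Configuration loading and network assembly.

A single YAML (or JSON) file declares the network: intrinsic periods,
synaptic conductances, optional neuron-parameter overrides and run
settings.  :func:`load_config` validates it and fills defaults;
:func:`calibrate_network` turns the declarative form into a
:class:`~prcnet.locking.NetworkConfig` with bias currents calibrated to
the target periods.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .locking import NetworkConfig
from .model import (
    ESYN_EXCITATORY,
    ESYN_INHIBITORY,
    MLNeuronParams,
    SynapseParams,
    calibrate_bias,
)

__all__ = ["RunConfig", "NetworkSpec", "ConfigError", "load_config",
           "calibrate_network", "config_hash"]


class ConfigError(ValueError):
    """Schema violation; the message names the offending keys."""


@dataclass
class NetworkSpec:
    """Declarative network description (pre-calibration)."""

    P1i: float = 60.0
    P2i: float = 70.0
    P3i: float = 80.0
    g12: float = 0.015
    g23: float = 0.0275
    g32: float = 0.002
    neuron_overrides: dict = field(default_factory=dict)


@dataclass
class RunConfig:
    """Run settings: seed, tolerances, grids, output."""

    seed: int = 0
    n_phases: int = 50
    cycles: int = 100
    discard: int = 20
    convergence_tol: float = 0.05
    convergence_window: int = 10
    calibration_tol: float = 0.05
    outdir: str = "."
    verbosity: int = 1

    def __post_init__(self) -> None:
        bad = [
            k
            for k in ("convergence_tol", "calibration_tol")
            if getattr(self, k) <= 0
        ]
        if bad:
            raise ConfigError(f"tolerances must be positive: {', '.join(bad)}")


_NETWORK_KEYS = {"periods", "synapses", "neuron"}
_RUN_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path: str | Path) -> tuple[RunConfig, NetworkSpec]:
    """Read and validate a YAML/JSON configuration file.

    Unknown keys, negative conductances and non-positive periods are
    reported together, each named."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top level of the config must be a mapping")

    errors: list[str] = []
    unknown = set(raw) - _NETWORK_KEYS - {"run"}
    if unknown:
        errors.append(f"unknown top-level keys: {sorted(unknown)}")

    periods = raw.get("periods", {}) or {}
    synapses = raw.get("synapses", {}) or {}
    net_kwargs: dict = {}
    for key in ("P1i", "P2i", "P3i"):
        if key in periods:
            value = periods[key]
            if not isinstance(value, (int, float)) or value <= 0:
                errors.append(f"periods.{key} must be a positive number")
            else:
                net_kwargs[key] = float(value)
    for key in set(periods) - {"P1i", "P2i", "P3i"}:
        errors.append(f"unknown key periods.{key}")
    for key in ("g12", "g23", "g32"):
        if key in synapses:
            value = synapses[key]
            if not isinstance(value, (int, float)) or value < 0:
                errors.append(f"synapses.{key} must be a non-negative number")
            else:
                net_kwargs[key] = float(value)
    for key in set(synapses) - {"g12", "g23", "g32"}:
        errors.append(f"unknown key synapses.{key}")

    overrides = raw.get("neuron", {}) or {}
    valid_fields = {f.name for f in dataclasses.fields(MLNeuronParams)}
    for key in set(overrides) - valid_fields:
        errors.append(f"unknown key neuron.{key}")

    run_raw = raw.get("run", {}) or {}
    for key in set(run_raw) - _RUN_KEYS:
        errors.append(f"unknown key run.{key}")

    if errors:
        raise ConfigError("; ".join(errors))

    spec = NetworkSpec(
        neuron_overrides={k: overrides[k] for k in overrides}, **net_kwargs
    )
    run = RunConfig(**{k: run_raw[k] for k in run_raw})
    return run, spec


def dump_config(run: RunConfig, spec: NetworkSpec, path: str | Path) -> None:
    doc = {
        "periods": {"P1i": spec.P1i, "P2i": spec.P2i, "P3i": spec.P3i},
        "synapses": {"g12": spec.g12, "g23": spec.g23, "g32": spec.g32},
    }
    if spec.neuron_overrides:
        doc["neuron"] = dict(spec.neuron_overrides)
    doc["run"] = dataclasses.asdict(run)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def calibrate_network(
    spec: NetworkSpec, *, calibration_tol: float = 0.05
) -> NetworkConfig:
    """Assemble the calibrated :class:`NetworkConfig` from a spec.

    Each neuron's bias current is searched so its free-running period
    matches the declared intrinsic period."""
    base = MLNeuronParams(**spec.neuron_overrides)
    neurons = []
    for target in (spec.P1i, spec.P2i, spec.P3i):
        I0 = calibrate_bias(base, target, tol=calibration_tol)
        neurons.append(base.with_bias(I0))
    return NetworkConfig(
        neuron1=neurons[0],
        neuron2=neurons[1],
        neuron3=neurons[2],
        syn12=SynapseParams(gsyn=spec.g12, Esyn=ESYN_EXCITATORY),
        syn23=SynapseParams(gsyn=spec.g23, Esyn=ESYN_EXCITATORY),
        syn32=SynapseParams(gsyn=spec.g32, Esyn=ESYN_INHIBITORY),
        P1i=spec.P1i,
        P2i=spec.P2i,
        P3i=spec.P3i,
    )


def config_hash(run: RunConfig, spec: NetworkSpec) -> str:
    """Stable short hash of the full configuration, for manifests."""
    doc = {
        "run": dataclasses.asdict(run),
        "network": dataclasses.asdict(spec),
    }
    payload = json.dumps(doc, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
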
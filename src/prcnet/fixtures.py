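"""Deterministic synthetic objects for testing and demonstration.

Everything here is reproducible from (spec, seed): periodic spike trains
with prescribed offsets, normal-form PRC tables with optional additive
noise, and random 2x2 return-map matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import SpikeTrain
from .prc import NormalFormPRC, PRCTable, default_phase_grid

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "make_spike_trains",
    "make_prc_table",
    "make_matrix",
]


@dataclass
class FixtureSpec:
    """Which synthetic object to build, with its parameters and seed."""

    kind: str  # "spike_trains" | "prc_table" | "matrix"
    params: dict = field(default_factory=dict)
    seed: int = 0


def make_spike_trains(
    period: float = 60.0,
    offsets: Sequence[float] = (40.0, 0.0, 15.0),
    n_cycles: int = 50,
    start: float = 0.0,
) -> tuple[SpikeTrain, SpikeTrain, SpikeTrain]:
    """Three perfectly periodic trains with fixed offsets per cycle.

    ``offsets`` are (master, slave, interneuron) delays relative to the
    common cycle origin; the default realizes slave cycles in which the
    interneuron fires 15 and the master 40 time units after each slave
    spike.
    """
    base = start + period * np.arange(n_cycles)
    return tuple(SpikeTrain(times=base + off) for off in offsets)


def make_prc_table(
    c: float = -0.1,
    period: float = 70.0,
    n_phases: int = 50,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> PRCTable:
    """Normal-form PRC sampled on the default grid, plus optional noise."""
    phases = default_phase_grid(n_phases)
    values = NormalFormPRC(c=c, period=period)(phases)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sigma, size=values.shape)
    return PRCTable(
        phases=phases, values=values, period=period,
        meta={"source": "fixture", "c": c, "noise_sigma": noise_sigma},
    )


def make_matrix(seed: int = 0, max_entry: float = 2.0) -> np.ndarray:
    """Random 2x2 matrix with entries uniform in [-max_entry, max_entry]."""
    rng = np.random.default_rng(seed)
    return rng.uniform(-max_entry, max_entry, size=(2, 2))


def make_fixture(spec: FixtureSpec):
    """Dispatch on :class:`FixtureSpec`; bit-identical for equal specs."""
    if spec.kind == "spike_trains":
        return make_spike_trains(**spec.params)
    if spec.kind == "prc_table":
        return make_prc_table(seed=spec.seed, **spec.params)
    if spec.kind == "matrix":
        return make_matrix(seed=spec.seed, **spec.params)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")
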
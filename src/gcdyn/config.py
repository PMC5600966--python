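"""Run configuration, validation and synthetic-population fixtures.

Configs are flat YAML or JSON mappings whose keys are the
:class:`~gcdyn.simulator.ModelParams` fields plus run-level options
(replicates, seed, sampling, output, labeling).  Unknown keys are rejected
so typos fail loudly, and an empty config yields the canonical default
parameter set.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .labeling import LabelingPlan
from .simulator import ModelParams, Population

__all__ = ["ConfigError", "RunConfig", "load_config", "save_config", "make_fixture"]


class ConfigError(ValueError):
    """A configuration file or value failed validation."""


_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParams)}


@dataclass
class RunConfig:
    """Everything needed to reproduce one ensemble run."""

    params: ModelParams = field(default_factory=ModelParams)
    replicates: int = 200
    seed: int = 0
    sample_interval: float = 1.0
    method: str = "tau"
    dt: float = 0.002
    out_dir: str = "gcdyn_out"
    label_day: float | None = None
    label_colors: int = 10
    label_prob: float | None = None

    def __post_init__(self):
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.sample_interval <= 0:
            raise ConfigError("sample_interval must be > 0")
        if self.method not in ("tau", "ssa"):
            raise ConfigError("method must be 'tau' or 'ssa'")
        if self.dt <= 0:
            raise ConfigError("dt must be > 0")

    @property
    def labeling(self) -> LabelingPlan | None:
        if self.label_prob is None:
            return None
        return LabelingPlan(self.label_day, self.label_colors, self.label_prob)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self.params)
        if isinstance(d["initial_affinity"], np.ndarray):
            d["initial_affinity"] = d["initial_affinity"].tolist()
        for f in dataclasses.fields(self):
            if f.name != "params":
                d[f.name] = getattr(self, f.name)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        run_fields = {f.name for f in dataclasses.fields(cls)} - {"params"}
        unknown = set(data) - _PARAM_FIELDS - run_fields
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            params = ModelParams(
                **{k: v for k, v in data.items() if k in _PARAM_FIELDS}
            )
            return cls(
                params=params,
                **{k: v for k, v in data.items() if k in run_fields},
            )
        except (ValueError, TypeError) as err:
            raise ConfigError(str(err)) from err


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML or JSON config; empty files give defaults."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text) if text.strip() else {}
    else:
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config that round-trips losslessly through ``load_config``."""
    path = Path(path)
    data = cfg.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def make_fixture(
    fractions: Sequence[float],
    affinities: Sequence[float] | float,
    total: int,
    t: float = 0.0,
    phase: str = "competition",
) -> Population:
    """Deterministic synthetic population with a prescribed composition.

    Clone ``i+1`` receives ``round(fractions[i] * total)`` cells (largest
    remainders absorb any rounding slack so the total is exact) at the
    requested affinity.  Fractions must sum to one.  Used to unit-test the
    statistics layer and competition-phase behavior without running a
    growth phase.
    """
    frac = np.asarray(fractions, dtype=float)
    if np.any(frac < 0):
        raise ConfigError("fractions must be >= 0")
    if abs(frac.sum() - 1.0) > 1e-9:
        raise ConfigError(f"fractions must sum to 1 (got {frac.sum():.6f})")
    if total < 1:
        raise ConfigError("total must be >= 1")
    aff = np.asarray(affinities, dtype=float)
    if aff.ndim == 0:
        aff = np.full(frac.size, float(aff))
    if aff.shape != frac.shape:
        raise ConfigError("affinities must align with fractions")
    if np.any(aff <= 0):
        raise ConfigError("affinities must be > 0")
    ideal = frac * total
    counts = np.floor(ideal).astype(np.int64)
    short = total - counts.sum()
    if short:
        order = np.argsort(-(ideal - counts), kind="stable")
        counts[order[:short]] += 1
    clone_id = np.repeat(np.arange(1, frac.size + 1), counts)
    affinity = np.repeat(aff, counts)
    return Population(clone_id, affinity, t=t, phase=phase)
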
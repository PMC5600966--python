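"""Tidy-file input/output for ensembles of simulated trajectories.

Trajectories are written long-format (one row per replicate × time × clone)
so they concatenate and group naturally with data-frame tooling; every
ensemble gets a ``params.json`` sidecar capturing the exact configuration,
seed and package version for bit-reproducibility.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .simulator import ModelParams, Trajectory

__all__ = [
    "ensemble_frame",
    "color_frame",
    "write_ensemble",
    "read_trajectories",
    "write_params_sidecar",
]


def ensemble_frame(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Concatenate replicate trajectories into one tidy table."""
    frames = []
    for i, traj in enumerate(trajectories):
        df = traj.to_frame()
        df.insert(0, "replicate", i)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def color_frame(trajectories: Sequence[Trajectory]) -> pd.DataFrame | None:
    """Tidy per-color counts (replicate, time, color, count); None if unlabeled."""
    rows = []
    for i, traj in enumerate(trajectories):
        if traj.color_counts is None:
            continue
        s, k = traj.color_counts.shape
        rows.append(
            pd.DataFrame(
                {
                    "replicate": i,
                    "time_days": np.repeat(traj.times, k),
                    "color": np.tile(np.arange(k), s),  # 0 = unlabeled
                    "count": traj.color_counts.ravel(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True) if rows else None


def write_params_sidecar(
    params: ModelParams, out_dir: Path, seed: int | None, replicates: int, **extra
) -> Path:
    d = dataclasses.asdict(params)
    if isinstance(d["initial_affinity"], np.ndarray):
        d["initial_affinity"] = d["initial_affinity"].tolist()
    payload = {
        "gcdyn_version": __version__,
        "seed": seed,
        "replicates": replicates,
        "params": d,
        **extra,
    }
    path = out_dir / "params.json"
    path.write_text(json.dumps(payload, indent=2))
    return path


def write_ensemble(
    trajectories: Sequence[Trajectory],
    out_dir: str | Path,
    seed: int | None = None,
    **sidecar_extra,
) -> Path:
    """Write trajectories.csv (+ colors.csv if labeled) and params.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ensemble_frame(trajectories).to_csv(out / "trajectories.csv", index=False)
    colors = color_frame(trajectories)
    if colors is not None:
        colors.to_csv(out / "colors.csv", index=False)
    write_params_sidecar(
        trajectories[0].params, out, seed, len(trajectories), **sidecar_extra
    )
    return out


def read_trajectories(path: str | Path) -> pd.DataFrame:
    """Load a tidy trajectories.csv written by :func:`write_ensemble`."""
    df = pd.read_csv(path)
    required = {"replicate", "phase", "time_days", "clone_id", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
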
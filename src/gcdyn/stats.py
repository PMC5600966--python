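"""Diversity, dominance and selection statistics of simulated germinal centers.

All statistics operate on :class:`ClonalSnapshot` (the per-clone composition
at one time point) or on collections of :class:`~gcdyn.simulator.Trajectory`
replicates, and reproduce the standard summaries of clonal competition:
dominant-clone fractions, surviving-clone counts, the participation ratio
(same-clone collision probability), heterozygosity, the occupancy
correlation with the end-of-growth state, affinity-wave summaries, and
cross-replicate correlation/dominance analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulator import Population, Trajectory

__all__ = [
    "ClonalSnapshot",
    "dominant_fraction",
    "surviving_clone_count",
    "participation_ratio",
    "heterozygosity",
    "occupancy_correlation",
    "cosine_similarity",
    "affinity_wave_stats",
    "diversity_affinity_correlation",
    "dominance_probability",
    "ensemble_summary",
    "SNAPSHOT_STATS",
]


@dataclass(frozen=True)
class ClonalSnapshot:
    """Per-clone composition of one germinal center at one time.

    ``counts[i]`` is the number of cells of clone ``i+1``;
    ``mean_affinity`` (optional) the per-clone mean affinity (NaN where
    extinct).
    """

    counts: np.ndarray
    mean_affinity: np.ndarray | None = None

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(counts < 0):
            raise ValueError("clone counts must be >= 0")
        object.__setattr__(self, "counts", counts)
        if self.mean_affinity is not None:
            ma = np.asarray(self.mean_affinity, dtype=float)
            if ma.shape != counts.shape:
                raise ValueError("mean_affinity must align with counts")
            object.__setattr__(self, "mean_affinity", ma)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_population(cls, pop: Population, n_clones: int) -> "ClonalSnapshot":
        return cls(pop.clone_counts(n_clones), pop.clone_mean_affinity(n_clones))

    @classmethod
    def from_trajectory(cls, traj: Trajectory, index: int = -1) -> "ClonalSnapshot":
        return cls(traj.counts[index], traj.clone_mean_affinity[index])


def _dominance_order(counts: np.ndarray) -> np.ndarray:
    """Clone indices sorted by decreasing count, ties broken by clone id."""
    return np.lexsort((np.arange(counts.size), -counts))


def dominant_fraction(s: ClonalSnapshot, rank: int = 1) -> float:
    """Fraction of the population held by the ``rank``-th largest clone.

    Ties are broken deterministically by smallest clone id; a rank beyond
    the number of surviving clones yields 0.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    total = s.total
    if total <= 0:
        raise ValueError("snapshot is empty")
    if rank > s.counts.size:
        return 0.0
    order = _dominance_order(s.counts)
    return float(s.counts[order[rank - 1]]) / total


def surviving_clone_count(s: ClonalSnapshot) -> int:
    """Number of clones with at least one living cell."""
    return int((s.counts > 0).sum())


def participation_ratio(s: ClonalSnapshot, without_replacement: bool = False) -> float:
    """Probability that two randomly chosen cells belong to the same clone.

    By default the with-replacement form Σ f_i² (the standard
    order-parameter convention); ``without_replacement`` selects
    Σ n_i(n_i - 1) / (N(N - 1)) instead.
    """
    total = s.total
    if total <= 0:
        raise ValueError("snapshot is empty")
    n = s.counts.astype(float)
    if without_replacement:
        if total < 2:
            raise ValueError("need at least two cells without replacement")
        return float((n * (n - 1)).sum() / (total * (total - 1)))
    f = n / total
    return float((f**2).sum())


def heterozygosity(s: ClonalSnapshot) -> float:
    """Probability that two randomly chosen cells belong to different clones."""
    return 1.0 - participation_ratio(s)


def occupancy_correlation(reference: ClonalSnapshot, current: ClonalSnapshot) -> float:
    """Overlap of the current composition with a reference composition.

    ``C = (1/N_tot(current)) Σ_i n_i(ref) n_i(current)``, normalized only by
    the current total, so the value carries units of cells.  With identical
    snapshots it equals ``participation_ratio × N_tot``.  For a
    dimensionless variant see :func:`cosine_similarity`.
    """
    if reference.counts.size != current.counts.size:
        raise ValueError("snapshots must share the clone index set")
    total = current.total
    if total <= 0:
        raise ValueError("current snapshot is empty")
    return float((reference.counts * current.counts).sum() / total)


def cosine_similarity(reference: ClonalSnapshot, current: ClonalSnapshot) -> float:
    """Dimensionless cosine overlap of two compositions (in [0, 1])."""
    if reference.counts.size != current.counts.size:
        raise ValueError("snapshots must share the clone index set")
    a = reference.counts.astype(float)
    b = current.counts.astype(float)
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        raise ValueError("cannot compare empty snapshots")
    return float(a @ b / denom)


def affinity_wave_stats(trajectory: Trajectory) -> pd.DataFrame:
    """Population affinity mean, spread and mean/STD ratio over time.

    The STD uses the population (divide-by-n) convention — it describes the
    standing affinity distribution.  The ratio is NaN (missing) wherever the
    STD is zero, e.g. the initial delta-function state.
    """
    mean = trajectory.mean_affinity
    std = trajectory.std_affinity
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(std > 0, mean / np.where(std > 0, std, 1.0), np.nan)
    return pd.DataFrame(
        {
            "time_days": trajectory.times,
            "comp_day": trajectory.comp_day,
            "mean_affinity": mean,
            "std_affinity": std,
            "mean_std_ratio": ratio,
        }
    )


def diversity_affinity_correlation(snapshots: Sequence[ClonalSnapshot]) -> float:
    """Pearson r across replicates between clone count and dominant affinity.

    For each replicate snapshot the pair (number of surviving clones, mean
    affinity of the rank-1 clone) is formed; returns their Pearson
    correlation, or NaN when fewer than 3 replicates or either variable is
    constant.
    """
    n_clones = []
    top_aff = []
    for s in snapshots:
        if s.total <= 0:
            continue
        if s.mean_affinity is None:
            raise ValueError("snapshots must carry per-clone mean affinities")
        n_clones.append(surviving_clone_count(s))
        order = _dominance_order(s.counts)
        top_aff.append(s.mean_affinity[order[0]])
    x = np.asarray(n_clones, dtype=float)
    y = np.asarray(top_aff, dtype=float)
    if x.size < 3 or x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(sps.pearsonr(x, y).statistic)


def dominance_probability(
    trajectories: Sequence[Trajectory], max_rank: int = 5, index: int = -1
) -> pd.DataFrame:
    """Per-clone probability of finishing at each dominance rank.

    All replicates must share the founding-affinity assignment (clone ids
    are comparable across replicates).  Returns a DataFrame indexed by
    clone id with columns ``rank_1..rank_k``; each column is an empirical
    distribution over clones among the replicates that had at least k
    surviving clones, so it sums to 1.
    """
    m = trajectories[0].counts.shape[1]
    hits = np.zeros((m, max_rank))
    denom = np.zeros(max_rank)
    for traj in trajectories:
        counts = traj.counts[index]
        if counts.sum() == 0:
            continue
        order = _dominance_order(counts)
        alive = int((counts > 0).sum())
        for k in range(min(max_rank, alive)):
            hits[order[k], k] += 1
            denom[k] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = np.where(denom > 0, hits / np.maximum(denom, 1), np.nan)
    return pd.DataFrame(
        prob,
        index=pd.Index(np.arange(1, m + 1), name="clone_id"),
        columns=[f"rank_{k + 1}" for k in range(max_rank)],
    )


#: snapshot-level statistics available to :func:`ensemble_summary`
SNAPSHOT_STATS: dict[str, Callable[[ClonalSnapshot], float]] = {
    "dominant_fraction": dominant_fraction,
    "surviving_clones": lambda s: float(surviving_clone_count(s)),
    "participation_ratio": participation_ratio,
    "heterozygosity": heterozygosity,
    "total": lambda s: float(s.total),
}


def ensemble_summary(
    trajectories: Sequence[Trajectory],
    statistics: Iterable[str] = ("dominant_fraction", "surviving_clones"),
) -> pd.DataFrame:
    """Cross-replicate mean and STD of snapshot statistics at every sample.

    All replicates must share the sample grid.  Returns a tidy DataFrame
    with one row per (time, statistic).
    """
    names = list(statistics)
    unknown = [n for n in names if n not in SNAPSHOT_STATS]
    if unknown:
        raise ValueError(f"unknown statistics {unknown}; choose from {sorted(SNAPSHOT_STATS)}")
    times = trajectories[0].times
    phases = trajectories[0].phases
    for traj in trajectories[1:]:
        if traj.n_samples != times.size or np.any(np.abs(traj.times - times) > 1e-9):
            raise ValueError("replicates must share the sample grid")
    rows = []
    for ti in range(times.size):
        values = {name: [] for name in names}
        for traj in trajectories:
            snap = ClonalSnapshot.from_trajectory(traj, ti)
            if snap.total == 0:
                continue
            for name in names:
                values[name].append(SNAPSHOT_STATS[name](snap))
        for name in names:
            v = np.asarray(values[name], dtype=float)
            rows.append(
                {
                    "time_days": times[ti],
                    "phase": phases[ti],
                    "statistic": name,
                    "mean": v.mean() if v.size else np.nan,
                    "std": v.std(ddof=1) if v.size > 1 else np.nan,
                    "n": v.size,
                }
            )
    return pd.DataFrame(rows)
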
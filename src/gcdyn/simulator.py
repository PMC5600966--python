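"""Agent-based stochastic simulation of one germinal center reaction.

The reaction has two phases.  During the *growth phase* (days 0..T_growth)
the ``M`` founding clones proliferate as independent linear birth-death
lineages with basal rates λ0 and μ0 and no mutation.  During the
*competition phase* (T_comp further days) the population is regulated
logistically — the death rate rises with total occupancy toward the birth
rate at the carrying capacity N — and B-cell receptor affinity ``w`` evolves:
every division copies the parent affinity to one daughter and perturbs the
other by a centred Gaussian whose scale is set by the diffusion constant
``D``.  Selection couples affinity to the demographic rates in one of three
ways:

``neutral``
    affinity is carried but ignored; birth λ0, death logistic.
``birth_limited``
    per-cell birth rate λ0 · w_i / ⟨w⟩, normalized so the population-mean
    birth rate stays exactly λ0; death logistic.
``death_limited`` / ``death_limited_normalized``
    birth λ0; per-cell death combines an affinity term A·exp(-α w_i)
    (optionally normalized to keep its population mean at μ0) with a
    crowding term proportional to total occupancy.

Two integrators are provided: an exact continuous-time SSA (next-event
sampling with rates recomputed after every event), and a fixed-step
Bernoulli tau-leap (default dt = 0.002 day) that is much faster at the
default population size and is validated against the SSA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SELECTION_MODES",
    "SD_CONVENTIONS",
    "ModelParams",
    "Population",
    "Trajectory",
    "SimulationError",
    "birth_rates",
    "death_rates",
    "mutate_on_division",
    "run_growth_phase",
    "run_competition_phase",
    "run_gc",
    "run_ensemble",
    "replicate_rng",
]

SELECTION_MODES = (
    "neutral",
    "birth_limited",
    "death_limited",
    "death_limited_normalized",
)
SD_CONVENTIONS = ("variance_2D", "literal_sd_2D")


class SimulationError(RuntimeError):
    """Raised when a run leaves the regime the rate model is meant for."""


@dataclass
class ModelParams:
    """Full parameter set of one germinal center simulation.

    Defaults are the canonical simulation conditions: M=50 founding clones,
    λ0=1.5/day, μ0=1/day, capacity N=2000 cells, D=0.001, w0=1.5, growth
    6 days, competition 16 days, birth-limited selection.

    Parameters
    ----------
    n_clones : int
        Number of founding clones M.
    birth_rate, death_rate : float
        Basal per-cell birth λ0 and death μ0 rates (1/day).
    capacity : int
        Carrying capacity N of the germinal center (cells).
    diffusion : float
        Affinity diffusion constant D controlling the per-division mutation
        scale (see ``mutation_sd_convention``).
    initial_affinity : float or sequence of float
        Founder affinity w0; a scalar (all clones identical) or a length-M
        vector of per-clone affinities.
    t_growth, t_comp : float
        Phase durations in days.
    selection : str
        One of ``SELECTION_MODES``.
    alpha : float
        Affinity sensitivity of the death-limited death rate (1/affinity).
    death_prefactor : float
        Prefactor A of the death-limited rate A·exp(-α w) (1/day).
    mutation_sd_convention : str
        ``"variance_2D"`` reads the mutation kernel N(0, 2D) as variance 2D
        (σ = √(2D), the standard notational convention; the default), while
        ``"literal_sd_2D"`` uses σ = 2D.
    affinity_floor : float
        Affinities are clamped below at this ε > 0 after mutation.
    mutate_during_growth : bool
        Mutation is normally off during the growth phase; enable for
        sensitivity checks.
    hard_cap_factor : float
        A run aborts with :class:`SimulationError` if the population exceeds
        ``hard_cap_factor * capacity`` (a rate-model misconfiguration).
    """

    n_clones: int = 50
    birth_rate: float = 1.5
    death_rate: float = 1.0
    capacity: int = 2000
    diffusion: float = 0.001
    initial_affinity: float | Sequence[float] = 1.5
    t_growth: float = 6.0
    t_comp: float = 16.0
    selection: str = "birth_limited"
    alpha: float = 1.0
    death_prefactor: float = math.e
    mutation_sd_convention: str = "variance_2D"
    affinity_floor: float = 1e-6
    mutate_during_growth: bool = False
    hard_cap_factor: float = 10.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        for name in ("birth_rate", "death_rate", "alpha", "death_prefactor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.capacity < 1:
            raise ValueError("capacity must be >= 1")
        if self.diffusion < 0:
            raise ValueError("diffusion must be >= 0")
        if self.t_growth < 0 or self.t_comp < 0:
            raise ValueError("t_growth and t_comp must be >= 0")
        if self.selection not in SELECTION_MODES:
            raise ValueError(
                f"selection must be one of {SELECTION_MODES}, got {self.selection!r}"
            )
        if self.mutation_sd_convention not in SD_CONVENTIONS:
            raise ValueError(
                f"mutation_sd_convention must be one of {SD_CONVENTIONS}"
            )
        if self.affinity_floor <= 0:
            raise ValueError("affinity_floor must be > 0")
        if self.hard_cap_factor <= 1:
            raise ValueError("hard_cap_factor must be > 1")
        w0 = self.w0_vector()
        if np.any(w0 <= 0):
            raise ValueError("initial_affinity entries must be > 0")

    def w0_vector(self) -> np.ndarray:
        """Founder affinities as a length-M vector."""
        w0 = np.asarray(self.initial_affinity, dtype=float)
        if w0.ndim == 0:
            return np.full(self.n_clones, float(w0))
        if w0.shape != (self.n_clones,):
            raise ValueError(
                f"initial_affinity vector must have length n_clones={self.n_clones}"
            )
        return w0.copy()

    @property
    def mutation_sigma(self) -> float:
        """Standard deviation of the per-division affinity perturbation."""
        if self.mutation_sd_convention == "literal_sd_2D":
            return 2.0 * self.diffusion
        return math.sqrt(2.0 * self.diffusion)


@dataclass
class Population:
    """Live state of a germinal center: one entry per cell.

    ``clone_id`` holds founder identities in 1..M; ``affinity`` the per-cell
    BCR affinity; ``color`` (optional) an inherited fluorescent label in
    0..K with 0 meaning unlabeled.
    """

    clone_id: np.ndarray
    affinity: np.ndarray
    t: float = 0.0
    phase: str = "growth"
    color: np.ndarray | None = None
    n_colors: int | None = None

    def __post_init__(self) -> None:
        self.clone_id = np.asarray(self.clone_id, dtype=np.int64)
        self.affinity = np.asarray(self.affinity, dtype=float)
        if self.clone_id.shape != self.affinity.shape:
            raise ValueError("clone_id and affinity must have equal length")
        if self.color is not None:
            self.color = np.asarray(self.color, dtype=np.int64)
            if self.color.shape != self.clone_id.shape:
                raise ValueError("color must have one entry per cell")

    @property
    def size(self) -> int:
        return int(self.clone_id.size)

    def clone_counts(self, n_clones: int) -> np.ndarray:
        """Cells per clone, indexed 0..M-1 for clones 1..M."""
        return np.bincount(self.clone_id, minlength=n_clones + 1)[1:]

    def clone_mean_affinity(self, n_clones: int) -> np.ndarray:
        """Per-clone mean affinity (NaN for extinct clones)."""
        counts = self.clone_counts(n_clones)
        sums = np.bincount(
            self.clone_id, weights=self.affinity, minlength=n_clones + 1
        )[1:]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


@dataclass
class Trajectory:
    """Time series of one run, sampled on a fixed grid.

    ``counts`` and ``clone_mean_affinity`` have shape (samples, M);
    ``mean_affinity``/``std_affinity`` are population-level (population,
    i.e. divide-by-n, standard deviation).  ``comp_day`` gives time relative
    to the start of competition (negative during growth).
    """

    times: np.ndarray
    phases: np.ndarray
    counts: np.ndarray
    clone_mean_affinity: np.ndarray
    mean_affinity: np.ndarray
    std_affinity: np.ndarray
    params: ModelParams
    seed: object = None
    color_counts: np.ndarray | None = None  # (samples, K+1), col 0 unlabeled
    final_population: "Population | None" = None  # live state at the last sample

    @property
    def n_samples(self) -> int:
        return int(self.times.size)

    @property
    def total(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def comp_day(self) -> np.ndarray:
        return self.times - self.params.t_growth

    def index_at(self, time: float) -> int:
        i = int(np.argmin(np.abs(self.times - time)))
        if abs(self.times[i] - time) > 1e-6:
            raise KeyError(f"no sample at t={time} (nearest {self.times[i]})")
        return i

    def to_frame(self):
        """Tidy long-format table: one row per (sample, clone)."""
        import pandas as pd

        s, m = self.counts.shape
        return pd.DataFrame(
            {
                "phase": np.repeat(self.phases, m),
                "time_days": np.repeat(self.times, m),
                "comp_day": np.repeat(self.comp_day, m),
                "clone_id": np.tile(np.arange(1, m + 1), s),
                "count": self.counts.ravel(),
                "mean_affinity": self.clone_mean_affinity.ravel(),
            }
        )


# ---------------------------------------------------------------------------
# rate model

def _birth_rate_arr(aff: np.ndarray, params: ModelParams):
    """Per-cell birth rates; scalar when uniform across cells."""
    if params.selection == "birth_limited" and aff.size:
        return params.birth_rate * aff / aff.mean()
    return params.birth_rate


def _death_rate_arr(aff: np.ndarray, n_tot: int, params: ModelParams):
    """Per-cell death rates (clamped at 0); scalar when uniform."""
    lam0, mu0 = params.birth_rate, params.death_rate
    dens = n_tot / params.capacity
    if params.selection in ("neutral", "birth_limited"):
        return max(mu0 + (lam0 - mu0) * dens, 0.0)
    mu_w = params.death_prefactor * np.exp(-params.alpha * aff)
    if params.selection == "death_limited":
        mu = mu_w + (lam0 - mu_w.mean()) * dens
    else:  # death_limited_normalized
        mu = mu0 * mu_w / mu_w.mean() + (lam0 - mu0) * dens
    return np.maximum(mu, 0.0)


def birth_rates(population: Population, params: ModelParams) -> np.ndarray:
    """Per-cell birth rates for the current population state.

    In birth-limited mode λ_i = λ0 · w_i / ⟨w⟩, whose population mean is λ0
    exactly; otherwise λ0 for every cell.
    """
    b = _birth_rate_arr(population.affinity, params)
    return np.broadcast_to(np.asarray(b, dtype=float), (population.size,)).copy()


def death_rates(population: Population, params: ModelParams) -> np.ndarray:
    """Per-cell death rates for the current population state.

    Neutral / birth-limited modes use the logistic rate
    μ(n) = μ0 + (λ0 - μ0) n/N (n = total cell count), which equals λ0 at
    n = N.  Death-limited modes add the affinity term A·exp(-α w_i) per the
    selected variant.  Negative values are clamped to zero.
    """
    d = _death_rate_arr(population.affinity, population.size, params)
    return np.broadcast_to(np.asarray(d, dtype=float), (population.size,)).copy()


def mutate_on_division(parent_affinity, params: ModelParams, rng: np.random.Generator):
    """Affinities of the two daughters of a dividing cell.

    One daughter keeps the parent affinity exactly; the other is displaced
    by N(0, σ²) with σ = ``params.mutation_sigma`` and clamped below at the
    affinity floor, so affinity rises or falls with equal probability.
    Accepts a scalar or an array of parent affinities.
    """
    parent = np.asarray(parent_affinity, dtype=float)
    offset = rng.normal(0.0, params.mutation_sigma, parent.shape)
    mutated = np.maximum(parent + offset, params.affinity_floor)
    if parent.ndim == 0:
        return float(parent), float(mutated)
    return parent.copy(), mutated


# ---------------------------------------------------------------------------
# growth phase

def _linear_bd_counts(
    lam: float,
    mu: float,
    t_end: float,
    rng: np.random.Generator,
    sample_times: np.ndarray | None = None,
) -> tuple[int, np.ndarray | None]:
    """Exact SSA of one linear BD lineage from a single cell.

    Returns the final count and, if ``sample_times`` is given, the count at
    each (sorted, absolute) sample time.
    """
    n = 1
    t = 0.0
    tot = lam + mu
    p_birth = lam / tot if tot > 0 else 0.0
    samples = None
    si = 0
    if sample_times is not None:
        samples = np.empty(sample_times.size, dtype=np.int64)
    while True:
        rate = n * tot
        t_next = t + rng.exponential(1.0 / rate) if rate > 0 else math.inf
        horizon = min(t_next, t_end)
        if samples is not None:
            while si < samples.size and sample_times[si] <= horizon + 1e-12:
                samples[si] = n
                si += 1
        if t_next >= t_end:
            break
        t = t_next
        n += 1 if rng.random() < p_birth else -1
        if n == 0:
            if samples is not None:
                samples[si:] = 0
            break
    return n, samples


def _mutating_bd_cells(
    lam: float,
    mu: float,
    t_end: float,
    w0: float,
    params: ModelParams,
    rng: np.random.Generator,
) -> list[float]:
    """Per-cell SSA of one lineage with mutation on division (growth-phase
    sensitivity variant).  Returns the list of cell affinities at t_end."""
    cells = [w0]
    t = 0.0
    tot = lam + mu
    p_birth = lam / tot if tot > 0 else 0.0
    while cells:
        rate = len(cells) * tot
        if rate <= 0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= t_end:
            break
        i = rng.integers(len(cells))
        if rng.random() < p_birth:
            _, daughter = mutate_on_division(cells[i], params, rng)
            cells.append(daughter)
        else:
            cells[i] = cells[-1]
            cells.pop()
    return cells


def run_growth_phase(
    params: ModelParams,
    rng: np.random.Generator,
    sample_times: np.ndarray | None = None,
):
    """Simulate the free-growth phase: M independent linear BD lineages.

    Each clone starts from one cell with its founder affinity and evolves
    for ``t_growth`` days at rates λ0/μ0 with no interaction and (by
    default) no mutation.  Returns the surviving :class:`Population` at
    ``t_growth``; with ``sample_times`` also returns a (samples, M) count
    matrix.  An all-extinct population is a valid empty result.
    """
    w0 = params.w0_vector()
    clone_ids: list[np.ndarray] = []
    affinities: list[np.ndarray] = []
    count_matrix = (
        np.zeros((len(sample_times), params.n_clones), dtype=np.int64)
        if sample_times is not None
        else None
    )
    for i in range(params.n_clones):
        if params.mutate_during_growth:
            cells = _mutating_bd_cells(
                params.birth_rate, params.death_rate, params.t_growth,
                w0[i], params, rng,
            )
            n = len(cells)
            samples = None
            if sample_times is not None:
                # per-sample counts not tracked in the mutating variant
                raise NotImplementedError(
                    "sampled growth trajectories require mutate_during_growth=False"
                )
            aff = np.asarray(cells, dtype=float)
        else:
            n, samples = _linear_bd_counts(
                params.birth_rate, params.death_rate, params.t_growth,
                rng, sample_times,
            )
            aff = np.full(n, w0[i])
        if count_matrix is not None and samples is not None:
            count_matrix[:, i] = samples
        if n > 0:
            clone_ids.append(np.full(n, i + 1, dtype=np.int64))
            affinities.append(aff)
    pop = Population(
        clone_id=np.concatenate(clone_ids) if clone_ids else np.empty(0, np.int64),
        affinity=np.concatenate(affinities) if affinities else np.empty(0, float),
        t=params.t_growth,
        phase="growth",
    )
    if sample_times is not None:
        return pop, count_matrix
    return pop


# ---------------------------------------------------------------------------
# competition phase

class _Recorder:
    """Accumulates per-sample snapshots of the cell arrays."""

    def __init__(self, params: ModelParams, n_colors: int | None):
        self.params = params
        self.n_colors = n_colors
        self.times: list[float] = []
        self.counts: list[np.ndarray] = []
        self.cma: list[np.ndarray] = []
        self.mean: list[float] = []
        self.std: list[float] = []
        self.colors: list[np.ndarray] = []

    def record(self, t: float, clone: np.ndarray, aff: np.ndarray,
               color: np.ndarray | None) -> None:
        m = self.params.n_clones
        counts = np.bincount(clone, minlength=m + 1)[1:]
        sums = np.bincount(clone, weights=aff, minlength=m + 1)[1:]
        with np.errstate(invalid="ignore"):
            cma = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        self.times.append(t)
        self.counts.append(counts)
        self.cma.append(cma)
        if aff.size:
            self.mean.append(float(aff.mean()))
            self.std.append(float(aff.std()))
        else:
            self.mean.append(math.nan)
            self.std.append(math.nan)
        if self.n_colors is not None:
            cc = np.bincount(
                color if color is not None else np.zeros(clone.size, np.int64),
                minlength=self.n_colors + 1,
            )[: self.n_colors + 1]
            self.colors.append(cc)

    def trajectory(self, phase: str, params: ModelParams, seed=None) -> Trajectory:
        n = len(self.times)
        return Trajectory(
            times=np.asarray(self.times),
            phases=np.asarray([phase] * n, dtype=object),
            counts=np.asarray(self.counts),
            clone_mean_affinity=np.asarray(self.cma),
            mean_affinity=np.asarray(self.mean),
            std_affinity=np.asarray(self.std),
            params=params,
            seed=seed,
            color_counts=np.asarray(self.colors) if self.colors else None,
        )


def _tau_leap(
    pop: Population,
    params: ModelParams,
    rng: np.random.Generator,
    duration: float,
    sample_times: np.ndarray,
    dt: float,
    rec: _Recorder,
) -> Population:
    """Fixed-step Bernoulli tau-leap.

    Per step each cell independently dies with probability d_i·dt, else
    divides with probability b_i·dt; rates are recomputed every step.  A
    division appends the mutated daughter while the surviving entry keeps
    the parent affinity (the two daughters are exchangeable, so which array
    slot mutates is unobservable).
    """
    clone = pop.clone_id
    aff = pop.affinity
    color = pop.color
    sigma = params.mutation_sigma
    eps = params.affinity_floor
    hard_cap = params.hard_cap_factor * params.capacity
    t0 = pop.t
    n_steps = int(round(duration / dt))
    si = 0
    while si < sample_times.size and sample_times[si] <= t0 + 1e-9:
        rec.record(t0, clone, aff, color)
        si += 1
    for k in range(1, n_steps + 1):
        t = t0 + k * dt
        n = clone.size
        if n:
            b = _birth_rate_arr(aff, params)
            d = _death_rate_arr(aff, n, params)
            u = rng.random((2, n))
            die = u[0] < d * dt
            divide = ~die & (u[1] < b * dt)
            parents = aff[divide]
            if parents.size:
                offsets = rng.normal(0.0, sigma, parents.size) if sigma > 0 else 0.0
                daughters = np.maximum(parents + offsets, eps)
                keep = ~die
                clone = np.concatenate([clone[keep], clone[divide]])
                aff = np.concatenate([aff[keep], daughters])
                if color is not None:
                    color = np.concatenate([color[keep], color[divide]])
            elif die.any():
                keep = ~die
                clone, aff = clone[keep], aff[keep]
                if color is not None:
                    color = color[keep]
            if clone.size > hard_cap:
                raise SimulationError(
                    f"population {clone.size} exceeded hard cap {hard_cap:.0f} "
                    "(rate-model misconfiguration?)"
                )
        while si < sample_times.size and sample_times[si] <= t + 1e-9:
            rec.record(sample_times[si], clone, aff, color)
            si += 1
    while si < sample_times.size:  # pragma: no cover - grid always covered
        rec.record(sample_times[si], clone, aff, color)
        si += 1
    return Population(clone, aff, t0 + duration, "competition", color, pop.n_colors)


def _ssa(
    pop: Population,
    params: ModelParams,
    rng: np.random.Generator,
    duration: float,
    sample_times: np.ndarray,
    rec: _Recorder,
    stop_when_monoclonal: bool = False,
) -> Population:
    """Exact next-event SSA with per-event rate recomputation.

    A uniform-rate fast path (O(1) per event) applies while mutation is off
    and all cells share one affinity, which covers neutral-drift studies;
    otherwise per-cell rate vectors are rebuilt after every event.  Cells
    live in preallocated arrays with swap-remove deletion.
    """
    cap = max(2 * pop.size + 16, 64)
    clone = np.empty(cap, dtype=np.int64)
    aff = np.empty(cap, dtype=float)
    n = pop.size
    clone[:n] = pop.clone_id
    aff[:n] = pop.affinity
    has_color = pop.color is not None
    color = np.empty(cap, dtype=np.int64)
    if has_color:
        color[:n] = pop.color
    sigma = params.mutation_sigma
    lam0 = params.birth_rate
    hard_cap = params.hard_cap_factor * params.capacity
    t = pop.t
    t_end = pop.t + duration
    si = 0
    counts = np.bincount(pop.clone_id, minlength=params.n_clones + 1)
    live_clones = int((counts[1:] > 0).sum())

    def flush(upto: float) -> None:
        nonlocal si
        while si < sample_times.size and sample_times[si] <= upto + 1e-12:
            rec.record(
                sample_times[si], clone[:n].copy(), aff[:n].copy(),
                color[:n].copy() if has_color else None,
            )
            si += 1

    flush(t)
    uniform = sigma == 0 and (n == 0 or np.ptp(aff[:n]) == 0.0)
    while True:
        if n == 0:
            break
        if uniform:
            b_tot = n * lam0
            d_scalar = _death_rate_arr(aff[:1], n, params)
            d_tot = n * float(np.asarray(d_scalar).ravel()[0])
            b_arr = d_arr = None
        else:
            a = aff[:n]
            b_arr = np.broadcast_to(
                np.asarray(_birth_rate_arr(a, params), dtype=float), (n,)
            )
            d_arr = np.broadcast_to(
                np.asarray(_death_rate_arr(a, n, params), dtype=float), (n,)
            )
            b_tot = float(b_arr.sum())
            d_tot = float(d_arr.sum())
        rate = b_tot + d_tot
        if rate <= 0:
            break
        t_next = t + rng.exponential(1.0 / rate)
        flush(min(t_next, t_end))
        if t_next >= t_end:
            t = t_end
            break
        t = t_next
        is_birth = rng.random() < b_tot / rate
        if uniform:
            i = int(rng.integers(n))
        else:
            arr = b_arr if is_birth else d_arr
            tot = b_tot if is_birth else d_tot
            i = min(
                int(np.searchsorted(np.cumsum(arr), rng.random() * tot)), n - 1
            )
        if is_birth:
            if n == cap:  # grow storage
                cap *= 2
                clone = np.resize(clone, cap)
                aff = np.resize(aff, cap)
                color = np.resize(color, cap)
            _, daughter = mutate_on_division(aff[i], params, rng)
            if sigma > 0 and rng.random() < 0.5:
                # which daughter mutates is chosen at random
                aff[n] = aff[i]
                aff[i] = daughter
            else:
                aff[n] = daughter
            clone[n] = clone[i]
            if has_color:
                color[n] = color[i]
            counts[clone[i]] += 1
            n += 1
            if n > hard_cap:
                raise SimulationError(
                    f"population {n} exceeded hard cap {hard_cap:.0f}"
                )
        else:
            cid = clone[i]
            counts[cid] -= 1
            if counts[cid] == 0:
                live_clones -= 1
            n -= 1
            clone[i] = clone[n]
            aff[i] = aff[n]
            if has_color:
                color[i] = color[n]
        if stop_when_monoclonal and live_clones <= 1:
            break
    flush(t_end)
    return Population(
        clone[:n].copy(),
        aff[:n].copy(),
        t_end,
        "competition",
        color[:n].copy() if has_color else None,
        pop.n_colors,
    )


def run_competition_phase(
    population: Population,
    params: ModelParams,
    rng: np.random.Generator,
    sample_interval: float = 1.0,
    method: str = "tau",
    dt: float = 0.002,
    duration: float | None = None,
    stop_when_monoclonal: bool = False,
    seed=None,
) -> Trajectory:
    """Advance a population through the logistic competition phase.

    Runs for ``duration`` days (default ``params.t_comp``) with the selected
    integrator (``"tau"``: fixed-step tau-leap with step ``dt``; ``"ssa"``:
    exact next-event simulation), recording a :class:`Trajectory` every
    ``sample_interval`` days, including the initial state.  With
    ``stop_when_monoclonal`` (SSA only) the run ends early once at most one
    clone survives — remaining samples repeat the frozen composition.
    """
    if sample_interval <= 0:
        raise ValueError("sample_interval must be > 0")
    if duration is None:
        duration = params.t_comp
    n_samp = int(round(duration / sample_interval))
    grid = population.t + np.arange(n_samp + 1) * sample_interval
    if grid[-1] < population.t + duration - 1e-9:
        grid = np.append(grid, population.t + duration)
    rec = _Recorder(params, population.n_colors)
    if method == "tau":
        if stop_when_monoclonal:
            raise ValueError("stop_when_monoclonal requires method='ssa'")
        final = _tau_leap(population, params, rng, duration, grid, dt, rec)
    elif method == "ssa":
        final = _ssa(
            population, params, rng, duration, grid, rec,
            stop_when_monoclonal=stop_when_monoclonal,
        )
    else:
        raise ValueError("method must be 'tau' or 'ssa'")
    traj = rec.trajectory("competition", params, seed=seed)
    traj.final_population = final
    return traj


def _growth_trajectory(
    params: ModelParams, counts: np.ndarray, sample_times: np.ndarray
) -> Trajectory:
    """Build the growth-phase Trajectory from per-clone count samples.

    Without growth-phase mutation every cell of clone i sits exactly at its
    founder affinity, so per-clone and population affinity summaries follow
    from the counts and the w0 vector.
    """
    w0 = params.w0_vector()
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(totals > 0, counts @ w0 / np.maximum(totals, 1), np.nan)
        second = np.where(
            totals > 0, counts @ (w0**2) / np.maximum(totals, 1), np.nan
        )
    var = np.maximum(second - mean**2, 0.0)
    cma = np.where(counts > 0, w0[None, :], np.nan)
    return Trajectory(
        times=sample_times.astype(float),
        phases=np.asarray(["growth"] * sample_times.size, dtype=object),
        counts=counts,
        clone_mean_affinity=cma,
        mean_affinity=mean,
        std_affinity=np.sqrt(var),
        params=params,
    )


def _concat_trajectories(a: Trajectory, b: Trajectory) -> Trajectory:
    color = None
    if a.color_counts is not None or b.color_counts is not None:
        k = 0
        for part in (a, b):
            if part.color_counts is not None:
                k = max(k, part.color_counts.shape[1])
        parts = []
        for part in (a, b):
            if part.color_counts is None:
                parts.append(np.zeros((part.n_samples, k), dtype=np.int64))
            else:
                cc = part.color_counts
                pad = np.zeros((cc.shape[0], k - cc.shape[1]), dtype=np.int64)
                parts.append(np.hstack([cc, pad]))
        color = np.vstack(parts)
    return Trajectory(
        times=np.concatenate([a.times, b.times]),
        phases=np.concatenate([a.phases, b.phases]),
        counts=np.vstack([a.counts, b.counts]),
        clone_mean_affinity=np.vstack([a.clone_mean_affinity, b.clone_mean_affinity]),
        mean_affinity=np.concatenate([a.mean_affinity, b.mean_affinity]),
        std_affinity=np.concatenate([a.std_affinity, b.std_affinity]),
        params=a.params,
        seed=a.seed if a.seed is not None else b.seed,
        color_counts=color,
        final_population=b.final_population,
    )


def run_gc(
    params: ModelParams,
    rng: np.random.Generator,
    sample_interval: float = 1.0,
    method: str = "tau",
    dt: float = 0.002,
    labeling=None,
    seed=None,
) -> Trajectory:
    """Run one full germinal center reaction: growth then competition.

    The returned :class:`Trajectory` covers both phases (phase marker per
    sample).  ``labeling``, if given, is a :class:`gcdyn.labeling.LabelingPlan`;
    the heritable color labels are applied at its (absolute) day, which must
    fall within the competition phase, and per-color counts are recorded
    from then on.
    """
    n_g = int(round(params.t_growth / sample_interval))
    growth_grid = np.arange(n_g + 1) * sample_interval
    if growth_grid.size == 0 or growth_grid[-1] < params.t_growth - 1e-9:
        growth_grid = np.append(growth_grid, params.t_growth)
    pop, gcounts = run_growth_phase(params, rng, sample_times=growth_grid)
    traj = _growth_trajectory(params, gcounts, growth_grid)
    traj.seed = seed
    t_end = params.t_growth + params.t_comp
    # segments share their boundary instant; the later segment's sample wins,
    # so sample times stay strictly increasing and a state change applied at
    # the boundary (start of competition, color labeling) is what is recorded
    traj = _slice_trajectory(traj, slice(0, -1))
    if labeling is None:
        comp = run_competition_phase(
            pop, params, rng, sample_interval, method, dt, seed=seed
        )
        return _concat_trajectories(traj, comp)

    from .labeling import apply_labeling  # local import to avoid a cycle

    day = labeling.day if labeling.day is not None else params.t_growth
    if not params.t_growth <= day <= t_end:
        raise ValueError("labeling day must fall within the competition phase")
    if day > params.t_growth:
        comp1 = run_competition_phase(
            pop, params, rng, sample_interval, method, dt,
            duration=day - params.t_growth, seed=seed,
        )
        pop = comp1.final_population
        traj = _concat_trajectories(traj, _slice_trajectory(comp1, slice(0, -1)))
    apply_labeling(pop, labeling.n_colors, labeling.p_recombine, rng)
    comp2 = run_competition_phase(
        pop, params, rng, sample_interval, method, dt,
        duration=t_end - day, seed=seed,
    )
    return _concat_trajectories(traj, comp2)


def _slice_trajectory(traj: Trajectory, sl: slice) -> Trajectory:
    return Trajectory(
        times=traj.times[sl],
        phases=traj.phases[sl],
        counts=traj.counts[sl],
        clone_mean_affinity=traj.clone_mean_affinity[sl],
        mean_affinity=traj.mean_affinity[sl],
        std_affinity=traj.std_affinity[sl],
        params=traj.params,
        seed=traj.seed,
        color_counts=traj.color_counts[sl] if traj.color_counts is not None else None,
        final_population=traj.final_population,
    )


def replicate_rng(base_seed: int, index: int) -> np.random.Generator:
    """Independent generator for replicate ``index`` of an ensemble.

    Derived with a counter-based spawn key, so any replicate can be
    reproduced solo without generating the others.
    """
    return np.random.default_rng(np.random.SeedSequence(base_seed, spawn_key=(index,)))


def run_ensemble(
    params: ModelParams,
    n_replicates: int,
    base_seed: int,
    sample_interval: float = 1.0,
    method: str = "tau",
    dt: float = 0.002,
    labeling=None,
) -> list[Trajectory]:
    """Run independent replicates with deterministically derived seeds."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    out = []
    for i in range(n_replicates):
        rng = replicate_rng(base_seed, i)
        out.append(
            run_gc(
                params, rng, sample_interval, method, dt,
                labeling=labeling, seed=(base_seed, i),
            )
        )
    return out
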
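"""Shared fixtures.

The heavy ensembles (200 replicates at the default germinal-center size)
are session-scoped and shared between the property tests and the
acceptance tests, so each study condition is simulated exactly once per
run.  All seeds are fixed so the suite is deterministic.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gcdyn

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

TABLE1 = dict(
    n_clones=50, birth_rate=1.5, death_rate=1.0, capacity=2000,
    diffusion=0.001, initial_affinity=1.5, t_growth=6.0, t_comp=16.0,
)


@pytest.fixture
def table1_params() -> gcdyn.ModelParams:
    return gcdyn.ModelParams()


@pytest.fixture(scope="session")
def growth_lineages_10k() -> np.ndarray:
    """Final sizes of 10^4 independent growth-phase lineages (λ0=1.5, μ0=1, 6 d)."""
    params = gcdyn.ModelParams(n_clones=10_000)
    pop = gcdyn.run_growth_phase(params, np.random.default_rng(7001))
    return pop.clone_counts(10_000)


@pytest.fixture(scope="session")
def growth_survivors_200() -> np.ndarray:
    """Surviving-clone count of 200 replicate growth phases at default size."""
    params = gcdyn.ModelParams()
    out = []
    for i in range(200):
        pop = gcdyn.run_growth_phase(params, gcdyn.replicate_rng(7002, i))
        out.append((pop.clone_counts(50) > 0).sum())
    return np.asarray(out)


def _ensemble(diffusion: float, **kw) -> list[gcdyn.Trajectory]:
    params = gcdyn.ModelParams(diffusion=diffusion, **kw)
    return gcdyn.run_ensemble(params, 200, 42)


@pytest.fixture(scope="session")
def ens_d0():
    return _ensemble(0.0)


@pytest.fixture(scope="session")
def ens_d001():
    return _ensemble(0.001)


@pytest.fixture(scope="session")
def ens_d005():
    return _ensemble(0.005)


@pytest.fixture(scope="session")
def ens_d02():
    return _ensemble(0.02)


@pytest.fixture(scope="session")
def ens_death_d02():
    # A = μ0 e^{α w0} so the affinity term of the death rate starts at μ0,
    # making the death-limited run demographically comparable at t=0
    return _ensemble(0.02, selection="death_limited",
                     death_prefactor=math.exp(1.5))


@pytest.fixture(scope="session")
def fixation_freqs() -> np.ndarray:
    """Neutral-drift fixation frequencies of 3 clones started at (0.5, 0.3, 0.2).

    2000 small-population replicates run to fixation with the exact SSA;
    under neutral drift each clone should fix with probability equal to its
    initial fraction.
    """
    params = gcdyn.ModelParams(
        n_clones=3, capacity=20, diffusion=0.0, selection="neutral",
        initial_affinity=1.0, t_comp=400.0,
    )
    wins = np.zeros(3)
    for i in range(2000):
        pop = gcdyn.make_fixture([0.5, 0.3, 0.2], 1.0, 20)
        traj = gcdyn.run_competition_phase(
            pop, params, gcdyn.replicate_rng(7003, i), sample_interval=400.0,
            method="ssa", stop_when_monoclonal=True,
        )
        counts = traj.final_population.clone_counts(3)
        assert (counts > 0).sum() == 1, "run did not reach fixation"
        wins[np.argmax(counts)] += 1
    return wins / wins.sum()


def final_snapshots(trajectories) -> list[gcdyn.ClonalSnapshot]:
    return [gcdyn.ClonalSnapshot.from_trajectory(t) for t in trajectories]


def dominant_fractions(trajectories, index: int = -1) -> np.ndarray:
    """Per-replicate dominant-clone fraction; fully extinct runs are skipped."""
    return np.asarray(
        [
            gcdyn.dominant_fraction(gcdyn.ClonalSnapshot(t.counts[index]))
            for t in trajectories
            if t.counts[index].sum() > 0
        ]
    )
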
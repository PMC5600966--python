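"""Closed-form results for the linear birth-death growth phase.

A germinal center reaction starts with ``M`` founder B cells that proliferate
freely (no competition, no mutation) for a growth period ``t``.  Each lineage
is an independent linear birth-death process with per-cell birth rate ``λ``
and death rate ``μ``, so the lineage-size distribution, its mean and the
extinction probability are all available in closed form.  These results serve
both as user-facing API and as the analytic oracle against which the
agent-based simulator is tested.

The module also provides :func:`master_equation_pmf`, a direct numerical
integration of the truncated master equation, used as an independent
numerical cross-check of the closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

__all__ = [
    "BDParams",
    "TruncationError",
    "expected_clone_size",
    "extinction_probability",
    "clone_size_pmf",
    "expected_surviving_clones",
    "neutral_fixation_time",
    "master_equation_pmf",
]

#: below this |λ - μ| the process is treated as exactly critical
_CRITICAL_TOL = 1e-10


class TruncationError(RuntimeError):
    """Raised when the truncated master equation leaks too much probability."""


@dataclass(frozen=True)
class BDParams:
    """Parameters of a linear birth-death growth phase.

    Parameters
    ----------
    birth_rate : float
        Per-cell birth rate λ (1/day).
    death_rate : float
        Per-cell death rate μ (1/day).
    n0 : int
        Founder cells per clone (default 1).
    n_clones : int
        Number of founding clones M (default 1).
    t : float
        Elapsed time in days.
    """

    birth_rate: float
    death_rate: float
    n0: int = 1
    n_clones: int = 1
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.birth_rate < 0:
            raise ValueError("birth_rate must be >= 0")
        if self.death_rate < 0:
            raise ValueError("death_rate must be >= 0")
        if self.n0 < 1:
            raise ValueError("n0 must be >= 1")
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if self.t < 0:
            raise ValueError("t must be >= 0")


def _geometric_params(lam: float, mu: float, t: float) -> tuple[float, float]:
    """Return ``(p0, eta)`` of the linear-BD solution for a single founder.

    The size distribution at time *t* is geometric on {1, 2, ...} with an
    atom ``p0`` at zero: ``P(n) = (1 - p0)(1 - eta) eta**(n-1)``.  Both
    parameters share the factor ``x = expm1(rt) / (λ expm1(rt) + r)`` with
    ``r = λ - μ``: ``p0 = μ x`` and ``eta = λ x``.  The formula is written
    with ``expm1`` so that the critical limit ``x -> t/(1 + λ t)`` is reached
    continuously as ``r -> 0``.
    """
    r = lam - mu
    rt = r * t
    if abs(r) < _CRITICAL_TOL:
        x = t / (1.0 + lam * t)
    elif rt > 0:
        # divide through by e^{rt}: stable for arbitrarily large rt
        em = -math.expm1(-rt)
        x = em / (lam * em + r * math.exp(-rt))
    else:
        em = math.expm1(rt)
        x = em / (lam * em + r)
    return mu * x, lam * x


def expected_clone_size(p: BDParams) -> float:
    """Mean lineage size ``n0 * exp((λ - μ) t)`` of one clone."""
    return p.n0 * math.exp((p.birth_rate - p.death_rate) * p.t)


def extinction_probability(p: BDParams) -> float:
    """Probability that a clone has no living cell at time ``t``.

    For a single founder this is ``μ (e^{rt} - 1) / (λ e^{rt} - μ)`` with
    ``r = λ - μ`` (continuous limit ``μt / (1 + μt)`` at criticality).  A
    clone founded by ``n0`` cells goes extinct iff its ``n0`` independent
    lineages all do, so the single-founder value is raised to ``n0``.
    """
    p0, _ = _geometric_params(p.birth_rate, p.death_rate, p.t)
    return p0**p.n0


def clone_size_pmf(p: BDParams, n) -> np.ndarray | float:
    """Probability that a single-founder clone has exactly ``n >= 1`` cells.

    The surviving-size distribution is geometric,
    ``P(n) = (1 - p0)(1 - eta) eta**(n-1)`` with ``eta = λ p0 / μ``; together
    with the extinction atom ``p0`` at ``n = 0`` it sums to one exactly and
    has mean ``e^{(λ-μ)t}``.
    """
    if p.n0 != 1:
        raise ValueError("clone_size_pmf is defined for a single founder (n0=1)")
    n_arr = np.asarray(n)
    if not np.issubdtype(n_arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(n_arr, 1), 0)):
            raise ValueError("n must be integer")
        n_arr = n_arr.astype(np.int64)
    if np.any(n_arr < 1):
        raise ValueError("n must be >= 1 (use extinction_probability for n=0)")
    p0, eta = _geometric_params(p.birth_rate, p.death_rate, p.t)
    out = (1.0 - p0) * (1.0 - eta) * eta ** (n_arr - 1)
    return out if out.ndim else float(out)


def expected_surviving_clones(p: BDParams) -> float:
    """Expected number of the ``M`` founding clones still alive at ``t``."""
    return p.n_clones * (1.0 - extinction_probability(p))


def neutral_fixation_time(n_clones: int) -> float:
    """Mean fixation time ``2 (M-1) log(M / (M-1))`` under neutral drift.

    For a fixed-size population seeded by ``M`` clones at equal fractions
    ``1/M``, neutral (Wright-Fisher-like) drift fixes a single clone after
    this mean time.  The natural time unit of the underlying neutral model
    (generations vs. rescaled generations) is deliberately left to the
    caller; the value is returned exactly as defined, dimensionless.
    Increasing in ``M``, approaching 2 from below.
    """
    if not isinstance(n_clones, (int, np.integer)):
        raise TypeError("n_clones must be an integer")
    if n_clones < 2:
        raise ValueError("n_clones must be >= 2")
    m = float(n_clones)
    return 2.0 * (m - 1.0) * math.log(m / (m - 1.0))


def master_equation_pmf(
    p: BDParams,
    n_max: int,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    tail_tol: float = 1e-8,
) -> np.ndarray:
    """Integrate the truncated linear-BD master equation numerically.

    Starting from all mass on ``n0``, integrates

    ``dP_n/dt = λ(n-1) P_{n-1} + μ(n+1) P_{n+1} - n(λ+μ) P_n``

    on the truncated state space {0..n_max} with an adaptive stiff solver,
    returning the probability vector at time ``p.t``.  Probability flowing
    above ``n_max`` is dropped, so truncation error shows up as lost mass;
    a :class:`TruncationError` is raised if either the missing mass or the
    occupancy of the top states exceeds ``tail_tol``.

    This routine is deliberately independent of the closed forms above and
    serves as their numerical cross-check.
    """
    if n_max < p.n0 + 1:
        raise ValueError("n_max must exceed n0")
    lam, mu = p.birth_rate, p.death_rate
    n = np.arange(n_max + 1, dtype=float)
    # tridiagonal generator acting on column vector P
    q = sparse.diags(
        [lam * n[:-1], -(lam + mu) * n, mu * n[1:]],
        offsets=[-1, 0, 1],
        format="csc",
    )
    p_init = np.zeros(n_max + 1)
    p_init[p.n0] = 1.0
    if p.t == 0:
        return p_init
    sol = solve_ivp(
        lambda _, y: q @ y,
        (0.0, p.t),
        p_init,
        method="BDF",
        jac=lambda _, y: q,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:  # pragma: no cover - solver failure is exceptional
        raise RuntimeError(f"master-equation integration failed: {sol.message}")
    out = sol.y[:, -1]
    lost = abs(1.0 - out.sum())
    tail = out[-3:].sum()
    if lost > tail_tol or tail > tail_tol:
        raise TruncationError(
            f"truncation at n_max={n_max} unsound: lost mass {lost:.2e}, "
            f"top-state mass {tail:.2e} (tolerance {tail_tol:.0e})"
        )
    return out
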
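"""Simulator correctness: growth phase vs. closed forms, rate model,
mutation operator, integrator agreement, determinism and guard rails."""

import math

import numpy as np
import pytest
from scipy import stats as sps

import gcdyn
from gcdyn.analytic import BDParams
from gcdyn.simulator import _birth_rate_arr, _death_rate_arr

from conftest import dominant_fractions, final_snapshots


class TestGrowthPhase:
    def test_mean_size_and_extinction_match_closed_forms(self, growth_lineages_10k):
        sizes = growth_lineages_10k
        p = BDParams(1.5, 1.0, t=6.0)
        sem = sizes.std(ddof=1) / math.sqrt(sizes.size)
        assert abs(sizes.mean() - gcdyn.expected_clone_size(p)) < 3 * sem
        p0 = gcdyn.extinction_probability(p)
        # 99% binomial CI on the extinct fraction
        half = 2.576 * math.sqrt(p0 * (1 - p0) / sizes.size)
        assert abs((sizes == 0).mean() - p0) < half

    def test_surviving_size_histogram_matches_pmf(self, growth_lineages_10k):
        """χ² goodness of fit of surviving lineage sizes to the geometric law."""
        sizes = growth_lineages_10k[growth_lineages_10k > 0]
        p = BDParams(1.5, 1.0, t=6.0)
        p0 = gcdyn.extinction_probability(p)
        edges = list(range(1, 61, 4))  # width-4 bins, tail pooled
        probs = []
        n = np.arange(1, 4000)
        pmf = gcdyn.clone_size_pmf(p, n) / (1 - p0)
        for lo, hi in zip(edges[:-1], edges[1:]):
            probs.append(pmf[lo - 1 : hi - 1].sum())
        probs.append(1.0 - sum(probs))
        observed = np.histogram(sizes, bins=edges + [10**9])[0]
        res = sps.chisquare(observed, sizes.size * np.asarray(probs))
        assert res.pvalue > 0.01

    def test_zero_rates_preserve_founders(self):
        params = gcdyn.ModelParams(n_clones=7, birth_rate=0.0, death_rate=0.0)
        pop = gcdyn.run_growth_phase(params, np.random.default_rng(0))
        assert pop.size == 7
        assert np.array_equal(np.sort(pop.clone_id), np.arange(1, 8))
        assert np.all(pop.affinity == 1.5)

    def test_all_extinct_is_valid_empty_population(self):
        params = gcdyn.ModelParams(n_clones=3, birth_rate=0.0, death_rate=30.0)
        pop = gcdyn.run_growth_phase(params, np.random.default_rng(1))
        assert pop.size == 0


class TestRates:
    def test_birth_rate_uniform_when_affinities_equal(self):
        pop = gcdyn.make_fixture([0.5, 0.5], 2.0, 40)
        params = gcdyn.ModelParams(n_clones=2)
        assert np.all(gcdyn.birth_rates(pop, params) == 1.5)

    def test_birth_rate_hand_example(self):
        # two cells, affinities (1, 3), λ0=1.5 → rates (0.75, 2.25)
        pop = gcdyn.Population(np.array([1, 2]), np.array([1.0, 3.0]))
        params = gcdyn.ModelParams(n_clones=2)
        assert gcdyn.birth_rates(pop, params) == pytest.approx([0.75, 2.25])

    def test_birth_limited_mean_is_basal_rate_exactly(self):
        rng = np.random.default_rng(3)
        pop = gcdyn.Population(
            np.ones(500, dtype=int), rng.lognormal(0.3, 0.6, 500)
        )
        params = gcdyn.ModelParams(n_clones=1)
        assert gcdyn.birth_rates(pop, params).mean() == pytest.approx(
            1.5, rel=1e-14
        )

    def test_logistic_death_rate_endpoints(self):
        params = gcdyn.ModelParams(selection="neutral")
        aff = np.full(1, 1.5)
        # at total = N the death rate equals the birth rate λ0
        assert _death_rate_arr(aff, 2000, params) == pytest.approx(1.5)
        # as total → 0 it relaxes to the basal rate μ0
        assert _death_rate_arr(aff, 0, params) == pytest.approx(1.0)

    def test_death_limited_affinity_term_hand_example(self):
        # A=e, α=1, w=1, vanishing occupancy → μ = e·e⁻¹ = 1
        params = gcdyn.ModelParams(
            selection="death_limited", death_prefactor=math.e, alpha=1.0
        )
        mu = _death_rate_arr(np.array([1.0]), 0, params)
        assert mu == pytest.approx([1.0])

    def test_death_rates_never_negative(self):
        params = gcdyn.ModelParams(
            selection="death_limited", death_prefactor=0.01, alpha=1.0,
            capacity=100,
        )
        pop = gcdyn.Population(np.ones(300, dtype=int), np.full(300, 5.0))
        assert np.all(gcdyn.death_rates(pop, params) >= 0.0)


class TestMutation:
    def test_no_diffusion_copies_parent(self):
        params = gcdyn.ModelParams(diffusion=0.0)
        d1, d2 = gcdyn.mutate_on_division(1.5, params, np.random.default_rng(0))
        assert d1 == d2 == 1.5

    def test_offset_distribution_and_symmetry(self):
        params = gcdyn.ModelParams(diffusion=0.005)
        sigma = params.mutation_sigma
        assert sigma == pytest.approx(math.sqrt(0.01))
        rng = np.random.default_rng(11)
        parents = np.full(100_000, 1.5)
        _, daughters = gcdyn.mutate_on_division(parents, params, rng)
        offsets = daughters - 1.5
        assert abs(offsets.mean()) < 4 * sigma / math.sqrt(offsets.size)
        assert offsets.std() == pytest.approx(sigma, rel=0.01)
        # affinity rises or falls with equal probability
        up = (offsets > 0).mean()
        assert abs(up - 0.5) < 2.576 * math.sqrt(0.25 / offsets.size)

    def test_literal_convention_sigma(self):
        params = gcdyn.ModelParams(
            diffusion=0.005, mutation_sd_convention="literal_sd_2D"
        )
        assert params.mutation_sigma == pytest.approx(0.01)

    def test_affinity_floor_applies(self):
        params = gcdyn.ModelParams(diffusion=2.0)
        _, d2 = gcdyn.mutate_on_division(
            np.full(1000, 1e-5), params, np.random.default_rng(5)
        )
        assert np.all(d2 >= params.affinity_floor)


class TestCompetitionPhase:
    def test_count_conservation_at_every_sample(self, ens_d001):
        for traj in ens_d001[:20]:
            assert np.all(traj.counts.sum(axis=1) == traj.total)
            assert np.all(np.diff(traj.times) > 0)

    def test_logistic_stationarity_near_capacity(self, ens_d001):
        """Late-time mean total within 5% of the carrying capacity."""
        late = np.mean([t.total[-1] for t in ens_d001])
        assert abs(late - 2000) / 2000 < 0.05

    def test_tau_leap_matches_ssa_distribution(self):
        """Dominant-fraction law agrees between tau-leap and exact SSA."""
        params = gcdyn.ModelParams(
            n_clones=4, capacity=100, diffusion=0.005, t_comp=5.0
        )

        def sample(method, seed):
            out = []
            for i in range(250):
                pop = gcdyn.make_fixture([0.4, 0.3, 0.2, 0.1], 1.5, 100)
                traj = gcdyn.run_competition_phase(
                    pop, params, gcdyn.replicate_rng(seed, i),
                    sample_interval=5.0, method=method,
                )
                out.append(gcdyn.dominant_fraction(
                    gcdyn.ClonalSnapshot.from_trajectory(traj)))
            return np.asarray(out)

        res = sps.ks_2samp(sample("tau", 21), sample("ssa", 22))
        assert res.pvalue > 0.01

    def test_selection_modes_coincide_without_mutation(self):
        """With D=0 and equal founder affinity, every selection mode reduces
        to the same neutral law of clone fractions."""
        def sample(selection, seed):
            params = gcdyn.ModelParams(
                n_clones=20, capacity=300, diffusion=0.0, t_comp=10.0,
                selection=selection, death_prefactor=math.exp(1.5),
            )
            return dominant_fractions(gcdyn.run_ensemble(params, 200, seed))

        neutral = sample("neutral", 31)
        assert sps.ks_2samp(neutral, sample("birth_limited", 32)).pvalue > 0.01
        assert sps.ks_2samp(neutral, sample("death_limited", 33)).pvalue > 0.01

    def test_neutral_fixation_probability_equals_initial_fraction(
        self, fixation_freqs
    ):
        for freq, expected in zip(fixation_freqs, (0.5, 0.3, 0.2)):
            half = 3.29 * math.sqrt(expected * (1 - expected) / 2000)  # 99.9% CI
            assert abs(freq - expected) < half

    def test_hard_cap_signals_misconfiguration(self):
        pop = gcdyn.make_fixture([1.0], 1.5, 100)
        params = gcdyn.ModelParams(n_clones=1, capacity=5)
        with pytest.raises(gcdyn.SimulationError):
            gcdyn.run_competition_phase(
                pop, params, np.random.default_rng(0), method="tau"
            )


class TestRunGC:
    def test_identical_seed_gives_identical_trajectory(self):
        params = gcdyn.ModelParams(n_clones=10, capacity=200, t_comp=4.0)
        a = gcdyn.run_gc(params, np.random.default_rng(99))
        b = gcdyn.run_gc(params, np.random.default_rng(99))
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.times, b.times)

    def test_phases_cover_both_stages(self):
        params = gcdyn.ModelParams(n_clones=10, capacity=200, t_comp=4.0)
        traj = gcdyn.run_gc(params, np.random.default_rng(1))
        assert set(traj.phases) == {"growth", "competition"}
        assert traj.times[0] == 0.0
        assert traj.times[-1] == pytest.approx(10.0)
        # competition-relative day axis
        assert traj.comp_day[0] == pytest.approx(-6.0)
        assert traj.comp_day[-1] == pytest.approx(4.0)

    def test_extinct_growth_yields_all_zero_competition(self):
        params = gcdyn.ModelParams(
            n_clones=2, birth_rate=0.0, death_rate=40.0, t_comp=3.0
        )
        traj = gcdyn.run_gc(params, np.random.default_rng(2))
        comp = traj.phases == "competition"
        assert np.all(traj.total[comp] == 0)

    def test_dominant_fraction_spread_is_wide(self, ens_d001):
        """Single runs scatter widely around the ensemble mean."""
        dom = dominant_fractions(ens_d001)
        q75, q25 = np.percentile(dom, [75, 25])
        assert q75 - q25 > 0.1


class TestEnsemble:
    def test_replicate_matches_solo_run_with_derived_seed(self):
        params = gcdyn.ModelParams(n_clones=8, capacity=150, t_comp=3.0)
        ens = gcdyn.run_ensemble(params, 3, base_seed=77)
        solo = gcdyn.run_gc(params, gcdyn.replicate_rng(77, 2))
        assert np.array_equal(ens[2].counts, solo.counts)

    def test_single_replicate_reduces_to_run_gc(self):
        params = gcdyn.ModelParams(n_clones=8, capacity=150, t_comp=3.0)
        ens = gcdyn.run_ensemble(params, 1, base_seed=5)
        solo = gcdyn.run_gc(params, gcdyn.replicate_rng(5, 0))
        assert np.array_equal(ens[0].counts, solo.counts)
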
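# Methods

## Model

One germinal center (GC) is a well-mixed population of B cells, each
carrying a founder identity (clone id 1..M) and a scalar BCR affinity
w > 0. The reaction has two phases.

**Growth phase (default 6 days).** The M founders proliferate as
independent linear birth–death lineages at basal rates λ₀ (birth) and μ₀
(death), with no mutation and no interaction. The phase is exactly
solvable: mean lineage size e^{(λ₀−μ₀)t}, extinction probability
p₀ = μ₀·expm1(rt)/(λ₀·expm1(rt)+r) with r = λ₀−μ₀, and a geometric
surviving-size law P(n) = (1−p₀)(1−η)η^{n−1} with η = λ₀p₀/μ₀. The
geometric exponent is n−1, not n: only that convention normalizes
(Σ_{n≥0} P(n) = 1) and reproduces the closed-form mean, so it is what the
package implements. Multi-founder clones use independence of lineages
(extinction probability p₀^{n₀}).

**Competition phase (default 16 further days).** Death becomes
density-dependent (stochastic logistic growth), μ(n) = μ₀ + (λ₀−μ₀)·n/N,
which equals λ₀ at the capacity N, so the total settles near N. Every
division copies the parent affinity to one daughter and displaces the
other by a centred Gaussian (below). Selection modes:

- *birth-limited*: λᵢ = λ₀wᵢ/⟨w⟩ (⟨w⟩ = current population mean), keeping
  the population-mean birth rate at λ₀ exactly; death as above.
- *death-limited*: λᵢ = λ₀; μᵢ = A·e^{−αwᵢ} + (λ₀−⟨μ⟩)·n/N, with
  ⟨μ⟩ the population mean of the affinity term. The *normalized* variant
  replaces the affinity term by μ₀·A·e^{−αwᵢ}/⟨μ⟩, pinning its mean at μ₀.
  Per-cell death rates are clamped at 0 if the crowding correction drives
  them negative (a regime the rate model does not otherwise define).
- *neutral*: λ₀ and μ(n) for every cell.

The phases hand over instantaneously at T_growth: the logistic term
applies from the first instant of competition.

## Mutation scale and the reading of N(0, 2D)

The mutation kernel is written N(0, 2D). The package reads the second
argument as a **variance**, i.e. per-division standard deviation
σ = √(2D) (`mutation_sd_convention="variance_2D"`, the default); the
literal reading σ = 2D is selectable. The variance reading is the standard
notational convention, and it is also the only one under which the model
shows its documented phenomenology at the documented D values: with
σ = 2D ∈ [0.002, 0.04] selection is so weak over 16 days that the
homogenization rate, the surviving-clone count and the dominant-clone
fraction are essentially independent of D (measured: mean dominant
fraction 0.23–0.30 across D = 0.001–0.02, diversity–affinity correlation
≈ 0), whereas with σ = √(2D) the D-dependence, the traveling affinity
wave, the interior-time maximum of dominance variability (peaking at
competition day 11 for D = 0.02) and the negative diversity–affinity
correlation all appear.

Affinities are floored at ε = 10⁻⁶ after mutation: the birth-limited rate
requires w > 0 and negative excursions are otherwise unconstrained.
Mutation is off during the growth phase (few to no BCR mutations occur
that early); `mutate_during_growth=True` enables it for sensitivity
checks. Which daughter keeps the parent affinity is exchangeable; the SSA
draws it uniformly, the tau-leap keeps the parent slot (unobservable).

## Integrators

*Exact SSA.* Next-event sampling over per-cell birth and death channels,
with all rates recomputed after every event (the process is Markov in the
full per-cell state). An O(1)-per-event uniform fast path applies while
mutation is off and all affinities are equal — the neutral-drift setting —
otherwise per-cell rate vectors are rebuilt each event.

*Bernoulli tau-leap.* Fixed step dt; per step each cell dies with
probability dᵢ·dt, else divides with probability bᵢ·dt, with rates frozen
at the step start. The default dt = 0.002 day was set by comparison with
the SSA at the default GC size: at dt = 0.01 the leap visibly damps
selection (day-16 mean dominant fraction 0.56 vs 0.61, mean affinity 3.08
vs 3.17 at D = 0.005), while at dt = 0.002 the dominant-fraction law,
surviving-clone count, affinity moments and the diversity–affinity
correlation are statistically indistinguishable from the SSA (KS tests and
200-replicate moment comparisons). A run aborts if the population exceeds
10·N (misconfigured rates).

*Sampling.* Trajectories are recorded on a fixed grid (default 1 day)
covering both phases; where two simulation segments share a boundary
instant (start of competition, a labeling day) the later segment's sample
is recorded, so grids are strictly increasing and a state change applied
at the boundary is what appears at that time stamp. Competition-relative
day (`comp_day`) is reported alongside absolute time.

*Seeds.* Ensembles derive replicate generators from
`SeedSequence(base_seed, spawn_key=(i,))`: replicate i of any ensemble is
bit-identical to a solo run with the same derived seed, and results are
independent of replicate order.

## Statistics

All snapshot statistics operate on per-clone counts (ties in dominance
ranks broken by smallest clone id, for determinism). The participation
ratio uses the with-replacement form Σfᵢ² (the standard order-parameter
convention; a without-replacement variant is available);
heterozygosity is its complement. The population affinity STD uses the
divide-by-n convention — it describes the standing distribution, not an
estimator — and the mean/STD ratio is reported missing while the STD is 0
(the initial δ(w−w₀) state). The occupancy correlation
C(t) = (1/N_tot(t))·Σᵢ nᵢ(T_growth)·nᵢ(T_growth+t) is implemented exactly
in that form, units of cells; a clearly named cosine-similarity variant is
offered separately and never silently substituted. Note that under
neutral drift C(t) is a martingale (flat in expectation); it decays only
through selection, and its cross-replicate *mean* is dominated by the rare
replicates whose largest founder lineage also wins, so the typical
(median) replicate is the stable summary at a few hundred replicates.
The diversity–affinity correlation is the Pearson r, across replicates,
between the surviving-clone count and the dominant clone's *mean*
affinity (the dominant clone's affinity is the diversity-facing proxy for
the population's); it is reported missing when either variable is
constant or fewer than 3 replicates have cells.

## Color labeling

`labeling` emulates confetti/brainbow fate mapping: at a configurable
absolute day (default: start of competition — the mapping from
experimental induction timing to model time is a free choice), each live
cell independently adopts one of K colors (uniformly; real reporter
alleles are non-uniform but no frequencies are available) with probability
p_recombine, else stays unlabeled; descendants inherit the label. The
dominance readout is the largest single-color share of labeled cells.
Because clones share colors, this overestimates dominance in diverse GCs
(checked against the K→∞ limit, which recovers sub-lineage structure).
Labeled ensembles write a separate tidy `colors.csv` (replicate, time,
color, count) next to `trajectories.csv`, since colors cut across the
per-clone rows of the trajectory table.

## Study conditions and problem sizes

The default parameter set (M=50, λ₀=1.5/day, μ₀=1/day, N=2000, D=0.001,
w₀=1.5, 6+16 days) is the package's canonical study condition. The test
suite runs the heavy ensemble checks at 200 replicates of that condition
(shared across tests through session fixtures, with matched per-replicate
seeds across D values as common-random-number variance reduction for the
monotonicity comparison); neutral-drift fixation uses 2000 replicates of
a 20-cell population (fixation probabilities are size-independent under
neutrality, and the small population fixes quickly); integrator
cross-checks use a 100-cell fixture where the exact SSA is cheap.
Death-limited comparisons set A = μ₀e^{αw₀} so the affinity term starts
at μ₀ and the modes are demographically matched at t = 0; the
death-limited showcase run uses α=1, A=e, w₀=1, D=0.01, N=2000.

## Known limitations

- No dark-zone/light-zone structure, T-cell agents, antigen dynamics,
  plasma/memory output or GC termination; rates are effective.
- Affinity is a scalar fitness proxy; no sequence or epitope structure.
- The synthetic populations and the simulator share the same model family,
  so ensemble tests demonstrate internal consistency and the model's
  qualitative regimes, not agreement with any particular biological GC.
- The diversity–affinity correlation is a noisy functional of a skewed
  ensemble: its 200-replicate sampling SD is ≈ 0.07, so single-ensemble
  values scatter accordingly.
- The tau-leap is first-order: statistics far outside the validated
  regime (much larger rates, much smaller N) warrant a fresh SSA
  comparison.
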
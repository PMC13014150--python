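# Methods

## Model and assumptions

`mutvortex` analyses the long-term genetic viability of a diploid
population of constant census size N under recurrent mutation. Relative
fitness is multiplicative within and between loci: each copy of a
mutation of effect s multiplies fitness by (1 + s), so a fixed mutation
changes log mean fitness by 2s. Effects are strictly co-dominant; there
is no epistasis, no dominance distribution, no back mutation, and no
density regulation — the population size is a parameter, not a dynamic
variable, and the vortex argument is a perturbation argument around the
tipping point rather than a demographic trajectory.

Fixation probabilities use the exact diploid Moran birth–death result
pfix(s) = (1 − e^−s)/(1 − e^−2Ns), with the limit 1/(2N) at s = 0.
"Worse than lethal" draws (2s < −1) are retained in the deleterious
distribution and passed through the same formula; they are effectively
never fixed and behave like lethals in the simulator (a zero block load
gives fitness zero, and fitness-zero individuals are never parents).

The linkage-equilibrium engine evaluates the fitness fluxes

    vd(N) = Ud N ∫_{-∞}^{0} p_d(s) 2s pfix(s, N) ds
    vb(N) = Ub N ∫_{0}^{∞}  p_b(s) 2s pfix(s, N) ds

and solves vnet = vd + vb + δenv = 0 for the critical size Ncrit,
treating N as a continuous positive real (reported unrounded). The
drought : meltdown ratio is (dvb/dN)/(dvd/dN) at Ncrit; both derivatives
are positive there, and δenv, being constant in N, does not affect them
— it moves only Ncrit.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| Ud | deleterious mutations per diploid genome per generation | 2 | consistent with the arithmetic lower bound ~2.2 from genome size × constraint × per-bp rate |
| Ub | beneficial rate | Ud/1000 | beneficial mutations are rare; the ratio analysis saturates above Ud/Ub ≈ 100 anyway |
| deleterious DFE | gamma on the \|s\| axis, support s < 0 | shape 0.169, scale 1327.4/23646 ≈ 0.05614 | the human non-synonymous estimate, published population-scaled and divided by 2Ne = 23,646; mean s̄d ≈ −0.00949, CV ≈ 2.43 |
| beneficial DFE | exponential, support s > 0 | mean 0.001 | conservatively weak beneficial effects |
| δenv | environmental log-fitness change per generation | 0 | static environment; the preset alternative −1.5×10⁻⁵ corresponds to a 10% fitness loss per ~6,700 generations |
| genome | chromosomes × linkage blocks | 23 × 100 | human-like chromosome number; 100 blocks per chromosome is ample to decorrelate selected backgrounds |
| crossovers | per chromosome per meiosis | exactly 2 | a count, not a Poisson mean; positions uniform without replacement over the 99 internal boundaries |
| run length | simulator generations | 100 N | long enough to accumulate many fixation events |
| burn-in | window, slope, wait | 200 gen, 0.07/N, 100 gen | the fitness-variance slope criterion: burn-in ends 100 generations after the trailing-200-generation OLS slope of var(w) first drops below 0.07/N (strict inequality, with a 1e-9 relative guard against float ties) |

The `with_mean` and `with_cv` adjusters vary the deleterious DFE while
holding, respectively, the CV or the mean fixed. `with_cv` preserves the
mean bit-for-bit by searching a few hundred ulps of the shape for a
(shape, scale) pair whose product is exactly the old mean — a relative
perturbation ~1e-13, far inside the 1e-12 CV tolerance.

## Numerical choices

**Quadrature.** The gamma density has an integrable singularity at 0
for shape < 1, so a single adaptive call over the half-line is
unreliable. Both flux integrals are evaluated on the |s| axis as a sum
of adaptive panels split at {1e-6, 1e-4, 1e-2, 1, ∞} with relative
tolerance 1e-10; any non-convergent panel raises rather than returning
silently. A Monte-Carlo estimate from 10⁷ DFE draws agrees with the
quadrature to well under 0.5% (test suite) and a 5×10⁶-draw cross-check
runs inside the acceptance script.

**pfix branches.** −expm1 forms are used throughout; for s < −36 both
expm1 terms overflow and the exponent difference e^{(2N−1)s} is used; for
−2Ns > 700 the denominator is replaced by its leading exponential. The
scalar path is verified against an exact linear solve of the 2N-state
birth–death absorption problem to 1e-12.

**Derivatives.** dv/dN is computed by differentiation under the integral
sign using d/dN[N pfix] = pfix · (1 − 2Ns/(e^{2Ns} − 1)), with a
central-difference cross-check at 0.1%. The environmental threshold
(the δenv at which the ratio reaches 1) is located two ways: exactly, by
root finding on ratio(δenv) − 1, and on a log-spaced grid of rates
(10^{−6} to 10^{−3.5}, 0.1-decade steps) as the first grid point at which
the ratio exceeds 1. The grid reading is what the threshold flux ratios
|δenv|/|vd(Ncrit)| are reported from; both values are returned.

**Root finding.** Ncrit uses Brent's method on a bracket expanded
outward by factors of two from [500, 1e5] (hard limits [10, 1e8]); a
missing sign change raises an error carrying the endpoint fluxes, which
is the defined behaviour for Ub = 0 (vnet < 0 everywhere, no tipping
point).

## The simulator

The forward simulator is the package's synthetic-data generator: its
defaults are the study conditions, not tuning knobs. Genomes are two
haplotypes of 23 chromosomes × L = 100 non-recombining linkage blocks;
a block stores only the product of (1 + s) over the mutations it
carries, and fitness is the product of all 4,600 block loads. One Moran
event kills a uniformly chosen individual and replaces it with the
offspring of two fitness-proportionally chosen hermaphroditic parents;
N events are one generation. Parents are drawn with replacement from
all N individuals — the dying individual may be a parent and selfing is
possible, the simplest reading of fitness-proportional biparental
replacement (a sensitivity knob, not a model commitment). Gametes take
a fair-coin starting haplotype per chromosome and switch source at
exactly two hotspot boundaries drawn uniformly without replacement;
mutations (Poisson Ud and Ub per offspring) hit a uniformly chosen block
copy after gamete union. Incrementally maintained fitness is re-derived
from the block loads every 100 generations and must agree to 1e-9
relative tolerance.

v̂net is the OLS slope of ln(mean population fitness) — not the mean of
ln fitness — over post-burn-in generations. Burn-in variance is computed
on fitness w itself (the literal reading of "variance in fitness").

The compiled event loop (numba) is used for all production runs; a
pure-Python implementation of the same model backs the mutation-ledger
runs and the low-level unit tests. Each path is deterministic given its
seed, but the two paths consume randomness differently and do not
reproduce each other draw-for-draw.

**What the generator emulates and what it does not.** It captures
linkage disequilibrium from physical linkage within blocks and from
finite genome size, background selection, hitchhiking and clonal
interference. It does not emulate demographic stochasticity (N is
pinned), population structure, dominance, epistasis, variable
recombination or mutation-rate heterogeneity. Tests passing against
this generator therefore validate the machinery and the LD physics of
this model class, not the behaviour of any real population.

## Stochastic root finding for the simulated Ncrit

Per replicate: bracket the root starting from N = 1500 and 6000,
expanding outward by factors of two (caps at N = 50 and 10⁶); iterate
the secant method, seeded with the two bracket evaluations, until the
successive v̂net magnitude changes by less than 15% (an option switches
the criterion to relative change in N, since the wording is ambiguous);
fit a line to the evaluated points with N within a factor of 3 of the
final N and take its zero-intercept; average intercepts over replicates.

Two safeguards are added: a 30-iteration cap (flagged) and termination
when the evaluation is exactly zero or N stops moving to machine
precision — without these, a noise-free evaluator never satisfies the
15% criterion (successive values keep shrinking by ~100%). The line fit
uses the secant-phase evaluations only: the two bracket seeds sit far
from the root, where the curvature of vnet(N) biases the intercept by
several percent; with them excluded the pipeline recovers the exact root
of noise-free evaluators (0.5% contract in the tests) and remains
unbiased under additive noise. When fewer than two secant points are
eligible (one-step convergence on a linear evaluator) the fit falls back
to all points, where no curvature exists to bias it.

## Fixation tracking and the simulated ratio

The ledger simulator registers every mutation, maintains its carrier
count among the 2N haplotypes incrementally (recount verified in tests),
and resolves fixation (count = 2N) and loss (count = 0) at generation
boundaries; the stamped fixation generation is the first boundary at
which the count equals 2N (boundary crossings back and forth below
fixation are not stamped). Fluxes over a window of G* post-burn-in
generations are vd = Σ 2s_d/G*, vb = Σ 2s_b/G* over mutations fixing in
the window. These are first-order estimates: the exact per-fixation
log-fitness change is 2 ln(1 + s), and the conservation test reconciles
Δ ln W̄ with Σ 2 ln(1+s) inside a 3-SD envelope of the post-burn-in
fluctuations, then checks the 2s form against the exact sum. Simulated
flux derivatives use runs at Ncrit ± ε with ε = 150 individuals at full
scale (ε = 0.04 N when scaled down, preserving the noise-versus-curvature
trade-off), a central difference of replicate means, and a delta-method
standard error for the ratio.

## Effective population size

Every run can carry a parent-pointer genealogy of one neutral mid-genome
block (chromosome 12, block 50 by default; capped into small test
genomes). Ne/N is estimated as the ratio of mean pairwise coalescence
times, focal run : matching neutral control (Ud = Ub = 0, same N and
architecture), from 100+ sampled copy pairs at run end; the
ratio-to-control design cancels the Moran timescale constant, so no
analytic T2 is assumed. Pairs without a common ancestor inside the run
are censored; runs with >10% censoring are re-run longer (warned).
Because all pairs share one genealogy, single-run T2 means have CV ≈ 0.5,
and the estimator averages replicate runs. Two further estimators are
provided: flux matching (the N′ at which the analytic vd equals a
simulated vd; a monotone 1-D root) and the critical-size rescaling
Ne = N · (analytic Ncrit)/(simulated Ncrit).

## Problem sizes in the test suite

The analytic results are exact desk-scale computations. The simulation
checks run at sizes chosen to give meaningful statistics in minutes on
one CPU: the linkage-equilibrium consistency check uses Ud = 0.02,
N = 300, 3,000 generations × 20 replicates (a 2-SE comparison of mean
v̂net with the analytic value); neutral fixation uses N = 20 with 10⁴
marker injections; ledger conservation uses N = 50 with a 6 × 25-block
genome over 2,500 generations; background selection uses Ud = 2 at
N = 300 with 16 replicate pairs of 2,000-generation runs. The full-scale
re-derivation of the simulated critical size and ratio (N near 4,600,
100 N generations, 10 replicates, ± ε runs) is wired up as the `fig6`
scenario and the `ncrit`/`ratio` CLI commands but is CPU-days of compute;
`desk_fig6` runs the same machinery at N = 200–400 with Ud = 0.2, where
both sizes sit far below the tipping point and the expected result is a
negative net flux consistent in sign with the analytic model.

## Known limitations

* Relative-fitness, constant-N formulation: the vortex is characterised
  by derivatives at the tipping point, not simulated demographic
  collapse.
* The per-generation stats and fixation stamps are boundary-resolved
  (granularity one generation = N events).
* The coalescent Ne estimator is a ratio design with replicate averaging;
  it is unbiased but noisy, and not a substitute for analytic
  linked-selection theory.
* The ledger simulator is pure Python and intended for toy-to-moderate
  scales; the compiled path does not carry the ledger.
* Exact-2 crossovers and uniform hotspots are a stylised recombination
  map; no interference model is implied.
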
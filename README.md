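# mutvortex

Fitness fluxes and tipping points of genetic extinction vortices.

Small populations face two self-reinforcing genetic feedback loops. In
**mutational meltdown**, weakened selection lets deleterious mutations fix,
lowering mean fitness and shrinking the population further. In **mutational
drought**, a small population produces too few new beneficial mutations to
offset deleterious fixations and environmental deterioration, with the same
downward spiral. `mutvortex` is for population geneticists and conservation
modellers who want to locate the tipping point between the two regimes and
to measure which feedback loop dominates near it.

## The model

Deleterious mutations arise at genome-wide rate *U*<sub>d</sub> per diploid
individual per generation with gamma-distributed co-dominant effects
(default: the human non-synonymous estimate, shape α = 0.169, scale
β = 1327.4 on the 2*N*<sub>e</sub>*s* axis, divided by 2*N*<sub>e</sub> = 23,646);
beneficial mutations arise at rate *U*<sub>b</sub> with exponential effects
(mean s̄<sub>b</sub> = 0.001). Under the diploid Moran model a new mutation of
effect *s* fixes with probability

```
pfix(s) = (1 − e^−s) / (1 − e^−2Ns)
```

and, once fixed, changes log mean fitness by 2*s*. The per-generation
fitness fluxes are

```
vd = Ud · N ∫ p_d(s) · 2s · pfix(s) ds   (s < 0)
vb = Ub · N ∫ p_b(s) · 2s · pfix(s) ds   (s > 0)
```

and a constant environmental deterioration δ<sub>env</sub> ≤ 0 may be added.
The **critical population size** *N*<sub>crit</sub> solves
v<sub>net</sub> = v<sub>d</sub> + v<sub>b</sub> + δ<sub>env</sub> = 0 — an unstable
equilibrium: below it the population enters the vortex. The
**drought : meltdown ratio** (d*v*<sub>b</sub>/d*N*) / (d*v*<sub>d</sub>/d*N*)
at *N*<sub>crit</sub> measures which flux reacts more strongly to a change in
population size; a value above 1 means drought dominates.

A whole-genome forward simulator (23 chromosomes × 100 non-recombining
linkage blocks, two crossovers per chromosome per meiosis, Moran
birth–death events) re-derives *N*<sub>crit</sub> and the ratio under linkage
disequilibrium, with stochastic root finding on the simulated net flux,
per-mutation fixation tracking, and coalescent effective-size estimation
from a neutral tracer block.

## Worked example

```python
from mutvortex import VortexModel

results = VortexModel.from_preset().fit()   # Ud=2, Ud/Ub=1000, static environment
print(results.summary())
```

```
Extinction-vortex tipping point (linkage equilibrium)
========================================================
Ud                    2
Ub                    0.002
deleterious DFE       gamma(shape=0.169, scale=0.0561363), mean -0.009487
beneficial DFE        exponential(mean=0.001)
delta_env             0
--------------------------------------------------------
Ncrit                 3664.3
closed-form approx.   2361.9
vd(Ncrit)             -2.9334e-05
vb(Ncrit)             2.9334e-05
dvd/dN at Ncrit       9.3265e-09
dvb/dN at Ncrit       7.9589e-09
drought:meltdown      0.8534
========================================================
```

Populations below ~3,660 individuals tip into the vortex; at the tipping
point, losing individuals weakens the beneficial flux 85% as much as it
strengthens the deleterious one — mutational drought is nearly as important
as mutational meltdown even in a constant environment. The closed-form
(exponential-DFE) approximation underestimates the tipping point because
the gamma DFE is overdispersed (CV ≈ 2.4 vs 1). Adding environmental
decline (`delta_env=-1.5e-5`) raises *N*<sub>crit</sub> to ~4,653 and pushes
the ratio above 1.

The same analyses are available from the shell:

```bash
mutvortex analytic --delta-env -1.5e-5
mutvortex sweep --ud-over-ub 10,100,1000 --out sweep.csv
mutvortex scenario fig2 --out fig2_out
mutvortex simulate --config sim.yaml --seed 1 --out sim_out
```

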
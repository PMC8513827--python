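# phenomem

Phenotypic memory in microbial populations: a multi-compartment model of
'on'/'off' switching, with deterministic and stochastic engines.

## The problem

Isogenic bacterial populations hedge against environmental shocks by
stochastically switching between phenotypic states — the canonical example
being persister cells that stop growing but tolerate antibiotics.  Classic
models use a two-state switch with constant rates, which forces the time a
cell spends in the alternative state to be exponentially distributed.
Single-cell experiments instead show gamma-distributed residence times and
over/undershooting population dynamics: cells appear to track how long they
have been in a state.  `phenomem` implements a mechanistic model of this
*cellular memory* and the population-level consequences that follow, for
researchers in microbial ecology, evolution and antibiotic-tolerance
modelling.

## The model

A cell is 'off' (compartment 0) or in one of *n* 'on' substates
(compartments 1..*n*).  Switching 'on' (rate μ) jumps to the freshest
substate *n*; the cell then *leaches* down one compartment at a time at
rate ε until it re-enters 'off'.  Compartment *i* has per-capita birth and
death rates *b<sub>i</sub>*, *d<sub>i</sub>*.  The abundances **x** obey
the linear system

    ẋ₀ = (b₀ − d₀)x₀ − μx₀ + εx₁
    ẋₙ = (bₙ − dₙ)xₙ − εxₙ + μx₀
    ẋᵢ = (bᵢ − dᵢ)xᵢ − εxᵢ + εxᵢ₊₁     (0 < i < n)

Key consequences, all computable here:

* the 'on' residence time is gamma(*n*, ε): *n* = 1 is the memory-less
  exponential switch, *n* > 1 is memory;
* under symmetric growth the dominant eigenvalue is *b* − *d* for every
  *n*, and the equilibrium 'on' fraction is *n*μ/(ε + *n*μ);
* more compartments bring complex subdominant eigenvalues closer to the
  dominant one, so the 'on' fraction overshoots and oscillates on its way
  to equilibrium (peak-to-peak amplitude grows with *n*);
* under fluctuating antibiotic treatment, a memory lineage can out- or
  under-perform a memory-less lineage calibrated to the same equilibrium
  'on' fraction — relative fitness *r* = (*g*ₘ − *g*ₘₗₑₛₛ)/*t*ₘₐₓ with
  *g* = log *N*(*t*ₘₐₓ)/*N*(0).

Engines: exact matrix-exponential propagation for the ODE (also under
piecewise-constant season schedules) and an exact Gillespie direct-method
simulator for the reaction network, plus gamma maximum-likelihood fitting
and a likelihood-ratio exponentiality test for residence-time samples.

## Worked example

```python
from phenomem import *

p = ModelParams(n_on=4, mu=0.2, epsilon=0.5, birth=1.0, death=0.98)
s = spectral_summary(p)
print(f"growth rate          : {s.growth_rate:.6f}")
print(f"equilibrium 'on' frac: {s.equilibrium_on_fraction:.6f}")
print(f"spectral gap         : {s.spectral_gap:.6f}")
print(f"complex subdominant  : {s.has_complex_subdominant}")

traj = integrate(p, CompartmentState.all_off(4, 1000.0), t_end=300.0, dt_out=0.01)
m = transient_metrics(traj, p)
print(f"overshoot            : {m.overshoot_value:.6f}")
print(f"peak-to-peak         : {m.peak_to_peak:.6f}")

sample = sample_residence_times(4, 0.3, 10_000, SSAConfig(seed=1))
fit = fit_gamma(sample.durations)
print(f"gamma shape, rate    : {fit.shape:.3f}, {fit.rate:.4f}")
```

prints

```
growth rate          : 0.020000
equilibrium 'on' frac: 0.615385
spectral gap         : 0.310992
complex subdominant  : True
overshoot            : 0.643136
peak-to-peak         : 0.027751
gamma shape, rate    : 3.948, 0.2967
```

The population grows at exactly *b* − *d* = 0.02 regardless of memory
length; with μ = 0.2 and ε = 0.5 the equilibrium 'on' fraction is
4·0.2/(0.5 + 0.8) ≈ 0.6154, which the trajectory overshoots (first peak
0.643) before oscillating in; and 10,000 simulated single-cell residence
times at *n* = 4, ε = 0.3 are fitted by a gamma with shape ≈ 4 and rate
≈ 0.3 — the memory signature.

The same operations are available from the shell:

```sh
phenomem spectrum --n-on 4 --mu 0.2 --epsilon 0.5 --b 1.0 --d 0.98 --out spec.tsv
phenomem residence --n-on 4 --epsilon 0.3 --samples 10000 --seed 1 --out res.txt
phenomem fit --input res.txt --out fit.tsv
phenomem amplitude --n-grid 5,15,25,35 --target-eq 0.8 --out amp.tsv
phenomem landscape --out landscape.tsv   # 31 memory sizes x 84 treatment schedules
```

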
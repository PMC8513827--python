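# Methods

## Model and assumptions

The population is structured into one 'off' compartment (index 0) and
`n_on` 'on' compartments (1..n).  Transitions:

* switch: 'off' → compartment n at rate μ (the freshest 'on' substate;
  switching never enters an intermediate compartment);
* leach: compartment i → i−1 at rate ε, identical for all compartments;
  compartment 1 leaches back to 'off';
* demography: per-capita birth b_i and death d_i in compartment i.

All rates are per arbitrary time unit; nothing in the package converts
units.  The dynamics are linear and Markovian — no density or frequency
dependence, no cell–cell interaction, no movement between compartments at
division.  Compartment-dependent leaching and switching into intermediate
compartments are deliberately out of scope.

The deterministic system is ẋ = A·x with A Metzler, so a real dominant
eigenvalue with a non-negative eigenvector always exists: the eigenvalue
is the asymptotic per-capita growth rate, the sum-normalised eigenvector
the stable compartment distribution.  Column j of A sums to b_j − d_j
(switching and leaching conserve cells), which is the invariant the unit
tests assert on random parameter draws.  Under fully symmetric growth
(b_i = b, d_i = d) the dominant eigenvalue is exactly b − d and the
stable 'on' fraction has the closed form nμ/(ε + nμ); the closed form is
exposed only for the symmetric case and asymmetric parameters are routed
to the numeric spectrum.

The single-cell consequence of the chain is that the 'on' residence time
(first passage from compartment n to 'off') is a sum of n independent
exponential(ε) sojourns, i.e. gamma(shape n, rate ε).  n = 1 reproduces
the memory-less exponential switch.

## Parameters that matter

| parameter | meaning | default used in examples | why |
|---|---|---|---|
| n_on | memory length ('on' substates) | varies (1–35) | the study variable |
| μ | 'off'→'on' switch rate | 0.2 | transient/treatment protocol value |
| ε | leaching rate | 0.5 (transients), 0.3 (residence), 0.25 (treatment) | protocol values per analysis |
| b, d | symmetric birth/death | 1.0, 0.98 | net growth 0.02 per unit time |
| N(0) | initial 'off' cells | 1000 | protocol value |

The memory-less comparator of an (n, ε) lineage is the n = 1 lineage with
ε' = ε/n: it matches both the equilibrium 'on' fraction and the mean
residence time n/ε.

## Deterministic engine

Propagation is by matrix exponential per output step: for a uniform grid
of step dt the propagator P = expm(A·dt) is computed once and applied
repeatedly, so grid values are exact up to round-off and `expm`'s backend
accuracy — there is no integration tolerance to tune.  Season schedules
integrate piecewise with the state vector carried across boundaries
unchanged (parameters switch instantaneously; no redistribution of 'on'
cells when μ changes).  A state with abundance below −1e-9 aborts with an
integration error; smaller negative round-off is clipped to zero.

Transient metrics: a grid point is a local extremum of fraction_on if it
differs from both neighbours in the right direction by at least 1e-9
(absolute), which suppresses floating-point ripple on flat stretches; the
default output step is 0.01 time units.  Peak-to-peak amplitude is (first
local maximum) − (first subsequent local minimum).  If the approach is
monotone the amplitude is 0; if a single overshoot decays monotonically
(no undershoot — typical for small n), the amplitude degrades to
overshoot − equilibrium and the result is flagged `degenerate_undershoot`.
A trajectory whose final fraction_on is further than 1e-3 from equilibrium
is flagged `not_converged` rather than rejected.  Amplitude sweeps pick
their horizon as ~60 spectral-gap times (clamped to [100, 5000]), long
enough for the transient to die at every sweep point used in the tests.

## Stochastic engine

Gillespie direct method: the full propensity vector is rebuilt after every
event (populations at desk scale are small; simplicity and auditability
beat the next-reaction method here).  Reproducibility contract: one
`numpy.random.default_rng(seed)` per run; the waiting time is an
inverse-CDF exponential draw and the reaction is selected by a single
uniform draw against the cumulative propensity vector in fixed order —
for each compartment ascending: birth, death, leach (i ≥ 1); switch last.
Identical seed and config give bit-identical event sequences.  Extinction
ends the trajectory at the extinction time with a flag (not an error);
exceeding the event cap sets a truncation flag.

The residence-time sampler places one cell in compartment n with births
and deaths off and returns first-passage times to 'off'.  With a single
cell and zero demographic rates the exact SSA of the pure leaching chain
reduces to drawing the n exponential(ε) sojourns and summing them, which
is what the sampler does; the tiny-but-nonzero birth/death variant remains
available through `gillespie()` and is checked against the same gamma law
in the test suite.

## Residence-time statistics

The two-parameter gamma MLE profiles the rate out as shape/mean and solves
log k − ψ(k) = log(mean) − mean(log x) by Newton iteration (ψ = digamma)
from the method-of-moments start, converged to 1e-10 in that equation;
no location parameter is fitted because first-passage times start at 0 by
construction.  Exponentiality is tested by the likelihood ratio of the
exponential (shape ≡ 1) against the free-shape gamma, compared to χ²(1);
the default α is 0.01 and is configurable.  Mixtures of gammas (cells
sampled from several 'on' compartments at once) are out of scope.

## Treatment protocol

Two seasons parameterise the persister scenario.  Permissive: 'off' cells
grow at b − d = 1.0 − 0.98 = 0.02, switch inactive (μ = 0).  Treatment:
switch triggered (μ = 0.2), 'off' cells decline at 1.0 − 1.02 = −0.02,
'on' cells are persisters with b_on = d_on = 0 (implemented as literally
no birth/death events, not equal nonzero rates — indistinguishable in the
deterministic engine and cleaner in the stochastic one).  ε = 0.25 in both
seasons.  Each environmental sequence is permissive(onset) →
treatment(length) → permissive(rest) with total t_max = 165; the default
grid uses treatment lengths 1..84 in unit steps.  The onset of treatment
is not pinned by the protocol description; the default is 40 time units,
and every property the tests assert (calibration identity, monotone
survival, interior maxima, sustained-treatment neutrality) is
onset-invariant.

Fitness: each lineage and its ε/n-calibrated memory-less comparator run as
separate monocultures from 1000 'off' cells; r = (g_m − g_mless)/t_max
with g = log N(t_max)/N(0).  The fitness engine is deterministic; an SSA
mode exists for extinction studies (extinction maps to a −infinity
sentinel) but is not part of the quantitative checks.  Sustained-treatment
neutrality (|r| < 1e-4 across memory lengths) requires a horizon long
enough for the transient share of g to decay: under treatment the
dominant eigenvalues of the memory and comparator lineages agree only to
~1e-5, and the O(1) transient difference divided by t_max dominates until
t_max is in the thousands.  The test uses a sustained horizon of 2000 time
units; at t_max = 165 only the qualitative "r shrinks toward 0" holds.

## Synthetic data and what the tests show

All inputs are generated by the package itself: seeded residence-time
samples, exact-gamma and exact-exponential draws for parameter-recovery
and null-calibration checks, short event logs, and an ODE trajectory with
a known overshoot.  The generator emulates the model's own study
conditions (protocol parameter values above, 1000-cell starts, 10,000
residence samples); it does not emulate features of real experiments —
measurement noise, growth-phase structure, nutrient depletion,
non-constant ε, sampling from mixtures of 'on' compartments — so passing
tests demonstrate internal correctness of the engines and analyses, not
agreement with any particular dataset.

Problem sizes: ensemble checks use 2000 runs of 1000 cells to t = 2 with
20 checkpoints (the transient window where the mean-field comparison is
informative); unit-level mean-field checks use 200 runs of 100 cells; the
fitness landscape is the full 31 × 84 cross; amplitude sweeps use
n ∈ {5, 15, 25, 35} calibrated to equilibrium 0.8.

## Numerical choices and edge cases

* Dominant-eigenvalue selection: maximal real part; ties within 1e-12
  prefer the sign-constant eigenvector.  Eigenvector sign is flipped so
  the largest-magnitude entry is positive; entries in [−1e-12, 0) are
  clipped to 0 before renormalising to sum 1.  A distinct eigenvalue
  within 1e-9 of the dominant sets a `defective_warning` flag instead of
  failing.
* μ = 0 leaves the 'off' column diagonal: all mass drains to 'off' and the
  equilibrium 'on' fraction is 0.
* Zero-duration seasons are dropped at schedule construction; a schedule
  that would be empty is rejected.
* Zero total propensity in the SSA freezes the state to the end of the run
  (absorbing), with zero events logged.
* All tabular output is tab-separated text with repr-precision floats and
  '#'-prefixed metadata; CLI runs write a `<out>.meta.json` sidecar with
  the resolved configuration, seed and package version, and remove partial
  outputs on failure.

## Known limitations

* The fitness landscape's exact values depend on the (unpinned) treatment
  onset; only onset-invariant properties are asserted.
* `expm`-per-step propagation is dense: fine for the ≤ 36-compartment
  systems used here, wasteful for very deep memories.
* No tau-leaping or hybrid acceleration in the SSA; runs with large
  populations and long horizons are event-bound by design.
* No evolutionary dynamics on n or ε, no density-dependent switching, no
  spatial structure.
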
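# Model and methods

`plasmidpol` models the replication control of non-conjugative (purely
vertically transmitted) bacterial plasmids as a two-level evolutionary
system: plasmids compete for replication inside a host cell, and host
cells compete through growth and division in a population. The package
has two coupled layers — a deterministic single-cell layer used for
stability analysis, and a stochastic multicellular simulator used for
evolutionary experiments — built on one shared pair of rate laws.

## Rate laws

**Host growth.** A cell of biomass M carrying n plasmid copies grows at
a per-biomass rate

    g(n) = g0 + B (1 − e^(−s n)) − c n − c_inh Σκ

where `g0` is the chromosomal (basal) growth rate, `B` the ceiling of a
saturating gene-dosage benefit with shape constant `s`, `c` the
maintenance cost per plasmid copy, and `c_inh` an optional policing cost
per unit of inhibitor produced (Σκ is the summed per-copy inhibitor
synthesis rate; zero in the baseline model). The saturating-benefit /
linear-cost geometry creates an interior optimal copy number
`n_opt = ln(B s / c) / s` and a copy number beyond which growth is
negative. A cell divides when its biomass doubles (M = 2 M0); a cell
whose biomass collapses dies.

**Plasmid replication.** Each plasmid carries three heritable traits:
a basal replication rate α (*selfishness*, cis-acting), an inhibitor
synthesis rate κ (*policing*, trans-acting), and a binding affinity β to
the inhibitor (*obedience*, cis-acting). The inhibitor is short-lived
(mean lifetime τ, much shorter than the cell cycle) and is treated at
quasi-steady state, diluted by biomass:

    I = τ Σκ / M,        r_i = α_i / (1 + β_i I)

The hyperbolic inhibition response is the standard quasi-equilibrium
inhibitor–target binding form; an exponential response `e^(−βI)` is
available as a toggle and satisfies the same qualitative claims. For a
cell whose plasmids share one genotype the dynamics depend on β and κ
only through their product — policing and obedience are interchangeable
under homogeneity, which the test suite asserts bitwise.

## Deterministic single-cell layer

Copy number is continuous here. One cell cycle integrates

    dM/dt = M g(n),      dn/dt = n α / (1 + β τ κ n / M)

from (M0, n0) with adaptive Runge–Kutta (rtol 1e-8) and event detection
on the division threshold; a fixed-step Euler integrator with crossing
interpolation doubles as an independent refinement oracle. Equipartition
at division yields the generation map `G(n0) = n_division / 2`. Fixed
points of G are the characteristic copy numbers; stability is read from
the map slope (central difference, |G′| < 1). Roots are bracketed on a
uniform grid and refined by Brent's method.

The *edge of stability* in α is located by bisection on stable-root
existence, then polished by tangency: the signed minimum of `G(n) − n`
over the inter-root window crosses zero exactly at the fold, where the
map touches the diagonal with slope 1 (the suite verifies the slope to
1e-3; in practice it agrees to ~1e-8). Without policing (βκ = 0) cell
fitness, defined as 1/T_div at the stable fixed point, increases with α
all the way to the fold — selection drives a passively controlled
plasmid to the brink of instability. With policing the fold moves to
much larger α and the fitness maximum becomes interior: control
decouples the optimum from the edge.

Because an asynchronous exponentially growing population observes each
cell at an exponentially biased random age, and copy number doubles over
a cycle, the *snapshot* mean copy number of infected cells is ≈ 2 ln2
times the cycle-start fixed point. `equilibrium_mean_copy_number`
computes this prediction exactly from the integrated trajectory and the
stationary age distribution; it is the deterministic quantity the
stochastic layer's infected-cell mean is compared against (they agree to
a few percent at desk scale).

Two classification details: "death" in the continuous layer is declared
when biomass falls to half the newborn value — once g < 0 on a
trajectory it cannot recover (n is non-decreasing and the benefit curve
concave), so any such crossing is irreversible — and a cycle that
neither divides nor dies within 50 plasmid-free division times is
classified "stalls".

## Stochastic multicellular layer

Discrete time steps of length dt. Per step and cell: biomass multiplies
by (1 + g dt); each plasmid replicates a Poisson(r dt) number of times
(implemented as one Poisson draw of the summed rate with rate-weighted
assignment — distributionally identical); each new copy mutates with
probability μ, in which case exactly one trait (uniform among the free
traits) receives an additive uniform perturbation of half-width 5% of
that trait's bound, clipped into bounds; cells at M ≥ 2 M0 divide with
independent binomial segregation of every copy; a hard cap regulates the
population by uniform random culling (selection-neutral, verified
against the hypergeometric expectation). Update order is fixed — grow,
replicate/mutate, deaths, divisions, regulate — for bit-reproducibility
under a seed.

Death uses the biomass rule M < 0 plus a floor (M < 1e-3 M0): a cell
shrinking geometrically with replication stalled (I → ∞ as M → 0) can
never divide again, and the floor removes such moribund cells in finite
time; it is unreachable from any state that can still divide.

Segregational loss is counted per the transmission-fidelity definition:
among divisions of plasmid-infected cells, the instances that produce a
plasmid-free daughter. Division and death rates are per cell per unit
time over each recording window. Trait variation is decomposed into the
within-host SD (plasmid values about their host mean, averaged over
infected hosts) and the between-host SD (host means about their global
mean).

The engine stores the population flat (one biomass array, one trait
matrix with a parallel cell index) and runs either through a vectorised
numpy reference path or a numba-compiled kernel (`_engine.py`) that
implements the identical update rule; the two paths draw different
random streams and are therefore equal in distribution, not bitwise,
which a consistency test checks. All multi-million-step experiments use
the compiled path (~25–60 μs per step at the sizes below).

## Default parameters

All defaults live in `CellParams`, `TraitBounds` and `EvolutionParams`:

| parameter | value | meaning / rationale |
|---|---|---|
| g0 | 0.01 /time | plasmid-free division time ln2/g0 ≈ 69 steps |
| B | 0.05 /time | benefit ceiling: a fully benefiting host grows ~3.5× faster than plasmid-free |
| s (steepness) | 0.1 /copy | sets n_opt = ln(Bs/c)/s ≈ 16.1 copies, a realistic multicopy regime |
| c | 0.001 /copy/time | maintenance cost; growth turns negative near n ≈ 60 |
| c_inh | 0 (baseline) | policing cost per unit inhibitor; swept up to 12·c |
| M0 | 1.0 | newborn biomass (units absorbed) |
| τ | 2.0 time | inhibitor lifetime ≪ cell cycle (~20–70 steps) → quasi-steady state |
| dt | 1.0 | step of the discrete update; all rates ≪ 1/dt |
| α_max, κ_max, β_max | 0.1, 0.05, 1.0 | physiological caps; β normalised to [0,1]; at full CNC βτκn/M ≈ 1 so policing roughly halves replication |
| μ | 0.005 /replication | mutation supply of order one event per population per step at desk scale |
| mutation step | 5% of bound | small bounded steps produce gradual, ladder-like co-evolution |

With these values the passive (NO-CNC) stable band is α ∈ (0.010,
0.0334), the full-CNC edge sits at α ≈ 0.0824 (a 2.5-fold widening), the
deterministic fitness optimum at full CNC is α ≈ 0.071, and the
stochastic net-growth optimum — which is what evolution feels — is
α ≈ 0.066, below the deterministic one because proximity to the edge
carries fluctuation load.

## Experiment protocols and problem sizes

Desk-scale sizes used by the test suite and the acceptance script
(chosen as this package's defaults for a single-CPU run):

* **Landscape / outcome grids**: caps 240–300 cells, 6–10·10³ steps,
  outcomes classified from the trailing window (collapse, stable
  infection, loss by under- or over-replication).
* **Obedience sweep**: α fixed at the stochastic landscape optimum at
  β_max; β levels {0.05, 0.6, 0.8, 1.0}; 5 seeds; histograms pool every
  infected host at every step over the whole course.
* **Ladder co-evolution**: founder (0.8·α_crit^{NO-CNC}, κ_max, β = 0),
  α and β free, cap 150, 2.6·10⁶ steps, 5 replicates, endpoint averaged
  over the final 30% (quasi-equilibrium). Mean obedience settles at
  0.95–0.98 of β_max; within-host trait SD sits an order of magnitude
  below between-host SD.
* **Policing-cost sweep**: costs c_inh/c ∈ {0, 4, 8, 12}, founder at the
  evolved maximal-CNC state (relaxation, which equilibrates far faster
  than the naive transit and measures the same evolved-state-vs-cost
  relation), 1.2·10⁵ steps, 3 replicates.
* **CNC vs NO-CNC**: each arm starts from its own evolved state (the
  naive-founder transit is a multi-million-step computation measured
  once in the ladder experiment, not re-run per arm) and continues to
  evolve its free traits; 10 paired replicates, one-sided rank-sum tests
  on replicate-level window means.
* **Invasion**: resident (α*, κ_max, β_max) vs an inhibitor-insensitive
  invader (β = 0, matched α and κ), mixed 50:50 within hosts or between
  hosts; 20 replicates; fixation = disappearance of one type's copies.

## What the simulations emulate, and known limitations

The generator emulates asynchronous clonal growth with binary fission,
autonomous intracellular replication, binomial segregation, and neutral
density regulation. It does not model conjugative transfer, spatial
structure, active partitioning systems, explicit antisense-RNA/Rep
kinetics, host chromosome evolution, or resource-explicit competition —
so passing tests speak to the logic of multilevel selection on
replication control, not to quantitative parameters of any real
plasmid.

Two parameterisation-specific behaviours deserve note:

* **A lineage-selection band above the single-cell edge.** For α up to
  ~1.3× the deterministic critical value the multicellular simulation
  sustains a persistently infected, dividing, high-burden state: hosts
  with fewer copies divide faster, deaths cull runaway lineages, and —
  because the growth-zero boundary (~60 copies) is far above n_opt —
  plasmid-free segregants (probability 2^(1−n) per division) essentially
  never arise to take over. Host-level selection thus extends effective
  stability beyond the single-cell map. Consistency between the layers
  is therefore asserted away from the fold (a declared 10% margin);
  inside the band the two layers genuinely disagree.
* **A single-peaked skewness profile.** Pooled copy-number skewness
  peaks near the stability boundary (β ≈ 0.8) and declines towards
  maximal obedience; weakly obedient stable states live in the band,
  where the hard upper boundary compresses the right tail into a broad
  but nearly symmetric distribution. The monotone decline of skewness
  with obedience therefore holds in the strong-control range, while SD
  and |mean − n_opt| are monotone across the full sweep.

## Numerical choices

Integration tolerances rtol 1e-8 / atol 1e-10 with event detection;
root bracketing on 120–500-point grids refined by Brent to 1e-8; map
slopes by central differences with step 1e-4·max(n*, 1); fold polishing
by bounded scalar minimisation of the diagonal gap inside a bracket
stepped back 2% of the scan range from the existence-bisection edge.
Replicate RNG streams are spawned from one master seed via
`numpy.random.SeedSequence`; there is no hidden global randomness in the
numpy path, and the compiled kernel is seeded once per run from the
population's stream. Degenerate inputs (plasmid-free cells, empty
populations, missing stable equilibria) return flagged values (NaN /
empty sets / typed exceptions) rather than zeros.
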
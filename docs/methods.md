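# Methods

`chanevo` couples two classical models: a modified Hodgkin–Huxley (HH)
propagating-action-potential cable model of the squid giant axon, and a
diploid K-allele Wright–Fisher model of the cis-regulatory alleles that set
sodium- and potassium-channel expression. The cable model turns a
conductance phenotype (G_Na, G_K) into physiological performance; fitness
functions turn performance into survival probability; the population model
iterates selection, mutation and drift on the alleles that produce the
phenotype.

## Axon model

Membrane potential on a cable of length L = 10 cm and radius r = 238 µm
obeys

    C_m(t) ∂V/∂t = G_a ∂²V/∂x² − G_K n⁴ (V−E_K) − G_Na m³h (V−E_Na)
                   − G_L (V−V_L) + I_stim

with G_a = r/(2R_a), R_a = 0.0354 kΩ·cm, G_L = 0.3 mS/cm², E_Na = 50 mV,
E_K = −77 mV, and the usual first-order gate kinetics for n, m, h. Two
modifications to classic HH matter here:

* **Potassium deactivation (β_n)** uses the Clay parameterization
  (β_n = 0.125·exp(−(V+65)/19.7)), which raises subthreshold potassium
  activation and gives the axon Type 3 excitability (one spike under a
  sustained current) at the normal conductance ratio. β_h is likewise the
  modified form 1.8/(1+exp(−(V+16)/10)), implemented as specified.
* **Gating capacitance.** Total capacitance is C_m = C₀ + C_g with
  C₀ = 0.88 µF/cm² and C_g = 0.13·(G_Na/120)·(1−m) µF/cm²: the gating
  charge of closed sodium channels loads the membrane in proportion to
  channel density. This term is what makes conduction velocity saturate
  and then decline at high G_Na, producing an interior velocity maximum.

All six rates are scaled by a single Q10 = 3^((T−6.3)/10). The leak
reversal V_L is not a free parameter: for every (G_Na, G_K) it is solved
from the steady-state current balance so that −65 mV is exactly stationary
(an unstimulated cable holds −65 mV to <0.1 mV indefinitely).

### Numerics

Staggered scheme in the style of Hines: gates advance on half steps with an
exponential integrator (rates frozen at the current voltage; gate values can
never leave [0,1]), then the voltage advances by backward Euler — linear in
V given the half-step gates — via the Thomas tridiagonal algorithm with
sealed (zero axial flux) ends. Defaults Δt = 1 µs, Δx = 100 µm (1001
nodes); halving both changes the measured velocity by <1% (tested). The
time-varying capacitance enters as a quasi-static coefficient on ∂V/∂t,
exactly as the PDE above is written; an optional flag
(`expand_cm_derivative`) adds the V·dC_m/dt term of the expanded product
rule for comparison — it lowers wave amplitudes slightly and is off by
default. Gate rates are evaluated from precomputed voltage tables
(0.025 mV spacing, linear interpolation) whose error is far below the
discretization error; the analytic expressions (with the removable
singularities of α_n at −55 mV and α_m at −40 mV filled by their limits)
remain the public `rate_constants`.

The stimulus (default 20 µA for 0.1 ms) is applied to the first compartment
as the areal density I/(2πr·Δx). Initiation is deliberately overdriven:
once a wave is launched, its steady amplitude and speed are independent of
the stimulus (velocity at 20 vs 40 µA differs by <0.5%).

### Operational definitions

* **Conduction success.** The model sustains two families of travelling
  waves near the failure boundaries at 26 °C: full-amplitude action
  potentials, and marginal small-amplitude waves (peaking ≈ +5.1 mV, ~70 mV
  above rest) that persist a little beyond the physiological cliffs.
  Success therefore requires the arrival at 9.5 cm of a *full* action
  potential — an upward crossing of +5.2 mV — followed by repolarization
  below −50 mV within the 30 ms window. The +5.2 mV level sits between the
  marginal-wave branch and the smallest full wave; any level in a ±0.1 mV
  band around it yields identical integer-grid thresholds. With this
  definition the conduction cliff in G_Na (G_K = 36, 26 °C) is at
  81 mS/cm² and the conducting G_K window (G_Na = 120) is [4, 88] mS/cm².
* **Velocity** is measured between the 2.5 cm and 7.5 cm sites from
  quadratically interpolated peak times (excluding stimulus and sealed-end
  artifacts).
* **Sodium flux per action potential** is −∫ G_Na m³h (V−E_Na) dt at the
  mid-axon node (nC/cm²); **APD50/APD90** are times from the mid-axon peak
  to 50%/90% repolarization of the peak-to-rest amplitude.
* **Excitability class.** At 6.3 °C, the just-threshold sustained current
  is bisected to 1% (relative), then a 100 ms step of twice that current is
  injected over the first 0.5 cm and spikes are counted mid-axon: ≥2 spikes
  ⇒ Type 2, one ⇒ Type 3. The 0.5 cm injection segment approximates a
  macroscopic electrode (axial-wire current clamp); a single 100 µm
  compartment produces an unphysically steep sustained gradient and shifts
  the boundary by ~1 mS/cm². Lengthening the window to 300 ms does not move
  the boundary. The resulting Type 3→Type 2 transition at G_Na = 120 is at
  G_K = 23 mS/cm²; since potassium phenotypes in the evolution model are
  even integers, a cliff placed at 23 or 24 selects identically.

### Known quantitative limitation

The conduction-velocity curve over G_Na at 18.5 °C is extremely flat near
its maximum (variations ~10⁻⁴ of the velocity across tens of mS/cm²). Its
grid-converged argmax here is ≈430 mS/cm², and the fractional velocity gap
between the maximum and the observed G_Na = 120 is ≈14%. A peak location on
a curve this flat is numerically delicate — the flatness is comparable to
the velocity quantization implied by µs-resolution peak timing — so the
peak position should be read as "≈400–470, far above the observed 120",
not as a sharply defined landmark. The acceptance suite records this
check honestly rather than tuning the model toward it.

## Landscape module

Discontinuities are located by bisection on a 1 mS/cm² grid (`find_threshold`,
which accepts the named predicates "conducts"/"type3" or any monotone
callable; agreement with brute-force unit-step scans is tested).
Smooth metrics are tabulated by 1D sweeps (`metric_curve`) and, for fitness
evaluation during evolution, interpolated piecewise-linearly — a cable
simulation per individual would be prohibitive and the curves are smooth.
2D tables (`build_landscape`) cache to CSV + JSON sidecar keyed by a
parameter hash and reload bit-identically. The 2D viable region
(`build_region2d`) is bounded by the interpolated conduction cliff
G_Na(G_K) sampled at five G_K values, plus horizontal potassium edges
(conducting window and Type 3 boundary) located at G_Na = 120; both
potassium boundaries vary only weakly with G_Na near the observed
phenotype, which is what the region is used for.

## Fitness functions

All fitness functions map phenotypes to [0,1]; step functions use plateau
value exactly 1, and survival at a threshold is inclusive (allele
granularity makes boundary membership well-defined; the choice moves
equilibria by less than one allele step). Graded functions are built from
tabulated curves:

* `velocity_fitness` — velocity rescaled onto [floor, 1] above the
  conduction cliff (default floor 0.9: weak graded selection, so drift is
  visible, matching the scenario it encodes);
* `velocity_minus_cost` — velocity minus a linear metabolic cost in G_Na,
  renormalized so the unique interior optimum has fitness 1;
* `apd_fitness` — action-potential duration inverted and scaled onto
  [1−scale, 1] over the tabulated G_K range, with a lethal cliff at low
  G_K where repolarization fails.

The scaling constants of the graded functions are genuine free parameters
of the scenarios (the original calibration constants are not recoverable from the reported results); they are
exposed as configuration with the defaults above and the corresponding
equilibria are treated as calibration demonstrations, not sharp targets.

## Wright–Fisher engine

Fixed population of N diploid individuals (default 5000), non-overlapping
generations, two independent loci (sodium, potassium). An allele is a
non-negative integer regulatory strength; a phenotype is step·(a₁+a₂) with
step 5 (Na) or 2 (K) mS/cm², plus optional zero-centered binomial noise
step·(Binom(N_noise, ½) − N_noise/2), clamped at zero. Noise widths used:
N_noise = 28 (Na, SD 13.2) and 16 (K, SD 4.0) for single-locus runs;
48 (SD 17.3) and 20 (SD 4.5) for the concurrent run.

Each offspring: draw two distinct allele copies from the parental 2N-copy
pool (pool restored between offspring), mutate each copy with probability
µ = 10⁻² (one step; downward with probability 0.9, floored at 0), evaluate
the noisy phenotype, accept with probability f(phenotype); on rejection
both alleles are redrawn and noise is redrawn (noise is attached to the
candidate individual, not the genotype). This repeats until N survivors
form the next generation; if ≳10⁶ consecutive candidates are rejected the
run aborts with an extinction error. Initial populations draw each allele
as mean − 3 + Binom(6, ½), clamped at 0.

`exact_transition_distribution` enumerates the same cycle exactly for
small states (N ≤ 4): all ordered pair draws, both mutation outcomes per
copy, and fitness acceptance, conditioned on acceptance and convolved over
N offspring. It is the correctness oracle for the simulator: Monte-Carlo
one-generation frequencies (10⁵ replicates, N = 3, three allele types)
match it within three standard errors per outcome across neutral, biased-
mutation, cliff and graded-fitness settings. Note the within-offspring
pairing makes the exact law the *without-replacement pairing* variant of
the classic multinomial transition, which treats the 2N copies as
independent; the enumeration, not the multinomial shortcut, is what the
simulator must match.

All randomness flows from a single `numpy` generator seeded per run;
replicate r uses seed base+r. Identical config + seed ⇒ identical
trajectory (tested).

### Reported statistics

A run records per-generation mean and SD of the genotypic phenotype (the
noise term is zero-centered, so genotypic and expressed means coincide in
expectation). At balance the population mean performs a slow random walk
around the equilibrium point — the restoring selection gradient near a
cliff is shallow — so a single-generation snapshot of the mean has a
replicate-to-replicate spread of several mS/cm². Reported "final" values
are therefore the time average of the phenotype mean over the last 1000
generations of each run, averaged over replicates; this is the standard
way to report a stationary quantity from an equilibrated trajectory and
converges to the same balance point as the snapshot convention.
Equilibrium is reached by ≈3000 generations; the library defaults to
5000-generation desk runs with 3 replicates, and the reference checks and
acceptance script use the full 10000 generations.

## What the model does and does not emulate

The generator *is* the system under study: there is no external data. What the
synthetic populations do not contain: linkage or recombination structure
beyond two freely recombining loci, overlapping generations, mate choice,
explicit sequence-level regulatory elements, homeostatic feedback between
activity and expression, and temperature acclimation. Passing tests
therefore demonstrate the internal consistency of the
selection–mutation–noise mechanism, not its sufficiency for real squid
populations.

## Reproducibility of the reference values

With everything at printed parameters this implementation reproduces: the
conduction cliff (81), the potassium window ([4, 88] vs [3, 88]), the
excitability boundary (23 vs 24; selection-equivalent), neutral decay
(≈1.3 vs 1.2 ± 0.1), cliff-only balance (≈96–99 vs 92.7 ± 2.2), cliff+noise
balance (≈124 vs 120.4 ± 4.4), potassium cliff balance (≈28–30 vs
28.6 ± 0.7) and cliff+noise (≈36–37.5 vs 36.2 ± 0.5); the sodium balances
sit systematically about one allele step above the reference means,
at the edge of their reported spread. Two quantities do not
reproduce sharply and are documented as red checks rather than tuned: the
velocity-peak location (above), and the concurrent 2D equilibrium, where
the printed (116.5, 36.0) is inconsistent with extrapolating the 1D noise
scaling above to the printed 2D noise widths — this implementation
converges from all starting points (the qualitative claim) to
≈(132, 35), which is where that extrapolation lands.
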
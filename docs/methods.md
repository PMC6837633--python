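# Methods

## Circuit model and fixed-point analysis

The self-activating gene is a one-species birth-death process with Hill
synthesis f(A) = k(α + (1−α)Aⁿᴴ/(Aⁿᴴ + K_Dⁿᴴ)) and linear degradation γA.
Because f is monotone, bounded in [kα, k] and positive at A = 0, the
deterministic flow f(A) − γA has an odd number of transversal roots (one or
three for Hill-type f), alternating stable/unstable with stable endpoints.

Fixed points are found by scanning the flow on a combined linear
(2001-point) and logarithmic (400-point) grid over [0, 1.05·k/γ] and
refining every sign-change bracket with Brent's method to an absolute
tolerance of 10⁻⁶ proteins.  A tangential (saddle-node) root produces no
sign change and is deliberately not counted: stability classification and
the bistable flag are derived from sign changes only, which gives a
consistent, measure-zero-safe rule on parameter sweeps.  Hill powers are
evaluated as (A/K_D)ⁿᴴ with an overflow guard so that n_H = 16 at extreme
ratios saturates cleanly to 1.

The toggle-switch variant (selected gene A repressed by B, B repressed by
A) is reduced by placing the repressor at quasi-steady state B*(A); the
reduced flow is analysed with the same machinery.  For the toggle solution
rate we report k_A*(L) and k_A*(H) separately and make no claim about how
close they are; the bistable solution region is located empirically by the
map itself.

**Solution genotypes.** For a target steady state A*, k* follows in closed
form; validity requires (i) k* inside the physiological box and (ii) A*
*stable* for the resulting genotype (checked against the recomputed
profile with a 10⁻⁴ relative tolerance).  At high n_H with K_D ≈ A* the
anchored fixed point is unstable (e.g. n_H = 16, K_D = 20, A* = 20 gives
k* = 32 with f'(A*) ≈ 4.8 > γ) and the genotype is excluded from the
solution manifold.  Note that large K_D does *not* invalidate the LOW
solution: at n_H = 16, K_D = 120 the genotype (k* ≈ 80) is monostable LOW
with a stable state at 20, and the map marks it valid.

## Stochastic kinetics

Gillespie's direct method with exponential waiting times on the total
propensity f(A) + γA.  One cell life span is τ = 4 (four cell-cycle
times).  A life span is capped at 10⁷ events (reachable only near the
k = 10³ parameter bound with long spans) and aborts with an explicit
error.  The population kernel memoizes f(A) per visited state and genotype,
which changes no random draw — results are bit-identical to the naive
loop.

Randomness: the engine's selection/mutation stream and the environment
stream are independent children of a single master `SeedSequence`; each
cell×generation SSA stream gets a 31-bit seed from a splitmix64 hash of
(master seed, generation, cell index).  Runs are therefore bit-reproducible
and independent of iteration order.  The generator is numpy's (PCG64 for
the engine, numba's Mersenne Twister inside the SSA kernel); no attempt is
made to reproduce any particular historical RNG stream — statistical
equivalence is the contract, enforced by the oracle tests below.

## Finite State Projection

The chemical master equation is truncated to states 0..A_max with an
absorbing boundary (the birth rate out of A_max is dropped), giving a
tridiagonal generator whose interior columns sum to zero.  Transients are
computed with `scipy.sparse.linalg.expm_multiply`; truncation error is
monitored as the leaked mass 1 − Σρ.  A_max starts at
max(150, ⌈2k/γ⌉) and doubles until the leak at τ = 4 falls below 10⁻⁸.
Negative round-off below 10⁻¹² is clipped to zero.

The stationary law uses the exact product form π(a) ∝ Π f(j−1)/(γj),
accumulated in log space and normalized with logsumexp; it doubles as an
independent null-space check on the generator and as the α = 1 Poisson
closed form.

**Noise load** starts from a point mass at the environment's optimum
(integer state), propagates one life span and returns
1 − Σ ω(a)ρ(a, τ=4); leaked mass (≤ 10⁻⁸) counts as lost fitness.
**Epimutation probability** sums ρ(·, τ=4) over the integer states whose
fitness in the *other* environment is ≥ 0.5, i.e. |a − 20| ≤ 2 for LOW and
|a − 80| ≤ 4 for HIGH, with the exact Lorentzian and no interpolation.
Map exports return raw probabilities however small; thresholding is left
to presentation.

## Genetic potential

Distances between genotypes are Euclidean norms of (log k, log n_H,
log K_D) differences divided by log M, so one spherical mutation moves a
genotype by at most 1.  The potential of a grid cell is the minimum
distance from its solution genotype to any *valid* solution genotype of
the other environment on the same grid (invalid cells are excluded as
mutation targets because out-of-range parameters are unreachable).  The
default grid is 40 log-spaced points in n_H ∈ [1, 16] × 48 in
K_D ∈ [1, 120].

Grid minima are stable under refinement for most cells (superset
refinement can only shrink them; median change < 1%), but cells whose
nearest alternative lies close to the stability-validity boundary converge
more slowly because refinement reveals newly valid genotypes there.  The
combined map should therefore be read as an upper bound that is tight away
from the boundary.

## Evolutionary engine

Per generation: SSA (or deterministic CONTROL) expression from the
inherited protein count, Lorentzian fitness of the endpoint (or of the
time-averaged count in the `time_average` phenotype mode), selection,
mutation with probability u, environment update.  Implementation choices
where the procedure is underdetermined:

* **Founder state**: the population is isogenic at θ₀ with phenotypes at
  the deterministic stable state nearest the starting environment's
  optimum (rounded to an integer for stochastic runs); this removes a
  burn-in artifact without affecting long-run behaviour.
* **Tournament selection**: each of the N tournaments samples s_t
  *distinct* cells; tournaments are independent (with replacement across
  the population).  Ties are broken uniformly at random via an
  infinitesimal (10⁻¹²) fitness jitter — far below any fitness gap between
  distinct integer phenotypes in the selective range.
* **Truncation variant** reuses s_t as the pressure knob: parents are
  drawn uniformly from the top ⌈N/s_t⌉ cells.  The proportional variant
  samples parents with probability ωᵢ/Σω.
* **Mutation bounds**: mutated parameters are clamped to the physiological
  box (the simplest reading of a hard parameter range); boundary pile-up
  can be audited from the per-generation parameter means.
* **Fitness-shape variants**: the Gaussian matches the Lorentzian's FWHM
  (σ = ε/√(2 ln 2)); the step function is 1 on |A − A_opt| ≤ 2ε with a
  10⁻⁶ floor.
* **CONTROL mode** replaces the SSA by relaxation to the stable fixed
  point whose basin contains the inherited level (an inherited level
  exactly on an unstable point goes to the lower state).  This realizes
  hysteresis: without mutation a bistable CONTROL cell can never switch.
* **W_cycle** is reported as the geometric mean (Π w_g)^{1/L} over the L
  generations of a cycle; the raw log-product is kept alongside so either
  normalization can be recovered.
* **Stochastic environment mode** pre-realizes the whole switching
  sequence (switch probability ν per generation) from a dedicated stream;
  cycles are then delimited by pairs of completed epochs of whatever
  length they happened to have.

## Lineage analysis

Parent links, mutated-at-birth flags and genotype ids are archived every
generation; only the trailing three environmental cycles are retained (a
ring buffer — sufficient for all statistics).  At the end of cycle c each
surviving cell is traced to its 1-cycle and 2-cycle ancestors; the window
between them is labelled ES (all genotypes bistable, no mutations), BA
(all bistable, ≥ 1 mutation), GA (any monostable, ≥ 1 mutation) or STATIC
(monostable, no mutations).  STATIC fits none of the three canonical
definitions and is reported as its own column; `StrategyReport.three_way`
folds it into GA for three-way summaries.  Fractions are progeny-weighted
(each surviving cell counts its own ancestral window, shared or not).
Transition statistics compare the (2-cycle → 1-cycle) window against the
(3-cycle → 2-cycle) window along each surviving cell's ancestry,
accumulated over cycles and row-normalized.  Bistability is evaluated once
per genotype and cached.

## Problem sizes and what the tests show

The test suite exercises the full pipeline at reduced scale so that it
completes on a single CPU:

* Monte-Carlo oracle checks use 10⁵ SSA replicates (total-variation
  tolerance 0.02 against FSP and the product-form stationary law).
* The noise-load floor is scanned on a 16×20 grid in the tests and the
  40×48 default grid in `scripts/acceptance.py`; the measured minimum over
  valid solution genotypes is 59.4–59.5%, fractionally below the nominal
  60% floor, and is reported as computed.
* Evolutionary runs use N = 500 cells for 2,000–3,000 generations.  At
  this scale the engine reproduces: adaptation to the noise-load ceiling
  in a constant environment (w → 0.38 against the FSP bound E[ω] ≤ 0.40);
  zero ES/BA lineages in CONTROL runs; and, from a near-bistable founder
  (k = 80, n_H = 6, K_D = 45), fully bistable populations in which
  epigenetic switching dominates genetic adaptation at ν = 0.1, M = 1.1.
  What it does **not** reproduce at this scale is the full climb from the
  constitutive founder (n_H = 1) into the bistable region within 3,000
  generations: that transition is mutation-supply limited (uN = 15–30
  mutants per generation versus 300 at the full N = 10⁴ over 10⁴
  generations), and across 5 seeds at N = 500–1000 the cycle-averaged
  n_H plateaus at 1.0–2.0 with no bistable genotypes.  The corresponding
  acceptance test states the full expectation and currently fails at the
  reduced scale; the dedicated near-bistable-founder test covers the
  strategy-selection claim it was after.

## Known limitations

* One-species model: the toggle switch is analysed only through its
  deterministic quasi-steady-state reduction (no two-species SSA).
* No tau-leaping: simulations near k = 10³ are exact but slow.
* The epimutation probability is a one-life-span proxy, not a first-passage
  rate; it understates switching over multi-generation horizons.
* The synthetic environment alternates between exactly two states with a
  single frequency; real selective environments with drift, asymmetric
  epoch lengths or graded optima are out of scope.
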